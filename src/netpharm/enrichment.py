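"""Pathway over-representation analysis (ORA) on gene-set collections.

For a query of n genes drawn from a universe of N annotated genes, the
overlap k with a pathway of K genes is tested against the hypergeometric
null: p = P(X >= k) for X ~ Hypergeometric(N, K, n).  The EASE variant —
the conservative score used by the DAVID service — discounts one overlapping
gene, i.e. it is the plain upper tail evaluated at k - 1.

The default background is the collection's own annotated universe (every
gene appearing in any set), the convention of annotation-based ORA tools;
a user-supplied universe is accepted.  Benjamini-Hochberg adjusted p-values
are always reported alongside, but the default significance filter uses the
raw p-value, the customary practice in network-pharmacology screens.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ingest import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "hypergeom_tail", "ease_tail", "enrich",
           "filter_significant"]


@dataclass(frozen=True)
class EnrichmentResult:
    """One pathway's overlap statistics against the query gene set."""

    pathway_id: str
    description: str
    k: int          # |query ∩ pathway|
    n: int          # query size within the universe
    K: int          # pathway size within the universe
    N: int          # universe size
    p_value: float
    p_adjusted: float
    fold_enrichment: float


def _check_bounds(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"invalid hypergeometric bounds: k={k}, n={n}, K={K}, N={N} "
            f"(need 0 <= k <= min(n, K), n <= N, K <= N)"
        )


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    Computed through the survival function, which works in a numerically
    stable regime; exact (to floating precision) for small N.
    """
    _check_bounds(k, n, K, N)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ease_tail(k: int, n: int, K: int, N: int) -> float:
    """Conservative one-removed tail: the plain tail evaluated at k - 1.

    Always >= :func:`hypergeom_tail` at the same arguments.
    """
    _check_bounds(k, n, K, N)
    return hypergeom_tail(max(k - 1, 0), n, K, N)


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    method: Literal["hypergeometric", "ease"] = "hypergeometric",
) -> list[EnrichmentResult]:
    """Test every pathway with non-empty query overlap for over-representation.

    Query genes absent from the universe are dropped with a warning and do
    not count toward n.  Results are sorted by p-value, ties broken by
    pathway id; the BH adjustment is computed over all tested pathways
    (every pathway with k >= 1).
    """
    tail = {"hypergeometric": hypergeom_tail, "ease": ease_tail}[method]
    uni = frozenset(universe) if universe is not None else collection.universe
    query_set = set(query)
    dropped = query_set - uni
    query_set &= uni
    if not query_set:
        raise ValueError(
            "query is disjoint from the universe; dropped symbols: "
            + ", ".join(sorted(dropped))
        )
    if dropped:
        logger.warning("dropped %d query gene(s) absent from the universe: %s",
                       len(dropped), ", ".join(sorted(dropped)))
    n, N = len(query_set), len(uni)

    rows: list[tuple[str, str, int, int]] = []
    for pid in sorted(collection.sets):
        genes = collection.genes(pid) & uni
        k = len(query_set & genes)
        if k >= 1:
            rows.append((pid, collection.description(pid), k, len(genes)))
    if not rows:
        return []

    p_values = [tail(k, n, K, N) for _, _, k, K in rows]
    _, p_adj, _, _ = multipletests(p_values, method="fdr_bh")
    results = [
        EnrichmentResult(
            pathway_id=pid,
            description=desc,
            k=k, n=n, K=K, N=N,
            p_value=p,
            p_adjusted=float(min(max(pa, p), 1.0)),
            fold_enrichment=(k / n) / (K / N),
        )
        for (pid, desc, k, K), p, pa in zip(rows, p_values, p_adj)
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def filter_significant(
    results: list[EnrichmentResult],
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> list[EnrichmentResult]:
    """Keep pathways with p strictly below alpha (raw p by default)."""
    if not 0 < alpha <= 1 or math.isnan(alpha):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    key = (lambda r: r.p_adjusted) if use_adjusted else (lambda r: r.p_value)
    return [r for r in results if key(r) < alpha]
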