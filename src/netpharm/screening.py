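"""ADME bioactivity screening and the multi-herb compound/target universe.

Candidate molecules are kept when oral bioavailability (OB) and drug-likeness
(DL) both reach their thresholds — inclusively, so a compound sitting exactly
on OB = 30 %, DL = 0.18 is retained.  Screened per-herb lists are then pooled,
duplicates (the same molecule appearing in several herbs) are merged while
remembering every contributing herb, and the formula's target set is
intersected with the disease gene list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .ingest import CompoundRecord

logger = logging.getLogger(__name__)

__all__ = ["ScreenResult", "IntersectResult", "adme_filter", "dedup_union",
           "intersect_targets", "herb_summary"]

OB_MIN_DEFAULT = 30.0
DL_MIN_DEFAULT = 0.18


@dataclass
class ScreenResult:
    """Partition of an input compound list by the OB/DL filter."""

    retained: list[CompoundRecord]
    removed: list[CompoundRecord]
    thresholds: tuple[float, float]

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.removed)


@dataclass
class IntersectResult:
    """Drug-target / disease-target overlap; ``shared`` drives all later stages."""

    drug_targets: frozenset[str]
    disease_targets: frozenset[str]
    shared: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.shared = frozenset(self.drug_targets & self.disease_targets)
        if not self.shared:
            logger.warning(
                "drug and disease target sets are disjoint; downstream "
                "stages will produce empty outputs"
            )

    @property
    def is_empty(self) -> bool:
        return not self.shared


def adme_filter(
    records: list[CompoundRecord],
    ob_min: float = OB_MIN_DEFAULT,
    dl_min: float = DL_MIN_DEFAULT,
) -> ScreenResult:
    """Partition records into retained (ob >= ob_min and dl >= dl_min) and removed.

    Input order is preserved within each partition; comparisons are inclusive.
    """
    for threshold, label in ((ob_min, "ob_min"), (dl_min, "dl_min")):
        if not (threshold == threshold and abs(threshold) != float("inf")):
            raise ValueError(f"{label} must be finite, got {threshold}")
    if ob_min < 0:
        raise ValueError(f"ob_min must be >= 0, got {ob_min}")
    retained = [r for r in records if r.ob >= ob_min and r.dl >= dl_min]
    removed = [r for r in records if not (r.ob >= ob_min and r.dl >= dl_min)]
    return ScreenResult(retained=retained, removed=removed, thresholds=(ob_min, dl_min))


def dedup_union(
    per_herb_results: list[ScreenResult],
) -> tuple[set[str], dict[str, set[str]]]:
    """Pool retained compounds across herbs and merge duplicates.

    Returns the distinct compound-id universe and, for each compound, the set
    of herbs contributing it.  Deduplication keys on ``compound_id`` (registry
    identifier when present, case-folded name otherwise).
    """
    membership: dict[str, set[str]] = {}
    for result in per_herb_results:
        for record in result.retained:
            membership.setdefault(record.compound_id, set()).add(record.herb)
    return set(membership), membership


def intersect_targets(
    drug_targets: set[str], disease_targets: set[str]
) -> IntersectResult:
    """Intersect the formula's target genes with the disease gene list."""
    return IntersectResult(
        drug_targets=frozenset(drug_targets),
        disease_targets=frozenset(disease_targets),
    )


def herb_summary(
    per_herb_results: dict[str, ScreenResult],
    target_map: set[tuple[str, str]] | None = None,
) -> list[dict[str, object]]:
    """Per-herb tally of screened compounds (and targets, when mapping given).

    Mirrors the customary per-herb reporting of network-pharmacology studies;
    intended for logging and summary tables, not for computation.
    """
    rows = []
    for herb, result in sorted(per_herb_results.items()):
        row: dict[str, object] = {
            "herb": herb,
            "n_candidates": result.n_input,
            "n_active": len(result.retained),
        }
        if target_map is not None:
            ids = {r.compound_id for r in result.retained}
            row["n_targets"] = len({g for c, g in target_map if c in ids})
        rows.append(row)
    return rows
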