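"""End-to-end orchestration: screen -> intersect -> network -> enrich -> EMG."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

from .emg import EquivalentMolecularGroup, main_components, reverse_screen, select_pathways
from .enrichment import EnrichmentResult, enrich
from .ingest import CompoundRecord, GeneSetCollection
from .network import TriNetwork, build_network
from .screening import (
    DL_MIN_DEFAULT,
    OB_MIN_DEFAULT,
    IntersectResult,
    ScreenResult,
    adme_filter,
    dedup_union,
    intersect_targets,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    screen: dict[str, ScreenResult]
    compound_universe: set[str]
    herb_membership: dict[str, set[str]]
    intersect: IntersectResult
    network: TriNetwork
    enrichment: list[EnrichmentResult]
    selected_pathways: list[str]
    emg: EquivalentMolecularGroup
    main_components: list[tuple[str, int]]


def run_pipeline(
    records_by_herb: Mapping[str, list[CompoundRecord]],
    target_pairs: Iterable[tuple[str, str]],
    disease_genes: Iterable[str],
    collection: GeneSetCollection,
    ob_min: float = OB_MIN_DEFAULT,
    dl_min: float = DL_MIN_DEFAULT,
    pathways: Iterable[str] | None = None,
    alpha: float = 0.05,
    method: Literal["hypergeometric", "ease"] = "hypergeometric",
) -> PipelineResult:
    """Run the whole analysis on in-memory inputs.

    ``pathways`` selects the reverse-screen pathways explicitly; when None,
    all pathways significant at ``alpha`` (raw p) are used.
    """
    screen = {herb: adme_filter(records, ob_min, dl_min)
              for herb, records in records_by_herb.items()}
    universe, membership = dedup_union(list(screen.values()))
    pairs = {(c, g) for c, g in target_pairs if c in universe}
    drug_targets = {g for _, g in pairs}
    inter = intersect_targets(drug_targets, set(disease_genes))
    net = build_network(membership, pairs, shared_targets=inter.shared)
    results = enrich(inter.shared, collection, method=method) if inter.shared else []
    selected = list(pathways) if pathways is not None else select_pathways(results, alpha)
    emg = reverse_screen(selected, collection, inter.shared, membership, pairs)
    return PipelineResult(
        screen=screen,
        compound_universe=universe,
        herb_membership=membership,
        intersect=inter,
        network=net,
        enrichment=results,
        selected_pathways=selected,
        emg=emg,
        main_components=main_components(emg),
    )
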