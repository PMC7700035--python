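"""Equivalent-molecular-group (EMG) construction by pathway reverse-screening.

The EMG is the disease-relevant subset of a formula: starting from a chosen
set of action pathways, keep the shared (drug ∩ disease) targets annotated to
at least one of them, then the compounds still hitting a kept target, then
the herbs still contributing a kept compound.  The induced subnetwork's
"main components" are the compounds whose degree strictly exceeds the mean
degree over compound nodes.

Pathway selection is an explicit id list; ``select_pathways`` offers the
convenience mode "all pathways significant at alpha".  Both positive- and
negative-acting disease-relevant compounds belong to the EMG; the group is
their union, with no attempt to assign a pharmacological direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .enrichment import EnrichmentResult, filter_significant
from .ingest import GeneSetCollection
from .network import TriNetwork, build_network, degree_report

logger = logging.getLogger(__name__)

__all__ = ["EquivalentMolecularGroup", "reverse_screen", "main_components",
           "select_pathways"]


@dataclass
class EquivalentMolecularGroup:
    pathways: frozenset[str]
    targets: frozenset[str]
    compounds: frozenset[str]
    herbs: frozenset[str]
    subnetwork: TriNetwork

    @property
    def is_empty(self) -> bool:
        return not self.targets


def select_pathways(
    results: list[EnrichmentResult], alpha: float = 0.05, use_adjusted: bool = False
) -> list[str]:
    """All pathway ids significant at ``alpha`` (raw p by default)."""
    return [r.pathway_id for r in filter_significant(results, alpha, use_adjusted)]


def reverse_screen(
    selected_pathways: Iterable[str],
    collection: GeneSetCollection,
    shared_targets: Iterable[str],
    herb_membership: Mapping[str, Iterable[str]],
    target_pairs: Iterable[tuple[str, str]],
) -> EquivalentMolecularGroup:
    """Reverse-screen targets, compounds and herbs from the selected pathways.

    Kept targets are the shared targets annotated to >= 1 selected pathway;
    kept compounds have >= 1 edge to a kept target; kept herbs contain >= 1
    kept compound.  The subnetwork is rebuilt from the kept members only, so
    it is node- and edge-wise contained in the full network.  An empty result
    (no target survives) is flagged, not an error.
    """
    selected = set(selected_pathways)
    missing = selected - set(collection.sets)
    if missing:
        raise KeyError(f"selected pathways absent from the collection: {sorted(missing)}")
    pathway_genes: set[str] = set()
    for pid in selected:
        pathway_genes |= collection.genes(pid)

    targets = frozenset(shared_targets) & pathway_genes
    pairs = [(c, g) for c, g in target_pairs if g in targets]
    compounds = frozenset(c for c, _ in pairs)
    membership = {c: set(herb_membership[c]) for c in compounds}
    herbs = frozenset(h for hs in membership.values() for h in hs)
    if not targets:
        logger.warning("no shared target is annotated to the selected pathways; EMG is empty")
    subnetwork = build_network(membership, pairs, shared_targets=targets)
    return EquivalentMolecularGroup(
        pathways=frozenset(selected),
        targets=targets,
        compounds=compounds,
        herbs=herbs,
        subnetwork=subnetwork,
    )


def main_components(
    emg: EquivalentMolecularGroup, targets_only: bool = False
) -> list[tuple[str, int]]:
    """Compounds whose subnetwork degree strictly exceeds the compound mean.

    Ranked by degree descending, ties by compound id.  By default a
    compound's degree counts both its herb and its target edges, as read off
    the full tripartite diagram; ``targets_only`` restricts the count (and
    the mean) to compound-target edges.
    """
    if emg.is_empty:
        return []
    if not targets_only:
        report = degree_report(emg.subnetwork, subset="compound")
        return report.above_mean()
    g = emg.subnetwork
    degrees = {
        c: sum(1 for nb in g.graph.neighbors(c) if g.node_type(nb) == "target")
        for c in g.nodes_of("compound")
    }
    mean = sum(degrees.values()) / len(degrees)
    ranked = sorted(degrees.items(), key=lambda item: (-item[1], item[0]))
    return [(c, d) for c, d in ranked if d > mean]
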