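"""Analysis of externally produced docking-affinity matrices.

AutoDock-Vina-style affinities are binding free energies in kcal/mol: a
negative value means the ligand can bind the receptor spontaneously, and the
more negative the value, the stronger the predicted binding.  "Best" per
target therefore means the column minimum; ties report every attaining
compound.  Missing cells (partial docking runs) are excluded everywhere;
positive cells are kept as printed but flagged on ingest as unusual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ingest import AffinityMatrix

__all__ = ["DockingSummary", "summarize", "spontaneous_count"]


@dataclass
class DockingSummary:
    """Per-target minima, spontaneous (< 0) pairs, and full rankings."""

    best_per_target: dict[str, tuple[float, frozenset[str]]]
    spontaneous_pairs: frozenset[tuple[str, str]]
    ranking: dict[str, list[tuple[str, float]]]

    def best_value(self, target: str) -> float:
        return self.best_per_target[target][0]

    def best_compounds(self, target: str) -> frozenset[str]:
        return self.best_per_target[target][1]


def summarize(matrix: AffinityMatrix) -> DockingSummary:
    """Column minima, spontaneity calls, and ascending per-target rankings.

    Every target column must have at least one present cell.  Rankings sort
    present cells ascending (strongest binder first), ties by compound name.
    """
    best: dict[str, tuple[float, frozenset[str]]] = {}
    ranking: dict[str, list[tuple[str, float]]] = {}
    spontaneous: set[tuple[str, str]] = set()
    for j, target in enumerate(matrix.targets):
        column = matrix.values[:, j]
        present = [
            (matrix.compounds[i], float(column[i]))
            for i in range(len(matrix.compounds))
            if not np.isnan(column[i])
        ]
        if not present:
            raise ValueError(f"target {target!r} has no docked affinity values")
        minimum = min(v for _, v in present)
        best[target] = (minimum, frozenset(c for c, v in present if v == minimum))
        ranking[target] = sorted(present, key=lambda cv: (cv[1], cv[0]))
        spontaneous.update((c, target) for c, v in present if v < 0)
    return DockingSummary(
        best_per_target=best,
        spontaneous_pairs=frozenset(spontaneous),
        ranking=ranking,
    )


def spontaneous_count(matrix: AffinityMatrix) -> int:
    """Number of present cells with affinity strictly below zero."""
    values = matrix.values
    return int(np.sum(values[~np.isnan(values)] < 0))
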