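"""Bundled reference data.

The package ships one small reference table: AutoDock Vina docking
affinities (kcal/mol) of 16 main components of the heart-failure formula
Fuxin mixture (FXHJ) against five heart-failure-related protein targets —
VEGFA (1VPF), TNF (2AZ5), PIK3CG (2CHZ), PTGS2 (5KIR) and MAPK1 (5NHV).
The table is stored as printed (Unicode minus signs and all), so loading it
also exercises the numeric normalization path.
"""

from __future__ import annotations

from importlib import resources

from .ingest import AffinityMatrix, read_affinity_table

__all__ = ["fxhj_docking_affinity"]


def fxhj_docking_affinity() -> AffinityMatrix:
    """The 16-compound x 5-target FXHJ docking-affinity reference table."""
    path = resources.files("netpharm").joinpath("data/fxhj_docking_affinity.csv")
    with resources.as_file(path) as p:
        return read_affinity_table(p)
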