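"""Seeded synthetic benchmark generator with planted ground truth.

The generator emulates the inputs a multi-herb network-pharmacology study
collects from public databases, without any download:

* per-herb candidate-compound tables whose OB/DL values straddle the
  screening thresholds (uniform marginals, so the expected pass fraction has
  a closed form);
* a compound-target bipartite map with a planted disease-relevant module — a
  chosen set of "active" compounds wired to a chosen set of disease targets
  — on top of sparse background edges that never touch the disease list;
* a disease gene list holding every planted target plus untargeted decoys
  (real disease lists are far larger than any one formula's target set);
* a GMT collection with one planted pathway covering the planted targets and
  noise pathways drawn from the annotation universe, so their query overlap
  follows the hypergeometric null.

One herb (the last, ``ZX`` in the default six-herb formula) receives no
active compounds, emulating a herb whose mechanism — e.g. a diuretic acting
outside the screened pathways — drops out of the equivalent molecular group.

All randomness flows from a single ``numpy`` generator seeded in the config;
one seed, one dataset.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .ingest import (
    AffinityMatrix,
    CompoundRecord,
    GeneSetCollection,
    write_affinity_table,
    write_gene_list,
    write_gmt,
    write_target_map,
)

__all__ = ["SynthConfig", "GroundTruth", "SyntheticDataset",
           "generate_dataset", "generate", "DEFAULT_HERB_CODES"]

DEFAULT_HERB_CODES = ("FZ", "DG", "HB", "TLZ", "YYH", "ZX")


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults give a six-herb formula-sized problem."""

    seed: int = 0
    n_herbs: int = 6
    compounds_per_herb: int = 20
    ob_range: tuple[float, float] = (10.0, 60.0)   # percent
    dl_range: tuple[float, float] = (0.0, 0.5)
    ob_min: float = 30.0
    dl_min: float = 0.18
    n_targets_total: int = 200
    n_disease_genes: int = 120
    n_active_compounds: int = 12
    n_disease_targets: int = 15
    planted_edge_density: float = 0.5
    n_pathways: int = 20
    planted_pathway_coverage: float = 1.0
    planted_pathway_filler: int = 10
    background_edge_rate: float = 0.02
    noise_pathway_size: tuple[int, int] = (10, 30)
    noise_overlap_planted: bool = True
    duplicate_active: bool = True
    with_affinity: bool = True

    def __post_init__(self) -> None:
        for name in ("n_herbs", "compounds_per_herb", "n_targets_total",
                     "n_disease_genes", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_active_compounds", "n_disease_targets",
                     "planted_pathway_filler"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("planted_edge_density", "planted_pathway_coverage",
                     "background_edge_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_disease_targets > self.n_targets_total:
            raise ValueError("n_disease_targets cannot exceed n_targets_total")
        if self.n_disease_targets > self.n_disease_genes:
            raise ValueError("n_disease_targets cannot exceed n_disease_genes")
        if self.n_active_compounds > (self.n_herbs - 1) * self.compounds_per_herb:
            raise ValueError("too many active compounds for n_herbs - 1 herbs")
        if self.n_active_compounds and self.n_herbs < 2:
            raise ValueError("planting actives needs >= 2 herbs (one stays inactive)")

    @property
    def herb_codes(self) -> tuple[str, ...]:
        codes = list(DEFAULT_HERB_CODES[: self.n_herbs])
        codes += [f"H{i:02d}" for i in range(len(codes) + 1, self.n_herbs + 1)]
        return tuple(codes)

    def pass_probability(self) -> float:
        """Closed-form P(a background compound passes the OB/DL filter)."""
        ob_lo, ob_hi = self.ob_range
        dl_lo, dl_hi = self.dl_range
        p_ob = min(max((ob_hi - self.ob_min) / (ob_hi - ob_lo), 0.0), 1.0)
        p_dl = min(max((dl_hi - self.dl_min) / (dl_hi - dl_lo), 0.0), 1.0)
        return p_ob * p_dl


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure the pipeline is expected to recover."""

    active_compounds: frozenset[str]
    disease_targets: frozenset[str]
    planted_pathway_id: str
    expected_emg_herbs: frozenset[str]
    expected_emg_compounds: frozenset[str]
    expected_emg_targets: frozenset[str]
    inactive_herb: str
    affinity_best: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            key: sorted(value) if isinstance(value, frozenset) else value
            for key, value in asdict(self).items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SyntheticDataset:
    """In-memory synthetic study: every pipeline input plus the ground truth."""

    config: SynthConfig
    records_by_herb: dict[str, list[CompoundRecord]]
    target_pairs: set[tuple[str, str]]
    disease_genes: set[str]
    collection: GeneSetCollection
    truth: GroundTruth
    affinity: AffinityMatrix | None = None


def _sample_compound(rng: np.random.Generator, cid: str, herb: str,
                     cfg: SynthConfig, force_pass: bool) -> CompoundRecord:
    ob_lo, ob_hi = cfg.ob_range
    dl_lo, dl_hi = cfg.dl_range
    if force_pass:
        ob = rng.uniform(max(cfg.ob_min, ob_lo), ob_hi)
        dl = rng.uniform(max(cfg.dl_min, dl_lo), dl_hi)
    else:
        ob = rng.uniform(ob_lo, ob_hi)
        dl = rng.uniform(dl_lo, dl_hi)
    return CompoundRecord(compound_id=cid, name=f"cpd-{cid[3:]}", herb=herb,
                          ob=float(ob), dl=float(dl))


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Generate the full synthetic study in memory.

    Deterministic: identical config (including seed) gives identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    herbs = cfg.herb_codes

    # --- gene namespaces -------------------------------------------------
    planted_targets = [f"GD{i:04d}" for i in range(1, cfg.n_disease_targets + 1)]
    n_bg = cfg.n_targets_total - cfg.n_disease_targets
    background_targets = [f"GB{i:04d}" for i in range(1, n_bg + 1)]
    n_decoys = cfg.n_disease_genes - cfg.n_disease_targets
    decoy_genes = [f"GX{i:04d}" for i in range(1, n_decoys + 1)]

    # --- compounds: globally numbered, actives only in the first n-1 herbs
    n_total = cfg.n_herbs * cfg.compounds_per_herb
    ids = [f"MOL{i:04d}" for i in range(1, n_total + 1)]
    id_to_herb = {
        cid: herbs[i // cfg.compounds_per_herb] for i, cid in enumerate(ids)
    }
    eligible = [cid for cid in ids if id_to_herb[cid] != herbs[-1]]
    active = sorted(
        str(c) for c in rng.choice(eligible, size=cfg.n_active_compounds, replace=False)
    )
    active_set = set(active)

    records_by_herb: dict[str, list[CompoundRecord]] = {h: [] for h in herbs}
    record_of: dict[str, CompoundRecord] = {}
    for cid in ids:
        rec = _sample_compound(rng, cid, id_to_herb[cid], cfg,
                               force_pass=cid in active_set)
        records_by_herb[id_to_herb[cid]].append(rec)
        record_of[cid] = rec

    # one active compound may also occur in a second herb (shared molecules
    # across herbs are common; exercises the dedup-union step)
    if cfg.duplicate_active and active and cfg.n_herbs >= 3:
        cid = active[0]
        home = id_to_herb[cid]
        other = next(h for h in herbs[:-1] if h != home)
        rec = record_of[cid]
        records_by_herb[other].append(
            CompoundRecord(compound_id=cid, name=rec.name, herb=other,
                           ob=rec.ob, dl=rec.dl)
        )

    # --- planted module edges -------------------------------------------
    pairs: set[tuple[str, str]] = set()
    if active and planted_targets:
        hits = rng.random((len(active), len(planted_targets))) < cfg.planted_edge_density
        for i, cid in enumerate(active):
            for j, gene in enumerate(planted_targets):
                if hits[i, j]:
                    pairs.add((cid, gene))
        # guarantee coverage in both directions so the planted module is
        # exactly recoverable
        for j, gene in enumerate(planted_targets):
            if not hits[:, j].any():
                pairs.add((str(rng.choice(active)), gene))
        for i, cid in enumerate(active):
            if not any((cid, g) in pairs for g in planted_targets):
                pairs.add((cid, str(rng.choice(planted_targets))))

    # background edges never touch the disease list, so they cannot leak
    # into the drug-disease intersection
    if background_targets and cfg.background_edge_rate > 0:
        bg_hits = rng.random((n_total, n_bg)) < cfg.background_edge_rate
        for i, cid in enumerate(ids):
            for j, gene in enumerate(background_targets):
                if bg_hits[i, j]:
                    pairs.add((cid, gene))

    disease_genes = set(planted_targets) | set(decoy_genes)

    # --- pathways --------------------------------------------------------
    n_covered = int(round(cfg.planted_pathway_coverage * len(planted_targets)))
    covered = sorted(
        str(g) for g in rng.choice(planted_targets, size=n_covered, replace=False)
    ) if planted_targets else []
    filler_pool = background_targets
    n_filler = min(cfg.planted_pathway_filler, len(filler_pool))
    filler = [str(g) for g in rng.choice(filler_pool, size=n_filler, replace=False)]

    planted_idx = int(rng.integers(1, cfg.n_pathways + 1))
    planted_pathway_id = f"PWY{planted_idx:04d}"
    noise_pool = (
        planted_targets + background_targets
        if cfg.noise_overlap_planted
        else list(background_targets)
    )
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    lo, hi = cfg.noise_pathway_size
    for i in range(1, cfg.n_pathways + 1):
        pid = f"PWY{i:04d}"
        if pid == planted_pathway_id:
            sets[pid] = ("planted disease pathway", frozenset(covered) | frozenset(filler))
        else:
            size = int(rng.integers(lo, hi + 1))
            size = min(size, len(noise_pool))
            members = rng.choice(noise_pool, size=size, replace=False)
            sets[pid] = (f"noise pathway {i}", frozenset(str(g) for g in members))
    collection = GeneSetCollection(sets=sets)

    # --- expected EMG under the default thresholds ----------------------
    emg_targets = frozenset(covered)
    emg_compounds = frozenset(
        cid for cid in active if any((cid, g) in pairs for g in emg_targets)
    )
    emg_herbs_set = {id_to_herb[cid] for cid in emg_compounds}
    if cfg.duplicate_active and active and cfg.n_herbs >= 3 and active[0] in emg_compounds:
        home = id_to_herb[active[0]]
        emg_herbs_set.add(next(h for h in herbs[:-1] if h != home))

    # --- optional docking table -----------------------------------------
    affinity = None
    affinity_best: dict[str, str] = {}
    if cfg.with_affinity and active and planted_targets:
        dock_targets = covered[: min(5, len(covered))] or planted_targets[:5]
        names = [record_of[cid].name for cid in active]
        values = np.round(rng.uniform(-8.5, -5.0, size=(len(names), len(dock_targets))), 1)
        for j, tgt in enumerate(dock_targets):
            i = int(rng.integers(len(names)))
            values[i, j] = round(float(rng.uniform(-11.0, -9.0)), 1)
            affinity_best[tgt] = names[i]
        affinity = AffinityMatrix(compounds=names, targets=list(dock_targets),
                                  values=values)

    truth = GroundTruth(
        active_compounds=frozenset(active),
        disease_targets=frozenset(planted_targets),
        planted_pathway_id=planted_pathway_id,
        expected_emg_herbs=frozenset(emg_herbs_set),
        expected_emg_compounds=emg_compounds,
        expected_emg_targets=emg_targets,
        inactive_herb=herbs[-1],
        affinity_best=affinity_best,
    )
    return SyntheticDataset(
        config=cfg,
        records_by_herb=records_by_herb,
        target_pairs=pairs,
        disease_genes=disease_genes,
        collection=collection,
        truth=truth,
        affinity=affinity,
    )


def generate(config: SynthConfig, outdir: str | Path) -> GroundTruth:
    """Generate the synthetic study and write every input file to ``outdir``.

    Emits ``<herb>.csv`` per herb (MOL_ID, Molecule, OB, DL columns),
    ``compound_targets.tsv``, ``disease_genes.txt``, ``pathways.gmt``,
    optionally ``affinity.csv``, and ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not outdir.is_dir():
        raise NotADirectoryError(outdir)
    data = generate_dataset(config)

    for herb, records in data.records_by_herb.items():
        with open(outdir / f"{herb}.csv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("MOL_ID,Molecule,OB,DL\n")
            for rec in records:
                # repr() keeps the exact float, so files and the in-memory
                # dataset screen identically at the thresholds
                fh.write(f"{rec.compound_id},{rec.name},{rec.ob!r},{rec.dl!r}\n")
    write_target_map(data.target_pairs, outdir / "compound_targets.tsv")
    write_gene_list(data.disease_genes, outdir / "disease_genes.txt")
    write_gmt(data.collection, outdir / "pathways.gmt")
    if data.affinity is not None:
        write_affinity_table(data.affinity, outdir / "affinity.csv")
    (outdir / "ground_truth.json").write_text(data.truth.to_json() + "\n",
                                              encoding="utf-8")
    return data.truth


def expected_pass_count(config: SynthConfig) -> tuple[float, float]:
    """Expected number of rows passing the OB/DL filter and its std dev.

    Active rows (including a duplicated active row, when configured) pass by
    construction; background rows pass independently with the closed-form
    uniform probability.
    """
    n_forced = config.n_active_compounds
    if config.duplicate_active and config.n_active_compounds and config.n_herbs >= 3:
        n_forced += 1
    n_rows = config.n_herbs * config.compounds_per_herb
    if config.duplicate_active and config.n_active_compounds and config.n_herbs >= 3:
        n_rows += 1
    n_background = n_rows - n_forced
    p = config.pass_probability()
    mean = n_forced + n_background * p
    sd = math.sqrt(n_background * p * (1.0 - p))
    return mean, sd
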