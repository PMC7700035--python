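"""Reading, validation and normalization of all tabular inputs and outputs.

Every external table enters the pipeline through this module.  Normalization
applied at the boundary:

* Unicode minus (U+2212) and full-width digits/punctuation become ASCII.
* Non-breaking spaces become ordinary spaces; fields are stripped.
* Gene symbols are uppercased (database exports mix cases).

All writers emit UTF-8 with LF line endings and ASCII minus signs, so every
writer/reader pair is an identity on normalized data.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "GeneSetCollection",
    "AffinityMatrix",
    "normalize_numeric_text",
    "parse_number",
    "normalize_symbol",
    "read_compound_table",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_target_map",
    "write_target_map",
    "read_affinity_table",
    "write_affinity_table",
    "load_alias_config",
    "DEFAULT_ALIASES",
]

GENE_SYMBOL_RE = re.compile(r"^[A-Z0-9][A-Z0-9-]*$")

# Translation of typographic/full-width characters to their ASCII forms.
_ASCII_TABLE = {0x2212: ord("-"), 0x00A0: ord(" "), 0xFF0D: ord("-"),
                0xFF0E: ord("."), 0xFF0C: ord(",")}
_ASCII_TABLE.update({0xFF10 + i: ord("0") + i for i in range(10)})


def normalize_numeric_text(text: str) -> str:
    """Map Unicode minus, NBSP and full-width digits to ASCII and strip.

    Idempotent: applying it to already-ASCII text is the identity.
    """
    return str(text).translate(_ASCII_TABLE).strip()


def parse_number(text: object) -> float | None:
    """Parse a numeric cell after normalization; ``None`` if unparseable."""
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return None
    if isinstance(text, (int, float)):
        return float(text)
    cleaned = normalize_numeric_text(text)
    if not cleaned:
        return None
    try:
        return float(cleaned)
    except ValueError:
        return None


def normalize_symbol(symbol: str) -> str:
    """Uppercase, strip, and ASCII-fold a gene symbol."""
    return normalize_numeric_text(symbol).upper()


@dataclass(frozen=True, order=True)
class CompoundRecord:
    """One candidate molecule of one herb.

    ``ob`` is oral bioavailability in percent; ``dl`` is the unitless
    drug-likeness index in [0, 1].  ``compound_id`` is an external registry
    identifier when the source table provides one, otherwise the case-folded
    compound name.
    """

    compound_id: str
    name: str
    herb: str
    ob: float
    dl: float

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if not self.herb:
            raise ValueError("herb must be non-empty")
        if self.ob < 0:
            raise ValueError(f"ob must be >= 0, got {self.ob}")
        if not 0.0 <= self.dl <= 1.0:
            raise ValueError(f"dl must be in [0, 1], got {self.dl}")


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) plus the implied annotation universe."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for pid, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {pid!r} is empty")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id][1]

    def description(self, pathway_id: str) -> str:
        return self.sets[pathway_id][0]


@dataclass
class AffinityMatrix:
    """Compound x target docking binding energies in kcal/mol.

    ``values[i, j]`` is the affinity of compound i against target j; missing
    cells are NaN.  PDB codes embedded in target labels, e.g. ``VEGFA (1VPF)``,
    are split off into ``pdb_codes`` and take no part in any computation.
    """

    compounds: list[str]
    targets: list[str]
    values: np.ndarray
    pdb_codes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compounds), len(self.targets)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.compounds)} compounds x {len(self.targets)} targets"
            )
        present = self.values[~np.isnan(self.values)]
        if not np.all(np.isfinite(present)):
            raise ValueError("affinity values must be finite or missing")
        n_pos = int((present > 0).sum())
        if n_pos:
            logger.warning(
                "affinity matrix contains %d positive value(s); positive "
                "binding energies are unusual for docked poses", n_pos,
            )

    def value(self, compound: str, target: str) -> float:
        return float(
            self.values[self.compounds.index(compound), self.targets.index(target)]
        )


# ---------------------------------------------------------------------------
# compound tables

DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "name": ("name", "molecule", "compound", "molecule name", "molecule_name"),
    "ob": ("ob", "ob(%)", "ob%", "oral bioavailability", "oral bioavailability(%)"),
    "dl": ("dl", "drug-likeness", "drug_likeness", "drug likeness"),
    "compound_id": ("compound_id", "mol_id", "molecule_id", "cid", "pubchem_cid", "id"),
}


def load_alias_config(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Load a YAML column-alias config {field: [alias, ...]} merged over defaults."""
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    merged = {k: tuple(v) for k, v in DEFAULT_ALIASES.items()}
    for key, aliases in user.items():
        if key not in merged:
            raise ValueError(f"unknown alias field {key!r}")
        merged[key] = tuple(str(a) for a in aliases)
    return merged


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _resolve_column(columns: Sequence[str], aliases: Iterable[str]) -> str | None:
    lookup = {str(c).strip().lower(): c for c in columns}
    for alias in aliases:
        if alias.lower() in lookup:
            return lookup[alias.lower()]
    return None


def read_compound_table(
    path: str | Path,
    herb: str,
    aliases: Mapping[str, tuple[str, ...]] | None = None,
) -> list[CompoundRecord]:
    """Read one herb's candidate-compound table (name, OB, DL columns).

    Column headers are matched case-insensitively against configurable
    aliases.  Rows whose OB or DL cannot be parsed as numbers are dropped;
    the skip tally is reported through the module logger.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if frame.empty:
        raise ValueError(f"{path}: compound table has no data rows")
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update({k: tuple(v) for k, v in aliases.items()})

    resolved: dict[str, str] = {}
    for field_name in ("name", "ob", "dl"):
        col = _resolve_column(frame.columns, alias_map[field_name])
        if col is None:
            raise ValueError(
                f"{path}: missing required column {field_name!r} "
                f"(accepted aliases: {', '.join(alias_map[field_name])})"
            )
        resolved[field_name] = col
    id_col = _resolve_column(frame.columns, alias_map["compound_id"])

    records: list[CompoundRecord] = []
    n_skipped = 0
    for _, row in frame.iterrows():
        name = normalize_numeric_text(row[resolved["name"]])
        ob = parse_number(row[resolved["ob"]])
        dl = parse_number(row[resolved["dl"]])
        if not name or ob is None or dl is None:
            n_skipped += 1
            continue
        cid = normalize_numeric_text(row[id_col]) if id_col else ""
        records.append(
            CompoundRecord(
                compound_id=cid or name.casefold(),
                name=name,
                herb=herb,
                ob=ob,
                dl=dl,
            )
        )
    if n_skipped:
        logger.warning("%s: skipped %d row(s) with unparseable fields", path, n_skipped)
    return records


# ---------------------------------------------------------------------------
# gene lists

def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line (or single-column) gene list.

    Symbols are uppercased and deduplicated; blank lines are dropped.  An
    empty result is an error: a disease list of zero genes is meaningless.
    """
    path = Path(path)
    symbols: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sym = normalize_symbol(line.split("\t")[0].split(",")[0])
            if sym and sym.lower() not in ("gene", "symbol", "gene_symbol"):
                symbols.add(sym)
    if not symbols:
        raise ValueError(f"{path}: gene list is empty")
    return symbols


def write_gene_list(symbols: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for sym in sorted({normalize_symbol(s) for s in symbols}):
            fh.write(sym + "\n")


# ---------------------------------------------------------------------------
# compound -> target maps

def read_target_map(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column (compound_id, gene_symbol) mapping table.

    Gene symbols are normalized as in :func:`read_gene_list`; duplicate pairs
    collapse.  Symbols failing the gene-symbol pattern are a hard error.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: target map needs compound and gene columns")
    pairs: set[tuple[str, str]] = set()
    for _, row in frame.iterrows():
        compound = normalize_numeric_text(row.iloc[0])
        gene = normalize_symbol(row.iloc[1])
        if not compound and not gene:
            continue
        if not GENE_SYMBOL_RE.match(gene):
            raise ValueError(f"{path}: invalid gene symbol {gene!r} for compound {compound!r}")
        pairs.add((compound, gene))
    if not pairs:
        raise ValueError(f"{path}: target map is empty")
    return pairs


def write_target_map(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"compound_id{sep}gene_symbol\n")
        for compound, gene in sorted(pairs):
            fh.write(f"{compound}{sep}{normalize_symbol(gene)}\n")


# ---------------------------------------------------------------------------
# GMT gene-set collections

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-delimited GMT file (set id, description, member genes...)."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pid = fields[0].strip()
            genes = frozenset(
                normalize_symbol(g) for g in fields[2:] if g.strip()
            )
            if pid in sets:
                logger.warning("%s:%d: duplicate pathway id %r, keeping the later one",
                               path, lineno, pid)
            sets[pid] = (fields[1].strip(), genes)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for pid in sorted(collection.sets):
            desc, genes = collection.sets[pid]
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# affinity matrices

_PDB_RE = re.compile(r"^(?P<label>.*?)\s*\((?P<pdb>[0-9][A-Za-z0-9]{3})\)\s*$")


def _split_target_label(label: str) -> tuple[str, str | None]:
    label = normalize_numeric_text(label)
    m = _PDB_RE.match(label)
    if m:
        return m.group("label"), m.group("pdb")
    return label, None


def read_affinity_table(path: str | Path) -> AffinityMatrix:
    """Read a compound x target affinity table (kcal/mol).

    First column holds compound names; remaining headers are target labels,
    optionally suffixed with a PDB code in parentheses.  Blank cells become
    missing values; any other non-numeric cell is a hard error.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: affinity table needs a compound column plus >= 1 target")
    compounds = [normalize_numeric_text(v) for v in frame.iloc[:, 0]]
    targets: list[str] = []
    pdb_codes: dict[str, str] = {}
    for raw in frame.columns[1:]:
        label, pdb = _split_target_label(str(raw))
        targets.append(label)
        if pdb:
            pdb_codes[label] = pdb
    values = np.full((len(compounds), len(targets)), np.nan)
    for i in range(len(compounds)):
        for j, col in enumerate(frame.columns[1:]):
            cell = normalize_numeric_text(frame.iloc[i][col])
            if not cell:
                continue
            parsed = parse_number(cell)
            if parsed is None:
                raise ValueError(
                    f"{path}: non-numeric affinity cell {cell!r} at "
                    f"(compound {compounds[i]!r}, target {targets[j]!r})"
                )
            values[i, j] = parsed
    return AffinityMatrix(compounds=compounds, targets=targets,
                          values=values, pdb_codes=pdb_codes)


def write_affinity_table(matrix: AffinityMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        header = ["Compound"]
        for t in matrix.targets:
            header.append(f"{t} ({matrix.pdb_codes[t]})" if t in matrix.pdb_codes else t)
        writer.writerow(header)
        for i, compound in enumerate(matrix.compounds):
            row: list[str] = [compound]
            for j in range(len(matrix.targets)):
                v = matrix.values[i, j]
                row.append("" if np.isnan(v) else f"{v:g}")
            writer.writerow(row)
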