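# Methods

## The analysis model

The pipeline formalizes the standard network-pharmacology workflow for a
multi-herb formula as a sequence of set and graph operations.

**ADME screening.** Each candidate molecule carries two database-provided
pharmacokinetic proxies: oral bioavailability OB (percent) and drug-likeness
DL (unitless, in [0, 1]). A compound is bioactive when OB ≥ 30 % **and**
DL ≥ 0.18; both comparisons are inclusive, so boundary compounds are kept.
The thresholds are parameters (`ob_min`, `dl_min`) with those defaults.
Screened per-herb lists are pooled; duplicates are merged on `compound_id`
(an external registry identifier when the table provides one, else the
case-folded name), keeping the set of contributing herbs per molecule.

**Target intersection.** The formula's drug-target set (genes mapped from
any retained compound) is intersected with the disease gene list. The shared
set drives everything downstream; an empty intersection is flagged, not an
error, and yields empty downstream outputs.

**Tripartite network.** Nodes are typed herb / compound / target; edges are
restricted to herb–compound (relation `contains`) and compound–target
(relation `targets`), undirected, with no self-loops or parallel edges.
When built against the shared target set, compounds whose every target was
filtered out are dropped, along with herbs left empty — network figures in
this field show no orphan nodes. The handshake lemma and the bipartition
constraint are enforced invariants.

**Degree rule.** "Main components" are compounds whose degree strictly
exceeds the arithmetic mean degree — computed over **compound nodes only**,
since the rule compares compounds with each other; the subset is a parameter
(`subset=` in `degree_report`), so an all-nodes reading is one flag away.
Strict inequality means a degree-regular compound set has no main
components. Ranking is degree descending, ties broken by identifier, so
output is deterministic. A compound's degree counts both its herb and its
target edges (degrees as read off the full tripartite diagram);
`targets_only=True` restricts the count and the mean to target edges.

**Over-representation.** For a query of n genes inside a universe of N
annotated genes, a pathway with K genes and overlap k is scored
p = P(X ≥ k), X ~ Hypergeometric(N, K, n), evaluated through the survival
function (numerically stable; exact to floating precision at small N — the
test suite checks agreement with exhaustive subset enumeration to 1e-12 for
all N ≤ 12). The EASE variant used by the DAVID service is the same tail at
k − 1, hence always ≥ the plain tail; it is available as `method="ease"`.
The default universe is the collection's own annotated background (every
gene in any set); an explicit universe can be supplied. Query genes outside
the universe are dropped with a warning and do not count toward n; a fully
disjoint query is a hard error. Only pathways with k ≥ 1 are tested;
Benjamini–Hochberg adjustment is computed across all tested pathways and
always reported, but the default significance filter is the **raw** p < 0.05
(strict), the convention of this analysis style; adjusted-p filtering is one
flag away. Fold enrichment is (k/n)/(K/N).

**Equivalent molecular group (EMG).** Given a pathway selection (an explicit
id list, or the convenience mode "all significant at alpha"), the reverse
screen keeps: targets = shared targets annotated to ≥ 1 selected pathway;
compounds = those with ≥ 1 edge to a kept target; herbs = those contributing
≥ 1 kept compound. The subnetwork is rebuilt from the kept members, so it is
node- and edge-wise contained in the full network, subnetwork degrees never
exceed full-network degrees, the construction is monotone in the pathway
selection, and re-running it on its own output is the identity (all
property-tested). Disease-relevant compounds of positive and negative
pharmacological direction are pooled — the EMG is their union; assigning a
direction is out of scope, as no formula for it exists.

**Docking reports.** Affinities are AutoDock-Vina-style binding free
energies in kcal/mol. "Best" per target is the column minimum (most
negative); all tied minimizers are reported, because real tables contain
genuine ties (the bundled reference table has one at VEGFA = −7.8).
Affinity < 0 (strict) marks a spontaneously binding pair. Missing cells are
legal (partial docking runs) and excluded from minima, rankings and
spontaneity counts; a fully missing column is an error. Positive affinities
are ingested as recorded — a sign correction would be an editorial decision,
not a computation — but flagged as unusual in a warning. PDB codes embedded
in target labels (`VEGFA (1VPF)`) are split into an annotation field and
ignored in computation.

## Input normalization

Published and exported tables mix Unicode minus (U+2212), full-width digits
and NBSP into numeric cells; gene lists mix cases. All readers fold these to
ASCII and uppercase gene symbols at the boundary; normalization is
idempotent, and all writers emit UTF-8/LF/ASCII-minus so every writer/reader
pair is an identity on normalized data. Compound-table columns are resolved
case-insensitively through configurable aliases (defaults:
name|molecule|compound, ob|ob(%)|oral bioavailability(%), dl|drug-likeness|
drug_likeness, plus optional id columns), since TCMSP-style exports vary.
Rows with unparseable OB/DL are dropped and tallied through the module
logger; missing columns and empty files are hard errors.

## The synthetic study

`SynthConfig` defaults define the study conditions used throughout the test
suite and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| `n_herbs` / `compounds_per_herb` | 6 / 20 | formula-sized problem (six herbs, 120 candidates) |
| `ob_range` / `dl_range` | U(10, 60) % / U(0, 0.5) | uniform marginals straddling the 30 / 0.18 thresholds, giving the closed-form pass probability 0.6 × 0.64 = 0.384 |
| `n_targets_total` | 200 | target-gene universe |
| `n_active_compounds` / `n_disease_targets` | 12 / 15 | planted disease module |
| `planted_edge_density` | 0.5 | Bernoulli rate of active-compound × planted-target edges, patched so every active compound and every planted target keeps ≥ 1 module edge |
| `n_disease_genes` | 120 | planted targets + untargeted decoys |
| `n_pathways` | 20 | one planted pathway (all planted targets + 10 filler genes) + 19 noise sets of size U{10..30} drawn from the annotation universe |
| `background_edge_rate` | 0.02 | per-pair rate of compound edges to non-disease targets |

Choices worth noting:

* Active compounds are sampled from the first n − 1 herbs only and their
  OB/DL are drawn from the passing region of the same uniforms, so the
  planted module always survives screening. The last herb (ZX in the default
  six-herb formula) gets no actives, emulating a herb whose mechanism falls
  outside the screened pathways and must drop out of the EMG.
* Disease-list decoys are never targeted by any compound and background
  edges never touch the disease list, so the drug–disease intersection
  equals the planted target set exactly and planted-module recovery has an
  unambiguous ground truth.
* Noise pathways are drawn from the full universe including planted targets
  (`noise_overlap_planted=True`), so their query overlap follows the
  hypergeometric null; the disjoint mode exists for exact-recovery tests
  that select *all* significant pathways.
* One active compound is listed in a second herb
  (`duplicate_active=True`), exercising the dedup-union step.
* All draws flow from one `numpy.random.default_rng(seed)`; one seed, one
  dataset, byte-identical files. Generated OB/DL are written with `repr()`
  so files and the in-memory dataset screen identically at the thresholds.

What the generator does **not** emulate: real chemistry (no structures or
masses), correlated OB/DL marginals, annotation idiosyncrasies of real
pathway databases, or the hub-dominated degree distributions of real TCMSP
maps. Passing tests therefore demonstrate correctness of the pipeline's
logic under controlled conditions, not database-level reproduction: the
published snapshot counts of this analysis style (e.g. 64 compounds, 144
intersection targets, 104 significant pathways, 39/47/17 EMG sizes) depend
on 2020-era database versions and are deliberately not reproduction targets;
the structural recoveries replace them.

## Problem sizes

The acceptance script measures: the bundled 16 × 5 docking table (exact
column minima and the 79/80 spontaneity count); the hypergeometric tail
against exhaustive enumeration over all 3,184 (k, n, K, N) tuples with
N ≤ 12; planted-pathway recovery over 200 seeded replicates at the default
effect size; and EMG target-set F1 plus inactive-herb exclusion over 20
seeded full-pipeline runs. These sizes keep the whole script at a few
seconds while giving tight binomial resolution (a ≥ 95 % recovery criterion
at n = 200 replicates).

## Known limitations

* Degree is the only centrality, by design; betweenness/closeness are out of
  scope.
* The enrichment universe choice (annotated background vs user-supplied)
  materially changes p-values, as in any ORA tool; the default mimics
  annotation-background services.
* The EMG pathway selection is a scientific input: different selections give
  different groups, and the package takes no stance on which pathways are
  "the" action pathways.
* Positive docking affinities are preserved as recorded even when a sign
  typo is plausible; downstream spontaneity counts treat them as
  non-binding.
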