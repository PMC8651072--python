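# Methods

## Problem setting

`ligsig` models quantitative small-molecule bioactivity against a
protein target (the motivating application is GPCR ligand screening)
from structure alone. Activity measurements of four kinds — Ki, Kd,
IC50, EC50 — are put on one dimensionless scale,

    bioactivity = −log10(activity in molar),

so 1 µM ↦ 6, 1 nM ↦ 9, and higher means more potent. Regression on
this scale lets a single model pool heterogeneous assay data and output
a ranked, interpretable potency estimate (convertible back to µM as
`10^(−ŷ)·10^6`).

## Curation

Input rows are validated individually: the SMILES must parse and
sanitize under RDKit, the activity must be positive, the measure type
must be one of the four supported. Rejections are logged with row and
reason, never silently dropped. Multi-component inputs keep their
largest covalent component (activity refers to the parent compound).
Replicates are grouped by canonical SMILES (plus receptor id when
present); a group whose transformed values span more than `max_spread`
log units is removed entirely as experimentally inconsistent, and
surviving groups collapse to the arithmetic mean of transformed values
(the geometric mean on the molar scale). Defaults: `max_spread = 1.0`
log unit — one order of magnitude is a common inter-assay tolerance —
and mean aggregation, with median available by config. Curation is
idempotent and its output is sorted by canonical SMILES.

## Graph signature

A molecule is a graph with atoms as nodes and covalent bonds as edges.
Each heavy atom receives a set of pharmacophore labels from a shipped,
editable SMARTS rule table (`ligsig/data/pharmacophores.smarts`):
Aromatic (perception-flagged), Hydrophobic (uncharged C/halogen with no
N/O/S/P neighbour), Donor, Acceptor, PositiveIonizable (aliphatic
amines, amidines/guanidines, cationic N), NegativeIonizable (acid
groups, tetrazoles). Atoms may carry several labels; labelling is
atom-order invariant.

Distance between atoms is the shortest-path bond count (integer graph
distance, not 3D geometry — the graphs contain covalent bonds only and
no conformers are involved). For every unordered label pair (A, B) —
21 pairs for 6 labels — and every cutoff d in the schedule, the
signature counts unordered heavy-atom pairs (i, j) with distance ≤ d
whose label sets supply A on one end and B on the other, at most once
per (pair, label pair). Counts therefore form a cumulative distance
distribution per label pair. Cross-fragment (unreachable) pairs never
count, making the signature additive over disconnected components.

Default cutoff schedule: 1..10 step 1 bonds, spanning typical
drug-like diameters; configurable. Counts are raw (unnormalized):
the downstream tree ensembles are scale-free.

The implementation is vectorized (per-label-pair distance histograms +
cumulative sums over the RDKit distance matrix); the test suite pins it
exactly to a brute-force oracle that recomputes everything with
networkx breadth-first search and explicit pair enumeration.

## Descriptors

Seventeen-plus general physicochemical properties computed with RDKit:
size (molecular weight, heavy atoms), flexibility (rotatable bonds),
polarity (TPSA), lipophilicity (Crippen clogP), H-bond donors and
acceptors, heteroatom/ring/aromatic-ring counts, the bicyclic fragment
count (`fr_bicyclic`), Labute ASA and the MOE-style surface-area
partitions SMR_VSA3/7, SlogP_VSA2/3/8, PEOE_VSA1. The set is fixed in
layout, extensible by any RDKit descriptor name, and a failed
descriptor is recorded as NaN with a warning rather than a silent zero.
The modelling feature table is the row-aligned concatenation
[signatures ‖ descriptors].

## Similarity-aware evaluation protocol

Random row splits leak near-duplicates across the train/test boundary.
Instead: Morgan radius-2 fingerprints (2048 bits), Butina
sphere-exclusion clustering with a Tanimoto ≥ 0.8 neighbour criterion
("80% similarity"), and whole-cluster assignment. Clusters are
shuffled with a seeded RNG and moved to the blind side until the
molecule-level blind fraction first reaches the 10% target (overshoot
by at most the last cluster is accepted and logged); no cluster ever
straddles the split, and the maximum train–blind Tanimoto is recorded
as a diagnostic. Sphere exclusion is deterministic: the unassigned item
with the most unassigned neighbours becomes the next centroid, ties to
the lower index.

Cross-validation on the training side is stratified for a continuous
target by quantile binning (default 10 bins, collapsed when duplicated
edges make fewer) and round-robin filling, giving balanced folds that
mirror the label distribution. k ∈ {5, 10, 20} supported; 10-fold is
the workflow default.

## Models and metrics

Four tree-ensemble families: Random Forest, Extra Trees, Gradient
Boosting (scikit-learn) and XGBoost, each with `random_state = 0` and
otherwise library-default hyperparameters — no tuning. Reported
metrics: Pearson r, Spearman ρ, Kendall τ-b (tie-corrected), MSE and
RMSE; correlations are reported as missing when either vector is
constant. Cross-validation pools out-of-fold predictions so every
training molecule is scored exactly once. Model selection ranks by
Pearson, then lower RMSE, then a fixed algorithm order; the decision is
written to the run manifest.

Forward-greedy feature selection starts empty and adds, per step, the
feature maximizing pooled-CV Pearson; ties go to the earlier column in
canonical order; stopping is non-improvement with patience 1 (simplest
faithful reading of "forward greedy"), with an optional feature cap.

Outlier-trimmed re-evaluation removes the ⌈0.1·n⌉ points of largest
absolute residual and recomputes metrics, reporting the dropped
identities; trimming can only decrease MSE.

The cross-measure experiment curates binding (Ki+Kd) and functional
(IC50+EC50) records separately, trains on the larger group and tests on
the smaller, reporting within-group CV alongside for contrast.

## Decoy augmentation

Appending presumed-inactive molecules at a hard-set bioactivity of −1
(10 molar) widens target variance and inflates correlation metrics
without improving real ranking ability. The experiment is reproduced
with a local sampler: for each seeded draw of an active, the pool
molecule minimizing the spread-normalized absolute difference over
{molecular weight, clogP, rotatable bonds, H-bond donors, acceptors}
subject to Tanimoto < 0.4 against that active is taken without
replacement. Augmentation adds round(0.2·n) decoys, labels them −1.0
exactly, and never touches an active's label. The paired report runs
the identical pipeline (same seeds) with and without augmentation and
prints signed metric deltas.

## Potency profiling

Potent ligands are those with bioactivity > 5 (better than 10 µM),
capped at the top 300 by potency — the cap-within-threshold reading is
used because it reproduces the behaviour of small datasets where fewer
than 300 molecules qualify; a union rule is available by config.
Profiles summarize the descriptor set (min/quartiles/median/mean +
histograms). Fragment enrichment compares presence frequencies between
the potent subset and the remainder over a named-substructure catalogue
(default: RDKit's `fr_*` fragment descriptors, covering aromatic,
bicyclic and nitrogen-containing motifs), with hypergeometric
upper-tail p-values, a smoothed ratio (ε = 1/(n₁+n₂)) and
Benjamini–Hochberg adjustment. This fixed-catalogue test is a
deterministic, desk-scale stand-in for de-novo frequent-subgraph
mining and is not claimed equivalent to it.

## Synthetic data generator

Molecules are assembled from a fragment grammar: ten heteroaromatic /
fused-ring scaffolds with two substituent slots and thirty substituents
(alkyl, alkoxy, halogen, amine, amide, acid, sulfonamide, nitrile,
aryl, saturated N-heterocycles). Assemblies are validity-checked,
canonicalized, deduplicated and filtered to 10–60 heavy atoms. The
grammar guarantees aromatic rings, H-bond donors/acceptors and
ionizable groups at realistic frequencies (≥2 rings and
nitrogen-containing fragments in well over half the library), so
profiling and enrichment are exercisable.

True bioactivity is a linear function of three signature features —
Aromatic:Aromatic-6 (w=0.025), Hydrophobic:Acceptor-4 (w=0.12),
Aromatic:Donor-3 (w=0.18), intercept 3.5 — plus Gaussian noise
(default sd 0.3), clipped to [3, 11]. The weights were calibrated once
against the default grammar so labels centre near 6.5 with sd ≈ 1.1
and span ≈ 4.5–9.5, the range typical of curated assay corpora; they
are frozen constants, not free knobs. Emitted activities are
`10^(−bioactivity)` molar with measure types drawn from a configurable
mix; an optional replicate spec duplicates a fraction of ligands at an
exact log-unit offset so curation's spread filter can be tested by
count. A ground-truth sidecar (per-feature contributions, noise,
true label) accompanies every table.

What the generator does not emulate: real structure–activity
relationships are non-linear, assay noise is heteroscedastic and
occasionally systematic, and chemical series structure is far more
correlated than a two-slot grammar. Passing tests therefore
demonstrate that the machinery is correct and leak-free under known
ground truth — not that any particular real corpus will reach the same
correlations.

## Problem sizes and numerical choices

The standard study runs at n = 400 molecules (10-fold CV, 90/10 blind
split), the decoy experiment at n = 120 actives + 24 decoys, and
oracle equivalence checks at 50–500 molecules — sizes chosen so the
whole suite runs comfortably on one CPU while keeping ≥ 36 blind
molecules for stable correlations. Determinism: every stochastic step
(cluster shuffling, fold shuffling, generator sampling, estimator
seeds) derives from explicit seeds; reruns are byte-identical.
Correlations on constant vectors are reported missing; quantile bins
with duplicate edges are collapsed; the blind-fraction greedy accepts
overshoot rather than splitting a cluster; disconnected atom pairs use
an explicit unreachable sentinel and never enter counts.

## Known limitations

- The pharmacophore rule table is a documented default, not a claim
  about any particular published feature definition; signatures change
  if the rules change (the file is versioned for that reason).
- Descriptor coverage is the main-text mandatory set; an exhaustive
  catalogue can be enabled by config but is not the tested default.
- The decoy sampler matches gross properties only; it does not
  enumerate protomers or charge states.
- Greedy selection cost grows as (features × folds × steps) model
  fits; on the full 200+-column table use a feature cap or a smaller
  candidate pool.
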