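# ligsig

Graph-based pharmacophore signatures and tree-ensemble regression for
quantitative small-molecule bioactivity prediction.

`ligsig` is for computational chemists building ligand-based potency
models when no receptor structure is available — the typical situation
for most GPCRs and other membrane targets. Given a table of SMILES
with heterogeneous activity measurements (Ki, Kd, IC50, EC50 in molar),
it curates the data onto one scale, represents each molecule by a
distance-pattern graph signature plus physicochemical descriptors,
and trains similarity-aware, leakage-free regression models of
bioactivity.

## The model

Activities are transformed to **bioactivity = −log10(activity/M)**, so
1 µM ↦ 6 and 1 nM ↦ 9; higher is more potent. Each molecule is a graph
(atoms = nodes, covalent bonds = edges) whose heavy atoms carry
pharmacophore labels (Aromatic, Hydrophobic, Donor, Acceptor,
Positive/NegativeIonizable) assigned by an editable SMARTS rule table.
The **graph signature** scans distance cutoffs d = 1..10 bonds and, for
every unordered label pair (A, B), counts atom pairs at shortest-path
distance ≤ d with A on one end and B on the other — a cumulative
distance distribution per label pair (21 pairs × 10 cutoffs = 210
counts). Concatenated with RDKit physicochemical descriptors (TPSA,
clogP, fr_bicyclic, SMR_VSA/SlogP_VSA/PEOE_VSA partitions, …), these
features drive Random Forest / Extra Trees / Gradient Boosting /
XGBoost regressors (seed 0, default hyperparameters).

Evaluation is deliberately conservative: molecules are clustered by
Morgan radius-2 fingerprint Tanimoto ≥ 0.8 (Butina sphere exclusion)
and whole clusters go to either the 90% training or the 10% blind
side, so no blind molecule has a close analogue in training. Stratified
k-fold CV, Pearson/Spearman/Kendall/MSE reporting, forward-greedy
feature selection, outlier-trimmed re-evaluation and a decoy-
augmentation bias study complete the protocol. See `docs/methods.md`.

## Worked example

Simulate a ligand table with known ground truth, run the full
pipeline, and predict a single compound:

```bash
ligsig simulate --n 100 --seed 7 -o ligands.csv
ligsig train --input ligands.csv --seed 7 -o run/
ligsig predict run/model.joblib "c1ccc2[nH]c(CCN)c(C)c2c1"
```

which prints (numbers from this exact invocation):

```
simulated 100 measurements of 100 molecules -> ligands.csv
best algorithm: gradient_boost; blind Pearson 0.924, MSE 0.117 (n=10) -> run/
c1ccc2[nH]c(CCN)c(C)c2c1  bioactivity 6.010  predicted activity 0.9769 uM
```

The blind Pearson is computed on the low-similarity 10% held-out
clusters, so 0.92 means the model ranks genuinely novel chemotypes
well, not just near-duplicates. The single-compound output converts
the predicted bioactivity back to a concentration: 6.01 on the −log10
molar scale is about 1 µM. `run/manifest.json` records the config hash,
seeds, per-algorithm CV metrics and the selection decision; the same
config and seed reproduce it byte-for-byte.

The same operations are available as a library:

```python
from ligsig import curate_dataset, run_pipeline
from ligsig.synth import GeneratorSpec, generate_ligand_library, simulate_bioactivity

spec = GeneratorSpec(n_molecules=400, seed=1, noise_sd=0.3)
records, truth = simulate_bioactivity(generate_ligand_library(spec), spec)
result = run_pipeline({"seed": 1, "cv_folds": 10}, dataset=curate_dataset(records))
print(result["best_algorithm"], result["blind_report"].pearson_r)
```

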