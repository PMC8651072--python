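"""Similarity-aware train/blind splitting and stratified cross-validation.

Blind-test sets built by random row sampling leak information through
near-duplicate analogues.  Here molecules are clustered by Morgan
(radius-2) fingerprint Tanimoto similarity with Butina sphere-exclusion
clustering at an 80% similarity threshold, and whole clusters are
assigned to either the training or the blind side, guaranteeing that no
blind molecule has a close analogue in training.  Cross-validation folds
on the training side are stratified over quantile bins of the continuous
bioactivity label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem import mol_from_smiles


def morgan_fingerprint(mol: Chem.Mol, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Morgan (circular) fingerprint as a boolean vector."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=bool)


def fingerprints_for(smiles_list: Sequence[str], radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    return np.stack([morgan_fingerprint(mol_from_smiles(s), radius, n_bits) for s in smiles_list])


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two equal-length bit vectors.

    Defined as |a AND b| / |a OR b|; two all-zero vectors count as
    identical (similarity 1.0).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def _tanimoto_matrix(fps: np.ndarray) -> np.ndarray:
    f = fps.astype(np.float64)
    inter = f @ f.T
    counts = f.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    return sim


def butina_cluster(fps: np.ndarray, similarity_threshold: float = 0.8) -> np.ndarray:
    """Sphere-exclusion (Butina) clustering on Tanimoto similarity.

    Neighbour lists are built at similarity >= threshold; the unassigned
    molecule with the most unassigned neighbours becomes the next
    cluster centroid and absorbs its unassigned neighbours; ties go to
    the lower original index, making the outcome deterministic.

    Returns an integer cluster id per molecule (ids ordered by cluster
    creation).
    """
    n = len(fps)
    if n == 0:
        raise ValueError("need at least one fingerprint")
    sim = _tanimoto_matrix(np.asarray(fps, dtype=bool))
    neighbours = [set(np.nonzero(sim[i] >= similarity_threshold)[0]) - {i} for i in range(n)]
    assignment = np.full(n, -1, dtype=np.int64)
    next_id = 0
    unassigned = set(range(n))
    while unassigned:
        # most unassigned neighbours, lowest index on ties
        centroid = max(
            unassigned,
            key=lambda i: (len(neighbours[i] & unassigned), -i),
        )
        members = {centroid} | (neighbours[centroid] & unassigned)
        for m in members:
            assignment[m] = next_id
        unassigned -= members
        next_id += 1
    return assignment


@dataclass
class SplitPlan:
    """Cluster ids, train/blind membership and CV fold ids for one dataset."""

    smiles: list[str]
    cluster_id: np.ndarray
    membership: list[str]  # "train" | "blind" per ligand
    folds: dict[int, np.ndarray] = field(default_factory=dict)  # k -> fold id per *train* ligand
    seed: int = 0
    max_cross_tanimoto: float | None = None  # diagnostic: max train-blind similarity

    @property
    def train_indices(self) -> np.ndarray:
        return np.nonzero(np.asarray(self.membership) == "train")[0]

    @property
    def blind_indices(self) -> np.ndarray:
        return np.nonzero(np.asarray(self.membership) == "blind")[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"smiles": self.smiles, "cluster_id": self.cluster_id, "membership": self.membership}
        )
        for k, fold in self.folds.items():
            col = np.full(len(self.smiles), -1, dtype=np.int64)
            col[self.train_indices] = fold
            df[f"fold_{k}"] = col
        return df


def cluster_split(
    smiles: Sequence[str],
    cluster_assignment: np.ndarray,
    blind_fraction: float = 0.1,
    seed: int = 0,
    fingerprints: np.ndarray | None = None,
) -> SplitPlan:
    """Assign whole clusters to train/blind at a molecule-level blind fraction.

    Clusters are shuffled with a seeded RNG and moved to the blind side
    greedily until the molecule count first reaches the target fraction
    (overshoot by at most one cluster is accepted).  When fingerprints
    are supplied, the maximum train-blind Tanimoto is recorded as a
    leakage diagnostic.

    Raises
    ------
    ValueError
        If all molecules fall in one cluster (no leak-free split exists).
    """
    if not (0 < blind_fraction < 1):
        raise ValueError(f"blind_fraction must be in (0, 1), got {blind_fraction}")
    cluster_assignment = np.asarray(cluster_assignment)
    n = len(smiles)
    ids = np.unique(cluster_assignment)
    if len(ids) < 2:
        raise ValueError("all molecules fall into a single similarity cluster; cannot split without leakage")
    rng = np.random.default_rng(seed)
    order = rng.permutation(ids)
    blind_clusters: set[int] = set()
    n_blind = 0
    target = blind_fraction * n
    for cid in order:
        if n_blind >= target:
            break
        size = int(np.count_nonzero(cluster_assignment == cid))
        if n_blind + size >= n:  # never blind everything
            continue
        blind_clusters.add(int(cid))
        n_blind += size
    membership = ["blind" if int(c) in blind_clusters else "train" for c in cluster_assignment]
    max_sim = None
    if fingerprints is not None:
        tr = np.asarray(membership) == "train"
        bl = ~tr
        if tr.any() and bl.any():
            sim = _tanimoto_matrix(np.asarray(fingerprints, dtype=bool))
            max_sim = float(sim[np.ix_(tr, bl)].max())
    return SplitPlan(
        smiles=list(smiles),
        cluster_id=cluster_assignment,
        membership=membership,
        seed=seed,
        max_cross_tanimoto=max_sim,
    )


def stratified_kfold(
    bioactivities: Sequence[float],
    k: int,
    n_bins: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Stratified k-fold assignment for a continuous target.

    Targets are cut into quantile bins (duplicate edges collapsed) and
    folds are filled round-robin within each bin after a seeded shuffle,
    so each fold mirrors the overall bioactivity distribution.  Returns
    a fold id in [0, k) per input.
    """
    y = np.asarray(bioactivities, dtype=float)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size n={n}")
    bins = min(n_bins, max(1, n // k))
    try:
        binned = pd.qcut(y, q=bins, labels=False, duplicates="drop")
    except ValueError:
        binned = np.zeros(n, dtype=int)
    binned = np.asarray(binned, dtype=int)
    rng = np.random.default_rng(seed)
    fold = np.full(n, -1, dtype=np.int64)
    start = 0
    for b in np.unique(binned):
        idx = np.nonzero(binned == b)[0]
        idx = idx[rng.permutation(len(idx))]
        # continue the round-robin across bins so fold sizes stay balanced
        for j, i in enumerate(idx):
            fold[i] = (start + j) % k
        start = (start + len(idx)) % k
    return fold


def make_split_plan(
    smiles: Sequence[str],
    bioactivities: Sequence[float],
    ks: Sequence[int] = (5, 10, 20),
    blind_fraction: float = 0.1,
    similarity_threshold: float = 0.8,
    n_bits: int = 2048,
    n_bins: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Full split protocol: fingerprint, cluster, 90/10 split, CV folds."""
    fps = fingerprints_for(smiles, n_bits=n_bits)
    clusters = butina_cluster(fps, similarity_threshold)
    plan = cluster_split(smiles, clusters, blind_fraction, seed, fingerprints=fps)
    y = np.asarray(bioactivities, dtype=float)[plan.train_indices]
    for k in ks:
        if k <= len(y):
            plan.folds[k] = stratified_kfold(y, k, n_bins=n_bins, seed=seed + k)
    return plan
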