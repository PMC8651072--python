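"""Distance-pattern graph signatures of small molecules.

The signature models a molecule as a graph (atoms = nodes, covalent
bonds = edges), labels atoms by pharmacophore role, and scans a schedule
of graph-distance cutoffs.  For every unordered pair of labels (A, B)
and cutoff d it counts the unordered heavy-atom pairs (i, j) whose
shortest-path bond distance is <= d and whose label sets supply A on one
end and B on the other.  Because counts accumulate over increasing d,
each label pair traces a cumulative distance distribution — the
signature captures how the molecule's pharmacophoric features are
spatially organized along its bond network.

Counts are kept raw (no normalization): the downstream tree ensembles
are scale-free, and raw counts remain interpretable as pair frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import mol_from_smiles
from .pharmacophores import LABELS, assign_pharmacophores

#: Graph distance reported between atoms in different covalent components.
UNREACHABLE = -1

# RDKit marks disconnected pairs with a huge float in GetDistanceMatrix.
_RDKIT_DISCONNECTED = 1.0e7


@dataclass(frozen=True)
class CutoffSchedule:
    """Integer bond-count cutoffs to scan: min, min+step, ..., <= max.

    The default (1..10 step 1) spans typical drug-like molecule
    diameters; distances beyond the largest cutoff are simply not
    resolved by the signature (pairs further apart than ``max`` never
    count).
    """

    min: int = 1
    max: int = 10
    step: int = 1

    def __post_init__(self) -> None:
        if self.min < 1 or self.step < 1 or self.max < self.min:
            raise ValueError(f"invalid cutoff schedule {self}")

    @property
    def cutoffs(self) -> tuple[int, ...]:
        return tuple(range(self.min, self.max + 1, self.step))


#: Unordered label pairs in canonical order — 21 pairs for 6 labels.
LABEL_PAIRS: tuple[tuple[str, str], ...] = tuple(
    combinations_with_replacement(LABELS, 2)
)


def signature_columns(schedule: CutoffSchedule = CutoffSchedule()) -> list[str]:
    """Fixed column layout ``"<A>:<B>-<cutoff>"``, label pairs outer, cutoffs inner."""
    return [f"{a}:{b}-{d}" for a, b in LABEL_PAIRS for d in schedule.cutoffs]


def graph_distances(mol: Chem.Mol) -> np.ndarray:
    """All-pairs shortest-path bond counts between heavy atoms.

    Entry (i, j) is the minimum number of covalent bonds on any path
    from atom i to atom j; the diagonal is 0 and pairs in different
    covalent components are :data:`UNREACHABLE`.
    """
    if mol.GetNumAtoms() == 0:
        return np.zeros((0, 0), dtype=np.int64)
    dist = Chem.GetDistanceMatrix(mol)
    out = np.where(dist >= _RDKIT_DISCONNECTED, UNREACHABLE, dist).astype(np.int64)
    return out


def compute_signature(
    mol: Chem.Mol,
    schedule: CutoffSchedule = CutoffSchedule(),
    rule_path: str | Path | None = None,
) -> np.ndarray:
    """Signature vector of one molecule under ``schedule``.

    Returns counts aligned with :func:`signature_columns`.  A pair of
    atoms contributes to every label pair derivable from its two label
    sets, but at most once per label pair (no double counting when both
    atoms carry the same label).  Unreachable (cross-fragment) pairs
    never count, so the signature of a multi-component input is the sum
    of its components' signatures.
    """
    cutoffs = schedule.cutoffs
    n_atoms = mol.GetNumAtoms()
    vec = np.zeros(len(LABEL_PAIRS) * len(cutoffs), dtype=np.int64)
    if mol.GetNumHeavyAtoms() == 0:
        warnings.warn("molecule has no heavy atoms; signature is all zeros")
        return vec
    labels = assign_pharmacophores(mol, rule_path)
    dist = graph_distances(mol)
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]

    # boolean atom-by-label matrix
    lab = np.zeros((n_atoms, len(LABELS)), dtype=bool)
    for i in heavy:
        for k, name in enumerate(LABELS):
            lab[i, k] = name in labels[i]

    hv = np.asarray(heavy, dtype=np.int64)
    iu, ju = np.triu_indices(len(hv), k=1)
    ai, aj = hv[iu], hv[ju]
    d = dist[ai, aj]
    reachable = d != UNREACHABLE
    ai, aj, d = ai[reachable], aj[reachable], d[reachable]

    max_cut = cutoffs[-1]
    pos = 0
    for ka, kb in combinations_with_replacement(range(len(LABELS)), 2):
        if ka == kb:
            mask = lab[ai, ka] & lab[aj, ka]
        else:
            mask = (lab[ai, ka] & lab[aj, kb]) | (lab[ai, kb] & lab[aj, ka])
        dm = d[mask]
        dm = dm[dm <= max_cut]
        if dm.size:
            hist = np.bincount(dm, minlength=max_cut + 1)
            cum = np.cumsum(hist)
            vec[pos : pos + len(cutoffs)] = cum[list(cutoffs)]
        pos += len(cutoffs)
    return vec


def signature_matrix(
    smiles_list: Sequence[str],
    schedule: CutoffSchedule = CutoffSchedule(),
    rule_path: str | Path | None = None,
) -> pd.DataFrame:
    """Batch signatures: one row per input SMILES, indexed by the input order.

    The DataFrame index holds the input SMILES; columns follow
    :func:`signature_columns`.  A per-molecule failure is re-raised with
    the offending SMILES attached.
    """
    if not schedule.cutoffs:
        raise ValueError("empty cutoff schedule")
    rows = []
    for smi in smiles_list:
        try:
            mol = mol_from_smiles(smi)
            rows.append(compute_signature(mol, schedule, rule_path))
        except Exception as exc:
            raise type(exc)(f"signature failed for {smi!r}: {exc}") from exc
    return pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(rows), -1),
        index=list(smiles_list),
        columns=signature_columns(schedule),
    )


def dataset_signature_matrix(dataset, schedule: CutoffSchedule = CutoffSchedule(), rule_path=None) -> pd.DataFrame:
    """Signature table for a curated dataset (rows ordered as the dataset)."""
    return signature_matrix([lig.smiles for lig in dataset], schedule, rule_path)
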