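"""Pharmacophore labelling, graph distances and signature vectors.

The signature implementation is vectorized; the oracle here recomputes
everything the slow way — networkx breadth-first shortest paths and an
explicit double loop over atom pairs and label pairs — and must agree
exactly.
"""

import itertools

import networkx as nx
import numpy as np
import pytest
from rdkit import Chem

from ligsig.chem import mol_from_smiles
from ligsig.pharmacophores import assign_pharmacophores, load_rule_table, RuleTableError
from ligsig.signatures import (
    UNREACHABLE,
    CutoffSchedule,
    LABEL_PAIRS,
    compute_signature,
    graph_distances,
    signature_columns,
    signature_matrix,
)


# ---------------------------------------------------------------- labelling

def test_benzene_carbons_aromatic_and_hydrophobic():
    labels = assign_pharmacophores(mol_from_smiles("c1ccccc1"))
    assert all(lab == frozenset({"Aromatic", "Hydrophobic"}) for lab in labels)


def test_methylamine_nitrogen_donor_and_positive_ionizable():
    labels = assign_pharmacophores(mol_from_smiles("CN"))
    nitrogen = [lab for atom, lab in zip(mol_from_smiles("CN").GetAtoms(), labels) if atom.GetSymbol() == "N"]
    assert nitrogen == [frozenset({"Donor", "PositiveIonizable"})]


def test_methane_hydrophobic_only():
    labels = assign_pharmacophores(mol_from_smiles("C"))
    assert labels == [frozenset({"Hydrophobic"})]


def test_carboxylate_negative_ionizable():
    labels = assign_pharmacophores(mol_from_smiles("CC(=O)O"))
    assert any("NegativeIonizable" in lab for lab in labels)


def test_labelling_invariant_to_atom_order():
    mol = mol_from_smiles("CCOc1ccc(CN)cc1")
    ref = assign_pharmacophores(mol)
    rng = np.random.default_rng(0)
    perm = list(rng.permutation(mol.GetNumAtoms()))
    renumbered = Chem.RenumberAtoms(mol, [int(p) for p in perm])
    got = assign_pharmacophores(renumbered)
    assert [got[perm.index(i)] for i in range(len(ref))] == list(ref)


def test_malformed_rule_table_rejected(tmp_path):
    bad = tmp_path / "rules.smarts"
    bad.write_text("[a] NotALabel\n")
    with pytest.raises(RuleTableError, match="NotALabel"):
        load_rule_table(bad)


# ---------------------------------------------------------------- distances

def test_benzene_graph_distances():
    d = graph_distances(mol_from_smiles("c1ccccc1"))
    assert d[0, 1] == 1          # bonded neighbours
    assert d[0, 3] == 3          # para positions
    assert np.all(np.diag(d) == 0)
    assert np.array_equal(d, d.T)


def test_disconnected_fragments_unreachable():
    d = graph_distances(mol_from_smiles("CCN.Cl"))
    assert d[3, 0] == UNREACHABLE and d[0, 3] == UNREACHABLE


# ---------------------------------------------------------------- signatures

def test_benzene_aromatic_pair_counts():
    sched = CutoffSchedule(1, 3, 1)
    sig = dict(zip(signature_columns(sched), compute_signature(mol_from_smiles("c1ccccc1"), sched)))
    assert (sig["Aromatic:Aromatic-1"], sig["Aromatic:Aromatic-2"], sig["Aromatic:Aromatic-3"]) == (6, 12, 15)


def test_methane_signature_all_zero():
    assert not compute_signature(mol_from_smiles("C")).any()


def test_signature_invariant_to_smiles_spelling():
    a = compute_signature(mol_from_smiles("c1ccccc1CCN"))
    b = compute_signature(mol_from_smiles("NCCc1ccccc1"))
    assert np.array_equal(a, b)


def test_signature_additive_over_fragments():
    combined = compute_signature(mol_from_smiles("CCO.c1ccccc1"))
    parts = compute_signature(mol_from_smiles("CCO")) + compute_signature(mol_from_smiles("c1ccccc1"))
    assert np.array_equal(combined, parts)


def _oracle_signature(mol, schedule):
    """Brute force: explicit BFS distances + pair enumeration."""
    graph = nx.Graph()
    graph.add_nodes_from(range(mol.GetNumAtoms()))
    for bond in mol.GetBonds():
        graph.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    dist = dict(nx.all_pairs_shortest_path_length(graph))
    labels = assign_pharmacophores(mol)
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    counts = {}
    for (la, lb) in LABEL_PAIRS:
        for cut in schedule.cutoffs:
            total = 0
            for i, j in itertools.combinations(heavy, 2):
                if j not in dist[i] or dist[i][j] > cut:
                    continue
                li, lj = labels[i], labels[j]
                if (la in li and lb in lj) or (lb in li and la in lj):
                    total += 1
            counts[f"{la}:{lb}-{cut}"] = total
    return np.array([counts[c] for c in signature_columns(schedule)])


def test_signature_matches_bruteforce_oracle(small_library):
    sched = CutoffSchedule(1, 8, 1)
    for smi in small_library[:50]:
        mol = mol_from_smiles(smi)
        assert np.array_equal(compute_signature(mol, sched), _oracle_signature(mol, sched)), smi


def test_signature_cumulative_monotone(small_library):
    sched = CutoffSchedule()
    n_cut = len(sched.cutoffs)
    for smi in small_library:
        sig = compute_signature(mol_from_smiles(smi), sched).reshape(len(LABEL_PAIRS), n_cut)
        assert np.all(np.diff(sig, axis=1) >= 0), smi


def test_signature_invariant_to_atom_renumbering(small_library):
    rng = np.random.default_rng(42)
    for smi in small_library[:20]:
        mol = mol_from_smiles(smi)
        perm = [int(p) for p in rng.permutation(mol.GetNumAtoms())]
        assert np.array_equal(
            compute_signature(mol), compute_signature(Chem.RenumberAtoms(mol, perm))
        ), smi


def test_signature_counts_bounded_by_pair_count(small_library):
    for smi in small_library[:20]:
        mol = mol_from_smiles(smi)
        n = mol.GetNumHeavyAtoms()
        assert compute_signature(mol).max() <= n * (n - 1) // 2


# ---------------------------------------------------------------- batch API

def test_signature_matrix_shape_and_columns(small_library):
    sched = CutoffSchedule(1, 4, 1)
    table = signature_matrix(small_library[:5], sched)
    assert table.shape == (5, 21 * 4)  # 21 unordered label pairs
    assert list(table.index) == small_library[:5]
    assert table.columns[0] == "Hydrophobic:Hydrophobic-1"


def test_signature_matrix_empty_schedule_rejected():
    with pytest.raises(ValueError):
        CutoffSchedule(1, 0, 1)


def test_signature_matrix_attaches_ligand_identity_on_failure():
    with pytest.raises(Exception, match="C1CC"):
        signature_matrix(["CCO", "C1CC"])


def test_all_methane_dataset_zero_table():
    table = signature_matrix(["C"])
    assert not table.to_numpy().any()
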