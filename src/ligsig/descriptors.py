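"""General physicochemical descriptors combined with graph signatures.

The mandatory set covers standard drug-likeness properties (size,
lipophilicity, polarity, flexibility, H-bonding, ring content) plus the
MOE-style approximate surface-area partitions (SMR_VSA, SlogP_VSA,
PEOE_VSA bins) and the bicyclic fragment count, all computed with RDKit.
Additional RDKit descriptors can be requested by name.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chem import mol_from_smiles

#: Mandatory descriptor layout: (column name, RDKit descriptor name).
DESCRIPTOR_SET: tuple[tuple[str, str], ...] = (
    ("molecular_weight", "MolWt"),
    ("heavy_atom_count", "HeavyAtomCount"),
    ("rotatable_bonds", "NumRotatableBonds"),
    ("tpsa", "TPSA"),
    ("clogp", "MolLogP"),
    ("h_bond_donors", "NumHDonors"),
    ("h_bond_acceptors", "NumHAcceptors"),
    ("heteroatom_count", "NumHeteroatoms"),
    ("ring_count", "RingCount"),
    ("aromatic_rings", "NumAromaticRings"),
    ("fr_bicyclic", "fr_bicyclic"),
    ("labute_asa", "LabuteASA"),
    ("SMR_VSA3", "SMR_VSA3"),
    ("SMR_VSA7", "SMR_VSA7"),
    ("SlogP_VSA2", "SlogP_VSA2"),
    ("SlogP_VSA3", "SlogP_VSA3"),
    ("SlogP_VSA8", "SlogP_VSA8"),
    ("PEOE_VSA1", "PEOE_VSA1"),
)

_RDKIT_FUNCS = dict(Descriptors._descList)


def descriptor_columns(extra: Sequence[str] = ()) -> list[str]:
    """Fixed column layout of :func:`compute_descriptors`."""
    return [name for name, _ in DESCRIPTOR_SET] + list(extra)


def compute_descriptors(mol: Chem.Mol, extra: Sequence[str] = ()) -> dict[str, float]:
    """Compute the mandatory descriptor vector (plus ``extra`` RDKit names).

    A descriptor that fails on a valid molecule is recorded as NaN with
    a warning rather than a silent zero, so downstream imputation or
    filtering stays explicit.
    """
    out: dict[str, float] = {}
    pairs = list(DESCRIPTOR_SET) + [(name, name) for name in extra]
    for col, rdkit_name in pairs:
        try:
            func = _RDKIT_FUNCS[rdkit_name]
        except KeyError:
            raise KeyError(f"unknown RDKit descriptor {rdkit_name!r}") from None
        try:
            val = float(func(mol))
            if not math.isfinite(val):
                raise ValueError("non-finite value")
        except Exception:
            warnings.warn(f"descriptor {col} failed on {Chem.MolToSmiles(mol)}; recorded as missing")
            val = float("nan")
        out[col] = val
    return out


def descriptor_matrix(smiles_list: Sequence[str], extra: Sequence[str] = ()) -> pd.DataFrame:
    """Descriptor table, one row per SMILES, indexed by the input order."""
    rows = []
    for smi in smiles_list:
        try:
            rows.append(compute_descriptors(mol_from_smiles(smi), extra))
        except Exception as exc:
            raise type(exc)(f"descriptors failed for {smi!r}: {exc}") from exc
    return pd.DataFrame(rows, index=list(smiles_list), columns=descriptor_columns(extra))


def dataset_descriptor_matrix(dataset, extra: Sequence[str] = ()) -> pd.DataFrame:
    return descriptor_matrix([lig.smiles for lig in dataset], extra)


def combined_feature_matrix(smiles_list: Sequence[str], schedule=None, rule_path=None, extra=()) -> pd.DataFrame:
    """[signatures || descriptors] feature table, rows aligned by SMILES order."""
    from .signatures import CutoffSchedule, signature_matrix

    schedule = schedule or CutoffSchedule()
    sig = signature_matrix(smiles_list, schedule, rule_path)
    desc = descriptor_matrix(smiles_list, extra)
    return pd.concat([sig, desc], axis=1)
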