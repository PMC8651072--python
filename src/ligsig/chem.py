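"""Small-molecule parsing helpers shared across the package.

All grouping, deduplication and reporting is keyed on RDKit canonical
SMILES.  Multi-component inputs (salts, solvates) are reduced to their
largest covalent component before canonicalization, since activity
measurements refer to the parent compound.
"""

from __future__ import annotations

from rdkit import Chem
from rdkit import RDLogger

# RDKit is chatty about every rejected SMILES; rejections are reported
# through our own logs instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")


class MoleculeError(ValueError):
    """Raised when a SMILES cannot be parsed or sanitized."""


def mol_from_smiles(smiles: str, largest_fragment: bool = False) -> Chem.Mol:
    """Parse and sanitize a SMILES string.

    Parameters
    ----------
    smiles:
        Molecular line notation.
    largest_fragment:
        If true, keep only the covalent component with the most heavy
        atoms (ties broken by canonical SMILES order).

    Raises
    ------
    MoleculeError
        If the SMILES does not parse to a valid, sanitizable molecule.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparsable SMILES: {smiles!r}")
    if largest_fragment:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        if len(frags) > 1:
            mol = max(
                frags,
                key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)),
            )
    return mol


def canonical_smiles(smiles: str, largest_fragment: bool = False) -> str:
    """Canonical SMILES of ``smiles`` (optionally of its largest component)."""
    return Chem.MolToSmiles(mol_from_smiles(smiles, largest_fragment=largest_fragment))


def was_multifragment(smiles: str) -> bool:
    """True if the input SMILES contains more than one covalent component."""
    return "." in smiles
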