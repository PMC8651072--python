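"""Pharmacophore labelling of heavy atoms via a SMARTS rule table.

Each heavy atom is assigned a (possibly empty) set of chemical-role
labels — Aromatic, Hydrophobic, Donor, Acceptor, PositiveIonizable,
NegativeIonizable — by matching SMARTS patterns from a plain-text rule
file.  The default table ships with the package and is deliberately
user-editable: labels feed directly into the graph signature, so they
must be reproducible and auditable rather than buried in code.
"""

from __future__ import annotations

from functools import lru_cache
from importlib.resources import files
from pathlib import Path

from rdkit import Chem

#: Canonical label order; fixes the layout of signature vectors.
LABELS = (
    "Hydrophobic",
    "Aromatic",
    "Acceptor",
    "Donor",
    "PositiveIonizable",
    "NegativeIonizable",
)

DEFAULT_RULES = files("ligsig") / "data" / "pharmacophores.smarts"


class RuleTableError(ValueError):
    """Raised on malformed rule files."""


@lru_cache(maxsize=8)
def load_rule_table(path: str | Path | None = None) -> tuple[tuple[Chem.Mol, str], ...]:
    """Parse a rule file into (compiled SMARTS, label) pairs.

    Format: one rule per line, ``SMARTS<whitespace>label``; ``#`` starts
    a comment.  Unknown labels and invalid SMARTS are hard errors.
    """
    source = DEFAULT_RULES if path is None else Path(path)
    rules = []
    for lineno, line in enumerate(source.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise RuleTableError(f"line {lineno}: expected 'SMARTS label', got {line!r}")
        smarts, label = parts
        if label not in LABELS:
            raise RuleTableError(f"line {lineno}: unknown label {label!r}")
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise RuleTableError(f"line {lineno}: invalid SMARTS {smarts!r}")
        rules.append((patt, label))
    if not rules:
        raise RuleTableError(f"rule file {source} contains no rules")
    return tuple(rules)


def assign_pharmacophores(
    mol: Chem.Mol, rule_path: str | Path | None = None
) -> list[frozenset]:
    """Label each heavy atom of ``mol`` with its pharmacophore roles.

    Returns one frozenset of labels per atom, indexed by RDKit atom
    index.  Hydrogens (if explicit) receive empty sets.  The assignment
    depends only on the molecular graph, not on atom input order.
    """
    if mol is None:
        raise ValueError("molecule is None; parse/sanitize it first")
    labels: list[set] = [set() for _ in range(mol.GetNumAtoms())]
    for patt, label in load_rule_table(rule_path):
        for match in mol.GetSubstructMatches(patt, uniquify=True):
            # rules are single-atom environments: the first matched atom
            # is the labelled one
            labels[match[0]].add(label)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            labels[atom.GetIdx()] = set()
    return [frozenset(s) for s in labels]
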