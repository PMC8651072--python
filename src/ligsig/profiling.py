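"""Potent-ligand characterization: selection, property profiles, fragment enrichment.

"Potent" follows the convention of bioactivity > 5 (activity below
10 uM), capped at the top-N most potent compounds.  The potent subset
is profiled over the standard physicochemical descriptors and screened
for substructure classes over-represented relative to the remainder of
the dataset, using a hypergeometric enrichment test with
Benjamini-Hochberg correction.  The fragment catalogue defaults to
RDKit's named fragment-count descriptors (fr_*), which cover aromatic,
bicyclic and nitrogen-containing motifs among many others.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import mol_from_smiles
from .curation import CuratedLigand
from .descriptors import descriptor_matrix

#: Default fragment catalogue: every RDKit fr_* fragment-count descriptor.
from rdkit.Chem import Descriptors as _Desc

DEFAULT_FRAGMENT_CATALOGUE: tuple[str, ...] = tuple(
    name for name, _ in _Desc._descList if name.startswith("fr_")
)


def select_potent(
    dataset: Sequence[CuratedLigand],
    top_n: int = 300,
    min_bioactivity: float = 5.0,
) -> tuple[list[CuratedLigand], list[CuratedLigand]]:
    """Split a dataset into its potent subset and the remainder.

    Candidates are ligands with bioactivity strictly above
    ``min_bioactivity``; the potent subset keeps at most ``top_n`` of
    them, highest bioactivity first (ties broken by canonical SMILES).
    Everything else is the remainder.
    """
    candidates = sorted(
        (lig for lig in dataset if lig.bioactivity > min_bioactivity),
        key=lambda lig: (-lig.bioactivity, lig.smiles),
    )
    potent = candidates[:top_n]
    if not potent:
        import warnings

        warnings.warn("no ligand exceeds the potency threshold; potent set is empty")
    potent_smiles = {lig.smiles for lig in potent}
    remainder = [lig for lig in dataset if lig.smiles not in potent_smiles]
    return potent, remainder


def property_profile(
    subset: Sequence[CuratedLigand],
    n_hist_bins: int = 10,
) -> tuple[pd.DataFrame, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Summary statistics and histograms of the standard descriptors.

    Returns a DataFrame (rows = descriptors; min, q1, median, q3, max,
    mean) and a dict of descriptor -> (counts, bin_edges) histograms.
    """
    if not subset:
        raise ValueError("cannot profile an empty subset")
    desc = descriptor_matrix([lig.smiles for lig in subset])
    summary = pd.DataFrame(
        {
            "min": desc.min(),
            "q1": desc.quantile(0.25),
            "median": desc.median(),
            "q3": desc.quantile(0.75),
            "max": desc.max(),
            "mean": desc.mean(),
        }
    )
    histograms = {
        col: np.histogram(desc[col].dropna(), bins=n_hist_bins) for col in desc.columns
    }
    return summary, histograms


def _fragment_presence(smiles_list: Sequence[str], catalogue: Sequence[str]) -> pd.DataFrame:
    funcs = dict(_Desc._descList)
    rows = []
    for smi in smiles_list:
        mol = mol_from_smiles(smi)
        rows.append({name: int(funcs[name](mol) > 0) for name in catalogue})
    return pd.DataFrame(rows, index=list(smiles_list))


def fragment_enrichment(
    potent: Sequence[CuratedLigand],
    remainder: Sequence[CuratedLigand],
    catalogue: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Test each catalogue fragment for over-representation in the potent set.

    For each fragment class, presence frequencies in the two sets are
    compared: ``enrichment_ratio`` = (freq_potent + eps)/(freq_rest + eps)
    with eps = 1/(n_potent + n_rest) guarding empty cells, and p_value
    is the hypergeometric upper tail (probability of drawing at least
    the observed number of fragment-positive molecules into the potent
    set by chance).  A Benjamini-Hochberg adjusted column is included.
    Rows are sorted by raw p-value.
    """
    if catalogue is None:
        catalogue = DEFAULT_FRAGMENT_CATALOGUE
    if not catalogue:
        raise ValueError("fragment catalogue is empty")
    if not potent or not remainder:
        raise ValueError("both potent and remainder sets must be non-empty")
    n_pot, n_rest = len(potent), len(remainder)
    pres_pot = _fragment_presence([lig.smiles for lig in potent], catalogue)
    pres_rest = _fragment_presence([lig.smiles for lig in remainder], catalogue)
    eps = 1.0 / (n_pot + n_rest)

    rows = []
    for frag in catalogue:
        k_pot = int(pres_pot[frag].sum())
        k_rest = int(pres_rest[frag].sum())
        freq_pot = k_pot / n_pot
        freq_rest = k_rest / n_rest
        # P(X >= k_pot), X ~ Hypergeom(N=n_pot+n_rest, K=k_pot+k_rest, n=n_pot)
        p = float(stats.hypergeom.sf(k_pot - 1, n_pot + n_rest, k_pot + k_rest, n_pot))
        rows.append(
            {
                "fragment": frag,
                "freq_potent": freq_pot,
                "freq_rest": freq_rest,
                "enrichment_ratio": (freq_pot + eps) / (freq_rest + eps),
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows).set_index("fragment")
    table["p_adjusted"] = _benjamini_hochberg(table["p_value"].to_numpy())
    return table.sort_values("p_value")


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone in the raw p-values)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
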