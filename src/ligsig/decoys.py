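"""Property-matched decoy generation and the decoy-augmentation experiment.

Padding a dataset with presumed-inactive "decoy" molecules at an
arbitrary very low label widens the target variance and can make a
regressor look better without any genuine gain in ranking ability.
This module reproduces that experiment locally: decoys are drawn from a
user-supplied pool so that each matches a sampled active's gross
physicochemical profile (molecular weight, clogP, rotatable bonds,
H-bond donors/acceptors) while staying topologically dissimilar
(Tanimoto < 0.4 on radius-2 Morgan fingerprints), then appended at a
fixed bioactivity of -1 (10 molar).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chem import canonical_smiles
from .curation import CuratedLigand
from .descriptors import descriptor_matrix
from .splitting import fingerprints_for, tanimoto

#: Bioactivity assigned to decoys: -log10(10 molar) = -1.
DECOY_BIOACTIVITY = -1.0

MATCH_PROPERTIES = ("molecular_weight", "clogp", "rotatable_bonds", "h_bond_donors", "h_bond_acceptors")

DEFAULT_MAX_SIMILARITY = 0.4


class DecoyError(RuntimeError):
    """Raised when the pool cannot supply the requested decoys."""


def generate_decoys(
    actives: Sequence[CuratedLigand],
    pool: Sequence[str],
    n: int,
    seed: int = 0,
    max_similarity: float = DEFAULT_MAX_SIMILARITY,
) -> list[CuratedLigand]:
    """Sample ``n`` property-matched, topology-dissimilar decoys from a pool.

    For each of ``n`` seeded draws of an active, the eligible pool
    molecule (Tanimoto to that active < ``max_similarity``) minimizing
    the normalized absolute property distance is taken, without
    replacement.  Pool molecules identical to any active (by canonical
    SMILES) are excluded up front.

    Raises
    ------
    DecoyError
        If fewer than ``n`` eligible pool molecules remain at any draw.
    """
    if n == 0:
        return []
    active_smiles = {lig.smiles for lig in actives}
    pool_canon = []
    for smi in pool:
        c = canonical_smiles(smi, largest_fragment=True)
        if c not in active_smiles and c not in pool_canon:
            pool_canon.append(c)
    if len(pool_canon) < n:
        raise DecoyError(
            f"decoy pool too small: need {n}, only {len(pool_canon)} "
            "pool molecules distinct from the actives"
        )

    act_list = sorted(active_smiles)
    act_desc = descriptor_matrix(act_list)[list(MATCH_PROPERTIES)]
    pool_desc = descriptor_matrix(pool_canon)[list(MATCH_PROPERTIES)]
    # scale each property by its spread over actives+pool so no single
    # property dominates the match distance
    both = pd.concat([act_desc, pool_desc])
    scale = both.std(ddof=0).replace(0.0, 1.0)

    act_fps = fingerprints_for(act_list)
    pool_fps = fingerprints_for(pool_canon)

    rng = np.random.default_rng(seed)
    available = list(range(len(pool_canon)))
    chosen: list[str] = []
    for _ in range(n):
        a = int(rng.integers(len(act_list)))
        dist = (
            (pool_desc.iloc[available] - act_desc.iloc[a]).abs() / scale
        ).sum(axis=1).to_numpy()
        sims = np.array([tanimoto(act_fps[a], pool_fps[j]) for j in available])
        eligible = np.nonzero(sims < max_similarity)[0]
        if eligible.size == 0:
            raise DecoyError(
                f"no eligible decoys for active {act_list[a]!r}: "
                f"{len(available)} pool candidates all at Tanimoto >= {max_similarity}"
            )
        best = eligible[np.argmin(dist[eligible])]
        chosen.append(pool_canon[available[best]])
        available.pop(best)
    return [
        CuratedLigand(smiles=s, bioactivity=DECOY_BIOACTIVITY, n_measurements=1, is_decoy=True)
        for s in chosen
    ]


def augment_with_decoys(
    dataset: Sequence[CuratedLigand],
    pool: Sequence[str],
    decoy_fraction: float = 0.2,
    seed: int = 0,
    max_similarity: float = DEFAULT_MAX_SIMILARITY,
) -> list[CuratedLigand]:
    """Append round(decoy_fraction * |dataset|) decoys at bioactivity -1.

    Active labels are never altered; decoys carry ``is_decoy=True``.
    """
    n_decoys = round(decoy_fraction * len(dataset))
    decoys = generate_decoys(dataset, pool, n_decoys, seed=seed, max_similarity=max_similarity)
    return list(dataset) + decoys


def decoy_inflation_report(
    dataset: Sequence[CuratedLigand],
    pool: Sequence[str],
    run_pipeline: Callable[[Sequence[CuratedLigand], int], dict],
    decoy_fraction: float = 0.2,
    seed: int = 0,
) -> dict:
    """Run the identical pipeline with and without decoy augmentation.

    ``run_pipeline(dataset, seed)`` must return a dict of metric name ->
    value (e.g. a MetricsReport.to_dict()).  The plain run uses the same
    seed as the augmented run, so the only difference is the appended
    decoys; the signed deltas (augmented - plain) quantify the
    performance inflation decoys induce.
    """
    plain = run_pipeline(list(dataset), seed)
    augmented_data = augment_with_decoys(dataset, pool, decoy_fraction, seed=seed)
    augmented = run_pipeline(augmented_data, seed)
    delta = {
        key: (augmented[key] - plain[key])
        for key in plain
        if isinstance(plain[key], (int, float))
        and isinstance(augmented.get(key), (int, float))
    }
    return {"plain": plain, "augmented": augmented, "delta": delta}
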