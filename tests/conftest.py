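"""Shared fixtures: a small synthetic ligand study reused across modules.

Everything is generated programmatically with fixed seeds, so the suite
needs no data files and every run sees identical inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

from ligsig.curation import curate_dataset
from ligsig.descriptors import combined_feature_matrix
from ligsig.synth import GeneratorSpec, generate_ligand_library, simulate_bioactivity


@pytest.fixture(scope="session")
def small_spec() -> GeneratorSpec:
    return GeneratorSpec(n_molecules=60, seed=1)


@pytest.fixture(scope="session")
def small_library(small_spec) -> list[str]:
    return generate_ligand_library(small_spec)


@pytest.fixture(scope="session")
def small_records(small_spec, small_library):
    records, truth = simulate_bioactivity(small_library, small_spec)
    return records, truth


@pytest.fixture(scope="session")
def small_dataset(small_records):
    records, _truth = small_records
    return curate_dataset(records)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return combined_feature_matrix([lig.smiles for lig in small_dataset])


@pytest.fixture(scope="session")
def small_targets(small_dataset) -> np.ndarray:
    return np.asarray([lig.bioactivity for lig in small_dataset])
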