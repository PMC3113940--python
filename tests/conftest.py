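"""Shared fixtures: a small synthetic world reused across the suite.

Everything is generated at test time from seeds; nothing is read from
disk.  Session scope keeps the expensive pieces (potential derivation,
feature computation) to a single build.
"""

import warnings

import numpy as np
import pytest

from stabscan.structure import load_structure
from stabscan.synthetic import (make_ground_truth, make_toy_structure,
                                simulate_mutant_dataset)
from stabscan.training import build_design

# underdetermination warnings are expected for the deliberately tiny fits
warnings.filterwarnings("ignore", message="only .* records for .* active")


@pytest.fixture(scope="session")
def truth():
    """Ground-truth world: 3 toy structures × 30 residues, derived potentials."""
    return make_ground_truth(n_structures=3, n_residues=30, noise_sd=0.3, seed=11)


@pytest.fixture(scope="session")
def noisy_data(truth):
    """600 simulated mutants at noise sd 0.3 with their noiseless values."""
    return simulate_mutant_dataset(truth, n_mutants=600, seed=12)


@pytest.fixture(scope="session")
def noisy_design(truth, noisy_data):
    return build_design(noisy_data.records, truth.structures, truth.potentials)


@pytest.fixture(scope="session")
def helix30():
    return load_structure(make_toy_structure(30, "helix", seed=1),
                          structure_id="helix30")


@pytest.fixture(scope="session")
def mixed20():
    return load_structure(make_toy_structure(20, "mixed", seed=2),
                          structure_id="mixed20")


@pytest.fixture(scope="session")
def polyala_pdb():
    return make_toy_structure(5, "helix", seed=3, sequence="AAAAA")
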