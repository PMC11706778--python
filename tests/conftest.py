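"""Shared fixtures: toy designs and seeded synthetic studies."""

import time

import numpy as np
import pandas as pd
import pytest

from evfrac.calibration import compare_strategies
from evfrac.design import make_design
from evfrac.matrix import IntensityMatrix
from evfrac.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_design():
    """Three donors x fractions 1-8 (fraction 8 keeps two donors)."""
    return make_design(donors=("A", "B", "C"), fraction8_donors=("B", "C"))


@pytest.fixture(scope="session")
def tiny_design():
    """Two donors x fractions {1, 4, 7}: one sample pair per group."""
    return make_design(donors=("A", "B"), fractions=(1, 4, 7), fraction8_donors=())


def make_matrix(design, values, accessions=None, seed=None):
    values = np.asarray(values, dtype=float)
    if accessions is None:
        accessions = [f"P{i}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=pd.Index(accessions, name="accession"),
                         columns=design["sample"].to_list())
    return IntensityMatrix(values=frame, design=design)


@pytest.fixture(scope="session")
def reduced_study():
    """1,000-protein / 300-DEP study on the default study conditions."""
    config = SimulationConfig(n_proteins=1000, n_dep=300, seed=7)
    return simulate_study(config)


@pytest.fixture(scope="session")
def default_study():
    """Full-scale default study: 6,105 proteins, 61 samples, 3,000 DEPs."""
    return simulate_study(SimulationConfig())


@pytest.fixture(scope="session")
def default_benchmark(default_study):
    """Three-strategy benchmark on the full-scale study, with wall time."""
    start = time.monotonic()
    table = compare_strategies(default_study, cutoff=12.0, seed=2024)
    duration = time.monotonic() - start
    return table, duration
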