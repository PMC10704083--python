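"""Shared fixtures; the full-design datasets are session-scoped because
simulating and inverting 5040 scans takes a few seconds each."""

from __future__ import annotations

import pytest

from gasmas import AmbientConditions, LinePair, h2o_line_820, o2_line_764
from gasmas.inversion import invert_dataset
from gasmas.scan_synthesis import default_design, sample_truth, simulate_experiment
from gasmas.stats_qc import flag_outliers

#: Fixed seed for the reference datasets used across the suite.
SUITE_SEED = 20231


@pytest.fixture(scope="session")
def conditions() -> AmbientConditions:
    return AmbientConditions()


@pytest.fixture(scope="session")
def lines() -> LinePair:
    return LinePair(o2=o2_line_764(), h2o=h2o_line_820())


@pytest.fixture(scope="session")
def clean_run(conditions, lines):
    """Default design at default noise, no mixing bias: truth + estimates."""
    design = default_design()
    truth = sample_truth(design, SUITE_SEED, conditions=conditions)
    dataset = simulate_experiment(design, truth, master_seed=SUITE_SEED)
    estimates = flag_outliers(invert_dataset(dataset, conditions, lines))
    return design, truth, dataset, estimates


@pytest.fixture(scope="session")
def biased_run(conditions, lines):
    """Default design with beta=0.2 gas-mixing bias."""
    design = default_design()
    truth = sample_truth(design, SUITE_SEED, conditions=conditions)
    dataset = simulate_experiment(design, truth, beta=0.2, master_seed=SUITE_SEED + 1)
    estimates = flag_outliers(invert_dataset(dataset, conditions, lines))
    return design, truth, dataset, estimates
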