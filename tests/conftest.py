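"""Shared fixtures.

The expensive full-calibration run is session-scoped and reused by the
end-to-end and robustness tests; unit tests use small purpose-built
cohorts instead.
"""

from __future__ import annotations

import numpy as np
import pytest

from tpsdate.cli import RunConfig, run_calibrate
from tpsdate.synthetic_cohort import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort for unit-level checks (200 samples x 600 SNPs)."""
    spec = CohortSpec(n_samples=200, n_snps=600, n_families=4, seed=11)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def calibrated():
    """One full calibration on the default study conditions (seed 1)."""
    return run_calibrate(RunConfig(seed=1, log_level="WARNING"))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
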