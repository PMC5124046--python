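"""Shared fixtures: published group-level parameters and expensive
replicate-fit batches reused across tests."""

import numpy as np
import pytest

from hepamri import (AcquisitionSchedule, EMMParams, fit_emm,
                     normalize_curve, simulate_dce_curve)

# group-mean EMM parameters of the two cohorts
CONTROL_MEANS = dict(A=57100.0, alpha=0.20, beta=0.037, gamma=0.001, q=0.432)
CONA_MEANS = dict(A=67355.0, alpha=0.11, beta=0.021, gamma=0.004, q=0.380)


@pytest.fixture(scope="session")
def control_params() -> EMMParams:
    return EMMParams(**CONTROL_MEANS)


@pytest.fixture(scope="session")
def cona_params() -> EMMParams:
    return EMMParams(**CONA_MEANS)


@pytest.fixture(scope="session")
def schedule() -> AcquisitionSchedule:
    return AcquisitionSchedule()


@pytest.fixture(scope="session")
def replicate_fits(control_params, schedule):
    """50 seeded 1%-noise curves at the control group means, fitted once
    and shared by the recovery/bias tests."""
    fits = []
    for seed in range(50):
        curve = simulate_dce_curve(control_params, schedule,
                                   noise_sd=0.01, seed=seed)
        fits.append(fit_emm(normalize_curve(curve)))
    return fits


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160509)
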