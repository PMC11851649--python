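"""Shared fixtures: small synthetic cohorts and deterministic RNGs."""

import numpy as np
import pytest

from rnflcast import CohortConfig, generate_cohort, preprocess_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_noise_free_config(**overrides):
    """A degenerate generator config: no noise, no artifacts, no progression."""
    base = dict(
        n_patients=20,
        seed=2,
        noise_scale_um=0.0,
        missing_rate=0.0,
        spike_rate=0.0,
        slope_mean_by_diagnosis={"normal": 0.0, "suspect": 0.0, "glaucoma": 0.0},
        slope_sd_um_yr=0.0,
        wedge_probability=0.0,
        prob_bad_quality=0.0,
    )
    base.update(overrides)
    return CohortConfig(**base)


def make_progressing_noise_free_config(**overrides):
    """Noise-free but progressing: scans differ across visits, so derived
    rules like 2*input2 - input1 are genuine extrapolations."""
    base = dict(
        n_patients=20,
        seed=2,
        noise_scale_um=0.0,
        missing_rate=0.0,
        spike_rate=0.0,
        slope_mean_by_diagnosis={"normal": -0.5, "suspect": -1.0, "glaucoma": -2.0},
        slope_sd_um_yr=0.3,
        wedge_probability=0.0,
        floor_thickness_um=1.0,  # keep the decline linear over the study window
        prob_bad_quality=0.0,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-patient cohort with default (noisy, progressing) settings."""
    cohort, truth = generate_cohort(CohortConfig(n_patients=20, seed=1))
    return cohort, truth


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort):
    cohort, _ = small_cohort
    return preprocess_cohort(cohort)
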