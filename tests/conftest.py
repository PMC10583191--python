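"""Shared fixtures: small synthetic campaigns with known ground truth."""

import math

import numpy as np
import pytest

from phenoseason import synthetic_data as synth
from phenoseason import trajectory


def closed_form_crossing(truth, q: float) -> float:
    """Closed-form decline crossing day (independent re-derivation)."""
    return truth.m_true + math.log(q ** (-1.0 / truth.theta_true) - 1.0) / truth.s_true


@pytest.fixture(scope="session")
def noiseless_daily_dataset():
    """Three species, daily sampling, zero noise, theta in {0.3, 1, 3}."""
    cfg = synth.GenerationConfig(
        n_species=3,
        cadence_days=1,
        first_day=1,
        noise_cv=0.0,
        shoot_k_cv=0.0,
        shoots_per_species=2,
        rng_seed=5,
    )
    truths = synth.generate_species(cfg)
    for theta, t in zip([0.3, 1.0, 3.0], truths):
        t.theta_true = theta
    measurements = synth.render_measurements(
        truths, cfg, np.random.default_rng(1)
    )
    return cfg, truths, measurements


@pytest.fixture(scope="session")
def noiseless_series(noiseless_daily_dataset):
    _, truths, measurements = noiseless_daily_dataset
    series = trajectory.measurements_to_series(measurements)
    by_species = {}
    for s in series:
        by_species.setdefault(s.species_id, []).append(s)
    return truths, by_species


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """Four species at the default study conditions (biweekly, 5 % noise)."""
    cfg = synth.GenerationConfig(n_species=4, rng_seed=11)
    return (cfg, *synth.simulate_dataset(cfg))
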