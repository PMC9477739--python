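"""Shared fixtures: synthetic ensembles at the reference study conditions.

The expensive ensembles are session-scoped and reused across modules; all
seeds are fixed so the suite is deterministic.
"""

from __future__ import annotations

import pytest

import cortexflux as cf
from cortexflux.volume import VolumeModel

#: Seed for the reference bounded ensemble used by recovery tests.
BOUNDED_SEED = 2025


@pytest.fixture(scope="session")
def true_volume_model() -> VolumeModel:
    """Volume relation with the generator's true coefficients."""
    return VolumeModel(coefficients=cf.DEFAULT_VOLUME)


@pytest.fixture(scope="session")
def bounded_ensemble():
    """2,000-track control ensemble at the reference noise levels."""
    cfg = cf.GeneratorConfig(rng_seed=BOUNDED_SEED)
    table, truth = cf.generate_ensemble(cfg, n_condensates=2000)
    return table, truth


@pytest.fixture(scope="session")
def bounded_table(bounded_ensemble):
    return bounded_ensemble[0]


@pytest.fixture(scope="session")
def bounded_points(bounded_table):
    """Per-point central-difference rates for the bounded ensemble."""
    return cf.derivatives_table(bounded_table)


@pytest.fixture(scope="session")
def control_fit(bounded_points, true_volume_model):
    """Kinetic fit of the control ensemble (bootstrap errors included)."""
    return cf.fit_kinetics(bounded_points, true_volume_model, n_boot=60, rng_seed=11)


@pytest.fixture(scope="session")
def clean_ensemble():
    """Noise-free ensemble with completed life cycles (long horizon)."""
    cfg = cf.GeneratorConfig(
        intrinsic_noise_sd=0.0, obs_noise_sd=0.0, duration=600.0, rng_seed=4
    )
    table, truth = cf.generate_ensemble(cfg, n_condensates=200)
    return table, truth


@pytest.fixture(scope="session")
def clean_points(clean_ensemble):
    return cf.derivatives_table(clean_ensemble[0])


@pytest.fixture(scope="session")
def mild_table():
    cfg = cf.GeneratorConfig(
        params=cf.rnai_preset("mild"), rng_seed=2026, condition="mild"
    )
    return cf.generate_ensemble(cfg, n_condensates=1500)[0]


@pytest.fixture(scope="session")
def moderate_table():
    cfg = cf.GeneratorConfig(
        params=cf.rnai_preset("moderate"), rng_seed=2027, condition="moderate"
    )
    return cf.generate_ensemble(cfg, n_condensates=1500)[0]
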