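"""Shared fixtures: small synthetic images and cohorts."""

import numpy as np
import pytest

from tmahet import synth


@pytest.fixture(scope="session")
def clean_image_spec() -> synth.SyntheticImageSpec:
    """Noiseless, disjoint-cell image at desk scale."""
    return synth.SyntheticImageSpec(image_size=256, n_cells=10, seed=7)


@pytest.fixture(scope="session")
def clean_image(clean_image_spec):
    return synth.generate_image(clean_image_spec)


@pytest.fixture(scope="session")
def noisy_image():
    spec = synth.SyntheticImageSpec(
        image_size=256, n_cells=10, seed=11, noise_sigma=3.0
    )
    return synth.generate_image(spec)


@pytest.fixture(scope="session")
def ratio_cohort():
    """Cell-level ratio cohort with a planted prognostic fraction."""
    return synth.sample_ratio_cohort(
        40, 150, log_hazard_coef=1.5, seed=5
    )


def make_survival_data(
    seed: int, n: int = 100, p: int = 10, coef: float = 0.0, cens_scale: float = 3000.0
):
    """Feature matrix + survival with optional signal in column 0."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    risk = coef * X[:, 0]
    t_event = rng.exponential(1000.0 * np.exp(-risk)) + 1.0
    t_cens = rng.exponential(cens_scale, n) + 1.0
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return X, time, event
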