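"""Shared fixtures: small geometry/forward assets and synthetic helpers."""

import numpy as np
import pytest

from windeeg.forward import build_lead_field
from windeeg.geometry import build_atlas, build_source_space
from windeeg.synth import (
    ParticipantProfile,
    make_trial_schedule,
    simulate_recording,
)


@pytest.fixture(scope="session")
def small_space():
    """66-vertex-per-hemisphere source space (subdivision level 3)."""
    return build_source_space(3)


@pytest.fixture(scope="session")
def small_atlas(small_space):
    return build_atlas(small_space, seed=0)


@pytest.fixture(scope="session")
def small_forward(small_space):
    return build_lead_field(small_space)


@pytest.fixture(scope="session")
def mid_space():
    """258-vertex-per-hemisphere source space (subdivision level 4)."""
    return build_source_space(4)


@pytest.fixture(scope="session")
def mid_forward(mid_space):
    return build_lead_field(mid_space)


@pytest.fixture(scope="session")
def tiny_recording(small_space, small_atlas, small_forward):
    """One short session (8 trials) with the default profile, fixed seed."""
    schedule = make_trial_schedule(n_sessions=1, trials_per_session=8, seed=11)
    profile = ParticipantProfile(seed=11)
    return simulate_recording(
        schedule, profile, small_forward, small_atlas, small_space
    )


def make_gaussian_trials(
    n_per_class: int = 60,
    d_prime: float = 6.0,
    n_features: int = 24,
    n_informative: int = 4,
    seed: int = 0,
):
    """Two Gaussian classes separated by d' on the informative features.

    Returns (features, labels); the Bayes error of the generating model is
    Phi(-d'/2) per informative dimension combination, far below 5% at d'=6.
    """
    rng = np.random.default_rng(seed)
    shift = np.zeros(n_features)
    shift[:n_informative] = d_prime / np.sqrt(n_informative)
    x0 = rng.standard_normal((n_per_class, n_features))
    x1 = rng.standard_normal((n_per_class, n_features)) + shift
    x = np.vstack([x0, x1])
    y = np.repeat([0, 1], n_per_class)
    perm = rng.permutation(len(y))
    return x[perm], y[perm]


def make_labeled_set(
    n_trials: int = 160,
    delta: float = 2.0,
    informative_band: str = "alpha",
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """A synthetic LabeledTrialSet whose signal lives in one band's columns."""
    from windeeg.classify import LabeledTrialSet
    from windeeg.features import FEATURE_COLUMNS

    rng = np.random.default_rng(seed)
    velocities = np.tile([0.44, 1.0, 2.0, 4.0], n_trials // 4)
    labels = rng.integers(0, 2, size=n_trials)
    features = rng.normal(0.0, noise_sd, size=(n_trials, len(FEATURE_COLUMNS)))
    cols = [i for i, c in enumerate(FEATURE_COLUMNS) if c.endswith(f"_{informative_band}")]
    features[:, cols] += delta * labels[:, None]
    scores = np.where(labels == 1, 7.0, 3.0)
    return LabeledTrialSet(
        features=features,
        labels=labels,
        velocities=velocities,
        scores=scores,
        feature_names=FEATURE_COLUMNS,
    )
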