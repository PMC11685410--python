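"""Shared fixtures: small synthetic sessions and hand-built feature
matrices, generated at test time (nothing on disk)."""

from __future__ import annotations

import numpy as np
import pytest

from emgintent import (ProtocolSpec, SegmentationConfig, build_windowset,
                       default_separability, generate_recording,
                       extract_matrix, NAMED_SETS, REGISTRY)
from emgintent.features.matrix import FeatureMatrix


def make_session(n_channels=3, n_movements=3, n_reps=3, fs=2000.0, sep=2.0,
                 seed=11, rep_jitter=0.1):
    """Scaled synthetic session: full protocol timing, reduced size."""
    proto = ProtocolSpec(n_channels=n_channels, fs=fs,
                         n_movements=n_movements, n_reps=n_reps)
    model = default_separability(n_movements, n_channels, sep=sep, seed=seed,
                                 rep_jitter=rep_jitter)
    return generate_recording(proto, model, seed=seed)


@pytest.fixture(scope="session")
def small_recording():
    return make_session()


@pytest.fixture(scope="session")
def small_windowset(small_recording):
    return build_windowset(small_recording, SegmentationConfig())


@pytest.fixture(scope="session")
def cfs_matrix(small_windowset):
    """CFS feature columns of the small separable session (4 classes)."""
    return extract_matrix(small_windowset,
                          [REGISTRY[f] for f in NAMED_SETS["CFS"]])


def clouds_matrix(n_classes=3, n_per_class=50, n_features=4, spacing=10.0,
                  seed=0, feature_ids=None):
    """Well-separated Gaussian clouds as a FeatureMatrix (unit variance,
    centroids ``spacing`` sigma apart along distinct axes)."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        mu = np.zeros(n_features)
        mu[c % n_features] = spacing * (1 + c // n_features)
        X.append(mu + rng.standard_normal((n_per_class, n_features)))
        y.append(np.full(n_per_class, c))
    ids = feature_ids or [f"f{j}" for j in range(n_features)]
    cols = [(ids[j], "ch1", 0) for j in range(n_features)]
    return FeatureMatrix(values=np.vstack(X), columns=cols,
                         labels=np.concatenate(y))


@pytest.fixture(scope="session")
def separable_clouds():
    return clouds_matrix()
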