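"""Shared fixtures: a small simulated scene with samples and fitted models.

The scene is generated once per session at a reduced grid so classifier-
level tests can reuse features and fitted backends without repeating the
expensive steps.
"""

from __future__ import annotations

import numpy as np
import pytest

from lulcfuse.classify import predict_proba, stratified_split, train_backend
from lulcfuse.features import assemble_features
from lulcfuse.synthetic import (
    default_scene_config,
    sample_reference_points,
    simulate_scene,
)
from lulcfuse.types import default_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def small_scene():
    """A 96x96 default-condition scene: (config, cube, dem, truth)."""
    cfg = default_scene_config(seed=7, shape=(96, 96))
    cube, dem, truth = simulate_scene(cfg)
    return cfg, cube, dem, truth


@pytest.fixture(scope="session")
def labelled_samples(small_scene):
    """120 points/class with C3 features and a 70/30 split."""
    _, cube, dem, truth = small_scene
    samples = sample_reference_points(truth, 120, homogeneity_window=3, seed=11)
    samples.features = assemble_features(
        cube, dem, "C3", points=(samples.rows, samples.cols)
    )
    return stratified_split(samples, 0.7, seed=13)


@pytest.fixture(scope="session")
def member_models(labelled_samples, scheme):
    """RF/SVM/WKNN fitted on the shared training split (fast settings)."""
    train = labelled_samples.split_part("train")
    hp = {"rf": {"n_estimators": 150}}
    return {
        kind: train_backend(kind, train, hyperparams=hp.get(kind), seed=17, scheme=scheme)
        for kind in ("rf", "svm", "wknn")
    }


@pytest.fixture(scope="session")
def member_test_probs(member_models, labelled_samples, scheme):
    """Per-kind (n_test, M) probabilities on the shared test split."""
    test = labelled_samples.split_part("test")
    return {
        kind: predict_proba(model, test.features, scheme=scheme)
        for kind, model in member_models.items()
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
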