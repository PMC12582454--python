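"""Shared fixtures.

The expensive fixture is ``overfit_run``: one desk-scale training job on the
default synthetic texture dataset (8 classes x 40 images, width-reduced
model).  It is session-scoped and shared by the training-sanity,
Grad-CAM-localization and determinism tests so the model is trained exactly
once per session.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from rntnet.estimator import RNTNetClassifier
from rntnet.synth import SynthSpec, generate_arrays

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def texture_dataset():
    """Default synthetic fixture: 8 balanced classes of 40 images, 150 px."""
    return generate_arrays(SynthSpec(n_classes=8, per_class=40, seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def overfit_run(texture_dataset):
    """Desk-scale training run: reduced model (widths / 4, one encoder
    layer), up to 30 epochs, stopping once validation accuracy reaches 90%.

    Returns the fitted estimator.
    """
    x, y = texture_dataset
    est = RNTNetClassifier(preset="reduced", epochs=30, batch_size=16,
                           learning_rate=1e-3, val_fraction=0.2,
                           early_stop_acc=0.9, random_state=FIXTURE_SEED)
    est.fit(x, y)
    return est


@pytest.fixture
def rng():
    return np.random.default_rng(0)
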