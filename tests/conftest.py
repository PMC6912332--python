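"""Shared fixtures: phantom frames, cohorts, and a strongly separated
training set used by the CNN and cascade tests.

Everything is generated programmatically at session scope so the slow
pieces (phantom rendering, ROI extraction) run once.
"""

from __future__ import annotations

import numpy as np
import pytest

from thyrocascade.dataio import GrayImage
from thyrocascade.phantom import PhantomSpec, generate_cohort, generate_phantom
from thyrocascade.roi import extract_roi


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benign_phantom():
    return generate_phantom(PhantomSpec(seed=11, n_calcifications=0))


@pytest.fixture(scope="session")
def malign_phantom():
    return generate_phantom(PhantomSpec(seed=11, n_calcifications=12))


@pytest.fixture(scope="session")
def phantom_cohort_dir(tmp_path_factory):
    """20 + 20 phantom cohort on disk (manifest + PNGs + ground truth)."""
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(20, 20, out, seed=7)
    return out


@pytest.fixture(scope="session")
def separable_training_set():
    """40 ROI crops (20/20) with large, bright calcifications in every
    malign phantom — a strongly separated fixture for training tests."""
    data = []
    for i in range(20):
        for ncal in (0, 12):
            spec = PhantomSpec(seed=500 + i, n_calcifications=ncal,
                               calcification_radius=6,
                               calcification_spacing=18,
                               nodule_radius=70,
                               calcification_intensity=255.0)
            img, label, _ = generate_phantom(spec)
            data.append((extract_roi(img).cropped, label))
    return data


@pytest.fixture()
def random_image(rng):
    """Small random-texture image for spectral tests."""
    return GrayImage(rng.integers(0, 256, size=(24, 24)).astype(float))
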