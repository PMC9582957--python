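"""Shared fixtures: phantoms, image sets and a trained score regressor.

Heavy artifacts (the 1,000-image training set and its regressor, the
300-image validation sets) are session-scoped so the end-to-end and
ensemble tests reuse one computation.
"""

import warnings

import numpy as np
import pytest

import aacquant as aq
from aacquant.pipeline import train_pipeline_regressor

warnings.filterwarnings("ignore", message=".*collinear.*")


@pytest.fixture(scope="session")
def noise_free_phantom():
    """One noise-free phantom with deposits on several walls."""
    cfg = aq.PhantomConfig(coverage={
        ("L1", "anterior"): 0.2, ("L2", "posterior"): 0.4,
        ("L3", "anterior"): 0.5, ("L4", "posterior"): 0.8,
    }, seed=3).noise_free()
    return aq.generate_phantom(cfg)


@pytest.fixture(scope="session")
def noise_free_set():
    """300 noise-free phantoms with default shared geometry."""
    return aq.generate_image_set(300, aq.PhantomConfig().noise_free(), seed=11)


@pytest.fixture(scope="session")
def noisy_validation_set():
    """300 phantoms under the default noise model (held-out validation)."""
    return aq.generate_image_set(300, aq.PhantomConfig(), seed=12)


@pytest.fixture(scope="session")
def trained_regressor():
    """Pipeline-2 regressor trained on 1,000 noisy phantoms."""
    train = aq.generate_image_set(1000, aq.PhantomConfig(), seed=100)
    return train_pipeline_regressor(train, seed=0)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, n=5,000."""
    return aq.generate_cohort(5000, seed=42)


def label_mask(gt):
    """Ground-truth label mask in the segmentation convention."""
    m = np.zeros(gt.vertebra_mask.shape, np.uint8)
    m[gt.pelvis_mask] = 1
    m[gt.vertebra_mask] = 2
    return m
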