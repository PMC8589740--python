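"""Shared fixtures: phantoms are generated programmatically at test time."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from ctnq.phantom import CohortSampler, PhantomSpec, make_cohort, make_phantom

logging.getLogger("ctnq").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def phantom_clean():
    """Noise-free phantom with mixed severities (deterministic geometry)."""
    return make_phantom(
        PhantomSpec(noise_sd=0.0, mta_left=2.0, mta_right=1.0, gca=1.5, fazekas=2.0)
    )


@pytest.fixture(scope="session")
def phantom_noisy():
    """Default-noise phantom with a small rigid pose."""
    return make_phantom(
        PhantomSpec(
            mta_left=1.5, mta_right=2.5, gca=1.0, fazekas=1.5,
            rng_seed=3, pose=(1.0, -2.0, 0.5, 3.0, -4.0, 2.0),
        )
    )


@pytest.fixture(scope="session")
def template_skull_mask():
    """Binary skull mask of the canonical (identity-pose) geometry."""
    pair = make_phantom(PhantomSpec(noise_sd=0.0))
    return pair.labels.like((pair.labels.data == 1).astype(np.uint8))


@pytest.fixture(scope="session")
def aligned_cohort():
    """Small aligned (identity-pose) cohort for segmenter tests."""
    return make_cohort(5, CohortSampler(randomize_pose=False), seed=7)
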