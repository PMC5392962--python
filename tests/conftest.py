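"""Shared fixtures: small phantoms and cohorts generated at test time."""

import numpy as np
import pytest

import mammoquad as mq


def small_phantom_spec(view="CC", size=160, noise_sd=4.0, seed=0, **kw):
    """A compact phantom spec that keeps FCM runs fast in unit tests."""
    defaults = dict(
        view=view,
        image_height=size,
        image_width=size,
        breast_semi_axes=(int(0.43 * size), int(0.62 * size)),
        n_dense_blobs=5,
        blob_radius_range=(4, 9),
        noise_sd=noise_sd,
        seed=seed,
    )
    defaults.update(kw)
    return mq.PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def cc_phantom_noiseless():
    return mq.generate_phantom(small_phantom_spec("CC", noise_sd=0.0, seed=3))


@pytest.fixture(scope="session")
def mlo_phantom_noiseless():
    return mq.generate_phantom(small_phantom_spec("MLO", noise_sd=0.0, seed=4))


@pytest.fixture(scope="session")
def cc_phantom_noisy():
    return mq.generate_phantom(small_phantom_spec("CC", noise_sd=4.0, seed=5))


@pytest.fixture(scope="session")
def mlo_phantom_noisy():
    return mq.generate_phantom(small_phantom_spec("MLO", noise_sd=4.0, seed=6))


@pytest.fixture(scope="session")
def default_cohort():
    """110 women at the default study conditions."""
    return mq.generate_cohort(mq.CohortSpec(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
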