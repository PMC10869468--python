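import numpy as np
import pytest

from pituseg.phantom import PhantomSpec, make_cohort, make_phantom
from pituseg.volume_io import LabelMask, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def mask_from_points(shape, points, spacing=(1.0, 1.0, 1.0)) -> LabelMask:
    data = np.zeros(shape, dtype=np.uint8)
    for p in points:
        data[tuple(p)] = 1
    return LabelMask(data=data, spacing=spacing)


@pytest.fixture(scope="session")
def tiny_spec():
    """A 16^3 phantom spec with an 8^3 patch, for fast training tests."""
    return PhantomSpec(
        shape=(16, 16, 16),
        head_semiaxes=(6.0, 6.5, 6.0),
        pg_center=(8.0, 8.5, 8.0),
        pg_center_jitter_sd=0.5,
        pg_semiaxes=(2.5, 2.0, 2.0),
        pg_contrast=80.0,
        noise_sd=5.0,
        patch_size=8,
        volume_base_mm3=40.0,
        volume_age_slope=-0.1,
        volume_sex_offset=-5.0,
        volume_noise_sd=2.0,
    )


@pytest.fixture(scope="session")
def phantom_pair():
    """One default-spec phantom (volume, mask, truth)."""
    return make_phantom(PhantomSpec(), rng=42)


@pytest.fixture(scope="session")
def small_cohort():
    """Six rendered default-grid phantoms with covariates."""
    return make_cohort(PhantomSpec(n_subjects=6, n_male=3, seed=11))
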