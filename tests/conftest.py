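import numpy as np
import pytest

from twdfc_parcel import PhantomSpec, WindowSpec, generate_cohort, generate_phantom
from twdfc_parcel.imaging import VolumeGrid


@pytest.fixture
def unit_grid():
    """1 mm isotropic grid with identity affine."""
    return VolumeGrid((8, 8, 8), np.eye(4))


@pytest.fixture(scope="session")
def small_spec():
    """A reduced phantom for unit tests (fast to generate)."""
    return PhantomSpec(
        grid_shape=(16, 16, 12),
        streamlines_per_bundle=60,
        n_subjects=4,
        n_timepoints=160,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_subject(small_spec):
    return generate_phantom(small_spec, 0)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_window():
    return WindowSpec(20)


def random_polyline(rng, n_points=5, scale=4.0, offset=2.0):
    pts = offset + np.cumsum(rng.uniform(-1, 1, size=(n_points, 3)), axis=0)
    return np.clip(pts * scale / n_points, 0.2, None)
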