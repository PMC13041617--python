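import numpy as np
import pytest

from sertquant import (
    Ellipsoid,
    PhantomSpec,
    Slab,
    build_label_volume,
    default_phantom_spec,
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Compact phantom (24^3 at 2 mm) for loop-oracle tests."""
    geometry = {
        "occipital": (Slab((8.0, 4.0, 10.0), (38.0, 14.0, 36.0)),),
        "midbrain": (Ellipsoid((24.0, 30.0, 32.0), (6.0, 6.0, 5.0)),),
        "pons": (Ellipsoid((24.0, 30.0, 20.0), (7.0, 7.0, 6.0)),),
        "striatum": (Ellipsoid((6.0, 36.0, 36.0), (4.0, 5.0, 4.0)),),
    }
    activity = {
        "background": 1.0,
        "occipital": 1.0,
        "midbrain": 2.7,
        "pons": 2.2,
        "striatum": 4.0,
    }
    return PhantomSpec(
        grid_shape=(24, 24, 24),
        voxel_size=(2.0, 2.0, 2.0),
        region_geometry=geometry,
        region_activity=activity,
        psf_fwhm=0.0,
        counts_scale=100.0,
    )


@pytest.fixture(scope="session")
def small_masks(small_spec):
    labels, masks = build_label_volume(small_spec)
    return labels, masks


@pytest.fixture(scope="session")
def default_masks():
    spec = default_phantom_spec()
    labels, masks = build_label_volume(spec)
    return spec, labels, masks


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
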