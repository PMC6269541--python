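import numpy as np
import pytest

from dxblink import BraggRing, DetectorGeometry, build_ring_mask


@pytest.fixture(scope="session")
def compact_geometry() -> DetectorGeometry:
    """Small square detector with the full Au(111) ring visible at ~44 px."""
    return DetectorGeometry(
        wavelength_nm=0.11,
        distance_mm=15.0,
        pixel_size_mm=0.172,
        n_rows=120,
        n_cols=120,
        beam_center=(59.5, 59.5),
    )


@pytest.fixture(scope="session")
def gapped_geometry() -> DetectorGeometry:
    """Same detector with a horizontal intermodular gap crossing the ring."""
    return DetectorGeometry(
        wavelength_nm=0.11,
        distance_mm=15.0,
        pixel_size_mm=0.172,
        n_rows=120,
        n_cols=120,
        beam_center=(59.5, 59.5),
        gap_regions=((55, 65, 0, 120),),
    )


@pytest.fixture(scope="session")
def compact_ring(compact_geometry) -> BraggRing:
    return BraggRing.from_geometry(compact_geometry, radial_halfwidth_px=2.0)


@pytest.fixture(scope="session")
def compact_mask(compact_geometry, compact_ring):
    return build_ring_mask(compact_geometry, compact_ring, background_annulus=(50.0, 56.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
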