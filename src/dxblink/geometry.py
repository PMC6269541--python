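"""Detector and Bragg-ring geometry.

Maps wavelength and lattice spacing to the Debye ring position on a flat
photon-counting detector, and partitions detector pixels into on-ring,
background-annulus and excluded (module-gap / out-of-band) classes.

Conventions
-----------
Pixel indices are 0-based ``(row, col)``; continuous coordinates refer to
pixel centers.  The azimuth ``chi`` is measured from the +col axis,
increasing toward +row (counter-clockwise when (row, col) is read as a
right-handed (y, x) pair), and lies in (-pi, pi].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyMaskError, GeometryError, ReflectionInaccessibleError

# Gold (111): cubic lattice constant 0.40782 nm / sqrt(3).
DEFAULT_AU111_D_NM = 0.2355

# Mask codes used in memory and in exported mask images.
MASK_EXCLUDED = 0
MASK_ON_RING = 1
MASK_BACKGROUND = 2


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat 2D photon-counting detector plus beam parameters.

    gap_regions are half-open pixel-index rectangles
    ``(row_start, row_stop, col_start, col_stop)`` excluded from all
    analyses (detector intermodular spaces).  The beam center may lie off
    the active area: only the ring arc crossing the detector is used.
    """

    wavelength_nm: float
    distance_mm: float
    pixel_size_mm: float
    n_rows: int
    n_cols: int
    beam_center: tuple[float, float]
    gap_regions: tuple[tuple[int, int, int, int], ...] = ()
    d_spacing_nm: float = DEFAULT_AU111_D_NM

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise GeometryError("wavelength must be positive")
        if self.distance_mm <= 0:
            raise GeometryError("sample-to-detector distance must be positive")
        if self.pixel_size_mm <= 0:
            raise GeometryError("pixel size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("detector must have at least one pixel")
        for r0, r1, c0, c1 in self.gap_regions:
            if not (0 <= r0 <= r1 <= self.n_rows and 0 <= c0 <= c1 <= self.n_cols):
                raise GeometryError(f"gap region {(r0, r1, c0, c1)} outside detector bounds")

    def gap_mask(self) -> np.ndarray:
        """Boolean (n_rows, n_cols) array, True on intermodular-gap pixels."""
        gaps = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        for r0, r1, c0, c1 in self.gap_regions:
            gaps[r0:r1, c0:c1] = True
        return gaps

    def radial_px(self) -> np.ndarray:
        """Radial distance (px) of every pixel center from the beam center."""
        rows = np.arange(self.n_rows, dtype=float)[:, None] - self.beam_center[0]
        cols = np.arange(self.n_cols, dtype=float)[None, :] - self.beam_center[1]
        return np.hypot(rows, cols)


def bragg_angle(wavelength_nm: float, d_spacing_nm: float) -> float:
    """Scattering angle 2*theta (rad) from the Bragg law lambda = 2 d sin(theta).

    Raises ReflectionInaccessibleError when ``wavelength >= 2 d`` (the
    reflection cannot be excited at this wavelength).
    """
    if wavelength_nm <= 0 or d_spacing_nm <= 0:
        raise GeometryError("wavelength and d-spacing must be positive")
    s = wavelength_nm / (2.0 * d_spacing_nm)
    if s >= 1.0:
        raise ReflectionInaccessibleError(
            f"lambda={wavelength_nm} nm >= 2d={2 * d_spacing_nm} nm: reflection inaccessible"
        )
    return 2.0 * math.asin(s)


def ring_radius(geometry: DetectorGeometry, two_theta: float) -> tuple[float, float]:
    """Debye-ring radius on the flat detector: ``(radius_mm, radius_px)``.

    radius_mm = L * tan(2 theta) for sample-to-detector distance L.
    """
    if not 0.0 < two_theta < math.pi / 2:
        raise GeometryError(f"2theta={two_theta} rad outside (0, pi/2)")
    radius_mm = geometry.distance_mm * math.tan(two_theta)
    return radius_mm, radius_mm / geometry.pixel_size_mm


@dataclass(frozen=True)
class BraggRing:
    """One powder reflection projected onto the detector."""

    d_spacing_nm: float
    two_theta: float
    radius_mm: float
    radius_px: float
    radial_halfwidth_px: float = 1.0

    @classmethod
    def from_geometry(
        cls,
        geometry: DetectorGeometry,
        d_spacing_nm: float | None = None,
        radial_halfwidth_px: float = 1.0,
    ) -> "BraggRing":
        d = geometry.d_spacing_nm if d_spacing_nm is None else d_spacing_nm
        tt = bragg_angle(geometry.wavelength_nm, d)
        r_mm, r_px = ring_radius(geometry, tt)
        return cls(d, tt, r_mm, r_px, radial_halfwidth_px)


@dataclass
class RingMask:
    """Partition of detector pixels into on-ring / background / excluded.

    ``codes`` is an (n_rows, n_cols) int8 image with values MASK_EXCLUDED,
    MASK_ON_RING, MASK_BACKGROUND; the three classes are pairwise disjoint
    and cover the detector.
    """

    codes: np.ndarray
    ring: BraggRing | None = None
    counts: dict = field(default_factory=dict)

    @property
    def on_ring(self) -> np.ndarray:
        """(n, 2) array of on-ring pixel indices in row-major order."""
        return np.argwhere(self.codes == MASK_ON_RING)

    @property
    def background(self) -> np.ndarray:
        return np.argwhere(self.codes == MASK_BACKGROUND)

    @property
    def excluded(self) -> np.ndarray:
        return np.argwhere(self.codes == MASK_EXCLUDED)


def build_ring_mask(
    geometry: DetectorGeometry,
    ring: BraggRing,
    background_annulus: tuple[float, float] | None = None,
) -> RingMask:
    """Classify every pixel by radial distance from the beam center.

    On-ring: ``|r - radius_px| <= radial_halfwidth_px``.  Background: the
    annulus ``inner_px <= r <= outer_px`` (radii from the beam center),
    which must not overlap the on-ring band.  Intermodular-gap pixels are
    always excluded, whatever band they fall in; everything else out of
    band is excluded too.  Partial arcs are accepted; an arc entirely off
    the active area raises EmptyMaskError.
    """
    r = geometry.radial_px()
    on = np.abs(r - ring.radius_px) <= ring.radial_halfwidth_px
    codes = np.zeros(r.shape, dtype=np.int8)
    codes[on] = MASK_ON_RING
    if background_annulus is not None:
        inner, outer = background_annulus
        if inner > outer:
            raise GeometryError("background annulus inner radius exceeds outer")
        band_lo = ring.radius_px - ring.radial_halfwidth_px
        band_hi = ring.radius_px + ring.radial_halfwidth_px
        if inner <= band_hi and outer >= band_lo:
            raise GeometryError("background annulus overlaps the on-ring band")
        bg = (r >= inner) & (r <= outer)
        codes[bg] = MASK_BACKGROUND
    gaps = geometry.gap_mask()
    codes[gaps] = MASK_EXCLUDED
    counts = {
        "on_ring": int(np.count_nonzero(codes == MASK_ON_RING)),
        "background": int(np.count_nonzero(codes == MASK_BACKGROUND)),
        "excluded": int(np.count_nonzero(codes == MASK_EXCLUDED)),
    }
    if counts["on_ring"] == 0:
        raise EmptyMaskError("ring arc does not intersect the active detector area")
    return RingMask(codes=codes, ring=ring, counts=counts)


def pixel_to_angles(
    geometry: DetectorGeometry, pixel: tuple[float, float]
) -> tuple[float, float]:
    """Scattering angle and azimuth ``(two_theta, chi)`` of a pixel center.

    two_theta = arctan(r * pixel_size / L); chi = atan2(d_row, d_col) in
    (-pi, pi].  The beam-center pixel itself maps to (0, 0) by convention.
    """
    drow = pixel[0] - geometry.beam_center[0]
    dcol = pixel[1] - geometry.beam_center[1]
    r_px = math.hypot(drow, dcol)
    if r_px == 0.0:
        return 0.0, 0.0
    two_theta = math.atan2(r_px * geometry.pixel_size_mm, geometry.distance_mm)
    return two_theta, math.atan2(drow, dcol)


def ring_point(
    geometry: DetectorGeometry, radius_px: float, chi: float
) -> tuple[float, float]:
    """Continuous (row, col) of the ring point at azimuth chi (inverse of
    pixel_to_angles for a point at the given radius)."""
    return (
        geometry.beam_center[0] + radius_px * math.sin(chi),
        geometry.beam_center[1] + radius_px * math.cos(chi),
    )
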