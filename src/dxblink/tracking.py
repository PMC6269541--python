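"""Classical diffracted-X-ray-tracking (DXT) branch.

Diffraction spots are detected frame by frame on the Bragg ring, linked
into trajectories by nearest-neighbour assignment, and their motion is
converted to angular displacements on the detector.  Displacement
histograms at each time interval are fitted with a zero-mean Gaussian;
the variance growth gives the mean squared angular displacement, and a
zero-offset fit of MSD = 4 D t yields the angular diffusion constant D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .geometry import MASK_ON_RING, DetectorGeometry, RingMask, pixel_to_angles

MIN_GAUSS_SAMPLES = 20


@dataclass
class Spot:
    frame: int
    centroid: tuple[float, float]      # continuous (row, col)
    angles: tuple[float, float]        # (two_theta, chi) rad
    intensity: float                   # summed counts


@dataclass
class Track:
    """Frame-ordered spot list; frame indices are consecutive (no gaps)."""

    id: int
    spots: list[Spot] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.spots)


@dataclass
class DisplacementSet:
    interval_s: float
    samples: np.ndarray                # signed angular displacements, rad


@dataclass
class MSDCurve:
    lags_s: np.ndarray
    msd: np.ndarray                    # rad^2


@dataclass
class DiffusionFit:
    D: float                           # rad^2/s
    se_D: float
    clipped: bool = False


def detect_spots(
    frame: np.ndarray,
    mask: RingMask,
    min_intensity: float,
    min_pixels: int = 1,
) -> list[Spot]:
    """Connected components of on-ring pixels above threshold.

    Connectivity is 8-neighbour but never crosses excluded (gap) pixels;
    centroids are intensity-weighted; components smaller than
    ``min_pixels`` are discarded.  Geometry for the angle conversion is
    attached later by the caller via pixel_to_angles.
    """
    if min_intensity <= 0 or min_pixels <= 0:
        raise ValueError("detection thresholds must be positive")
    candidate = (mask.codes == MASK_ON_RING) & (frame >= min_intensity)
    labels, n = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
    spots: list[Spot] = []
    for lbl in range(1, n + 1):
        idx = np.argwhere(labels == lbl)
        if len(idx) < min_pixels:
            continue
        w = frame[idx[:, 0], idx[:, 1]].astype(float)
        total = w.sum()
        r = float(np.dot(w, idx[:, 0]) / total)
        c = float(np.dot(w, idx[:, 1]) / total)
        spots.append(Spot(frame=-1, centroid=(r, c), angles=(0.0, 0.0), intensity=float(total)))
    return spots


def _attach(spots: list[Spot], frame_index: int, geometry: DetectorGeometry) -> list[Spot]:
    for s in spots:
        s.frame = frame_index
        s.angles = pixel_to_angles(geometry, s.centroid)
    return spots


def detect_all(
    stack_counts: np.ndarray,
    mask: RingMask,
    geometry: DetectorGeometry,
    min_intensity: float,
    min_pixels: int = 1,
) -> list[list[Spot]]:
    """Per-frame spot lists for a whole stack."""
    return [
        _attach(detect_spots(stack_counts[f], mask, min_intensity, min_pixels), f, geometry)
        for f in range(stack_counts.shape[0])
    ]


def link_tracks(spots_per_frame: Sequence[list[Spot]], max_step_px: float) -> list[Track]:
    """Greedy smallest-distance-first linking between consecutive frames.

    Candidate pairs are sorted by distance (exact ties broken by row-major
    order of the previous spot, then of the new spot); pairs farther than
    ``max_step_px`` stay unlinked; unmatched spots start new tracks.
    Deterministic given the input order.
    """
    if max_step_px <= 0:
        raise ValueError("max_step_px must be positive")
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    next_id = 0
    for spots in spots_per_frame:
        pairs = []
        for i, tr in enumerate(open_tracks):
            prev = tr.spots[-1].centroid
            for j, sp in enumerate(spots):
                d = math.hypot(prev[0] - sp.centroid[0], prev[1] - sp.centroid[1])
                if d <= max_step_px:
                    pairs.append((d, prev, sp.centroid, i, j))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_tr: set[int] = set()
        used_sp: set[int] = set()
        assigned: dict[int, int] = {}
        for d, _, _, i, j in pairs:
            if i in used_tr or j in used_sp:
                continue
            used_tr.add(i)
            used_sp.add(j)
            assigned[j] = i
        new_open: list[Track] = []
        for j, sp in enumerate(spots):
            if j in assigned:
                tr = open_tracks[assigned[j]]
                tr.spots.append(sp)
                new_open.append(tr)
            else:
                tr = Track(id=next_id, spots=[sp])
                next_id += 1
                tracks.append(tr)
                new_open.append(tr)
        open_tracks = new_open  # unmatched previous tracks terminate (no gap memory)
    return tracks


def _wrap(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap to (-pi, pi]."""
    return -((-np.asarray(angle) + math.pi) % (2.0 * math.pi) - math.pi)


def angular_displacements(
    tracks: Sequence[Track],
    frame_interval: float,
    intervals: Sequence[int],
    axis_mode: str = "both",
) -> dict[int, DisplacementSet]:
    """Signed angular displacements pooled per lag interval.

    For every spot pair exactly ``dn`` frames apart within one track the
    azimuthal displacement d(chi) and the radial angular displacement
    d(two_theta)/2 are emitted.  ``axis_mode`` selects which axes are
    pooled: "both" (default), "chi" or "theta" — with a monochromatic
    beam the rendered spot moves only azimuthally, in which case the
    chi-only mode is the consistent estimator.
    """
    if axis_mode not in ("both", "chi", "theta"):
        raise ValueError("axis_mode must be 'both', 'chi' or 'theta'")
    out: dict[int, DisplacementSet] = {}
    for dn in intervals:
        samples: list[float] = []
        for tr in tracks:
            for i in range(len(tr.spots) - dn):
                a0 = tr.spots[i].angles
                a1 = tr.spots[i + dn].angles
                if axis_mode in ("both", "theta"):
                    samples.append((a1[0] - a0[0]) / 2.0)
                if axis_mode in ("both", "chi"):
                    samples.append(float(_wrap(a1[1] - a0[1])))
        out[dn] = DisplacementSet(interval_s=dn * frame_interval,
                                  samples=np.asarray(samples, dtype=float))
    return out


def fit_gaussian_sigma(samples: np.ndarray) -> tuple[float, float, bool]:
    """Zero-mean Gaussian width from a displacement histogram.

    Bins follow a Freedman-Diaconis-style width 2*IQR*n^(-1/3) with at
    least 8 bins; amplitude and sigma are fitted by least squares on bin
    centers with the mean fixed at zero.  Returns (sigma, stderr, ok);
    degenerate all-equal samples yield (0, 0, False).
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < MIN_GAUSS_SAMPLES:
        raise ValueError(f"need >= {MIN_GAUSS_SAMPLES} samples, got {len(x)}")
    if np.ptp(x) == 0.0:
        return 0.0, 0.0, False
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    width = 2.0 * iqr * len(x) ** (-1.0 / 3.0)
    span = x.max() - x.min()
    n_bins = max(8, int(math.ceil(span / width)) if width > 0 else 8)
    hist, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(t, a, sigma):
        return a * np.exp(-(t**2) / (2.0 * sigma**2))

    p0 = (float(hist.max()), float(x.std()) or span / 4.0)
    try:
        popt, pcov = curve_fit(model, centers, hist, p0=p0, maxfev=10_000)
    except RuntimeError:
        return float(x.std()), float("nan"), False
    sigma = abs(float(popt[1]))
    se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    return sigma, se, True


def msd_and_diffusion(
    sigmas: dict[float, float], max_points: int = 5
) -> tuple[MSDCurve, DiffusionFit]:
    """MSD curve and angular diffusion constant from per-interval widths.

    ``sigmas`` maps lag (s) to the fitted 1-D Gaussian sigma (rad).  The
    MSD is 2*sigma^2 (pooled per-axis variance 2 D t gives MSD = 4 D t
    for two-angle diffusion); a least-squares line through the origin
    over the first ``max_points`` intervals gives slope 4 D.  A negative
    slope is clipped to D = 0 and flagged.
    """
    if len(sigmas) < 3:
        raise ValueError("need at least 3 intervals for an MSD fit")
    lags = np.array(sorted(sigmas))
    msd = np.array([2.0 * sigmas[t] ** 2 for t in lags])
    n = min(max_points, len(lags))
    x, y = lags[:n], msd[:n]
    sxx = float(np.dot(x, x))
    slope = float(np.dot(x, y)) / sxx
    resid = y - slope * x
    dof = max(n - 1, 1)
    se_slope = math.sqrt(float(np.dot(resid, resid)) / dof / sxx)
    clipped = slope < 0
    d = max(slope, 0.0) / 4.0
    return MSDCurve(lags_s=lags, msd=msd), DiffusionFit(D=d, se_D=se_slope / 4.0, clipped=clipped)


def relative_motion(d_a: float, d_b: float) -> float:
    """Relative motion amplitude between two states, sqrt(D_a / D_b).

    D has dimensions rad^2/s, so the ratio of angular excursion amplitudes
    at matched times is the square root of the diffusion-constant ratio.
    """
    if d_a < 0 or d_b <= 0:
        raise ValueError("diffusion constants must be positive")
    return math.sqrt(d_a / d_b)


def dxt_pipeline(
    stack_counts: np.ndarray,
    mask: RingMask,
    geometry: DetectorGeometry,
    frame_interval: float,
    min_intensity: float,
    max_step_px: float,
    intervals: Sequence[int] = (1, 2, 3, 4, 5),
    min_pixels: int = 1,
    axis_mode: str = "both",
) -> tuple[list[Track], MSDCurve, DiffusionFit]:
    """detect -> link -> displacements -> Gaussian widths -> MSD -> D."""
    per_frame = detect_all(stack_counts, mask, geometry, min_intensity, min_pixels)
    tracks = link_tracks(per_frame, max_step_px)
    disp = angular_displacements(tracks, frame_interval, intervals, axis_mode)
    sigmas: dict[float, float] = {}
    for dn in intervals:
        ds = disp[dn]
        if len(ds.samples) < MIN_GAUSS_SAMPLES:
            continue
        sigma, _, ok = fit_gaussian_sigma(ds.samples)
        if ok:
            sigmas[ds.interval_s] = sigma
    curve, fit = msd_and_diffusion(sigmas)
    return tracks, curve, fit
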