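"""Rotational-Brownian blinking simulator.

Nanocrystals carry a (111) plane normal that undergoes rotational Brownian
motion; diffraction is emitted only while the normal lies close to the
Bragg condition, so each crystal's diffraction spot blinks in and out with
a correlation time set by the angular diffusion constant D and the width
of the rocking (acceptance) curve.  The simulator renders full detector
frame stacks (Poisson photon counting, module gaps, configurable spot
footprint) and also offers a fast per-pixel trajectory path that skips
imaging.  A deterministic goniometer-scan mode sweeps the rocking offset
at a known angular speed for decay-constant calibration.

Geometry of the internal model: the beam runs along +x.  A normal at
polar angle pi/2 + theta from the beam satisfies the Bragg condition for
scattering angle 2*theta; the rocking deviation alpha is the (signed)
departure of the polar angle from that cone, and the azimuth of the
normal about the beam sets the azimuth chi of the diffraction spot on the
Debye ring.  Rotating in azimuth therefore moves the spot along the ring
without dimming it, while rocking misorientation suppresses the
diffracted intensity through a Gaussian acceptance of width
``rocking_sigma``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.constants import k as BOLTZMANN
from scipy.spatial.transform import Rotation

from .acf import IntensityTrajectory
from .errors import ConfigError, EmptyMaskError
from .geometry import BraggRing, DetectorGeometry, ring_point


@dataclass
class Crystallite:
    """A nanocrystal: current (111) normal direction in the lab frame and
    its angular diffusion constant (rad^2/s)."""

    normal: np.ndarray
    D: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if not math.isclose(n, 1.0, rel_tol=1e-9):
            raise ConfigError("crystallite normal must be a unit vector")
        if self.D < 0:
            raise ConfigError("angular diffusion constant must be nonnegative")


@dataclass
class SimConfig:
    """Simulation conditions.

    Timing defaults follow the synchrotron acquisition used for the
    temperature series: 1.0 s exposure per frame, 1.85 s frame interval,
    1000-frame records.  The default D is the ligand-free AChBP angular
    diffusion constant (3.78e-3 rad^2/s); ``temperature``, ``viscosity``
    and ``hydrodynamic_radius`` may be given instead to derive D from the
    Stokes-Einstein-Debye relation.  ``scan_speed`` > 0 switches to the
    deterministic goniometer sweep.
    """

    n_crystallites: int = 10
    D: float | None = 3.78e-3
    temperature: float | None = None          # K
    viscosity: float | None = None            # Pa s
    hydrodynamic_radius: float | None = None  # m
    rocking_sigma: float = 2e-3               # rad, Gaussian acceptance sigma
    peak_rate: float = 200.0                  # photons/s per crystallite at Bragg
    background_rate: float = 1.0              # photons/s per pixel
    n_frames: int = 1000
    exposure: float = 1.0                     # s
    frame_interval: float = 1.85              # s
    substeps_per_frame: int = 10
    scan_speed: float = 0.0                   # rad/s; 0 = Brownian mode
    scan_halfwidth: float | None = None       # rad; default 3 * rocking_sigma
    initial_offset: float = 0.0               # rad, rocking offset at t=0
    init_spread: float = 0.0                  # rad, uniform initial rocking spread
    misorientation_bound: float | None = None # rad, reflecting rocking bound
    footprint_sigma_px: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D is None:
            if None in (self.temperature, self.viscosity, self.hydrodynamic_radius):
                raise ConfigError("give D or the full temperature/viscosity/radius triple")
            self.D = sed_diffusion(self.temperature, self.viscosity, self.hydrodynamic_radius)
        if self.D < 0:
            raise ConfigError("D must be nonnegative")
        if self.rocking_sigma <= 0:
            raise ConfigError("rocking_sigma must be positive")
        if self.peak_rate < 0 or self.background_rate < 0:
            raise ConfigError("rates must be nonnegative")
        if self.exposure <= 0 or self.frame_interval <= 0:
            raise ConfigError("exposure and frame_interval must be positive")
        if self.exposure > self.frame_interval:
            raise ConfigError("exposure must not exceed the frame interval")
        if self.substeps_per_frame < 1:
            raise ConfigError("substeps_per_frame must be >= 1")
        if self.n_frames < 1 or self.n_crystallites < 1:
            raise ConfigError("n_frames and n_crystallites must be >= 1")
        if self.scan_speed < 0:
            raise ConfigError("scan_speed must be nonnegative")
        if self.scan_halfwidth is None:
            self.scan_halfwidth = 3.0 * self.rocking_sigma


@dataclass
class FrameStack:
    """Time-ordered photon-count images with acquisition timing metadata."""

    counts: np.ndarray                 # (n_frames, n_rows, n_cols) uint32
    timestamps: np.ndarray             # s, strictly increasing
    frame_interval: float
    exposure: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ConfigError("counts must be (n_frames, n_rows, n_cols)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ConfigError("counts must be integral")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ConfigError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]


# ---------------------------------------------------------------------------
# Elementary physics
# ---------------------------------------------------------------------------

def sed_diffusion(temperature: float, viscosity: float, radius: float) -> float:
    """Stokes-Einstein-Debye rotational diffusion constant,
    D = k_B T / (8 pi eta r^3), in rad^2/s."""
    if temperature <= 0 or viscosity <= 0 or radius <= 0:
        raise ConfigError("temperature, viscosity and radius must be positive")
    return BOLTZMANN * temperature / (8.0 * math.pi * viscosity * radius**3)


def rotate_step(orientation: np.ndarray, D: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Advance unit vector(s) by one Brownian rotation step.

    Applies a random rotation whose rotation-vector components are i.i.d.
    N(0, 2 D dt) per axis; the mean squared angular excursion of the
    vector then grows as 4 D dt (two transverse axes of 2 D dt each).
    """
    if D < 0:
        raise ConfigError("D must be nonnegative")
    if dt <= 0:
        raise ConfigError("dt must be positive")
    v = np.asarray(orientation, dtype=float)
    if D == 0:
        return v.copy()
    w = rng.normal(0.0, math.sqrt(2.0 * D * dt), size=v.shape if v.ndim > 1 else (3,))
    return Rotation.from_rotvec(np.atleast_2d(w)).apply(np.atleast_2d(v)).reshape(v.shape)


def bragg_normal(two_theta: float, chi: float) -> np.ndarray:
    """Unit normal exactly at the Bragg condition whose spot lands at
    azimuth chi on the ring (beam along +x)."""
    theta = two_theta / 2.0
    return np.array([-math.sin(theta), math.cos(theta) * math.cos(chi),
                     math.cos(theta) * math.sin(chi)])


def rocking_deviation(normal: np.ndarray, two_theta: float) -> np.ndarray:
    """Signed departure of the normal's beam-polar angle from the Bragg cone."""
    n = np.atleast_2d(np.asarray(normal, dtype=float))
    polar = np.arccos(np.clip(n[:, 0], -1.0, 1.0))
    alpha = polar - (math.pi / 2.0 + two_theta / 2.0)
    return alpha if np.asarray(normal).ndim > 1 else float(alpha[0])


def normal_azimuth(normal: np.ndarray) -> np.ndarray:
    """Azimuth chi of the normal (hence of the diffraction spot) about the beam."""
    n = np.atleast_2d(np.asarray(normal, dtype=float))
    chi = np.arctan2(n[:, 2], n[:, 1])
    return chi if np.asarray(normal).ndim > 1 else float(chi[0])


def diffraction_rate(
    crystallite: Crystallite,
    two_theta: float,
    rocking_sigma: float,
    peak_rate: float,
) -> tuple[float, float]:
    """Instantaneous diffracted photon rate and spot azimuth.

    rate = peak_rate * exp(-delta^2 / (2 rocking_sigma^2)) where delta is
    the angular deviation of the (111) normal from the nearest exactly-
    diffracting orientation (the Bragg cone); chi is the azimuth at which
    the diffracted beam intersects the ring.
    """
    if rocking_sigma <= 0:
        raise ConfigError("rocking_sigma must be positive")
    delta = rocking_deviation(crystallite.normal, two_theta)
    rate = peak_rate * math.exp(-(delta**2) / (2.0 * rocking_sigma**2))
    return rate, normal_azimuth(crystallite.normal)


def _reflect(x: np.ndarray, bound: float) -> np.ndarray:
    """Fold free Brownian paths into [-bound, bound] (reflecting walls)."""
    z = np.mod(x + bound, 4.0 * bound)
    return np.where(z <= 2.0 * bound, z - bound, 3.0 * bound - z)


def _triangle(p: np.ndarray, halfwidth: float) -> np.ndarray:
    """Triangle wave: fold an unbounded sweep position into [-H, H]."""
    return _reflect(p, halfwidth)


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------

def _apply_rocking_bound(normals: np.ndarray, two_theta: float,
                         bound: float | None) -> np.ndarray:
    """Reflect the rocking deviation into [-bound, bound], keeping azimuth.

    Models a bounded mosaic spread (e.g. surface-tethered crystals whose
    tilt excursions are confined) so long records stay quasi-stationary.
    """
    if bound is None:
        return normals
    alpha = rocking_deviation(normals, two_theta)
    refl = _reflect(alpha, bound)
    if np.allclose(alpha, refl):
        return normals
    chi = normal_azimuth(normals)
    polar = math.pi / 2.0 + two_theta / 2.0 + refl
    return np.column_stack([
        np.cos(polar), np.sin(polar) * np.cos(chi), np.sin(polar) * np.sin(chi)])


def _visible_azimuths(geometry: DetectorGeometry, ring: BraggRing, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """n well-separated azimuths whose ring point lies on the active area."""
    grid = np.linspace(-math.pi, math.pi, 2048, endpoint=False)
    gaps = geometry.gap_mask()
    ok = []
    for chi in grid:
        r, c = ring_point(geometry, ring.radius_px, chi)
        ri, ci = int(round(r)), int(round(c))
        if 0 <= ri < geometry.n_rows and 0 <= ci < geometry.n_cols and not gaps[ri, ci]:
            ok.append(chi)
    if not ok:
        raise EmptyMaskError("ring arc does not intersect the active detector area")
    ok = np.asarray(ok)
    # evenly spaced along the visible arc with a random start offset
    start = rng.integers(0, len(ok))
    idx = (start + np.round(np.arange(n) * len(ok) / n).astype(int)) % len(ok)
    return ok[idx]


def _deposit(counts: np.ndarray, frame: int, row: float, col: float, photons: int,
             sigma_px: float, active: np.ndarray, rng: np.random.Generator) -> None:
    """Spread a spot's photons over a 5x5 Gaussian footprint (multinomial split)."""
    if photons <= 0:
        return
    r0, c0 = int(round(row)), int(round(col))
    rr, cc = np.meshgrid(np.arange(r0 - 2, r0 + 3), np.arange(c0 - 2, c0 + 3), indexing="ij")
    w = np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma_px**2)).ravel()
    w /= w.sum()
    split = rng.multinomial(photons, w)
    n_rows, n_cols = counts.shape[1:]
    for k, (ri, ci) in enumerate(zip(rr.ravel(), cc.ravel())):
        if 0 <= ri < n_rows and 0 <= ci < n_cols and active[ri, ci]:
            counts[frame, ri, ci] += split[k]


def render_frames(config: SimConfig, geometry: DetectorGeometry, ring: BraggRing) -> FrameStack:
    """Render a Poisson photon-counting frame stack of blinking spots.

    Each crystallite is advanced by ``substeps_per_frame`` Brownian
    substeps across the exposure (the dead time frame_interval - exposure
    is advanced without photons), its diffraction rate averaged over the
    substeps, a Poisson photon total drawn and deposited on the spot
    footprint at the crystallite's azimuth; Poisson background is added on
    all non-gap pixels.  Bit-identical for identical config and seed.
    """
    if config.scan_speed > 0:
        return goniometer_scan(config, geometry, ring)
    rng = np.random.default_rng(config.seed)
    chis = _visible_azimuths(geometry, ring, config.n_crystallites, rng)
    if config.init_spread > 0:
        alpha0 = rng.uniform(-config.init_spread, config.init_spread, len(chis))
    else:
        alpha0 = np.full(len(chis), config.initial_offset)
    polar = math.pi / 2.0 + ring.two_theta / 2.0 + alpha0
    normals = np.column_stack([
        np.cos(polar),
        np.sin(polar) * np.cos(chis),
        np.sin(polar) * np.sin(chis),
    ])
    active = ~geometry.gap_mask()
    counts = np.zeros((config.n_frames, geometry.n_rows, geometry.n_cols), dtype=np.uint32)
    dt_sub = config.exposure / config.substeps_per_frame
    dead = config.frame_interval - config.exposure
    sigma2 = 2.0 * config.rocking_sigma**2
    n_active = int(active.sum())
    expected = 0.0
    for f in range(config.n_frames):
        rates = np.zeros(len(chis))
        mid = None
        for s in range(config.substeps_per_frame):
            normals = rotate_step(normals, config.D, dt_sub, rng)
            normals = _apply_rocking_bound(normals, ring.two_theta,
                                           config.misorientation_bound)
            alpha = rocking_deviation(normals, ring.two_theta)
            rates += np.exp(-(alpha**2) / sigma2)
            if s == config.substeps_per_frame // 2:
                mid = normals.copy()
        rates *= config.peak_rate / config.substeps_per_frame
        spot_chis = normal_azimuth(mid)
        photons = rng.poisson(rates * config.exposure)
        for i, chi in enumerate(spot_chis):
            r, c = ring_point(geometry, ring.radius_px, chi)
            _deposit(counts, f, r, c, int(photons[i]), config.footprint_sigma_px, active, rng)
        if config.background_rate > 0:
            bgc = rng.poisson(config.background_rate * config.exposure, size=n_active)
            counts[f][active] += bgc.astype(np.uint32)
        expected += float(rates.sum()) * config.exposure
        expected += config.background_rate * config.exposure * n_active
        if dead > 0 and config.D > 0:
            normals = rotate_step(normals, config.D, dead, rng)
            normals = _apply_rocking_bound(normals, ring.two_theta,
                                           config.misorientation_bound)
    return FrameStack(
        counts=counts,
        timestamps=np.arange(config.n_frames) * config.frame_interval,
        frame_interval=config.frame_interval,
        exposure=config.exposure,
        provenance={"config": asdict(config), "expected_counts_total": expected,
                    "crystallite_azimuths": chis.tolist()},
    )


def goniometer_scan(config: SimConfig, geometry: DetectorGeometry, ring: BraggRing) -> FrameStack:
    """Deterministic rocking sweep at angular speed ``scan_speed``.

    The rocking offset follows a triangle wave across
    [-scan_halfwidth, +scan_halfwidth] so trajectories contain repeated
    blink events; the spot azimuth stays fixed.  Brownian motion may be
    superposed by setting D > 0 (applied to the rocking coordinate).
    """
    if config.scan_speed <= 0:
        raise ConfigError("goniometer scan requires scan_speed > 0")
    rng = np.random.default_rng(config.seed)
    chis = _visible_azimuths(geometry, ring, config.n_crystallites, rng)
    active = ~geometry.gap_mask()
    counts = np.zeros((config.n_frames, geometry.n_rows, geometry.n_cols), dtype=np.uint32)
    dt_sub = config.exposure / config.substeps_per_frame
    sigma2 = 2.0 * config.rocking_sigma**2
    n_active = int(active.sum())
    alpha_brown = np.zeros(len(chis))
    expected = 0.0
    for f in range(config.n_frames):
        t0 = f * config.frame_interval
        rates = np.zeros(len(chis))
        for s in range(config.substeps_per_frame):
            t = t0 + (s + 0.5) * dt_sub
            if config.D > 0:
                alpha_brown += rng.normal(0.0, math.sqrt(2.0 * config.D * dt_sub), len(chis))
            sweep = _triangle(np.full(len(chis), config.initial_offset + config.scan_speed * t),
                              config.scan_halfwidth)
            alpha = sweep + alpha_brown
            rates += np.exp(-(alpha**2) / sigma2)
        rates *= config.peak_rate / config.substeps_per_frame
        photons = rng.poisson(rates * config.exposure)
        for i, chi in enumerate(chis):
            r, c = ring_point(geometry, ring.radius_px, chi)
            _deposit(counts, f, r, c, int(photons[i]), config.footprint_sigma_px, active, rng)
        if config.background_rate > 0:
            counts[f][active] += rng.poisson(
                config.background_rate * config.exposure, size=n_active
            ).astype(np.uint32)
        expected += float(rates.sum()) * config.exposure
        expected += config.background_rate * config.exposure * n_active
    return FrameStack(
        counts=counts,
        timestamps=np.arange(config.n_frames) * config.frame_interval,
        frame_interval=config.frame_interval,
        exposure=config.exposure,
        provenance={"config": asdict(config), "expected_counts_total": expected,
                    "crystallite_azimuths": chis.tolist()},
    )


# ---------------------------------------------------------------------------
# Fast per-pixel trajectory path (no imaging)
# ---------------------------------------------------------------------------

def simulate_pixel_trajectories(config: SimConfig, n_pixels: int = 1) -> list[IntensityTrajectory]:
    """Per-pixel photon-count trajectories without rendering images.

    Each "pixel" watches an independent replicate of ``n_crystallites``
    crystallites whose rocking offsets start uniformly in
    [-init_spread, init_spread] (or at ``initial_offset``) and evolve by
    1-D Brownian increments of variance 2 D dt, optionally reflected at
    ``+/- misorientation_bound`` (a bounded mosaic spread that keeps
    blinking quasi-stationary over long records).  With scan_speed > 0
    the deterministic triangle sweep replaces the initial offset.
    Counts are Poisson(total rate * exposure + background * exposure).
    """
    rng = np.random.default_rng(config.seed)
    nf, nc, ns = config.n_frames, config.n_crystallites, config.substeps_per_frame
    dt_sub = config.exposure / ns
    dead = config.frame_interval - config.exposure
    # per-frame time grid: ns exposure substeps then one dead-time step
    dts = np.tile(np.concatenate([np.full(ns, dt_sub), [dead]]), nf)
    if config.init_spread > 0:
        a0 = rng.uniform(-config.init_spread, config.init_spread, (n_pixels, nc, 1))
    else:
        a0 = np.full((n_pixels, nc, 1), config.initial_offset)
    steps = rng.normal(0.0, 1.0, (n_pixels, nc, len(dts))) * np.sqrt(
        np.maximum(2.0 * config.D * dts, 0.0)
    )
    alpha = a0 + np.cumsum(steps, axis=-1)
    if config.misorientation_bound is not None:
        alpha = _reflect(alpha, config.misorientation_bound)
    if config.scan_speed > 0:
        t = np.cumsum(dts)
        alpha = alpha + _triangle(config.initial_offset + config.scan_speed * t,
                                  config.scan_halfwidth)
    # keep only exposure substeps for the rate integral
    keep = np.tile(np.concatenate([np.ones(ns, bool), [False]]), nf)
    a_exp = alpha[:, :, keep].reshape(n_pixels, nc, nf, ns)
    rate = config.peak_rate * np.exp(-(a_exp**2) / (2.0 * config.rocking_sigma**2))
    frame_rate = rate.mean(axis=-1).sum(axis=1)  # (n_pixels, n_frames)
    mean_counts = frame_rate * config.exposure + config.background_rate * config.exposure
    counts = rng.poisson(mean_counts)
    return [
        IntensityTrajectory(pixel=(0, i), values=counts[i].astype(float),
                            frame_interval=config.frame_interval)
        for i in range(n_pixels)
    ]
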