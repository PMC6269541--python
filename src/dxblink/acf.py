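"""Diffracted X-ray blinking (DXB) core analysis.

Per-pixel intensity trajectories on the Bragg ring are autocorrelated,

    ACF(tau) = <I(t) I(t+tau)> / <I(t)^2>,

fitted to a single-exponential decay ACF(t) = k + A exp(-T t), screened by
the k > 0, A > 0, T > 0 validity rule, averaged with per-lag standard
errors, and refitted with 1/stderr^2 weights.  The decay constant T of the
final weighted fit is the blinking observable: faster nanocrystal rotation
decorrelates the diffracted intensity sooner and yields a larger T.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import warnings

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import EmptySelectionError, PipelineError, UndefinedACFError
from .geometry import MASK_BACKGROUND, MASK_ON_RING, RingMask

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import FrameStack

log = logging.getLogger("dxblink.acf")

# "Positive" fit parameters must clear this floor so that numerically-zero
# amplitudes are not accepted as valid decays.
POSITIVITY_TOL = 1e-9

MIN_FRAMES = 10
MIN_FIT_LAGS = 5


@dataclass
class IntensityTrajectory:
    """Photon-count time series of one detector pixel."""

    pixel: tuple[int, int]
    values: np.ndarray
    frame_interval: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trajectory values must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("photon counts must be nonnegative")


@dataclass
class ACFCurve:
    """Normalized autocorrelation of one trajectory.

    ``lags`` are delay times in seconds (multiples of the frame interval,
    including lag 0 where the value is exactly 1); ``n_pairs`` is the
    number of frame pairs contributing at each lag.
    """

    lags: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray
    pixel: tuple[int, int] | None = None


@dataclass
class ExpFit:
    """Parameters of ACF(t) = k + A exp(-T t) with standard errors.

    ``valid`` is True iff the fit converged and k, A and T are all
    positive (beyond POSITIVITY_TOL).
    """

    k: float
    A: float
    T: float
    se_k: float
    se_A: float
    se_T: float
    chi_square: float
    fit_window: tuple[float, float]
    valid: bool
    message: str = ""


@dataclass
class AveragedACF:
    """Per-lag mean and standard error over the selected (valid-fit) pixels."""

    lags: np.ndarray
    mean: np.ndarray
    stderr: np.ndarray
    n_curves: int


# ---------------------------------------------------------------------------
# Trajectory extraction and normalisation
# ---------------------------------------------------------------------------

def extract_trajectories(stack: "FrameStack", mask: RingMask) -> list[IntensityTrajectory]:
    """One IntensityTrajectory per on-ring pixel, in row-major pixel order.

    Excluded (gap / out-of-band) pixels are never emitted.
    """
    counts = np.asarray(stack.counts)
    if counts.shape[1:] != mask.codes.shape:
        raise PipelineError(
            f"extract: stack frames {counts.shape[1:]} do not match mask {mask.codes.shape}"
        )
    pixels = np.argwhere(mask.codes == MASK_ON_RING)
    if len(pixels) == 0:
        raise EmptySelectionError("extract: mask has no on-ring pixels")
    return [
        IntensityTrajectory(
            pixel=(int(r), int(c)),
            values=counts[:, r, c].astype(float),
            frame_interval=stack.frame_interval,
        )
        for r, c in pixels
    ]


def background_total(stack: "FrameStack", mask: RingMask) -> np.ndarray:
    """Per-frame summed counts over the background-annulus pixels."""
    bg = mask.codes == MASK_BACKGROUND
    if not bg.any():
        raise EmptySelectionError("mask defines no background pixels")
    return np.asarray(stack.counts)[:, bg].sum(axis=1).astype(float)


def normalize_by_background(
    traj: IntensityTrajectory, background: np.ndarray
) -> IntensityTrajectory:
    """Divide out shared illumination drift using the summed background.

    output(t) = I(t) * mean(B) / B(t).  Frames where B(t) = 0 are imputed
    with mean(B) (i.e. left unscaled) and logged, keeping the lag grid
    uniform.  Invariant under a uniform rescaling of B.
    """
    b = np.asarray(background, dtype=float)
    if b.shape != traj.values.shape:
        raise ValueError("background trajectory length mismatch")
    mean_b = b.mean()
    if mean_b <= 0:
        raise ValueError("background is identically zero; cannot normalise")
    zero = b == 0
    if zero.any():
        log.warning("normalize: %d frames with zero background imputed with the mean", zero.sum())
        b = np.where(zero, mean_b, b)
    return IntensityTrajectory(
        pixel=traj.pixel,
        values=traj.values * mean_b / b,
        frame_interval=traj.frame_interval,
        normalized=True,
    )


# ---------------------------------------------------------------------------
# Autocorrelation
# ---------------------------------------------------------------------------

def compute_acf(traj: IntensityTrajectory, max_lag_frames: int) -> ACFCurve:
    """Normalized autocorrelation <I(t)I(t+tau)> / <I(t)^2>.

    Each lag's product sum is divided by its own pair count (N - m) and
    the denominator by N, so ACF(0) is exactly 1 for any nonzero
    trajectory.  Lag times are reported in seconds, m * frame_interval.
    """
    x = traj.values
    n = len(x)
    if n < MIN_FRAMES:
        raise ValueError(f"trajectory has {n} < {MIN_FRAMES} frames")
    if not 0 < max_lag_frames < n:
        raise ValueError("max_lag_frames must lie in [1, len-1]")
    denom = float(np.dot(x, x)) / n
    if denom == 0.0:
        raise UndefinedACFError(f"pixel {traj.pixel}: identically-zero trajectory")
    lags = np.arange(max_lag_frames + 1)
    values = np.empty(max_lag_frames + 1)
    values[0] = 1.0
    for m in range(1, max_lag_frames + 1):
        values[m] = float(np.dot(x[:-m], x[m:])) / (n - m) / denom
    return ACFCurve(
        lags=lags * traj.frame_interval,
        values=values,
        n_pairs=(n - lags).astype(int),
        pixel=traj.pixel,
    )


# ---------------------------------------------------------------------------
# Exponential fitting
# ---------------------------------------------------------------------------

def _exp_model(t, k, A, T):
    with np.errstate(over="ignore", invalid="ignore"):
        return k + A * np.exp(np.clip(-T * t, -700.0, 700.0))


def _window_slice(acf: ACFCurve, fit_fraction: float, window_override) -> np.ndarray:
    """Boolean selector of the lags entering the fit (lag 0 always excluded)."""
    if window_override is not None:
        lo, hi = window_override
        sel = (acf.lags >= lo) & (acf.lags <= hi) & (acf.lags > 0)
    else:
        n_frames = int(acf.n_pairs[0])
        m_max = math.floor(fit_fraction * n_frames) + 1
        m = np.rint(acf.lags / (acf.lags[1] - acf.lags[0])).astype(int)
        sel = (m >= 1) & (m <= m_max)
    return sel


def _fit(
    lags: np.ndarray,
    values: np.ndarray,
    sigma: np.ndarray | None,
) -> ExpFit:
    """Shared nonlinear least-squares core (unweighted or 1/sigma^2-weighted)."""
    span = lags[-1] - lags[0] if len(lags) > 1 else lags[0]
    tail = values[-max(1, len(values) // 5):]
    k0 = float(tail.mean())
    a0 = float(values[0] - k0)
    t0 = 3.0 / span if span > 0 else 1.0
    a0 = a0 if abs(a0) > 1e-12 else 1e-6
    # multi-start over the decay-rate guess: the k/A trade-off has a
    # degenerate near-linear local minimum that a single start can hit
    best = None
    message = ""
    for scale in (1.0, 0.1, 10.0, 100.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                popt_i, pcov_i = curve_fit(
                    _exp_model,
                    lags,
                    values,
                    p0=(k0, a0, t0 * scale),
                    sigma=sigma,
                    absolute_sigma=sigma is not None,
                    maxfev=10_000,
                    xtol=1e-12,
                    ftol=1e-12,
                )
        except RuntimeError as exc:
            message = str(exc)
            continue
        if not np.all(np.isfinite(popt_i)):
            continue
        resid_i = values - _exp_model(lags, *popt_i)
        cost = float(np.sum((resid_i / sigma) ** 2)) if sigma is not None else float(
            np.sum(resid_i**2))
        # prefer the admissible (all-positive) solution on near-ties
        admissible = all(p > POSITIVITY_TOL for p in popt_i)
        key = (cost * (1.0 - 1e-9) if admissible else cost)
        if best is None or key < best[0]:
            best = (key, popt_i, pcov_i)
    if best is not None:
        _, popt, pcov = best
        converged = True
    else:  # non-convergence is a result, not an exception
        popt = np.array((k0, a0, t0))
        pcov = np.full((3, 3), np.nan)
        converged = False
    k, A, T = (float(v) for v in popt)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    resid = values - _exp_model(lags, k, A, T)
    if sigma is not None:
        chisq = float(np.sum((resid / sigma) ** 2))
    else:
        chisq = float(np.sum(resid**2))
    # non-finite standard errors mean a singular Jacobian: the parameters
    # are not identifiable (e.g. a flat curve), which is not a valid decay
    identifiable = bool(np.all(np.isfinite(se)))
    valid = bool(
        converged and identifiable
        and k > POSITIVITY_TOL and A > POSITIVITY_TOL and T > POSITIVITY_TOL
    )
    return ExpFit(
        k=k, A=A, T=T,
        se_k=float(se[0]), se_A=float(se[1]), se_T=float(se[2]),
        chi_square=chisq,
        fit_window=(float(lags[0]), float(lags[-1])),
        valid=valid,
        message=message,
    )


def fit_exponential(
    acf: ACFCurve,
    fit_fraction: float = 0.10,
    window_override: tuple[float, float] | None = None,
) -> ExpFit:
    """Unweighted single-exponential fit over the early-lag window.

    The default window covers the first 10% of the observed time: lags
    1 .. floor(fit_fraction * n_frames) + 1, lag 0 excluded (e.g. frames
    1-101 of a 1000-frame record).  ``window_override`` gives an explicit
    (tau_min, tau_max) in seconds instead, e.g. a 1-30 s overlap refit.
    Non-convergence is reported via ``valid=False``, never raised.
    """
    sel = _window_slice(acf, fit_fraction, window_override)
    if sel.sum() < MIN_FIT_LAGS:
        raise ValueError(f"fit window contains {int(sel.sum())} < {MIN_FIT_LAGS} lags")
    return _fit(acf.lags[sel], acf.values[sel], sigma=None)


def average_acfs(curves: Sequence[ACFCurve], fits: Sequence[ExpFit]) -> AveragedACF:
    """Average the ACF curves whose exponential fit passed k, A, T > 0.

    Per-lag mean and standard error (sample std / sqrt(n)) over the
    selected curves; all curves must share one lag grid.
    """
    if len(curves) != len(fits):
        raise ValueError("curves and fits must be parallel lists")
    kept = [c for c, f in zip(curves, fits) if f.valid]
    if not kept:
        raise EmptySelectionError("no ACF curve passed the k>0, A>0, T>0 selection")
    lags = kept[0].lags
    for c in kept[1:]:
        if len(c.lags) != len(lags) or not np.allclose(c.lags, lags):
            raise ValueError("ACF curves do not share a lag grid")
    stacked = np.vstack([c.values for c in kept])
    mean = stacked.mean(axis=0)
    if len(kept) > 1:
        stderr = stacked.std(axis=0, ddof=1) / math.sqrt(len(kept))
    else:
        stderr = np.zeros_like(mean)
    return AveragedACF(lags=lags, mean=mean, stderr=stderr, n_curves=len(kept))


def fit_averaged(
    avg: AveragedACF,
    fit_fraction: float = 0.10,
    window_override: tuple[float, float] | None = None,
    n_frames: int | None = None,
) -> ExpFit:
    """Weighted fit of the averaged ACF with weights 1/stderr^2.

    With ``n_frames`` the window is the same first-10%-of-record rule as
    the per-pixel fits; otherwise every positive lag of the averaged
    curve enters (the curve is normally already restricted to the fit
    window).  Lags with stderr = 0 inside the window are assigned the
    smallest positive stderr on the window (logged); chi-square is
    sum(((data - model) / stderr)^2).
    """
    if window_override is None and n_frames is None:
        window_override = (float(avg.lags[avg.lags > 0].min()), float(avg.lags.max()))
    proxy = ACFCurve(
        lags=avg.lags, values=avg.mean,
        n_pairs=np.array([n_frames if n_frames is not None else len(avg.lags)]),
    )
    sel = _window_slice(proxy, fit_fraction, window_override)
    if sel.sum() < MIN_FIT_LAGS:
        raise ValueError(f"fit window contains {int(sel.sum())} < {MIN_FIT_LAGS} lags")
    sigma = avg.stderr[sel].copy()
    if np.any(sigma <= 0):
        positive = sigma[sigma > 0]
        if len(positive) == 0:
            # a noiseless average: uniform weights reproduce the unweighted fit
            sigma = np.ones_like(sigma)
            log.info("fit_averaged: all stderr zero on window; using uniform weights")
        else:
            log.info(
                "fit_averaged: %d zero-stderr lags given the smallest positive stderr",
                int(np.sum(sigma <= 0)),
            )
            sigma[sigma <= 0] = positive.min()
    return _fit(avg.lags[sel], avg.mean[sel], sigma=sigma)


def decay_ratio(fit_a: ExpFit, fit_b: ExpFit) -> float:
    """Ratio T_a / T_b of two decay constants (e.g. ligand-bound vs free)."""
    if not (fit_a.valid and fit_b.valid):
        raise ValueError("decay_ratio requires two valid fits")
    if fit_b.T <= 0:
        raise ValueError("denominator decay constant must be positive")
    return fit_a.T / fit_b.T


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class DXBReport:
    """Everything the DXB pipeline computed, with per-stage counts."""

    per_pixel_fits: list[tuple[tuple[int, int], ExpFit]]
    averaged: AveragedACF
    final_fit: ExpFit
    counts: dict = field(default_factory=dict)


def dxb_pipeline(
    stack: "FrameStack",
    mask: RingMask,
    normalize: bool = False,
    fit_fraction: float = 0.10,
    window_override: tuple[float, float] | None = None,
    max_lag_frames: int | None = None,
) -> DXBReport:
    """extract -> (normalise) -> ACF -> per-pixel fit -> select -> average -> weighted refit.

    Deterministic given its inputs.  Identically-zero pixels are dropped
    with a logged count before the ACF stage; failures carry their stage
    label.  ``normalize`` enables the lab-source background normalisation
    (requires a background annulus in the mask).
    """
    trajs = extract_trajectories(stack, mask)
    n_extracted = len(trajs)
    if normalize:
        bg = background_total(stack, mask)
        trajs = [normalize_by_background(t, bg) for t in trajs]
    nonzero = [t for t in trajs if np.any(t.values > 0)]
    n_dropped = n_extracted - len(nonzero)
    if n_dropped:
        log.info("pipeline: dropped %d identically-zero pixel trajectories", n_dropped)
    if not nonzero:
        raise PipelineError("acf: every on-ring pixel trajectory is identically zero")
    n_frames = len(nonzero[0].values)
    if max_lag_frames is None:
        if window_override is not None:
            dt = nonzero[0].frame_interval
            max_lag_frames = min(n_frames - 1, int(math.ceil(window_override[1] / dt)))
        else:
            max_lag_frames = min(n_frames - 1, math.floor(fit_fraction * n_frames) + 1)
    curves = [compute_acf(t, max_lag_frames) for t in nonzero]
    fits = [fit_exponential(c, fit_fraction, window_override) for c in curves]
    try:
        averaged = average_acfs(curves, fits)
    except EmptySelectionError as exc:
        raise PipelineError(f"average: {exc}") from exc
    final = fit_averaged(averaged, fit_fraction, window_override, n_frames=n_frames)
    return DXBReport(
        per_pixel_fits=[(c.pixel, f) for c, f in zip(curves, fits)],
        averaged=averaged,
        final_fit=final,
        counts={
            "pixels_extracted": n_extracted,
            "pixels_zero_dropped": n_dropped,
            "pixels_analysed": len(nonzero),
            "valid_fits": averaged.n_curves,
        },
    )
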