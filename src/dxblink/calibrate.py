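"""Decay-constant calibration.

The DXB decay constant T is a relative observable; connecting it to
physical angular motion needs a calibration line.  Two routes are
covered: a zero-intercept regression of the angular diffusion constant D
(from DXT/MSD analysis) against T, and a goniometer-scan procedure in
which samples are swept at known angular speeds and the fitted decay
constants form an invertible T <-> speed curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .acf import dxb_pipeline
from .errors import PipelineError
from .geometry import RingMask
from .simulate import FrameStack

log = logging.getLogger("dxblink.calibrate")


@dataclass
class CalibrationLine:
    """y = slope * x (+ intercept), with the fitted points kept alongside."""

    slope: float
    intercept: float
    se_slope: float
    r_squared: float
    n_points: int
    x: np.ndarray = field(default_factory=lambda: np.array([]))
    y: np.ndarray = field(default_factory=lambda: np.array([]))
    y_err: np.ndarray | None = None

    def predict_y(self, x: float) -> float:
        """Evaluate the line, clamping to the calibrated x range (warned)."""
        if len(self.x) and not (self.x.min() <= x <= self.x.max()):
            log.warning("calibration query x=%g outside calibrated range [%g, %g]; clamped",
                        x, self.x.min(), self.x.max())
            x = float(np.clip(x, self.x.min(), self.x.max()))
        return self.slope * x + self.intercept

    def predict_x(self, y: float) -> float:
        """Invert the line (clamped to the calibrated y range)."""
        if self.slope == 0:
            raise ZeroDivisionError("calibration line has zero slope")
        if len(self.y) and not (min(self.y) <= y <= max(self.y)):
            log.warning("calibration query y=%g outside calibrated range; clamped", y)
            y = float(np.clip(y, min(self.y), max(self.y)))
        return (y - self.intercept) / self.slope


def zero_intercept_fit(
    x: Sequence[float],
    y: Sequence[float],
    y_err: Sequence[float] | None = None,
) -> CalibrationLine:
    """Weighted zero-intercept regression y = slope * x.

    slope = sum(w x y) / sum(w x^2) with w = 1/y_err^2 (or 1); invariant
    under a uniform rescaling of y_err.  R^2 is reported against the
    zero-intercept model with the weighted-mean total sum of squares, so
    it may be negative for strongly non-proportional data.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) != len(ya) or len(xa) < 2:
        raise ValueError("need >= 2 paired points")
    if np.all(xa == 0):
        raise ValueError("all x are zero")
    if y_err is not None:
        ea = np.asarray(y_err, dtype=float)
        if np.any(ea <= 0):
            raise ValueError("y_err must be positive")
        w = 1.0 / ea**2
    else:
        ea = None
        w = np.ones_like(xa)
    sxx = float(np.sum(w * xa * xa))
    slope = float(np.sum(w * xa * ya)) / sxx
    resid = ya - slope * xa
    ybar = float(np.sum(w * ya) / np.sum(w))
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (ya - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    dof = max(len(xa) - 1, 1)
    se_slope = math.sqrt(float(np.sum(w * resid**2)) / dof / sxx)
    return CalibrationLine(slope=slope, intercept=0.0, se_slope=se_slope,
                           r_squared=r2, n_points=len(xa), x=xa, y=ya, y_err=ea)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least squares: (slope, intercept, R^2).

    Used for the diffusion-constant-versus-temperature line.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(np.unique(xa)) < 2:
        raise ValueError("need >= 2 distinct x values")
    res = stats.linregress(xa, ya)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def goniometer_calibration(
    stacks: Sequence[FrameStack],
    speeds: Sequence[float],
    mask: RingMask,
    labels: Sequence[str] | None = None,
    **acf_options,
) -> CalibrationLine:
    """Calibration line from goniometer scans at known angular speeds.

    Runs the DXB pipeline on each stack, pairs the fitted decay constant
    T_i with the scan speed omega_i, and fits a zero-intercept line
    omega = slope * T weighted by the T standard errors (error propagated
    onto omega via the fitted slope is neglected at this stage).  The
    returned line is invertible: ``predict_y(T)`` gives the interpolated
    angular speed, clamped to the calibrated range.
    """
    if len(stacks) != len(speeds):
        raise ValueError("stacks and speeds must be paired")
    if len(set(speeds)) < 3:
        raise ValueError("goniometer calibration needs >= 3 distinct scan speeds")
    labels = labels or [f"scan_{i}" for i in range(len(stacks))]
    ts, tse = [], []
    for stack, label in zip(stacks, labels):
        try:
            report = dxb_pipeline(stack, mask, **acf_options)
        except Exception as exc:
            raise PipelineError(f"{label}: {exc}") from exc
        ts.append(report.final_fit.T)
        tse.append(report.final_fit.se_T)
    y_err = None
    if all(e > 0 and math.isfinite(e) for e in tse):
        # propagate T uncertainty onto the dependent axis with a first-pass slope
        first = zero_intercept_fit(ts, list(speeds))
        y_err = [abs(first.slope) * e for e in tse]
        if any(e <= 0 for e in y_err):
            y_err = None
    return zero_intercept_fit(ts, list(speeds), y_err=y_err)
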