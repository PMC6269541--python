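"""File formats and run configuration.

Stacks and masks travel as multi-page TIFF (unsigned 32-bit counts /
int8 mask codes) with an optional JSON sidecar carrying acquisition
metadata and provenance; tabular results (per-pixel fits, averaged ACF,
tracks, MSD) are CSV; reports and calibration lines are JSON.  Run
configuration is a YAML file with ``geometry``, ``simulation`` and
``analysis`` blocks validated against known keys before any computation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .acf import AveragedACF, ExpFit, IntensityTrajectory
from .errors import ConfigError, FormatError
from .geometry import DEFAULT_AU111_D_NM, DetectorGeometry, RingMask
from .simulate import FrameStack, SimConfig

SIDECAR_SUFFIX = ".json"


# ---------------------------------------------------------------------------
# Stacks and masks
# ---------------------------------------------------------------------------

def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Multi-page TIFF of uint32 counts plus a JSON sidecar of metadata."""
    path = Path(path)
    tifffile.imwrite(path, stack.counts.astype(np.uint32))
    sidecar = {
        "frame_interval": stack.frame_interval,
        "exposure": stack.exposure,
        "n_frames": int(stack.n_frames),
        "shape": list(stack.counts.shape),
        "provenance": _jsonable(stack.provenance),
    }
    path.with_suffix(path.suffix + SIDECAR_SUFFIX).write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(path: str | Path) -> FrameStack:
    """Read a stack TIFF (+ sidecar when present); lossless round-trip.

    Non-integer or negative pixel data is a format error.
    """
    path = Path(path)
    counts = tifffile.imread(path)
    if counts.ndim == 2:
        counts = counts[None, ...]
    if not np.issubdtype(counts.dtype, np.integer):
        raise FormatError(f"{path}: pixel data must be integer counts, got {counts.dtype}")
    if np.any(np.asarray(counts, dtype=np.int64) < 0):
        raise FormatError(f"{path}: negative counts are not valid photon data")
    frame_interval, exposure, provenance = 1.0, 1.0, {}
    sidecar = path.with_suffix(path.suffix + SIDECAR_SUFFIX)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("shape") is not None and list(counts.shape) != list(meta["shape"]):
            raise FormatError(f"{path}: stack shape {counts.shape} != sidecar {meta['shape']}")
        frame_interval = float(meta.get("frame_interval", frame_interval))
        exposure = float(meta.get("exposure", exposure))
        provenance = meta.get("provenance", {})
    return FrameStack(
        counts=counts,
        timestamps=np.arange(counts.shape[0]) * frame_interval,
        frame_interval=frame_interval,
        exposure=exposure,
        provenance=provenance,
    )


def write_mask(mask: RingMask, path: str | Path) -> Path:
    """Integer-coded mask image: 0=excluded, 1=on_ring, 2=background."""
    path = Path(path)
    tifffile.imwrite(path, mask.codes.astype(np.uint8))
    return path


def read_mask(path: str | Path) -> RingMask:
    codes = tifffile.imread(Path(path))
    if not np.issubdtype(codes.dtype, np.integer):
        raise FormatError(f"{path}: mask codes must be integer")
    if codes.max() > 2:
        raise FormatError(f"{path}: mask codes must be in {{0, 1, 2}}")
    return RingMask(codes=codes.astype(np.int8))


# ---------------------------------------------------------------------------
# Tabular results
# ---------------------------------------------------------------------------

def trajectories_to_csv(trajs: list[IntensityTrajectory], path: str | Path) -> Path:
    """Long-format trajectory table: pixel_row, pixel_col, frame, t_s, counts."""
    frames = []
    for t in trajs:
        n = len(t.values)
        frames.append(pd.DataFrame({
            "pixel_row": t.pixel[0],
            "pixel_col": t.pixel[1],
            "frame": np.arange(n),
            "t_s": np.arange(n) * t.frame_interval,
            "counts": t.values,
        }))
    path = Path(path)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_trajectories_csv(path: str | Path) -> list[IntensityTrajectory]:
    df = pd.read_csv(Path(path))
    required = {"pixel_row", "pixel_col", "frame", "t_s", "counts"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    out = []
    for (r, c), grp in df.groupby(["pixel_row", "pixel_col"], sort=True):
        grp = grp.sort_values("frame")
        t = grp["t_s"].to_numpy()
        dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
        out.append(IntensityTrajectory(pixel=(int(r), int(c)),
                                       values=grp["counts"].to_numpy(dtype=float),
                                       frame_interval=dt))
    return out


def fits_to_csv(per_pixel_fits, path: str | Path) -> Path:
    rows = [{
        "pixel_row": px[0], "pixel_col": px[1],
        "k": f.k, "A": f.A, "T": f.T,
        "se_k": f.se_k, "se_A": f.se_A, "se_T": f.se_T,
        "chisq": f.chi_square, "valid": f.valid,
    } for px, f in per_pixel_fits]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def averaged_to_csv(avg: AveragedACF, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"lag_s": avg.lags, "mean": avg.mean,
                  "stderr": avg.stderr, "n": avg.n_curves}).to_csv(path, index=False)
    return path


def fit_to_dict(fit: ExpFit) -> dict:
    """Final-fit record mirroring the reported table fields."""
    return {
        "k": fit.k, "se_k": fit.se_k,
        "A": fit.A, "se_A": fit.se_A,
        "T_per_s": fit.T, "se_T": fit.se_T,
        "chi_square": fit.chi_square,
        "fit_window_s": list(fit.fit_window),
        "valid": fit.valid,
    }


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_GEOMETRY_KEYS = {"wavelength_nm", "distance_mm", "pixel_size_mm", "n_rows", "n_cols",
                  "beam_center", "gaps", "d_spacing_nm"}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}
_ANALYSIS_KEYS = {"fit_fraction", "normalize", "window", "min_intensity", "max_step_px",
                  "intervals", "background_annulus", "radial_halfwidth_px", "min_pixels",
                  "axis_mode"}
_TOP_KEYS = {"geometry", "simulation", "analysis", "seed", "outdir"}


def load_config(path: str | Path) -> dict:
    """Load and schema-validate a YAML run config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top level")
    if "geometry" in raw:
        _reject_unknown(raw["geometry"], _GEOMETRY_KEYS, "geometry")
    if "simulation" in raw:
        _reject_unknown(raw["simulation"], _SIM_KEYS, "simulation")
    if "analysis" in raw:
        _reject_unknown(raw["analysis"], _ANALYSIS_KEYS, "analysis")
    return raw


def _reject_unknown(block: dict, allowed: set, label: str) -> None:
    if not isinstance(block, dict):
        raise ConfigError(f"{label} block must be a mapping")
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown {label} keys: {sorted(unknown)}")


def geometry_from_config(cfg: dict) -> DetectorGeometry:
    g = cfg.get("geometry")
    if g is None:
        raise ConfigError("config has no geometry block")
    return DetectorGeometry(
        wavelength_nm=float(g["wavelength_nm"]),
        distance_mm=float(g["distance_mm"]),
        pixel_size_mm=float(g["pixel_size_mm"]),
        n_rows=int(g["n_rows"]),
        n_cols=int(g["n_cols"]),
        beam_center=tuple(float(v) for v in g["beam_center"]),
        gap_regions=tuple(tuple(int(v) for v in gap) for gap in g.get("gaps", [])),
        d_spacing_nm=float(g.get("d_spacing_nm", DEFAULT_AU111_D_NM)),
    )


def sim_config_from_config(cfg: dict) -> SimConfig:
    block = dict(cfg.get("simulation", {}))
    if "seed" in cfg and "seed" not in block:
        block["seed"] = cfg["seed"]
    return SimConfig(**block)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config for run reports."""
    return hashlib.sha256(json.dumps(_jsonable(cfg), sort_keys=True).encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
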