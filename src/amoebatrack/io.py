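"""File-format plumbing: image stacks, CSV schemas, JSON sidecars, manifests.

CSV files are comma-separated UTF-8 with a header row, '.' decimals, times in
hours and floats at 6 significant digits so that identical runs produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .activity import ActivitySeries, CumulativeActivityCurve, ImageStack
from .model import FitResult, TwoPhaseParams

__all__ = [
    "read_stack",
    "write_stack",
    "write_activity_csv",
    "write_curve_csv",
    "read_curve_csv",
    "fits_to_frame",
    "write_fits_csv",
    "read_fits_csv",
    "write_json",
    "sha256_file",
    "natural_key",
]

FLOAT_FMT = "%.6g"

_IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


def natural_key(name: str):
    """Sort key that orders embedded numbers numerically (img2 < img10)."""
    return [int(p) if p.isdigit() else p.lower() for p in re.split(r"(\d+)", name)]


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        rgb = frame[..., :3].astype(np.float64)
        gray = rgb @ np.array([0.299, 0.587, 0.114])  # ITU-R BT.601 luminance
        return np.round(gray).astype(frame.dtype)
    raise ValueError(f"unsupported frame shape {frame.shape}")


def read_stack(path, frame_interval: float = 30.0, start_time: float = 0.0) -> ImageStack:
    """Read a multi-page TIFF, or a directory of numbered PNG/JPEG frames
    (natural-sort order).  RGB frames are converted to luminance grayscale.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS),
            key=lambda p: natural_key(p.name),
        )
        if len(files) < 2:
            raise ValueError(f"no image sequence found in {path}")
        frames = np.stack([_to_gray(np.asarray(iio.imread(f))) for f in files])
        source = [f.name for f in files]
    elif path.suffix.lower() in (".tif", ".tiff"):
        frames = np.asarray(tifffile.imread(path))
        if frames.ndim == 2:
            raise ValueError("TIFF contains a single page; a stack needs >= 2")
        if frames.ndim == 4:
            frames = np.stack([_to_gray(f) for f in frames])
        source = [path.name]
    else:
        raise ValueError(f"unsupported stack input {path}")
    return ImageStack(
        frames=frames,
        frame_interval=frame_interval,
        start_time=start_time,
        metadata={"source": source},
    )


def write_stack(stack: ImageStack, path) -> None:
    tifffile.imwrite(Path(path), stack.frames)


def write_activity_csv(series: ActivitySeries, path) -> None:
    df = pd.DataFrame({"time_h": series.times, "count": series.counts})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_curve_csv(curve: CumulativeActivityCurve, path) -> None:
    df = pd.DataFrame({"time_h": curve.times, "ca_au": curve.ca})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_curve_csv(path) -> CumulativeActivityCurve:
    df = pd.read_csv(path)
    if not {"time_h", "ca_au"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_h, ca_au")
    return CumulativeActivityCurve(
        times=df["time_h"].to_numpy(float), ca=df["ca_au"].to_numpy(float)
    )


_FIT_COLUMNS = [
    "condition", "replicate", "cIA", "cCA", "tx", "tp", "tc", "tg",
    "tc_censored", "colonization_absent", "rel_colonization", "rmse", "r2",
    "window_end", "n_points", "converged",
]


def fits_to_frame(fits, conditions, replicates) -> pd.DataFrame:
    rows = []
    for fit, cond, rep in zip(fits, conditions, replicates):
        p = fit.params
        rows.append(
            dict(
                condition=cond, replicate=rep,
                cIA=p.cIA, cCA=p.cCA, tx=p.tx, tp=p.tp, tc=p.tc, tg=p.tg,
                tc_censored=fit.tc_censored,
                colonization_absent=fit.colonization_absent,
                rel_colonization=fit.relative_colonization,
                rmse=fit.rmse, r2=fit.r_squared,
                window_end=fit.window_end, n_points=fit.n_points,
                converged=fit.converged,
            )
        )
    return pd.DataFrame(rows, columns=_FIT_COLUMNS)


def write_fits_csv(fits, conditions, replicates, path) -> None:
    fits_to_frame(fits, conditions, replicates).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_fits_csv(path) -> pd.DataFrame:
    """Read a fit table and reattach FitResult objects (column 'fit')."""
    df = pd.read_csv(path)
    fits = []
    for _, r in df.iterrows():
        params = TwoPhaseParams(
            cIA=r.cIA, cCA=r.cCA, tx=r.tx, tp=r.tp, tc=r.tc, tg=r.tg
        )
        fits.append(
            FitResult(
                params=params,
                tc_censored=bool(r.tc_censored),
                colonization_absent=bool(r.colonization_absent),
                window_end=float(r.window_end),
                relative_colonization=float(r.rel_colonization),
                rmse=float(r.rmse),
                r_squared=float(r.r2),
                n_points=int(r.n_points),
                converged=bool(r.converged),
            )
        )
    df = df.copy()
    df["fit"] = fits
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
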