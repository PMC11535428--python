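"""Blood-pool time–signal curves: extraction from perfusion stacks and file I/O.

A first-pass perfusion scan is a 2D+time image series acquired while a
contrast bolus passes through the heart, ECG-triggered at roughly one frame
per heartbeat.  Placing a region of interest (ROI) in each ventricular blood
pool and averaging the signal over the ROI voxels at every frame yields one
time–signal curve per chamber; the arithmetic mean over voxels also mitigates
saturation of individual bright voxels.  Downstream, the right-ventricular
(RV) and left-ventricular (LV) curves are all that the transit-time
estimation needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CurveError",
    "PerfusionSeries",
    "ROIMask",
    "TimeSignalCurve",
    "extract_time_signal_curve",
    "read_curves_csv",
    "write_curves_csv",
    "read_perfusion_nifti",
    "write_perfusion_nifti",
    "read_mask_nifti",
    "write_mask_nifti",
]

CHAMBERS = ("RV", "LV")

CURVE_COLUMNS = ("time_s", "rv_signal", "lv_signal")


class CurveError(ValueError):
    """Invalid perfusion series, ROI mask, or time–signal curve."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise CurveError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class PerfusionSeries:
    """2D+time perfusion image stack with per-frame trigger times.

    Parameters
    ----------
    voxels
        Signal grid of shape ``(rows, cols, frames)`` in arbitrary units.
    trigger_times
        Acquisition time of each frame in seconds, strictly increasing.
        With ECG triggering there is one frame per heartbeat, so successive
        differences are R-R intervals.
    patient_id
        Free-form identifier.
    """

    voxels: np.ndarray
    trigger_times: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        voxels = _as_float_array(self.voxels, "voxels")
        times = _as_float_array(self.trigger_times, "trigger_times")
        if voxels.ndim != 3:
            raise CurveError(f"voxels must be 3D (rows, cols, frames), got shape {voxels.shape}")
        if times.ndim != 1 or voxels.shape[2] != times.size:
            raise CurveError(
                f"number of frames ({voxels.shape[2]}) must equal number of "
                f"trigger times ({times.size})"
            )
        if np.any(voxels < 0):
            raise CurveError("voxels must be non-negative")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise CurveError("trigger times must be strictly increasing")
        object.__setattr__(self, "voxels", voxels)
        object.__setattr__(self, "trigger_times", times)

    @property
    def n_frames(self) -> int:
        return int(self.trigger_times.size)

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.voxels.shape[0], self.voxels.shape[1]


@dataclass(frozen=True)
class ROIMask:
    """Boolean region-of-interest mask for one ventricular blood pool."""

    grid: np.ndarray
    chamber: str

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        if grid.ndim != 2:
            raise CurveError(f"mask grid must be 2D, got shape {grid.shape}")
        if not grid.any():
            raise CurveError("empty ROI")
        if self.chamber not in CHAMBERS:
            raise CurveError(f"chamber must be one of {CHAMBERS}, got {self.chamber!r}")
        object.__setattr__(self, "grid", grid)

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class TimeSignalCurve:
    """Sampled contrast signal for one chamber: times (s) and values (a.u.)."""

    times: np.ndarray
    values: np.ndarray
    chamber: str = "RV"

    def __post_init__(self) -> None:
        times = _as_float_array(self.times, "times")
        values = _as_float_array(self.values, "values")
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise CurveError("times and values must be 1D arrays of equal length")
        if times.size < 2:
            raise CurveError("a curve needs at least 2 samples")
        if not np.all(np.diff(times) > 0):
            raise CurveError("times must be strictly increasing")
        if self.chamber not in CHAMBERS:
            raise CurveError(f"chamber must be one of {CHAMBERS}, got {self.chamber!r}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def median_frame_interval(self) -> float:
        return float(np.median(np.diff(self.times)))


def extract_time_signal_curve(series: PerfusionSeries, mask: ROIMask) -> TimeSignalCurve:
    """Average the signal over ROI voxels at every frame.

    The value at frame ``k`` is the arithmetic mean of ``series.voxels`` over
    the masked voxels at frame ``k``; the curve's times are the series'
    trigger times.  Averaging over all ROI voxels per time step is the
    standard mitigation of per-voxel saturation in blood-pool curves.
    """
    if mask.grid.shape != series.spatial_shape:
        raise CurveError(
            f"mask shape {mask.grid.shape} does not match series spatial shape "
            f"{series.spatial_shape}"
        )
    if not mask.grid.any():  # unreachable through ROIMask, kept for raw arrays
        raise CurveError("empty ROI")
    values = series.voxels[mask.grid].mean(axis=0)
    return TimeSignalCurve(series.trigger_times.copy(), values, mask.chamber)


# ---------------------------------------------------------------------------
# CSV dialect: columns time_s, rv_signal, lv_signal
# ---------------------------------------------------------------------------


def write_curves_csv(rv: TimeSignalCurve, lv: TimeSignalCurve, path) -> None:
    """Write an RV/LV curve pair sharing a time base to CSV (full precision)."""
    if len(rv) != len(lv) or not np.array_equal(rv.times, lv.times):
        raise CurveError("RV and LV curves must share the same time base")
    df = pd.DataFrame(
        {"time_s": rv.times, "rv_signal": rv.values, "lv_signal": lv.values}
    )
    df.to_csv(path, index=False)


def read_curves_csv(path) -> tuple[TimeSignalCurve, TimeSignalCurve]:
    """Read an RV/LV curve pair; returns ``(rv, lv)``."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in CURVE_COLUMNS:
        if col not in df.columns:
            raise CurveError(f"missing column {col!r} in {path}")
    times = df["time_s"].to_numpy(dtype=float)
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise CurveError(f"times in {path} must be strictly increasing")
    rv = TimeSignalCurve(times, df["rv_signal"].to_numpy(dtype=float), "RV")
    lv = TimeSignalCurve(times.copy(), df["lv_signal"].to_numpy(dtype=float), "LV")
    return rv, lv


# ---------------------------------------------------------------------------
# NIfTI: 2D+t volume with frame times in a sidecar JSON ("trigger_times_s")
# ---------------------------------------------------------------------------


def _sidecar_path(image_path: Path) -> Path:
    name = image_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return image_path.with_name(name[: -len(suffix)] + ".json")
    return image_path.with_suffix(".json")


def read_perfusion_nifti(image_path, sidecar_path=None, patient_id: str = "") -> PerfusionSeries:
    """Load a 2D+t NIfTI plus its trigger-time sidecar JSON.

    The sidecar carries the per-frame acquisition times under the key
    ``"trigger_times_s"``; by default it sits next to the image with a
    ``.json`` extension.  Accepts ``(rows, cols, frames)`` volumes or 4D
    volumes with a singleton third axis.
    """
    image_path = Path(image_path)
    sidecar = Path(sidecar_path) if sidecar_path is not None else _sidecar_path(image_path)
    data = np.asarray(nib.load(str(image_path)).get_fdata(), dtype=float)
    if data.ndim == 4:
        if data.shape[2] != 1:
            raise CurveError(f"expected a single-slice 4D volume, got shape {data.shape}")
        data = data[:, :, 0, :]
    if data.ndim != 3:
        raise CurveError(f"expected a 2D+t volume, got shape {data.shape}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    if "trigger_times_s" not in meta:
        raise CurveError(f"sidecar {sidecar} lacks key 'trigger_times_s'")
    return PerfusionSeries(data, np.asarray(meta["trigger_times_s"], dtype=float), patient_id)


def write_perfusion_nifti(series: PerfusionSeries, image_path, sidecar_path=None) -> None:
    image_path = Path(image_path)
    sidecar = Path(sidecar_path) if sidecar_path is not None else _sidecar_path(image_path)
    nib.save(nib.Nifti1Image(series.voxels, affine=np.eye(4)), str(image_path))
    with open(sidecar, "w") as fh:
        json.dump({"trigger_times_s": series.trigger_times.tolist()}, fh)


def read_mask_nifti(path, chamber: str) -> ROIMask:
    data = np.asarray(nib.load(str(path)).get_fdata())
    data = np.squeeze(data)
    if data.ndim != 2:
        raise CurveError(f"expected a 2D mask, got shape {data.shape}")
    return ROIMask(data > 0.5, chamber)


def write_mask_nifti(mask: ROIMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), affine=np.eye(4)), str(path))
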