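"""Volumetric stack containers and I/O.

All arrays in this package are indexed ``(z, y, x)`` = (plane, row, column);
x increases with the column index, matching camera readout. Coordinates are
0-based and intervals are half-open ``[a, b)``. The focus coordinate z is in
micrometres along the detection axis; every derived metric is a difference of
z values, so the sign convention of the stage cancels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

__all__ = ["FocusStack", "Volume", "read_stack", "write_stack", "write_report"]


@dataclass
class FocusStack:
    """A through-focus image stack of a calibration target.

    Parameters
    ----------
    data : ndarray, shape (n_planes, height, width)
        Non-negative intensities, one camera frame per focus position.
    z_positions_um : ndarray, shape (n_planes,)
        Focus position of each plane in µm, strictly monotonic.
    channel : str
        Free-text channel label (e.g. a filter name).
    pixel_size_um : float, optional
        Lateral pixel pitch in µm, if known.
    """

    data: np.ndarray
    z_positions_um: np.ndarray
    channel: str = ""
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.z_positions_um = np.asarray(self.z_positions_um, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3D (z, y, x), got ndim={self.data.ndim}")
        if self.data.size == 0:
            raise ValueError("stack data is empty")
        if self.z_positions_um.ndim != 1 or len(self.z_positions_um) != self.data.shape[0]:
            raise ValueError(
                f"z_positions_um length {len(self.z_positions_um)} does not match "
                f"{self.data.shape[0]} planes"
            )
        dz = np.diff(self.z_positions_um)
        if len(dz) and not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z_positions_um must be strictly monotonic")

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass
class Volume:
    """A 3D image volume with voxel calibration.

    ``voxel_size_um`` is ordered (z, y, x), matching the array axes.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D (z, y, x), got ndim={self.data.ndim}")
        if self.data.size == 0:
            raise ValueError("volume data is empty")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_um must be 3 positive values, got {self.voxel_size_um}")
        self.voxel_size_um = vs
        if np.issubdtype(self.data.dtype, np.floating) and np.nanmin(self.data) < 0:
            raise ValueError("volume intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def read_stack(
    path: str | Path,
    z_start_um: float,
    z_step_um: float,
    channel: str = "",
    pixel_size_um: float | None = None,
) -> FocusStack:
    """Read a multi-page grayscale TIFF as a :class:`FocusStack`.

    Plane ``k`` (in stored order) is assigned focus position
    ``z_start_um + k * z_step_um``. Any ImageJ-style metadata in the file is
    ignored; the z calibration is always supplied by the caller because
    acquisition stacks carry it only implicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack file: {path}")
    if not np.isfinite(z_step_um) or z_step_um == 0:
        raise ValueError(f"z_step_um must be finite and non-zero, got {z_step_um}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"{path} is not a grayscale multi-page TIFF (ndim={data.ndim})")
    z = z_start_um + z_step_um * np.arange(data.shape[0], dtype=float)
    return FocusStack(data=data, z_positions_um=z, channel=channel, pixel_size_um=pixel_size_um)


def read_volume(path: str | Path, voxel_size_um: tuple[float, float, float]) -> Volume:
    """Read a multi-page TIFF as a calibrated :class:`Volume`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis]
    return Volume(data=data, voxel_size_um=voxel_size_um)


def write_stack(stack: "FocusStack | Volume | np.ndarray", path: str | Path) -> None:
    """Write a stack or volume as a plain multi-page grayscale TIFF.

    Integer data round-trips bit-exactly through :func:`read_stack`; float
    data is stored as float32.
    """
    data = stack.data if isinstance(stack, (FocusStack, Volume)) else np.asarray(stack)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3 or data.size == 0:
        raise ValueError("can only write a non-empty 3D array")
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data, photometric="minisblack")


def _jsonable(obj: Any) -> Any:
    """Recursively convert to JSON-serializable types; NaN/inf become null."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: Any, path: str | Path, fmt: str = "json") -> None:
    """Serialize an analysis report.

    ``fmt="json"`` writes the full nested report (``report.to_dict()``)
    including metadata; ``fmt="csv"`` writes the flat per-item table
    (``report.to_frame()``: per-subregion, per-bead or per-candidate rows).
    NaN entries become JSON nulls / empty CSV cells.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        payload = report.to_dict() if hasattr(report, "to_dict") else report
        with open(path, "w") as fh:
            json.dump(_jsonable(payload), fh, indent=2, sort_keys=True, allow_nan=False)
            fh.write("\n")
    elif fmt == "csv":
        frame = report.to_frame() if hasattr(report, "to_frame") else pd.DataFrame(report)
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported report format: {fmt!r} (expected 'json' or 'csv')")
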