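"""Full-field objective contrast and field-flatness analysis.

A through-focus stack of a back-illuminated square-wave grating probes the
modulation transfer at the grating frequency across the whole camera field.
Each plane is split into a grid of subregions (default 32 x 20) and a
percentile-based Michelson contrast

    C = (P99 - P1) / (P99 + P1)

is computed per subregion per plane (1st/99th percentiles rather than
min/max, to reject noise). The resulting 3D contrast map C(x, y, z) yields:

* the best-focus surface z0(x, y) — the location of the contrast peak
  along z per subregion;
* the field-flatness sag — peak-to-valley of z0 after removing its
  least-squares tilt plane, which compensates residual tip/tilt of the
  test target;
* the maximum-contrast map C_max(x, y) (tilt-invariant), with mean and
  coefficient of variation as uniformity figures;
* a per-subregion depth-of-field map (relative-threshold z-extent of the
  local contrast curve);
* chromatic focal offsets between channels, from per-channel best-focus
  surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stacks import FocusStack

__all__ = [
    "SubregionGrid",
    "ContrastMap3D",
    "BestFocusSurface",
    "FlatnessReport",
    "ChromaticReport",
    "partition_grid",
    "subregion_contrast",
    "build_contrast_map",
    "max_contrast_map",
    "best_focus_surface",
    "fit_tilt_plane",
    "field_flatness",
    "depth_of_field_map",
    "contrast_uniformity",
    "chromatic_focal_offset",
    "RonchiContrastModel",
    "FlatnessResults",
]


# ---------------------------------------------------------------------------
# Subregion grid
# ---------------------------------------------------------------------------

@dataclass
class SubregionGrid:
    """A full-coverage grid of half-open pixel subregions.

    Boundary ``i`` sits at ``floor(i * extent / n_sub)``, so subregion sizes
    differ by at most one pixel across the grid.
    """

    nx_sub: int
    ny_sub: int
    width_px: int
    height_px: int
    col_bounds: np.ndarray
    row_bounds: np.ndarray

    @property
    def centers_px(self) -> tuple[np.ndarray, np.ndarray]:
        """(centers_x, centers_y) of subregions in pixel coordinates."""
        cx = (self.col_bounds[:-1] + self.col_bounds[1:] - 1) / 2.0
        cy = (self.row_bounds[:-1] + self.row_bounds[1:] - 1) / 2.0
        return cx, cy

    def normalized_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (xn, yn) of subregion centers in [-1, 1] field units."""
        cx, cy = self.centers_px
        xn = 2.0 * (cx + 0.5) / self.width_px - 1.0
        yn = 2.0 * (cy + 0.5) / self.height_px - 1.0
        return np.meshgrid(xn, yn)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ny_sub, self.nx_sub


def partition_grid(width_px: int, height_px: int, nx_sub: int = 32, ny_sub: int = 20) -> SubregionGrid:
    """Partition a frame into an ``nx_sub`` x ``ny_sub`` subregion grid."""
    if nx_sub < 1 or ny_sub < 1:
        raise ValueError("subregion counts must be >= 1")
    if nx_sub > width_px or ny_sub > height_px:
        raise ValueError(
            f"more subregions ({nx_sub}x{ny_sub}) than pixels ({width_px}x{height_px})"
        )
    col = np.floor(np.arange(nx_sub + 1) * width_px / nx_sub).astype(int)
    row = np.floor(np.arange(ny_sub + 1) * height_px / ny_sub).astype(int)
    return SubregionGrid(nx_sub, ny_sub, width_px, height_px, col, row)


# ---------------------------------------------------------------------------
# Percentile contrast
# ---------------------------------------------------------------------------

def subregion_contrast(values: np.ndarray) -> float:
    """Percentile-based Michelson contrast of an intensity sample.

    ``C = (P99 - P1) / (P99 + P1)`` with linear-interpolation percentiles
    (rank ``1 + q/100 * (n-1)``). Returns NaN when ``P99 + P1 == 0``
    (zero-signal subregion).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 intensity values")
    if not np.all(np.isfinite(v)):
        raise ValueError("intensities must be finite")
    if np.any(v < 0):
        raise ValueError("intensities must be non-negative")
    p1, p99 = np.percentile(v, [1.0, 99.0])
    denom = p99 + p1
    if denom == 0:
        return float("nan")
    return float((p99 - p1) / denom)


@dataclass
class ContrastMap3D:
    """Per-subregion contrast over the focus sweep, shape (ny_sub, nx_sub, n_planes)."""

    values: np.ndarray
    z_positions_um: np.ndarray
    grid: SubregionGrid
    channel: str = ""

    @property
    def n_planes(self) -> int:
        return self.values.shape[2]


def build_contrast_map(
    stack: FocusStack,
    grid: Optional[SubregionGrid] = None,
    saturation_value: Optional[float] = "auto",
    saturation_fraction: float = 0.01,
) -> ContrastMap3D:
    """Compute the 3D contrast map C(x, y, z) of a focus stack.

    A subregion is flagged NaN in a plane when more than
    ``saturation_fraction`` of its pixels sit at the saturation value (the
    99th percentile is meaningless under clipping). For integer stacks
    ``saturation_value="auto"`` uses the dtype maximum; pass None to disable.
    """
    h, w = stack.frame_shape
    if grid is None:
        grid = partition_grid(w, h)
    if grid.width_px != w or grid.height_px != h:
        raise ValueError(
            f"grid frame {grid.width_px}x{grid.height_px} does not match stack {w}x{h}"
        )
    sat = saturation_value
    if sat == "auto":
        sat = float(np.iinfo(stack.data.dtype).max) if np.issubdtype(
            stack.data.dtype, np.integer
        ) else None

    data = stack.data
    if np.issubdtype(data.dtype, np.floating) and np.nanmin(data) < 0:
        raise ValueError("stack intensities must be non-negative")
    nz = stack.n_planes
    out = np.empty((grid.ny_sub, grid.nx_sub, nz))
    for j in range(grid.ny_sub):
        r0, r1 = grid.row_bounds[j], grid.row_bounds[j + 1]
        for i in range(grid.nx_sub):
            c0, c1 = grid.col_bounds[i], grid.col_bounds[i + 1]
            sub = data[:, r0:r1, c0:c1].reshape(nz, -1).astype(float)
            p1, p99 = np.percentile(sub, [1.0, 99.0], axis=1)
            denom = p99 + p1
            with np.errstate(invalid="ignore", divide="ignore"):
                c = np.where(denom > 0, (p99 - p1) / denom, np.nan)
            if sat is not None:
                frac_sat = np.mean(sub >= sat, axis=1)
                c = np.where(frac_sat > saturation_fraction, np.nan, c)
            out[j, i] = c
    return ContrastMap3D(
        values=out, z_positions_um=stack.z_positions_um.copy(), grid=grid, channel=stack.channel
    )


def max_contrast_map(cmap: ContrastMap3D) -> np.ndarray:
    """Maximum contrast over z per subregion, C_max(x, y).

    Tilting the test target shifts where along z each subregion peaks, not
    the peak value, so this map is tip/tilt-invariant. Subregions that are
    invalid (NaN) at every plane stay NaN; an entirely NaN map is an error.
    """
    if cmap.values.shape[2] < 1:
        raise ValueError("contrast map has no planes")
    if np.all(np.isnan(cmap.values)):
        raise ValueError("contrast map is entirely NaN")
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmax(cmap.values, axis=2)


# ---------------------------------------------------------------------------
# Best-focus surface
# ---------------------------------------------------------------------------

@dataclass
class BestFocusSurface:
    """Best-focus position per subregion, with validity mask."""

    z0_um: np.ndarray
    peak_contrast: np.ndarray
    valid_mask: np.ndarray
    grid: SubregionGrid
    z_positions_um: np.ndarray = field(default=None, repr=False)
    channel: str = ""

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


def _parabolic_vertex(z: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Vertex of the parabola through three (z, c) points (Lagrange form)."""
    # quadratic coefficients via divided differences
    d1 = (c[1] - c[0]) / (z[1] - z[0])
    d2 = ((c[2] - c[1]) / (z[2] - z[1]) - d1) / (z[2] - z[0])
    if d2 >= 0:  # not concave: no interior maximum
        k = int(np.argmax(c))
        return float(z[k]), float(c[k])
    zv = 0.5 * (z[0] + z[1]) - d1 / (2.0 * d2)
    cv = c[0] + d1 * (zv - z[0]) + d2 * (zv - z[0]) * (zv - z[1])
    return float(zv), float(cv)


def _gaussian_peak(z: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Peak location/value from a full Gaussian + offset fit of c(z)."""
    k = int(np.argmax(c))
    p0 = [c[k] - c.min(), z[k], max((z.max() - z.min()) / 6.0, 1e-6), c.min()]

    def model(zz, a, mu, w, b):
        return a * np.exp(-((zz - mu) ** 2) / (2.0 * w**2)) + b

    try:
        popt, _ = curve_fit(model, z, c, p0=p0, maxfev=5000)
        a, mu, w_, b = popt
        if a <= 0 or not (z.min() <= mu <= z.max()):
            raise RuntimeError
        return float(mu), float(a + b)
    except Exception:
        lo = max(k - 1, 0)
        return _parabolic_vertex(z[lo:lo + 3], c[lo:lo + 3])


def best_focus_surface(cmap: ContrastMap3D, refine: str = "parabolic") -> BestFocusSurface:
    """Locate the contrast-vs-z peak per subregion.

    ``refine`` selects the peak estimator: ``"argmax"`` (sampled plane),
    ``"parabolic"`` (3-point interpolation around the argmax; default) or
    ``"gaussian"`` (full Gaussian + offset fit of the profile). Subregions
    whose peak falls on the sweep boundary, or that are all-NaN, are flagged
    invalid.
    """
    if refine not in ("argmax", "parabolic", "gaussian"):
        raise ValueError(f"unknown refine mode {refine!r}")
    z = cmap.z_positions_um
    if refine != "argmax" and len(z) < 3:
        raise ValueError(f"refine={refine!r} needs at least 3 planes")
    ny, nx, _ = cmap.values.shape
    z0 = np.full((ny, nx), np.nan)
    pk = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)
    for j in range(ny):
        for i in range(nx):
            prof = cmap.values[j, i]
            good = np.isfinite(prof)
            if good.sum() < (1 if refine == "argmax" else 3):
                continue
            zg, cg = z[good], prof[good]
            k = int(np.argmax(cg))
            if k == 0 or k == len(cg) - 1:
                continue  # peak at sweep boundary: unreliable
            if refine == "argmax":
                z0[j, i], pk[j, i] = zg[k], cg[k]
            elif refine == "parabolic":
                z0[j, i], pk[j, i] = _parabolic_vertex(zg[k - 1:k + 2], cg[k - 1:k + 2])
            else:
                z0[j, i], pk[j, i] = _gaussian_peak(zg, cg)
            valid[j, i] = True
    return BestFocusSurface(
        z0_um=z0, peak_contrast=pk, valid_mask=valid, grid=cmap.grid,
        z_positions_um=z.copy(), channel=cmap.channel,
    )


def fit_tilt_plane(surface: BestFocusSurface) -> tuple[float, float, float]:
    """Least-squares plane (a0, ax, ay) through valid z0 entries.

    Coordinates are subregion centers in normalized field units ([-1, 1]
    across each frame axis), so ax and ay are µm of focus shift per
    half-field. The plane absorbs residual tip/tilt of the test target.
    """
    xn, yn = surface.grid.normalized_centers()
    m = surface.valid_mask & np.isfinite(surface.z0_um)
    if m.sum() < 3:
        raise ValueError(f"need >= 3 valid subregions to fit a plane, have {int(m.sum())}")
    a = np.column_stack([np.ones(int(m.sum())), xn[m], yn[m]])
    if np.linalg.matrix_rank(a) < 3:
        raise ValueError("valid subregions are collinear; tilt plane is degenerate")
    coef, *_ = np.linalg.lstsq(a, surface.z0_um[m], rcond=None)
    return float(coef[0]), float(coef[1]), float(coef[2])


def field_flatness(surface: BestFocusSurface) -> tuple[tuple, np.ndarray, float, float]:
    """Tilt-compensated field flatness of a best-focus surface.

    Returns ``(plane_fit, detrended_z0, sag_um, sag_robust_um)`` where the
    sag is the peak-to-valley of z0 after subtracting the least-squares
    tilt plane, and the robust variant is the 2nd–98th percentile span
    (resistant to outlier subregions).
    """
    plane = fit_tilt_plane(surface)
    xn, yn = surface.grid.normalized_centers()
    trend = plane[0] + plane[1] * xn + plane[2] * yn
    det = np.where(surface.valid_mask, surface.z0_um - trend, np.nan)
    vals = det[np.isfinite(det)]
    sag = float(vals.max() - vals.min())
    sag_robust = float(np.percentile(vals, 98) - np.percentile(vals, 2))
    return plane, det, sag, sag_robust


def depth_of_field_map(cmap: ContrastMap3D, rel_threshold: float = 0.5) -> np.ndarray:
    """Per-subregion z-extent over which contrast stays above a relative threshold.

    The threshold is ``rel_threshold`` times the local peak contrast; the
    crossing points are linearly interpolated between focus samples. For a
    Gaussian contrast-vs-defocus curve of half-width w and the default
    threshold 0.5 this is the FWHM, ``2 w sqrt(2 ln 2)``. Subregions whose
    curve never falls below the threshold inside the sweep (peak at or near
    a boundary) are flagged NaN.
    """
    if not (0 < rel_threshold <= 1):
        raise ValueError("rel_threshold must lie in (0, 1]")
    z = cmap.z_positions_um
    ny, nx, _ = cmap.values.shape
    dof = np.full((ny, nx), np.nan)
    for j in range(ny):
        for i in range(nx):
            prof = cmap.values[j, i]
            good = np.isfinite(prof)
            if good.sum() < 3:
                continue
            zg, cg = z[good], prof[good]
            k = int(np.argmax(cg))
            peak = cg[k]
            if peak <= 0:
                continue
            thr = rel_threshold * peak
            # walk left from the peak to the first sample below threshold
            left = None
            for a in range(k, 0, -1):
                if cg[a - 1] < thr:
                    f = (thr - cg[a - 1]) / (cg[a] - cg[a - 1])
                    left = zg[a - 1] + f * (zg[a] - zg[a - 1])
                    break
            right = None
            for a in range(k, len(cg) - 1):
                if cg[a + 1] < thr:
                    f = (thr - cg[a]) / (cg[a + 1] - cg[a])
                    right = zg[a] + f * (zg[a + 1] - zg[a])
                    break
            if left is not None and right is not None:
                dof[j, i] = right - left
    return dof


@dataclass
class UniformityStats:
    mean: float
    sd: float
    cv: float
    min: float
    max: float
    argmin: tuple
    argmax: tuple


def contrast_uniformity(cmax: np.ndarray) -> UniformityStats:
    """NaN-aware mean, SD (population), CV and extrema of a C_max map."""
    v = np.asarray(cmax, dtype=float)
    m = np.isfinite(v)
    if not m.any():
        raise ValueError("uniformity undefined: all entries NaN")
    vals = v[m]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    masked = np.where(m, v, np.nan)
    amin = np.unravel_index(np.nanargmin(masked), v.shape)
    amax = np.unravel_index(np.nanargmax(masked), v.shape)
    return UniformityStats(
        mean=mean, sd=sd, cv=sd / mean if mean != 0 else float("nan"),
        min=float(vals.min()), max=float(vals.max()),
        argmin=tuple(int(a) for a in amin), argmax=tuple(int(a) for a in amax),
    )


# ---------------------------------------------------------------------------
# Chromatic offsets
# ---------------------------------------------------------------------------

@dataclass
class ChromaticReport:
    """Per-channel best-focus offsets relative to a reference channel.

    ``offsets_um[ch]`` is the median over the valid overlap of
    ``z0_ch - z0_ref``; offset maps for every ordered channel pair are kept
    (antisymmetric by construction).
    """

    reference_channel: str
    channel_centers_um: dict
    offsets_um: dict
    pairwise_offsets_um: dict
    offset_maps_um: dict

    def to_dict(self) -> dict:
        return {
            "reference_channel": self.reference_channel,
            "channel_centers_um": self.channel_centers_um,
            "offsets_um": self.offsets_um,
            "pairwise_offsets_um": {f"{a}->{b}": v for (a, b), v in self.pairwise_offsets_um.items()},
            "offset_maps_um": {f"{a}->{b}": m.tolist() for (a, b), m in self.offset_maps_um.items()},
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"channel": ch, "offset_um": off, "center_um": self.channel_centers_um[ch]}
            for ch, off in self.offsets_um.items()
        ]
        return pd.DataFrame(rows)


def chromatic_focal_offset(
    surfaces: dict[str, BestFocusSurface], reference: str
) -> ChromaticReport:
    """Chromatic focal offsets between per-channel best-focus surfaces.

    When an objective is tested through immersion medium the best-focus
    plane shifts with wavelength, so each channel must be refocused; the
    scalar offset per channel is the median of the per-subregion z0
    difference to the reference channel (robust to residual differences in
    field curvature).
    """
    if reference not in surfaces:
        raise ValueError(f"reference channel {reference!r} not among surfaces")
    shapes = {ch: s.grid.shape for ch, s in surfaces.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"surfaces use different grids: {shapes}")

    def overlap_median(sa: BestFocusSurface, sb: BestFocusSurface) -> tuple[float, np.ndarray]:
        m = sa.valid_mask & sb.valid_mask
        if m.sum() < 3:
            raise ValueError("fewer than 3 overlapping valid subregions")
        dmap = np.where(m, sa.z0_um - sb.z0_um, np.nan)
        return float(np.median(dmap[m])), dmap

    ref = surfaces[reference]
    offsets, centers = {}, {}
    pairwise, maps = {}, {}
    for ch, s in surfaces.items():
        centers[ch] = float(np.median(s.z0_um[s.valid_mask]))
        offsets[ch], _ = overlap_median(s, ref)
    chans = list(surfaces)
    for a in chans:
        for b in chans:
            v, dmap = overlap_median(surfaces[a], surfaces[b])
            pairwise[(a, b)] = v
            maps[(a, b)] = dmap
    return ChromaticReport(
        reference_channel=reference, channel_centers_um=centers,
        offsets_um=offsets, pairwise_offsets_um=pairwise, offset_maps_um=maps,
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class FlatnessReport:
    """Field-flatness metrics of one objective/channel measurement."""

    plane_fit: tuple
    detrended_z0_um: np.ndarray
    sag_um: float
    sag_robust_um: float
    cmax_map: np.ndarray
    contrast_mean: float
    contrast_sd: float
    contrast_cv: float
    dof_map_um: np.ndarray
    dof_median_um: float
    z_positions_um: np.ndarray
    grid_shape: tuple
    channel: str
    n_valid_subregions: int
    refine: str
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sag_um": self.sag_um,
            "sag_robust_um": self.sag_robust_um,
            "plane_fit": list(self.plane_fit),
            "detrended_z0_um": self.detrended_z0_um.tolist(),
            "cmax_map": self.cmax_map.tolist(),
            "contrast_mean": self.contrast_mean,
            "contrast_sd": self.contrast_sd,
            "contrast_cv": self.contrast_cv,
            "dof_map_um": self.dof_map_um.tolist(),
            "dof_median_um": self.dof_median_um,
            "z_positions_um": self.z_positions_um.tolist(),
            "grid_shape": list(self.grid_shape),
            "channel": self.channel,
            "n_valid_subregions": self.n_valid_subregions,
            "refine": self.refine,
            "metadata": self.metadata,
        }

    def to_frame(self) -> pd.DataFrame:
        ny, nx = self.grid_shape
        jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        return pd.DataFrame({
            "row_sub": jj.ravel(),
            "col_sub": ii.ravel(),
            "detrended_z0_um": self.detrended_z0_um.ravel(),
            "cmax": self.cmax_map.ravel(),
            "dof_um": self.dof_map_um.ravel(),
        })


class FlatnessResults:
    """Results of a :class:`RonchiContrastModel` fit.

    Carries the 3D contrast map, the best-focus surface and the flatness
    report; delegates report attributes for convenience.
    """

    def __init__(self, model: "RonchiContrastModel", contrast_map: ContrastMap3D,
                 surface: BestFocusSurface, report: FlatnessReport):
        self.model = model
        self.contrast_map = contrast_map
        self.surface = surface
        self.report = report

    def __getattr__(self, name):
        return getattr(self.report, name)

    def to_dict(self) -> dict:
        return self.report.to_dict()

    def to_frame(self) -> pd.DataFrame:
        return self.report.to_frame()

    def summary(self) -> str:
        r = self.report
        a0, ax, ay = r.plane_fit
        lines = [
            "Field flatness / contrast summary",
            "=" * 48,
            f"channel:              {r.channel or '(unnamed)'}",
            f"grid:                 {r.grid_shape[1]} x {r.grid_shape[0]} subregions",
            f"planes:               {len(r.z_positions_um)} "
            f"({r.z_positions_um[0]:+.0f} .. {r.z_positions_um[-1]:+.0f} um)",
            f"valid subregions:     {r.n_valid_subregions}",
            f"peak refinement:      {r.refine}",
            "-" * 48,
            f"sag (peak-to-valley): {r.sag_um:10.2f} um",
            f"sag (2-98% robust):   {r.sag_robust_um:10.2f} um",
            f"tilt plane a0,ax,ay:  {a0:+.2f}, {ax:+.2f}, {ay:+.2f} um",
            f"max contrast (mean):  {r.contrast_mean:10.4f}",
            f"max contrast (CV):    {r.contrast_cv:10.4f}",
            f"depth of field (med): {r.dof_median_um:10.2f} um",
        ]
        return "\n".join(lines)


class RonchiContrastModel:
    """Objective contrast/field-flatness analysis of a grating focus stack.

    Parameters
    ----------
    stack : FocusStack
        Through-focus stack of the back-illuminated grating.
    nx_sub, ny_sub : int
        Subregion grid (default 32 x 20).
    saturation_value : "auto", float or None
        Intensity treated as sensor saturation when flagging subregions.

    ``fit()`` returns a :class:`FlatnessResults`.
    """

    def __init__(self, stack: FocusStack, nx_sub: int = 32, ny_sub: int = 20,
                 saturation_value="auto"):
        self.stack = stack
        h, w = stack.frame_shape
        self.grid = partition_grid(w, h, nx_sub, ny_sub)
        self.saturation_value = saturation_value

    def fit(self, refine: str = "parabolic", dof_threshold: float = 0.5,
            metadata: Optional[dict] = None) -> FlatnessResults:
        cmap = build_contrast_map(self.stack, self.grid, self.saturation_value)
        surface = best_focus_surface(cmap, refine=refine)
        plane, det, sag, sag_rob = field_flatness(surface)
        cmax = max_contrast_map(cmap)
        uni = contrast_uniformity(cmax)
        dof = depth_of_field_map(cmap, dof_threshold)
        dof_vals = dof[np.isfinite(dof)]
        report = FlatnessReport(
            plane_fit=plane, detrended_z0_um=det, sag_um=sag, sag_robust_um=sag_rob,
            cmax_map=cmax, contrast_mean=uni.mean, contrast_sd=uni.sd, contrast_cv=uni.cv,
            dof_map_um=dof, dof_median_um=float(np.median(dof_vals)) if dof_vals.size else float("nan"),
            z_positions_um=self.stack.z_positions_um.copy(), grid_shape=self.grid.shape,
            channel=self.stack.channel, n_valid_subregions=surface.n_valid, refine=refine,
            metadata=metadata or {},
        )
        return FlatnessResults(self, cmap, surface, report)
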