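"""System resolution from sub-resolution fluorescent beads.

Bead centers are detected as 26-neighborhood local maxima above a robust
(median/MAD) noise floor, near-coincident beads (clusters) are excluded,
and each remaining bead is fitted with a Gaussian: a 2D elliptical Gaussian
with constant background on the bead's best plane for the lateral widths,
and a 1D Gaussian along z through the refined center for the axial width.
Widths convert to resolution as FWHM = 2 sqrt(2 ln 2) sigma; per-bead FWHMs
are summarized as field maps, histograms, mean and standard deviation.

The 0.2 µm physical bead diameter is neglected relative to the PSF width
(no deconvolution of the bead size) — a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit

from .stacks import Volume

__all__ = [
    "BeadCandidate",
    "BeadFit",
    "PSFReport",
    "detect_bead_candidates",
    "filter_bead_clusters",
    "fit_bead_gaussian",
    "sigma_to_fwhm",
    "summarize_psf",
    "BeadPSFModel",
    "PSFResults",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.35482


def sigma_to_fwhm(sigma: float) -> float:
    """Full width at half maximum of a Gaussian of width ``sigma``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return FWHM_PER_SIGMA * sigma


@dataclass
class BeadCandidate:
    """A detected local-maximum bead seed (integer voxel coordinates)."""

    center_vox: tuple  # (z, y, x)
    peak_intensity: float
    local_background: float


@dataclass
class BeadFit:
    """Gaussian fit of one bead; widths and FWHMs in µm."""

    status: str  # ok | edge | poor_fit | cluster
    center_um: Optional[tuple] = None  # (z, y, x)
    center_vox: Optional[tuple] = None
    sigma_x_um: Optional[float] = None
    sigma_y_um: Optional[float] = None
    sigma_z_um: Optional[float] = None
    amplitude: Optional[float] = None
    background: Optional[float] = None
    fwhm_x_um: Optional[float] = None
    fwhm_y_um: Optional[float] = None
    fwhm_lateral_um: Optional[float] = None
    fwhm_z_um: Optional[float] = None
    r_squared: Optional[float] = None


def detect_bead_candidates(
    volume: Volume, min_snr: float = 8.0, min_intensity: float = 0.0
) -> list[BeadCandidate]:
    """Detect bead seeds as 26-neighborhood local maxima above the noise floor.

    Background and noise are estimated globally and robustly (median and
    1.4826*MAD, insensitive to the sparse bright beads); a voxel qualifies
    when it exceeds ``background + min_snr * noise`` and ``min_intensity``.
    """
    data = np.asarray(volume.data, dtype=float)
    if data.shape[0] < 3:
        raise ValueError("bead detection needs a volume with >= 3 planes")
    bg = float(np.median(data))
    noise = 1.4826 * float(np.median(np.abs(data - bg)))
    thr = max(bg + min_snr * noise, min_intensity)
    local_max = data == ndimage.maximum_filter(data, size=3, mode="nearest")
    mask = local_max & (data > thr)
    # intensity ties on a plateau mark every tied voxel; keep one seed per
    # connected plateau (its rounded centroid)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    out = []
    for com in ndimage.center_of_mass(mask, labels, range(1, n + 1)):
        z, y, x = (int(round(c)) for c in com)
        out.append(BeadCandidate(
            center_vox=(z, y, x),
            peak_intensity=float(data[z, y, x]),
            local_background=bg,
        ))
    return out


def filter_bead_clusters(
    candidates: list[BeadCandidate],
    min_separation_um: float,
    voxel_size_um: tuple[float, float, float],
) -> list[BeadCandidate]:
    """Drop every candidate with a neighbor closer than ``min_separation_um``.

    Both members of a close pair are removed (a merged or overlapping pair
    cannot be fitted reliably); input order is preserved for the survivors.
    """
    if min_separation_um < 0:
        raise ValueError("min_separation_um must be >= 0")
    vs = np.asarray(voxel_size_um, dtype=float)
    pos = np.array([c.center_vox for c in candidates], dtype=float) * vs if candidates else np.empty((0, 3))
    drop = np.zeros(len(candidates), dtype=bool)
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if np.linalg.norm(pos[i] - pos[j]) < min_separation_um:
                drop[i] = drop[j] = True
    return [c for c, d in zip(candidates, drop) if not d]


def _gauss2d(coords, a, y0, x0, sy, sx, b):
    yy, xx = coords
    return (a * np.exp(-((yy - y0) ** 2) / (2 * sy**2) - ((xx - x0) ** 2) / (2 * sx**2)) + b).ravel()


def _gauss1d(z, a, z0, s, b):
    return a * np.exp(-((z - z0) ** 2) / (2 * s**2)) + b


def _r_squared(y: np.ndarray, fit: np.ndarray) -> float:
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return max(0.0, 1.0 - ss_res / ss_tot)


def fit_bead_gaussian(
    volume: Volume,
    candidate: BeadCandidate,
    window_vox: tuple[int, int, int] = (5, 4, 4),
    r2_min: float = 0.8,
) -> BeadFit:
    """Fit one bead with lateral (2D elliptical) and axial (1D) Gaussians.

    ``window_vox`` are half-widths (z, y, x) of the fit window around the
    seed. The lateral fit runs on the bead's best plane — the plane of
    maximum windowed intensity after a 3-plane z average (robust to
    single-plane noise); the axial profile is taken through the refined
    lateral center. Beads whose window clips the volume get status
    ``edge``; fits with r² < ``r2_min`` or widths pinned at the bounds get
    ``poor_fit``.
    """
    wz, wy, wx = (int(w) for w in window_vox)
    z, y, x = candidate.center_vox
    nz, ny, nx = volume.data.shape
    if z - wz < 0 or z + wz >= nz or y - wy < 0 or y + wy >= ny or x - wx < 0 or x + wx >= nx:
        return BeadFit(status="edge", center_vox=candidate.center_vox)
    win = np.asarray(
        volume.data[z - wz:z + wz + 1, y - wy:y + wy + 1, x - wx:x + wx + 1], dtype=float
    )

    smoothed = ndimage.uniform_filter1d(win, size=3, axis=0, mode="nearest")
    zb = int(np.argmax(smoothed.max(axis=(1, 2))))
    plane = win[zb]

    yy, xx = np.meshgrid(np.arange(plane.shape[0], dtype=float),
                         np.arange(plane.shape[1], dtype=float), indexing="ij")
    b0 = float(plane.min())
    a0 = float(plane.max() - b0)
    if a0 <= 0:
        return BeadFit(status="poor_fit", center_vox=candidate.center_vox)
    p0 = [a0, wy, wx, 1.5, 1.5, b0]
    smin, smax = 0.25, max(wy, wx)
    bounds = ([0, 0, 0, smin, smin, -np.inf],
              [np.inf, plane.shape[0] - 1, plane.shape[1] - 1, smax, smax, np.inf])
    try:
        popt, _ = curve_fit(_gauss2d, (yy, xx), plane.ravel(), p0=p0, bounds=bounds, maxfev=10000)
    except Exception:
        return BeadFit(status="poor_fit", center_vox=candidate.center_vox)
    a, y0, x0, sy, sx, b = popt
    r2_lat = _r_squared(plane.ravel(), _gauss2d((yy, xx), *popt))

    zi = np.arange(win.shape[0], dtype=float)
    yc, xc = int(round(y0)), int(round(x0))
    yc = min(max(yc, 0), win.shape[1] - 1)
    xc = min(max(xc, 0), win.shape[2] - 1)
    prof = win[:, yc, xc]
    pz0 = [float(prof.max() - prof.min()), float(zb), 1.5, float(prof.min())]
    zb_lo, zb_hi = ([0, 0, smin, -np.inf], [np.inf, win.shape[0] - 1, float(wz * 2), np.inf])
    try:
        poptz, _ = curve_fit(_gauss1d, zi, prof, p0=pz0, bounds=(zb_lo, zb_hi), maxfev=10000)
    except Exception:
        return BeadFit(status="poor_fit", center_vox=candidate.center_vox)
    az, zc, szv, bz = poptz
    r2_ax = _r_squared(prof, _gauss1d(zi, *poptz))

    r2 = min(r2_lat, r2_ax)
    pinned = (
        min(sy, sx) <= smin * 1.01 or max(sy, sx) >= smax * 0.99
        or szv <= smin * 1.01 or szv >= wz * 2 * 0.99
    )
    vz, vy, vx = volume.voxel_size_um
    sx_um, sy_um, sz_um = sx * vx, sy * vy, szv * vz
    center_um = ((z - wz + zc) * vz, (y - wy + y0) * vy, (x - wx + x0) * vx)
    status = "poor_fit" if (r2 < r2_min or pinned) else "ok"
    fx, fy, fz = (sigma_to_fwhm(s) for s in (sx_um, sy_um, sz_um))
    return BeadFit(
        status=status, center_um=center_um, center_vox=candidate.center_vox,
        sigma_x_um=sx_um, sigma_y_um=sy_um, sigma_z_um=sz_um,
        amplitude=float(a), background=float(b),
        fwhm_x_um=fx, fwhm_y_um=fy,
        fwhm_lateral_um=float(np.sqrt(fx * fy)),  # geometric mean of x/y FWHM
        fwhm_z_um=fz, r_squared=float(r2),
    )


@dataclass
class PSFReport:
    """Field-wide summary of per-bead FWHM measurements."""

    fits: list
    n_detected: int
    n_kept: int
    fwhm_lateral_mean_um: float
    fwhm_lateral_sd_um: float
    fwhm_axial_mean_um: float
    fwhm_axial_sd_um: float
    lateral_hist: tuple  # (counts, bin_edges_um)
    axial_hist: tuple
    positions_um: np.ndarray  # (n_ok, 3) bead centers (z, y, x)
    lateral_values_um: np.ndarray
    axial_values_um: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_ok(self) -> int:
        return len(self.lateral_values_um)

    def to_dict(self) -> dict:
        return {
            "n_detected": self.n_detected,
            "n_kept": self.n_kept,
            "n_ok": self.n_ok,
            "fwhm_lateral_mean_um": self.fwhm_lateral_mean_um,
            "fwhm_lateral_sd_um": self.fwhm_lateral_sd_um,
            "fwhm_axial_mean_um": self.fwhm_axial_mean_um,
            "fwhm_axial_sd_um": self.fwhm_axial_sd_um,
            "lateral_hist_counts": self.lateral_hist[0].tolist(),
            "lateral_hist_edges_um": self.lateral_hist[1].tolist(),
            "axial_hist_counts": self.axial_hist[0].tolist(),
            "axial_hist_edges_um": self.axial_hist[1].tolist(),
            "positions_um": self.positions_um.tolist(),
            "lateral_values_um": self.lateral_values_um.tolist(),
            "axial_values_um": self.axial_values_um.tolist(),
            "metadata": self.metadata,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            rows.append({
                "status": f.status,
                "z_um": f.center_um[0] if f.center_um else np.nan,
                "y_um": f.center_um[1] if f.center_um else np.nan,
                "x_um": f.center_um[2] if f.center_um else np.nan,
                "sigma_x_um": f.sigma_x_um, "sigma_y_um": f.sigma_y_um,
                "sigma_z_um": f.sigma_z_um,
                "fwhm_lateral_um": f.fwhm_lateral_um, "fwhm_z_um": f.fwhm_z_um,
                "amplitude": f.amplitude, "background": f.background,
                "r_squared": f.r_squared,
            })
        return pd.DataFrame(rows)


def summarize_psf(
    fits: list[BeadFit],
    bin_width_um: float = 0.25,
    n_detected: Optional[int] = None,
    metadata: Optional[dict] = None,
) -> PSFReport:
    """Summarize bead fits: mean/SD and histograms of lateral and axial FWHM.

    Statistics run over ``status == "ok"`` fits only; histogram bins have a
    fixed width (default 0.25 µm) starting at zero.
    """
    ok = [f for f in fits if f.status == "ok"]
    if not ok:
        raise ValueError("no bead fit with status 'ok' to summarize")
    lat = np.array([f.fwhm_lateral_um for f in ok])
    ax = np.array([f.fwhm_z_um for f in ok])
    pos = np.array([f.center_um for f in ok])

    def hist(v):
        hi = bin_width_um * (np.ceil(v.max() / bin_width_um) + 1)
        edges = np.arange(0.0, hi + bin_width_um / 2, bin_width_um)
        counts, edges = np.histogram(v, bins=edges)
        return counts, edges

    return PSFReport(
        fits=fits, n_detected=n_detected if n_detected is not None else len(fits),
        n_kept=len(fits),
        fwhm_lateral_mean_um=float(lat.mean()), fwhm_lateral_sd_um=float(lat.std(ddof=0)),
        fwhm_axial_mean_um=float(ax.mean()), fwhm_axial_sd_um=float(ax.std(ddof=0)),
        lateral_hist=hist(lat), axial_hist=hist(ax),
        positions_um=pos, lateral_values_um=lat, axial_values_um=ax,
        metadata=metadata or {},
    )


class PSFResults:
    """Results of a :class:`BeadPSFModel` fit."""

    def __init__(self, model: "BeadPSFModel", report: PSFReport):
        self.model = model
        self.report = report

    def __getattr__(self, name):
        return getattr(self.report, name)

    def to_dict(self) -> dict:
        return self.report.to_dict()

    def to_frame(self) -> pd.DataFrame:
        return self.report.to_frame()

    def summary(self) -> str:
        r = self.report
        return "\n".join([
            "Bead PSF summary",
            "=" * 48,
            f"candidates detected:  {r.n_detected}",
            f"kept after cluster/edge filtering: {r.n_ok}",
            "-" * 48,
            f"lateral FWHM: {r.fwhm_lateral_mean_um:6.2f} +/- {r.fwhm_lateral_sd_um:.2f} um",
            f"axial FWHM:   {r.fwhm_axial_mean_um:6.2f} +/- {r.fwhm_axial_sd_um:.2f} um",
        ])


class BeadPSFModel:
    """Bead-based PSF/resolution measurement on a calibrated volume.

    Detection, cluster exclusion and Gaussian fitting parameters are all
    explicit; ``fit()`` returns a :class:`PSFResults`.
    """

    def __init__(self, volume: Volume, min_snr: float = 8.0, min_intensity: float = 0.0,
                 min_separation_um: float = 10.0, window_vox: tuple = (5, 4, 4),
                 r2_min: float = 0.8, hist_bin_um: float = 0.25):
        self.volume = volume
        self.min_snr = min_snr
        self.min_intensity = min_intensity
        self.min_separation_um = min_separation_um
        self.window_vox = window_vox
        self.r2_min = r2_min
        self.hist_bin_um = hist_bin_um

    def fit(self, metadata: Optional[dict] = None) -> PSFResults:
        cands = detect_bead_candidates(self.volume, self.min_snr, self.min_intensity)
        kept = filter_bead_clusters(cands, self.min_separation_um, self.volume.voxel_size_um)
        removed = {id(c) for c in cands} - {id(c) for c in kept}
        fits = [BeadFit(status="cluster", center_vox=c.center_vox)
                for c in cands if id(c) in removed]
        fits += [fit_bead_gaussian(self.volume, c, self.window_vox, self.r2_min) for c in kept]
        report = summarize_psf(fits, self.hist_bin_um, n_detected=len(cands),
                               metadata=metadata or {})
        return PSFResults(self, report)
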