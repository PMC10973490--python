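"""Ground-truthed synthetic inputs for every pipeline.

Three generators emulate the calibration acquisitions the analyses consume:

* a through-focus stack of a back-illuminated square-wave (Ronchi) grating
  with a known, possibly curved and tilted, best-focus surface;
* a volume of sub-resolution fluorescent beads rendered as 3D anisotropic
  Gaussians with known centers and widths;
* a pair of repeated volumetric scans sharing sparse multi-plane bright
  tracks under independent noise realizations.

Each generator returns the simulated data together with a
:class:`GroundTruth` record, and is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .stacks import FocusStack, Volume

__all__ = [
    "RonchiConfig",
    "BeadConfig",
    "TrackConfig",
    "GroundTruth",
    "generate_focus_positions",
    "simulate_ronchi_stack",
    "simulate_bead_volume",
    "simulate_scan_pair",
    "ronchi_config_for_sag",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class GroundTruth:
    """Known truth emitted alongside a simulated dataset.

    Only the fields relevant to the generator that produced it are set.
    """

    # Ronchi stack truth
    z0_map_um: Optional[np.ndarray] = None            # per-pixel best focus (H, W)
    z0_subregions_um: Optional[np.ndarray] = None     # best focus at grid centers (ny, nx)
    true_sag_um: Optional[float] = None               # peak-to-valley of detrended z0 samples
    dof_width_um: Optional[float] = None
    cmax_subregions: Optional[np.ndarray] = None
    # bead volume truth
    bead_centers_vox: Optional[np.ndarray] = None     # (n, 3) sub-voxel (z, y, x)
    bead_sigma_um: Optional[tuple] = None             # (sx, sy, sz)
    cluster_pair_indices: Optional[list] = None       # list of (i, j) index pairs
    # scan-pair truth
    track_voxels_a: Optional[list] = None             # per track: (L, 3) int voxels in scan A
    track_voxels_b: Optional[list] = None
    registration_offset_vox: Optional[tuple] = None

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if v is None:
                continue
            if isinstance(v, np.ndarray):
                out[k] = v.tolist()
            elif isinstance(v, list):
                out[k] = [x.tolist() if isinstance(x, np.ndarray) else x for x in v]
            else:
                out[k] = v
        return out


def generate_focus_positions(z_min_um: float, z_max_um: float, step_um: float) -> np.ndarray:
    """Inclusive arithmetic focus sweep ``z_min, z_min+step, ..., z_max``.

    The count is ``floor((z_max - z_min)/step) + 1``; e.g. a sweep from
    -300 to +300 µm in 10 µm steps yields 61 positions.
    """
    if step_um <= 0:
        raise ValueError(f"step_um must be positive, got {step_um}")
    if z_max_um < z_min_um:
        raise ValueError("z_max_um must be >= z_min_um")
    n = int(np.floor((z_max_um - z_min_um) / step_um + 1e-9)) + 1
    return z_min_um + step_um * np.arange(n, dtype=float)


# ---------------------------------------------------------------------------
# Ronchi grating focus stacks
# ---------------------------------------------------------------------------

@dataclass
class RonchiConfig:
    """Configuration for a simulated through-focus Ronchi-grating stack.

    The grating is a horizontal-line square wave at ``lp_per_mm`` line pairs
    per mm (default 40). Local contrast falls off with defocus as a Gaussian
    of half-width ``dof_width_um`` around a best-focus surface

        z0(x, y) = a0 + ax*xn + ay*yn + c2*r**2 + c4*r**4   [µm]

    with (xn, yn) normalized to [-1, 1] across the frame and r the radial
    coordinate normalized to 1 at the frame corner. ``surface_coeffs`` is
    (a0, ax, ay, c2, c4). Peak contrast may fall off radially:
    C_peak(x, y) = cmax_peak * (1 - cmax_radial_falloff * r**2).
    """

    width_px: int = 320
    height_px: int = 200
    lp_per_mm: float = 40.0
    pixel_size_um: float = 5.0
    z_start_um: float = -300.0
    z_step_um: float = 10.0
    n_planes: int = 61
    surface_coeffs: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    dof_width_um: float = 40.0
    cmax_peak: float = 0.8
    cmax_radial_falloff: float = 0.0
    mean_level: float = 1000.0
    noise_sd: float = 20.0
    chromatic_offset_um: float = 0.0
    channel: str = ""
    nx_sub: int = 32
    ny_sub: int = 20
    phase_jitter_px: float = 0.0

    def __post_init__(self) -> None:
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.dof_width_um <= 0:
            raise ValueError("dof_width_um must be positive")
        if not (0.0 <= self.cmax_peak <= 1.0):
            raise ValueError("cmax_peak must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def period_px(self) -> float:
        return 1000.0 / (self.lp_per_mm * self.pixel_size_um)


def _normalized_coords(width: int, height: int, x: np.ndarray, y: np.ndarray):
    """Map pixel-center coordinates to [-1, 1] field coordinates and radius."""
    xn = 2.0 * (x + 0.5) / width - 1.0
    yn = 2.0 * (y + 0.5) / height - 1.0
    r2 = (xn**2 + yn**2) / 2.0  # r = 1 at the frame corner
    return xn, yn, r2


def _surface_z0(cfg: RonchiConfig, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    a0, ax, ay, c2, c4 = cfg.surface_coeffs
    xn, yn, r2 = _normalized_coords(cfg.width_px, cfg.height_px, x, y)
    return a0 + ax * xn + ay * yn + c2 * r2 + c4 * r2**2 + cfg.chromatic_offset_um


def _subregion_centers(n_px: int, n_sub: int) -> np.ndarray:
    bounds = np.floor(np.arange(n_sub + 1) * n_px / n_sub).astype(int)
    return (bounds[:-1] + bounds[1:] - 1) / 2.0


def _detrended_ptp(z0: np.ndarray, xn: np.ndarray, yn: np.ndarray) -> float:
    """Peak-to-valley after removing the least-squares plane (analytic truth)."""
    a = np.column_stack([np.ones(z0.size), xn.ravel(), yn.ravel()])
    coef, *_ = np.linalg.lstsq(a, z0.ravel(), rcond=None)
    resid = z0.ravel() - a @ coef
    return float(resid.max() - resid.min())


def simulate_ronchi_stack(cfg: RonchiConfig, seed: int) -> tuple[FocusStack, GroundTruth]:
    """Simulate a defocus sweep of a back-illuminated square-wave grating.

    Pixel model: ``I(x, y, z) = mean_level * (1 + C_local(x,y,z) * s(y)) + noise``
    where ``s(y)`` is a ±1 square wave along rows and
    ``C_local = C_peak(x,y) * exp(-(z - z0(x,y))**2 / (2 * dof_width_um**2))``.
    Output frames are rounded to uint16.
    """
    period = cfg.period_px
    if period < 4:
        raise ValueError(
            f"grating period {period:.2f} px is unresolvable; need >= 4 px "
            f"(lp_per_mm={cfg.lp_per_mm}, pixel_size_um={cfg.pixel_size_um})"
        )
    rng = np.random.default_rng(seed)
    h, w = cfg.height_px, cfg.width_px
    y = np.arange(h, dtype=float)
    x = np.arange(w, dtype=float)
    xx, yy = np.meshgrid(x, y)

    z0 = _surface_z0(cfg, xx, yy)
    _, _, r2 = _normalized_coords(w, h, xx, yy)
    c_peak = cfg.cmax_peak * (1.0 - cfg.cmax_radial_falloff * r2)

    phase = rng.uniform(0, period) if cfg.phase_jitter_px > 0 else 0.0
    s = np.where(((y + phase) % period) < period / 2.0, 1.0, -1.0)[:, None]

    z = generate_focus_positions(
        cfg.z_start_um, cfg.z_start_um + cfg.z_step_um * (cfg.n_planes - 1), cfg.z_step_um
    ) if cfg.n_planes > 1 else np.array([cfg.z_start_um])

    data = np.empty((cfg.n_planes, h, w), dtype=np.uint16)
    for k, zk in enumerate(z):
        c = c_peak * np.exp(-((zk - z0) ** 2) / (2.0 * cfg.dof_width_um**2))
        frame = cfg.mean_level * (1.0 + c * s)
        if cfg.noise_sd > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sd, size=frame.shape)
        data[k] = np.clip(np.rint(frame), 0, 65535).astype(np.uint16)

    # truth sampled at the analysis subregion centers
    cx = _subregion_centers(w, cfg.nx_sub)
    cy = _subregion_centers(h, cfg.ny_sub)
    gx, gy = np.meshgrid(cx, cy)
    z0_sub = _surface_z0(cfg, gx, gy)
    xn, yn, r2_sub = _normalized_coords(w, h, gx, gy)
    truth = GroundTruth(
        z0_map_um=z0,
        z0_subregions_um=z0_sub,
        true_sag_um=_detrended_ptp(z0_sub, xn, yn),
        dof_width_um=cfg.dof_width_um,
        cmax_subregions=cfg.cmax_peak * (1.0 - cfg.cmax_radial_falloff * r2_sub),
    )
    stack = FocusStack(
        data=data, z_positions_um=z, channel=cfg.channel, pixel_size_um=cfg.pixel_size_um
    )
    return stack, truth


def ronchi_config_for_sag(sag_um: float, **overrides) -> RonchiConfig:
    """Build a :class:`RonchiConfig` whose true (detrended) sag equals ``sag_um``.

    The field curvature term c2 is chosen so that the peak-to-valley of the
    best-focus surface sampled at the subregion centers is exactly the
    requested sag. Tilt terms in ``overrides`` do not change the detrended
    sag and may be combined freely.
    """
    if sag_um < 0:
        raise ValueError("sag_um must be >= 0")
    cfg = RonchiConfig(**overrides)
    cx = _subregion_centers(cfg.width_px, cfg.nx_sub)
    cy = _subregion_centers(cfg.height_px, cfg.ny_sub)
    gx, gy = np.meshgrid(cx, cy)
    _, _, r2 = _normalized_coords(cfg.width_px, cfg.height_px, gx, gy)
    span = float(r2.max() - r2.min())
    c2 = sag_um / span if sag_um > 0 else 0.0
    a0, ax, ay, _, c4 = cfg.surface_coeffs
    cfg.surface_coeffs = (a0, ax, ay, c2, c4)
    return cfg


# ---------------------------------------------------------------------------
# Bead volumes
# ---------------------------------------------------------------------------

@dataclass
class BeadConfig:
    """Configuration for a simulated sub-resolution fluorescent bead volume.

    Beads are rendered as 3D anisotropic Gaussians (the 0.2 µm physical bead
    diameter is far below typical mesoscale PSF widths, so point emitters are
    an adequate model). ``sigma_um`` is ordered (σx, σy, σz).
    """

    shape_vox: tuple = (48, 96, 96)
    voxel_size_um: tuple = (1.0, 0.85, 0.85)  # (z, y, x)
    n_beads: int = 50
    sigma_um: tuple = (0.66, 0.66, 1.40)      # (x, y, z): FWHM ~ 1.55 µm lat, 3.3 µm ax
    amplitude: float = 1000.0
    background: float = 100.0
    noise_sd: float = 50.0
    min_separation_vox: float = 12.0
    cluster_fraction: float = 0.0
    margin_vox: Optional[tuple] = None        # (z, y, x) keep-out from borders

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma_um):
            raise ValueError("sigma_um entries must be positive")
        if self.n_beads < 0:
            raise ValueError("n_beads must be >= 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    def sigma_vox(self) -> tuple[float, float, float]:
        """True widths in voxel units, ordered (z, y, x)."""
        sx, sy, sz = self.sigma_um
        vz, vy, vx = self.voxel_size_um
        return sz / vz, sy / vy, sx / vx


def _default_margin(cfg: BeadConfig) -> np.ndarray:
    sz, sy, sx = cfg.sigma_vox()
    return np.ceil(np.array([4 * sz, 4 * sy, 4 * sx])) + 3


def simulate_bead_volume(cfg: BeadConfig, seed: int) -> tuple[Volume, GroundTruth]:
    """Simulate a bead volume with known sub-voxel centers and widths.

    Centers are drawn uniformly at least a fit-window half-width from the
    borders and at least ``min_separation_vox`` apart (bounded rejection
    sampling). A ``cluster_fraction`` of the beads get a near-coincident
    companion, flagged as planted pairs in the ground truth.
    """
    rng = np.random.default_rng(seed)
    shape = np.asarray(cfg.shape_vox, dtype=int)
    margin = np.asarray(cfg.margin_vox, float) if cfg.margin_vox is not None else _default_margin(cfg)
    lo, hi = margin, shape - 1 - margin
    if np.any(hi <= lo):
        raise ValueError("volume too small for the bead keep-out margin")

    centers: list[np.ndarray] = []
    max_tries = 1000 * max(cfg.n_beads, 1)
    tries = 0
    while len(centers) < cfg.n_beads:
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {cfg.n_beads} beads with min_separation_vox="
                f"{cfg.min_separation_vox} in shape {tuple(shape)}"
            )
        tries += 1
        cand = rng.uniform(lo, hi)
        if all(np.linalg.norm(cand - c) >= cfg.min_separation_vox for c in centers):
            centers.append(cand)

    n_pairs = int(round(cfg.cluster_fraction * cfg.n_beads))
    pair_indices: list[tuple[int, int]] = []
    for i in range(n_pairs):
        base = centers[i]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        companion = np.clip(base + direction * rng.uniform(1.5, 3.0), lo, hi)
        pair_indices.append((i, len(centers)))
        centers.append(companion)

    data = np.full(tuple(shape), float(cfg.background))
    sz, sy, sx = cfg.sigma_vox()
    sig = np.array([sz, sy, sx])
    half = np.ceil(4 * sig).astype(int)
    for c in centers:
        c0 = np.rint(c).astype(int)
        lo_w = np.maximum(c0 - half, 0)
        hi_w = np.minimum(c0 + half + 1, shape)
        zz, yy, xx = np.meshgrid(
            *(np.arange(lo_w[d], hi_w[d], dtype=float) for d in range(3)), indexing="ij"
        )
        g = cfg.amplitude * np.exp(
            -((zz - c[0]) ** 2) / (2 * sz**2)
            - ((yy - c[1]) ** 2) / (2 * sy**2)
            - ((xx - c[2]) ** 2) / (2 * sx**2)
        )
        data[lo_w[0]:hi_w[0], lo_w[1]:hi_w[1], lo_w[2]:hi_w[2]] += g

    if cfg.noise_sd > 0:
        data = data + rng.normal(0.0, cfg.noise_sd, size=data.shape)
    data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)

    truth = GroundTruth(
        bead_centers_vox=np.array(centers) if centers else np.empty((0, 3)),
        bead_sigma_um=tuple(cfg.sigma_um),
        cluster_pair_indices=pair_indices,
    )
    return Volume(data=data, voxel_size_um=cfg.voxel_size_um), truth


# ---------------------------------------------------------------------------
# Repeated-scan pairs with planted tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackConfig:
    """Configuration for a pair of repeated scans sharing sparse tracks.

    Tracks are anti-diagonal runs of bright voxels advancing one voxel per
    plane, spanning ``track_length_planes`` planes — the morphology of a
    linear structure crossing the light sheet obliquely. The second scan
    holds the same structures shifted by ``registration_offset_vox`` under an
    independent noise realization.
    """

    shape_vox: tuple = (32, 64, 64)
    n_tracks: int = 3
    track_length_planes: int = 5
    track_intensity: float = 100.0
    background_mean: float = 100.0
    background_sd: float = 10.0
    registration_offset_vox: tuple = (1, 1, 1)
    voxel_size_um: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.track_length_planes < 1:
            raise ValueError("track_length_planes must be >= 1")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        if any(abs(o) > 3 for o in self.registration_offset_vox):
            raise ValueError("registration_offset_vox entries must be within ±3")


def simulate_scan_pair(cfg: TrackConfig, seed: int) -> tuple[Volume, Volume, GroundTruth]:
    """Simulate two consecutive scans of the same sparse bright structures."""
    shape = np.asarray(cfg.shape_vox, dtype=int)
    L = cfg.track_length_planes
    if L > shape[0]:
        raise ValueError(f"track spans {L} planes but volume has only {shape[0]}")
    rng = np.random.default_rng(seed)
    off = np.asarray(cfg.registration_offset_vox, dtype=int)

    # keep tracks clear of borders in both scans (halo for the offset + margin)
    margin = np.maximum(np.abs(off), 0) + 4
    step = np.array([1, 1, -1])  # anti-diagonal: +z, +y, -x
    starts: list[np.ndarray] = []
    tries = 0
    while len(starts) < cfg.n_tracks:
        if tries > 1000 * max(cfg.n_tracks, 1):
            raise RuntimeError("could not place tracks inside the volume")
        tries += 1
        lo = margin + np.where(step < 0, L, 0)
        hi = shape - margin - np.where(step > 0, L, 0)
        if np.any(hi <= lo):
            raise ValueError("volume too small for the requested tracks")
        cand = rng.integers(lo, hi)
        if all(np.linalg.norm(cand - s) > 2 * L for s in starts):
            starts.append(cand)

    tracks_a = [np.array([s + t * step for t in range(L)]) for s in starts]
    tracks_b = [ta + off for ta in tracks_a]

    def render(tracks: list[np.ndarray]) -> np.ndarray:
        vol = np.full(tuple(shape), float(cfg.background_mean))
        for tr in tracks:
            vol[tr[:, 0], tr[:, 1], tr[:, 2]] += cfg.track_intensity
        if cfg.background_sd > 0:
            vol = vol + rng.normal(0.0, cfg.background_sd, size=vol.shape)
        return np.clip(np.rint(vol), 0, 65535).astype(np.uint16)

    scan_a = render(tracks_a)
    scan_b = render(tracks_b)
    truth = GroundTruth(
        track_voxels_a=tracks_a,
        track_voxels_b=tracks_b,
        registration_offset_vox=tuple(int(o) for o in off),
    )
    return (
        Volume(data=scan_a, voxel_size_um=cfg.voxel_size_um),
        Volume(data=scan_b, voxel_size_um=cfg.voxel_size_um),
        truth,
    )
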