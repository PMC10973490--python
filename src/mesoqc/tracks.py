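"""Cross-correlation validation of rare fluorescent structures.

Sparse bright multi-plane structures (e.g. candidate particle tracks from
fluorescent lattice defects in an irradiated crystal) found in one
volumetric scan are validated against an independent repeated scan of the
same sample: each cluster is cut out as a template and normalized
cross-correlation (NCC) is computed over a search window around the
corresponding region of the other scan. On structureless noise the NCC
values follow a Gaussian null centered on zero; a genuine structure shows
up as a far outlier (several sigma) of that null. Candidates flagged in
both directions (A against B and B against A) are reported as confirmed —
a structure found repeatedly in more than one scan is unlikely to be a
noise artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import match_template

from .stacks import Volume

__all__ = [
    "BackgroundModel",
    "StructureCluster",
    "CandidateScore",
    "TrackReport",
    "estimate_background",
    "find_structure_clusters",
    "ncc_map",
    "score_candidate",
    "validate_scan_pair",
    "ScanPairModel",
    "TrackResults",
]


@dataclass
class BackgroundModel:
    """Per-dataset background intensity statistics (camera noise / blanks)."""

    mean: float
    sd: float
    n_frames_used: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("background sd must be >= 0")
        if self.n_frames_used < 1:
            raise ValueError("n_frames_used must be >= 1")


def estimate_background(frames, robust: bool = False) -> BackgroundModel:
    """Estimate background mean and SD from dark/blank frames.

    Accepts a :class:`Volume` or a 2D/3D array; statistics run over all
    voxels. With ``robust=True`` the median and 1.4826*MAD are used instead,
    which tolerates sparse bright outliers in blank-control stacks.
    """
    data = frames.data if isinstance(frames, Volume) else np.asarray(frames)
    if data.size == 0:
        raise ValueError("no frames provided")
    if data.ndim == 2:
        data = data[np.newaxis]
    v = data.astype(float).ravel()
    if robust:
        med = float(np.median(v))
        sd = 1.4826 * float(np.median(np.abs(v - med)))
        return BackgroundModel(mean=med, sd=sd, n_frames_used=data.shape[0])
    return BackgroundModel(mean=float(v.mean()), sd=float(v.std(ddof=0)),
                           n_frames_used=data.shape[0])


@dataclass
class StructureCluster:
    """A 26-connected component of above-threshold voxels."""

    voxels: np.ndarray          # (n, 3) int (z, y, x)
    bbox: tuple                 # ((z0, z1), (y0, y1), (x0, x1)) half-open
    n_planes_spanned: int
    total_intensity: float
    centroid: tuple             # (z, y, x) float

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def find_structure_clusters(
    volume: Volume,
    bg: BackgroundModel,
    k_sigma: float = 5.0,
    min_voxels: int = 4,
) -> list[StructureCluster]:
    """Find 26-connected clusters of voxels above ``bg.mean + k_sigma*bg.sd``.

    Raw sensor data is never literally zero, so "non-zero intensity" is
    operationalized as exceeding the background by ``k_sigma`` standard
    deviations; components smaller than ``min_voxels`` are discarded.
    """
    if k_sigma < 0:
        raise ValueError("k_sigma must be >= 0")
    data = np.asarray(volume.data, dtype=float)
    thr = bg.mean + k_sigma * bg.sd
    mask = data > thr
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    out: list[StructureCluster] = []
    if n == 0:
        return out
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        vox = np.argwhere(labels == lab)
        if len(vox) < min_voxels:
            continue
        zs, ys, xs = vox[:, 0], vox[:, 1], vox[:, 2]
        out.append(StructureCluster(
            voxels=vox,
            bbox=((int(zs.min()), int(zs.max()) + 1),
                  (int(ys.min()), int(ys.max()) + 1),
                  (int(xs.min()), int(xs.max()) + 1)),
            n_planes_spanned=int(zs.max() - zs.min() + 1),
            total_intensity=float(data[zs, ys, xs].sum()),
            centroid=tuple(float(c) for c in vox.mean(axis=0)),
        ))
    return out


def ncc_map(template: np.ndarray, search: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of a template over a search volume.

    At each valid placement the Pearson correlation between the template and
    the overlapping search window is returned (values in [-1, 1]); the
    output shape is ``search.shape - template.shape + 1`` per axis.
    Zero-variance search windows yield 0.
    """
    t = np.asarray(template, dtype=float)
    s = np.asarray(search, dtype=float)
    if t.ndim != s.ndim:
        raise ValueError("template and search must have the same dimensionality")
    if any(ts > ss for ts, ss in zip(t.shape, s.shape)):
        raise ValueError(f"template {t.shape} larger than search {s.shape}")
    if float(t.std()) == 0.0:
        raise ValueError("template has zero variance")
    res = match_template(s, t, pad_input=False)
    res = np.nan_to_num(res, nan=0.0, posinf=0.0, neginf=0.0)
    return np.clip(res, -1.0, 1.0)


@dataclass
class CandidateScore:
    """NCC validation score of one cluster against the repeated scan."""

    cluster: StructureCluster
    ncc_peak: float
    peak_offset_vox: tuple        # peak location minus expected (registered) location
    null_mean: float
    null_sd: float
    z_score: float
    flagged: bool
    ncc_values: np.ndarray = field(repr=False, default=None)  # null sample (peak excluded)
    ncc_hist: tuple = None        # (counts, bin_edges)


def score_candidate(
    cluster: StructureCluster,
    scan_a: Volume,
    scan_b: Volume,
    pad_vox: int = 2,
    search_halo_vox: int = 10,
    threshold_sigma: float = 5.0,
    robust_null: bool = False,
) -> CandidateScore:
    """Score a cluster found in scan A against the repeated scan B.

    The template is the cluster bounding box padded by ``pad_vox`` cut from
    scan A; the search region is the corresponding region of scan B grown by
    ``search_halo_vox`` (absorbing small rigid misregistration between
    consecutive scans). The Gaussian null (mean, sd) is fitted to all NCC
    values excluding the 3x3x3 neighborhood of the global peak, so a genuine
    match does not inflate the null; the candidate is flagged when
    ``z_score >= threshold_sigma``.
    """
    shape = np.asarray(scan_a.data.shape)
    lo = np.array([b[0] for b in cluster.bbox]) - pad_vox
    hi = np.array([b[1] for b in cluster.bbox]) + pad_vox
    lo_t = np.maximum(lo, 0)
    hi_t = np.minimum(hi, shape)
    template = np.asarray(
        scan_a.data[lo_t[0]:hi_t[0], lo_t[1]:hi_t[1], lo_t[2]:hi_t[2]], dtype=float
    )
    lo_s = np.maximum(lo_t - search_halo_vox, 0)
    hi_s = np.minimum(hi_t + search_halo_vox, np.asarray(scan_b.data.shape))
    search = np.asarray(
        scan_b.data[lo_s[0]:hi_s[0], lo_s[1]:hi_s[1], lo_s[2]:hi_s[2]], dtype=float
    )
    res = ncc_map(template, search)

    peak_idx = np.unravel_index(int(np.argmax(res)), res.shape)
    peak = float(res[peak_idx])
    # placement index of a perfectly registered match
    expected = lo_t - lo_s
    offset = tuple(int(p - e) for p, e in zip(peak_idx, expected))

    excl = np.zeros(res.shape, dtype=bool)
    sl = tuple(slice(max(p - 1, 0), min(p + 2, n)) for p, n in zip(peak_idx, res.shape))
    excl[sl] = True
    null_vals = res[~excl]
    if null_vals.size < 8:
        raise ValueError("search window too small to fit an NCC null distribution")
    if robust_null:
        mu = float(np.median(null_vals))
        sd = 1.4826 * float(np.median(np.abs(null_vals - mu)))
    else:
        mu = float(null_vals.mean())
        sd = float(null_vals.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate NCC null distribution (sd = 0)")
    z = (peak - mu) / sd
    counts, edges = np.histogram(null_vals, bins=40, range=(-1.0, 1.0))
    return CandidateScore(
        cluster=cluster, ncc_peak=peak, peak_offset_vox=offset,
        null_mean=mu, null_sd=sd, z_score=float(z),
        flagged=bool(z >= threshold_sigma),
        ncc_values=null_vals, ncc_hist=(counts, edges),
    )


@dataclass
class TrackReport:
    """Two-directional validation report for a repeated-scan pair."""

    scores_ab: list               # clusters from A scored against B
    scores_ba: list
    confirmed: list               # list of (score_ab, score_ba) matched pairs
    n_clusters_a: int
    n_clusters_b: int
    n_confirmed: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def score_dict(s: CandidateScore) -> dict:
            return {
                "centroid_vox": list(s.cluster.centroid),
                "n_voxels": s.cluster.n_voxels,
                "n_planes_spanned": s.cluster.n_planes_spanned,
                "ncc_peak": s.ncc_peak,
                "peak_offset_vox": list(s.peak_offset_vox),
                "null_mean": s.null_mean,
                "null_sd": s.null_sd,
                "z_score": s.z_score,
                "flagged": s.flagged,
            }
        return {
            "n_clusters_a": self.n_clusters_a,
            "n_clusters_b": self.n_clusters_b,
            "n_confirmed": self.n_confirmed,
            "candidates_ab": [score_dict(s) for s in self.scores_ab],
            "candidates_ba": [score_dict(s) for s in self.scores_ba],
            "confirmed": [
                {"a": score_dict(sa), "b": score_dict(sb)} for sa, sb in self.confirmed
            ],
            "params": self.params,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for direction, scores in (("A->B", self.scores_ab), ("B->A", self.scores_ba)):
            for s in scores:
                rows.append({
                    "direction": direction,
                    "z_vox": s.cluster.centroid[0], "y_vox": s.cluster.centroid[1],
                    "x_vox": s.cluster.centroid[2],
                    "n_voxels": s.cluster.n_voxels,
                    "n_planes_spanned": s.cluster.n_planes_spanned,
                    "ncc_peak": s.ncc_peak, "null_mean": s.null_mean,
                    "null_sd": s.null_sd, "z_score": s.z_score, "flagged": s.flagged,
                })
        return pd.DataFrame(rows)


def validate_scan_pair(
    scan_a: Volume,
    scan_b: Volume,
    bg: BackgroundModel,
    k_sigma: float = 5.0,
    min_voxels: int = 4,
    pad_vox: int = 2,
    search_halo_vox: int = 10,
    threshold_sigma: float = 5.0,
    match_radius_vox: Optional[float] = None,
    robust_null: bool = False,
) -> TrackReport:
    """Detect clusters in both scans and confirm them by mutual NCC scoring.

    A candidate is confirmed when a cluster is flagged scoring A against B
    and a cluster at the corresponding (offset-corrected) location is
    flagged scoring B against A.
    """
    if scan_a.data.shape != scan_b.data.shape:
        raise ValueError(
            f"scan shapes differ: {scan_a.data.shape} vs {scan_b.data.shape}"
        )
    if match_radius_vox is None:
        match_radius_vox = float(search_halo_vox)

    clusters_a = find_structure_clusters(scan_a, bg, k_sigma, min_voxels)
    clusters_b = find_structure_clusters(scan_b, bg, k_sigma, min_voxels)
    scores_ab = [
        score_candidate(c, scan_a, scan_b, pad_vox, search_halo_vox, threshold_sigma,
                        robust_null)
        for c in clusters_a
    ]
    scores_ba = [
        score_candidate(c, scan_b, scan_a, pad_vox, search_halo_vox, threshold_sigma,
                        robust_null)
        for c in clusters_b
    ]
    confirmed = []
    used_b: set[int] = set()
    for sa in scores_ab:
        if not sa.flagged:
            continue
        ca = np.asarray(sa.cluster.centroid)
        best, best_d = None, np.inf
        for jb, sb in enumerate(scores_ba):
            if not sb.flagged or jb in used_b:
                continue
            d = float(np.linalg.norm(np.asarray(sb.cluster.centroid) - ca))
            if d < best_d:
                best, best_d = jb, d
        if best is not None and best_d <= match_radius_vox:
            used_b.add(best)
            confirmed.append((sa, scores_ba[best]))
    return TrackReport(
        scores_ab=scores_ab, scores_ba=scores_ba, confirmed=confirmed,
        n_clusters_a=len(clusters_a), n_clusters_b=len(clusters_b),
        n_confirmed=len(confirmed),
        params={
            "k_sigma": k_sigma, "min_voxels": min_voxels, "pad_vox": pad_vox,
            "search_halo_vox": search_halo_vox, "threshold_sigma": threshold_sigma,
            "match_radius_vox": match_radius_vox, "robust_null": robust_null,
            "background_mean": bg.mean, "background_sd": bg.sd,
        },
    )


class TrackResults:
    """Results of a :class:`ScanPairModel` fit."""

    def __init__(self, model: "ScanPairModel", report: TrackReport):
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
        lines = [
            "Repeated-scan track validation",
            "=" * 48,
            f"clusters in scan A:   {r.n_clusters_a}",
            f"clusters in scan B:   {r.n_clusters_b}",
            f"confirmed candidates: {r.n_confirmed}",
        ]
        for sa, sb in r.confirmed:
            lines.append(
                f"  at (z,y,x)=({sa.cluster.centroid[0]:.0f},"
                f"{sa.cluster.centroid[1]:.0f},{sa.cluster.centroid[2]:.0f}) vox: "
                f"z-score {sa.z_score:.1f} (A->B), {sb.z_score:.1f} (B->A)"
            )
        return "\n".join(lines)


class ScanPairModel:
    """Repeated-scan validation of sparse bright structures.

    If no :class:`BackgroundModel` is given it is estimated robustly
    (median/MAD) from scan A, which is valid when structures are sparse.
    ``fit()`` returns a :class:`TrackResults`.
    """

    def __init__(self, scan_a: Volume, scan_b: Volume,
                 background: Optional[BackgroundModel] = None,
                 k_sigma: float = 5.0, min_voxels: int = 4, pad_vox: int = 2,
                 search_halo_vox: int = 10, threshold_sigma: float = 5.0,
                 robust_null: bool = False):
        self.scan_a = scan_a
        self.scan_b = scan_b
        self.background = background or estimate_background(scan_a, robust=True)
        self.k_sigma = k_sigma
        self.min_voxels = min_voxels
        self.pad_vox = pad_vox
        self.search_halo_vox = search_halo_vox
        self.threshold_sigma = threshold_sigma
        self.robust_null = robust_null

    def fit(self) -> TrackResults:
        report = validate_scan_pair(
            self.scan_a, self.scan_b, self.background,
            k_sigma=self.k_sigma, min_voxels=self.min_voxels, pad_vox=self.pad_vox,
            search_halo_vox=self.search_halo_vox, threshold_sigma=self.threshold_sigma,
            robust_null=self.robust_null,
        )
        return TrackResults(self, report)
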