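import numpy as np
import pytest

from mesoqc import (
    BeadConfig,
    RonchiConfig,
    TrackConfig,
    simulate_bead_volume,
    simulate_ronchi_stack,
    simulate_scan_pair,
)


def sorted_percentile(values, q):
    """Independent percentile oracle: sorted-order linear interpolation,
    rank = 1 + q/100 * (n - 1) (1-based)."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    rank = q / 100.0 * (v.size - 1)
    lo = int(np.floor(rank))
    hi = min(lo + 1, v.size - 1)
    frac = rank - lo
    # interpolate from the nearer endpoint so rounding is symmetric
    if frac < 0.5:
        return v[lo] + (v[hi] - v[lo]) * frac
    return v[hi] - (v[hi] - v[lo]) * (1 - frac)


def contrast_oracle(values):
    """Brute-force percentile contrast used to cross-check the pipeline."""
    p1 = sorted_percentile(values, 1.0)
    p99 = sorted_percentile(values, 99.0)
    return (p99 - p1) / (p99 + p1)


def ncc_oracle(template, search):
    """Direct triple-loop normalized cross-correlation (no FFT tricks)."""
    t = np.asarray(template, dtype=float)
    s = np.asarray(search, dtype=float)
    tz, ty, tx = t.shape
    out_shape = tuple(np.array(s.shape) - np.array(t.shape) + 1)
    out = np.empty(out_shape)
    tc = t - t.mean()
    tn = np.sqrt((tc**2).sum())
    for i in range(out_shape[0]):
        for j in range(out_shape[1]):
            for k in range(out_shape[2]):
                w = s[i:i + tz, j:j + ty, k:k + tx]
                wc = w - w.mean()
                denom = tn * np.sqrt((wc**2).sum())
                out[i, j, k] = (tc * wc).sum() / denom if denom > 0 else 0.0
    return out


@pytest.fixture(scope="session")
def small_ronchi():
    """Noiseless flat-field grating stack: contrast peaks at z = 0 everywhere."""
    cfg = RonchiConfig(width_px=160, height_px=100, n_planes=21, z_start_um=-100.0,
                       noise_sd=0.0, nx_sub=16, ny_sub=10)
    stack, truth = simulate_ronchi_stack(cfg, seed=11)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def bead_volume_snr20():
    cfg = BeadConfig(n_beads=30, shape_vox=(40, 80, 80))
    vol, truth = simulate_bead_volume(cfg, seed=5)
    return cfg, vol, truth


@pytest.fixture(scope="session")
def scan_pair():
    cfg = TrackConfig()
    a, b, truth = simulate_scan_pair(cfg, seed=7)
    return cfg, a, b, truth
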