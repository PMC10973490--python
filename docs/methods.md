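# Methods

This note documents the models, estimators, defaults and numerical choices
behind each pipeline, what the synthetic generators do and do not emulate,
and the known limitations.

## Contrast and field flatness

### Measurement model

A back-illuminated square-wave grating (default 40 line pairs/mm,
horizontal bars) is imaged through the detection path while the objective
sweeps focus in fixed steps (default 10 µm over ±300 µm, 61 planes). Each
plane is partitioned into a 32 × 20 grid of half-open pixel subregions
(boundary *i* at `floor(i·W/n)`, so sizes differ by ≤1 px), and the
contrast of subregion (i, j) at focus k is

    C = (P99 − P1) / (P99 + P1),

the 1st/99th percentiles standing in for min/max so that isolated hot or
cold pixels cannot dominate. Percentiles use sorted-order linear
interpolation (rank `1 + q/100·(n−1)`), the dominant convention, fixed so
results are bit-reproducible. A subregion is flagged invalid (NaN) in a
plane when more than 1% of its pixels sit at the sensor saturation value,
because the 99th percentile is meaningless under clipping.

`C(x, y, z)` samples the modulation transfer at the grating frequency; no
attempt is made to probe other frequencies or orientations, or to
decompose the maps into named aberrations.

### Best-focus surface and sag

Per subregion, the best focus `z0` is the peak of `C(z)`. Three estimators
are available:

* `argmax` — the sampled plane of maximum contrast;
* `parabolic` (default) — vertex of the parabola through the argmax and
  its two neighbors, a standard sub-step refinement;
* `gaussian` — peak of a Gaussian-plus-offset fit to the whole profile.

Peaks falling on the sweep boundary are flagged invalid rather than
extrapolated. Field flatness is reported as the **sag**: the peak-to-valley
of `z0` after subtracting its ordinary-least-squares plane (fitted over
valid subregions in normalized field coordinates). The plane subtraction
compensates residual tip/tilt of the physical test target, which shifts
`z0` but not the shape of the surface. A robust variant (2nd–98th
percentile span of the detrended surface) is reported alongside, since
peak-to-valley is an extreme-value statistic.

That last point drives an important practical choice: peak-to-valley
aggregates the *extremes* of per-subregion noise, so with 640 subregions
even sub-µm noise in each `z0` inflates the sag of a genuinely flat field
by many times that noise. The 3-point parabolic estimator, which uses only
three samples near the peak, leaves ~1 µm of per-subregion jitter at 2%
camera noise — enough to report ~10 µm of sag on a perfectly flat field.
For flatness measurements we therefore recommend (and use, wherever sag is
the quantity of interest) the `gaussian` estimator, which pools all ~60
profile samples and cuts the jitter by an order of magnitude; `parabolic`
remains the general-purpose default because it makes no assumption about
the profile shape away from the peak.

Whether sag should be peak-to-valley or a fitted-amplitude per field
section is genuinely open; peak-to-valley over the valid grid is the
default here, with the robust span as the alternative reading.

### Maximum contrast, uniformity, depth of field

`C_max(x, y) = max_z C` (NaN-aware) is invariant to target tip/tilt and is
the map to compare across objectives; its mean and coefficient of
variation (population SD / mean) summarize absolute contrast and
uniformity. Depth of field per subregion is the z-extent over which `C`
stays above a relative threshold (default 50% of the local peak), with
linearly interpolated crossings; for a Gaussian contrast-vs-defocus curve
of half-width w this equals `2w√(2 ln 2)`. Profiles that never fall below
threshold inside the sweep are flagged NaN.

Note a known small bias: percentile contrast is noise-inflated, because
P99 of the bright bars rides ~2.3 noise SDs above their mean and P1
symmetrically below the dark bars. At 2% camera noise and C = 0.8 the
measured `C_max` reads ≈ 0.83, and the measured DOF widens by a few
percent. This is a property of the percentile estimator itself (shared by
any implementation of it), not of the fitting.

### Chromatic focal offsets

With an immersion medium in the detection path the best-focus plane shifts
with wavelength, so each channel needs its own refocus. Given per-channel
best-focus surfaces on the same grid, the scalar offset of channel A
relative to the reference is the **median** over their valid overlap of
`z0_A − z0_ref` — robust to residual field-curvature differences between
channels — with full per-pair offset maps retained. Offsets are
antisymmetric by construction.

## Bead PSF

Candidates are 26-neighborhood local maxima above
`median + min_snr · (1.4826·MAD)` (default `min_snr` 8); median/MAD are
insensitive to the sparse bright beads themselves. Intensity ties on a
plateau (possible in noiseless or quantized data) are merged to one seed
per connected plateau. Any candidate with a neighbor closer than
`min_separation_um` (default 10 µm) is removed *together with* the
neighbor, since an overlapping pair corrupts both fits.

Each kept bead is fitted in a window of half-widths (5, 4, 4) voxels
(z, y, x): a 2D elliptical Gaussian plus constant background on the bead's
best plane (the plane of maximum windowed intensity after a 3-plane z
average, robust to single-plane noise), then a 1D Gaussian along z through
the refined lateral center. The window is deliberately tight around the
spot: a much larger window mostly adds pure-background pixels, which caps
the achievable R² at moderate SNR and starves the quality cut. Fits with
R² < 0.8 or widths pinned at the bounds are labelled `poor_fit`; beads
whose window clips the volume are labelled `edge` and excluded rather than
partially fit.

FWHM = 2√(2 ln 2)·σ per axis; the lateral figure is the geometric mean of
x and y FWHMs. Summaries (mean, SD, fixed-width 0.25 µm histograms, field
maps at bead positions) run over `ok` fits only.

Limitations: the 0.2 µm physical bead diameter is neglected relative to
the PSF width (no bead-size deconvolution); the z profile is sampled at
the nearest voxel column of the refined center, which leaves σ_z unbiased
for a separable Gaussian but slightly lowers the fitted amplitude.

## Repeated-scan track validation

Background is estimated from dark frames (laser off) or blank controls —
mean and SD over all voxels, or median/MAD when outliers are expected.
"Signal" voxels exceed `mean + k_sigma·SD` (default k = 5; raw sensor data
is never literally zero, so a threshold stands in for "non-zero
intensity"); clusters are 26-connected components of ≥ `min_voxels`
(default 4) signal voxels.

Each cluster's bounding box, padded by 2 voxels, is cut from its own scan
as the template; the corresponding region of the other scan, grown by a
10-voxel halo, is the search window. The halo absorbs the small rigid
misregistration expected between consecutive scans (no volumetric
registration is attempted). NCC is computed by the standard fast
normalized cross-correlation (scikit-image's `match_template`), with
outputs clipped to [−1, 1] and non-finite values from zero-variance
windows zeroed; tests verify it against a direct triple-loop sum to 1e−10.
Padded boxes and halos are clipped at the volume border, which keeps
near-face clusters scoreable; only a degenerate null (zero SD) is an
error.

The Gaussian null (μ, s) is fitted as the mean/SD of all NCC values
excluding the 3³ neighborhood of the global peak, so a genuine match
cannot inflate its own null; a median/MAD null is available. The score is
`z = (peak − μ)/s`, flagged at `z ≥ 5` (deliberately conservative relative
to the 7–8σ outliers a real structure typically produces), and per-
candidate nulls are the default (pooling across candidates is an option).
A candidate is **confirmed** when flagged in both scoring directions and
the two flagged clusters sit within the match radius (default = halo) of
each other.

## Synthetic data: what it emulates, and what it does not

The generators define the test conditions for every pipeline and carry
full ground truth.

**Grating stacks.** `I = mean·(1 + C_local·s(y)) + N(0, noise_sd)`,
rounded to uint16, with `s(y)` a ±1 square wave (fixed phase, edge at
row 0; optional jitter) and
`C_local = C_peak(x, y)·exp(−(z − z0)²/(2w²))`. The Gaussian-in-z shape is
a modelling choice: the true through-focus MTF shape is instrument-
specific, but only the peak location and amplitude are consumed
downstream, so a symmetric unimodal model with analytically known peak is
the right level of realism. The best-focus surface is
`z0 = a0 + ax·xn + ay·yn + c2·r² + c4·r⁴` (normalized field coordinates,
r = 1 at the corner) plus a per-channel chromatic offset;
`ronchi_config_for_sag` sets c2 so the detrended peak-to-valley at the
subregion centers equals a requested sag exactly. Defaults are a 320 × 200
px frame at 5 µm pixels (grating period 5 px, subregions 10 × 10 px), mean
level 1000, noise SD 20 (2%), w = 40 µm, C_peak = 0.8 — chosen as a
faithful desk-scale miniature of a large-sensor acquisition; the full
sensor size is one config parameter away.

**Bead volumes.** Anisotropic 3D Gaussians at sub-voxel centers on a
constant background with additive Gaussian noise, uint16-rounded; default
50 beads at amplitude/noise = 20, widths matching ~1.55 µm lateral /
3.3 µm axial FWHM on (1, 0.85, 0.85) µm voxels, ≥ 12 voxels apart and a
fit-window margin from the borders. A `cluster_fraction` plants
near-coincident companions (flagged in truth) to exercise the cluster
filter.

**Scan pairs.** Sparse anti-diagonal runs of bright voxels (one voxel per
plane, default 5 planes, intensity 100 over an N(100, 10) background:
SNR 10) shared between two volumes under independent noise, the second
shifted by a small rigid offset (≤3 voxels). Default volume 32 × 64 × 64.

Not emulated: photon (Poisson) noise, pixel-area integration, diffractive
PSF structure and aberration cross-terms, vignetting beyond a radial
C_peak falloff, sensor fixed-pattern noise, or sample-induced scattering.
Additive Gaussian noise is adequate here because every estimator consumed
downstream is either percentile-based, least-squares, or
correlation-based — all distribution-insensitive at these SNRs. Passing
the recovery tests therefore demonstrates correctness of the estimators
under the stated noise model, not performance on a physical instrument;
on real data the absolute contrast and FWHM values additionally reflect
optics that no simulator parameter represents.

All generators are bit-reproducible for a fixed seed and config
(`numpy.random.default_rng`).

## Problem sizes

Test and acceptance runs use the generator defaults above: 61-plane
320 × 200 grating stacks with the full 32 × 20 grid, 50-bead volumes of
48 × 96 × 96 voxels, and 32 × 64 × 64 scan pairs, with 10–20 seeds where
rates are estimated. These sizes keep every recovery quantity comfortably
measurable (640 subregions, ~250 bead fits per condition, 74k-value NCC
nulls) while the whole suite runs in tens of seconds.
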