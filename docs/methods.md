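# Methods

This note documents the models, algorithms, defaults and known limitations of
focikit, in the order data flows through the package.

## Synthetic imaging

The generator exists so that every analysis stage can be validated against
known ground truth. It emulates the acquisition geometry of confocal
DNA-damage experiments, not their full optics.

**Nuclei.** Each nucleus is a filled ellipse with a flat interior and a
smoothstep rim falloff (default 2 px wide, standing in for the finite PSF at
the chromatin boundary). The ground-truth label map draws the nucleus
boundary at the 50%-intensity contour of that falloff — the FWHM convention —
because a boundary drawn at the zero-intensity edge would include pixels no
intensity thresholder can claim. Placement is rejection-sampled; when
touching is disallowed, bounding circles must keep a 1 px gap and exhausting
the attempt budget raises `PlacementError`.

**Foci.** A focus is an isotropic 2D Gaussian sampled at pixel centers with
σ = 6 px / 2.355 ≈ 2.55 px, so the rendered FWHM matches the 6 px focus
diameter that calibrates the proximity bins. Focus pairs are placed at exact
real-valued centroid separations (recorded distances match requests to
1e-9 px); `snap_to_pixel` rounds both centroids to the pixel grid so that a
noiseless pixel-grid detector can recover them exactly, at the price of the
recorded distance moving up to ~0.7 px from the request. Same-channel foci
keep a configurable minimum separation (default 8 px) so each remains an
individually resolvable object (see "Resolution limit" below).

**Noise.** Poisson shot noise (at `poisson_scale` photons per intensity unit)
is applied first, then Gaussian read noise, then a detector offset; pixels
are clipped at zero. Defaults are noiseless — noise is an explicit study
condition, typically set through `noise_for_snr(level, snr)` where SNR is
the signal level divided by the read-noise SD. Near-zero backgrounds with
large read noise are heavily clipped and bias ROI means; realistic use keeps
the background a few SD above zero.

**Stripe movies.** `generate_stripe_movie` renders one cell for `n_frames`
frames (default 80) at `frame_interval` seconds (default 15), with a
`stripe_length × stripe_width` damage rectangle (defaults 6.5 × 1 µm at
0.1 µm/px) centered on the nucleus. The damage-ROI signal follows

    S(t) = B(t) · [1 + A·(1 − exp(−(t − t_dmg)/τ))]   for t ≥ t_dmg
    S(t) = B(t)                                        before t_dmg

with `t_dmg = damage_frame × frame_interval` (damage initiated after frame 5,
so frames 1–5 are baseline) and whole-cell exponential bleaching
`B(t) = B0·exp(−bleach_rate·t)`. Because the recruitment factor multiplies
the total in-ROI signal and bleaching multiplies the whole frame, the
double-normalized ratio recovers `1 + A·(1 − exp(−(t − t_dmg)/τ))` exactly on
noiseless input for *any* bleach rate — asserted numerically over a grid of
rates at < 1e-9 deviation.

**What the generator does not model:** chromatin texture, 3D/z effects,
stage drift, defocus, spectral bleed-through, cell motion. Passing tests
therefore demonstrate the correctness of the *computations* under the
declared image-formation model, not robustness to every artifact of real
microscopy.

**Determinism.** A single integer seed is threaded through all stochastic
steps; per-scene/per-frame sub-generators are derived via `SeedSequence`, so
identical specs and seeds give bit-identical images.

## Segmentation

Foreground is selected by the Huang fuzzy-entropy threshold with the
dark-background convention (foreground strictly above threshold). For each
candidate threshold the gray levels split into background/foreground; each
level's fuzzy membership to its class mean is u = 1/(1 + |g − µ|/C) with C
the occupied gray range, and the Shannon fuzziness −u·ln u − (1−u)·ln(1−u),
weighted by the histogram, is minimized. Ties (bitwise-equal costs arise when
empty bins separate the same class split) break to the middle tied candidate,
which places the threshold centrally between separable populations. Images
are histogrammed into 256 equal-width bins over their occupied range (the
8-bit convention), making segmentation invariant to positive intensity
scaling.

Instances are split by a watershed on the negated Euclidean distance
transform of the foreground. The EDT is smoothed (σ = 1 px) before h-maxima
seed suppression (`watershed_h`, default 2 px): without smoothing,
discretization bumps along an elongated nucleus's ridge seed spurious
splits. Components smaller than `min_nucleus_area` (default 100 px², a
deliberately permissive floor — configure per magnification) are removed,
and border-touching nuclei are excluded by default since partial nuclei bias
per-cell focus counts. Labels are renumbered 1..n and each is one
4-connected component. No hole-filling or mask smoothing is applied.

## Focus detection

Channels are pre-blurred with a mild Gaussian (σ = 0.8 px, reflective
boundaries; σ = 0 is the identity). Maxima are then found per nucleus with a
prominence rule: a local maximum is reported iff one cannot reach it from any
strictly higher maximum without descending more than `prominence` below its
level; the globally highest maximum of a mask is measured against the mask
minimum, so a uniform region reports nothing. The implementation is a
topographic-persistence sweep (union-find over pixels in descending
intensity, 8-connected); equal-valued plateaus merge into one record at the
plateau centroid, and two equal-valued summits connected above the cutoff
are both reported. The test suite checks this against an exhaustive
path-search oracle on random images.

**Prominence choice.** The cutoff adapts to staining level:
`prominence_k` (default 5) × a MAD-based noise SD estimated from the
background (pixels outside nuclei), floored at a small fraction of the
channel's dynamic range so noiseless images still detect. An explicit
`prominence` overrides per run.

**Focus area and size filter.** A focus's area counts pixels above half its
measured prominence, 8-connected to the maximum *within the focus's own
watershed basin* — the basin restriction prevents a bright focus's area
flooding across a shallow saddle into a neighbour. Defaults retain areas of
2–50 px² (up to ~8 px diameter, consistent with 6 px FWHM foci); this also
removes merged doublets and the broad diffuse-EGFP dome of an expressing
nucleus, both of which have much larger half-prominence footprints.

**Resolution limit.** Two 6 px-FWHM foci separated by ~6 px produce an
intensity dip of only ~1.6% of their amplitude — below any noise-safe
prominence at SNR 10 — so such pairs merge into one maximum. Detection
recall/precision ≥ 0.95 is therefore validated at 8 px spacing (above the
Rayleigh limit), where both reach 1.0; closer pairs are a physical, not
algorithmic, limitation.

**Expression gating.** A nucleus enters the analysis iff its mean EGFP
exceeds the Huang threshold of the whole EGFP channel; a contrast-free EGFP
channel raises `NoExpressingCellsError`. Per-cell focus counts are reported
over gated cells only, and an empty gate yields a missing (not zero) mean.

## Proximity classification

For each focus in the source channel (by convention the EGFP-tagged protein;
the reverse direction is available), the nearest comparator-channel focus in
the same nucleus is found by exact per-candidate Euclidean distance with ties
to the lowest index; records are directional, so A→B and B→A counts differ
by design. Distances are binned overlapping (d ≤ 5 px), proximal
(5 < d ≤ 15 px), distant (d > 15 px): the integer pixel bins are read as
half-open real intervals because detected centroid distances are
real-valued. The default reporting scale, 1.07/15 ≈ 0.0713 µm/px, is derived
from the 15 px ↔ 1.07 µm correspondence that defines the bins (the
acquisition pixel size is configurable where it differs). Unmatched foci
(no comparator focus in the cell) are excluded from class fractions and
reported in their own column. Summaries give per-cell counts/fractions and
population mean counts per class with the number of cells.

## Recruitment quantification

Mean intensities over the damage and a disjoint same-cell control ROI are
extracted per frame (no interpolation; frame times are index × interval).
Baseline means F(−) are taken over frames 1–5 by default (the five
pre-damage frames; configurable — whether F(−) should instead be the single
frame before damage is not determinable, and the mean is the lower-variance
choice). The double ratio R(t) = [F(t)/F(−)]_damage / [F(t)/F(−)]_control is
invariant to global intensity scaling and uniform bleaching, and averages to
1 over the baseline on noiseless data (tolerance 1e-9). Non-positive
baselines raise `NormalizationError`.

Aggregation is a pointwise mean with SEM = sd/√n (sample SD, n−1); a single
trace reports SEM as missing, and unequal trace lengths are an error (frames
align by index under a common protocol). Classification implements the
"active iff R > 1" criterion with a guard band: active iff the mean over the
final `window` frames (default 10) exceeds 1 + 2 × (SEM of that window mean,
approximated as the mean per-frame SEM / √window; 0 when SEM is
unavailable) — so a curve exactly at 1 is "none".

The kinetic fit is nonlinear least squares of 1 + A·(1 − exp(−(t−t_dmg)/τ))
over post-damage frames (≥ 4 required), parameterized in (A, log τ) with A
bounded below by −1, multi-started over τ ∈ {15, 60, 120, 300, 600} s and
keeping the best RSS. Parameter recovery at the study conditions (SNR 10,
n = 20 cells, A ∈ {0.25, 0.5, 1}, τ ∈ {60, 150, 300} s) is better than 1%
median relative error; the acceptance bound of 15% is met with wide margin.

**Control-ROI auto-placement:** the largest axis-aligned rectangle inscribed
in the nucleus mask minus the damage ROI dilated by 5 px (exact
histogram-stack algorithm). No drift correction or bleaching correction
beyond the double ratio is applied.

## Pipelines and I/O

YAML-configured batch pipelines pool per-cell records across tiled
acquisitions (each tile processed independently, nucleus ids offset to stay
globally unique), write tidy CSVs, label-map TIFFs, fit JSON, optional QC
overlay PNGs, and a manifest (package version, SHA-256 config hash, seed).
Config validation is performed by explicit dataclass checks. Images are
OME-TIFF: CYX stills with named channels, TYX movies with the frame
interval; channel names and pixel size are read from OME metadata with
explicit overrides.

## Problem sizes used in the test suite

Property and acceptance tests run on deliberately small instances chosen as
the package's own operating points: 16×16 random images (1000) for the
maxima oracle, 200 random histograms for the Huang oracle, 1000 random cells
(≤ 20 foci/channel) for the nearest-neighbour oracle, 125 focus pairs at
1–25 px across five 470² scenes for end-to-end class recovery, and 20
simulated 128² × 80-frame movies per kinetic condition. All are exercised
through the same public API as full-size data.

## Known limitations

* 2D only; distances are in-plane. No pixel-intensity (Pearson/Manders)
  colocalization and no permutation-null association testing.
* The Huang threshold on heavily zero-clipped backgrounds (read noise
  comparable to the background level) can split on the clip spike; keep the
  detector offset above the clip in acquisitions and simulations.
* Sub-Rayleigh focus pairs merge (see Resolution limit).
* Frames are assumed registered; cells that move during the time-lapse bias
  both ROIs.
* The exponential-plateau recruitment model is a single-process
  approximation; multi-phase recruitment will fit with intermediate τ.
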