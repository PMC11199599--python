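# focikit

Quantitative image analysis for DNA-damage microscopy: **object-based
colocalization of nuclear repair foci** and **recruitment kinetics at
laser-microirradiation stripes**, with a ground-truthed synthetic-imaging
generator so every stage is testable without microscopy data.

## Who this is for

Labs scoring relationships between damage-induced subnuclear foci (e.g.
EGFP-tagged repair proteins versus γH2AX or 53BP1 chromatin marks) from
multi-channel confocal stills, and labs quantifying protein recruitment to
405 nm laser damage tracks from time-lapse stacks. The package reimplements
the classical ImageJ-macro workflow as a tested, reusable Python library.

## What it computes

**Foci pipeline** (multi-channel stills, Hoechst + up to three focus channels):

1. *Segmentation* — Huang fuzzy-entropy auto-threshold of the Hoechst channel
   (dark-background convention) followed by watershed splitting of touching
   nuclei seeded from h-maxima of the distance transform.
2. *Detection* — per nucleus and channel: mild Gaussian pre-blur (σ = 0.8 px),
   prominence-based local maxima (a maximum counts only if one must descend
   more than the prominence below it to reach higher terrain), and size
   filtering. Analysis is gated to EGFP-expressing cells (mean nuclear EGFP
   above the channel's Huang threshold).
3. *Proximity* — for every focus in the source channel, the Euclidean distance
   to its nearest neighbour in the comparator channel within the same nucleus,
   binned as

   | class | distance *d* | in µm (at 1.07 µm / 15 px) |
   |---|---|---|
   | overlapping | d ≤ 5 px | ≤ 0.36 µm |
   | proximal | 5 px < d ≤ 15 px | 0.36–1.07 µm |
   | distant | d > 15 px | > 1.07 µm |

**Stripe pipeline** (single-channel time-lapse, 80 frames at 15 s, damage
initiated after frame 5): mean intensities F(t) are extracted from a damage
ROI and a same-cell control ROI, normalized by their pre-damage baselines
F(−), and combined into the double-normalized ratio

    R(t) = [F(t)/F(−)]_damage / [F(t)/F(−)]_control

which cancels photobleaching and global drift; active recruitment means
R(t) > 1. Curves are aggregated across cells (mean ± SEM) and optionally
fitted with R(t) = 1 + A·(1 − exp(−(t − t_dmg)/τ)).

**Synthetic imaging** renders elliptical Hoechst nuclei, Gaussian foci
(6 px FWHM) at controlled cross-channel separations, EGFP-expressing versus
non-expressing cells, and stripe movies with configurable recruitment
amplitude, τ, photobleaching, and Poisson + Gaussian noise — each scene with
a machine-readable ground-truth record.

## Worked example

`examples/stripe_recruitment.py` simulates ten cells (A = 0.8, τ = 120 s,
SNR 10, with photobleaching) and runs the full recruitment analysis:

```
n cells                  : 10
plateau (last 10 frames) : 1.803 +/- 0.005 (model: 1.8)
classification           : active
fitted A                 : 0.804 (true 0.800)
fitted tau               : 120.3 s (true 120.0 s)
```

The plateau of the double-normalized ratio reaches 1 + A despite the
simulated bleaching (which the double ratio cancels), the curve is classified
as active recruitment (R > 1), and the kinetic fit recovers the generative
parameters to within ~1%. See also `examples/proximity_classification.py`
(distance-bin classification against generator truth) and
`examples/segment_and_count_foci.py` (segmentation, EGFP gating, per-cell
counts).

## Command line

```sh
focikit simulate foci   --config scene.yaml    --out scenes/
focikit simulate stripe --config kinetics.yaml --out movies/
focikit foci   --config run.yaml --out results/
focikit stripe --config run.yaml --rois movies/rois.json --baseline 1:5 --out results/
```

Images are OME-TIFF (CYX stills, TYX movies); outputs are label-map TIFFs,
tidy CSVs, fit JSON, and a run manifest (version, config hash, seed) for
reproducibility.

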