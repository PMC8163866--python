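# mirscan

Simulation and analysis toolkit for **multiphotometric mid-infrared (MIR)
flying-spot tissue scanning** — the question it lets you exercise end-to-end,
with no instrument and no animal tissue, is whether **3–4 discrete laser
wavenumbers are enough to segment tissue structures and tumour margins the way
full FT-IR hyperspectral imaging does**.

It is written for spectroscopic-imaging researchers and method developers: the
package provides synthetic tissue phantoms, two virtual instruments (a 4-laser
flying-spot scanner and an FT-IR imager), the standard pre-processing and
k-means segmentation workflow for both modalities, and the cross-modality
similarity and throughput accounting needed to compare them.

## The model

A tissue phantom is a 2D class-label raster on a physical grid; each class
carries an absorbance model

A(ν̃) = baseline + Σ_b a_b · exp(−(ν̃ − c_b)² / (2 σ_b²)),

a sum of Gaussian bands on a scattering baseline, with the canonical
functional-group bands: lipid C–H stretch at 2926 cm⁻¹, amide-A N–H stretch at
3350 cm⁻¹, and an optional broad O–H water band (3400 cm⁻¹) scaled by a
residual-water fraction. Low-absorbance wings near 2790 and 3700 cm⁻¹ serve as
reference-laser positions.

The virtual MIR scanner measures, per laser and per raw detector sample,

I = I₀ · R_slide · 10^(−A(ν̃_laser)) · (1 + ε),  ε ~ N(0, σ),

averaging `oversampling` samples per 20 µm pixel (noise ∝ 1/√f) and recording
a bare-slide background raster per laser; absorbance is recovered as
A = −log10(I / I_bg). The stock geometry (5.3 m/s mirror velocity, 20 µm
pitch, 10× oversampling) yields 5000 samples per 1 cm line, a 2.65 MS/s sample
rate and 250 000 pixels per cm². The virtual FT-IR imager records a full
absorbance spectrum per pixel (4000 → 750 cm⁻¹ at 8 cm⁻¹ by default),
averaged over accumulations.

Both data streams then pass through the standard workflow: background-
referenced absorbance → alignment → weak-signal threshold adjustment → locally
adaptive total-variation denoising → normalisation (MIR), and spectral
smoothing → vector normalisation → fingerprint + functional-group range
restriction (FT-IR); per-pixel features are clustered by k-means
(k-means++/Lloyd, seeded restarts), and clusters dominated by off-tissue
pixels are rejected. Modalities are compared channel-by-channel with the
structural similarity index (SSIM) and MSE, and segmentations with optimal
label matching (Dice) plus the adjusted Rand index.

## Worked example

```python
from mirscan.pipeline import brain_study, liver_study, similarity_study

b = brain_study(seed=1)
print(f"hippocampus: cluster {b.hippocampus_cluster}, Dice {b.hippocampus_dice:.3f}")
l = liver_study(seed=1)
print(f"tumour: Dice {l.tumour_dice:.3f}, boundary Hausdorff {l.boundary_hausdorff_px:.1f} px")
print(f"margin cluster {l.margin_cluster}: {100*l.margin_concentration:.1f}% of pixels at the margin")
s = similarity_study(seed=1, noise_sd=0.05)
print(f"mean SSIM {s.report.mean_ssim:.3f}, segmentation ARI {s.agreement_ari:.3f}")
```

prints

```
hippocampus: cluster 2, Dice 0.999
tumour: Dice 0.998, boundary Hausdorff 1.0 px
margin cluster 2: 99.9% of pixels at the margin
mean SSIM 0.937, segmentation ARI 1.000
```

Reading: on a brain-like phantom scanned with 5 % relative intensity noise,
k-means at k = 4 recovers the hippocampal band almost perfectly (Dice 0.999);
on a liver-like phantom the 3 mm tumour nodule boundary is recovered to within
one pixel at k = 2, and at k = 3 the extra cluster lands almost entirely on
the graded infiltration margin. The three matched laser channels agree with
the corresponding FT-IR channels at mean SSIM 0.937, and the two modalities'
segmentations are statistically identical (adjusted Rand index 1.0).

There is also a CLI mirroring the workflow stage by stage:

```sh
mirscan pipeline --config run.yaml --out results/run1
mirscan phantom  --config run.yaml --out ph && mirscan segment --phantom ph --k 4 --out lm
```

Every run writes a manifest (resolved config, seeds, versions, stage timings)
from which any stage can be re-run identically.

## Layout

- `mirscan.phantom` — synthetic tissue phantoms (brain-like, liver-like) and
  per-class spectral profiles
- `mirscan.acquisition` — the virtual MIR scanner and FT-IR imager, plus
  sampling arithmetic
- `mirscan.preprocess` — absorbance referencing, alignment, threshold
  adjustment, adaptive TV denoising, normalisation, cube preprocessing
- `mirscan.segment` — feature stacking, k-means, background-cluster rejection
- `mirscan.compare` — grid resampling, SSIM/MSE, label concordance, throughput
- `mirscan.io` / `mirscan.config` / `mirscan.cli` — formats (TIFF, ENVI-style
  cubes, CSV, YAML), run configuration, command-line surface

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
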