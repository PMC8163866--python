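# Methods

This note records the models behind `mirscan`, the parameters that matter,
the numerical choices, and what the synthetic studies do and do not show
about real measurements.

## Forward model

**Spectra.** Each tissue class is a sum of Gaussian absorbance bands on a
constant scattering baseline. Gaussians are an analytic stand-in for real
vibrational band shapes (typically Voigt-like); they are smooth, linear in
their amplitudes, and place the reference wavenumbers 2790 and 3700 cm⁻¹ in
genuinely low-absorbance wings, which is all the downstream workflow relies
on. Default band table: lipid C–H (2926 cm⁻¹, σ 60), amide A N–H
(3350 cm⁻¹, σ 90), water O–H (3400 cm⁻¹, σ 180, amplitude 0.5 × water
fraction), baselines 0.02–0.10 AU per class.

**Class amplitudes** are free parameters: absolute per-class absorbances are
not published for these tissues, so the defaults fix only the orderings the
analysis depends on — at 2926 cm⁻¹ white matter (0.80) > hippocampal band
(0.50) > grey matter (0.35), and the tumour differing from healthy liver
essentially only in the C–H band (0.75 vs 0.45) with near-equal amide
amplitudes. The hippocampal band also carries the lowest baseline (0.04), so
the 2790 cm⁻¹ reference laser sees it at low absorbance.

**Transflection** (beam passes the section, reflects off the silvered slide,
passes back) is folded into a single effective absorbance: only the ratio of
sample to bare-slide intensity is observable, so the double pass is not
modelled separately.

**MIR scanner.** Raw samples are I₀·R_slide·10^(−A)·(1+ε) with multiplicative
Gaussian relative-intensity noise ε per raw sample; a pixel is the arithmetic
mean of its `oversampling` samples, so pixel noise scales as 1/√f. The
background raster is generated by the identical process with A ≡ 0. Lasers
are simulated sequentially with independent noise streams spawned from one
seed. Line offsets (0.5 cm at each end) are discarded samples and enter
timing accounting only. The multiplicative noise model keeps absorbance noise
approximately additive at small σ (σ_A ≈ σ/ln 10). No point-spread blur is
applied by default (the optics' PSF is unspecified); scan pitches must be
integer multiples of the phantom pitch, and coarser scans block-average the
underlying absorbance (partial-volume mixing at class boundaries — a physical
effect the liver experiments rely on).

**FT-IR imager.** Descending axis ν_max, ν_max−Δ, … (407 channels for
4000→750 cm⁻¹ at Δ = 8); per pixel the class absorbance spectrum plus
additive Gaussian noise of sd `noise_sd`, averaged over `accumulations`
independent draws (noise ∝ 1/√accumulations).

**Stage speed is derived, never pinned.** The instrument's printed stage
speed (~3.3 mm/s) is not reproducible from its printed line geometry (1 cm
line + 2 × 0.5 cm offsets at 5.3 m/s imply 5.3 mm/s); the line duty cycle is
unspecified. The simulator therefore computes stage speed and scan time from
its own configured geometry and treats measured scan times as *inputs* in all
throughput accounting.

## Phantoms

`make_brain_phantom` builds a schematic coronal section: an elliptical
grey-matter section inside a bare-slide margin, a thick dorsal white-matter
arc, and a thinner curved hippocampal band nested beneath it. The geometry is
topological, not atlas-derived: what matters for the studies is a thin curved
structure whose lipid/amide ratio differs from both neighbours. Seeds jitter
centre, orientation and radii slightly.

`make_liver_phantom` builds a homogeneous section with a nodule of the
requested diameter. The boundary radius is perturbed by seeded cosine
harmonics (orders 2–32, amplitudes ∝ 1/m beyond order 6) with rms relative
amplitude 0.12 × `margin_irregularity`; at irregularity 0 the nodule is an
exact disc and the equivalent-disc diameter is preserved to within a pixel.
`infiltration_mm > 0` additionally interdigitates tumour and healthy pixels
at the raster scale within a band of that width, with tumour density graded
from 1 to 0 across it — microscopic infiltration that block-averages into
genuinely intermediate spectra when scanned at coarser pitch. It is off by
default; the margin study uses 0.2 mm, a plausible infiltration depth for a
hepatocellular carcinoma margin.

## Pre-processing

Fixed chain order, MIR: absorbance → alignment → threshold adjustment → TV
denoising → normalisation. FT-IR: spectral smoothing → vector normalisation →
range restriction. All stages are deterministic and shape-preserving (the
range restriction changes only the spectral axis).

- **Absorbance**: A = −log10(I/I_bg), clipped below at a floor (default 0);
  noise can push I above I_bg, and non-negative features keep clustering
  well-behaved. Non-positive background pixels are a data error reported by
  index.
- **Threshold adjustment** amplifies weak signals with a continuous strictly
  monotone piecewise-linear transfer: gain·x up to the knot x₀ = t/(gain+1),
  then slope 1/gain up to (t, t), identity above the threshold t (a
  percentile level by default). Gain 1 is the identity. Default gain is 1 —
  the stage is exposed but neutral unless configured, since the studies'
  class contrasts need no amplification.
- **Locally adaptive TV denoising** minimises Σ w(x)|∇u| + ½‖u−f‖² by the
  Chambolle–Pock primal–dual scheme (σ = τ = 1/√8, which satisfies the
  step-size condition for ‖∇‖² ≤ 8; 120 iterations default). The per-pixel
  weight w(x) equals the nominal strength in flat windows and is scaled down
  where the local gradient-magnitude variance (7-px windows, referenced to
  its image median) is high — edges keep their contrast, flat regions are
  smoothed hard. Output is clamped to the input range. When no strength is
  given, the pipeline sets it per channel to 8 × a robust noise estimate
  (median absolute deviation of horizontal neighbour differences): a
  noiseless image passes through unchanged, and the weight always sits well
  below the class contrasts (~0.15–0.45 AU) that carry the segmentation. A
  fixed weight of that magnitude would halo structure boundaries and bleed
  thin structures into their neighbours.
- **Normalisation**: MIR images are robustly rescaled per channel
  (percentiles 1→0 and 99→1, clipped) — with only 3–4 channels, per-pixel
  vector norms would be unstable. FT-IR spectra are scaled to unit Euclidean
  norm per pixel (vector normalisation, the standard FT-IR choice) after a
  moving-average smoothing (default window 9 channels). The vector
  normalisation is optionally stabilised by a norm floor: spectra whose norm
  falls below a fraction (0.25 in the studies) of the median spectral norm
  are zeroed rather than normalised, because a bare-slide spectrum is pure
  noise and its direction is meaningless — without the floor, background
  pixels scatter over the unit sphere and absorb clusters.
- **Alignment** estimates integer-pixel shifts by phase cross-correlation
  against the first channel (the simulated lasers are perfectly
  co-registered, so this is a no-op unless misalignment is injected); an
  estimated shift beyond 10 % of the image extent flags failure and leaves
  that image unmodified.
- **Range restriction** keeps the fingerprint (750–1500 cm⁻¹) and
  functional-group (2500–4000 cm⁻¹) intervals; on the default axis this is
  282 of 407 channels.

## Segmentation

k-means (k-means++ seeding, Lloyd iterations, best of 10 restarts by WCSS,
fixed seed) on per-pixel feature vectors; clusters are relabelled in
descending size for stable ids. k is a user parameter — no model selection.
Background handling is an explicit, testable rule: clusters whose off-tissue
pixel fraction exceeds a majority threshold (default 0.5, mask = phantom
truth in simulation, Otsu on mean absorbance for real data) are rejected and
re-indexed densely.

**Cluster budgeting.** Requested k counts *all* clusters. A
background-referenced scan always spends one cluster on the bare slide, and —
whenever the scan pitch is coarser than the specimen structure — one more on
the partial-volume slide/tissue outline. The brain study (scan pitch equal to
phantom pitch, no outline mixing) uses k = 4 = 3 tissue classes + slide; the
liver studies use k = 4 and 5 for 2 and 3 tissue clusters respectively.

k-means reproducibility is not assumed: the acceptance script reports the
mean pairwise adjusted Rand index across 10 clustering seeds on one fixed
feature set (1.0 under the study conditions — the class structure is strong
enough that restarts always find the same optimum).

## Comparison

Matched channels are scored on a common grid (bilinear resampling with linear
edge extrapolation, so affine fields resample exactly) with windowed SSIM
(uniform 7-px window, standard constants) and MSE, after identical optional
TV denoising and identical robust normalisation on both sides; symmetric
treatment makes the noiseless same-phantom comparison exactly 1.
Segmentations are compared by optimal one-to-one label matching (assignment
problem on overlaps) giving per-class Dice, plus the adjusted Rand index over
all pixels (rejected background counts as a label) as a chance-adjusted
agreement score.

The similarity study samples the FT-IR axis at 2 cm⁻¹ over the
functional-group region so that each laser wavenumber has an exactly matching
channel; with the default 8 cm⁻¹ axis the nearest channel sits up to 4 cm⁻¹
off the laser line and the noiseless identity holds only approximately.

Throughput accounting multiplies pixel counts (from the field and pitch) by
channel counts (lasers for MIR, the restricted clustered axis for FT-IR) and
takes ratios; scan times are supplied measurements, never derived. With the
published scan times (3 s vs 675 s per cm²) the time ratio is 225; the data
ratio depends on the channel accounting and the report prints the counts it
used.

## Study conditions and problem sizes

The packaged studies run at 5 % relative intensity noise (MIR) / 0.05 AU
additive spectral noise (FT-IR), the stock instrument settings (20 µm pitch,
10× oversampling, 2 accumulations), and fields chosen so every study carries
its full structure at realistic pixel counts while a complete run stays
interactive: brain 6 × 6 mm at 20 µm (90 000 px), liver 6 × 6 mm with a
10 µm phantom raster scanned at 20 µm, similarity 4 × 4 mm (40 000 px,
751-channel cube). Scores are insensitive to the field size beyond the
structure scale.

## What the phantoms do not emulate

No Mie/resonant scattering distortions, no atmospheric water-vapour bands, no
baseline drift, no detector nonlinearity or drift between lasers, no optical
PSF, no stage/mirror geometric distortion, no within-class biological
heterogeneity (class spectra are exactly constant up to noise), no section
thickness variation, and no 3D structure. Passing studies therefore show the
*workflow* — reduced-band acquisition plus this pre-processing and clustering
— preserves the information needed for segmentation under realistic noise and
partial-volume conditions; they do not show robustness to the systematic
artefacts real transflection measurements add. The degrees of freedom those
artefacts would stress (alignment, threshold adjustment, rejection masks via
Otsu) are exposed in the API but exercised only with synthetic transforms.

## Degenerate inputs and tie-breaks

Geometry must divide exactly (line length / resolution, field / pitch,
scan / phantom pitch ratios): violations raise configuration errors rather
than silently rounding. Constant images: threshold adjustment and TV return
them unchanged; normalisation raises a data error (degenerate percentiles).
k exceeding the number of distinct feature vectors is an error. Cluster size
ties in the stable relabelling keep k-means' internal order. Equal-distance
assignment ties follow scikit-learn's convention. The Hausdorff distance is
computed between boundary pixel sets (mask minus its erosion) symmetrically.
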