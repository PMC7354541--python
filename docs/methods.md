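# Methods

`eqctta` implements equilibrium contrast-enhanced CT (EQ-CT) texture
analysis of the liver together with extracellular volume fraction (ECV)
computation and rank-correlation of the resulting features against
fibrosis markers.  This note documents the model, the conventions chosen
where the technique admits choices, what the synthetic phantoms emulate,
and the limits of what the test suite demonstrates.

## The filtration-histogram technique

A single axial CT slice in Hounsfield units (HU) is convolved with a
band-pass filter parameterised by a *spatial scale filter* (SSF) value in
mm, then six histogram statistics of the filtered values are read off
inside a region of interest (ROI): mean, standard deviation (SD), Shannon
entropy, mean of the positive pixels (MPP), skewness, and kurtosis.  The
scales follow the conventional banding — fine 2 mm, medium 3–5 mm, coarse
6 mm — plus SSF = 0, the unfiltered control.

### Kernel

The filter is the negated, scale-normalised Laplacian of Gaussian (LoG):

    K(x) = −(σ_r² ∂²/∂r² + σ_c² ∂²/∂c²) G_σ(x),
    σ (pixels, per axis) = SSF / (2√2 · spacing_mm)

Design choices and reasons:

* **SSF → σ mapping.**  σ = SSF/(2√2) makes the LoG zero-crossing ring
  diameter (2√2·σ in 2-D) equal the SSF, i.e. "SSF in mm" is the diameter
  of the bright object the filter amplifies most.  Commercial texture
  packages do not publish their kernels; this mapping is an open,
  documented interpretation with that stated behaviour.
* **Negation** makes bright objects give positive responses, so MPP and
  skewness grow with the prevalence of bright features.
* **Scale normalisation** (the σ² factor, Lindeberg's convention) is what
  makes the response across scales peak at the matching object size;
  without it the unfiltered response to any blob is monotone decreasing
  in σ and "scale selection" is meaningless.
* **Truncation at 4σ, mean subtraction.**  The sampled kernel is
  truncated at 4σ per axis and mean-subtracted so its entries sum to
  exactly zero: a constant image yields an identically zero map (zero DC
  gain).  Boundary handling is mirror reflection.
* **Anisotropic spacing** is handled per axis (separate σ along rows and
  columns).  σ below half a pixel triggers a `ResolutionWarning`.

A direct consequence of exact zero DC gain, worth stating because it
shapes everything downstream: the mean of a filtered map over a region
sampled away from intensity non-stationarities is exactly zero in
expectation — any feature whose kernel support lies inside the region
contributes zero net response.  ROI means of filtered maps are therefore
*boundary-contrast detectors*; only structure near the ROI border (within
4σ) moves them.

### Sampling and erosion

The full image is filtered first and the ROI is applied afterwards;
masking before filtering would inject the ROI boundary into the map as a
large artificial step.  Before statistics are computed the mask is eroded
by ceil(2σ) pixels (default on; none at SSF = 0) to suppress ring
artefacts from structure just outside the ROI.  A minimum of 50 sampled
pixels is enforced — higher moments are unstable below that.

### Statistics conventions

* Moments use the population divisor n (sample-corrected estimators are
  available via `population=False`); ROIs hold thousands of pixels, so
  the distinction is cosmetic but the uncorrected forms match the plain
  histogram definitions and the brute-force oracle exactly.
* Skewness is Fisher–Pearson g1 = m₃/m₂^1.5; kurtosis is excess
  g2 = m₄/m₂² − 3 (Gaussian → 0; the raw form is a switch away).
* Entropy is Shannon entropy in bits over a 256-bin equal-width histogram
  spanning the observed [min, max] of the sampled values, 0·log 0 := 0;
  a constant region has entropy 0.  Bin count configurable.
* A zero-variance region returns skewness = kurtosis = 0 with a
  `zero_variance` flag; an ROI with no positive pixels returns MPP = 0
  with a `no_positive_pixels` flag — flagged zeros, never NaN, so feature
  tables stay rectangular.

### Difference features

Equilibrium-minus-pre features are metric-wise differences of the two
phases' texture vectors (`subtract_features`), the subtracted-enhancement
signature.  The alternative — filtering the voxel-wise difference image —
is deliberately not the default; the per-phase parameter subtraction is
the primary definition, and the voxel-wise route can be built from the
library primitives if wanted.

## ECV

    ECV_liver = (1 − haematocrit) · δHU_liver / δHU_blood

with δHU = equilibrium − pre-contrast mean ROI attenuation, liver from a
parenchymal ROI and blood from an aortic ROI (no partial-volume
correction).  Haematocrit is a fraction in (0, 1); values in [1, 100] are
auto-interpreted as percent with a logged conversion.  A non-positive
blood delta is an error (failed equilibrium or swapped ROIs); an ECV
outside [0, 1] is returned flagged, never clipped.  When several
contiguous sections per phase are supplied, per-section ROI means are
averaged before the formula — the clinical measurement protocol — which
roughly halves the aortic-noise contribution to the ECV error.  ROI means
for ECV use the drawn masks without erosion (erosion is a texture
concern).

## Registration and partial data

Registration between phases is assumed, never computed: ROIs may be
copied between phases only when shapes match and spacings agree to
1e-6 mm.  Mis-registration downgrades a patient to single-phase features
with a logged skip.  Partial cohorts are first-class: patients without
equilibrium imaging contribute pre-contrast features and missing values
in difference/ECV columns, and the association analysis is
pairwise-complete, so the effective n differs per feature.

## Association analysis

Spearman's r_s with average-rank ties; two-sided p from the
t-approximation t = r_s·√((n−2)/(1−r_s²)) with n−2 df (an exact
permutation option exists for n ≤ 10; |r_s| = 1 reports the permutation
bound 2/n!).  Significance at p ≤ 0.05.  **No multiple-testing
correction is applied by default**: the filter scales are strongly
dependent, so independence-assuming corrections are deliberately
avoided; a Benjamini–Hochberg q-value column can be switched on for
sensitivity analysis and never drives the significance flag.

## The phantom generator

The generator produces pre/equilibrium slice pairs, masks (whole liver,
segment VII wedge, aorta), and clinical markers from one severity
parameter s ∈ [0, 1].  Geometry is a fixed idealisation: an elliptical
liver (~75 cm² cross-section at the default 128² grid, 1 mm pixels), a
peripherally based wedge whose outer edge lies on the liver margin, an
aortic disc (~1.5 cm²), and a few vessel discs excluded from the liver
masks with a safety dilation.  Severity acts through:

* **Feature density.**  Bright Gaussian blobs (default 1/e full width
  4 mm, ~12 HU amplitude with lognormal jitter) at base + gain·s per cm²
  (default 1 + 6 s).  The blob width convention equals the filter's SSF
  convention, so diameter-d blobs respond maximally at SSF = d.
* **ECV.**  ecv_true = 0.22 + 0.15 s; the equilibrium liver gains a mean
  of ecv_true·δHU_blood/(1−hct) over the whole-liver ROI exactly, so the
  partition relation holds by construction.  Blood delta is 40 HU;
  haematocrit ~ N(0.42, 0.03) truncated to (0.25, 0.55).
* **Interstitial enhancement.**  Each blob brightens at equilibrium by a
  fixed multiple (default 1.5×) of its own pre-contrast amplitude —
  contrast pooling in each feature's expanded interstitium — with the
  spatially uniform remainder adjusted to keep the whole-liver mean on
  the ECV target.  (An earlier design that redistributed a *fixed total*
  over the blobs was discarded: it made per-feature enhancement fall as
  density rose, inverting the difference-phase MPP/skewness trends.)
* **Septal rim.**  Fibrosis in progressing disease is septal and
  segmentally heterogeneous — some segments are spared while the
  biopsied segment is not.  The generator paints an equilibrium-only
  enhancement band along the segment VII watershed (default 4 mm wide,
  inner edge 4 mm inside the ROI boundary, amplitude 14·s HU, lightly
  smoothed), representing the collagen-rich high-ECV septum of the
  affected segment.  Because ROI means of zero-DC-filtered maps respond
  only to boundary-band contrast (see above), this is the channel that
  carries the planted positive difference-mean signal at medium scales in
  segment VII — and it correctly contributes *nothing* to whole-liver
  means or to the ECV relation.  The 14 HU amplitude corresponds to a
  septal ECV of ~0.6 against parenchymal ~0.37 at full severity.
* **Markers.**  ELF = 8 + 4 s + N(0, 0.4); CPA = 2 + 25 s + N(0, 2) %,
  floored at 0; Ishak = round(6 s + N(0, 0.5)) clipped to 0..6.  Ranges
  match a chronic-hepatitis cohort (ECV ~0.22–0.37, ELF 8–12, CPA
  2–27 %).
* **Hepatocyte-loss mode** (off by default) adds a coarse (6 mm)
  background texture of 12 HU whose amplitude falls by 70 % from s = 0
  to s = 1 — a hypothesis for the empirically observed *negative*
  pre-contrast SD/entropy/MPP association with fibrosis (textured
  hepatocellular tissue being replaced); it exists to plant a negative
  coarse-scale SD-vs-CPA effect and is labelled a modelling hypothesis,
  not a measured fact.

Each phantom carries three independent-noise "contiguous sections" per
phase used only for the ECV ROI means; texture always uses the first
(porta-level) slice.  Pixel noise is iid Gaussian, 10 HU per phase.
All randomness flows from an explicit seed (per-patient seeds spawned
from the cohort master seed); equal seeds are bitwise reproducible.

**What the phantoms do not emulate:** real liver anatomy and segmental
shape, scanner physics (beam hardening, structured noise, partial
volume), respiratory motion and true inter-phase mis-registration,
reader variability in ROI placement, and the joint distribution of real
clinical markers.  Tests passing on phantoms demonstrate that the
*pipeline* is correct and can recover structure it is pointed at — not
that the clinical effect sizes would reproduce.

## Validation studies (eqctta.validation)

Problem sizes were chosen to make each study's Monte-Carlo error small
relative to its acceptance band:

* **ECV recovery** — 100 phantoms, severities sweeping [0, 1]: recovered
  ECV within ±0.02 of truth (the noise-propagated band for the default
  10 HU noise and ROI sizes), mean bias < 0.005.
* **Scale selection** — single analytic blobs of diameter 2–6 mm at
  0.5 mm pixel spacing (typical abdominal CT): the SSF maximising the
  mean positive response equals the diameter for all five sizes.
  Response is measured as the mean of positive filter values — on a flat
  background exactly the blob's central lobe — because the lobe is
  self-similar across scales; restricting to a fixed disc biases the
  argmax upward, and much coarser grids under-sample the 2 mm scale.
* **Type-I calibration** — 1000 null cohorts at n = 29, 8 features each:
  rejection at α = 0.05 within 5 % ± 2 %.
* **ELF power** — 100 replicates of the default cohort (n = 29, EQ for
  21): positive significant segment VII difference-mean (SSF 4 mm) vs
  ELF; the study itself estimates the power (≈0.95+, median r_s ≈ 0.7).
* **CPA sign recovery** — 200 hepatocyte-loss cohorts (n = 29):
  whole-liver pre-contrast SD at SSF 6 mm vs CPA negative (median
  r_s ≈ −0.77).

## Numerical and degenerate-input policy

HU outside [−1024, 3071], non-finite pixels, or non-positive spacing are
validation errors, never silently fixed.  Empty masks, masks emptied by
erosion, sub-minimum pixel counts, zero-variance correlation inputs,
non-positive blood enhancement, and duplicate patient ids all raise
typed exceptions.  NIfTI-1 stores spacing as float32; round-trip spacing
agreement is within the 1e-6 mm registration tolerance (pixel data
round-trips bitwise as float64).

## Known limitations

Single-slice 2-D analysis only (by design); no registration or
segmentation; the LoG kernel is an interpretation of an unpublished
commercial filter, so absolute feature values are not comparable across
implementations (rank correlations largely are); entropy is computed on
the min–max-scaled filtered-value histogram, one of several conventions
in use; the planted-effect studies demonstrate sensitivity to the
specific spatial structure the generator encodes, not to every fibrosis
phenotype.
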