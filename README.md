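# eqctta — equilibrium-CT texture analysis for liver fibrosis

`eqctta` is a tested, reproducible implementation of filtration-histogram
CT texture analysis (CTTA) on paired pre-contrast / equilibrium-phase
liver CT, together with extracellular volume fraction (ECV) computation
and rank-correlation of every texture feature against fibrosis markers.
It is aimed at quantitative-imaging researchers who want the technique as
an open, scriptable pipeline rather than a black box, and at
methodologists who want to probe its conventions on synthetic phantoms
with known ground truth.

## The method

For each patient, a single axial slice per phase is convolved with a
negated, scale-normalised Laplacian-of-Gaussian band-pass filter at
spatial scale filter (SSF) values of 2 mm (fine), 3–5 mm (medium) and
6 mm (coarse), with SSF = 0 as the unfiltered control; σ = SSF/(2√2) per
axis in pixels, so the SSF equals the diameter of the bright feature the
filter enhances most.  Inside each ROI (whole liver and a segment VII
wedge, eroded by ceil(2σ) to suppress edge rings), six histogram
statistics are computed: mean, SD, entropy (bits, 256 bins), mean of the
positive pixels (MPP), skewness and kurtosis.  Equilibrium-minus-pre
differences of these parameters form the subtracted-enhancement texture
signature.  The liver ECV follows the contrast partition relation

    ECV = (1 − haematocrit) · δHU_liver / δHU_blood,

δHU being the equilibrium-minus-pre change of mean ROI attenuation in
liver parenchyma and aortic blood.  Every feature is correlated against
CPA (collagen proportionate area, %), ECV, ELF (enhanced liver fibrosis
score) and Ishak stage with Spearman's r_s (average-rank ties,
t-approximation p, α = 0.05, deliberately no multiple-testing
correction — the filter scales are not independent).

Because no clinical images ship with the package, a first-class phantom
generator (`eqctta.synthetic`) produces seeded pre/EQ slice pairs, masks
and markers from a single fibrosis-severity parameter, with the ECV
partition relation holding by construction and monotone marker links —
every stage of the pipeline is testable end to end against known truth.
See `docs/methods.md` for the model and all conventions.

## Worked example

```bash
eqctta all --n 29 --seed 7 --out demo_out
```

simulates the default 29-patient cohort (equilibrium imaging available
for 21), extracts 216 texture features per patient (2 ROIs × 3 phases ×
6 SSFs × 6 metrics), computes ECV, and correlates everything against the
markers.  The run prints the significant-association digest, strongest
first (525 of 864 feature–marker pairs are significant in this cohort):

```
Significant Spearman associations (p <= 0.05, no multiplicity correction)
==========================================================================
whole_liver  pre   SSF   0 mm mean      vs ecv         r_s = +0.969  p = 5.683e-13  (n = 21)
whole_liver  pre   SSF   0 mm mpp       vs ecv         r_s = +0.969  p = 5.683e-13  (n = 21)
whole_liver  eq    SSF   2 mm mpp       vs ecv         r_s = +0.968  p = 8.333e-13  (n = 21)
...
segment7     diff  SSF   4 mm mean      vs elf         r_s = +0.786  p = 2.433e-05  (n = 21)
```

The top rows are mechanical (ECV is itself derived from the images); the
scientifically interesting rows, such as the last one shown, are the
planted effect: the generator paints an equilibrium-only septal
enhancement band around the segment VII watershed whose amplitude grows
with severity, and the pipeline recovers it as a positive, significant
difference-mean association with ELF at medium scales in segment VII
(n = 21 because difference features exist only for the equilibrium
subset).  `demo_out/` also holds
`features.csv`, `ecv.csv`, `correlations_long.csv`, a wide
SSF-block × metric table mirroring the conventional report layout, and
`run.log` with the config hash and seeds; rerunning with the same seed
reproduces every file byte for byte.

The same workflow runs on real data via `eqctta extract --config
cfg.yaml` with a manifest CSV pointing at NIfTI slices and masks.

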