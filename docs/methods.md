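# Methods

This note documents the models, numerical choices and limitations of the
`nucleotyping` package in enough detail to reproduce or audit any stage.

## Conventions

Grey levels encode transmitted light: larger pixel value = brighter = less
DNA. All optical densities are `log10(background / pixel)`, so IOD depends
only on the pixel/background ratio (exposure invariant) and is always
computed on the original grey depth, never on re-quantised pixels.
Re-quantisation (1024 → 64 levels by default) is linear floor binning,
`floor(pixel * G / depth)`, which preserves OD ordering. Area intervals are
A₀ < 1000 px, A_a = 1000·a … 1000·a+999 for a = 1…9, A₁₀ ≥ 10 000 px; the
boundary value 10 000 px is assigned to A₁₀ so the mapping is total.

## GLEM computation

Local first-order entropy at a pixel is computed over the w×w window
(w = 9) clipped at the image border, counting **only mask-true pixels** and
normalising by the pixels actually counted. Background glass would
otherwise dominate edge windows of every nucleus; the mask-restricted
choice is isolated in one code path (`glem._mask_entropies`) should the
alternative ever be needed. Entropy is in bits (base 2); the entropy axis
is divided into B = 64 equal bins on [0, log₂ G] with the top edge clamped
into the last bin, keeping the matrix square at 64×64. The implementation
uses per-grey-level summed-area tables and an integer x·log₂x lookup, and
is verified element-for-element (±1e−12) against a brute-force per-pixel
oracle in the tests.

## Adaptive features

Class statistics are fitted in two steps — element-wise mean/variance of
each case's nuclear GLEMs, then an unweighted average across the cases of a
class — so cases contribute equally regardless of nucleus count. Per-case
variance uses the population (divide-by-n) formula; a single-nucleus case
contributes zero variance. The Mahalanobis denominator carries a
regulariser ε = 1e−8: without it, rare GLEM elements with zero sample
variance but non-zero class difference would produce infinite weights.
Class 1 is fixed as "dysplastic", making the sign of Δ and the roles of
f⁺/f⁻ deterministic. Statistics are fitted only for A₁–A₅ because patient
features aggregate only over those groups; nuclei in other groups (or in
groups where a class is absent from the training set) are dropped, and a
patient with no eligible nucleus is reported unscorable and excluded.
Scaling all d² by a constant scales both features linearly and leaves the
downstream classification unchanged (tested).

## Ploidy analysis

The per-patient IOD sample (≥100 nuclei required) is smoothed with a
Gaussian kernel of **fixed** bandwidth 0.04 × median IOD. An automatic
(Scott/Silverman) bandwidth is deliberately not used: it scales with the
full-sample standard deviation, which for a bimodal DNA histogram is set by
the peak separation rather than the peak widths, and merges 2c/3c peaks.
Peaks need a prominence of 5% of the maximum density; the highest peak is
the 2c reference (an external reference-cell IOD can be supplied instead).
DNA index is the ratio of the most prominent peak outside both the diploid
window [0.9, 1.1] and the tetraploid window [1.9, 2.1] to the 2c reference,
or 1.0 when no such peak exists. 5cER/9cER count nuclei above 2.5×/4.5× the
2c IOD over all analysed nuclei. Calls: aneuploid if an off-window peak
exists or 5cER > 1%; tetraploid if the fraction of nuclei with DI in
[1.9, 2.1] exceeds 10% without aneuploidy; else diploid. All windows and
limits are fields of `PloidyRules` — they are a deliberate simplification
of the consensus cytometry guidelines, not a full implementation.

## Classification and evaluation

A two-class linear discriminant on one feature with equal priors reduces to
a threshold at the midpoint of the class means (the pooled variance
cancels); unequal priors shift it by s²·ln(π₂/π₁)/(m₁−m₂). Equal priors are
the default even for mildly unequal group sizes, matching how a plain CCR
is reported. Feature selection is the training-CCR argmax over f⁺, f⁻,
f⁺−f⁻ with exact ties resolved in that fixed order (logged). Pearson χ² on
the 2×2 table uses no continuity correction and is reported absent when a
marginal is zero. The combined NT/ICM panel uses an OR rule with missing
ICM treated as negative so those patients are retained; both the rule and
the missing-data handling are configurable. Percentages are carried
unrounded and printed rounded to integers.

## Synthetic data generator

The generator emulates the measurable structure of Feulgen monolayer
galleries:

* **Cohort shape** — two classes, by default 60 patients each with 1500
  nuclei per case, randomly split 1:1 into training and test sets per class.
* **Areas** — log-normal with median 3000 px and log-sd 0.45, covering
  A₀–A₁₀ with every feature group A₁–A₅ receiving ≥1% of nuclei.
* **Texture** — white noise smoothed by a Gaussian kernel (the class's
  correlation length), normalised in-mask and scaled to the class contrast
  (default s.d. 60 grey levels of 1024). Defaults: correlation length 2 px
  (non-dysplastic, busy heterochromatin granularity) vs 6 px (dysplastic,
  coarser aggregates) at matched contrast. No per-nucleus texture summary
  of the original patient images is published, so these values are chosen
  to exercise the pipeline, not calibrated to real tissue.
* **DNA content** — each patient is drawn DNA-abnormal with the class's
  rate (defaults 0% non-dysplastic, 65% dysplastic, mirroring the reported
  group difference) and then samples nuclear c-values from a diploid
  profile (single 2c peak, CV 3%, 5% uniform S-phase fill between 2c and
  4c) or an aneuploid profile (2c + 3.2c peaks at 50/50, CV 3%/5%, 6%
  S-phase, 3% tail uniform in 5.5–8c). IOD per c is an arbitrary fixed
  constant (250 OD·px), background 800 of 1024.
* **IOD targeting** — intensities are rescaled in OD space (with integer
  rounding and clipping to [1, background−1]) by a multiplicative fixed
  point with bisection fallback until the measured IOD is within 0.5% of
  target; the contract tested is 2%. For a *constant* (zero-contrast)
  nucleus the integer grey grid limits attainable precision to one grey
  step (~0.5–1% at typical parameters), which the iteration's best-effort
  fallback handles.

All randomness flows from one integer seed through a single
`numpy.random.Generator`; regeneration is bit-identical, including the
written TIFFs.

What the generator does **not** emulate: optics (point-spread, shading,
focus), segmentation errors, overlapping/cut nuclei, staining batch
effects, genuine biological between-patient variability within a class
(beyond the sampled areas and c-values), or any calibrated relation between
texture parameters and real chromatin. Passing recovery tests therefore
demonstrates the pipeline's internal correctness and sensitivity, not
clinical performance on tissue.

## Problem sizes used in validation

The bundled validation runs use scaled-down cohorts chosen as the smallest
sizes at which the checked effects are comfortably resolved: recovery uses
10+10 patients × 200 nuclei; the no-signal null uses 20 cohorts of 20+20
patients × 50 nuclei with median area 2200 px; quick unit fixtures use 3+3
patients × 120 nuclei. The generator's own defaults (60+60 × 1500) remain
the emulated study conditions.

## Known behaviour under the null

On cohorts whose two classes are generated identically, the **training**
CCR of the selected feature averages well above 50% (≈0.66 at 50
nuclei/patient, higher with more nuclei): the weight matrices, the feature
choice and the threshold are all fitted on the same cases, so the training
figure absorbs sampling noise by construction. The held-out **test** CCR
stays at chance (tested to the binomial band). This is the expected
behaviour of any adaptively weighted feature scheme and the reason the
train/test split is integral to the design; training CCRs should never be
quoted as performance.

## Limitations

* The ploidy rule set is a configurable simplification; near-diploid
  aneuploidy below the DI window resolution (±10%) and high-CV histograms
  are called diploid.
* Patients whose nuclei all fall outside A₁–A₅ are unscorable by the
  texture arm and excluded from its evaluation rather than imputed.
* `gaussian_kde` requires non-degenerate IOD samples; a zero-variance
  sample is rejected.
* The gallery format (TIFF + `_mask` + CSV manifests) is this package's
  own; original instrument galleries are proprietary and would need a
  reader shim.
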