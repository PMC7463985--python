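# Methods

This note documents the models, conventions and numerical choices
behind each stage of the pipeline, what the synthetic generators do and
do not emulate, and the known limitations.

## Stain model and deconvolution

A brightfield pixel is modelled by Beer–Lambert absorption: with
incident intensity `I0 = 255` (8-bit), the per-channel optical density
`OD_c = log10(I0 / I_c)` is the linear superposition of three stains —
PAS reaction product, melanin pigment, and a blue-green background tone
— each with a fixed unit RGB absorption vector. Stacking the vectors as
rows of `M`, concentrations solve `od = c · M` per pixel via the
explicit matrix inverse (`cond(M) ≈ 5.6` for the default vectors, so
the solve is well-behaved). Conventions:

* **Intensity floor.** Intensity 0 is floored to 1 before the log,
  bounding OD at `log10(255) ≈ 2.407` and avoiding infinities.
* **Negative concentrations** produced by noise or crosstalk are
  clamped to 0 *after* solving; the unclamped solution reproduces the
  input OD to machine precision (verified in tests).
* **Green-minimum adjustment.** The magenta PAS signal is intensified
  before OD conversion by remapping the green channel,
  `g' = clamp(round((g − gmin)·255/(255 − gmin)), 0, 255)` with
  `gmin = 104` by default — the effect of an 8-bit minimum-display
  slider applied to pixel data. Deconvolution operates on the
  green-adjusted image; the adjustment precedes unmixing in the
  workflow this package implements.
* **8-bit layer encoding.** The PAS concentration layer is mapped to 8
  bits on the fixed absolute scale `c / log10(255)` (so intensities are
  comparable across sections), encoded brightfield-style (255 = no
  stain), and then inverted (`v' = 255 − v`) to put stain bright on a
  dark background. The inverted image — the one measurements are
  redirected to — is therefore *linear* in the clamped concentration,
  which the ratio-based glycogen estimate below requires. Encoding the
  scaled layer with stain dark and measuring only after inversion
  mirrors how deconvolved transmittance layers are handled in
  ImageJ-style workflows.
* **Background correction** is an optional white-point division by a
  user-supplied blank-region mean; no specific algorithm is prescribed,
  and it defaults to off.

## Differential glycogen estimate

Per tumor and condition (untreated vs amylase-pretreated), integrated
densities (sum of inverted-PAS values inside the tumor mask) are pooled
across images area-weighted: `μ = Σ ID / Σ area`, *not* the mean of
per-image means. The glycogen estimate is
`100·(μ_u − μ_a)/μ_u`; it is invariant to common rescaling of both
conditions. Negative estimates (amylase section staining darker) are
retained and flagged rather than clipped, preserving rank statistics.
Group assignment uses the standard sample median with ties going to
"high" (the grouping is defined as at-or-above the median). No
registration between the untreated and amylase sections is attempted —
they are different physical sections; only pooled means are compared.

**Accuracy regime.** The green-minimum rescale is nonlinear in
concentration, so the measured intensity is a convex function of the
true PAS density. Forward-model analysis shows the differential
estimate is accurate to ≤ 3 percentage points only for faint staining
(peak PAS OD ≲ 0.12 with little pigment and OD noise ≲ 0.005); at
higher stain density or noise the mid-range estimates bias upward by
5–15 points (Jensen effect through the remap plus the ≥ 0 clamp), and
co-localized pigment leaks into the PAS layer after the green remap,
biasing the estimate low at high glycogen fractions. The simulator
defaults sit in the accurate regime; the pigment-crosstalk regime is
exercised separately in tests (full digestion still recovers ≥ 90%).

## FISH scoring

Zero-signal nuclei are treated as hybridization failures: they leave
the denominator of the percent-monosomy score but stay in the
denominator of the chromosomal index, whose definition is total signals
over nuclei counted. Nuclei with ≥ 3 signals count as non-monosomic;
polysomy is not separately classed. A warning (not an error) is raised
below 203 scorable nuclei, the protocol minimum for a reliable
percentage. Cohort medians are recomputed from the input by default;
externally established medians (31.94% / 1.01) can be supplied to
reproduce a published classification. Observed chromosomal indices fall
well below the disomic expectation of 2 because 6 µm sections truncate
nuclei; the simulator reproduces this with an explicit signal-dropout
probability (`E[index] = 2(1 − t)` for disomic nuclei).

## Expression screen

* Monosomy-3 = loss of both 3p and 3q arm calls; samples missing either
  call are excluded.
* Signed fold change `sign(Δ)·2^|Δ|` from group medians of
  log2(FPKM-uq+1) values; magnitudes are never inside (0, 1), and
  swapping groups flips the sign.
* Mann–Whitney U: exact enumeration when the smaller group has ≤ 8
  observations and no ties; otherwise the tie-corrected normal
  approximation without continuity correction (cross-checked against
  scipy in tests). All-identical data returns p = 1.
* Bonferroni multiplier defaults to the number of panel genes actually
  tested; it is configurable because a smaller family (e.g. only a
  reported subset) is a defensible alternative.
* "Aberrant copy number" for the rerun means any non-neutral call
  (loss *or* gain) at the gene's locus. "Differential regardless of
  copy number" = adjusted p < α in the all-patients test AND (adjusted
  p < α in the rerun OR rerun not applicable because the gene is on
  chromosome 3). This conjunction reproduces the published membership
  of the differential set.
* p-values are kept raw in machine output and displayed rounded to two
  decimals, half away from zero, with "0.00" permitted.
* Validation-cohort-style analyses (grouping by metastasis or gender
  instead of monosomy-3) use the same two-group machinery via
  `associate` / `mwu_test`; multiple probes per gene are kept separate
  by giving them distinct row identifiers.

## Clinical statistics

No Yates continuity correction anywhere: the uncorrected Pearson
statistic is required to reproduce the published two-decimal p-values
(e.g. the nuclear-BAP1 association holds at 0.01 uncorrected but not
with Yates). Low expected counts warn instead of failing — one
published cell has an expectation below 1. Kaplan–Meier estimation and
the log-rank test delegate to lifelines; survival time is in months
with censoring at last follow-up. The median-expression split uses the
same tie rule as the glycogen grouping.

## Synthetic generators

All generators are pure functions of (params, seed) — the same seed
gives bit-identical output.

* **Image pairs**: uniform PAS + pigment concentrations inside a disk
  or randomly-wobbled blob mask, composited by the exact Beer–Lambert
  forward model with the default stain vectors; the amylase image
  scales PAS by (1 − f). Gaussian noise is added in OD space (i.e.
  multiplicatively in intensity, mimicking staining variability) before
  8-bit quantization, keeping the forward model exact. Defaults: 96×96,
  peak PAS OD 0.08, no pigment, OD noise 0.005 — a faint, lightly
  pigmented tumor region, deliberately inside the accuracy regime
  described above. Not emulated: tumor morphology, vasculogenic-mimicry
  arcs, focal staining texture, batch effects.
* **FISH counts**: true copy number 1 with probability m else 2, each
  signal independently dropped with probability t.
* **Expression cohorts**: `baseline + Δ_g·1[monosomy3] + dosage +
  N(0, σ)`, floored at 0; defaults n = 80 samples (the cohort scale of
  the source data), monosomy probability 0.5, baseline 8, σ = 0.5
  log2 units. Off-chromosome-3 loci get aberrant calls at rate 0.05
  with a ±0.8 log2 dosage shift — an arbitrary but documented value
  used only to exercise the omission rerun.
* **Clinical tables**: even high/low split, a binary covariate tied to
  the group by a configurable odds ratio, exponential survival with a
  group hazard ratio (baseline 0.02 events/month), uniform censoring
  over 108 months.

Passing the recovery tests on these generators demonstrates that the
estimators are unbiased and calibrated under the model they assume; it
does not establish robustness to the spatial heterogeneity, section
artefacts, or annotation noise of real slides and cohorts.

## Problem sizes and test design

The statistical checks run at sizes chosen to make their Monte-Carlo
error small relative to the asserted bounds: fraction recovery over
f ∈ {0, 0.25, 0.5, 0.75, 1}; planted-effect recovery at ~200/200
samples; family-wise error over 1000 null panels at n = 77; rank-test
and log-rank calibration over 2000 null replicates (rejection rate
within [0.03, 0.07] at α = 0.05); log-rank power over 200 replicates at
hazard ratio 4. Sub-seeds for each block are derived from the single
CLI seed.

## Known limitations

* The intensity scale is only comparable across sections under the
  fixed 8-bit mapping; estimates from images processed with different
  display settings are not comparable.
* The green-minimum step makes the PAS intensity nonlinear in
  concentration; the differential percentage is trustworthy for faint
  stains and biased for dense ones (quantified above). Pigment
  crosstalk after the green remap biases estimates low in heavily
  pigmented regions.
* The percent-monosomy score cannot distinguish true monosomy from
  truncation-induced single signals; the dual-score design (percentage
  + index against cohort medians) mitigates but does not remove this.
* The packaged panel beyond the 23 published entries is a synthetic
  completion; locus annotations there are approximate and only the
  chromosome assignment affects computation (the chromosome-3 rerun
  rule).
* No automated tumor segmentation, stain-vector estimation, Cox
  regression, or enrichment analysis; heatmap/plot rendering is out of
  scope beyond KM step-function export.
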