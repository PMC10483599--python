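# Methods

## The aneuploidy score

A LINE-1 amplicon library samples reads genome-wide with arm-level density
roughly proportional to the local abundance of LINE-1 elements. After
alignment, reads with MAPQ < 15 are discarded and the rest are assigned to
the chromosome arm containing the leftmost aligned base (0-based; 150 bp
single-end amplicon reads cannot straddle a centromere in practice, so no
split handling is attempted). The acrocentric short arms 13p, 14p, 15p, 22p
and the whole of chromosome Y carry too few LINE-1 targets and are excluded;
reads there are dropped before normalization, so the normalized vector is a
probability vector over the 42 analyzed arms. 21p is acrocentric too but is
*not* excluded by default — the exclusion list is deliberately the minimal
published one — and an `exclude_21p` switch exists for stricter analyses.
Samples with fewer than 90,000 retained reads (counted after the MAPQ
filter, before arm exclusion) carry a `qc_low_yield` flag; re-sequencing is
an upstream operational matter, not pipeline logic. PCR duplicates are kept:
the assay is amplicon-based and deduplication would destroy the signal.
Secondary and supplementary alignment records are skipped to avoid double
counting.

Per included arm *a*, with x_a the sample's normalized count and (μ_a, σ_a)
the mean and SD of normalized counts across a healthy/diploid reference
panel (SD with the n−1 denominator; the panel is small, typically n = 17,
so the unbiased estimator matters), the arm Z-score is

    z_a = (x_a − μ_a) / σ_a.

The per-sample sum of squares S = Σ_a z_a² aggregates deviation across the
genome. Two conventions circulate for the quantity that is thresholded:

* the raw sum S itself (`genome_wide_score`, `standardize=False`), and
* the **panel-standardized score** (S − m) / s, where m and s are the mean
  and SD of the panel members' own sums of squares (`standardize=True`,
  the default in `score_cohort`).

The package implements both and dichotomizes on the standardized score by
default. The standardized form is the one under which the conventional
threshold of 5 is meaningful: with ~41 arms the raw sum concentrates around
the arm count even for perfectly healthy samples (E[S] ≈ 41), so a raw
threshold of 5 would label every sample aneuploid, whereas the standardized
score scatters around 0 for healthy samples, can be negative, and admits
data-driven thresholds near 2. Panel members' sums are computed against
panel statistics that include themselves; with n = 17 the self-inclusion
deflation is ≈ 6% and identical for every member, so it cancels in the
standardization. The threshold comparison is inclusive (score ≥ 5 ⇒
aneuploid). An optional `per_arm_z_min` zeroes |z| below a per-arm cut
before summation (off by default; some arm-level variants of the assay sum
only large deviations).

The score is depth-invariant (it depends on counts only through fractions)
and invariant to arm ordering; both properties are asserted in tests.

## Synthetic cohorts

The generator produces every input the analysis consumes, with the
dependence structure the method assumes:

* **Arm counts.** Baseline arm weights w_a are proportional to arm length —
  a proxy for LINE-1 density that preserves the rank structure normalization
  must handle; no LINE-1 map is shipped. A tumour with cell fraction f and
  arm copy numbers c_a shifts the weights to w_a (2(1−f) + f·c_a)/2,
  renormalized; f = 0 reduces exactly to the healthy model. Counts are
  Dirichlet-multinomial: proportions drawn from Dirichlet(w/δ) with a single
  overdispersion parameter δ (`depth_dispersion`, default 5·10⁻⁵, i.e.
  concentration 20,000, giving arm-fraction CVs of a few percent as seen
  between healthy subjects), then a multinomial draw at Poisson depth
  (`depth_mean`, default 200,000 reads — comfortably above the 90,000-read
  QC floor). δ = 0 is a pure multinomial; `deterministic_counts=True` gives
  expected counts rounded, for exact tests.
* **Tumour fraction.** A point mass at 0 (probability 0.4) mixed with a
  Beta(2, 4) on (0, 1]: a realistic mCRPC cohort in which a substantial
  minority shed no detectable ctDNA and shedders centre near f ≈ 0.3.
* **Copy-number profiles.** Non-shedders stay diploid. For shedders the
  default profile generator alters 1 + Poisson(9) arms (gains to 3–4 copies
  with probability 0.6, losses to 1 copy otherwise) — heavily rearranged
  genomes, as in advanced prostate cancer.
* **CTC counts.** Negative binomial with log-mean log(1.5) + 8f and
  dispersion 0.8: overdispersed non-negative integers whose mean rises
  steeply with tumour fraction, so the CTC ≥ 5 dichotomy correlates with the
  score as observed in real cohorts.
* **Survival.** Exponential event times with hazard
  h₀ exp(β₁·I[aneuploid_true] + β₂·I[CTC ≥ 5]), h₀ = 0.035/month,
  β₁ = log 3.24, β₂ = log 2.92, and independent exponential censoring at
  0.04/month. Proportional hazards holds by construction, so Cox recovery of
  (β₁, β₂) is a valid oracle. Under these defaults ~70% of patients are
  observed to die, matching the discovery-cohort regime (92 deaths among
  131). The true label `aneuploid_true` is f > 0 with a non-diploid profile.
* **Covariates.** Age, Gleason, PSA, WHO status and the laboratory values
  are drawn with realistic locations/spreads but independent of outcome —
  deliberate nulls for testing the P < 0.1 screen's calibration. `max_vaf`
  tracks tumour fraction with noise (and a small clonal-hematopoiesis floor
  for non-shedders); 10% of values are missing to exercise pairwise-complete
  handling.

One integer seed determines the whole cohort bit-for-bit; the generator
draws component streams (panel, counts, biomarkers, survival) from
independent sub-generators of that seed.

**What the generator does not emulate:** GC and fragment-length biases,
batch effects between sequencing runs, subclonal heterogeneity, arm-level
LINE-1 density variation (lengths are a proxy), informative censoring, and
measured-covariate effects on survival beyond the two markers. Passing
tests therefore demonstrate the *statistical machinery* — not robustness to
these real-data artefacts.

## Measurement error and the recovery oracle

The hazard acts on the true label, while the pipeline dichotomizes the
*measured* score. Near the detection boundary (f small, or alterations
concentrated on short arms) the two disagree, and misclassification
attenuates hazard ratios fitted on the measured label — on replicate
131-patient cohorts the mutually adjusted HR for the measured status comes
out near 2.5 against a generative 3.24. This is a property of any
plug-in-dichotomized biomarker, not a defect of the fit. The
parameter-recovery check therefore fits Cox on the true labels (and the
exactly observed CTC dichotomy), isolating the estimator from the
measurement chain; the measurement chain itself is validated separately
through monotonicity-in-f and correlation properties.

## Survival analysis choices

* Cox partial-likelihood fits use the Efron tie correction by default
  (matching the R `survival` ecosystem's default), with Breslow available;
  the two coincide exactly on tie-free data (asserted). Inference is Wald:
  HR = exp(β), CI = exp(β ± 1.96 SE), two-sided p from the normal
  approximation. AIC = 2k − 2·log partial likelihood with k the number of β
  terms.
* The univariate screen retains covariates with Wald P < 0.1, each fit on
  its own complete cases. Backward selection drops one term at a time — the
  largest Wald p ≥ 0.1 — and is deterministic given data; if everything is
  dropped an explicit empty (null) model is returned.
* The combined model codes the 2×2 CTC × aneuploidy factor as three
  indicators against the double-negative reference group, and emits the four
  Kaplan–Meier curves and the overall log-rank test.
* WHO performance status is pooled 0 vs 1–2.
* The required-events computation is the Schoenfeld formula
  D = ⌈(z_{1−α/2} + z_{power})² / (p(1−p) ln²HR)⌉; it is reported under
  explicitly assumed inputs (HR and group fraction), since a target event
  count is only meaningful relative to those.
* KM medians are the earliest time with S(t) ≤ 0.5, NaN when never reached.

## Cutpoint optimization

Candidate thresholds are midpoints between consecutive distinct scores plus
∓∞ sentinels (every distinct classification outcome appears exactly once);
`candidates="observed"` uses the observed values instead, matching tools
that report an attained score as the threshold. The rule score ≥ t predicts
death; the objective is sensitivity + specificity (the same argmax as the
Youden index), with ties broken toward the smallest threshold (up to 1e-12
rounding of the rates). Survival status is the event indicator at end of
follow-up, ignoring time — a deliberate, documented simplification of the
published procedure. Bootstrap replicates resample patients with
replacement; replicates that lose one class entirely are redrawn (they
carry no cutpoint information). The bootstrap summarizes threshold
variability (median, 2.5–97.5 percentile interval) only; no bias-corrected
intervals are attempted. Optimal cutpoints are intrinsically unstable —
replicate cohorts scatter their optima widely — which is exactly what the
bootstrap output shows.

## Associations

Spearman ρ uses average ranks for ties and the t-approximation with n−2 df
for the two-sided p (adequate at cohort sizes above ~25; for tiny n an exact
permutation is used in tests as an oracle). Pairs with a missing member are
dropped and counted. The descriptive least-squares line is fit on raw
values, regressing the partner variable on the score; any logarithmic
display scaling is a plotting concern outside the analysis.

## Numerical and degenerate-input conventions

* A reference panel needs ≥ 2 samples; an arm whose panel SD is zero up to
  rounding (relative tolerance 1e-9) is rejected as degenerate rather than
  yielding huge spurious Z-scores.
* Normalization of an all-zero count vector, Cox fits without events or
  with constant covariates, single-class cutpoint inputs, empty KM inputs
  and single-group log-rank calls all raise informative errors.
* Reads on chromosomes absent from the arm definitions are tallied in an
  `unassigned` bucket, never silently dropped; the read-fate categories
  partition the input exactly (asserted on fixtures).
* Tabular outputs are TSV with floats at 10 significant digits, so
  data-driven thresholds round-trip through text; the pipeline summary is
  sorted-key JSON and byte-identical for a fixed seed.

## Problem sizes in the checks

The verification suite uses replicate sizes chosen to give adequate
Monte-Carlo resolution at interactive runtimes: 200 replicates of
500-patient cohorts for hazard-ratio recovery (Monte-Carlo SE ≈ 0.05 on the
HR scale), 2,000 replicates of 131-patient null cohorts for screen
calibration (SE ≈ 0.7 percentage points on the 10% retention rate), 100
random instances for the cutpoint sweep-vs-brute-force equivalence, and
30 replicate cohorts plus a 10,000-iteration bootstrap in the acceptance
script.

## Known limitations

* The condensed hg19 cytoband table bundled with the package carries only
  the p/q boundary per chromosome; full UCSC cytoBand files are parsed
  identically when sub-band resolution is available.
* No GC or length correction of counts is applied, and no absolute tumour
  fraction is estimated from the score; the score *reflects* ctDNA burden
  but is not calibrated to it.
* Whether the 90,000-read QC floor applies before or after MAPQ filtering
  is a judgment call; it is applied after, and the flag records that choice.
* Complete-case handling per model is the only missing-data strategy.
* The KM plot is a minimal visual aid; publication-grade survival graphics
  are out of scope.
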