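# aneuscore

Genome-wide aneuploidy scoring of cell-free DNA from chromosome-arm read
counts, and the survival analysis that evaluates the dichotomized score as a
prognostic biomarker.

## The problem

In metastatic castration-resistant prostate cancer (mCRPC), the fraction of
tumour-derived DNA (ctDNA) in plasma cell-free DNA reflects tumour burden.
LINE-1 amplicon shallow sequencing (the mFast-SeqS approach) samples the
genome through a single primer pair; arm-level imbalances in the resulting
read counts reveal tumour aneuploidy without prior knowledge of the tumour's
mutations. This package implements the complete analysis from aligned reads
(or a precomputed count table) to a prognostic report:

1. **Arm counting** — reads with MAPQ < 15 are excluded; the rest are counted
   per chromosome arm. The acrocentric short arms 13p, 14p, 15p, 22p and all
   of chromosome Y are excluded from analysis. Samples with fewer than 90,000
   retained reads are flagged for re-sequencing.
2. **Scoring** — per arm *a*, the normalized count of a sample is converted
   to a Z-score against a reference panel of healthy/diploid controls,
   z_a = (x_a − μ_a)/σ_a. The squared Z-scores are summed,
   S = Σ_a z_a², and S is standardized against the panel's own
   sum-of-squares distribution to give the signed genome-wide aneuploidy
   score. A sample is called **aneuploid** when its score is ≥ 5.
3. **Survival analysis** — Kaplan–Meier curves and log-rank tests; univariate
   Cox proportional-hazards screening (retain P < 0.1); multivariable Cox
   with backward selection (drop at P ≥ 0.1, Efron ties); the combined
   CTC (< 5 vs ≥ 5) × aneuploidy 2×2 strata model; and the Schoenfeld
   required-events power formula.
4. **Cutpoint optimization** — a data-driven alternative dichotomization
   threshold maximizing sensitivity + specificity against survival status,
   with patient bootstrap (10,000 iterations by default).
5. **Associations** — Spearman ρ of the score with CTC counts and with the
   maximum variant allele frequency from a targeted panel.

A synthetic-data module generates cohorts with the statistical structure the
analysis assumes (Dirichlet-multinomial arm counts shifted by tumour
fraction under an arm-level copy-number profile, negative-binomial CTC
counts rising with tumour fraction, exponential survival with proportional
hazards on both dichotomized markers), so every stage is testable end to end
without sequencing data.

## Worked example

```python
from aneuscore import (PipelineConfig, SimulationConfig, run_all)

summary = run_all(PipelineConfig(
    outdir="demo_out", seed=11, n_boot=500,
    simulate=SimulationConfig(n_patients=131),
))
print(round(summary["univariate"]["aneuploid"]["HR"], 2))   # 3.53
print(round(summary["univariate"]["ctc_high"]["HR"], 2))    # 3.13
print({k: round(v["HR"], 2) for k, v in summary["multivariable"]["terms"].items()})
# {'psa': 1.0, 'aneuploid': 2.45, 'ctc_high': 2.38}
print(round(summary["association"]["score_vs_ctc_count"]["rho"], 2))  # 0.61
```

With seed 11 this simulates a 131-patient cohort (95 deaths, 67 samples
called aneuploid) plus a 17-subject healthy reference panel, scores every
sample, and prints a univariate hazard ratio of 3.53 for the dichotomized
aneuploidy score and 3.13 for the dichotomized CTC count — i.e. aneuploid
patients die at roughly three times the rate of euploid patients in this
cohort. The multivariable model (after the P < 0.1 screen and backward
selection) keeps both markers at attenuated, mutually adjusted hazard ratios
(2.45 and 2.38; PSA squeaks through the screen at HR ≈ 1.00 per unit), and
the score correlates with CTC counts at ρ = 0.61. `demo_out/summary.json` holds every statistic
(HRs with 95% CIs, AICs, log-rank p-values, the optimal cutpoint and its
bootstrap distribution) plus the per-sample score and Z-score tables.

The same pipeline runs from files: an arm-count TSV (or SAM/BAM via
`aneuscore count`), a healthy-control count TSV and a clinical CSV with
`sample_id, os_months, event, ctc_count, who_status, ...` columns.

```bash
aneuscore simulate --seed 4 --outdir sim/
aneuscore score --counts sim/patient_counts.tsv --reference sim/reference_counts.tsv
aneuscore cutpoint --scores scores.tsv --clinical sim/clinical.csv --n-boot 10000 --seed 4
aneuscore run-all --seed 11 --outdir demo_out
```

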