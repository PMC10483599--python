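"""Generative model for arm-count profiles, biomarkers and survival outcomes.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without sequencing data:

* Arm-level read counts are Dirichlet-multinomial. Expected arm weights are
  proportional to arm length (a proxy for LINE-1 element density); a tumour
  sample with cell fraction ``f`` and per-arm copy numbers ``c_a`` shifts the
  weight of arm ``a`` by the factor ``(2(1-f) + f*c_a)/2`` before
  renormalization, so ``f=0`` reduces exactly to the healthy model.
* CTC counts are negative-binomial with log-mean linear in tumour fraction.
* Survival is exponential with hazard
  ``baseline_hazard * exp(b_aneu*I[aneuploid] + b_ctc*I[CTC>=5])`` and
  independent exponential censoring, so proportional hazards holds by
  construction and Cox recovery is a valid oracle.

A point mass at zero tumour fraction mixed with a Beta on (0, 1] mimics
cohorts in which part of the patients shed no detectable ctDNA.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .arm_counting import ArmCountVector, ArmDefinition, write_count_table

#: Default aneuploidy/CTC log hazard ratios: univariate effect sizes typical of
#: dichotomized ctDNA-burden and CTC-count markers in mCRPC cohorts.
DEFAULT_LOG_HR_ANEUPLOIDY = math.log(3.24)
DEFAULT_LOG_HR_CTC = math.log(2.92)


def default_cna_profile(rng: np.random.Generator, n_arms: int) -> np.ndarray:
    """Random arm-level copy-number profile for an aneuploid genome.

    Draws the number of altered arms from 1 + Poisson(9) (heavily rearranged
    genomes, as in advanced prostate cancer) and assigns gains (3-4 copies,
    60%) or losses (1 copy) to randomly chosen arms; all other arms stay at 2.
    """
    n_alt = min(n_arms, 1 + rng.poisson(9))
    altered = rng.choice(n_arms, size=n_alt, replace=False)
    profile = np.full(n_arms, 2, dtype=int)
    for i in altered:
        if rng.random() < 0.6:
            profile[i] = 3 if rng.random() < 0.7 else 4
        else:
            profile[i] = 1
    return profile


@dataclass
class SimulationConfig:
    """Knobs of the generative model; ``seed`` fully determines all outputs."""

    n_reference: int = 17
    n_patients: int = 131
    depth_mean: float = 200_000.0
    depth_dispersion: float = 5e-5  # Dirichlet overdispersion; 0 = pure multinomial
    tumor_fraction_distribution: dict = field(
        default_factory=lambda: {
            "name": "zero_beta_mixture",
            "p_zero": 0.4,
            "alpha": 2.0,
            "beta": 4.0,
        }
    )
    cna_profile_generator: Callable[[np.random.Generator, int], np.ndarray] = (
        default_cna_profile
    )
    baseline_hazard: float = 0.035  # events per month for the reference group
    log_hr_aneuploidy: float = DEFAULT_LOG_HR_ANEUPLOIDY
    log_hr_ctc: float = DEFAULT_LOG_HR_CTC
    censoring_rate: float = 0.04  # per month; yields ~70% observed events under defaults
    ctc_model: dict = field(
        default_factory=lambda: {
            "intercept": math.log(1.5),
            "slope": 8.0,
            "dispersion": 0.8,
        }
    )
    seed: int = 0
    deterministic_counts: bool = False  # expected counts, rounded (no sampling)

    def __post_init__(self) -> None:
        if self.n_reference < 2:
            raise ValueError("n_reference must be >= 2 (panel SD undefined otherwise)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        tf = self.tumor_fraction_distribution
        if tf.get("name") != "zero_beta_mixture":
            raise ValueError(f"unknown tumour-fraction distribution {tf.get('name')!r}")
        if not 0 <= tf["p_zero"] <= 1:
            raise ValueError("p_zero must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one component, derived from the seed."""
        return np.random.default_rng([int(self.seed), int(stream)])


def arm_weights(arms: Sequence[ArmDefinition]) -> tuple[list[str], np.ndarray]:
    """Baseline expected arm proportions, proportional to included-arm length."""
    included = [a for a in arms if a.included]
    lengths = np.array([a.end - a.start for a in included], dtype=float)
    return [a.name for a in included], lengths / lengths.sum()


def expected_arm_weights(
    f: float, cna: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Mixture of diploid background and tumour copy numbers at fraction ``f``."""
    if not 0 <= f <= 1:
        raise ValueError(f"tumour fraction {f} outside [0, 1]")
    cna = np.asarray(cna, dtype=float)
    if (cna < 0).any():
        raise ValueError("copy numbers must be >= 0")
    shifted = w * (2.0 * (1.0 - f) + f * cna) / 2.0
    total = shifted.sum()
    if total <= 0:
        raise ValueError("degenerate profile: all expected weights are zero")
    return shifted / total


def _draw_counts(
    rng: np.random.Generator,
    weights: np.ndarray,
    cfg: SimulationConfig,
) -> np.ndarray:
    if cfg.deterministic_counts:
        return np.round(cfg.depth_mean * weights).astype(int)
    depth = rng.poisson(cfg.depth_mean)
    if cfg.depth_dispersion > 0:
        p = rng.dirichlet(weights / cfg.depth_dispersion)
    else:
        p = weights
    return rng.multinomial(depth, p)


def simulate_reference_panel(
    cfg: SimulationConfig,
    arms: Sequence[ArmDefinition],
    rng: np.random.Generator | None = None,
) -> list[ArmCountVector]:
    """Healthy/diploid control profiles (tumour fraction 0)."""
    rng = rng if rng is not None else cfg.rng(1)
    names, w = arm_weights(arms)
    out = []
    for i in range(cfg.n_reference):
        counts = _draw_counts(rng, w, cfg)
        out.append(
            ArmCountVector(
                sample_id=f"ref{i + 1:02d}", counts=dict(zip(names, counts.tolist()))
            )
        )
    return out


def simulate_tumor_sample(
    f: float,
    cna: np.ndarray,
    cfg: SimulationConfig,
    arms: Sequence[ArmDefinition],
    rng: np.random.Generator | None = None,
    sample_id: str = "tumor",
) -> ArmCountVector:
    """One sample at tumour fraction ``f`` with arm copy numbers ``cna``."""
    rng = rng if rng is not None else cfg.rng(2)
    names, w = arm_weights(arms)
    q = expected_arm_weights(f, cna, w)
    counts = _draw_counts(rng, q, cfg)
    return ArmCountVector(sample_id=sample_id, counts=dict(zip(names, counts.tolist())))


def _draw_tumor_fraction(rng: np.random.Generator, tf: dict) -> float:
    if rng.random() < tf["p_zero"]:
        return 0.0
    return float(rng.beta(tf["alpha"], tf["beta"]))


def _draw_ctc(rng: np.random.Generator, f: float, model: dict) -> int:
    mu = math.exp(model["intercept"] + model["slope"] * f)
    k = model["dispersion"]
    if k <= 0:  # Poisson limit
        return int(rng.poisson(mu))
    return int(rng.negative_binomial(k, k / (k + mu)))


@dataclass
class SimulatedCohort:
    """Reference-panel and patient count profiles with matched clinical table."""

    reference: list[ArmCountVector]
    arm_counts: list[ArmCountVector]  # one per patient
    truth: pd.DataFrame  # sample_id, tumor_fraction, aneuploid_true, cna
    clinical: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write count TSVs, clinical CSV and truth JSON; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference_counts": outdir / "reference_counts.tsv",
            "patient_counts": outdir / "patient_counts.tsv",
            "clinical": outdir / "clinical.csv",
            "truth": outdir / "truth.json",
        }
        write_count_table(self.reference, paths["reference_counts"])
        write_count_table(self.arm_counts, paths["patient_counts"])
        self.clinical.to_csv(paths["clinical"], index=False, float_format="%.10g")
        truth = {
            row.sample_id: {
                "tumor_fraction": row.tumor_fraction,
                "aneuploid_true": bool(row.aneuploid_true),
                "cna": list(map(int, row.cna)),
            }
            for row in self.truth.itertuples()
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        return paths


def simulate_cohort(
    cfg: SimulationConfig, arms: Sequence[ArmDefinition]
) -> SimulatedCohort:
    """Full cohort draw: counts, biomarkers, covariates and survival outcomes.

    Per patient a tumour fraction is drawn; non-shedding patients (f = 0)
    keep a diploid profile. The true aneuploidy label is f > 0 with a
    non-diploid profile. The hazard acts on the true label and the drawn CTC
    count; all laboratory covariates are prognostically null by construction.
    """
    rng_f = cfg.rng(3)
    rng_counts = cfg.rng(4)
    rng_clin = cfg.rng(5)
    rng_surv = cfg.rng(6)

    names, w = arm_weights(arms)
    n_arms = len(names)
    reference = simulate_reference_panel(cfg, arms)

    rows_truth, rows_clin, patients = [], [], []
    for i in range(cfg.n_patients):
        sid = f"pt{i + 1:03d}"
        f = _draw_tumor_fraction(rng_f, cfg.tumor_fraction_distribution)
        if f > 0:
            cna = cfg.cna_profile_generator(rng_f, n_arms)
        else:
            cna = np.full(n_arms, 2, dtype=int)
        aneuploid_true = bool(f > 0 and (cna != 2).any())
        q = expected_arm_weights(f, cna, w)
        counts = _draw_counts(rng_counts, q, cfg)
        patients.append(
            ArmCountVector(sample_id=sid, counts=dict(zip(names, counts.tolist())))
        )

        ctc = _draw_ctc(rng_clin, f, cfg.ctc_model)
        # Event process: exponential with proportional hazards on the two markers.
        h = cfg.baseline_hazard * math.exp(
            cfg.log_hr_aneuploidy * aneuploid_true + cfg.log_hr_ctc * (ctc >= 5)
        )
        t_event = rng_surv.exponential(1.0 / h)
        t_cens = (
            rng_surv.exponential(1.0 / cfg.censoring_rate)
            if cfg.censoring_rate > 0
            else math.inf
        )
        os_months = min(t_event, t_cens)
        event = int(t_event <= t_cens)

        # Baseline covariates; distributions loosely match an mCRPC cohort and
        # are independent of outcome (null covariates for the Cox screen).
        if f > 0:
            max_vaf = float(np.clip(f * (0.3 + 0.7 * rng_clin.beta(2, 2)), 0, 1))
        else:
            max_vaf = float(rng_clin.exponential(0.005))
        if rng_clin.random() < 0.1:
            max_vaf = np.nan
        rows_clin.append(
            {
                "sample_id": sid,
                "os_months": os_months,
                "event": event,
                "ctc_count": ctc,
                "who_status": int(rng_clin.choice([0, 1, 2], p=[0.38, 0.55, 0.07])),
                "age": float(np.clip(np.round(rng_clin.normal(70, 8)), 46, 89)),
                "gleason": int(rng_clin.choice([6, 7, 8, 9, 10], p=[0.1, 0.35, 0.3, 0.15, 0.1])),
                "psa": float(rng_clin.lognormal(math.log(85.6), 1.2)),
                "alb": float(rng_clin.normal(40, 4)),
                "anc": float(rng_clin.lognormal(math.log(4.9), 0.35)),
                "hbg": float(rng_clin.normal(7.7, 0.9)),
                "wbc": float(rng_clin.lognormal(math.log(7.5), 0.3)),
                "alp": float(rng_clin.lognormal(math.log(121.5), 0.7)),
                "ldh": float(rng_clin.lognormal(math.log(238.5), 0.7)),
                "max_vaf": max_vaf,
                "aneuploid_true": aneuploid_true,
            }
        )
        rows_truth.append(
            {
                "sample_id": sid,
                "tumor_fraction": f,
                "aneuploid_true": aneuploid_true,
                "cna": cna.tolist(),
            }
        )

    return SimulatedCohort(
        reference=reference,
        arm_counts=patients,
        truth=pd.DataFrame(rows_truth),
        clinical=pd.DataFrame(rows_clin),
        config=cfg,
    )
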