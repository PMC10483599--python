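"""Genome-wide aneuploidy scoring of arm-level read-count profiles.

Per included chromosome arm, a sample's normalized read count is converted to
a Z-score against a reference panel of healthy/diploid controls (subtract the
panel mean, divide by the panel SD of normalized counts). The squared Z-scores
are summed into a per-sample sum-of-squares statistic; that sum is in turn
standardized against the panel's own sum-of-squares distribution, yielding the
signed genome-wide aneuploidy score on which samples are dichotomized
(aneuploid iff score >= 5 by default). The raw sum of squares is retained
alongside the standardized score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arm_counting import ArmCountVector

#: Dichotomization threshold for the aneuploidy call.
DEFAULT_THRESHOLD = 5.0


def normalize(v: ArmCountVector) -> dict[str, float]:
    """Normalized read counts: per-arm fraction of the included-arm total."""
    if v.total_reads == 0:
        raise ValueError(f"sample {v.sample_id!r}: no retained reads to normalize")
    return {arm: c / v.total_reads for arm, c in v.counts.items()}


@dataclass
class ReferencePanel:
    """Per-arm mean/SD of normalized counts over healthy controls.

    ``sumsq_mean``/``sumsq_sd`` are the mean and SD of the panel members' own
    sums of squared Z-scores, used to standardize patient sums onto the
    genome-wide score scale.
    """

    arms: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n_panel: int
    sumsq_mean: float
    sumsq_sd: float

    def __post_init__(self) -> None:
        if self.n_panel < 2:
            raise ValueError("reference panel needs >= 2 samples")
        zero = [a for a, s in zip(self.arms, self.sd) if s <= 0]
        if zero:
            raise ValueError(f"degenerate panel: zero SD on arm(s) {zero}")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"mean": self.mean, "sd": self.sd}, index=self.arms)
        df.index.name = "arm"
        with open(path, "w") as fh:
            fh.write(
                f"# n_panel={self.n_panel}\tsumsq_mean={self.sumsq_mean!r}"
                f"\tsumsq_sd={self.sumsq_sd!r}\n"
            )
            df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferencePanel":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing panel metadata header line")
            meta = dict(
                item.split("=", 1) for item in header.lstrip("# ").rstrip().split("\t")
            )
            df = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(
            arms=list(df.index.astype(str)),
            mean=df["mean"].to_numpy(),
            sd=df["sd"].to_numpy(),
            n_panel=int(meta["n_panel"]),
            sumsq_mean=float(meta["sumsq_mean"]),
            sumsq_sd=float(meta["sumsq_sd"]),
        )


def build_reference(panel: Sequence[ArmCountVector]) -> ReferencePanel:
    """Panel statistics (mean, SD with n-1 denominator) of normalized counts."""
    if len(panel) < 2:
        raise ValueError("reference panel needs >= 2 samples")
    arms = sorted(panel[0].counts)
    for v in panel[1:]:
        if sorted(v.counts) != arms:
            raise ValueError(f"panel sample {v.sample_id!r}: arm set mismatch")
    fracs = np.array([[normalize(v)[a] for a in arms] for v in panel])
    mean = fracs.mean(axis=0)
    sd = fracs.std(axis=0, ddof=1)
    # numerically-zero SD (identical panel fractions up to rounding) is degenerate
    zero = [a for a, s, m in zip(arms, sd, mean) if s <= 1e-9 * max(m, 1e-300)]
    if zero:
        raise ValueError(f"degenerate panel: zero SD on arm(s) {zero}")
    # Panel members' own sums of squared Z-scores (self-included, as the
    # panel is used unchanged for patients).
    z = (fracs - mean) / sd
    sumsq = (z**2).sum(axis=1)
    return ReferencePanel(
        arms=list(arms),
        mean=mean,
        sd=sd,
        n_panel=len(panel),
        sumsq_mean=float(sumsq.mean()),
        sumsq_sd=float(sumsq.std(ddof=1)),
    )


def arm_zscores(v: ArmCountVector, ref: ReferencePanel) -> dict[str, float]:
    """Per-arm Z-scores: (normalized count - panel mean) / panel SD."""
    if sorted(v.counts) != sorted(ref.arms):
        raise ValueError(
            f"sample {v.sample_id!r}: arm set does not match reference panel"
        )
    fracs = normalize(v)
    return {
        a: (fracs[a] - m) / s for a, m, s in zip(ref.arms, ref.mean, ref.sd)
    }


@dataclass
class AneuploidyResult:
    """Per-sample aneuploidy scoring outcome."""

    sample_id: str
    z: dict[str, float]
    score: float  # quantity the threshold applies to
    threshold: float
    status: str  # "aneuploid" | "euploid"
    raw_sumsq: float  # sum of squared per-arm Z-scores
    qc_low_yield: bool = False


def genome_wide_score(
    z: Mapping[str, float],
    threshold: float = DEFAULT_THRESHOLD,
    sample_id: str = "sample",
) -> AneuploidyResult:
    """Sum of squared per-arm Z-scores, dichotomized at ``threshold`` (inclusive)."""
    if not z:
        raise ValueError("empty Z-score map")
    s = float(sum(val**2 for val in z.values()))
    status = "aneuploid" if s >= threshold else "euploid"
    return AneuploidyResult(
        sample_id=sample_id,
        z=dict(z),
        score=s,
        threshold=threshold,
        status=status,
        raw_sumsq=s,
    )


def standardized_score(raw_sumsq: float, ref: ReferencePanel) -> float:
    """Standardize a sum of squared Z-scores against the panel's own sums."""
    if ref.sumsq_sd <= 0:
        raise ValueError("panel sum-of-squares SD is zero; cannot standardize")
    return (raw_sumsq - ref.sumsq_mean) / ref.sumsq_sd


def score_sample(
    v: ArmCountVector,
    ref: ReferencePanel,
    threshold: float = DEFAULT_THRESHOLD,
    standardize: bool = True,
    per_arm_z_min: float | None = None,
) -> AneuploidyResult:
    """Score one sample against the reference panel.

    With ``standardize=True`` (default) the dichotomized score is the panel-
    standardized sum of squared Z-scores (signed; healthy samples scatter
    around 0). With ``standardize=False`` the raw sum of squares itself is
    thresholded. ``per_arm_z_min``, if set, zeroes out arms with |z| below the
    cut before summation (off by default).
    """
    z = arm_zscores(v, ref)
    zz = z
    if per_arm_z_min is not None:
        zz = {a: (val if abs(val) >= per_arm_z_min else 0.0) for a, val in z.items()}
    raw = float(sum(val**2 for val in zz.values()))
    score = standardized_score(raw, ref) if standardize else raw
    return AneuploidyResult(
        sample_id=v.sample_id,
        z=z,
        score=score,
        threshold=threshold,
        status="aneuploid" if score >= threshold else "euploid",
        raw_sumsq=raw,
        qc_low_yield=v.qc_low_yield,
    )


def score_cohort(
    samples: Sequence[ArmCountVector],
    ref: ReferencePanel,
    threshold: float = DEFAULT_THRESHOLD,
    standardize: bool = True,
    per_arm_z_min: float | None = None,
) -> list[AneuploidyResult]:
    """Score every sample; see :func:`score_sample`."""
    return [
        score_sample(v, ref, threshold, standardize, per_arm_z_min) for v in samples
    ]


def scores_frame(results: Sequence[AneuploidyResult]) -> pd.DataFrame:
    """Per-sample score table (sample_id, score, raw_sumsq, status, qc flag)."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "score": [r.score for r in results],
            "raw_sumsq": [r.raw_sumsq for r in results],
            "status": [r.status for r in results],
            "qc_low_yield": [r.qc_low_yield for r in results],
        }
    )


def write_scores(results: Sequence[AneuploidyResult], path: str | Path) -> None:
    scores_frame(results).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_zmatrix(results: Sequence[AneuploidyResult], path: str | Path) -> None:
    """Arm x sample matrix of per-arm Z-scores."""
    df = pd.DataFrame({r.sample_id: pd.Series(r.z) for r in results})
    df.index.name = "arm"
    df.to_csv(path, sep="\t", float_format="%.10g")
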