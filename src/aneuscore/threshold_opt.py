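"""Data-driven dichotomization threshold for aneuploidy scores.

Chooses the cutpoint that maximizes sensitivity + specificity (equivalently
the Youden index) for classifying survival status (dead vs. alive, ignoring
time) by the rule score >= t, and quantifies cutpoint variability by patient
bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


def evaluate_threshold(
    scores: np.ndarray, status: np.ndarray, t: float
) -> tuple[float, float]:
    """(sensitivity, specificity) of the rule score >= t for predicting death."""
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status).astype(bool)
    pred = scores >= t
    n_dead = status.sum()
    n_alive = (~status).sum()
    sens = (pred & status).sum() / n_dead if n_dead else math.nan
    spec = (~pred & ~status).sum() / n_alive if n_alive else math.nan
    return float(sens), float(spec)


def _candidates(scores: np.ndarray, mode: str) -> np.ndarray:
    uniq = np.unique(scores)
    if mode == "observed":
        cand = uniq
    elif mode == "midpoint":
        cand = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.empty(0)
    else:
        raise ValueError(f"unknown candidate mode {mode!r}")
    return np.concatenate(([-math.inf], cand, [math.inf]))


def _sweep(scores: np.ndarray, status: np.ndarray, cand: np.ndarray):
    # Vectorized confusion-matrix sweep over all candidate thresholds.
    dead = scores[status]
    alive = scores[~status]
    sens = (dead[None, :] >= cand[:, None]).mean(axis=1)
    spec = (alive[None, :] < cand[:, None]).mean(axis=1)
    total = sens + spec
    # ties (up to float rounding of the rates) break toward the smallest threshold
    best = int(np.nonzero(total >= total.max() - 1e-12)[0][0])
    return best, sens, spec


@dataclass
class CutpointResult:
    optimal_threshold: float
    youden: float  # sensitivity + specificity - 1 at the optimum
    sensitivity: float
    specificity: float
    table: pd.DataFrame  # per-candidate threshold, sensitivity, specificity
    bootstrap: np.ndarray  # per-replicate optimal thresholds
    bootstrap_median: float
    bootstrap_ci: tuple[float, float]  # 2.5-97.5 percentile interval
    n_boot: int
    seed: int


def optimize_cutpoint(
    scores,
    status_dead,
    n_boot: int = 10_000,
    seed: int = 0,
    candidates: str = "midpoint",
) -> CutpointResult:
    """Exhaustive sweep for the sensitivity+specificity-optimal cutpoint.

    Candidate thresholds are midpoints between consecutive distinct scores
    (plus -inf/+inf sentinels) or the observed values themselves
    (``candidates="observed"``). Ties are broken toward the smallest
    threshold. Bootstrap replicates resample patients with replacement and
    record each replicate's optimal threshold.
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status_dead).astype(bool)
    if scores.shape != status.shape:
        raise ValueError("scores and status must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if status.all() or not status.any():
        raise ValueError("both survival classes (dead and alive) must be present")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    cand = _candidates(scores, candidates)
    best, sens, spec = _sweep(scores, status, cand)
    table = pd.DataFrame(
        {"threshold": cand, "sensitivity": sens, "specificity": spec}
    )

    rng = np.random.default_rng(seed)
    n = len(scores)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        s, d = scores[idx], status[idx]
        # replicates missing a class carry no cutpoint information; redraw
        tries = 0
        while d.all() or not d.any():
            idx = rng.integers(0, n, n)
            s, d = scores[idx], status[idx]
            tries += 1
            if tries > 1000:
                raise RuntimeError("bootstrap cannot produce two-class replicates")
        c = _candidates(s, candidates)
        i, _, _ = _sweep(s, d, c)
        boot[b] = c[i]

    finite = boot[np.isfinite(boot)]
    med = float(np.median(finite)) if len(finite) else math.nan
    ci = (
        (float(np.percentile(finite, 2.5)), float(np.percentile(finite, 97.5)))
        if len(finite)
        else (math.nan, math.nan)
    )
    return CutpointResult(
        optimal_threshold=float(cand[best]),
        youden=float(sens[best] + spec[best] - 1),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        table=table,
        bootstrap=boot,
        bootstrap_median=med,
        bootstrap_ci=ci,
        n_boot=n_boot,
        seed=seed,
    )
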