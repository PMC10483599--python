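"""Survival analysis for dichotomized liquid-biopsy biomarkers.

Kaplan-Meier estimation and log-rank testing (via lifelines), Cox
proportional-hazards regression (via statsmodels PHReg, Efron tie correction
by default, Breslow available), a univariate screen retaining covariates at
P < 0.1, backward selection at the same threshold, the combined
CTC x aneuploidy four-group model, and the Schoenfeld required-events power
formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

DURATION_COL = "os_months"
EVENT_COL = "event"

#: Covariates screened in the univariate Cox analysis (dichotomized markers
#: plus baseline clinical characteristics).
DEFAULT_CANDIDATES = [
    "age",
    "gleason",
    "psa",
    "who_high",
    "alb",
    "anc",
    "hbg",
    "wbc",
    "alp",
    "ldh",
    "aneuploid",
    "ctc_high",
]


def add_dichotomized(df: pd.DataFrame) -> pd.DataFrame:
    """Recompute dichotomized covariates from raw values (never trusted from input).

    ``ctc_high`` = CTC count >= 5 per 7.5 mL; ``who_high`` = WHO performance
    status 1-2 vs 0.
    """
    df = df.copy()
    if "ctc_count" in df:
        df["ctc_high"] = (df["ctc_count"] >= 5).astype(int)
    if "who_status" in df:
        df["who_high"] = (df["who_status"] >= 1).astype(int)
    return df


@dataclass
class CoxTerm:
    name: str
    coef: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary (Wald inference, partial-likelihood AIC)."""

    terms: list[CoxTerm]
    aic: float
    log_likelihood: float
    n: int
    n_events: int
    ties_method: str

    def term(self, name: str) -> CoxTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [t.name for t in self.terms],
                "coef": [t.coef for t in self.terms],
                "se": [t.se for t in self.terms],
                "HR": [t.hr for t in self.terms],
                "ci95_low": [t.ci_low for t in self.terms],
                "ci95_high": [t.ci_high for t in self.terms],
                "p": [t.p for t in self.terms],
            }
        )


def _null_loglik(times: np.ndarray, events: np.ndarray, ties: str) -> float:
    # Partial log-likelihood of the model with all coefficients zero.
    model = PHReg(times, np.zeros((len(times), 1)), status=events, ties=ties)
    return float(model.loglike(np.zeros(1)))


def cox_fit(
    records: pd.DataFrame,
    covariate_names: Sequence[str],
    ties: str = "efron",
    duration_col: str = DURATION_COL,
    event_col: str = EVENT_COL,
) -> CoxFit:
    """Maximize the Cox partial likelihood; Wald HRs, 95% CIs and p per term.

    AIC = 2 * n_terms - 2 * log partial likelihood at the optimum. Missing
    values in the selected columns are an error (complete-case subsetting is
    the caller's responsibility; see :func:`univariate_screen`).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    cols = [duration_col, event_col, *covariate_names]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"missing column(s): {missing}")
    sub = records[cols]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in column(s) {bad}; drop incomplete cases first")

    times = sub[duration_col].to_numpy(dtype=float)
    events = sub[event_col].to_numpy(dtype=float)
    if events.sum() < 1:
        raise ValueError("no events in data; Cox model undefined")

    if not covariate_names:
        ll0 = _null_loglik(times, events, ties)
        return CoxFit([], aic=-2 * ll0, log_likelihood=ll0, n=len(sub),
                      n_events=int(events.sum()), ties_method=ties)

    X = sub[list(covariate_names)].to_numpy(dtype=float)
    const = [c for c, v in zip(covariate_names, X.std(axis=0)) if v == 0]
    if const:
        raise ValueError(f"covariate(s) constant across patients: {const}")

    model = PHReg(times, X, status=events, ties=ties)
    res = model.fit(disp=False)
    if not (np.isfinite(res.params).all() and np.isfinite(res.bse).all()):
        raise RuntimeError("Cox fit did not converge to finite estimates")

    terms = []
    for name, b, se in zip(covariate_names, res.params, res.bse):
        z = b / se
        terms.append(
            CoxTerm(
                name=name,
                coef=float(b),
                se=float(se),
                hr=float(math.exp(b)),
                ci_low=float(math.exp(b - 1.96 * se)),
                ci_high=float(math.exp(b + 1.96 * se)),
                p=float(2 * stats.norm.sf(abs(z))),
            )
        )
    ll = float(model.loglike(res.params))
    return CoxFit(
        terms=terms,
        aic=2 * len(terms) - 2 * ll,
        log_likelihood=ll,
        n=len(sub),
        n_events=int(events.sum()),
        ties_method=ties,
    )


@dataclass
class KMCurve:
    """Product-limit survival curve."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float  # nan if S(t) never reaches 0.5
    n: int
    n_events: int


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimate; censoring reduces the risk set only."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=int)
    med = float(kmf.median_survival_time_)
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=at_risk,
        median=(math.nan if math.isinf(med) else med),
        n=int(times.size),
        n_events=int(events.sum()),
    )


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float


def logrank_test(
    times: Sequence[float], events: Sequence[int], group: Sequence
) -> LogRankResult:
    """k-group log-rank test, chi-square with k-1 degrees of freedom."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    group = np.asarray(group)
    labels, counts = np.unique(group, return_counts=True)
    if len(labels) < 2:
        raise ValueError("log-rank test needs >= 2 non-empty groups")
    res = multivariate_logrank_test(times, group, events)
    return LogRankResult(
        chi2=float(res.test_statistic), df=len(labels) - 1, p=float(res.p_value)
    )


def univariate_screen(
    records: pd.DataFrame,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    p_keep: float = 0.1,
    ties: str = "efron",
) -> list[str]:
    """One Cox model per candidate; retain covariates with Wald P below ``p_keep``.

    Each candidate is fit on its complete cases (rows missing that covariate
    or the outcome are dropped for that model only).
    """
    retained = []
    for name in candidates:
        fit = univariate_fit(records, name, ties=ties)
        if fit.term(name).p < p_keep:
            retained.append(name)
    return retained


def univariate_fit(
    records: pd.DataFrame, covariate: str, ties: str = "efron"
) -> CoxFit:
    """Single-covariate Cox fit on the covariate's complete cases."""
    sub = records.dropna(subset=[DURATION_COL, EVENT_COL, covariate])
    return cox_fit(sub, [covariate], ties=ties)


def univariate_table(
    records: pd.DataFrame,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    ties: str = "efron",
) -> pd.DataFrame:
    """Per-candidate univariate HR/CI/p table (one row per covariate)."""
    rows = []
    for name in candidates:
        fit = univariate_fit(records, name, ties=ties)
        t = fit.term(name)
        rows.append(
            {
                "term": name,
                "n": fit.n,
                "n_events": fit.n_events,
                "HR": t.hr,
                "ci95_low": t.ci_low,
                "ci95_high": t.ci_high,
                "p": t.p,
                "aic": fit.aic,
            }
        )
    return pd.DataFrame(rows)


def backward_selection(
    records: pd.DataFrame,
    covariates: Sequence[str],
    p_drop: float = 0.1,
    ties: str = "efron",
) -> CoxFit:
    """Drop the worst term (largest Wald p >= ``p_drop``) until all remain significant.

    Deterministic given the data. If every term is removed, returns the
    explicit empty (null) model rather than raising.
    """
    current = list(covariates)
    sub = records.dropna(subset=[DURATION_COL, EVENT_COL, *current])
    while True:
        fit = cox_fit(sub, current, ties=ties)
        if not current:
            return fit
        worst = max(fit.terms, key=lambda t: t.p)
        if worst.p < p_drop:
            return fit
        current.remove(worst.name)


@dataclass
class CombinedStrataResult:
    """Four-group CTC x aneuploidy model: Cox fit, KM curves and overall log-rank."""

    cox: CoxFit
    km: dict[str, KMCurve]
    logrank: LogRankResult
    group_labels: pd.Series

    GROUPS = (
        "ctc_low_euploid",  # reference
        "ctc_low_aneuploid",
        "ctc_high_euploid",
        "ctc_high_aneuploid",
    )


def combined_strata_fit(
    records: pd.DataFrame, ties: str = "efron"
) -> CombinedStrataResult:
    """Cox model over the 2x2 CTC/aneuploidy factor (reference: both low).

    Requires the boolean/0-1 columns ``aneuploid`` and ``ctc_high``. Fits
    three indicator terms against the double-negative reference group and
    emits the four Kaplan-Meier curves plus the overall log-rank test.
    """
    req = {"aneuploid", "ctc_high", DURATION_COL, EVENT_COL}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    df = records.dropna(subset=list(req)).copy()
    aneu = df["aneuploid"].astype(bool)
    ctc = df["ctc_high"].astype(bool)
    labels = pd.Series(
        np.select(
            [~ctc & ~aneu, ~ctc & aneu, ctc & ~aneu],
            CombinedStrataResult.GROUPS[:3],
            default=CombinedStrataResult.GROUPS[3],
        ),
        index=df.index,
        name="combined_group",
    )
    if (labels == CombinedStrataResult.GROUPS[0]).sum() == 0:
        raise ValueError("empty reference group (CTC < 5 and euploid)")
    if labels.nunique() < 2:
        raise ValueError("all patients fall in a single combined group")

    for g in CombinedStrataResult.GROUPS[1:]:
        df[g] = (labels == g).astype(int)
    present = [g for g in CombinedStrataResult.GROUPS[1:] if df[g].sum() > 0]
    fit = cox_fit(df, present, ties=ties)

    km = {
        g: km_estimate(grp[DURATION_COL], grp[EVENT_COL])
        for g, grp in df.groupby(labels)
    }
    lr = logrank_test(df[DURATION_COL], df[EVENT_COL], labels)
    return CombinedStrataResult(cox=fit, km=km, logrank=lr, group_labels=labels)


def required_events(
    hr: float,
    alpha: float = 0.05,
    power: float = 0.8,
    p_group: float = 0.5,
) -> int:
    """Schoenfeld required number of events for a two-group log-rank/Cox test.

    D = ceil( (z_{1-alpha/2} + z_power)^2 / (p(1-p) * ln(hr)^2) ), with
    ``p_group`` the fraction of patients in the index group.
    """
    if hr <= 0 or hr == 1:
        raise ValueError("hazard ratio must be positive and != 1")
    if not 0 < p_group < 1:
        raise ValueError("p_group must be in (0, 1)")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    return int(math.ceil((z_a + z_b) ** 2 / (p_group * (1 - p_group) * math.log(hr) ** 2)))


def plot_km(
    records: pd.DataFrame,
    group_col: str,
    path: str | Path | None = None,
    title: str | None = None,
):
    """Minimal Kaplan-Meier plot per group (visual aid only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, grp in records.groupby(group_col):
        kmf = KaplanMeierFitter(label=str(label))
        kmf.fit(grp[DURATION_COL], grp[EVENT_COL])
        kmf.plot_survival_function(ax=ax, ci_show=False)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
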