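"""Association of aneuploidy scores with orthogonal ctDNA-burden markers.

Two-sided Spearman rank correlation (average ranks for ties, t-approximation
for the p-value) between the genome-wide score and either the maximum variant
allele frequency from a targeted panel or the baseline CTC count, plus a
descriptive ordinary-least-squares line on the raw values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class AssociationResult:
    rho: float  # Spearman rank correlation; nan if undefined
    p_two_sided: float
    n: int  # pairwise-complete sample size
    slope: float
    intercept: float
    n_dropped: int  # incomplete pairs removed


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep], int((~keep).sum())


def linear_fit(x, y) -> tuple[float, float]:
    """Ordinary least squares y = slope * x + intercept."""
    x, y, _ = _pairwise_complete(x, y)
    if len(x) < 2:
        raise ValueError("need >= 2 complete pairs for a linear fit")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def spearman(x, y) -> AssociationResult:
    """Spearman rho with two-sided p, plus the descriptive OLS line.

    Incomplete pairs are dropped (count reported). Zero variance in either
    variable leaves rho undefined (nan, with a warning).
    """
    xc, yc, dropped = _pairwise_complete(x, y)
    if len(xc) < 3:
        raise ValueError("need >= 3 complete pairs for a rank correlation")
    if np.ptp(xc) == 0 or np.ptp(yc) == 0:
        warnings.warn("zero variance in one variable; Spearman rho undefined")
        rho, p = math.nan, math.nan
    else:
        rho, p = stats.spearmanr(xc, yc)
    try:
        slope, intercept = linear_fit(xc, yc)
    except ValueError:
        slope, intercept = math.nan, math.nan
    return AssociationResult(
        rho=float(rho),
        p_two_sided=float(p),
        n=len(xc),
        slope=slope,
        intercept=intercept,
        n_dropped=dropped,
    )
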