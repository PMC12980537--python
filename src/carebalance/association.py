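"""Correlation and simple linear fit between demand and resource concentration."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AssociationResult", "pearson_correlation"]


@dataclass
class AssociationResult:
    """Pearson r, its two-tailed p, and the least-squares line."""

    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    n: int
    p_two_tailed: float

    def to_dict(self) -> dict:
        return {
            "r": self.pearson_r,
            "r2": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "n": self.n,
            "p": self.p_two_tailed,
        }


def pearson_correlation(x, y, log_scale: bool = False) -> AssociationResult:
    """Product-moment correlation with two-tailed t test and LS line.

    ``log_scale`` applies log10 to both vectors first (exploratory option for
    heavily skewed concentration indices; off by default).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if log_scale:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log scale requires strictly positive values")
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return AssociationResult(
        pearson_r=float(r),
        r_squared=float(r) ** 2,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(x.size),
        p_two_tailed=float(p),
    )
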