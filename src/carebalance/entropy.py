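"""Entropy-weight composite scoring.

Objective indicator weighting: each indicator column is min-max normalized
(with a small positivity offset so the Shannon entropy is defined at zero),
its information entropy e_j is computed across districts, and the weight is
proportional to the information content d_j = 1 - e_j. Composite scores are
the weighted sums of the normalized cells, so they lie in
[offset, 1 + offset].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "IndicatorMatrix",
    "minmax_normalize",
    "entropy_weights",
    "composite_scores",
    "entropy_composite",
    "DEFAULT_OFFSET",
]

DEFAULT_OFFSET = 1e-4

BENEFIT = "benefit"
COST = "cost"


@dataclass
class IndicatorMatrix:
    """Districts x indicators value matrix with per-indicator orientation.

    ``orientation`` flags each column ``benefit`` (higher is better/more) or
    ``cost`` (lower is better); unlisted columns default to ``benefit``.
    """

    values: pd.DataFrame
    orientation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.values
        if df.isna().any().any():
            raise ValueError("indicator matrix must have no missing cells")
        if df.shape[0] < 2:
            raise ValueError("need at least 2 districts (rows)")
        if df.shape[1] < 1:
            raise ValueError("need at least 1 indicator (column)")
        bad = set(self.orientation) - set(df.columns)
        if bad:
            raise ValueError(f"orientation for unknown columns: {sorted(bad)}")
        for col, o in self.orientation.items():
            if o not in (BENEFIT, COST):
                raise ValueError(f"orientation for {col!r} must be benefit|cost")

    def orientation_of(self, col: str) -> str:
        return self.orientation.get(col, BENEFIT)


def minmax_normalize(X: IndicatorMatrix, offset: float = DEFAULT_OFFSET) -> IndicatorMatrix:
    """Min-max normalize each column into [offset, 1 + offset].

    Benefit columns map x -> (x - min)/(max - min); cost columns are reversed.
    A constant column carries no information and maps to ``offset`` everywhere.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    df = X.values.astype(float)
    out = {}
    for col in df.columns:
        x = df[col].to_numpy()
        lo, hi = x.min(), x.max()
        if hi == lo:
            z = np.zeros_like(x)
        elif X.orientation_of(col) == COST:
            z = (hi - x) / (hi - lo)
        else:
            z = (x - lo) / (hi - lo)
        out[col] = z + offset
    return IndicatorMatrix(
        values=pd.DataFrame(out, index=df.index), orientation={}
    )


def entropy_weights(Xn: IndicatorMatrix) -> pd.Series:
    """Entropy weights of the (already normalized, strictly positive) matrix.

    For column j with shares p_ij = x_ij / sum_i x_ij:
    e_j = -(1/ln n) sum_i p_ij ln p_ij, d_j = 1 - e_j, w_j = d_j / sum_j d_j.
    All-constant input (every d_j = 0) yields uniform weights.
    """
    df = Xn.values.astype(float)
    n = df.shape[0]
    if n < 2:
        raise ValueError("entropy weights undefined for a single district")
    if (df.to_numpy() <= 0).any():
        raise ValueError(
            "normalized matrix must be strictly positive; use a positivity offset"
        )
    P = df / df.sum(axis=0)
    e = -(P * np.log(P)).sum(axis=0) / np.log(n)
    d = 1.0 - e
    d = d.clip(lower=0.0)  # guard tiny negative rounding at e_j ~= 1
    total = d.sum()
    if total <= 0:
        w = pd.Series(1.0 / df.shape[1], index=df.columns)
    else:
        w = d / total
    w.name = "weight"
    return w


def composite_scores(Xn: IndicatorMatrix, w: Mapping[str, float] | pd.Series) -> pd.Series:
    """Weighted-sum composite score per district from normalized cells."""
    df = Xn.values.astype(float)
    w = pd.Series(w, dtype=float)
    missing = set(df.columns) ^ set(w.index)
    if missing:
        raise ValueError(f"indicator codes do not match weights: {sorted(missing)}")
    scores = df.mul(w, axis=1).sum(axis=1)
    scores.name = "score"
    return scores


def entropy_composite(
    values: pd.DataFrame,
    orientation: Mapping[str, str] | None = None,
    offset: float = DEFAULT_OFFSET,
) -> tuple[pd.Series, pd.Series]:
    """Convenience pipeline: normalize -> weights -> scores.

    Returns ``(weights, scores)`` indexed by indicator code and district.
    """
    X = IndicatorMatrix(values=values, orientation=dict(orientation or {}))
    Xn = minmax_normalize(X, offset=offset)
    w = entropy_weights(Xn)
    return w, composite_scores(Xn, w)
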