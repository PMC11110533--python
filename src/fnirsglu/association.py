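"""Feature–glucose association: z-scoring and matrix-form Pearson r.

The correlation is computed in the centered-covariance matrix form

    S_xy = X_cᵀ G_c/(n−1),  S_xx = diag(X_cᵀ X_c)/(n−1),  S_yy = G_cᵀ G_c/(n−1)
    R    = S_xy / sqrt(S_xx·S_yy)

with a two-sided p-value from the exact t transform
t = r·sqrt(n−2)/sqrt(1−r²) on n−2 degrees of freedom.
"""
from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .features import FEATURE_NAMES


class NormalizedSeries(NamedTuple):
    y: np.ndarray
    mean: float
    std: float


def zscore(x, population: bool = True, name: str | None = None) -> NormalizedSeries:
    """y = (x − x̄)/σ with the population σ by default (sample σ via flag).

    The output has mean 0 and unit σ under the chosen convention; a
    constant input raises an error naming the offending series.
    """
    x = np.asarray(x, dtype=float)
    mean = float(x.mean())
    std = float(x.std(ddof=0 if population else 1))
    if std == 0:
        label = f" '{name}'" if name else ""
        raise DataError(f"cannot z-score constant series{label} (zero std)")
    return NormalizedSeries((x - mean) / std, mean, std)


def pearson_features_vs_glucose(X: np.ndarray, G: np.ndarray,
                                feature_names: Sequence[str] | None = None
                                ) -> pd.DataFrame:
    """Per-feature Pearson r (matrix form) and two-sided p against glucose.

    Constant feature columns are flagged (r and p set to NaN) rather than
    raising, so one degenerate feature does not abort the table.
    """
    X = np.asarray(X, dtype=float)
    G = np.asarray(G, dtype=float).ravel()
    if X.ndim != 2:
        raise DataError("X must be 2-D (samples × features)")
    n, m = X.shape
    if G.size != n:
        raise DataError("glucose vector length must match the sample count")
    if n < 3:
        raise DataError("need at least 3 samples for a correlation test")
    names = list(feature_names) if feature_names is not None else (
        list(FEATURE_NAMES[:m]) if m <= 10 else [f"f{i+1}" for i in range(m)])
    if np.ptp(G) == 0:
        raise DataError("glucose vector is constant")

    Xc = X - X.mean(axis=0)
    Gc = G - G.mean()
    sxy = Xc.T @ Gc / (n - 1)
    sxx = np.einsum("ij,ij->j", Xc, Xc) / (n - 1)
    syy = Gc @ Gc / (n - 1)
    constant = sxx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    r = np.where(constant, np.nan, np.clip(r, -1.0, 1.0))

    p = np.full(m, np.nan)
    ok = ~constant
    near_one = ok & (np.abs(r) >= 1.0)
    p[near_one] = 0.0
    mid = ok & ~near_one
    t = r[mid] * np.sqrt(n - 2) / np.sqrt(1.0 - r[mid] ** 2)
    p[mid] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return pd.DataFrame({"feature": names, "r": r, "p": p,
                         "constant": constant})
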