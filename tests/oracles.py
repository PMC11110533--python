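"""Independent brute-force oracles used to validate the package formulas.

Everything here is written as plain loops / direct textbook formulas,
deliberately sharing no code with the implementation under test.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import stats


def features_oracle(x, dt):
    """λ1..λ10 evaluated with explicit loops."""
    x = [float(v) for v in x]
    T = len(x)
    lam1 = sum(x) / T
    lam2 = math.sqrt(sum((v - lam1) ** 2 for v in x) / T)
    d1 = [x[i] - x[i - 1] for i in range(1, T)]
    lam3 = sum(d1) / (T - 1)
    m1 = sum(d1) / len(d1)
    lam4 = math.sqrt(sum((v - m1) ** 2 for v in d1) / len(d1))
    d2 = [x[i] - 2 * x[i - 1] + x[i - 2] for i in range(2, T)]
    lam5 = sum(d2) / (T - 2)
    m2 = sum(d2) / len(d2)
    lam6 = math.sqrt(sum((v - m2) ** 2 for v in d2) / len(d2))
    lam7 = max(x)
    lam8 = max(x) - min(x)
    lam9 = sum(v * v for v in x) * dt
    lam10 = -sum(v * v * math.log(v * v) for v in x if v != 0) * dt
    return [lam1, lam2, lam3, lam4, lam5, lam6, lam7, lam8, lam9, lam10]


def welch_oracle(a, b):
    """Welch two-sample t with Satterthwaite df; two-sided p."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p_two = 2 * stats.t.sf(abs(t), df)
    return t, p_two, va, vb


def zscore_oracle(x):
    x = [float(v) for v in x]
    m = sum(x) / len(x)
    s = math.sqrt(sum((v - m) ** 2 for v in x) / len(x))
    return [(v - m) / s for v in x]


def pearson_oracle(x, y):
    """Direct pairwise Pearson r and two-sided p (scipy reference)."""
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def cbsi_oracle(hbo, hbr):
    hbo = np.asarray(hbo, float)
    hbr = np.asarray(hbr, float)
    alpha = hbo.std() / hbr.std()
    hbo2 = (hbo - alpha * hbr) / 2.0
    return hbo2, -hbo2 / alpha


def od_oracle(intensity):
    """Per-sample −log10(I/mean) on a 1-D series."""
    I = [float(v) for v in intensity]
    m = sum(I) / len(I)
    return [-math.log10(v / m) for v in I]


def metrics_oracle(pred, true):
    pred = [float(v) for v in pred]
    true = [float(v) for v in true]
    n = len(pred)
    rmse = math.sqrt(sum((p - t) ** 2 for p, t in zip(pred, true)) / n)
    mard = 100.0 * sum(abs(p - t) / t for p, t in zip(pred, true)) / n
    return rmse, mard


def xi_ranking_oracle(vectors, between, within, ridge):
    """Brute-force ξ ranking: per-eigenvector quadratic forms and a python
    sort by (−ξ, −eigenvalue-position, index).  Returns the permutation."""
    b = vectors.shape[1]
    xi = []
    for k in range(b):
        c = vectors[:, k]
        num = float(c @ between @ c)
        den = float(c @ within @ c) + ridge
        xi.append(num / den)
    return xi


def scatter_oracle(X, labels):
    """Total / within / between scatter via explicit loops."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    grand = X.mean(axis=0)
    b = X.shape[1]
    total = np.zeros((b, b))
    for row in X:
        d = (row - grand)[:, None]
        total += d @ d.T
    within = np.zeros((b, b))
    between = np.zeros((b, b))
    for cls in np.unique(labels):
        Xi = X[labels == cls]
        mi = Xi.mean(axis=0)
        for row in Xi:
            d = (row - mi)[:, None]
            within += d @ d.T
        d = (mi - grand)[:, None]
        between += Xi.shape[0] * (d @ d.T)
    return total, within, between


def make_two_class(rng, n_per):
    """Two-class Gaussian fixture whose discriminative directions carry the
    smallest variance: dims 1–2 are high-variance nuisance, dims 3–10 carry
    graded mean separation on low-variance axes.  Adversarial for
    variance-ranked component selection."""
    sd = np.array([3.0, 2.4, 0.9, 0.8, 0.72, 0.64, 0.57, 0.5, 0.44, 0.38])
    eff = np.array([0.0, 0.0, 0.9, 0.85, 0.8, 0.75, 0.7, 0.65, 0.6, 0.55])
    diff = eff * sd
    X0 = rng.normal(0.0, 1.0, (n_per, 10)) * sd
    X1 = rng.normal(0.0, 1.0, (n_per, 10)) * sd + diff
    X = np.vstack([X0, X1])
    y = np.array([0] * n_per + [1] * n_per)
    return X, y
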