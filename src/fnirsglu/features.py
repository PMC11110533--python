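"""The ten λ features of windowed mean-HbO signals.

For a window x_1..x_T (μM, sampled every dt seconds):

    λ1  mean                      λ6  population std of 2nd differences
    λ2  population std            λ7  peak ψmax
    λ3  mean of 1st differences   λ8  peak-to-peak ψmax − ψmin
    λ4  population std of 1st differences
    λ5  mean of 2nd differences   λ9  energy        Σ x_i²·dt
                                  λ10 energy entropy −Σ x_i²·ln(x_i²)·dt

Population (divide-by-count) denominators are used throughout, and the
energy integrals are discretised as rectangle sums with step dt.  λ10
follows the printed un-normalised form with the 0·ln 0 → 0 convention; a
normalised Shannon-entropy variant is available behind a flag.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import DataError
from .preprocessing import HemoTimeSeries

FEATURE_NAMES = tuple(f"lambda{i}" for i in range(1, 11))


@dataclass
class SignalWindow:
    """One channel-averaged HbO window paired with a reference glucose."""

    x: np.ndarray                  # (T,) μM
    dt: float                      # s per sample
    subject_id: str = ""
    state: str = ""
    window_index: int = 0
    glucose: float = float("nan")  # mmol/L
    t_center: float = float("nan")

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.dt <= 0:
            raise DataError("dt must be positive")


class FeatureVector(NamedTuple):
    lambda1: float
    lambda2: float
    lambda3: float
    lambda4: float
    lambda5: float
    lambda6: float
    lambda7: float
    lambda8: float
    lambda9: float
    lambda10: float


def compute_features(window: SignalWindow,
                     normalized_entropy: bool = False) -> FeatureVector:
    """Evaluate λ1–λ10 on one window (requires T ≥ 4 so second differences
    have a spread)."""
    x = window.x
    T = x.size
    if T < 4:
        raise DataError(f"window too short for features: T={T} < 4")
    dt = window.dt

    lam1 = x.mean()
    lam2 = x.std()                         # population, /T
    d1 = np.diff(x)
    lam3 = d1.mean()
    lam4 = d1.std()
    d2 = np.diff(x, n=2)
    lam5 = d2.mean()
    lam6 = d2.std()
    lam7 = x.max()
    lam8 = x.max() - x.min()
    e = x ** 2
    lam9 = e.sum() * dt
    if normalized_entropy:
        tot = e.sum()
        if tot == 0:
            lam10 = 0.0
        else:
            p = e / tot
            lam10 = float(-np.sum(np.where(p > 0, p * np.log(p), 0.0)))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = e * np.log(e)
        term[e == 0] = 0.0                 # 0·ln 0 → 0 convention
        lam10 = float(-term.sum() * dt)
    return FeatureVector(float(lam1), float(lam2), float(lam3), float(lam4),
                         float(lam5), float(lam6), float(lam7), float(lam8),
                         float(lam9), lam10)


def segment_windows(hemo: HemoTimeSeries, selected_channels: Iterable[int],
                    window_s: float, glucose_refs: pd.DataFrame,
                    tolerance_s: float | None = None) -> list[SignalWindow]:
    """Average ΔHbO across the selected channels and cut each state's block
    into non-overlapping windows, attaching the nearest-in-time reference
    glucose (windows without a reference within the tolerance are dropped
    with a warning)."""
    channels = sorted(int(c) for c in selected_channels)
    if not channels:
        raise DataError("no channels selected for windowing")
    C = hemo.dhbo.shape[1]
    bad = [c for c in channels if not 1 <= c <= C]
    if bad:
        raise DataError(f"channels {bad} outside 1..{C}")
    w = int(round(window_s * hemo.sampling_rate))
    if w < 4:
        raise DataError("window shorter than 4 samples")
    if w > hemo.dhbo.shape[0]:
        raise DataError("window longer than the recording")
    tol = window_s / 2.0 if tolerance_s is None else tolerance_s
    sig = hemo.dhbo[:, [c - 1 for c in channels]].mean(axis=1)
    labels = np.asarray(hemo.state_labels)
    ref_t = glucose_refs["time_s"].to_numpy(dtype=float)
    ref_g = glucose_refs["glucose_mmol_per_l"].to_numpy(dtype=float)

    windows: list[SignalWindow] = []
    n_dropped = 0
    for state in pd.unique(labels):
        idx = np.flatnonzero(labels == state)
        for k in range(idx.size // w):
            sl = idx[k * w: (k + 1) * w]
            center = float(hemo.times[sl].mean())
            j = int(np.argmin(np.abs(ref_t - center)))
            if abs(ref_t[j] - center) > tol:
                n_dropped += 1
                continue
            windows.append(SignalWindow(
                x=sig[sl], dt=1.0 / hemo.sampling_rate,
                subject_id=hemo.subject_id, state=str(state), window_index=k,
                glucose=float(ref_g[j]), t_center=center))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} window(s) without a glucose "
                      f"reference within ±{tol:g} s")
    return windows


def feature_table(windows: Iterable[SignalWindow],
                  normalized_entropy: bool = False) -> pd.DataFrame:
    """Feature matrix: one row per window with λ1..λ10, the reference
    glucose and window metadata."""
    rows = []
    for win in windows:
        fv = compute_features(win, normalized_entropy)
        row = {"subject_id": win.subject_id, "state": win.state,
               "window_index": win.window_index}
        row.update({name: val for name, val in zip(FEATURE_NAMES, fv)})
        row["glucose_mmol_per_l"] = win.glucose
        rows.append(row)
    if not rows:
        raise DataError("no windows to featurise")
    return pd.DataFrame(rows)
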