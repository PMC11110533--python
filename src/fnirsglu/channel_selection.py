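"""Fasting-vs-glucose channel screening via two-sample t-tests.

The unit of replication is the per-subject, per-window mean ΔHbO of each
channel (one value per subject per window per state); channels whose mean
HbO change differs between states at p < α are retained for feature
extraction.
"""
from __future__ import annotations

import warnings
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .preprocessing import HemoTimeSeries

#: p = sf(|t|): the one-sided tail of the absolute statistic.  This is the
#: convention consistent with published channel tables in this setting,
#: where significant channels appear with either sign of t.
ONE_SIDED_ABS = "one-sided-abs"
TWO_SIDED = "two-sided"


class TTestResult(NamedTuple):
    t: float
    p: float
    fasting_variance: float
    glucose_variance: float


def state_ttest(fasting_samples, glucose_samples,
                tails: str = ONE_SIDED_ABS) -> TTestResult:
    """Welch two-sample t-test between state groups.

    Returns the t statistic, the p-value under the configured tail
    convention, and the (sample) variance of each group.  A fully
    degenerate input (both groups constant) yields t = 0 with the maximal
    p for the convention.
    """
    f = np.asarray(fasting_samples, dtype=float)
    g = np.asarray(glucose_samples, dtype=float)
    if f.size < 2 or g.size < 2:
        raise DataError("each group needs at least 2 samples")
    if tails not in (ONE_SIDED_ABS, TWO_SIDED):
        raise DataError(f"unknown tail convention '{tails}'")
    var_f = float(f.var(ddof=1))
    var_g = float(g.var(ddof=1))
    if var_f == 0 and var_g == 0:
        p_max = 0.5 if tails == ONE_SIDED_ABS else 1.0
        return TTestResult(0.0, p_max, var_f, var_g)
    t, p_two = stats.ttest_ind(f, g, equal_var=False)
    p = p_two / 2.0 if tails == ONE_SIDED_ABS else p_two
    return TTestResult(float(t), float(p), var_f, var_g)


def window_state_means(hemo: HemoTimeSeries, window_s: float) -> pd.DataFrame:
    """Cut each state's contiguous block into non-overlapping windows and
    return the per-window mean ΔHbO of every channel."""
    if window_s <= 0:
        raise DataError("window_s must be positive")
    labels = np.asarray(hemo.state_labels)
    w = int(round(window_s * hemo.sampling_rate))
    rows = []
    for state in pd.unique(labels):
        idx = np.flatnonzero(labels == state)
        n_win = idx.size // w
        for k in range(n_win):
            seg = hemo.dhbo[idx[k * w: (k + 1) * w]]
            means = seg.mean(axis=0)
            for c in range(means.size):
                rows.append({"subject_id": hemo.subject_id, "state": state,
                             "window_index": k, "channel": c + 1,
                             "mean_dhbo_um": means[c]})
    return pd.DataFrame(rows)


def collect_state_samples(hemos: Iterable[HemoTimeSeries],
                          window_s: float = 600.0) -> pd.DataFrame:
    """Pool window means across subjects into one long table."""
    frames = [window_state_means(h, window_s) for h in hemos]
    if not frames:
        raise DataError("no hemodynamic series supplied")
    return pd.concat(frames, ignore_index=True)


def compute_channel_stats(samples: pd.DataFrame, tails: str = ONE_SIDED_ABS,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Per-channel Welch t-test of fasting vs glucose window means.

    Returns a table shaped like the published per-channel summary:
    channel, fasting_variance, glucose_variance, t, p, selected.
    """
    required = {"state", "channel", "mean_dhbo_um"}
    missing = required - set(samples.columns)
    if missing:
        raise DataError(f"samples table missing columns {sorted(missing)}")
    rows = []
    for channel, grp in samples.groupby("channel"):
        f = grp.loc[grp["state"] == "fasting", "mean_dhbo_um"].to_numpy()
        g = grp.loc[grp["state"] == "glucose", "mean_dhbo_um"].to_numpy()
        res = state_ttest(f, g, tails)
        rows.append({"channel": int(channel),
                     "fasting_variance": res.fasting_variance,
                     "glucose_variance": res.glucose_variance,
                     "t": res.t, "p": res.p})
    stats_df = pd.DataFrame(rows).sort_values("channel").reset_index(drop=True)
    stats_df["selected"] = stats_df["p"] < alpha
    return stats_df


def select_channels(stats_df: pd.DataFrame, alpha: float = 0.05,
                    method: str | None = None) -> list[int]:
    """Channels with p < alpha in ascending channel order.

    ``method='bh'`` applies a Benjamini–Hochberg step-up correction first
    (off by default; the raw-p rule is the reference behaviour).  An empty
    selection is allowed and reported with a warning.
    """
    if not {"channel", "p"} <= set(stats_df.columns):
        raise DataError("stats table must contain 'channel' and 'p' columns")
    p = stats_df["p"].to_numpy(dtype=float)
    if method == "bh":
        m = p.size
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        passed = ranked <= alpha
        keep = np.zeros(m, dtype=bool)
        if passed.any():
            keep[order[: np.max(np.flatnonzero(passed)) + 1]] = True
    elif method is None:
        keep = p < alpha
    else:
        raise DataError(f"unknown correction method '{method}'")
    selected = sorted(int(c) for c in stats_df.loc[keep, "channel"])
    if not selected:
        warnings.warn("no channels selected at the requested alpha")
    return selected
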