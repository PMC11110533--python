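"""Nested leave-one-subject-out (LOSO) evaluation of glucose predictors.

The outer loop holds each subject out once; within every training fold the
features are z-scored with training statistics, reduced with DR-PCA (or
plain PCA) fitted on the training fold only, and the estimator's
hyperparameter is chosen by an inner LOSO over the training subjects.
Metrics are pooled over the out-of-fold predictions: RMSE (mmol/L),
MARD (%), Pearson r for regression, and fasting-vs-glucose classification
accuracy (%) for the state task.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (GradientBoostingClassifier,
                              GradientBoostingRegressor,
                              RandomForestClassifier, RandomForestRegressor)
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import SVC, SVR

from .drpca import DRPCA
from .errors import ConfigError, DataError
from .features import FEATURE_NAMES

REGRESSION = "regression"
CLASSIFICATION = "classification"

#: Inner-loop hyperparameter grids (fixed; see docs/methods.md).
MODEL_GRIDS: dict[str, list[dict]] = {
    "knn": [{"n_neighbors": k} for k in (1, 3, 5, 7, 9)],
    "rf": [{"n_estimators": n} for n in (100, 300)],
    "svm": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "gboost": [{"max_depth": d} for d in (2, 3)],
}

try:  # gradient-boosted trees: prefer xgboost, degrade to sklearn
    from xgboost import XGBClassifier, XGBRegressor  # type: ignore
    _HAVE_XGB = True
except Exception:  # pragma: no cover - depends on the environment
    _HAVE_XGB = False


def make_estimator(name: str, task: str, hp: dict, seed: int = 0):
    if task not in (REGRESSION, CLASSIFICATION):
        raise ConfigError(f"unknown task '{task}'")
    reg = task == REGRESSION
    if name == "knn":
        cls = KNeighborsRegressor if reg else KNeighborsClassifier
        return cls(**hp)
    if name == "rf":
        cls = RandomForestRegressor if reg else RandomForestClassifier
        return cls(random_state=seed, **hp)
    if name == "svm":
        return SVR(kernel="rbf", **hp) if reg else SVC(kernel="rbf", **hp)
    if name == "gboost":
        if _HAVE_XGB:
            cls = XGBRegressor if reg else XGBClassifier
            return cls(n_estimators=100, random_state=seed,
                       verbosity=0, **hp)
        cls = GradientBoostingRegressor if reg else GradientBoostingClassifier
        return cls(random_state=seed, **hp)
    raise ConfigError(f"unknown model '{name}'")


def loso_split(subject_ids) -> list[tuple[list, object]]:
    """One fold per subject: (train ids, held-out id)."""
    ids = list(subject_ids)
    if len(ids) != len(set(ids)):
        raise DataError("duplicate subject ids")
    if len(ids) < 2:
        raise DataError("LOSO needs at least 2 subjects")
    return [([s for s in ids if s != test], test) for test in ids]


@dataclass
class FoldResult:
    test_subject: object
    y_true: np.ndarray
    y_pred: np.ndarray
    chosen_hp: dict
    reducer_mean: np.ndarray = field(default=None, repr=False)
    reducer_vectors: np.ndarray = field(default=None, repr=False)


def _targets(df: pd.DataFrame, task: str) -> np.ndarray:
    if task == REGRESSION:
        return df["glucose_mmol_per_l"].to_numpy(dtype=float)
    # states encoded 0 = fasting, 1 = glucose (keeps every backend happy)
    return (df["state"].to_numpy() == "glucose").astype(int)


def _fit_transform_fold(train_df: pd.DataFrame, test_X: np.ndarray,
                        reducer: str, d: int):
    """Scale by training statistics, fit the reducer on the training fold
    only and project both partitions."""
    Xtr = train_df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    red = DRPCA(mode=reducer, n_components=d)
    red.fit((Xtr - mu) / sd, train_df["state"].to_numpy())
    return red, mu, sd, red.transform((Xtr - mu) / sd), red.transform((test_X - mu) / sd)


def _inner_score(train_df: pd.DataFrame, reducer: str, d: int, model: str,
                 hp: dict, task: str, seed: int) -> float:
    """Inner-LOSO loss of one hyperparameter candidate (lower is better)."""
    subjects = list(pd.unique(train_df["subject_id"]))
    if len(subjects) < 2:
        return 0.0
    losses = []
    for inner_train_ids, inner_test_id in loso_split(subjects):
        tr = train_df[train_df["subject_id"].isin(inner_train_ids)]
        te = train_df[train_df["subject_id"] == inner_test_id]
        te_X = te[list(FEATURE_NAMES)].to_numpy(dtype=float)
        _, _, _, Ztr, Zte = _fit_transform_fold(tr, te_X, reducer, d)
        est = make_estimator(model, task, hp, seed)
        est.fit(Ztr, _targets(tr, task))
        pred = est.predict(Zte)
        truth = _targets(te, task)
        if task == REGRESSION:
            losses.append(float(np.sqrt(np.mean((pred - truth) ** 2))))
        else:
            losses.append(float(np.mean(pred != truth)))
    return float(np.mean(losses))


def fit_predict_fold(train_df: pd.DataFrame, test_df: pd.DataFrame,
                     reducer: str = "drpca", model: str = "knn",
                     n_components: int = 6, task: str = REGRESSION,
                     seed: int = 0, inner_cv: bool = True,
                     grids: dict | None = None) -> FoldResult:
    """Fit reducer+model on the training fold and predict the held-out fold.

    Raises on subject leakage (a subject present in both partitions).  The
    hyperparameter is chosen by inner LOSO over the training subjects.
    """
    grids = grids or MODEL_GRIDS
    train_subjects = set(train_df["subject_id"])
    test_subjects = set(test_df["subject_id"])
    overlap = train_subjects & test_subjects
    if overlap:
        raise DataError(f"subject leakage: {sorted(overlap)} in both partitions")

    grid = grids[model]
    if inner_cv and len(grid) > 1:
        scores = [_inner_score(train_df, reducer, n_components, model, hp,
                               task, seed) for hp in grid]
        chosen = grid[int(np.argmin(scores))]
    else:
        chosen = grid[0]

    test_X = test_df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    red, mu, sd, Ztr, Zte = _fit_transform_fold(train_df, test_X, reducer,
                                                n_components)
    est = make_estimator(model, task, chosen, seed)
    y_train = _targets(train_df, task)
    est.fit(Ztr, y_train)
    pred = est.predict(Zte)
    return FoldResult(test_subject=sorted(test_subjects),
                      y_true=_targets(test_df, task), y_pred=np.asarray(pred),
                      chosen_hp=dict(chosen),
                      reducer_mean=red.ranking_.mean + 0.0,
                      reducer_vectors=red.ranking_.vectors + 0.0)


def compute_metrics(y_pred, y_true, task: str = REGRESSION) -> dict:
    """Pooled prediction metrics.

    Regression: RMSE (mmol/L), MARD (%), Pearson r (NaN when either side is
    constant).  Classification: accuracy (%).
    """
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if y_pred.shape != y_true.shape:
        raise DataError("prediction and reference lengths differ")
    if task == CLASSIFICATION:
        return {"accuracy_percent": float(np.mean(y_pred == y_true) * 100.0)}
    y_pred = y_pred.astype(float)
    y_true = y_true.astype(float)
    if np.any(y_true <= 0):
        raise DataError("MARD undefined: non-positive reference glucose")
    rmse = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    mard = float(np.mean(np.abs(y_pred - y_true) / y_true) * 100.0)
    if np.ptp(y_pred) == 0 or np.ptp(y_true) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(y_pred, y_true)[0])
    return {"rmse": rmse, "mard_percent": mard, "pearson_r": r}


def loso_evaluate(features_df: pd.DataFrame, reducer: str = "drpca",
                  model: str = "knn", n_components: int = 6,
                  task: str = REGRESSION, seed: int = 0,
                  inner_cv: bool = True) -> tuple[dict, list[FoldResult]]:
    """Outer LOSO over subjects; returns pooled metrics and fold results."""
    subjects = list(pd.unique(features_df["subject_id"]))
    folds = []
    for train_ids, test_id in loso_split(subjects):
        tr = features_df[features_df["subject_id"].isin(train_ids)]
        te = features_df[features_df["subject_id"] == test_id]
        folds.append(fit_predict_fold(tr, te, reducer, model, n_components,
                                      task, seed, inner_cv))
    y_true = np.concatenate([f.y_true for f in folds])
    y_pred = np.concatenate([f.y_pred for f in folds])
    return compute_metrics(y_pred, y_true, task), folds


def mean_baseline_metrics(features_df: pd.DataFrame) -> dict:
    """Predict-the-training-mean baseline under the same outer LOSO."""
    subjects = list(pd.unique(features_df["subject_id"]))
    y_true, y_pred = [], []
    for train_ids, test_id in loso_split(subjects):
        tr = features_df[features_df["subject_id"].isin(train_ids)]
        te = features_df[features_df["subject_id"] == test_id]
        mean_g = tr["glucose_mmol_per_l"].mean()
        y_true.append(te["glucose_mmol_per_l"].to_numpy(dtype=float))
        y_pred.append(np.full(len(te), mean_g))
    return compute_metrics(np.concatenate(y_pred), np.concatenate(y_true),
                           REGRESSION)


def run_evaluation(features_df: pd.DataFrame,
                   reducers=("pca", "drpca"), models=("knn",),
                   d_values=(1, 2, 3, 4, 5, 6),
                   tasks=(REGRESSION, CLASSIFICATION), seed: int = 0,
                   inner_cv: bool = True) -> tuple[pd.DataFrame, list]:
    """Full evaluation grid {reducer} × {model} × {d} × {task}.

    Returns a results table (one row per cell, the classification task
    contributing the accuracy column) plus per-fold prediction records;
    a model whose backend fails is skipped with a warning row.
    """
    b = len(FEATURE_NAMES)
    rows = []
    fold_records = []
    for reducer in reducers:
        for model in models:
            for d in d_values:
                if d > b:
                    raise ConfigError(f"d={d} exceeds feature dimension {b}")
                row = {"reducer": reducer, "model": model, "d": d}
                for task in tasks:
                    try:
                        metrics, folds = loso_evaluate(
                            features_df, reducer, model, d, task, seed,
                            inner_cv)
                    except ImportError as exc:  # missing optional backend
                        import warnings
                        warnings.warn(f"skipping {model}: {exc}")
                        continue
                    row.update(metrics)
                    for f in folds:
                        fold_records.append({
                            "reducer": reducer, "model": model, "d": d,
                            "task": task, "test_subject": f.test_subject[0],
                            "chosen_hp": f.chosen_hp,
                            "y_true": f.y_true.tolist(),
                            "y_pred": np.asarray(f.y_pred).tolist()})
                rows.append(row)
    baseline = mean_baseline_metrics(features_df)
    baseline_row = {"reducer": "none", "model": "mean_baseline", "d": 0}
    baseline_row.update(baseline)
    rows.append(baseline_row)
    return pd.DataFrame(rows), fold_records
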