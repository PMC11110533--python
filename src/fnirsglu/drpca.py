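"""Decreasing-rule PCA (DR-PCA) and plain PCA.

Plain PCA orders the eigenvectors of the training scatter matrix by
eigenvalue.  DR-PCA keeps the same eigenvectors but re-ranks them by the
Fisher-style ratio

    ξ(C_k) = (C_kᵀ Π_IS C_k) / (C_kᵀ Π_ICS C_k + ridge)

of between-class (Π_IS) to within-class (Π_ICS) scatter projected onto
each eigenvector, so directions that separate the classes are retained
first even when they carry little variance.  Both variants span the same
subspace at full dimension; they differ only in ordering and truncation.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError

_EIG_TOL = 1e-10


@dataclass
class PCABasis:
    vectors: np.ndarray        # (b, b), unit-norm columns, eigenvalue-desc
    eigenvalues: np.ndarray    # (b,), non-negative, descending
    mean: np.ndarray           # (b,) training mean x̄_tra
    degenerate: bool = False   # all-zero variance input


@dataclass
class ScatterSet:
    total: np.ndarray          # scatter about the grand mean
    within: np.ndarray         # Π_ICS
    between: np.ndarray        # Π_IS


@dataclass
class EigenRanking:
    vectors: np.ndarray        # (b, b) columns reordered by the rule
    eigenvalues: np.ndarray    # matching eigenvalues
    xi: np.ndarray             # ξ scores, non-increasing
    order: np.ndarray          # permutation of the eigenvalue-desc basis
    mean: np.ndarray


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude entry positive."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        j = int(np.argmax(np.abs(out[:, k])))
        if out[j, k] < 0:
            out[:, k] = -out[:, k]
    return out


def fit_pca(X: np.ndarray) -> PCABasis:
    """Eigendecomposition of the centered scatter matrix Σ(x−x̄)(x−x̄)ᵀ.

    Eigenvalues are clipped at zero and sorted descending; eigenvectors
    are unit-norm with a deterministic sign convention.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("need a 2-D training matrix with at least 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    S = Xc.T @ Xc
    eigvals, eigvecs = np.linalg.eigh(S)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _fix_signs(eigvecs[:, order])
    degenerate = bool(np.all(eigvals < _EIG_TOL))
    if degenerate:
        warnings.warn("zero-variance training data: all eigenvalues are 0")
    return PCABasis(vectors=eigvecs, eigenvalues=eigvals, mean=mean,
                    degenerate=degenerate)


def compute_scatter(X: np.ndarray, labels) -> ScatterSet:
    """Within-class (Π_ICS) and between-class (Π_IS) scatter matrices.

    Π_ICS = Σ_i Σ_j (x_ij − x̄_i)(x_ij − x̄_i)ᵀ and
    Π_IS  = Σ_i a_i (K_i − K̄)(K_i − K̄)ᵀ; their sum equals the total
    scatter about the grand mean.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise DataError("labels length must match the number of samples")
    b = X.shape[1]
    grand = X.mean(axis=0)
    total = (X - grand).T @ (X - grand)
    within = np.zeros((b, b))
    between = np.zeros((b, b))
    classes = np.unique(labels)
    if classes.size < 2:
        warnings.warn("single class: between-class scatter is zero")
    for cls in classes:
        Xi = X[labels == cls]
        mi = Xi.mean(axis=0)
        within += (Xi - mi).T @ (Xi - mi)
        d = (mi - grand)[:, None]
        between += Xi.shape[0] * (d @ d.T)
    return ScatterSet(total=total, within=within, between=between)


def rank_eigenvectors(basis: PCABasis, scatter: ScatterSet,
                      ridge: float | None = None) -> EigenRanking:
    """Apply the decreasing rule: sort the eigenvectors by non-increasing
    ξ(C_k), ties broken by descending eigenvalue then index.

    When Π_IS vanishes (a single class), all ξ are zero and the order
    falls back to the eigenvalue order, i.e. plain PCA.  Eigenvectors in
    the data's null space (eigenvalue ≈ 0, e.g. when there are fewer
    samples than features) carry no scatter in either matrix, so their ξ
    is a numerically meaningless 0/0; they are assigned ξ = 0 and thereby
    sort to the end in eigenvalue order.
    """
    V = basis.vectors
    b = V.shape[1]
    if ridge is None:
        ridge = 1e-12 * np.trace(scatter.within) / b
    if np.allclose(scatter.between, 0.0):
        xi = np.zeros(b)
        order = np.arange(b)
    else:
        num = np.einsum("ik,ij,jk->k", V, scatter.between, V)
        den = np.einsum("ik,ij,jk->k", V, scatter.within, V) + ridge
        xi = num / den
        null = basis.eigenvalues < 1e-9 * max(basis.eigenvalues.max(), 1e-300)
        xi[null] = 0.0
        # lexsort: last key is primary → (-xi, -eigenvalue, index)
        order = np.lexsort((np.arange(b), -basis.eigenvalues, -xi))
    return EigenRanking(vectors=V[:, order],
                        eigenvalues=basis.eigenvalues[order],
                        xi=xi[order], order=order, mean=basis.mean)


def select_components(ranking: EigenRanking, mode: str = "contribution",
                      threshold: float = 0.9, d: int | None = None) -> int:
    """Retained dimension d.

    mode="explicit": d as given.  mode="contribution": the smallest d whose
    cumulative normalised score reaches the threshold; scores are the ξ
    values, falling back to eigenvalues when all ξ are zero (plain PCA).
    """
    b = ranking.vectors.shape[1]
    if mode == "explicit":
        if d is None or not 1 <= d <= b:
            raise ConfigError(f"explicit d must lie in 1..{b}")
        return int(d)
    if mode != "contribution":
        raise ConfigError(f"unknown selection mode '{mode}'")
    if not 0 < threshold <= 1:
        raise ConfigError("threshold must lie in (0, 1]")
    scores = ranking.xi if np.any(ranking.xi > 0) else ranking.eigenvalues
    total = scores.sum()
    if total <= 0:
        return 1
    cum = np.cumsum(scores) / total
    if threshold >= 1.0:
        return int(np.count_nonzero(scores))
    return int(np.searchsorted(cum, threshold) + 1)


def project(ranking: EigenRanking, samples: np.ndarray, d: int) -> np.ndarray:
    """Center samples by the *training* mean and project onto the first d
    ranked eigenvectors (θ_k for training data, ω_k for test data)."""
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.shape[1] != ranking.vectors.shape[0]:
        raise DataError(f"sample dimension {X.shape[1]} != basis dimension "
                        f"{ranking.vectors.shape[0]}")
    if not 1 <= d <= ranking.vectors.shape[1]:
        raise ConfigError(f"d={d} outside 1..{ranking.vectors.shape[1]}")
    return (X - ranking.mean) @ ranking.vectors[:, :d]


class DRPCA:
    """Sklearn-style reducer with mode 'drpca' (decreasing rule) or 'pca'.

    fit(X, y) requires class labels in drpca mode (the fasting/glucose
    state in this pipeline); transform centers by the training mean.
    """

    def __init__(self, mode: str = "drpca", n_components: int | None = None,
                 threshold: float = 0.9, ridge: float | None = None):
        if mode not in ("drpca", "pca"):
            raise ConfigError(f"unknown mode '{mode}'")
        self.mode = mode
        self.n_components = n_components
        self.threshold = threshold
        self.ridge = ridge
        self.ranking_: EigenRanking | None = None
        self.d_: int | None = None

    def fit(self, X, y=None) -> "DRPCA":
        basis = fit_pca(X)
        if self.mode == "drpca":
            if y is None:
                raise DataError("drpca mode requires class labels")
            scatter = compute_scatter(np.asarray(X, dtype=float), y)
            self.ranking_ = rank_eigenvectors(basis, scatter, self.ridge)
        else:
            self.ranking_ = EigenRanking(vectors=basis.vectors,
                                         eigenvalues=basis.eigenvalues,
                                         xi=np.zeros_like(basis.eigenvalues),
                                         order=np.arange(basis.vectors.shape[1]),
                                         mean=basis.mean)
        if self.n_components is not None:
            self.d_ = select_components(self.ranking_, "explicit",
                                        d=self.n_components)
        else:
            self.d_ = select_components(self.ranking_, "contribution",
                                        threshold=self.threshold)
        return self

    def transform(self, X) -> np.ndarray:
        if self.ranking_ is None:
            raise DataError("reducer not fitted")
        return project(self.ranking_, X, self.d_)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def to_json(self) -> str:
        if self.ranking_ is None:
            raise DataError("reducer not fitted")
        return json.dumps({
            "mode": self.mode, "d": self.d_,
            "mean": self.ranking_.mean.tolist(),
            "vectors": self.ranking_.vectors.tolist(),
            "eigenvalues": self.ranking_.eigenvalues.tolist(),
            "xi": self.ranking_.xi.tolist(),
            "order": self.ranking_.order.tolist(),
        })

    @classmethod
    def from_json(cls, payload: str) -> "DRPCA":
        d = json.loads(payload)
        obj = cls(mode=d["mode"], n_components=d["d"])
        obj.ranking_ = EigenRanking(
            vectors=np.asarray(d["vectors"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            xi=np.asarray(d["xi"], dtype=float),
            order=np.asarray(d["order"], dtype=int),
            mean=np.asarray(d["mean"], dtype=float))
        obj.d_ = int(d["d"])
        return obj
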