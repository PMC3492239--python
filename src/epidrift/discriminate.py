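"""Multivariate discrimination of cell groups from per-nucleus features.

The merged per-cell feature table is standardized, projected by PCA for
visualization, separated by regularized linear discriminant analysis, and
tested globally with a one-way MANOVA (Wilks' lambda, Rao's F
approximation).  These are the descriptive tools of high-content screening:
no cross-validation is attempted, the question is whether the cell
populations occupy distinguishable regions of feature space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "FeatureMatrix",
    "feature_matrix_from_table",
    "standardize",
    "pca",
    "lda",
    "manova",
    "PCAResult",
    "LDAResult",
    "ManovaResult",
]


@dataclass
class FeatureMatrix:
    """Cells x features matrix with per-row group labels.

    ``scaling`` records the per-column center/scale applied by
    :func:`standardize` (empty until then).
    """

    X: pd.DataFrame
    labels: pd.Series
    scaling: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["center", "scale"])
    )

    def __post_init__(self):
        if len(self.X) != len(self.labels):
            raise ValueError("labels length must match row count")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def groups(self):
        return sorted(pd.unique(self.labels))

    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)


def feature_matrix_from_table(
    table: pd.DataFrame, feature_columns=None, label_column: str = "group_id"
) -> FeatureMatrix:
    """Build a FeatureMatrix from an `imaging` per-cell table."""
    from .imaging import FEATURE_COLUMNS

    cols = list(feature_columns) if feature_columns is not None else list(FEATURE_COLUMNS)
    return FeatureMatrix(
        X=table[cols].reset_index(drop=True).astype(float),
        labels=table[label_column].reset_index(drop=True),
    )


def standardize(m: FeatureMatrix) -> FeatureMatrix:
    """Center each column to mean 0 and scale to unit variance.

    Zero-variance columns carry no discriminative information and would
    produce NaNs; they are dropped with a warning.  Idempotent.
    """
    X = m.values()
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    keep = scale > 0
    if not keep.any():
        raise ValueError("all columns have zero variance; nothing to standardize")
    if not keep.all():
        dropped = list(m.X.columns[~keep])
        warnings.warn(f"dropping zero-variance columns: {dropped}")
    Z = (X[:, keep] - center[keep]) / scale[keep]
    cols = m.X.columns[keep]
    scaling = pd.DataFrame(
        {"center": center[keep], "scale": scale[keep]}, index=cols
    )
    return FeatureMatrix(
        X=pd.DataFrame(Z, columns=cols), labels=m.labels.reset_index(drop=True),
        scaling=scaling,
    )


@dataclass
class PCAResult:
    scores: np.ndarray                 # (cells, k)
    loadings: np.ndarray               # (features, k)
    explained_variance_fraction: np.ndarray
    feature_names: list


def pca(m: FeatureMatrix, k: int | None = None) -> PCAResult:
    """Principal components of a standardized feature matrix.

    Components are ordered by decreasing explained variance; each loading
    vector is signed so its largest-magnitude entry is positive (stable,
    reproducible plots).  ``scores = X @ loadings``.
    """
    X = m.values()
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k is None:
        k = rank
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    var = s**2
    evf = var[:k] / var.sum()
    load = Vt[:k].T
    # sign convention
    flip = np.sign(load[np.argmax(np.abs(load), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    load = load * flip
    return PCAResult(
        scores=Xc @ load,
        loadings=load,
        explained_variance_fraction=evf,
        feature_names=list(m.X.columns),
    )


@dataclass
class LDAResult:
    scores: np.ndarray                 # (cells, n_axes)
    axes: np.ndarray                   # (features, n_axes)
    centroids: pd.DataFrame            # group -> centroid in LD space
    reclassification_rate: float
    assigned: np.ndarray               # nearest-centroid label per cell


def lda(m: FeatureMatrix, ridge: float | None = None) -> LDAResult:
    """Fisher linear discriminants with ridge-regularized within-scatter.

    At most ``n_groups - 1`` axes.  The within-group scatter is
    regularized as ``Sw + eps*I`` with ``eps = 1e-6 * trace(Sw)/d`` (near
    collinear features such as integrated vs mean intensity make Sw
    ill-conditioned).  Reports the training-set nearest-centroid
    reclassification rate in discriminant space.
    """
    X = m.values()
    y = np.asarray(m.labels)
    groups = m.groups
    if len(groups) < 2:
        raise ValueError("LDA requires at least two groups")
    d = X.shape[1]
    grand = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for g in groups:
        Xg = X[y == g]
        mu = Xg.mean(axis=0)
        dev = Xg - mu
        Sw += dev.T @ dev
        Sb += len(Xg) * np.outer(mu - grand, mu - grand)
    eps = ridge if ridge is not None else 1e-6 * np.trace(Sw) / d
    if np.linalg.cond(Sw) > 1e12:
        warnings.warn("within-group scatter is near-singular; applying ridge")
    Sw_r = Sw + eps * np.eye(d)

    evals, evecs = linalg.eigh(Sb, Sw_r)
    order = np.argsort(evals)[::-1]
    n_axes = min(len(groups) - 1, d)
    W = evecs[:, order[:n_axes]]
    # sign convention as in pca
    flip = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(n_axes)])
    flip[flip == 0] = 1.0
    W = W * flip

    scores = X @ W
    cents = pd.DataFrame(
        [scores[y == g].mean(axis=0) for g in groups],
        index=pd.Index(groups, name="group"),
        columns=[f"LD{i+1}" for i in range(n_axes)],
    )
    dists = np.stack([
        np.linalg.norm(scores - cents.loc[g].to_numpy(), axis=1) for g in groups
    ])
    assigned = np.array(groups, dtype=object)[np.argmin(dists, axis=0)]
    rate = float(np.mean(assigned == y))
    return LDAResult(scores=scores, axes=W, centroids=cents,
                     reclassification_rate=rate, assigned=assigned)


@dataclass
class ManovaResult:
    wilks_lambda: float
    f_value: float
    df1: float
    df2: float
    p_value: float


def manova(m: FeatureMatrix) -> ManovaResult:
    """One-way MANOVA: Wilks' lambda with Rao's F approximation.

    Lambda = det(W) / det(W + B) where W and B are the within- and
    between-group SSCP matrices; determinants are evaluated via slogdet.
    Requires more rows than features + groups so W has full rank.
    """
    X = m.values()
    y = np.asarray(m.labels)
    groups = m.groups
    n, p = X.shape
    g = len(groups)
    if g < 2:
        raise ValueError("MANOVA requires at least two groups")
    if n < p + g:
        raise ValueError(
            f"rank condition violated: need more rows ({n}) than "
            f"features + groups ({p} + {g}) for a full-rank within-group SSCP"
        )
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for lab in groups:
        Xg = X[y == lab]
        mu = Xg.mean(axis=0)
        dev = Xg - mu
        W += dev.T @ dev
        B += len(Xg) * np.outer(mu - grand, mu - grand)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise ValueError(
            "rank-deficient SSCP matrix: groups are degenerate "
            "(identical rows or zero within-group variance)"
        )
    lam = float(np.exp(logdet_w - logdet_t))

    # Rao's F approximation
    mh = g - 1                      # hypothesis df
    me = n - g                      # error df
    num = p * p * mh * mh - 4.0
    den = p * p + mh * mh - 5.0
    t = np.sqrt(num / den) if den > 0 and num > 0 else 1.0
    df1 = p * mh
    w = me + mh - (p + mh + 1) / 2.0
    df2 = w * t - (p * mh - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    f = (1.0 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(f, df1, df2))
    return ManovaResult(wilks_lambda=lam, f_value=float(f),
                        df1=float(df1), df2=float(df2), p_value=pval)
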