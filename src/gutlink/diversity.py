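"""Alpha diversity, PCA ordination, and PC-vs-diversity correlation.

Links host-genotype structure to gut-community structure: PCA of the
(functional-)SNV dosage matrix and of the species table, per-sample
Simpson diversity, and the correlation between a principal-component
score and any per-sample quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "simpson_alpha",
    "alpha_diversity",
    "pca",
    "pc_correlation",
    "PcaResult",
    "CorrelationResult",
    "clr_transform",
]


def simpson_alpha(abundances, form: str = "gini") -> float:
    """Simpson-family diversity of one sample's abundance vector.

    The vector is renormalized to sum 1, so the index is invariant to
    rescaling by any positive constant.

    form:
        ``"gini"`` (default) — Gini-Simpson, 1 - sum(p_i^2); higher means
        more diverse, 0 for a monoculture, 1 - 1/S for S equal species.
        ``"dominance"`` — plain sum(p_i^2).
        ``"inverse"`` — 1 / sum(p_i^2).
    """
    p = np.asarray(abundances, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a single sample's 1-D abundance vector")
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero; diversity undefined")
    p = p / total
    dominance = float(np.sum(p * p))
    if form == "gini":
        return 1.0 - dominance
    if form == "dominance":
        return dominance
    if form == "inverse":
        return 1.0 / dominance
    raise ValueError(f"unknown form {form!r}; use gini | dominance | inverse")


def alpha_diversity(table: pd.DataFrame, form: str = "gini") -> pd.Series:
    """Per-sample Simpson diversity for a samples x species table."""
    return pd.Series(
        [simpson_alpha(row, form=form) for row in table.to_numpy()],
        index=table.index,
        name=f"simpson_{form}",
    )


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # retained features x components
    explained_variance: np.ndarray  # non-increasing
    total_variance: float
    dropped_features: list

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.total_variance


def pca(matrix, n_components: int | None = None, scale: bool = False) -> PcaResult:
    """PCA of a samples x features matrix via SVD of the centered data.

    Constant features are dropped before decomposition. Explained
    variances are the centered covariance eigenvalues (ddof=1) and sum to
    the total centered variance. Component signs follow a deterministic
    convention: the largest-magnitude loading of each component is
    positive, so results are reproducible and invariant (up to nothing)
    to feature ordering.
    """
    X = pd.DataFrame(matrix).astype(float)
    if X.shape[0] < 2:
        raise ValueError(f"PCA needs at least 2 samples, got {X.shape[0]}")
    variances = X.var(axis=0, ddof=1)
    dropped = list(X.columns[variances == 0.0])
    X = X.loc[:, variances > 0.0]
    if X.shape[1] == 0:
        raise ValueError("all features are constant; PCA undefined")
    C = X.to_numpy() - X.to_numpy().mean(axis=0)
    if scale:
        C = C / C.std(axis=0, ddof=1)
    n = C.shape[0]
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    k_max = int((s > s[0] * 1e-12).sum()) if s.size else 0
    k = k_max if n_components is None else min(n_components, k_max)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    for a in range(k):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            Vt[a] *= -1.0
            U[:, a] *= -1.0
    comp_names = [f"PC{a + 1}" for a in range(k)]
    total_var = float((C * C).sum() / (n - 1))
    return PcaResult(
        scores=pd.DataFrame(U * s, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=comp_names),
        explained_variance=(s * s) / (n - 1),
        total_variance=total_var,
        dropped_features=dropped,
    )


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str = "pearson"


def pc_correlation(scores_component, values, method: str = "pearson") -> CorrelationResult:
    """Correlation between a component score and a per-sample quantity.

    Pearson by default (two-sided t-distributed p on n - 2 df); Spearman
    available for a rank-based check.
    """
    x = np.asarray(scores_component, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError(f"need at least 3 samples, got {x.size}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input; correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=x.size, method=method)


def clr_transform(table: pd.DataFrame, pseudocount: float = 1e-6) -> pd.DataFrame:
    """Centered log-ratio transform of a relative-abundance table."""
    logged = np.log(table.to_numpy(dtype=float) + pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=table.index, columns=table.columns)
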