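"""Pairwise screens across the cohort's omics layers.

Covers the four association machines the integration needs:

* covariate-adjusted linear regression of a (transformed) feature on SNV
  dosage, with age and sex as fixed covariates and Benjamini-Hochberg
  FDR within each screen family;
* Spearman rank-correlation matrices between two feature tables
  (midrank ties, two-sided t-based p);
* Mann-Whitney U group comparison of log cytokine levels — exact null
  distribution when both groups have at most 8 samples, otherwise the
  tie- and continuity-corrected normal approximation — with BH FDR;
* PLS-DA variable importance in projection (VIP, NIPALS algorithm) and
  the three-way differential-metabolite rule VIP > 1, t-test p < 0.05,
  fold change beyond 1.5.

Default feature transforms before regression: log10(x + 1e-6) for
relative abundances (species, pathways), natural log for cytokines,
per-feature autoscaling for metabolite intensities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "ConstantInputError",
    "transform_values",
    "adjusted_regression",
    "association_screen",
    "bh_adjust",
    "spearman_screen",
    "mannwhitney_diff",
    "plsda_vip",
    "differential_metabolites",
]

DEFAULT_TRANSFORMS = {
    "species": "log10_offset",
    "pathways": "log10_offset",
    "cytokines": "log",
    "metabolites": "autoscale",
}

EXACT_MWU_LIMIT = 8  # exact enumeration cost grows combinatorially past this


class ConstantInputError(ValueError):
    """A screen input (e.g. genotype column) has no variation."""


@dataclass
class AssociationResult:
    snv_id: str
    feature_id: str
    beta: float
    se: float
    t_stat: float
    p: float
    q: Optional[float] = None
    n: int = 0


def transform_values(values, transform) -> np.ndarray:
    """Apply a named or callable feature transform.

    Names: ``log10_offset`` (log10(x + 1e-6)), ``log`` (natural log,
    positive values required), ``autoscale`` (z-score), ``identity``.
    """
    x = np.asarray(values, dtype=float)
    if transform is None or transform == "identity":
        return x
    if callable(transform):
        return np.asarray(transform(x), dtype=float)
    if transform == "log10_offset":
        return np.log10(x + 1e-6)
    if transform == "log":
        if (x <= 0).any():
            raise ValueError(
                "log transform requires positive values; configure an offset "
                "(e.g. transform=lambda v: np.log(v + offset))"
            )
        return np.log(x)
    if transform == "autoscale":
        sd = x.std(ddof=1)
        if sd == 0:
            raise ConstantInputError("cannot autoscale a constant feature")
        return (x - x.mean()) / sd
    raise ValueError(f"unknown transform {transform!r}")


def _design(genotype, covariates: pd.DataFrame, coding: str) -> np.ndarray:
    g = np.asarray(genotype, dtype=float)
    if coding == "dominant":
        g = (g > 0).astype(float)
    elif coding != "additive":
        raise ValueError(f"unknown genotype coding {coding!r}")
    X = np.column_stack(
        [np.ones_like(g), g, covariates["age"].to_numpy(float), covariates["sex"].to_numpy(float)]
    )
    return X


def adjusted_regression(
    genotype,
    feature,
    covariates: pd.DataFrame,
    transform=None,
    coding: str = "additive",
    snv_id: str = "snv",
    feature_id: str = "feature",
) -> AssociationResult:
    """OLS of a transformed feature on [1, dosage, age, sex].

    The reported p is the two-sided t-test on the dosage coefficient
    (n - 4 residual df). Constant genotypes raise
    :class:`ConstantInputError` so screens can skip them with a reason.
    """
    y = transform_values(feature, transform)
    X = _design(genotype, covariates, coding)
    n, k = X.shape
    if n < 5:
        raise ValueError(f"need at least 5 samples, got {n}")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values are not allowed in the regression")
    if np.ptp(X[:, 1]) == 0:
        raise ConstantInputError(f"genotype {snv_id} is constant; skipped")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [("intercept", "dosage", "age", "sex")[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or 'unknown'}")
    beta, se, t_stat, p = _ols_tstats(X, y[:, None])
    return AssociationResult(
        snv_id=snv_id, feature_id=feature_id,
        beta=float(beta[0]), se=float(se[0]), t_stat=float(t_stat[0]), p=float(p[0]), n=n,
    )


def _ols_tstats(X: np.ndarray, Y: np.ndarray):
    """Dosage-coefficient beta/se/t/p for OLS of each column of Y on X."""
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ Y)  # k x F
    resid = Y - X @ B
    df = n - k
    sigma2 = (resid * resid).sum(axis=0) / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    beta = B[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t_stat), df)
    return beta, se, t_stat, p


def association_screen(
    genotypes: pd.DataFrame,
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    transform=None,
    coding: str = "additive",
) -> pd.DataFrame:
    """All SNV x feature adjusted regressions, BH-corrected as one family.

    Returns a tidy frame (snv_id, feature_id, beta, se, t_stat, p, q);
    constant SNVs are skipped and listed in ``result.attrs['skipped']``.
    """
    shared = genotypes.index.intersection(covariates.index).intersection(features.index)
    if len(shared) < 5:
        raise ValueError(f"only {len(shared)} shared samples; need at least 5")
    G = genotypes.loc[shared]
    cov = covariates.loc[shared]
    Y = np.column_stack(
        [transform_values(features.loc[shared, f], transform) for f in features.columns]
    )
    rows, skipped = [], []
    for snv in G.columns:
        g = G[snv].to_numpy(float)
        if np.ptp(g) == 0:
            skipped.append((snv, "constant genotype"))
            continue
        X = _design(g, cov, coding)
        beta, se, t_stat, p = _ols_tstats(X, Y)
        for j, feat in enumerate(features.columns):
            rows.append((snv, feat, beta[j], se[j], t_stat[j], p[j]))
    out = pd.DataFrame(rows, columns=["snv_id", "feature_id", "beta", "se", "t_stat", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    out.attrs["skipped"] = skipped
    out.attrs["n"] = int(len(shared))
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    raw = m * p[order] / ranks
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    np.clip(q_sorted, 0.0, 1.0, out=q_sorted)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Spearman screen
# ---------------------------------------------------------------------------

def spearman_screen(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho and two-sided p for every feature pair across tables.

    Ranks use midranks for ties; p is the t-approximation on n - 2 df
    (scipy's convention). Constant features yield undefined pairs,
    flagged and excluded from significance marking. Stars follow the
    usual convention: * p < 0.05, ** p < 0.01.
    """
    shared = table_a.index.intersection(table_b.index)
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared samples; need at least 4")
    A = table_a.loc[shared]
    B = table_b.loc[shared]
    rows = []
    for fa in A.columns:
        for fb in B.columns:
            x, y = A[fa].to_numpy(float), B[fb].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((fa, fb, np.nan, np.nan, "undefined"))
                continue
            res = stats.spearmanr(x, y)
            p = float(res.pvalue)
            star = "**" if p < 0.01 else "*" if p < 0.05 else ""
            rows.append((fa, fb, float(res.statistic), p, star))
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "rho", "p", "significance"])


# ---------------------------------------------------------------------------
# Mann-Whitney differential cytokines
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _u_count(u: int, m: int, n: int) -> int:
    """Number of rank arrangements of m-vs-n samples with U statistic u."""
    if u < 0 or u > m * n:
        return 0
    if m == 0 or n == 0:
        return 1 if u == 0 else 0
    return _u_count(u - n, m - 1, n) + _u_count(u, m, n - 1)


def exact_mwu_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p via the null permutation distribution.

    Tie-free data use the classical integer recursion over rank
    arrangements; tied data fall back to full enumeration of group
    assignments with midranks. Two-sided p is twice the smaller tail,
    capped at 1. Returns (U of the first group, p).
    """
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    total = math.comb(n1 + n2, n1)
    if len(np.unique(pooled)) == len(pooled):  # no ties: integer recursion
        u_int = int(round(u1))
        count_le = sum(_u_count(u, n1, n2) for u in range(0, u_int + 1))
        count_ge = sum(_u_count(u, n1, n2) for u in range(u_int, n1 * n2 + 1))
        p = min(1.0, 2.0 * min(count_le, count_ge) / total)
        return u1, p
    # ties: enumerate group assignments over the observed (midrank) values
    count_le = count_ge = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        if u <= u1 + 1e-9:
            count_le += 1
        if u >= u1 - 1e-9:
            count_ge += 1
    p = min(1.0, 2.0 * min(count_le, count_ge) / total)
    return u1, p


def mannwhitney_diff(
    cytokines: pd.DataFrame,
    groups,
    fdr_cut: float = 0.05,
    log_offset: float = 0.0,
    exact_limit: int = EXACT_MWU_LIMIT,
) -> pd.DataFrame:
    """Differential cytokines: Mann-Whitney U on log levels, BH FDR.

    ``groups`` is a per-sample case/control labeling aligned with the
    table (accepts a covariate table with a ``group`` column, a Series,
    or an array of 'case'/'control'). The exact null distribution is used
    when both groups have at most ``exact_limit`` samples, otherwise the
    normal approximation with tie and continuity corrections.
    """
    is_case = _case_mask(groups, cytokines.index)
    if is_case.all() or (~is_case).all():
        raise ValueError("both groups must be non-empty")
    rows = []
    for feat in cytokines.columns:
        raw = cytokines[feat].to_numpy(float)
        if (raw + log_offset <= 0).any():
            raise ValueError(
                f"cytokine {feat!r} has non-positive values under log; "
                "configure log_offset to shift them positive"
            )
        vals = np.log(raw + log_offset)
        x, y = vals[is_case], vals[~is_case]
        if len(x) <= exact_limit and len(y) <= exact_limit:
            u, p = exact_mwu_p(x, y)
        else:
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            u, p = float(res.statistic), float(res.pvalue)
        fc = _fold_change(raw[is_case], raw[~is_case])
        rows.append((feat, u, p, fc))
    out = pd.DataFrame(rows, columns=["feature_id", "stat", "p", "fold_change"])
    out["fdr"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    out["significant"] = out["fdr"] < fdr_cut
    return out


def _case_mask(groups, index) -> np.ndarray:
    if isinstance(groups, pd.DataFrame):
        groups = groups.loc[index, "group"]
    if isinstance(groups, pd.Series):
        groups = groups.loc[index]
    arr = np.asarray(groups)
    if arr.dtype.kind in "OU":
        return arr == "case"
    return arr.astype(bool)


def _fold_change(case_vals: np.ndarray, control_vals: np.ndarray) -> float:
    denom = control_vals.mean()
    if denom == 0:
        return float("nan")
    return float(case_vals.mean() / denom)


# ---------------------------------------------------------------------------
# PLS-DA VIP and the differential-metabolite rule
# ---------------------------------------------------------------------------

def plsda_vip(
    metabolites: pd.DataFrame,
    groups,
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> pd.Series:
    """Variable importance in projection from PLS-DA (NIPALS).

    Features are autoscaled, the response is the centered binary group
    code, and components are extracted by NIPALS with deflation of both
    blocks. VIP_j = sqrt(p * sum_a w_ja^2 SSY_a / sum_a SSY_a) with p the
    feature count, w the unit loading weights and SSY_a the response
    variation explained by component a; sum of VIP^2 over features is p
    by construction.
    """
    is_case = _case_mask(groups, metabolites.index)
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    X = metabolites.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        const = list(metabolites.columns[sd == 0])
        raise ConstantInputError(f"constant metabolite features: {const}")
    X = (X - X.mean(axis=0)) / sd
    y = is_case.astype(float)
    y = y - y.mean()
    n, p = X.shape
    A = min(n_components, n - 1, p)
    weights, ssy = [], []
    Xa, ya = X.copy(), y.copy()
    for a in range(A):
        cov = Xa.T @ ya
        norm = np.linalg.norm(cov)
        if norm < tol:
            break
        w = cov / norm
        for it in range(max_iter):
            t = Xa @ w
            tt = float(t @ t)
            if tt < tol:
                break
            q = float(ya @ t) / tt
            w_new = Xa.T @ (ya * q)
            nrm = np.linalg.norm(w_new)
            if nrm < tol:
                break
            w_new /= nrm
            if np.linalg.norm(w_new - np.sign(w_new @ w) * w) < 1e-10:
                w = w_new
                break
            w = w_new
        else:
            raise RuntimeError(f"NIPALS did not converge for component {a + 1}")
        t = Xa @ w
        tt = float(t @ t)
        if tt < tol:
            break
        q = float(ya @ t) / tt
        p_load = (Xa.T @ t) / tt
        Xa = Xa - np.outer(t, p_load)
        ya = ya - q * t
        weights.append(w)
        ssy.append(q * q * tt)
    if not weights or sum(ssy) <= 0:
        raise ValueError("PLS found no response-related variation; VIP undefined")
    W = np.column_stack(weights)  # p x A
    ssy = np.asarray(ssy)
    vip = np.sqrt(p * (W**2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=metabolites.columns, name="vip")


def differential_metabolites(
    metabolites: pd.DataFrame,
    groups,
    vip_cut: float = 1.0,
    p_cut: float = 0.05,
    fc_cut: float = 1.5,
    n_components: int = 2,
    two_sided_fc: bool = True,
    ttest_on_log: bool = True,
) -> pd.DataFrame:
    """Differential metabolites: VIP > 1 AND Welch t-test p < 0.05 AND
    fold change beyond 1.5.

    Fold change is case mean / control mean on the raw intensity scale;
    by default the cut is two-sided (FC > 1.5 or FC < 1/1.5) so depleted
    metabolites qualify too, with the literal one-sided reading behind
    ``two_sided_fc=False``. The t-test runs on log10 intensities by
    default. Metabolites with a zero control mean get an undefined FC and
    are flagged, never called significant.
    """
    is_case = _case_mask(groups, metabolites.index)
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    vip = plsda_vip(metabolites, is_case, n_components=n_components)
    rows = []
    for feat in metabolites.columns:
        raw = metabolites[feat].to_numpy(float)
        vals = np.log10(raw + 1e-12) if ttest_on_log else raw
        t_res = stats.ttest_ind(vals[is_case], vals[~is_case], equal_var=False)
        fc = _fold_change(raw[is_case], raw[~is_case])
        rows.append((feat, float(t_res.statistic), float(t_res.pvalue), fc, float(vip[feat])))
    out = pd.DataFrame(rows, columns=["feature_id", "stat", "p", "fold_change", "vip"])
    out["fdr"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    fc = out["fold_change"]
    fc_ok = (fc > fc_cut) | ((fc < 1.0 / fc_cut) if two_sided_fc else False)
    fc_ok &= fc.notna()
    out["fc_defined"] = fc.notna()
    out["significant"] = (out["vip"] > vip_cut) & (out["p"] < p_cut) & fc_ok
    return out
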