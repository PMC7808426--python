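"""Four-condition causal inference test for SNV -> microbe -> metabolite trios.

For an instrument L (SNV dosage), candidate mediator M (transformed
microbe abundance) and outcome T (transformed metabolite intensity), the
test requires all four conditions to hold for the mediated-causal call:

1. L and M are associated;
2. L and M are associated after adjusting for T;
3. M and T are associated after adjusting for L;
4. L is independent of T after adjusting for M.

Conditions 1-3 are F-tests on the focal coefficient in multivariate
linear regressions (age and sex enter every model when covariates are
supplied). Condition 4 is the delicate one — independence is the
*alternative*, so an ordinary test of the L coefficient cannot support
it. We use an equivalence-style permutation construction: the observed
F for L in ``T ~ L + M + covariates`` is compared against a reference
distribution of the same F computed with *non-mediating surrogates* of
M. Each surrogate M*_b keeps M's relation to L (the fit of M on L and
covariates) but carries permuted residuals, so it cannot absorb any
L-related signal in T. Under a genuine chain the true M soaks up the
entire L - T association while no surrogate can, so the observed F falls
far below the reference distribution and

    p4 = (1 + #{F*_b <= F_obs}) / (B + 1)

is small. Under a pleiotropic (independent-effects) SNV the direct
L - T association survives adjustment for real and surrogate mediators
alike, leaving p4 large. The omnibus p is the intersection-union
combination p_cit = max(p1, p2, p3, p4), which is conservative under the
complete null.

Directionality is resolved by running the test in both orientations:
``causal`` iff the forward (microbe-mediated) p_cit clears alpha while
the reverse does not, ``reactive`` for the mirror image, ``independent``
when neither clears, ``ambiguous`` when both do.

Before the permutation loop samples are put into a canonical order
keyed by the data values, so p4 is reproducible under a fixed seed and
invariant to sample reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .association import DEFAULT_TRANSFORMS, transform_values

__all__ = ["TrioResult", "cit_test", "classify_direction", "screen_trios"]

MIN_PERMUTATIONS = 100


@dataclass
class TrioResult:
    p1: float
    p2: float
    p3: float
    p4: float
    p_cit: float
    stats: dict = field(default_factory=dict)
    n: int = 0
    n_perm: int = 0
    seed: Optional[int] = None
    direction: Optional[str] = None

    def components(self) -> tuple[float, float, float, float]:
        return (self.p1, self.p2, self.p3, self.p4)


def _residualize(v: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Residuals of v (vector or matrix) on the column space of W."""
    coef, *_ = np.linalg.lstsq(W, v, rcond=None)
    return v - W @ coef


def _f_single(y: np.ndarray, x: np.ndarray, others: np.ndarray, df2: int):
    """F statistic and p for x in y ~ x + others (columns already include 1)."""
    X = np.column_stack([x, others])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(np.sum((y - X @ coef) ** 2))
    coef_r, *_ = np.linalg.lstsq(others, y, rcond=None)
    rss_red = float(np.sum((y - others @ coef_r) ** 2))
    if rss_full <= 0:
        return np.inf, 0.0
    F = (rss_red - rss_full) / (rss_full / df2)
    return F, float(stats.f.sf(F, 1, df2))


def cit_test(
    L,
    M,
    T,
    covariates: Optional[pd.DataFrame] = None,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    perm_scheme: str = "mediator",
) -> TrioResult:
    """Run the four-condition test on one (instrument, mediator, outcome) trio.

    ``perm_scheme`` selects the condition-4 construction: ``"mediator"``
    (default, non-mediating surrogate mediators, described in the module
    docstring), ``"instrument"`` (surrogate instruments built from
    permuted residuals of L on M, p4 = 1 - tail), or ``"parametric"``
    (p4 = 1 - parametric F-test p; crude, for comparison only).
    """
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    T = np.asarray(T, dtype=float)
    if not (L.shape == M.shape == T.shape) or L.ndim != 1:
        raise ValueError("L, M, T must be equal-length 1-D vectors")
    n = L.size
    if covariates is not None:
        cov = np.column_stack(
            [covariates["age"].to_numpy(float), covariates["sex"].to_numpy(float)]
        )
    else:
        cov = np.empty((n, 0))
    if n < cov.shape[1] + 4:
        raise ValueError(f"insufficient samples: n={n} < covariates + 4")
    if np.ptp(L) == 0:
        raise ValueError("instrument L is constant")
    if np.ptp(M) == 0 or np.ptp(T) == 0:
        raise ValueError("mediator or outcome is constant")
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be >= {MIN_PERMUTATIONS}, got {n_perm}")

    # canonical sample order: permutation p-value invariant to input order
    order = np.lexsort((cov.T[::-1].tolist() or [np.zeros(n)]) + [T, M, L])
    L, M, T, cov = L[order], M[order], T[order], cov[order]

    ones = np.ones((n, 1))
    Z = np.column_stack([ones, cov])  # intercept + covariates
    q = Z.shape[1]

    f1, p1 = _f_single(M, L, Z, n - q - 1)
    f2, p2 = _f_single(M, L, np.column_stack([Z, T]), n - q - 2)
    f3, p3 = _f_single(T, M, np.column_stack([Z, L]), n - q - 2)
    f_obs, p_param = _f_single(T, L, np.column_stack([Z, M]), n - q - 2)

    rng = np.random.default_rng(np.random.SeedSequence(seed if seed is not None else 0))
    if perm_scheme == "parametric":
        p4 = 1.0 - p_param
        stats_extra = {}
    elif perm_scheme in ("mediator", "instrument"):
        p4, stats_extra = _permutation_p4(
            L, M, T, Z, f_obs, n_perm, rng, scheme=perm_scheme
        )
    else:
        raise ValueError(f"unknown perm_scheme {perm_scheme!r}")

    p_cit = max(p1, p2, p3, p4)
    result = TrioResult(
        p1=p1, p2=p2, p3=p3, p4=p4, p_cit=p_cit,
        stats={"f1": f1, "f2": f2, "f3": f3, "f4_obs": f_obs,
               "p4_parametric": p_param, **stats_extra},
        n=n, n_perm=n_perm, seed=seed,
    )
    assert result.p_cit == max(result.components())
    return result


def _permutation_p4(L, M, T, Z, f_obs, n_perm, rng, scheme):
    """Permutation reference distribution for the condition-4 F statistic."""
    n = L.size
    df2 = n - Z.shape[1] - 2
    if scheme == "mediator":
        # surrogates keep M's fit on (L, Z), permute its residuals
        ZL = np.column_stack([Z, L])
        coef, *_ = np.linalg.lstsq(ZL, M, rcond=None)
        fitted = ZL @ coef
        resid = np.sort(M - fitted)  # canonical residual order
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        surrogates = fitted[:, None] + resid[perm_idx].T  # n x B
        f_ref = _f_vectorized(y=T, x=L, varying=surrogates, Z=Z, df2=df2)
        count = int(np.sum(f_ref <= f_obs))
        p4 = (1 + count) / (n_perm + 1)
    else:  # instrument scheme: surrogate L* with permuted residuals of L on (M, Z)
        ZM = np.column_stack([Z, M])
        coef, *_ = np.linalg.lstsq(ZM, L, rcond=None)
        fitted = ZM @ coef
        resid = np.sort(L - fitted)
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        surrogates = fitted[:, None] + resid[perm_idx].T
        f_ref = _f_varying_x(y=T, xs=surrogates, M=M, Z=Z, df2=df2)
        tail = (1 + int(np.sum(f_ref >= f_obs))) / (n_perm + 1)
        p4 = 1.0 - tail
    return p4, {"f4_ref_median": float(np.median(f_ref))}


def _f_vectorized(y, x, varying, Z, df2):
    """F for x in y ~ x + varying_b + Z, vectorized over columns of varying."""
    y0 = _residualize(y, Z)
    x0 = _residualize(x, Z)
    V0 = _residualize(varying, Z)
    vv = np.einsum("ib,ib->b", V0, V0)
    vv = np.where(vv > 0, vv, np.inf)
    ay = (y0 @ V0) / vv
    ax = (x0 @ V0) / vv
    y_perp = y0[:, None] - V0 * ay
    x_perp = x0[:, None] - V0 * ax
    xx = np.einsum("ib,ib->b", x_perp, x_perp)
    xy = np.einsum("ib,ib->b", x_perp, y_perp)
    yy = np.einsum("ib,ib->b", y_perp, y_perp)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = xy / xx
        rss = yy - beta * xy
        F = np.where(rss > 0, (beta * xy) / (rss / df2), np.inf)
    return F


def _f_varying_x(y, xs, M, Z, df2):
    """F for x_b in y ~ x_b + M + Z, vectorized over columns of xs."""
    W = np.column_stack([Z, M])
    y0 = _residualize(y, W)
    X0 = _residualize(xs, W)
    xx = np.einsum("ib,ib->b", X0, X0)
    xy = y0 @ X0
    yy = float(y0 @ y0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(xx > 0, xy / xx, 0.0)
        rss = yy - beta * xy
        F = np.where(rss > 0, (beta * xy) / (rss / df2), np.inf)
    return F


def classify_direction(forward: TrioResult, reverse: TrioResult, alpha: float = 0.05) -> str:
    """Resolve trio directionality from the two orientations' omnibus p.

    causal iff forward.p_cit < alpha <= reverse.p_cit; reactive for the
    mirror; independent if neither clears alpha; ambiguous if both do.
    """
    if forward.n != reverse.n:
        raise ValueError(
            f"forward and reverse runs use different samples (n={forward.n} vs {reverse.n})"
        )
    fwd, rev = forward.p_cit < alpha, reverse.p_cit < alpha
    if fwd and not rev:
        return "causal"
    if rev and not fwd:
        return "reactive"
    if not fwd and not rev:
        return "independent"
    return "ambiguous"


def screen_trios(
    snv_microbe_hits: pd.DataFrame,
    genotypes: pd.DataFrame,
    species: pd.DataFrame,
    metabolites: pd.DataFrame,
    diff_metabolites,
    covariates: Optional[pd.DataFrame] = None,
    n_perm: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    species_transform=DEFAULT_TRANSFORMS["species"],
    metabolite_transform=DEFAULT_TRANSFORMS["metabolites"],
) -> pd.DataFrame:
    """Evaluate every surviving (SNV, microbe) pair against every
    differential metabolite, both orientations, and classify.

    ``snv_microbe_hits`` needs columns snv_id and feature_id (the
    microbe); ``diff_metabolites`` is an iterable of metabolite ids.
    Mediator/outcome transforms default to the association screen's so
    upstream hits and the causal test see identical data. Pairs with a
    constant layer are skipped with a reason (``result.attrs['skipped']``);
    seeds derive from the root seed and the trio index so each trio is
    independently reproducible. Rows are sorted by forward p_cit.
    """
    diff_metabolites = list(diff_metabolites)
    rows, skipped = [], []
    pairs = snv_microbe_hits[["snv_id", "feature_id"]].drop_duplicates().to_numpy()
    samples = genotypes.index
    root = np.random.SeedSequence(seed)
    trio_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(max(1, len(pairs) * max(1, len(diff_metabolites))) )]
    k = 0
    for snv, microbe in pairs:
        for met in diff_metabolites:
            trio_seed = trio_seeds[k]
            k += 1
            L = genotypes.loc[samples, snv].to_numpy(float)
            M = species.loc[samples, microbe].to_numpy(float)
            T = metabolites.loc[samples, met].to_numpy(float)
            if np.ptp(M) == 0 or np.ptp(T) == 0 or np.ptp(L) == 0:
                skipped.append(((snv, microbe, met), "constant input"))
                continue
            Mt = transform_values(M, species_transform)
            Tt = transform_values(T, metabolite_transform)
            cov = covariates.loc[samples] if covariates is not None else None
            fwd = cit_test(L, Mt, Tt, cov, n_perm=n_perm, seed=trio_seed)
            rev = cit_test(L, Tt, Mt, cov, n_perm=n_perm, seed=trio_seed + 1)
            direction = classify_direction(fwd, rev, alpha=alpha)
            rows.append(
                (snv, microbe, met,
                 fwd.p1, fwd.p2, fwd.p3, fwd.p4, fwd.p_cit,
                 rev.p1, rev.p2, rev.p3, rev.p4, rev.p_cit,
                 direction, fwd.n, n_perm, trio_seed)
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "snv_id", "microbe_id", "metabolite_id",
            "p1_fwd", "p2_fwd", "p3_fwd", "p4_fwd", "p_cit_forward",
            "p1_rev", "p2_rev", "p3_rev", "p4_rev", "p_cit_reverse",
            "direction", "n", "n_perm", "seed",
        ],
    )
    out = out.sort_values("p_cit_forward", kind="mergesort").reset_index(drop=True)
    out.attrs["skipped"] = skipped
    return out
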