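"""Recovery- and calibration-based validation experiments.

Each function runs one self-contained experiment on synthetic data with
known ground truth and returns summary rates: filter-cascade concordance
against the generator's fate ledger, type-I error and causal/pleiotropy
discrimination of the trio causal test, and end-to-end recovery of
embedded differential cytokines and causal trios at the emulated cohort
size (26 + 26). The problem sizes used by callers are deliberately
modest (hundreds of trios, a few hundred permutations) — large enough
for stable rates, small enough to run routinely.
"""

from __future__ import annotations

import numpy as np

from .association import DEFAULT_TRANSFORMS, mannwhitney_diff, transform_values
from .cit import cit_test, classify_direction
from .synthetic import CohortConfig, generate_cohort, generate_variant_stream
from .variants import classify_variant

__all__ = [
    "cascade_concordance",
    "cit_null_type1",
    "cit_discrimination",
    "endtoend_recovery",
]


def cascade_concordance(n_records: int = 40, seed: int = 0) -> dict:
    """Fraction of cascade verdicts matching the generator's fate ledger."""
    records, truth = generate_variant_stream(n_records, seed=seed)
    matches = sum(
        classify_variant(rec, truth.frequency_table) == truth.variant_fate[rec.variant_id]
        for rec in records
    )
    return {"concordance": matches / len(records), "n": len(records)}


def _draw_instrument(rng, n):
    L = rng.binomial(2, 0.3, n).astype(float)
    while np.ptp(L) == 0:
        L = rng.binomial(2, 0.3, n).astype(float)
    return L


def _z(x):
    return (x - x.mean()) / x.std()


def cit_null_type1(
    n_trios: int = 1000, n: int = 200, n_perm: int = 200, alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Fraction of completely null trios (L independent of M and T) with
    p_cit below alpha; the max-p construction keeps this at or below alpha."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    hits = 0
    for i in range(n_trios):
        L = _draw_instrument(rng, n)
        M = rng.normal(size=n)
        T = rng.normal(size=n)
        res = cit_test(L, M, T, n_perm=n_perm, seed=seed * 1000003 + i)
        hits += res.p_cit < alpha
    rate = hits / n_trios
    se = float(np.sqrt(alpha * (1 - alpha) / n_trios))
    return {"type1_rate": rate, "binomial_se": se, "n": n_trios}


def cit_discrimination(
    n_trios: int = 500, n: int = 200, slope: float = 0.5, noise_sd: float = 0.5,
    n_perm: int = 500, alpha: float = 0.05, seed: int = 0,
) -> dict:
    """Causal-classification rates for chain trios vs pleiotropy trios.

    Chain: M = slope*z(L) + e, T = slope*z(M) + e'. Pleiotropy: M and T
    both driven by L through independent noises. Reported rates are the
    fraction of each class labelled 'causal' by the two-orientation rule.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    causal_calls = {"chain": 0, "pleiotropy": 0}
    for i in range(n_trios):
        L = _draw_instrument(rng, n)
        M = slope * _z(L) + rng.normal(0, noise_sd, n)
        T_chain = slope * _z(M) + rng.normal(0, noise_sd, n)
        T_pleio = slope * _z(L) + rng.normal(0, noise_sd, n)
        M_pleio = slope * _z(L) + rng.normal(0, noise_sd, n)
        base = seed * 1000003 + 4 * i
        fwd = cit_test(L, M, T_chain, n_perm=n_perm, seed=base)
        rev = cit_test(L, T_chain, M, n_perm=n_perm, seed=base + 1)
        causal_calls["chain"] += classify_direction(fwd, rev, alpha) == "causal"
        fwd = cit_test(L, M_pleio, T_pleio, n_perm=n_perm, seed=base + 2)
        rev = cit_test(L, T_pleio, M_pleio, n_perm=n_perm, seed=base + 3)
        causal_calls["pleiotropy"] += classify_direction(fwd, rev, alpha) == "causal"
    return {
        "chain_causal_rate": causal_calls["chain"] / n_trios,
        "pleiotropy_causal_rate": causal_calls["pleiotropy"] / n_trios,
        "n": n_trios,
    }


def endtoend_recovery(
    n_seeds: int = 20, n_null_trios: int = 20, n_perm: int = 200, seed: int = 0,
) -> dict:
    """Recovery at the emulated cohort size (26 + 26 samples).

    Per root seed: (a) how many of the 5 embedded differential cytokines
    (1 log-unit shift among 7) reach BH FDR < 0.05, and (b) whether every
    embedded causal trio's forward p_cit falls below the median forward
    p_cit of null (non-embedded) trios. A seed succeeds when >= 4/5
    cytokines are recovered and (b) holds.
    """
    successes = 0
    cyt_recovered = []
    for s in range(n_seeds):
        cfg = CohortConfig(
            seed=seed * 1000 + s,
            n_causal_trios=3, n_reactive_trios=0, n_pleiotropy_trios=0,
        )
        cohort = generate_cohort(cfg)
        truth_cyt = {f for _, f, _ in cohort.truth.differential_features}
        diff = mannwhitney_diff(cohort.cytokines, cohort.covariates)
        called = set(diff.loc[diff["significant"], "feature_id"])
        n_recovered = len(called & truth_cyt)
        cyt_recovered.append(n_recovered)

        cov = cohort.covariates
        embedded_p, null_p = [], []
        rng = np.random.default_rng(np.random.SeedSequence(seed * 1000 + s + 500_000))
        trios = list(cohort.truth.trio_labels)
        for k in range(n_null_trios):
            snv = cohort.genotypes.columns[3 + (k % (len(cohort.genotypes.columns) - 3))]
            sp = cohort.species.columns[3 + (k % (len(cohort.species.columns) - 3))]
            met = cohort.metabolites.columns[3 + ((k + 7) % (len(cohort.metabolites.columns) - 3))]
            trios.append((snv, sp, met))
        for j, (snv, sp, met) in enumerate(trios):
            L = cohort.genotypes[snv].to_numpy(float)
            if np.ptp(L) == 0:
                continue
            M = transform_values(cohort.species[sp], DEFAULT_TRANSFORMS["species"])
            T = transform_values(cohort.metabolites[met], DEFAULT_TRANSFORMS["metabolites"])
            res = cit_test(L, M, T, cov, n_perm=n_perm, seed=int(rng.integers(2**31)))
            if (snv, sp, met) in cohort.truth.trio_labels:
                embedded_p.append(res.p_cit)
            else:
                null_p.append(res.p_cit)
        trio_ok = bool(embedded_p) and bool(null_p) and max(embedded_p) < float(np.median(null_p))
        successes += (n_recovered >= 4) and trio_ok
    return {
        "success_rate": successes / n_seeds,
        "mean_cytokines_recovered": float(np.mean(cyt_recovered)),
        "n": n_seeds,
    }
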