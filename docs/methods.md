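# Methods

This note documents the statistical procedures `gutlink` implements,
the modelling choices behind the synthetic cohort generator, and the
numerical conventions that matter for reproducing results.

## Variant triage

The cascade treats every rule as a pure predicate of one record, so the
final candidate set equals the intersection of the per-rule kept sets
and is order-independent; only the *reported reason* uses the canonical
order (quality, depth, alt reads, gap distance, control-carried, common
in a database, too few case carriers).

Conventions adopted where a rule admits two readings:

* **"more than two" case carriers** is read literally as ≥ 3
  (`min_case_carriers=3`); the ≥ 2 reading is one flag away.
* **MAF boundary is strict**: a database entry at exactly 0.05 removes
  the variant.
* **Database-absent variants pass** the frequency rule: a variant unseen
  in population panels of this size is rarer than the cutoff by
  construction; the rule exists to remove *common* variants.
* **"within 5 bp of a gap"** removes `gap_distance ≤ 5`; kept requires
  strictly more than 5 bp.
* Coordinates are 1-based (VCF convention).

Mutation spectra fold purine-reference records by reverse complement so
all counts land in the six pyrimidine-reference classes; the fold is
idempotent. The 96 bins follow the COSMIC class-major order
`A[C>A]A … T[T>G]T`. Spectrum comparison uses cosine similarity of the
normalized 96-bin vectors (the six-class vector is also available);
cosine is the natural choice for count profiles of very different
depths, as when comparing a small candidate set against a large
external catalogue.

## Diversity and ordination

Alpha diversity defaults to the Gini–Simpson form 1 − Σ pᵢ² (higher =
more diverse; 0 for a monoculture, 1 − 1/S for S equal species), with
plain dominance Σ pᵢ² and inverse Simpson 1/Σ pᵢ² as options. Input
vectors are renormalized, so any positive rescaling of abundances gives
identical values.

PCA operates on the column-centered matrix via SVD. Genotype PCA is
*not* variance-scaled by default (dosages share a scale); a `scale`
flag enables it. Species PCA uses the centered relative abundances by
default, with a CLR transform available for compositional treatment.
Constant features are dropped and listed. Explained variances are the
covariance eigenvalues (ddof = 1) and sum to the total centered
variance; the sign of each component is fixed by making its
largest-magnitude loading positive, which makes scores reproducible and
invariant to feature order. PC-vs-diversity correlation is Pearson with
the two-sided t p-value on n − 2 df (Spearman available).

## Association screens

* **Adjusted regression**: OLS of the transformed feature on
  [1, dosage, age, sex]; the dosage coefficient's two-sided t-test on
  n − 4 residual df is the association p. Genotypes enter as additive
  dosage {0,1,2} (dominant 0/1 coding optional). Default transforms:
  log10(x + 1e-6) for relative abundances, natural log for cytokines,
  per-feature autoscaling for metabolite intensities — all overridable,
  and the causal test reuses the same transforms so upstream hits and
  mediation see identical data.
* **FDR**: Benjamini–Hochberg step-up, applied within one screen family
  (one genotype table × one feature table), matching per-analysis
  reporting. The implementation is the literal
  q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j.
* **Mann-Whitney cytokines**: levels are natural-log transformed
  (non-positive values raise with an instruction to configure an
  offset), two-sided U test, BH across the panel, significant at
  FDR < 0.05. With both groups ≤ 8 the exact null distribution is used
  (integer count recursion; full enumeration with midranks under ties);
  larger groups use the normal approximation with tie and continuity
  corrections. The switch point reflects the combinatorial cost of
  enumeration, and the group-size regimes agree to the approximation
  error at the boundary.
* **PLS-DA VIP**: NIPALS partial least squares against the centered
  binary group code on autoscaled features, 2 components by default.
  VIPⱼ = √(p · Σₐ w²ⱼₐ SSYₐ / Σₐ SSYₐ) with SSYₐ = q²ₐ·tₐᵀtₐ, so
  Σ VIP² = p identically. Plain PLS-DA is used rather than orthogonal
  PLS: orthogonal filtering redistributes predictive variance between
  components but does not change the VIP identity or the ranking tested
  here; this is a deliberate simplification.
* **Differential metabolites**: significant iff VIP > 1 AND Welch
  t-test p < 0.05 AND fold change beyond 1.5. The fold-change cut is
  two-sided (FC > 1.5 or FC < 1/1.5) so depleted metabolites qualify —
  consistent with reporting down-shifted metabolites — with the literal
  one-sided reading behind a flag. FC is case mean / control mean on
  the raw intensity scale; the t-test runs on log10 intensities. A zero
  control mean leaves FC undefined and the feature flagged, never
  significant.

## Causal inference test

Conditions 1–3 are single-coefficient F-tests in multivariate linear
regressions; age and sex enter every model when covariates are given.

**Condition 4 (SNV ⫫ metabolite | microbe)** is an equivalence problem:
independence is the hypothesis we want to *support*, so a significant/
non-significant F on the SNV coefficient cannot serve directly. The
implemented construction compares the observed F for L in
`T ~ L + M + covariates` against a reference distribution generated
with non-mediating surrogate mediators: M*_b = fit(M | L, covariates) +
permuted residuals. Each surrogate preserves the SNV-microbe
relationship but, by construction, carries no metabolite-relevant
information beyond the SNV, so the reference F distribution describes
the conditional SNV-metabolite association *when nothing mediates*.
Under a genuine chain the real microbe absorbs the SNV-metabolite
association and no surrogate can, so F_obs falls in the far left tail
and p₄ = (1 + #{F*_b ≤ F_obs})/(B + 1) is small; under a pleiotropic
SNV the direct association survives both real and surrogate adjustment
and p₄ stays large. Two alternative constructions are selectable:
permuting instrument residuals (p₄ = 1 − permutation tail; note that
under an exact chain the observed and permuted F are exchangeable,
making that p₄ uniform rather than small — it cannot power the max-p
combination, which is why it is not the default) and a crude parametric
1 − p variant.

p_CIT = max(p₁, p₂, p₃, p₄) (asserted on every call). Under the
complete null p₁ is uniform and the max is conservative; measured
type-I at n = 200 is ≈ 0. Directionality: the test runs in both
orientations and a trio is **causal** iff forward p_CIT < α ≤ reverse
p_CIT, **reactive** for the mirror, **independent**/ **ambiguous** when
neither/both clear α = 0.05. Under a forward chain the reverse
orientation's condition 2 (SNV ~ metabolite | microbe) is exactly the
chain's conditional independence, so reverse p_CIT is uniform and the
causal label is recovered ≈ 95 − 5% of the time at strong signal.

Numerical details: B defaults to 1,000 for single trios (≥ 100
enforced; screens use 200–500), permutation seeds derive from the root
seed and trio index so each trio reproduces independently, and samples
are put in a canonical value-sorted order before permuting so p₄ is
invariant to input row order. Constant L, M or T and n < #covariates +
4 raise immediately.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: 26 cases
and 26 controls, exonic SNVs at MAF 0.05–0.30 (dosage ~ Binomial(2,
maf)), ~40 species and ~25 pathways with log-normal latent abundances
closed to per-sample compositions, ~30 log-normal metabolite
intensities, a 7-cytokine serum panel (IL-1b, IL-4, IL-6, IL-10,
IL-17a, MCP-1, TGF-b), and child-cohort covariates (age uniform on
3–12 y, sex Bernoulli(½), independent of group by default; a
`confound_age_shift` mode adds a group → age shift so covariate
adjustment can be tested under confounding).

Embedded effects, all recorded in the truth ledger:

* causal trios: microbe latent log-abundance = b₁·z(G) + ε, metabolite
  log-intensity = c₁·z(microbe) + ε (defaults b₁ = c₁ = 0.8, noise sd
  0.5);
* reactive trios: the mirrored chain through the metabolite;
* pleiotropy trios: microbe and metabolite driven by the SNV through
  independent noises — the null condition 4 must refuse to call causal;
* differential cytokines: +1 log-unit case shift on 5 of 7 cytokines.

Trio effects are injected on the **latent (pre-closure)** log scale so
the standardized slopes stay interpretable after closure; with ~40
species the closure denominator perturbs the realized correlation only
mildly. All randomness flows from one root seed through named
`SeedSequence` children (one stream per data layer, fixed order), so a
config reproduces bit-identical cohorts and byte-identical files.

What the generator does **not** emulate: real taxon co-occurrence and
phylogenetic correlation structure, sequencing zero-inflation and
depth-dependent noise, linkage disequilibrium between SNVs, batch
effects, or matched-pair sampling (covariates are drawn independently
per sample, approximating a "matched" design only in distribution).
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under its stated assumptions, not robustness to
every failure mode of real multi-omic data.

The labeled variant stream cycles through ten fate templates — one
failure per cascade rule (quality 29, depth 29, 2 alt reads, 4 bp gap
distance, control-carried, MAF exactly 0.05, 2 case carriers) and three
passes (all-boundary values 30/30/3/6 with MAF 0.049 everywhere,
database-absent, comfortable) — so any stream of ≥ 10 records exercises
both sides of every rule, and the expected verdict for each record is
recorded for exact concordance checking.

## Pipeline

One declarative YAML config drives simulate-or-ingest, triage,
diversity, screens, causal testing and reporting; every threshold
defaults to the canonical value and is validated (all problems
reported, not just the first). Each stage writes its artifacts before
the next starts; failures leave a `FAILED` marker naming the stage.
Outputs are byte-deterministic: floats are written at fixed precision,
the JSON report carries no timestamps, and timing appears only in the
log stream.

## Validation experiment sizes

The evaluation module runs the recovery experiments at sizes chosen for
stable rates at routine cost: 40-record triage streams; 1,000 null
trios (n = 200, B = 200) for type-I; 500 chain + 500 pleiotropy trios
(slopes 0.5, noise sd 0.5, n = 200, B = 500) for discrimination; and 20
independent 26 + 26 cohorts for end-to-end recovery. One caveat worth
stating: at the emulated cohort size, per-cytokine Mann-Whitney power
for a 1-log-unit shift at FDR < 0.05 is ≈ 0.9, so the per-cohort
probability of recovering ≥ 4/5 embedded cytokines is itself ≈ 0.9 —
the end-to-end success rate hovers at that value and is the least
stable of the reported quantities across root seeds.

## Known limitations

* The frequency filter trusts the supplied database tables; no liftover
  or allele-matching beyond exact (chrom, pos, ref, alt).
* No omnibus FDR across trios (each trio reports its own p_CIT); no
  multi-mediator or non-linear mediation.
* Spearman screens compute all pairs densely; very wide tables (10⁴+
  features a side) would need chunking.
* The Mann-Whitney exact branch enumerates under ties, which is only
  practical for the small-group regime it is limited to.
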