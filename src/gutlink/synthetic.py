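"""Seeded synthetic cohorts with embedded, ledgered ground truth.

The generator emulates a small two-group child cohort (cases with the
condition of interest vs typically developing controls, 26 + 26 by
default) profiled on four layers: exonic SNV genotypes, species-level
gut-microbiome relative abundances, fecal metabolite intensities, and
serum cytokine levels, plus age/sex covariates.

Embedded structure, all recorded in a :class:`SyntheticTruth` ledger:

* **causal trios** — a chain SNV -> microbe -> metabolite: the microbe's
  latent log-abundance is ``b1 * z(G) + noise`` and the metabolite's
  log-intensity is ``c1 * z(microbe) + noise``;
* **reactive trios** — the mirrored chain SNV -> metabolite -> microbe;
* **pleiotropy trios** — the SNV drives microbe and metabolite through
  independent noises (no mediation), the null a causal-inference test's
  conditional-independence condition must reject;
* **differential cytokines** — a group mean shift on the log scale.

Trio effects are injected on the latent (pre-closure) log-abundance so
the stated standardized slopes stay interpretable after the per-sample
closure to relative abundances. All randomness flows from one root seed
through named ``numpy`` SeedSequence children (one stream per layer, in
a fixed order), so identical configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import io as glio
from .variants import FrequencyTable, VariantRecord

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "Cohort",
    "CYTOKINE_PANEL",
    "generate_cohort",
    "generate_variant_stream",
    "write_cohort",
    "read_cohort",
]

#: seven-cytokine serum panel used when n_cytokines == 7
CYTOKINE_PANEL = ("IL-1b", "IL-4", "IL-6", "IL-10", "IL-17a", "MCP-1", "TGF-b")

_STREAMS = (
    "mafs", "genotypes", "species", "pathways", "metabolites",
    "cytokines", "covariates", "trios", "variant_meta",
)


class ConfigurationError(ValueError):
    """Raised for infeasible cohort configurations."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for one synthetic cohort.

    Defaults mirror the emulated study design: 26 cases vs 26 controls,
    low-MAF exonic SNVs, a seven-cytokine serum panel with five shifted
    one log-unit in cases, and a handful of embedded trios with
    standardized slopes 0.8 over noise sd 0.5.
    """

    n_case: int = 26
    n_control: int = 26
    n_snv: int = 60
    maf_range: tuple[float, float] = (0.05, 0.30)
    n_species: int = 40
    n_pathways: int = 25
    n_metabolites: int = 30
    n_cytokines: int = 7
    n_causal_trios: int = 3
    n_reactive_trios: int = 2
    n_pleiotropy_trios: int = 2
    n_diff_cytokines: int = 5
    effect_snv_to_microbe: float = 0.8
    effect_microbe_to_metabolite: float = 0.8
    cytokine_shift: float = 1.0  # log-units added to case means
    noise_sd: float = 0.5
    age_range: tuple[float, float] = (3.0, 12.0)  # years, child age band
    confound_age_shift: float = 0.0  # optional group->age shift (years)
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_case": self.n_case, "n_control": self.n_control,
            "n_snv": self.n_snv, "n_species": self.n_species,
            "n_pathways": self.n_pathways, "n_metabolites": self.n_metabolites,
            "n_cytokines": self.n_cytokines, "n_causal_trios": self.n_causal_trios,
            "n_reactive_trios": self.n_reactive_trios,
            "n_pleiotropy_trios": self.n_pleiotropy_trios,
            "n_diff_cytokines": self.n_diff_cytokines,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5):
            raise ConfigurationError(f"maf_range must lie within (0, 0.5), got {self.maf_range}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be positive, got {self.noise_sd}")
        n_trios = self.n_causal_trios + self.n_reactive_trios + self.n_pleiotropy_trios
        if n_trios > min(self.n_snv, self.n_species, self.n_metabolites):
            raise ConfigurationError(
                f"{n_trios} trios do not fit in n_snv={self.n_snv}, "
                f"n_species={self.n_species}, n_metabolites={self.n_metabolites}"
            )
        if self.n_diff_cytokines > self.n_cytokines:
            raise ConfigurationError(
                f"n_diff_cytokines={self.n_diff_cytokines} exceeds n_cytokines={self.n_cytokines}"
            )

    @property
    def n_trios(self) -> int:
        return self.n_causal_trios + self.n_reactive_trios + self.n_pleiotropy_trios


@dataclass
class SyntheticTruth:
    """Ledger of every embedded effect; nothing is injected silently."""

    trio_labels: dict = field(default_factory=dict)  # (snv, species, metabolite) -> label
    differential_features: set = field(default_factory=set)  # (kind, feature, direction)
    variant_fate: dict = field(default_factory=dict)  # variant_id -> pass | fail:<rule>
    frequency_table: Optional[FrequencyTable] = None


@dataclass
class Cohort:
    """One generated cohort; tables are pandas DataFrames indexed by sample."""

    genotypes: pd.DataFrame  # samples x SNVs, dosage {0,1,2}
    species: pd.DataFrame  # samples x species, closed relative abundances
    pathways: pd.DataFrame
    metabolites: pd.DataFrame  # raw positive intensities
    cytokines: pd.DataFrame  # raw positive levels
    covariates: pd.DataFrame  # age, sex, group
    truth: SyntheticTruth
    variant_meta: pd.DataFrame  # per-SNV VCF fields
    config: CohortConfig

    def __iter__(self):
        # supports the documented 7-tuple unpacking
        return iter(
            (self.genotypes, self.species, self.pathways, self.metabolites,
             self.cytokines, self.covariates, self.truth)
        )


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one cohort under ``config``; see the module docstring for the model."""
    rng = _rngs(config.seed)
    n = config.n_case + config.n_control
    samples = [f"asd{i + 1:03d}" for i in range(config.n_case)] + [
        f"td{i + 1:03d}" for i in range(config.n_control)
    ]
    is_case = np.array([1] * config.n_case + [0] * config.n_control)

    snv_ids = [f"snv{j + 1:04d}" for j in range(config.n_snv)]
    sp_ids = [f"sp{j + 1:03d}" for j in range(config.n_species)]
    pw_ids = [f"pw{j + 1:03d}" for j in range(config.n_pathways)]
    met_ids = [f"met{j + 1:03d}" for j in range(config.n_metabolites)]
    if config.n_cytokines == len(CYTOKINE_PANEL):
        cyt_ids = list(CYTOKINE_PANEL)
    else:
        cyt_ids = [f"cyt{j + 1:02d}" for j in range(config.n_cytokines)]

    # genotypes: per-SNV MAF uniform in range, dosage ~ Binomial(2, maf)
    mafs = rng["mafs"].uniform(*config.maf_range, size=config.n_snv)
    dosage = rng["genotypes"].binomial(2, mafs, size=(n, config.n_snv)).astype(np.int64)
    for j in range(min(config.n_trios, config.n_snv)):
        # trio SNVs must vary across samples; redraw the column if constant
        attempts = 0
        while np.ptp(dosage[:, j]) == 0:
            dosage[:, j] = rng["genotypes"].binomial(2, mafs[j], size=n)
            attempts += 1
            if attempts > 1000:  # pragma: no cover - probability ~0
                raise ConfigurationError(f"could not draw a non-constant dosage for {snv_ids[j]}")

    # latent log-abundances / log-intensities, feature-specific baselines
    sp_mu = rng["species"].uniform(-2.0, 2.0, size=config.n_species)
    sp_latent = sp_mu + rng["species"].normal(0.0, 1.0, size=(n, config.n_species))
    pw_mu = rng["pathways"].uniform(-2.0, 2.0, size=config.n_pathways)
    pw_latent = pw_mu + rng["pathways"].normal(0.0, 1.0, size=(n, config.n_pathways))
    met_mu = rng["metabolites"].normal(5.0, 1.0, size=config.n_metabolites)
    met_log = met_mu + rng["metabolites"].normal(0.0, 1.0, size=(n, config.n_metabolites))
    cyt_mu = rng["cytokines"].normal(3.0, 1.0, size=config.n_cytokines)
    cyt_log = cyt_mu + rng["cytokines"].normal(0.0, 1.0, size=(n, config.n_cytokines))

    truth = SyntheticTruth()
    b1 = config.effect_snv_to_microbe
    c1 = config.effect_microbe_to_metabolite
    inject = not (b1 == 0 and c1 == 0)

    labels = (
        ["causal"] * config.n_causal_trios
        + ["reactive"] * config.n_reactive_trios
        + ["pleiotropy"] * config.n_pleiotropy_trios
    )
    trng = rng["trios"]
    sd = config.noise_sd
    for j, label in enumerate(labels):
        if not inject:
            break
        g = _zscore(dosage[:, j].astype(float))
        if label == "causal":
            m = sp_mu[j] + b1 * g + trng.normal(0.0, sd, size=n)
            t = met_mu[j] + c1 * _zscore(m) + trng.normal(0.0, sd, size=n)
        elif label == "reactive":
            t = met_mu[j] + b1 * g + trng.normal(0.0, sd, size=n)
            m = sp_mu[j] + c1 * _zscore(t) + trng.normal(0.0, sd, size=n)
        else:  # pleiotropy: independent noises, no mediation
            m = sp_mu[j] + b1 * g + trng.normal(0.0, sd, size=n)
            t = met_mu[j] + b1 * g + trng.normal(0.0, sd, size=n)
        sp_latent[:, j] = m
        met_log[:, j] = t
        truth.trio_labels[(snv_ids[j], sp_ids[j], met_ids[j])] = label

    # differential cytokines: group shift on the log scale
    if config.cytokine_shift != 0:
        for j in range(config.n_diff_cytokines):
            cyt_log[:, j] += config.cytokine_shift * is_case
            truth.differential_features.add(("cytokines", cyt_ids[j], "up"))

    species_rel = np.exp(sp_latent)
    species_rel /= species_rel.sum(axis=1, keepdims=True)
    pathways_rel = np.exp(pw_latent)
    pathways_rel /= pathways_rel.sum(axis=1, keepdims=True)

    age = rng["covariates"].uniform(*config.age_range, size=n).round(1)
    if config.confound_age_shift:
        age = age + config.confound_age_shift * is_case
    sex = rng["covariates"].integers(0, 2, size=n)

    idx = pd.Index(samples, name="sample")
    cohort = Cohort(
        genotypes=pd.DataFrame(dosage, index=idx, columns=snv_ids),
        species=pd.DataFrame(species_rel, index=idx, columns=sp_ids),
        pathways=pd.DataFrame(pathways_rel, index=idx, columns=pw_ids),
        metabolites=pd.DataFrame(np.exp(met_log), index=idx, columns=met_ids),
        cytokines=pd.DataFrame(np.exp(cyt_log), index=idx, columns=cyt_ids),
        covariates=pd.DataFrame(
            {"age": age, "sex": sex, "group": np.where(is_case == 1, "case", "control")},
            index=idx,
        ),
        truth=truth,
        variant_meta=_variant_meta(snv_ids, rng["variant_meta"]),
        config=config,
    )
    for name in ("species", "pathways"):
        getattr(cohort, name).attrs["kind"] = name
        getattr(cohort, name).attrs["scale"] = "relative"
    cohort.metabolites.attrs.update(kind="metabolites", scale="intensity")
    cohort.cytokines.attrs.update(kind="cytokines", scale="concentration")
    return cohort


_EFFECT_CYCLE = ("nonsynonymous", "stopgain", "stoploss", "synonymous", "noncoding")
_BASES = "ACGT"


def _draw_site(rng, i):
    chrom = f"chr{1 + i % 22}"
    pos = 10_000 + 997 * i
    ref = _BASES[rng.integers(4)]
    alt = rng.choice([b for b in _BASES if b != ref])
    context = _BASES[rng.integers(4)] + ref + _BASES[rng.integers(4)]
    return chrom, pos, ref, alt, context


def _variant_meta(snv_ids, rng) -> pd.DataFrame:
    """Benign VCF-field dressing for cohort SNVs (all pass QC)."""
    rows = []
    for i, snv in enumerate(snv_ids):
        chrom, pos, ref, alt, context = _draw_site(rng, i)
        rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "base_quality": float(rng.integers(35, 60)),
                "depth": int(rng.integers(40, 200)),
                "alt_reads": int(rng.integers(10, 40)),
                "gap_distance": int(rng.integers(20, 500)),
                "gene": f"GENE{i + 1:03d}",
                "effect": _EFFECT_CYCLE[i % len(_EFFECT_CYCLE)],
                "context": context,
            }
        )
    meta = pd.DataFrame(rows, index=snv_ids)
    return meta


# ---------------------------------------------------------------------------
# labeled variant stream for the filter cascade
# ---------------------------------------------------------------------------

# (fate, overrides) templates; the base record passes every rule.
_STREAM_TEMPLATES = (
    ("fail:qc_quality", {"base_quality": 29.0}),
    ("fail:qc_depth", {"depth": 29, "alt_reads": 10}),
    ("fail:qc_alt_reads", {"alt_reads": 2}),
    ("fail:qc_gap", {"gap_distance": 5}),
    ("fail:control_carried", {"control_carriers": 1}),
    ("fail:common_maf", {"maf": {"CMDB": 0.05}}),
    ("fail:few_carriers", {"case_carriers": 2}),
    ("pass", {"boundary": True}),  # bq=30, dp=30, ao=3, gap=6, maf 0.049 everywhere
    ("pass", {"maf": {}}),  # absent from every database
    ("pass", {}),
)

STREAM_FATES = tuple(sorted({fate for fate, _ in _STREAM_TEMPLATES}))


def generate_variant_stream(
    n_records: int, seed: int
) -> tuple[list[VariantRecord], SyntheticTruth]:
    """Emit a labeled record stream spanning both sides of every filter rule.

    Records cycle through fate templates (QC failures at each threshold,
    control-carried, common-in-database, too few case carriers, and
    boundary / database-absent / comfortable passes), so any stream of at
    least 10 records exercises every declared fate at least once. The
    matching allele-frequency lookups are attached to the returned
    truth ledger (``truth.frequency_table``) alongside ``variant_fate``.
    """
    if n_records < 1:
        raise ValueError(f"n_records must be >= 1, got {n_records}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    case_pool = [f"asd{i + 1:03d}" for i in range(26)]
    control_pool = [f"td{i + 1:03d}" for i in range(26)]
    freqs = FrequencyTable()
    truth = SyntheticTruth(frequency_table=freqs)
    records = []
    for i in range(n_records):
        fate, overrides = _STREAM_TEMPLATES[i % len(_STREAM_TEMPLATES)]
        chrom, pos, ref, alt, context = _draw_site(rng, i)
        boundary = overrides.get("boundary", False)
        n_case = overrides.get("case_carriers", int(rng.integers(3, 7)))
        n_control = overrides.get("control_carriers", 0)
        rec = VariantRecord(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            base_quality=overrides.get("base_quality", 30.0 if boundary else float(rng.integers(35, 60))),
            depth=overrides.get("depth", 30 if boundary else int(rng.integers(40, 200))),
            alt_reads=overrides.get("alt_reads", 3 if boundary else int(rng.integers(10, 30))),
            gap_distance=overrides.get("gap_distance", 6 if boundary else int(rng.integers(20, 500))),
            gene=f"GENE{i + 1:03d}",
            effect=_EFFECT_CYCLE[i % len(_EFFECT_CYCLE)],
            context=context,
            carriers_case=frozenset(rng.choice(case_pool, size=n_case, replace=False)),
            carriers_control=frozenset(
                rng.choice(control_pool, size=n_control, replace=False)
            ),
        )
        if "maf" in overrides:
            for db, maf in overrides["maf"].items():
                freqs.add(chrom, pos, ref, alt, db, maf)
        elif boundary:
            for db in FrequencyTable.KNOWN_DBS:
                freqs.add(chrom, pos, ref, alt, db, 0.049)
        else:
            # default: rare in every database
            for db in FrequencyTable.KNOWN_DBS:
                freqs.add(chrom, pos, ref, alt, db, round(float(rng.uniform(0.0, 0.04)), 4))
        records.append(rec)
        truth.variant_fate[rec.variant_id] = fate
    return records, truth


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_cohort(outdir, cohort: Cohort, stream=None, stream_truth=None):
    """Write every cohort table (and an optional variant stream) under ``outdir``."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        glio.write_genotype_vcf(out / "genotypes.vcf", cohort.variant_meta, cohort.genotypes)
        for name in ("species", "pathways", "metabolites", "cytokines"):
            glio.write_feature_table(out / f"{name}.tsv", getattr(cohort, name))
        glio.write_covariates(out / "covariates.tsv", cohort.covariates)
        _write_truth(out, cohort.truth)
        if stream is not None:
            samples = sorted(
                set().union(*(r.carriers_case | r.carriers_control for r in stream))
            ) if stream else []
            glio.write_variant_vcf(out / "variant_stream.vcf", stream, samples)
            st = stream_truth
            if st is not None:
                if st.frequency_table is not None:
                    st.frequency_table.to_tsv(out / "frequencies.tsv")
                with open(out / "truth_variant_fate.tsv", "w", encoding="utf-8") as fh:
                    fh.write("variant_id\tfate\n")
                    for vid, fate in st.variant_fate.items():
                        fh.write(f"{vid}\t{fate}\n")
    except OSError as exc:
        raise OSError(f"failed writing cohort file: {exc.filename or outdir}: {exc}") from exc
    return out


def _write_truth(out, truth: SyntheticTruth):
    with open(out / "truth_trios.tsv", "w", encoding="utf-8") as fh:
        fh.write("snv_id\tspecies_id\tmetabolite_id\tlabel\n")
        for (snv, sp, met), label in sorted(truth.trio_labels.items()):
            fh.write(f"{snv}\t{sp}\t{met}\t{label}\n")
    with open(out / "truth_differential.tsv", "w", encoding="utf-8") as fh:
        fh.write("table\tfeature\tdirection\n")
        for kind, feat, direction in sorted(truth.differential_features):
            fh.write(f"{kind}\t{feat}\t{direction}\n")


def read_cohort(outdir) -> Cohort:
    """Read a written cohort back; inverse of :func:`write_cohort`."""
    import pathlib

    out = pathlib.Path(outdir)
    dosage, meta = glio.read_genotype_vcf(out / "genotypes.vcf")
    dosage = dosage[sorted(dosage.columns)]  # VCF is coordinate-sorted
    meta = meta.loc[dosage.columns]
    covariates = glio.read_covariates(out / "covariates.tsv")
    truth = SyntheticTruth()
    trios = pd.read_csv(out / "truth_trios.tsv", sep="\t")
    for row in trios.itertuples(index=False):
        truth.trio_labels[(row.snv_id, row.species_id, row.metabolite_id)] = row.label
    diffs = pd.read_csv(out / "truth_differential.tsv", sep="\t")
    for row in diffs.itertuples(index=False):
        truth.differential_features.add((row.table, row.feature, row.direction))
    return Cohort(
        genotypes=dosage,
        species=glio.read_feature_table(out / "species.tsv", kind="species"),
        pathways=glio.read_feature_table(out / "pathways.tsv", kind="pathways"),
        metabolites=glio.read_feature_table(out / "metabolites.tsv", kind="metabolites"),
        cytokines=glio.read_feature_table(out / "cytokines.tsv", kind="cytokines"),
        covariates=covariates,
        truth=truth,
        variant_meta=meta,
        config=None,
    )
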