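"""End-to-end orchestration: simulate/ingest -> filter -> composition ->
screens -> causal test -> report.

A run is driven by one declarative config (YAML on disk or a
:class:`PipelineConfig` in memory) holding either a ``simulate`` block
(cohort generator settings) or an ``inputs`` block (paths to a
multi-sample VCF, an allele-frequency TSV, and the abundance /
metabolite / cytokine / covariate tables), plus per-stage thresholds
that default to the canonical values (QC at 30/30/3/5 bp, MAF < 5%,
>= 3 case carriers, BH FDR 0.05, VIP > 1, t-test p < 0.05, FC > 1.5).

Every stage's artifacts are written before the next stage starts; a
stage failure leaves a ``FAILED`` marker naming the stage. Reruns with
the same config are byte-identical: all randomness flows from the root
seed and no artifact embeds wall-clock state (timing goes to the log
stream only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
import time
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as glio
from . import __version__
from .association import (
    DEFAULT_TRANSFORMS,
    association_screen,
    differential_metabolites,
    mannwhitney_diff,
)
from .cit import screen_trios
from .diversity import alpha_diversity, pc_correlation, pca
from .synthetic import (
    Cohort,
    CohortConfig,
    generate_cohort,
    generate_variant_stream,
    write_cohort,
)
from .variants import (
    FUNCTIONAL_EFFECTS,
    CASCADE_RULES,
    FrequencyTable,
    mutation_spectrum,
    run_cascade,
)

logger = logging.getLogger("gutlink")

__all__ = ["Thresholds", "PipelineConfig", "RunReport", "validate", "run"]


@dataclass(frozen=True)
class Thresholds:
    """Stage thresholds; defaults are the canonical analysis values."""

    min_bq: float = 30.0
    min_depth: int = 30
    min_alt: int = 3
    min_gap_dist: int = 6  # kept requires > 5 bp from the nearest gap
    max_maf: float = 0.05
    min_case_carriers: int = 3  # 'more than two' case samples
    fdr: float = 0.05
    vip_cut: float = 1.0
    p_cut: float = 0.05
    fc_cut: float = 1.5
    cit_alpha: float = 0.05
    n_perm: int = 200

    def range_errors(self) -> list[str]:
        errors = []
        if not 0.0 < self.max_maf <= 0.5:
            errors.append(f"max_maf must lie in (0, 0.5], got {self.max_maf}")
        for name in ("fdr", "p_cut", "cit_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                errors.append(f"{name} must lie in (0, 1), got {v}")
        if self.fc_cut <= 1.0:
            errors.append(f"fc_cut must exceed 1, got {self.fc_cut}")
        for name in ("min_depth", "min_alt", "min_case_carriers", "n_perm"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_perm < 100:
            errors.append(f"n_perm must be >= 100, got {self.n_perm}")
        return errors


_INPUT_KEYS = (
    "vcf", "frequencies", "species", "pathways", "metabolites", "cytokines", "covariates"
)


@dataclass
class PipelineConfig:
    outdir: str = "gutlink_out"
    seed: int = 0
    simulate: Optional[CohortConfig] = None
    inputs: Optional[dict] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_stream_records: int = 40  # simulate mode: labeled variant stream length

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.get("simulate")
        return cls(
            outdir=raw.get("outdir", "gutlink_out"),
            seed=int(raw.get("seed", 0)),
            simulate=CohortConfig(**sim) if sim is not None else None,
            inputs=raw.get("inputs"),
            thresholds=Thresholds(**raw.get("thresholds", {})),
            n_stream_records=int(raw.get("n_stream_records", 40)),
        )

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "simulate": asdict(self.simulate) if self.simulate else None,
            "inputs": dict(self.inputs) if self.inputs else None,
            "thresholds": asdict(self.thresholds),
            "n_stream_records": self.n_stream_records,
        }


@dataclass
class RunReport:
    version: str
    seed: int
    config: dict
    counts: dict
    results: dict

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "counts": self.counts,
            "results": self.results,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def validate(config: PipelineConfig) -> list[str]:
    """Schema, range, and cross-file consistency checks. Returns all problems."""
    errors = []
    if (config.simulate is None) == (config.inputs is None):
        errors.append("config must set exactly one of 'simulate' or 'inputs'")
    errors.extend(config.thresholds.range_errors())
    if config.inputs is not None:
        missing = [k for k in _INPUT_KEYS if k not in config.inputs]
        if missing:
            errors.append(f"inputs block missing keys: {missing}")
        for key in _INPUT_KEYS:
            path = config.inputs.get(key)
            if path and not pathlib.Path(path).exists():
                errors.append(f"inputs.{key}: no such file: {path}")
        if not errors:
            errors.extend(_consistency_errors(config.inputs))
    return errors


def _consistency_errors(inputs: dict) -> list[str]:
    errors = []
    try:
        covariates = glio.read_covariates(inputs["covariates"])
    except Exception as exc:
        return [f"covariates unreadable: {exc}"]
    if covariates[["age", "sex", "group"]].isna().any().any():
        bad = covariates.index[covariates[["age", "sex", "group"]].isna().any(axis=1)]
        errors.append(f"missing covariates for samples: {list(bad)}")
    cov_samples = set(covariates.index)
    for key in ("species", "pathways", "metabolites", "cytokines"):
        try:
            table = glio.read_feature_table(inputs[key])
        except Exception as exc:
            errors.append(f"{key} unreadable: {exc}")
            continue
        orphans = sorted(set(table.index) - cov_samples)
        if orphans:
            errors.append(f"{key} samples absent from covariates: {orphans}")
    return errors


def run(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline; returns the report and writes artifacts."""
    problems = validate(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    counts: dict = {}
    results: dict = {}
    stage = "start"
    try:
        stage = "ingest"
        t0 = time.perf_counter()
        cohort, stream, stream_truth, freqs = _load_or_simulate(config, out)
        _log_stage(stage, t0, samples=len(cohort.covariates), variants=len(stream))
        counts["samples"] = int(len(cohort.covariates))
        counts["stream_variants_in"] = len(stream)

        stage = "filter"
        t0 = time.perf_counter()
        th = config.thresholds
        kept, removed = run_cascade(
            stream, freqs,
            min_bq=th.min_bq, min_depth=th.min_depth, min_alt=th.min_alt,
            min_gap_dist=th.min_gap_dist, max_maf=th.max_maf,
            min_case_carriers=th.min_case_carriers,
        )
        _write_cascade(out, kept, removed)
        counts["stream_variants_kept"] = len(kept)
        counts["stream_removed_by_rule"] = {
            rule: sum(1 for _, r in removed if r == rule) for rule in CASCADE_RULES
        }
        spec = mutation_spectrum(stream)
        spec.to_frame().to_csv(out / "spectrum_96.tsv", sep="\t", index=False)
        _log_stage(stage, t0, kept=len(kept), removed=len(removed))

        stage = "diversity"
        t0 = time.perf_counter()
        functional = [
            snv for snv in cohort.genotypes.columns
            if cohort.variant_meta.loc[snv, "effect"] in FUNCTIONAL_EFFECTS
        ]
        geno_pca = pca(cohort.genotypes[functional], n_components=5)
        micro_pca = pca(cohort.species, n_components=5)
        diversity = alpha_diversity(cohort.species)
        corr_div = pc_correlation(geno_pca.scores["PC1"], diversity)
        corr_comp = pc_correlation(geno_pca.scores["PC1"], micro_pca.scores["PC1"])
        div_table = pd.DataFrame(
            {"genotype_pc1": geno_pca.scores["PC1"], "microbiome_pc1": micro_pca.scores["PC1"],
             "simpson": diversity}
        )
        glio.write_feature_table(out / "diversity.tsv", div_table)
        results["pc1_vs_diversity"] = {"r": corr_div.r, "p": corr_div.p, "n": corr_div.n}
        results["pc1_vs_microbiome_pc1"] = {"r": corr_comp.r, "p": corr_comp.p, "n": corr_comp.n}
        _log_stage(stage, t0, r=round(corr_div.r, 3), p=round(corr_div.p, 4))

        stage = "associate"
        t0 = time.perf_counter()
        screens = {}
        for kind in ("species", "pathways"):
            scr = association_screen(
                cohort.genotypes, getattr(cohort, kind), cohort.covariates,
                transform=DEFAULT_TRANSFORMS[kind],
            )
            scr.to_csv(out / f"assoc_snv_{kind}.tsv", sep="\t", index=False,
                       float_format="%.6g")
            screens[kind] = scr
            counts[f"snv_{kind}_pairs_tested"] = int(len(scr))
            counts[f"snv_{kind}_pairs_significant"] = int((scr["q"] < th.fdr).sum())
        cyt = mannwhitney_diff(cohort.cytokines, cohort.covariates, fdr_cut=th.fdr)
        cyt.to_csv(out / "diff_cytokines.tsv", sep="\t", index=False, float_format="%.6g")
        counts["cytokines_tested"] = int(len(cyt))
        counts["cytokines_significant"] = int(cyt["significant"].sum())
        mets = differential_metabolites(
            cohort.metabolites, cohort.covariates,
            vip_cut=th.vip_cut, p_cut=th.p_cut, fc_cut=th.fc_cut,
        )
        mets.to_csv(out / "diff_metabolites.tsv", sep="\t", index=False, float_format="%.6g")
        counts["metabolites_tested"] = int(len(mets))
        counts["metabolites_significant"] = int(mets["significant"].sum())
        _log_stage(stage, t0, cytokines=counts["cytokines_significant"],
                   metabolites=counts["metabolites_significant"])

        stage = "cit"
        t0 = time.perf_counter()
        hits = screens["species"][screens["species"]["q"] < th.fdr]
        diff_mets = list(mets.loc[mets["significant"], "feature_id"])
        if len(hits) == 0 or not diff_mets:
            logger.info("cit: empty candidate set (hits=%d, diff metabolites=%d)",
                        len(hits), len(diff_mets))
            trios = pd.DataFrame()
        else:
            trios = screen_trios(
                hits, cohort.genotypes, cohort.species, cohort.metabolites,
                diff_mets, cohort.covariates,
                n_perm=th.n_perm, seed=config.seed, alpha=th.cit_alpha,
            )
        trios.to_csv(out / "trios.tsv", sep="\t", index=False, float_format="%.6g")
        counts["trios_evaluated"] = int(len(trios))
        if len(trios):
            counts["trios_by_direction"] = {
                d: int((trios["direction"] == d).sum())
                for d in ("causal", "reactive", "independent", "ambiguous")
            }
        _log_stage(stage, t0, trios=len(trios))

        stage = "report"
        report = RunReport(
            version=__version__, seed=config.seed, config=config.to_dict(),
            counts=counts, results=results,
        )
        (out / "report.json").write_text(report.to_json() + "\n", encoding="utf-8")
        return report
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n", encoding="utf-8")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _load_or_simulate(config: PipelineConfig, out: pathlib.Path):
    if config.simulate is not None:
        cohort_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        cohort = generate_cohort(cohort_cfg)
        stream, stream_truth = generate_variant_stream(
            config.n_stream_records, seed=config.seed + 1
        )
        write_cohort(out / "inputs", cohort, stream=stream, stream_truth=stream_truth)
        return cohort, stream, stream_truth, stream_truth.frequency_table
    inputs = config.inputs
    dosage, meta = glio.read_genotype_vcf(inputs["vcf"])
    covariates = glio.read_covariates(inputs["covariates"])
    missing = sorted(set(dosage.index) - set(covariates.index))
    if missing:
        raise ValueError(f"VCF samples missing covariates: {missing}")
    case_ids = set(covariates.index[covariates["group"] == "case"])
    records = glio.read_variant_vcf(inputs["vcf"], case_ids,
                                    set(covariates.index) - case_ids)
    freqs = FrequencyTable.from_tsv(inputs["frequencies"])
    cohort = Cohort(
        genotypes=dosage,
        species=glio.read_feature_table(inputs["species"], kind="species"),
        pathways=glio.read_feature_table(inputs["pathways"], kind="pathways"),
        metabolites=glio.read_feature_table(inputs["metabolites"], kind="metabolites"),
        cytokines=glio.read_feature_table(inputs["cytokines"], kind="cytokines"),
        covariates=covariates,
        truth=None,
        variant_meta=meta,
        config=None,
    )
    return cohort, records, None, freqs


def _write_cascade(out, kept, removed):
    with open(out / "variants_kept.tsv", "w", encoding="utf-8") as fh:
        fh.write("variant_id\tgene\teffect\n")
        for rec in kept:
            fh.write(f"{rec.variant_id}\t{rec.gene}\t{rec.effect}\n")
    with open(out / "variants_removed.tsv", "w", encoding="utf-8") as fh:
        fh.write("variant_id\tgene\teffect\treason\n")
        for rec, reason in removed:
            fh.write(f"{rec.variant_id}\t{rec.gene}\t{rec.effect}\t{reason}\n")


def _log_stage(stage: str, t0: float, **fields):
    extras = " ".join(f"{k}={v}" for k, v in fields.items())
    logger.info("stage=%s elapsed=%.2fs %s", stage, time.perf_counter() - t0, extras)
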