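"""Readers and writers for the pipeline's on-disk formats.

Formats: VCF v4.2 for variants (INFO keys BQ, DP, AO, GAPDIST, GENE,
EFFECT, CONTEXT; per-sample GT), tab-delimited feature tables (first
column the sample id, '.' for missing), and a six-column allele-frequency
TSV. VCF reading goes through pysam; writing emits plain VCF text so
outputs are byte-stable across runs.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .variants import FrequencyTable, VariantRecord

__all__ = [
    "write_variant_vcf",
    "write_genotype_vcf",
    "read_variant_vcf",
    "read_genotype_vcf",
    "write_feature_table",
    "read_feature_table",
    "write_covariates",
    "read_covariates",
]

_VCF_INFO_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=BQ,Number=1,Type=Float,Description="Mean base quality supporting the alternate allele">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at the site">
##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate-allele read count">
##INFO=<ID=GAPDIST,Number=1,Type=Integer,Description="Distance in bp to the nearest alignment gap">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Functional class: nonsynonymous|stopgain|stoploss|synonymous|noncoding">
##INFO=<ID=CONTEXT,Number=1,Type=String,Description="Reference-strand trinucleotide context">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _vcf_header(samples: Sequence[str], contigs: Iterable[str]) -> str:
    lines = [_VCF_INFO_HEADER.rstrip("\n")]
    for contig in contigs:
        lines.append(f"##contig=<ID={contig}>")
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    cols.extend(samples)
    lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def _info_string(rec: VariantRecord) -> str:
    return (
        f"BQ={rec.base_quality:.6g};DP={rec.depth};AO={rec.alt_reads};"
        f"GAPDIST={rec.gap_distance};GENE={rec.gene};EFFECT={rec.effect};"
        f"CONTEXT={rec.context}"
    )


def write_variant_vcf(path, records: Sequence[VariantRecord], samples: Sequence[str]):
    """Write carrier-style records: carriers get GT 0/1, others 0/0."""
    contigs = sorted({r.chrom for r in records}, key=_contig_key)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_vcf_header(samples, contigs))
        for rec in sorted(records, key=lambda r: (_contig_key(r.chrom), r.pos)):
            carriers = rec.carriers_case | rec.carriers_control
            gts = ["0/1" if s in carriers else "0/0" for s in samples]
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.variant_id}\t{rec.ref}\t{rec.alt}"
                f"\t.\tPASS\t{_info_string(rec)}\tGT\t" + "\t".join(gts) + "\n"
            )


def write_genotype_vcf(path, meta: pd.DataFrame, dosage: pd.DataFrame):
    """Write a dosage matrix (samples x SNVs, values 0/1/2) as VCF.

    ``meta`` is indexed by SNV id with columns chrom, pos, ref, alt,
    base_quality, depth, alt_reads, gap_distance, gene, effect, context.
    """
    samples = list(dosage.index)
    contigs = sorted(set(meta["chrom"]), key=_contig_key)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    order = meta.assign(_k=[_contig_key(c) for c in meta["chrom"]]).sort_values(
        ["_k", "pos"]
    ).index
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_vcf_header(samples, contigs))
        for snv in order:
            row = meta.loc[snv]
            rec = VariantRecord(
                chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
                base_quality=float(row["base_quality"]), depth=int(row["depth"]),
                alt_reads=int(row["alt_reads"]), gap_distance=int(row["gap_distance"]),
                gene=row["gene"], effect=row["effect"], context=row["context"],
            )
            gts = [gt_map[int(dosage.at[s, snv])] for s in samples]
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{snv}\t{rec.ref}\t{rec.alt}\t.\tPASS\t"
                f"{_info_string(rec)}\tGT\t" + "\t".join(gts) + "\n"
            )


def _contig_key(chrom: str):
    body = chrom[3:] if chrom.startswith("chr") else chrom
    return (0, int(body)) if body.isdigit() else (1, body)


def read_variant_vcf(
    path, case_ids: Iterable[str], control_ids: Iterable[str]
) -> list[VariantRecord]:
    """Read a carrier VCF back into VariantRecord objects.

    Carrier sets are split into case/control using the supplied sample-id
    groups; samples absent from both groups raise.
    """
    case_ids, control_ids = set(case_ids), set(control_ids)
    records = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        unknown = set(vcf.header.samples) - case_ids - control_ids
        if unknown:
            raise ValueError(f"VCF samples not in case or control group: {sorted(unknown)}")
        for row in vcf:
            carriers = {
                s for s in row.samples
                if any(a and a > 0 for a in (row.samples[s]["GT"] or ()))
            }
            info = row.info
            records.append(
                VariantRecord(
                    chrom=row.chrom,
                    pos=row.pos,
                    ref=row.ref,
                    alt=row.alts[0],
                    base_quality=float(info["BQ"]),
                    depth=int(info["DP"]),
                    alt_reads=int(info["AO"]),
                    gap_distance=int(info["GAPDIST"]),
                    gene=str(info["GENE"]),
                    effect=str(info["EFFECT"]),
                    context=str(info["CONTEXT"]),
                    carriers_case=frozenset(carriers & case_ids),
                    carriers_control=frozenset(carriers & control_ids),
                )
            )
    return records


def read_genotype_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a dosage VCF: returns (dosage samples x SNVs, meta per SNV)."""
    dosages, meta_rows, snv_ids = [], [], []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        for row in vcf:
            snv_ids.append(row.id)
            info = row.info
            meta_rows.append(
                {
                    "chrom": row.chrom, "pos": row.pos, "ref": row.ref,
                    "alt": row.alts[0], "base_quality": float(info["BQ"]),
                    "depth": int(info["DP"]), "alt_reads": int(info["AO"]),
                    "gap_distance": int(info["GAPDIST"]), "gene": str(info["GENE"]),
                    "effect": str(info["EFFECT"]), "context": str(info["CONTEXT"]),
                }
            )
            dosages.append(
                [sum(a or 0 for a in (row.samples[s]["GT"] or (0, 0))) for s in samples]
            )
    dosage = pd.DataFrame(
        np.array(dosages, dtype=np.int64).T if dosages else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample"),
        columns=snv_ids,
    )
    meta = pd.DataFrame(meta_rows, index=snv_ids)
    return dosage, meta


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_feature_table(path, table: pd.DataFrame):
    """samples x features TSV; first column 'sample', '.' for missing."""
    out = table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", na_rep=".", float_format="%.12g")


def read_feature_table(path, kind: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample", na_values=["."])
    if kind is not None:
        df.attrs["kind"] = kind
    return df


def write_covariates(path, covariates: pd.DataFrame):
    out = covariates.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", na_rep=".", float_format="%.12g")


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample", na_values=["."])
    required = {"age", "sex", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: covariate table missing columns {sorted(missing)}")
    return df
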