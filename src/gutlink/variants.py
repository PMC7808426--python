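"""Rare-variant triage and mutation-spectrum summaries.

The candidate-SNV cascade mirrors a case/control exome design: per-record
QC (base quality, depth, alt-read support, distance to the nearest
alignment gap), removal of variants carried by any control sample,
a rarity filter against population allele-frequency databases, and a
minimum case-carrier count. Each rule is a pure predicate, so the final
kept set is the intersection of the individually kept sets and does not
depend on the order the rules are applied in; reported removal reasons
follow the canonical cascade order.

Mutation spectra are tabulated in the pyrimidine-reference convention:
purine-reference substitutions are reverse-complement folded so every
record lands in one of the six classes C>A, C>G, C>T, T>A, T>C, T>G and,
with its trinucleotide context, in one of 96 context bins (COSMIC-style
order A[C>A]A ... T[T>G]T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EFFECTS",
    "FUNCTIONAL_EFFECTS",
    "SUBSTITUTION_CLASSES",
    "NINETY_SIX_BINS",
    "VariantRecord",
    "FrequencyTable",
    "MutationSpectrum",
    "qc_filter",
    "remove_control_variants",
    "frequency_filter",
    "carrier_filter",
    "select_functional",
    "classify_variant",
    "run_cascade",
    "fold_substitution",
    "mutation_spectrum",
    "spectrum_similarity",
]

EFFECTS = frozenset(
    {"nonsynonymous", "stopgain", "stoploss", "synonymous", "noncoding"}
)
FUNCTIONAL_EFFECTS = frozenset({"nonsynonymous", "stopgain", "stoploss"})

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: 96 trinucleotide-context bins, class-major, then 5' base, then 3' base.
NINETY_SIX_BINS = tuple(
    f"{five}[{cls}]{three}"
    for cls in SUBSTITUTION_CLASSES
    for five in "ACGT"
    for three in "ACGT"
)
_BIN_INDEX = {b: i for i, b in enumerate(NINETY_SIX_BINS)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Canonical cascade order: the order removal reasons are reported in.
QC_RULES = ("qc_quality", "qc_depth", "qc_alt_reads", "qc_gap")
CASCADE_RULES = QC_RULES + ("control_carried", "common_maf", "few_carriers")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNV with QC fields and per-sample carrier status."""

    chrom: str
    pos: int
    ref: str
    alt: str
    base_quality: float
    depth: int
    alt_reads: int
    gap_distance: int
    gene: str
    effect: str
    context: str
    carriers_case: frozenset = frozenset()
    carriers_control: frozenset = frozenset()

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        for base, name in ((self.ref, "ref"), (self.alt, "alt")):
            if base not in _COMPLEMENT:
                raise ValueError(f"{name} must be one of ACGT, got {base!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth})"
            )
        if len(self.context) != 3 or any(b not in _COMPLEMENT for b in self.context):
            raise ValueError(f"context must be an ACGT trinucleotide, got {self.context!r}")
        if self.context[1] != self.ref:
            raise ValueError(
                f"context middle base {self.context[1]!r} != ref {self.ref!r}"
            )
        if self.effect not in EFFECTS:
            raise ValueError(
                f"unknown effect {self.effect!r}; expected one of {sorted(EFFECTS)}"
            )
        object.__setattr__(self, "carriers_case", frozenset(self.carriers_case))
        object.__setattr__(self, "carriers_control", frozenset(self.carriers_control))

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


class FrequencyTable:
    """Population allele frequencies keyed by (chrom, pos, ref, alt, db)."""

    #: database names emulating the public panels used for rarity lookups
    KNOWN_DBS = ("1000G", "ExAC", "CMDB")

    def __init__(self, entries: Mapping[tuple, float] | None = None):
        self._maf: dict[tuple, float] = {}
        if entries:
            for key, maf in entries.items():
                self.add(*key, maf)

    def add(self, chrom: str, pos: int, ref: str, alt: str, db_name: str, maf: float):
        maf = float(maf)
        if not 0.0 <= maf <= 0.5:
            raise ValueError(f"maf must lie in [0, 0.5], got {maf}")
        self._maf[(str(chrom), int(pos), ref, alt, db_name)] = maf

    def lookup(self, record: VariantRecord) -> dict[str, float]:
        """All database entries matching a variant, as {db_name: maf}."""
        out = {}
        for db in self.KNOWN_DBS:
            key = (record.chrom, record.pos, record.ref, record.alt, db)
            if key in self._maf:
                out[db] = self._maf[key]
        # also surface entries under non-standard db names
        for (c, p, r, a, db), maf in self._maf.items():
            if db not in self.KNOWN_DBS and (c, p, r, a) == (
                record.chrom,
                record.pos,
                record.ref,
                record.alt,
            ):
                out[db] = maf
        return out

    def __len__(self) -> int:
        return len(self._maf)

    def items(self):
        return self._maf.items()

    def to_tsv(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("chrom\tpos\tref\talt\tdb_name\tmaf\n")
            for (c, p, r, a, db), maf in sorted(self._maf.items()):
                fh.write(f"{c}\t{p}\t{r}\t{a}\t{db}\t{maf:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "FrequencyTable":
        table = cls()
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["chrom", "pos", "ref", "alt", "db_name", "maf"]
            if header != expected:
                raise ValueError(
                    f"{path}: expected columns {expected}, got {header}"
                )
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 6:
                    raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
                c, p, r, a, db, maf = parts
                try:
                    table.add(c, int(p), r, a, db, float(maf))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
        return table


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

def qc_filter(
    records: Iterable[VariantRecord],
    min_bq: float = 30.0,
    min_depth: int = 30,
    min_alt: int = 3,
    min_gap_dist: int = 6,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Per-record QC: kept iff bq >= 30, depth >= 30, alt reads >= 3 and
    the variant is more than 5 bp from the nearest gap.

    Removed records carry the first failing rule's tag, in cascade order.
    """
    kept, removed = [], []
    for rec in records:
        reason = _qc_reason(rec, min_bq, min_depth, min_alt, min_gap_dist)
        if reason is None:
            kept.append(rec)
        else:
            removed.append((rec, reason))
    return kept, removed


def _qc_reason(rec, min_bq, min_depth, min_alt, min_gap_dist):
    if rec.base_quality < min_bq:
        return "qc_quality"
    if rec.depth < min_depth:
        return "qc_depth"
    if rec.alt_reads < min_alt:
        return "qc_alt_reads"
    if rec.gap_distance < min_gap_dist:
        return "qc_gap"
    return None


def remove_control_variants(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Drop every variant carried by at least one control sample."""
    return [rec for rec in records if not rec.carriers_control]


def frequency_filter(
    records: Iterable[VariantRecord],
    freqs: FrequencyTable,
    max_maf: float = 0.05,
) -> list[VariantRecord]:
    """Keep variants rare in every population database.

    A variant is kept iff every matching database entry has maf strictly
    below ``max_maf``. A variant absent from all databases is kept: unseen
    in large population panels implies rarer than the cutoff.
    """
    kept = []
    for rec in records:
        mafs = freqs.lookup(rec)
        if all(maf < max_maf for maf in mafs.values()):
            kept.append(rec)
    return kept


def carrier_filter(
    records: Iterable[VariantRecord], min_case_carriers: int = 3
) -> list[VariantRecord]:
    """Keep variants detected in at least ``min_case_carriers`` case samples
    (default 3, i.e. 'more than two')."""
    return [rec for rec in records if len(rec.carriers_case) >= min_case_carriers]


def select_functional(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Protein-altering subset: non-synonymous, stop-gain, stop-loss."""
    out = []
    for rec in records:
        if rec.effect not in EFFECTS:  # defensive: records may be user-built
            raise ValueError(f"unknown effect {rec.effect!r}")
        if rec.effect in FUNCTIONAL_EFFECTS:
            out.append(rec)
    return out


def classify_variant(
    rec: VariantRecord,
    freqs: FrequencyTable,
    *,
    min_bq: float = 30.0,
    min_depth: int = 30,
    min_alt: int = 3,
    min_gap_dist: int = 6,
    max_maf: float = 0.05,
    min_case_carriers: int = 3,
) -> str:
    """Cascade verdict for one record: 'pass' or 'fail:<first failing rule>'."""
    reason = _qc_reason(rec, min_bq, min_depth, min_alt, min_gap_dist)
    if reason is not None:
        return f"fail:{reason}"
    if rec.carriers_control:
        return "fail:control_carried"
    if any(maf >= max_maf for maf in freqs.lookup(rec).values()):
        return "fail:common_maf"
    if len(rec.carriers_case) < min_case_carriers:
        return "fail:few_carriers"
    return "pass"


def run_cascade(
    records: Sequence[VariantRecord],
    freqs: FrequencyTable,
    **thresholds,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Full triage: returns (candidates, removed-with-reason)."""
    kept, removed = [], []
    for rec in records:
        verdict = classify_variant(rec, freqs, **thresholds)
        if verdict == "pass":
            kept.append(rec)
        else:
            removed.append((rec, verdict.split(":", 1)[1]))
    return kept, removed


# ---------------------------------------------------------------------------
# mutation spectra
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def fold_substitution(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    """Fold a substitution into the pyrimidine-reference convention.

    Purine-reference records (ref A or G) are mapped to the reverse
    complement; pyrimidine-reference records are returned unchanged, so
    the map is idempotent.
    """
    if ref in "AG":
        return _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(context)
    return ref, alt, context


@dataclass
class MutationSpectrum:
    """Counts over the 6 substitution classes and 96 context bins."""

    six_class: dict = field(default_factory=lambda: {c: 0 for c in SUBSTITUTION_CLASSES})
    ninety_six: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=np.int64))

    @property
    def total(self) -> int:
        return int(self.ninety_six.sum())

    def six_vector(self) -> np.ndarray:
        return np.array([self.six_class[c] for c in SUBSTITUTION_CLASSES], dtype=float)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"bin": NINETY_SIX_BINS, "count": self.ninety_six.astype(int)}
        )


def mutation_spectrum(records: Iterable[VariantRecord]) -> MutationSpectrum:
    """Tabulate six-class and 96-bin spectra with purine folding."""
    spec = MutationSpectrum()
    for rec in records:
        ref, alt, context = fold_substitution(rec.ref, rec.alt, rec.context)
        cls = f"{ref}>{alt}"
        spec.six_class[cls] += 1
        spec.ninety_six[_BIN_INDEX[f"{context[0]}[{cls}]{context[2]}"]] += 1
    return spec


def spectrum_similarity(a: MutationSpectrum, b: MutationSpectrum) -> float:
    """Cosine similarity of the two normalized 96-bin vectors, in [0, 1]."""
    va = a.ninety_six.astype(float)
    vb = b.ninety_six.astype(float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for an all-zero spectrum")
    return float(np.dot(va / na, vb / nb))
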