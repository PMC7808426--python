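"""Filter-cascade semantics and mutation-spectrum bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gutlink.variants import (
    NINETY_SIX_BINS,
    FrequencyTable,
    MutationSpectrum,
    VariantRecord,
    carrier_filter,
    classify_variant,
    fold_substitution,
    frequency_filter,
    mutation_spectrum,
    qc_filter,
    remove_control_variants,
    run_cascade,
    select_functional,
    spectrum_similarity,
)


def make_record(**kw):
    base = dict(
        chrom="chr1", pos=100, ref="C", alt="T", base_quality=45.0, depth=80,
        alt_reads=12, gap_distance=50, gene="G1", effect="nonsynonymous",
        context="ACA", carriers_case=frozenset({"a1", "a2", "a3"}),
        carriers_control=frozenset(),
    )
    base.update(kw)
    if "ref" in kw and "context" not in kw:
        base["context"] = "A" + base["ref"] + "A"
    return VariantRecord(**base)


class TestVariantRecordValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"ref": "C", "alt": "C"},
            {"pos": 0},
            {"alt_reads": 200, "depth": 80},
            {"context": "AAA"},  # middle base != ref C
            {"context": "AXA"},
            {"effect": "missense"},
        ],
    )
    def test_invalid_fields_rejected(self, kw):
        with pytest.raises(ValueError):
            make_record(**kw)


class TestQcFilter:
    @pytest.mark.parametrize(
        "fields,expected",
        [
            # all four thresholds exactly at the keep boundary
            ({"base_quality": 30.0, "depth": 30, "alt_reads": 3, "gap_distance": 6}, None),
            ({"base_quality": 29.0}, "qc_quality"),
            ({"depth": 29}, "qc_depth"),
            ({"base_quality": 35.0, "depth": 100, "alt_reads": 2, "gap_distance": 100}, "qc_alt_reads"),
            ({"base_quality": 35.0, "depth": 100, "alt_reads": 10, "gap_distance": 5}, "qc_gap"),
            # first failing rule wins when several fail
            ({"base_quality": 10.0, "depth": 5, "alt_reads": 1, "gap_distance": 0}, "qc_quality"),
        ],
    )
    def test_boundaries_and_reasons(self, fields, expected):
        kept, removed = qc_filter([make_record(**fields)])
        if expected is None:
            assert len(kept) == 1 and not removed
        else:
            assert not kept and removed[0][1] == expected

    def test_permissive_thresholds_keep_everything(self):
        recs = [make_record(base_quality=1.0, depth=2, alt_reads=0, gap_distance=0)]
        kept, removed = qc_filter(recs, min_bq=-np.inf, min_depth=0, min_alt=0, min_gap_dist=0)
        assert kept == recs and not removed

    def test_empty_input(self):
        assert qc_filter([]) == ([], [])


class TestControlAndCarrierFilters:
    def test_control_carried_removed(self):
        assert remove_control_variants([make_record(carriers_control=frozenset({"td07"}))]) == []

    def test_case_only_kept(self):
        rec = make_record(carriers_case=frozenset({"a1"}), carriers_control=frozenset())
        assert remove_control_variants([rec]) == [rec]

    def test_all_control_carried_gives_empty(self):
        recs = [make_record(pos=p, carriers_control=frozenset({"td1"})) for p in (1, 2, 3)]
        assert remove_control_variants(recs) == []

    @pytest.mark.parametrize("n_carriers,min_req,kept", [(3, 3, True), (2, 3, False), (1, 1, True)])
    def test_carrier_threshold(self, n_carriers, min_req, kept):
        rec = make_record(carriers_case=frozenset(f"a{i}" for i in range(n_carriers)))
        assert bool(carrier_filter([rec], min_case_carriers=min_req)) is kept


class TestFrequencyFilter:
    def _freqs(self, maf_by_db):
        t = FrequencyTable()
        for db, maf in maf_by_db.items():
            t.add("chr1", 100, "C", "T", db, maf)
        return t

    def test_rare_in_all_databases_kept(self):
        freqs = self._freqs({"1000G": 0.049, "ExAC": 0.049, "CMDB": 0.049})
        assert frequency_filter([make_record()], freqs) == [make_record()]

    def test_boundary_is_strict(self):
        freqs = self._freqs({"1000G": 0.001, "ExAC": 0.05, "CMDB": 0.001})
        assert frequency_filter([make_record()], freqs) == []

    def test_absent_from_every_database_kept(self):
        assert frequency_filter([make_record()], FrequencyTable()) == [make_record()]

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "freq.tsv"
        path.write_text("chrom\tpos\tref\talt\tdb_name\tmaf\nchr1\t100\tC\tT\tExAC\t0.9\n")
        with pytest.raises(ValueError, match=":2"):
            FrequencyTable.from_tsv(path)

    def test_roundtrip(self, tmp_path):
        freqs = self._freqs({"1000G": 0.01, "CMDB": 0.2})
        freqs.to_tsv(tmp_path / "f.tsv")
        back = FrequencyTable.from_tsv(tmp_path / "f.tsv")
        assert dict(back.items()) == dict(freqs.items())


class TestSelectFunctional:
    @pytest.mark.parametrize(
        "effect,kept",
        [("nonsynonymous", True), ("stopgain", True), ("stoploss", True),
         ("synonymous", False), ("noncoding", False)],
    )
    def test_protein_altering_definition(self, effect, kept):
        assert bool(select_functional([make_record(effect=effect)])) is kept

    def test_mixed_list(self):
        effects = ["stopgain", "synonymous", "noncoding", "nonsynonymous", "synonymous"]
        recs = [make_record(pos=i + 1, effect=e) for i, e in enumerate(effects)]
        assert [r.effect for r in select_functional(recs)] == ["stopgain", "nonsynonymous"]


class TestCascadeComposition:
    def test_kept_set_is_intersection_of_rules(self, labeled_stream):
        records, truth = labeled_stream
        freqs = truth.frequency_table
        kept, _ = run_cascade(records, freqs)
        qc_ids = {r.variant_id for r in qc_filter(records)[0]}
        ctrl_ids = {r.variant_id for r in remove_control_variants(records)}
        maf_ids = {r.variant_id for r in frequency_filter(records, freqs)}
        carrier_ids = {r.variant_id for r in carrier_filter(records)}
        assert {r.variant_id for r in kept} == qc_ids & ctrl_ids & maf_ids & carrier_ids

    def test_verdicts_match_generator_ledger(self, labeled_stream):
        records, truth = labeled_stream
        for rec in records:
            assert classify_variant(rec, truth.frequency_table) == truth.variant_fate[rec.variant_id]


class TestMutationSpectrum:
    def test_purine_fold_example(self):
        # G>T in context AGC folds to C>A in context GCT
        assert fold_substitution("G", "T", "AGC") == ("C", "A", "GCT")

    @given(
        ref=st.sampled_from("ACGT"),
        five=st.sampled_from("ACGT"),
        three=st.sampled_from("ACGT"),
        alt_i=st.integers(0, 2),
    )
    @settings(max_examples=100, deadline=None)
    def test_folding_is_idempotent(self, ref, five, three, alt_i):
        alt = [b for b in "ACGT" if b != ref][alt_i]
        once = fold_substitution(ref, alt, five + ref + three)
        assert fold_substitution(*once[:2], once[2]) == once

    def test_total_count_conserved(self, labeled_stream):
        records, _ = labeled_stream
        spec = mutation_spectrum(records)
        assert spec.total == len(records)
        assert sum(spec.six_class.values()) == len(records)

    def test_concentrated_spectrum(self):
        recs = [make_record(pos=i + 1, ref="C", alt="T", context="ACA") for i in range(5)]
        spec = mutation_spectrum(recs)
        assert spec.six_class == {"C>A": 0, "C>G": 0, "C>T": 5, "T>A": 0, "T>C": 0, "T>G": 0}
        assert spec.ninety_six[NINETY_SIX_BINS.index("A[C>T]A")] == 5
        assert spec.ninety_six.sum() == 5


class TestSpectrumSimilarity:
    def _spec(self, counts):
        s = MutationSpectrum()
        for bin_label, c in counts.items():
            s.ninety_six[NINETY_SIX_BINS.index(bin_label)] = c
        return s

    def test_self_similarity_is_one(self, labeled_stream):
        spec = mutation_spectrum(labeled_stream[0])
        assert spectrum_similarity(spec, spec) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_support_is_zero(self):
        a = self._spec({"A[C>A]A": 3})
        b = self._spec({"T[T>G]T": 7})
        assert spectrum_similarity(a, b) == 0.0

    def test_hand_cosine(self):
        a = self._spec({"A[C>A]A": 1, "A[C>A]C": 1})
        b = self._spec({"A[C>A]A": 1})
        assert spectrum_similarity(a, b) == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            spectrum_similarity(MutationSpectrum(), MutationSpectrum())
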