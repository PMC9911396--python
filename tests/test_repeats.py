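import numpy as np
import pandas as pd
import pytest

from ervkit.intervals import GenomicInterval
from ervkit.io import AnnotationRecord
from ervkit.repeats import (
    CountTable,
    cpm_normalize,
    cross_kd_correlation,
    expressed_lncrna_filter,
    hervh_lncrna_correlation,
    ks_two_sample,
    lncrna_hervh_overlap,
    log2_fold_change,
    make_subtype_groups,
    quantify_repeats,
    subfamily_ks_scan,
    unit_log2fc,
)


def _loci(rows):
    return pd.DataFrame(rows).set_index("locus_id")


def _table(counts, conditions, loci=None):
    counts = pd.DataFrame(counts)
    samples = pd.DataFrame(
        {"condition": conditions, "replicate": range(1, len(conditions) + 1)},
        index=counts.columns,
    )
    return CountTable(counts, samples, loci if loci is not None else pd.DataFrame())


TWO_LOCI = _loci([
    {"locus_id": "a", "chrom": "chr1", "start": 100, "end": 200, "strand": "+",
     "repeat_class": "LTR", "family": "ERV1", "subfamily": "LTR7"},
    {"locus_id": "b", "chrom": "chr1", "start": 200, "end": 300, "strand": "+",
     "repeat_class": "LTR", "family": "ERV1", "subfamily": "HERVH-int"},
])


class TestQuantify:
    def test_contained_fragment_counts_once(self):
        table = quantify_repeats({"control_1": [GenomicInterval("chr1", 120, 150)]}, TWO_LOCI)
        assert table.counts.loc["a", "control_1"] == 1
        assert table.counts.loc["b", "control_1"] == 0

    def test_spanning_fragment_increments_both(self):
        table = quantify_repeats({"control_1": [GenomicInterval("chr1", 150, 250)]}, TWO_LOCI)
        assert table.counts["control_1"].tolist() == [1, 1]

    def test_unique_assignment_mode_picks_largest_overlap(self):
        table = quantify_repeats(
            {"control_1": [GenomicInterval("chr1", 150, 250)]}, TWO_LOCI,
            unique_assignment=True,
        )
        # 50 bp in both: tie broken to the leftmost locus
        assert table.counts["control_1"].tolist() == [1, 0]

    def test_abutting_fragment_not_counted(self):
        table = quantify_repeats({"control_1": [GenomicInterval("chr1", 50, 100)]}, TWO_LOCI)
        assert table.counts["control_1"].sum() == 0

    def test_fragment_order_invariance(self, rng):
        frags = [
            GenomicInterval("chr1", int(s), int(s) + 30)
            for s in rng.integers(0, 400, size=50)
        ]
        t1 = quantify_repeats({"control_1": frags}, TWO_LOCI)
        t2 = quantify_repeats({"control_1": frags[::-1]}, TWO_LOCI)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)


class TestCpm:
    def test_known_values(self):
        table = _table({"control_1": [10, 90]}, ["control"])
        cpm = cpm_normalize(table)
        assert cpm["control_1"].tolist() == [100_000.0, 900_000.0]

    def test_columns_sum_to_one_million(self, rng):
        table = _table({"control_1": rng.integers(1, 100, 20),
                        "knockdown_1": rng.integers(1, 100, 20)},
                       ["control", "knockdown"])
        totals = cpm_normalize(table).sum(axis=0)
        assert np.allclose(totals, 1e6, atol=1e-6)

    def test_proportional_samples_have_identical_cpm(self):
        table = _table({"control_1": [10, 30], "control_2": [20, 60]},
                       ["control", "control"])
        cpm = cpm_normalize(table)
        assert cpm["control_1"].tolist() == cpm["control_2"].tolist()

    def test_zero_total_sample_named_in_error(self):
        table = _table({"control_1": [0, 0]}, ["control"])
        with pytest.raises(ValueError, match="control_1"):
            cpm_normalize(table)


class TestLog2FoldChange:
    def test_equal_means_give_zero(self):
        table = _table({"control_1": [50, 50], "knockdown_1": [50, 50]},
                       ["control", "knockdown"])
        assert log2_fold_change(table).tolist() == [0.0, 0.0]

    def test_known_cpm_ratio(self):
        # library of 1e6 makes cpm equal raw counts: kd 40 vs ctrl 10
        table = _table(
            {"control_1": [10, 999_990], "knockdown_1": [40, 999_960]},
            ["control", "knockdown"],
        )
        fc = log2_fold_change(table, pseudocount=0.5)
        assert fc.iloc[0] == pytest.approx(np.log2(40.5 / 10.5), abs=1e-9)
        assert fc.iloc[0] == pytest.approx(1.9475, abs=1e-4)

    def test_zero_in_both_conditions_gives_zero(self):
        table = _table({"control_1": [0, 100], "knockdown_1": [0, 100]},
                       ["control", "knockdown"])
        assert log2_fold_change(table).iloc[0] == 0.0


class TestKsTwoSample:
    def test_identical_multisets_give_zero_d(self):
        res = ks_two_sample([1, 2, 2, 3], [3, 2, 1, 2])
        assert res.D == 0.0

    def test_disjoint_samples_give_d_one(self):
        assert ks_two_sample([1, 2, 3], [4, 5, 6]).D == 1.0

    def test_interleaved_samples(self):
        assert ks_two_sample([1, 3], [2, 4]).D == 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_d_matches_ecdf_oracle(self, rng):
        for _ in range(300):
            x = rng.integers(0, 6, size=rng.integers(1, 9)).astype(float)
            y = rng.integers(0, 6, size=rng.integers(1, 9)).astype(float)
            d_oracle = max(
                abs((x <= t).mean() - (y <= t).mean())
                for t in np.concatenate([x, y])
            )
            assert ks_two_sample(x, y).D == pytest.approx(d_oracle, abs=1e-12)


class TestSubfamilyScan:
    def test_group_membership_partition(self, loci_frame):
        groups = make_subtype_groups(loci_frame)
        assert set(groups) == {"LINE", "SINE", "LTR", "ERV1", "LTR7/HERVH",
                               "MERs", "other-ERV1"}
        erv1 = set(groups["ERV1"])
        assert set(groups["LTR7/HERVH"]) | set(groups["MERs"]) | set(
            groups["other-ERV1"]
        ) == erv1
        assert not set(groups["LTR7/HERVH"]) & set(groups["MERs"])

    def test_self_comparison_rejected(self, loci_frame, rng):
        fc = pd.Series(rng.normal(size=len(loci_frame)), index=loci_frame.index)
        groups = make_subtype_groups(loci_frame)
        with pytest.raises(ValueError, match="self-comparison"):
            subfamily_ks_scan(fc, loci_frame,
                              groups={"MERs": groups["MERs"], "copy": groups["MERs"]},
                              reference="MERs")

    def test_background_reference_excludes_group(self, loci_frame, rng):
        fc = pd.Series(rng.normal(size=len(loci_frame)), index=loci_frame.index)
        report = subfamily_ks_scan(fc, loci_frame, reference="background")
        hervh = report.set_index("group").loc["LTR7/HERVH"]
        assert hervh.n1 == 300 and hervh.n2 == len(loci_frame) - 300

    def test_mers_reference(self, loci_frame, rng):
        fc = pd.Series(rng.normal(size=len(loci_frame)), index=loci_frame.index)
        report = subfamily_ks_scan(fc, loci_frame, reference="MERs")
        assert "MERs" not in report["group"].tolist()
        assert (report["n2"] == 300).all()


class TestCrossKdCorrelation:
    def test_perfect_anticorrelation(self, rng):
        a = pd.Series(rng.normal(size=50))
        res = cross_kd_correlation(a, -a)
        assert res.R == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        a = pd.Series(np.arange(10.0))
        with pytest.raises(ValueError, match="constant"):
            cross_kd_correlation(a, pd.Series(np.ones(10)))

    def test_too_few_shared_loci_rejected(self):
        a = pd.Series([1.0, 2.0], index=["x", "y"])
        with pytest.raises(ValueError):
            cross_kd_correlation(a, a * 2)


def _lnc(gene_id, start, end, strand="+"):
    return AnnotationRecord(GenomicInterval("chr1", start, end, strand),
                            "gene", gene_id, "", "lncRNA")


HERVH_LOCI = _loci([
    {"locus_id": "u1_ltr5", "chrom": "chr1", "start": 1000, "end": 1450, "strand": "+",
     "repeat_class": "LTR", "family": "ERV1", "subfamily": "LTR7", "unit_id": "u1"},
    {"locus_id": "u1_int", "chrom": "chr1", "start": 1450, "end": 3000, "strand": "+",
     "repeat_class": "LTR", "family": "ERV1", "subfamily": "HERVH-int", "unit_id": "u1"},
    {"locus_id": "u2_ltr5", "chrom": "chr1", "start": 10_000, "end": 10_450, "strand": "+",
     "repeat_class": "LTR", "family": "ERV1", "subfamily": "LTR7", "unit_id": "u2"},
    {"locus_id": "mer", "chrom": "chr1", "start": 5_000, "end": 5_500, "strand": "+",
     "repeat_class": "LTR", "family": "ERV1", "subfamily": "MER41A", "unit_id": None},
])


class TestLncrnaOverlap:
    def test_containing_lncrna_reported_once_per_unit(self):
        pairs = lncrna_hervh_overlap([_lnc("l1", 900, 3100)], HERVH_LOCI)
        assert pairs.values.tolist() == [["l1", "u1"]]

    def test_abutting_lncrna_not_reported(self):
        pairs = lncrna_hervh_overlap([_lnc("l1", 500, 1000)], HERVH_LOCI)
        assert pairs.empty

    def test_lncrna_spanning_two_units_gives_two_pairs(self):
        pairs = lncrna_hervh_overlap([_lnc("l1", 900, 10_100)], HERVH_LOCI)
        assert pairs.values.tolist() == [["l1", "u1"], ["l1", "u2"]]

    def test_mer_overlap_does_not_pair(self):
        pairs = lncrna_hervh_overlap([_lnc("l1", 4_900, 5_600)], HERVH_LOCI)
        assert pairs.empty

    def test_strand_matched_mode(self):
        pairs = lncrna_hervh_overlap([_lnc("l1", 900, 3100, "-")], HERVH_LOCI,
                                     stranded=True)
        assert pairs.empty


class TestExpressedFilter:
    def _table(self):
        # totals 1e6 => cpm equals raw counts; mean over two control reps
        counts = {"control_1": [1, 2, 999_997], "control_2": [1, 0, 999_999]}
        loci = _loci([
            {"locus_id": "l1", "chrom": "chr1", "start": 0, "end": 1, "strand": "+",
             "repeat_class": "lncRNA", "family": "lncRNA", "subfamily": "lncRNA"},
            {"locus_id": "l2", "chrom": "chr1", "start": 1, "end": 2, "strand": "+",
             "repeat_class": "lncRNA", "family": "lncRNA", "subfamily": "lncRNA"},
            {"locus_id": "filler", "chrom": "chr1", "start": 2, "end": 3, "strand": "+",
             "repeat_class": "other", "family": "other", "subfamily": "other"},
        ])
        counts = pd.DataFrame(counts, index=loci.index)
        samples = pd.DataFrame({"condition": ["control", "control"], "replicate": [1, 2]},
                               index=counts.columns)
        return CountTable(counts, samples, loci)

    def test_exactly_one_cpm_excluded_strictly(self):
        # l1 mean cpm = 1.0 exactly -> excluded; l2 mean = 1.0 -> excluded
        kept = expressed_lncrna_filter(self._table(), ["l1", "l2"], 1.0)
        assert kept == []

    def test_above_threshold_retained(self):
        kept = expressed_lncrna_filter(self._table(), ["l1", "l2"], 0.99)
        assert kept == ["l1", "l2"]

    def test_empty_id_list(self):
        assert expressed_lncrna_filter(self._table(), [], 1.0) == []


class TestHervhLncrnaCorrelation:
    def test_copied_fold_changes_give_r_one(self):
        pairs = pd.DataFrame({"lncrna_id": [f"l{i}" for i in range(5)],
                              "unit_id": [f"u{i}" for i in range(5)]})
        ufc = pd.Series(np.arange(5.0), index=[f"u{i}" for i in range(5)])
        lfc = pd.Series(np.arange(5.0), index=[f"l{i}" for i in range(5)])
        res, per_pair = hervh_lncrna_correlation(pairs, ufc, lfc)
        assert res.R == pytest.approx(1.0)
        assert len(per_pair) == 5

    def test_too_few_pairs_rejected(self):
        pairs = pd.DataFrame({"lncrna_id": ["l1"], "unit_id": ["u1"]})
        with pytest.raises(ValueError):
            hervh_lncrna_correlation(pairs, pd.Series({"u1": 1.0}), pd.Series({"l1": 1.0}))


class TestUnitPooling:
    def test_pooled_counts_use_library_totals(self):
        loci = HERVH_LOCI
        counts = pd.DataFrame(
            {"control_1": [100, 200, 50, 650], "knockdown_1": [200, 400, 50, 350]},
            index=loci.index,
        )
        samples = pd.DataFrame(
            {"condition": ["control", "knockdown"], "replicate": [1, 1]},
            index=counts.columns,
        )
        table = CountTable(counts, samples, loci)
        ufc = unit_log2fc(table, pseudocount=0.5)
        # totals equal (1000), so pooled cpm are raw sums * 1000
        expected_u1 = np.log2((600_000 + 0.5) / (300_000 + 0.5))
        assert ufc.loc["u1"] == pytest.approx(expected_u1, abs=1e-9)
        assert set(ufc.index) == {"u1", "u2"}
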