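import math

import numpy as np
import pytest
from scipy import stats

from ervkit.intervals import GenomicInterval, reverse_complement
from ervkit.io import AnnotationRecord, FastqRead
from ervkit.tss import (
    AnnotationIndex,
    Pwm,
    TssPeak,
    annotate_peaks,
    call_tss_clusters,
    demultiplex,
    extract_promoters,
    filter_peaks,
    motif_enrichment,
    pwm_hits,
    read_jaspar,
    stage_specific_peaks,
    trim_reads,
)

BARCODES = {"s1": "AAAAAA", "s2": "TTTTTT"}


def _read(seq, rid="r"):
    return FastqRead(rid, seq, "I" * len(seq))


class TestDemultiplex:
    def test_exact_prefix_assigned(self):
        assigned, un = demultiplex([_read("AAAAAA" + "C" * 20)], BARCODES)
        assert len(assigned["s1"]) == 1 and not un

    def test_two_mismatches_still_assigned(self):
        assigned, un = demultiplex([_read("AACCAA" + "G" * 20)], BARCODES)
        assert len(assigned["s1"]) == 1 and not un

    def test_three_mismatches_unassigned(self):
        _assigned, un = demultiplex([_read("AACCCA" + "G" * 20)], BARCODES)
        assert len(un) == 1

    def test_tie_between_barcodes_unassigned(self):
        # distance 2 to both barcodes -> conservative unassigned
        barcodes = {"a": "AAAA", "b": "AATT"}
        _assigned, un = demultiplex([_read("AAAT" + "G" * 10)], barcodes, max_mismatch=2)
        assert len(un) == 1

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            demultiplex([_read("A" * 20)], {"a": "AAAAAA", "b": "AAAAAA"})


class TestTrim:
    def test_trim_lengths(self):
        out, dropped = trim_reads([_read("A" * 150)], 11)
        assert len(out[0].seq) == 139 and dropped == 0

    def test_short_read_dropped_and_counted(self):
        out, dropped = trim_reads([_read("A" * 11)], 11)
        assert out == [] and dropped == 1

    def test_empty_input(self):
        assert trim_reads([], 11) == ([], 0)


class TestClustering:
    def test_nearby_positions_merge_with_mode(self):
        positions = [("chr1", 100, "+")] * 5 + [("chr1", 105, "+")] * 3
        peaks = call_tss_clusters(positions, merge_window=20)
        assert len(peaks) == 1
        assert peaks[0].read_support == 8
        assert peaks[0].mode_position == 100

    def test_distant_positions_split(self):
        peaks = call_tss_clusters([("chr1", 100, "+"), ("chr1", 150, "+")], 20)
        assert len(peaks) == 2

    def test_mode_tie_breaks_leftmost(self):
        positions = [("chr1", 100, "+")] * 3 + [("chr1", 104, "+")] * 3
        peaks = call_tss_clusters(positions, 20)
        assert peaks[0].mode_position == 100

    def test_opposite_strands_never_merge(self):
        peaks = call_tss_clusters([("chr1", 100, "+"), ("chr1", 100, "-")], 20)
        assert len(peaks) == 2

    def test_chained_extension_uses_current_boundary(self):
        # 100 -> 115 -> 130: each step within 20 of the boundary, one cluster
        peaks = call_tss_clusters(
            [("chr1", 100, "+"), ("chr1", 115, "+"), ("chr1", 130, "+")], 20
        )
        assert len(peaks) == 1
        assert (peaks[0].interval.start, peaks[0].interval.end) == (100, 131)


class TestFilter:
    def test_min_reads_boundary(self):
        peaks = [
            TssPeak(GenomicInterval("chr1", i, i + 1, "+"), i, support)
            for i, support in enumerate([29, 30, 31])
        ]
        kept = filter_peaks(peaks, 30)
        assert [p.read_support for p in kept] == [30, 31]

    def test_min_one_is_identity(self):
        peaks = [TssPeak(GenomicInterval("chr1", 0, 1, "+"), 0, 5)]
        assert filter_peaks(peaks, 1) == peaks

    def test_all_below_threshold(self):
        peaks = [TssPeak(GenomicInterval("chr1", 0, 1, "+"), 0, 5)]
        assert filter_peaks(peaks, 30) == []


def _gene_models():
    # + strand transcript at [10_000, 16_000): TSS at 10_000; exons at the
    # ends, 3'UTR inside the final exon
    recs = [
        AnnotationRecord(GenomicInterval("chr1", 10_000, 16_000, "+"), "transcript", "g", "t"),
        AnnotationRecord(GenomicInterval("chr1", 10_000, 10_600, "+"), "exon", "g", "t"),
        AnnotationRecord(GenomicInterval("chr1", 15_000, 16_000, "+"), "exon", "g", "t"),
        AnnotationRecord(GenomicInterval("chr1", 15_700, 16_000, "+"), "three_prime_utr",
                         "g", "t"),
    ]
    return recs


class TestAnnotate:
    def test_within_1kb_is_tss_with_signed_distance(self):
        peaks = [TssPeak(GenomicInterval("chr1", 10_500, 10_501, "+"), 10_500, 40)]
        out = annotate_peaks(peaks, _gene_models())
        assert out[0].category == "TSS"
        assert out[0].distance_to_tss == 500  # downstream of the + strand TSS

    def test_upstream_distance_is_negative(self):
        peaks = [TssPeak(GenomicInterval("chr1", 9_600, 9_601, "+"), 9_600, 40)]
        out = annotate_peaks(peaks, _gene_models())
        assert out[0].category == "TSS" and out[0].distance_to_tss == -400

    def test_intron_beyond_1kb(self):
        peaks = [TssPeak(GenomicInterval("chr1", 13_000, 13_001, "+"), 13_000, 40)]
        assert annotate_peaks(peaks, _gene_models())[0].category == "intronic"

    def test_utr_beats_exon(self):
        peaks = [TssPeak(GenomicInterval("chr1", 15_800, 15_801, "+"), 15_800, 40)]
        assert annotate_peaks(peaks, _gene_models())[0].category == "three_prime_utr"

    def test_exonic_category(self):
        peaks = [TssPeak(GenomicInterval("chr1", 15_200, 15_201, "+"), 15_200, 40)]
        assert annotate_peaks(peaks, _gene_models())[0].category == "exonic"

    def test_no_annotation_gives_intergenic(self):
        peaks = [TssPeak(GenomicInterval("chr1", 50_000, 50_001, "+"), 50_000, 40)]
        assert annotate_peaks(peaks, [])[0].category == "intergenic"

    def test_minus_strand_tss_at_transcript_end(self):
        recs = [AnnotationRecord(GenomicInterval("chr1", 1_000, 5_000, "-"),
                                 "transcript", "g", "t")]
        index = AnnotationIndex(recs)
        signed, strand = index.nearest_tss("chr1", 4_500)
        assert strand == "-" and signed == 499  # downstream along - strand


class TestPromoters:
    GENOME = None

    @classmethod
    def setup_class(cls):
        rng = np.random.default_rng(4)
        cls.GENOME = {"chr1": "".join(rng.choice(list("ACGT"), size=3000))}

    def _peak(self, pos, strand):
        return TssPeak(GenomicInterval("chr1", pos, pos + 1, strand), pos, 30)

    def test_plus_strand_window_coordinates(self):
        w = extract_promoters([self._peak(1000, "+")], self.GENOME)[0]
        assert (w.interval.start, w.interval.end) == (750, 1050)
        assert len(w.sequence) == 300 and not w.clipped
        assert w.sequence == self.GENOME["chr1"][750:1050]

    def test_minus_strand_window_mirrored_and_reverse_complemented(self):
        w = extract_promoters([self._peak(1000, "-")], self.GENOME)[0]
        assert (w.interval.start, w.interval.end) == (951, 1251)
        assert w.sequence == reverse_complement(self.GENOME["chr1"][951:1251])

    def test_both_windows_contain_the_tss_base(self):
        for strand in "+-":
            w = extract_promoters([self._peak(1000, strand)], self.GENOME)[0]
            assert w.interval.start <= w.tss_position < w.interval.end

    def test_edge_window_clipped_and_flagged(self):
        w = extract_promoters([self._peak(100, "+")], self.GENOME)[0]
        assert w.clipped and w.interval.start == 0

    def test_strand_flip_symmetry(self):
        """Mirroring the genome (reverse complement + coordinate flip) and
        flipping peak strands leaves strand-adjusted promoter sequences
        invariant."""
        L = len(self.GENOME["chr1"])
        flipped = {"chr1": reverse_complement(self.GENOME["chr1"])}
        for pos, strand in [(1000, "+"), (1500, "-"), (2000, "+")]:
            w = extract_promoters([self._peak(pos, strand)], self.GENOME)[0]
            m_strand = "-" if strand == "+" else "+"
            m = extract_promoters(
                [TssPeak(GenomicInterval("chr1", L - 1 - pos, L - pos, m_strand),
                         L - 1 - pos, 30)],
                flipped,
            )[0]
            assert m.sequence == w.sequence


class TestStageSpecific:
    def _peak(self, start, support=40, strand="+"):
        return TssPeak(GenomicInterval("chr1", start, start + 10, strand), start, support)

    def test_unique_peak_is_specific(self):
        out = stage_specific_peaks({"A": [self._peak(0)], "B": [self._peak(100)]})
        assert len(out["A"]) == 1 and len(out["B"]) == 1

    def test_overlapping_peak_not_specific(self):
        out = stage_specific_peaks({"A": [self._peak(0)], "B": [self._peak(5)]})
        assert out["A"] == [] and out["B"] == []

    def test_identical_sets_give_nothing(self):
        out = stage_specific_peaks({"A": [self._peak(0)], "B": [self._peak(0)]})
        assert out["A"] == [] and out["B"] == []

    def test_subthreshold_other_stage_does_not_block(self):
        out = stage_specific_peaks({"A": [self._peak(0, 40)], "B": [self._peak(5, 10)]})
        assert len(out["A"]) == 1

    def test_single_stage_rejected(self):
        with pytest.raises(ValueError):
            stage_specific_peaks({"A": [self._peak(0)]})


def _window(seq):
    from ervkit.tss import PromoterWindow

    return PromoterWindow(GenomicInterval("chr1", 1, 1 + len(seq), "+"), 1, seq)


class TestMotifEnrichment:
    CONSENSUS = "TGACGTCA"

    def _pwm(self):
        mat = np.full((4, len(self.CONSENSUS)), 0.01)
        for j, b in enumerate(self.CONSENSUS):
            mat["ACGT".index(b), j] = 0.97
        return Pwm("test", mat / mat.sum(axis=0))

    def test_planted_consensus_gives_clean_table(self, rng):
        fg = [_window("".join(rng.choice(list("ACGT"), 20)) + self.CONSENSUS
                      + "".join(rng.choice(list("ACGT"), 20))) for _ in range(10)]
        bg = [_window("".join(rng.choice(list("AC"), 48))) for _ in range(10)]
        report = motif_enrichment(fg, bg, [self._pwm()])
        row = report.iloc[0]
        assert (row.fg_hits, row.bg_hits) == (10, 0)
        # one-sided hypergeometric oracle for the clean 10/0 table
        assert stats.hypergeom.sf(9, 20, 10, 10) == pytest.approx(1 / math.comb(20, 10))
        assert row.p == pytest.approx(2 / math.comb(20, 10), rel=1e-6)
        assert row.significant

    def test_identical_sets_give_null_result(self, rng):
        seqs = [_window("".join(rng.choice(list("ACGT"), 40))) for _ in range(4)]
        seqs += [_window(self.CONSENSUS + "".join(rng.choice(list("ACGT"), 32)))
                 for _ in range(4)]
        report = motif_enrichment(seqs, seqs, [self._pwm()])
        assert report.iloc[0].odds_ratio == pytest.approx(1.0)
        assert report.iloc[0].p == pytest.approx(1.0)

    def test_reverse_complement_hits_count(self):
        assert pwm_hits(reverse_complement(self.CONSENSUS), self._pwm())

    def test_single_base_pwm_matches_any_occurrence(self):
        pwm = Pwm("A", np.array([[1.0], [0.0], [0.0], [0.0]]))
        assert pwm_hits("CCCAC", pwm)
        assert not pwm_hits("CCCCC", pwm)

    def test_overlong_pwm_skipped(self, rng):
        seqs = [_window("ACGTACGT")] * 3
        long_pwm = Pwm("long", np.full((4, 500), 0.25))
        report = motif_enrichment(seqs, seqs, [long_pwm])
        assert report.empty

    def test_fisher_agrees_with_hypergeometric_enumeration(self, rng):
        """Two-sided Fisher p equals summing all hypergeometric outcomes with
        probability <= that of the observed table (n <= 30)."""
        for _ in range(50):
            n_fg = int(rng.integers(1, 15))
            n_bg = int(rng.integers(1, 15))
            a = int(rng.integers(0, n_fg + 1))
            b = int(rng.integers(0, n_bg + 1))
            K, N = a + b, n_fg + n_bg
            _odds, p = stats.fisher_exact([[a, n_fg - a], [b, n_bg - b]])
            probs = [
                stats.hypergeom.pmf(k, N, K, n_fg)
                for k in range(max(0, K - n_bg), min(K, n_fg) + 1)
            ]
            obs = stats.hypergeom.pmf(a, N, K, n_fg)
            expected = sum(q for q in probs if q <= obs * (1 + 1e-9))
            assert p == pytest.approx(expected, abs=1e-9)

    def test_bh_correction_properties(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = np.sort(rng.random(20))
        q = multipletests(p, method="fdr_bh")[1]
        assert (q >= p - 1e-12).all()
        assert (np.diff(q) >= -1e-12).all()


class TestReadJaspar:
    def test_parse_counts_matrix(self, tmp_path):
        p = tmp_path / "pwm.txt"
        p.write_text(
            ">MA0001 test\n"
            "A [ 10  0 ]\n"
            "C [  0 10 ]\n"
            "G [  0  0 ]\n"
            "T [  0  0 ]\n"
        )
        pwms = read_jaspar(p)
        assert pwms[0].name == "MA0001"
        assert pwms[0].matrix[0, 0] == pytest.approx(1.0)
        assert pwms[0].matrix[1, 1] == pytest.approx(1.0)
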