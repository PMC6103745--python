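"""Peak filtering, overlap counting, shuffling and event annotation."""

import numpy as np
import pytest

from splicescreen import (
    GenomeLayout,
    GenomicInterval,
    PeakSet,
    RegionAnnotation,
    SpliceEvent,
    Transcript,
    annotate_events_with_peaks,
    assign_region,
    count_overlap,
    filter_peaks,
    overlap_permutation_test,
    shuffle_intervals,
)

from .oracles import count_overlap_quadratic


def random_peaks(rng, n, genome, max_len=400, label="P"):
    intervals = []
    chroms = sorted(genome.lengths)
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, genome[chrom] - length))
        intervals.append(GenomicInterval(chrom, start, start + length, name=f"{label}{i}"))
    return PeakSet(label, intervals, genome=genome)


class TestFilterPeaks:
    def test_significance_rule(self, peaks_factory):
        stats = [(1e-6, 10), (1e-5, 8), (2e-5, 9), (1e-7, 7), (1e-4, 12)]
        peaks = PeakSet(
            "p",
            [
                GenomicInterval("chr1", i * 100, i * 100 + 50, p_value=p, fold_enrichment=f)
                for i, (p, f) in enumerate(stats)
            ],
        )
        kept = filter_peaks(peaks)
        assert len(kept) == 2
        assert [iv.p_value for iv in kept.intervals] == [1e-6, 1e-5]

    def test_boundary_inclusive(self):
        peak = GenomicInterval("chr1", 0, 10, p_value=1e-5, fold_enrichment=8.0)
        assert len(filter_peaks(PeakSet("p", [peak]))) == 1

    def test_empty_set(self):
        assert len(filter_peaks(PeakSet("p", []))) == 0


class TestCountOverlap:
    def test_single_bp_overlap(self, peaks_factory):
        a = peaks_factory("a", [("chr1", 0, 10)])
        b = peaks_factory("b", [("chr1", 9, 20)])
        assert count_overlap(a, b) == 1

    def test_adjacent_half_open_no_overlap(self, peaks_factory):
        a = peaks_factory("a", [("chr1", 0, 10)])
        b = peaks_factory("b", [("chr1", 10, 20)])
        assert count_overlap(a, b) == 0

    def test_each_a_counted_once(self, peaks_factory):
        a = peaks_factory("a", [("chr1", 0, 100)])
        b = peaks_factory("b", [("chr1", 10, 20), ("chr1", 30, 40)])
        assert count_overlap(a, b) == 1

    def test_matches_quadratic_oracle_on_random_sets(self, toy_genome):
        rng = np.random.default_rng(17)
        for _ in range(5):
            a = random_peaks(rng, 200, toy_genome, label="A")
            b = random_peaks(rng, 200, toy_genome, label="B")
            assert count_overlap(a, b) == count_overlap_quadratic(a, b)

    def test_stranded_mode_respects_strand(self):
        a = PeakSet("a", [GenomicInterval("chr1", 0, 50, strand="+")])
        b = PeakSet("b", [GenomicInterval("chr1", 10, 30, strand="-")])
        assert count_overlap(a, b) == 1
        assert count_overlap(a, b, stranded=True) == 0


class TestShuffle:
    def test_same_seed_identical(self, toy_genome):
        rng = np.random.default_rng(18)
        peaks = random_peaks(rng, 50, toy_genome)
        s1 = shuffle_intervals(peaks, toy_genome, seed=3)
        s2 = shuffle_intervals(peaks, toy_genome, seed=3)
        assert s1.intervals == s2.intervals

    def test_lengths_and_chromosomes_conserved(self, toy_genome):
        rng = np.random.default_rng(19)
        peaks = random_peaks(rng, 80, toy_genome)
        shuffled = shuffle_intervals(peaks, toy_genome, seed=4)
        for before, after in zip(peaks.intervals, shuffled.intervals):
            assert before.chrom == after.chrom
            assert len(before) == len(after)
            assert 0 <= after.start < after.end <= toy_genome[after.chrom]

    def test_oversized_interval_rejected(self):
        genome = GenomeLayout({"chr1": 100})
        peaks = PeakSet("p", [GenomicInterval("chr1", 0, 99)])
        with pytest.raises(ValueError, match="longer"):
            shuffle_intervals(peaks, GenomeLayout({"chr1": 50}), seed=0)

    def test_pairwise_overlap_probability_matches_closed_form(self):
        # one fixed and one shuffled interval on a single chromosome:
        # P(overlap) = (lenA + lenB - 1) / (L - lenB + 1)
        genome = GenomeLayout({"chr1": 1000})
        a = PeakSet("a", [GenomicInterval("chr1", 400, 450)])
        b = PeakSet("b", [GenomicInterval("chr1", 0, 30)])
        hits = sum(
            count_overlap(a, shuffle_intervals(b, genome, seed=s)) for s in range(4000)
        )
        expected = (50 + 30 - 1) / (1000 - 30 + 1)
        assert hits / 4000 == pytest.approx(expected, abs=0.02)


class TestOverlapPermutationTest:
    def test_identical_sets_minimal_p(self, toy_genome):
        rng = np.random.default_rng(20)
        peaks = random_peaks(rng, 200, toy_genome, max_len=100)
        result = overlap_permutation_test(peaks, peaks, toy_genome, n_perm=99, seed=5)
        assert result["observed"] == 200
        assert result["p"] == pytest.approx(1 / 100)

    def test_deterministic_for_seed(self, toy_genome):
        rng = np.random.default_rng(21)
        a = random_peaks(rng, 50, toy_genome, label="A")
        b = random_peaks(rng, 50, toy_genome, label="B")
        r1 = overlap_permutation_test(a, b, toy_genome, n_perm=99, seed=6)
        r2 = overlap_permutation_test(a, b, toy_genome, n_perm=99, seed=6)
        assert r1 == r2

    def test_tiny_case_matches_exhaustive_enumeration(self):
        # one A interval, one shuffled B interval on a 60 bp chromosome:
        # enumerate every possible B start to get the exact null.
        genome = GenomeLayout({"chr1": 60})
        a = PeakSet("a", [GenomicInterval("chr1", 20, 30)])
        b = PeakSet("b", [GenomicInterval("chr1", 22, 28)])
        observed = count_overlap(a, b)
        n_positions = 60 - 6 + 1
        exact = sum(
            1
            for start in range(n_positions)
            if count_overlap(a, PeakSet("b", [GenomicInterval("chr1", start, start + 6)]))
            >= observed
        ) / n_positions
        result = overlap_permutation_test(a, b, genome, n_perm=999, seed=7)
        assert result["p"] == pytest.approx(exact, abs=3 * np.sqrt(exact * (1 - exact) / 1000) + 1e-3)

    def test_n_perm_floor(self, toy_genome):
        peaks = PeakSet("p", [GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError, match="n_perm"):
            overlap_permutation_test(peaks, peaks, toy_genome, n_perm=10)


def make_annotation():
    coding = Transcript(
        "tx1", "chr1", "+",
        ((100, 200, "5UTR"), (300, 500, "CDS"), (600, 800, "3UTR")),
    )
    overlapping = Transcript("tx2", "chr1", "+", ((520, 560, "3UTR"),))
    noncoding = Transcript("tx3", "chr2", "+", ((0, 100, "noncoding_exon"),))
    return RegionAnnotation([coding, overlapping, noncoding])


class TestAssignRegion:
    def test_midpoint_in_cds(self):
        assert assign_region(GenomicInterval("chr1", 390, 410), make_annotation()) == "CDS"

    def test_priority_3utr_over_intron(self):
        # midpoint 540: intron of tx1, 3UTR of overlapping tx2
        assert assign_region(GenomicInterval("chr1", 530, 550), make_annotation()) == "3UTR"

    def test_intron_between_exons(self):
        assert assign_region(GenomicInterval("chr1", 240, 260), make_annotation()) == "intron"

    def test_unknown_chromosome_intergenic(self):
        assert assign_region(GenomicInterval("chrX", 0, 100), make_annotation()) == "intergenic"

    def test_strand_aware_when_stranded_peak(self):
        peak = GenomicInterval("chr1", 390, 410, strand="-")
        assert assign_region(peak, make_annotation()) == "intergenic"

    def test_every_peak_gets_exactly_one_label(self):
        rng = np.random.default_rng(23)
        annotation = make_annotation()
        labels = {
            assign_region(
                GenomicInterval("chr1", int(s), int(s) + 10), annotation
            )
            for s in rng.integers(0, 1000, 50)
        }
        assert labels <= {"CDS", "3UTR", "5UTR", "noncoding_exon", "intron", "intergenic"}


def make_event(i, base):
    return SpliceEvent(
        event_id=f"ev{i}",
        gene=f"g{i}",
        etype="SE",
        chrom="chr1",
        strand="+",
        exon_start=base + 500,
        exon_end=base + 650,
        upstream_exon=(base, base + 200),
        downstream_exon=(base + 1000, base + 1200),
    )


class TestAnnotateEvents:
    def test_peak_in_downstream_intron_of_both_sets(self, se_event):
        # mirrors an exon whose flanking intron is bound by both proteins
        peak = GenomicInterval("chr3", 1500, 1550)
        cats, summary = annotate_events_with_peaks(
            [se_event], PeakSet("a", [peak]), PeakSet("b", [peak])
        )
        assert cats["ev1"] == "both"
        assert summary["both"] == 1

    def test_peak_in_upstream_exon_outside_window(self, se_event):
        peak = GenomicInterval("chr3", 450, 500)
        cats, _ = annotate_events_with_peaks(
            [se_event], PeakSet("a", [peak]), PeakSet("b", [peak])
        )
        assert cats["ev1"] == "neither"

    def test_window_boundaries_half_open(self, se_event):
        # window is (600, 2000); a peak ending exactly at 600 is outside
        before = GenomicInterval("chr3", 550, 600)
        inside = GenomicInterval("chr3", 599, 601)
        cats, _ = annotate_events_with_peaks(
            [se_event], PeakSet("a", [before]), PeakSet("b", [inside])
        )
        assert cats["ev1"] == "B_only"

    def test_planted_construction_counts(self):
        events = [make_event(i, i * 5000) for i in range(200)]
        bound = events[:36]
        peaks = [
            GenomicInterval("chr1", ev.exon_start + 10, ev.exon_start + 40) for ev in bound
        ]
        cats, summary = annotate_events_with_peaks(
            events, PeakSet("a", list(peaks)), PeakSet("b", list(peaks))
        )
        assert summary["both"] == 36
        assert summary["neither"] == 164

    def test_flank_cap_restricts_window(self, se_event):
        far_intronic = GenomicInterval("chr3", 1900, 1950)
        cats, _ = annotate_events_with_peaks(
            [se_event], PeakSet("a", [far_intronic]), PeakSet("b", []), flank_bp=100
        )
        assert cats["ev1"] == "neither"
        cats, _ = annotate_events_with_peaks(
            [se_event], PeakSet("a", [far_intronic]), PeakSet("b", [])
        )
        assert cats["ev1"] == "A_only"
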