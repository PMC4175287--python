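"""Interval operations checked against brute-force oracles on toy genomes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tssbind.genome import (
    GeneAnnotation,
    GenomeLayout,
    Peak,
    PeakSet,
    annotate_elements,
    bound_genes,
    distance_to_nearest_tss,
    distances_to_nearest_tss,
    intersect_replicates,
    random_control_peaks,
    tss_distance_histogram,
)

from conftest import random_peakset


def brute_force_intersection(a, b):
    """O(n^2) all-pairs overlap scan — the independent oracle."""
    out = []
    for pa in a:
        for pb in b:
            if pa.chrom == pb.chrom and pa.start < pb.end and pb.start < pa.end:
                out.append((pa.chrom, max(pa.start, pb.start), min(pa.end, pb.end)))
    return sorted(out)


class TestIntersectReplicates:
    def test_partial_overlap_span(self):
        layout = GenomeLayout((("chr1", 1000),))
        a = PeakSet([Peak("chr1", 100, 200)], layout)
        b = PeakSet([Peak("chr1", 150, 300)], layout)
        result = list(intersect_replicates(a, b))
        assert [(p.chrom, p.start, p.end) for p in result] == [("chr1", 150, 200)]

    def test_touching_intervals_share_no_base(self):
        layout = GenomeLayout((("chr1", 1000),))
        a = PeakSet([Peak("chr1", 100, 200)], layout)
        b = PeakSet([Peak("chr1", 200, 300)], layout)
        assert len(intersect_replicates(a, b)) == 0

    def test_matches_all_pairs_scan(self, rng):
        layout = GenomeLayout((("chr1", 1_000_000),))
        a = random_peakset(layout, 50, rng, min_len=100, max_len=5000)
        b = random_peakset(layout, 50, rng, min_len=100, max_len=5000)
        result = sorted(
            (p.chrom, p.start, p.end) for p in intersect_replicates(a, b)
        )
        assert result == brute_force_intersection(a, b)

    def test_commutative_and_bounded(self, toy_layout, rng):
        a = random_peakset(toy_layout, 30, rng)
        b = random_peakset(toy_layout, 25, rng)
        ab = sorted((p.chrom, p.start, p.end) for p in intersect_replicates(a, b))
        ba = sorted((p.chrom, p.start, p.end) for p in intersect_replicates(b, a))
        assert ab == ba
        assert len(ab) <= len(brute_force_intersection(a, b))

    def test_mismatched_namespace_raises(self):
        la = GenomeLayout((("chr1", 1000),))
        lb = GenomeLayout((("chr1", 1000), ("chr2", 1000)))
        a = PeakSet([Peak("chr1", 0, 10)], la)
        b = PeakSet([Peak("chr2", 0, 10)], lb)
        with pytest.raises(ValueError, match="chr2"):
            intersect_replicates(a, b)


class TestNearestTss:
    def test_upstream_on_plus_strand_is_negative(self):
        genes = [GeneAnnotation("g1", "chr1", "+", 1200)]
        gid, d = distance_to_nearest_tss(Peak("chr1", 900, 1100), genes)
        assert (gid, d) == ("g1", -200)

    def test_strand_mirror(self):
        genes = [GeneAnnotation("g1", "chr1", "-", 800)]
        gid, d = distance_to_nearest_tss(Peak("chr1", 900, 1100), genes)
        assert (gid, d) == ("g1", -200)

    def test_no_gene_on_chromosome_raises(self):
        with pytest.raises(ValueError, match="chr9"):
            distance_to_nearest_tss(
                Peak("chr9", 0, 10), [GeneAnnotation("g1", "chr1", "+", 5)]
            )

    def test_matches_exhaustive_search(self, toy_layout, rng):
        genes = [
            GeneAnnotation(
                f"g{i:03d}",
                toy_layout.names[int(rng.integers(2))],
                "+" if rng.random() < 0.5 else "-",
                int(rng.integers(0, 4000)),
            )
            for i in range(50)
        ]
        peaks = random_peakset(toy_layout, 200, rng)
        table = distances_to_nearest_tss(peaks, genes)
        for p, row in zip(peaks, table.itertuples()):
            same = [g for g in genes if g.chrom == p.chrom]
            expect = min(same, key=lambda g: (abs(g.tss - p.midpoint), g.gene_id))
            assert row.gene_id == expect.gene_id
            sign = 1 if expect.strand == "+" else -1
            assert row.distance == sign * (p.midpoint - expect.tss)


class TestBoundGenes:
    def test_window_boundary_inclusive(self):
        genes = [GeneAnnotation("g1", "chr1", "+", 5000)]
        layout = GenomeLayout((("chr1", 20000),))
        # midpoint of [3990, 4010) is 4000 = tss - 1000 exactly
        peaks = PeakSet([Peak("chr1", 3990, 4010)], layout)
        assert bound_genes(peaks, genes, window=1000) == {"g1"}

    def test_no_peaks_empty_set(self):
        genes = [GeneAnnotation("g1", "chr1", "+", 5000)]
        assert bound_genes(PeakSet([]), genes) == set()

    def test_monotone_in_window(self, toy_layout, rng):
        genes = [
            GeneAnnotation(f"g{i}", "chrA", "+", int(rng.integers(0, 6000)))
            for i in range(30)
        ]
        peaks = random_peakset(toy_layout, 40, rng)
        previous = set()
        for window in (50, 200, 1000, 5000):
            current = bound_genes(peaks, genes, window=window)
            assert previous <= current
            previous = current

    def test_recovers_planted_binding(self):
        # peaks planted exactly at bound TSSs, jitter < window
        layout = GenomeLayout((("chr1", 100_000),))
        genes = [
            GeneAnnotation(f"g{i:02d}", "chr1", "+", 2000 + 3000 * i)
            for i in range(30)
        ]
        planted = {g.gene_id for i, g in enumerate(genes) if i % 3 == 0}
        peaks = PeakSet(
            [
                Peak(g.chrom, g.tss - 100, g.tss + 100)
                for g in genes
                if g.gene_id in planted
            ],
            layout,
        )
        assert bound_genes(peaks, genes, window=1000) == planted


class TestAnnotateElements:
    def test_promoter_and_enhancer_windows(self):
        genes = [GeneAnnotation("g1", "chr1", "+", 50_000)]
        layout = GenomeLayout((("chr1", 200_000),))
        near = PeakSet([Peak("chr1", 49_400, 49_600)], layout)  # 500 bp upstream
        far = PeakSet([Peak("chr1", 39_900, 40_100)], layout)  # 10 kb upstream
        assert annotate_elements(near, genes).table["category"].iloc[0] == "promoter"
        assert annotate_elements(far, genes).table["category"].iloc[0] == "enhancer"

    def test_uniform_peaks_match_window_coverage(self, rng):
        # sparse genome: expected category fractions follow window lengths
        layout = GenomeLayout((("chr1", 1_000_000),))
        genes = [
            GeneAnnotation("g1", "chr1", "+", 300_000),
            GeneAnnotation("g2", "chr1", "+", 800_000),
        ]

        def dense_category(mid):
            g = min(genes, key=lambda g: (abs(g.tss - mid), g.gene_id))
            d = mid - g.tss
            if -2000 <= d <= 0:
                return "promoter"
            if -30_000 <= d < 0:
                return "enhancer"
            if 0 < d <= 30_000:
                return "gene_body"
            return "intergenic"

        n = 4000
        mids = rng.integers(0, 1_000_000 - 1, size=n)
        peaks = PeakSet([Peak("chr1", int(m), int(m) + 1) for m in mids], layout)
        ann = annotate_elements(peaks, genes)
        expected = pd.Series([dense_category(int(m)) for m in mids]).value_counts(
            normalize=True
        )
        for cat, freq in ann.frequencies.items():
            assert freq == pytest.approx(expected.get(cat, 0.0), abs=1e-9)


class TestRandomControlPeaks:
    def test_chromosome_fractions_proportional_to_length(self):
        genome = GenomeLayout((("chr1", 700_000), ("chr2", 300_000)))
        template = PeakSet([Peak("chr1", 0, 100)])
        n = 10_000
        result = random_control_peaks(n, template, genome, seed=7)
        frac = sum(p.chrom == "chr1" for p in result) / n
        sigma = np.sqrt(0.7 * 0.3 / n)
        assert abs(frac - 0.7) < 3 * sigma

    def test_deterministic_under_seed(self, toy_layout, rng):
        template = random_peakset(toy_layout, 20, rng)
        a = random_control_peaks(500, template, toy_layout, seed=3)
        b = random_control_peaks(500, template, toy_layout, seed=3)
        assert [(p.chrom, p.start, p.end) for p in a] == [
            (p.chrom, p.start, p.end) for p in b
        ]

    def test_template_lengths_resampled(self):
        genome = GenomeLayout((("chr1", 10_000),))
        template = PeakSet([Peak("chr1", 0, 100), Peak("chr1", 500, 600)])
        result = random_control_peaks(200, template, genome, seed=1)
        assert all(len(p) == 100 for p in result)

    def test_positions_uniform_chi_square(self):
        genome = GenomeLayout((("chr1", 1_000_000),))
        template = PeakSet([Peak("chr1", 0, 50)])
        result = random_control_peaks(100_000, template, genome, seed=11)
        starts = np.array([p.start for p in result])
        counts, _ = np.histogram(starts, bins=10, range=(0, 1_000_000))
        assert stats.chisquare(counts).pvalue > 0.001


class TestTssDistanceHistogram:
    def test_all_peaks_at_tss_fill_central_bin(self):
        hist = tss_distance_histogram([0.0] * 25, half_range=2000, bin_width=100)
        central = hist[(hist["bin_start"] <= 0) & (hist["bin_end"] > 0)]
        assert central["count"].iloc[0] == 25
        assert hist["count"].sum() == 25

    def test_modal_bin_contains_zero_for_centred_offsets(self, rng):
        d = rng.normal(0, 300, size=5000)
        hist = tss_distance_histogram(d, half_range=2000, bin_width=100)
        mode = hist.loc[hist["count"].idxmax()]
        assert mode["bin_start"] <= 0 < mode["bin_end"] or abs(mode["bin_start"]) <= 100

    def test_both_figure_ranges_from_one_distance_list(self, rng):
        d = rng.normal(0, 5000, size=2000)
        wide = tss_distance_histogram(d, half_range=75_000, bin_width=1000)
        narrow = tss_distance_histogram(d, half_range=2_000, bin_width=100)
        assert wide["count"].sum() <= 2000
        assert narrow["count"].sum() <= wide["count"].sum()
        # out-of-range and exact +half_range values excluded
        in_range = np.sum((d >= -2000) & (d < 2000))
        assert narrow["count"].sum() == in_range

    def test_range_must_be_multiple_of_bin(self):
        with pytest.raises(ValueError):
            tss_distance_histogram([0.0], half_range=1050, bin_width=100)


def test_layout_invariants():
    with pytest.raises(ValueError):
        GenomeLayout((("chr1", 100), ("chr1", 200)))
    with pytest.raises(ValueError):
        GenomeLayout((("chr1", 0),))
    layout = GenomeLayout((("chr1", 100), ("chr2", 200)))
    assert layout.n_basepairs == 300


def test_peak_invariants():
    with pytest.raises(ValueError):
        Peak("chr1", 10, 10)
    p = Peak("chr1", 10, 21)
    assert p.midpoint == 15
    assert p.start <= p.midpoint < p.end
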