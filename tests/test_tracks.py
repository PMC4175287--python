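"""Track similarity: dense per-base oracles, metric laws, rank statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from tssbind.genome import GenomeLayout, Peak, PeakSet
from tssbind.tracks import (
    SimilarityRanking,
    TrackLabel,
    WeightTrack,
    median_label_rank_profile,
    rank_compendium,
    rank_label_enrichment,
    similarity,
    similarity_matrix,
    track_from_peaks,
    weighted_dot,
)

from conftest import random_peakset


def random_track(layout, n_intervals, rng, label=None):
    """Random disjoint intervals with positive weights."""
    data = {}
    for chrom, L in layout.chromosomes:
        cuts = np.sort(rng.choice(L, size=2 * n_intervals, replace=False))
        starts, ends = cuts[0::2], cuts[1::2]
        keep = starts < ends
        weights = rng.random(keep.sum()) * 5
        data[chrom] = (starts[keep], ends[keep], weights)
    return WeightTrack(layout, data, label=label)


def dense_similarity(a, b, mode):
    """Per-base arrays on a toy genome — the independent oracle."""
    dot = sq_a = sq_b = tot_a = tot_b = 0.0
    for chrom, _ in a.layout.chromosomes:
        va, vb = a.dense(chrom), b.dense(chrom)
        dot += float(va @ vb)
        sq_a += float(va @ va)
        sq_b += float(vb @ vb)
        tot_a += float(va.sum())
        tot_b += float(vb.sum())
    if sq_a == 0 or sq_b == 0:
        return 0.0
    if mode == "cosine":
        return dot / np.sqrt(sq_a * sq_b)
    return a.layout.n_basepairs * dot / (tot_a**2 * tot_b**2)


class TestTrackFromPeaks:
    def test_overlap_arithmetic(self):
        layout = GenomeLayout((("chr1", 100),))
        peaks = PeakSet([Peak("chr1", 0, 10, 1.0), Peak("chr1", 5, 15, 1.0)], layout)
        track = track_from_peaks(peaks, layout)
        assert track.intervals() == [
            ("chr1", 0, 5, 1.0),
            ("chr1", 5, 10, 2.0),
            ("chr1", 10, 15, 1.0),
        ]

    def test_empty_peaks_empty_track(self, toy_layout):
        track = track_from_peaks(PeakSet([]), toy_layout)
        assert track.is_empty
        assert track.total_weight == 0.0

    def test_matches_dense_pileup(self, toy_layout, rng):
        peaks = random_peakset(toy_layout, 100, rng, scores=True)
        track = track_from_peaks(peaks, toy_layout)
        for chrom, L in toy_layout.chromosomes:
            dense = np.zeros(L)
            for p in peaks:
                if p.chrom == chrom:
                    dense[p.start : p.end] += p.score
            np.testing.assert_allclose(track.dense(chrom), dense, atol=1e-12)


class TestSimilarity:
    def test_identical_track_cosine_is_one(self, toy_layout, rng):
        t = random_track(toy_layout, 20, rng)
        assert similarity(t, t) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_tracks_zero(self):
        layout = GenomeLayout((("chr1", 100),))
        a = WeightTrack.from_intervals(layout, [("chr1", 0, 40, 1.0)])
        b = WeightTrack.from_intervals(layout, [("chr1", 50, 90, 2.0)])
        assert similarity(a, b) == 0.0
        assert similarity(a, b, mode="literal") == 0.0

    @pytest.mark.parametrize("mode", ["cosine", "literal"])
    def test_sweep_equals_dense_oracle(self, mode, rng):
        layout = GenomeLayout((("chrA", 3000), ("chrB", 2000)))
        for _ in range(30):
            a = random_track(layout, 50, rng)
            b = random_track(layout, 50, rng)
            assert similarity(a, b, mode=mode) == pytest.approx(
                dense_similarity(a, b, mode), abs=1e-12
            )

    def test_symmetry(self, toy_layout, rng):
        for _ in range(10):
            a = random_track(toy_layout, 30, rng)
            b = random_track(toy_layout, 30, rng)
            assert abs(similarity(a, b) - similarity(b, a)) < 1e-12

    def test_cosine_scale_invariance_and_bounds(self, toy_layout, rng):
        a = random_track(toy_layout, 25, rng)
        b = random_track(toy_layout, 25, rng)
        scaled = WeightTrack(
            toy_layout,
            {c: (s, e, 7.5 * w) for c, (s, e, w) in a._data.items()},
        )
        assert similarity(scaled, b) == pytest.approx(similarity(a, b), abs=1e-12)
        assert 0.0 <= similarity(a, b) <= 1.0

    def test_empty_track_scores_zero(self, toy_layout, rng):
        a = random_track(toy_layout, 10, rng)
        empty = WeightTrack(toy_layout, {})
        assert similarity(a, empty) == 0.0

    def test_layout_mismatch_raises(self, rng):
        a = random_track(GenomeLayout((("chr1", 1000),)), 5, rng)
        b = random_track(GenomeLayout((("chr1", 2000),)), 5, rng)
        with pytest.raises(ValueError, match="layout"):
            similarity(a, b)

    def test_bin_width_one_is_exact(self, toy_layout, rng):
        a = random_track(toy_layout, 20, rng)
        b = random_track(toy_layout, 20, rng)
        assert similarity(a, b, bin_width=1) == similarity(a, b)

    def test_binning_preserves_mass(self, toy_layout, rng):
        a = random_track(toy_layout, 20, rng)
        assert a.binned(100).total_weight == pytest.approx(a.total_weight)


class TestRankCompendium:
    def test_query_ranks_itself_first(self, toy_layout, rng):
        tracks = [
            random_track(toy_layout, 20, rng, label=TrackLabel("f", "", f"e{i}"))
            for i in range(5)
        ]
        ranking = rank_compendium(tracks[2], tracks)
        assert ranking.entries[0][0].experiment_id == "e2"
        assert ranking.entries[0][1] == pytest.approx(1.0, abs=1e-12)

    def test_single_track_compendium(self, toy_layout, rng):
        q = random_track(toy_layout, 10, rng, label=TrackLabel("q", "", "q"))
        t = random_track(toy_layout, 10, rng, label=TrackLabel("t", "", "t"))
        assert len(rank_compendium(q, [t]).entries) == 1

    def test_shared_generative_signal_ranks_higher(self, world, compendium):
        query, tracks = compendium
        ranking = rank_compendium(query, tracks)
        df = ranking.to_frame()
        same_model = df[df["factor"] == "POL2"]["rank"]
        random_tracks = df[df["factor"] == "RANDOM"]["rank"]
        assert same_model.median() < random_tracks.median()


class TestRankLabelEnrichment:
    @staticmethod
    def _ranking(n):
        entries = [
            (TrackLabel("f", "", f"e{i:02d}"), float(n - i)) for i in range(n)
        ]
        return SimilarityRanking(TrackLabel("query"), entries)

    def test_top_block_attains_smallest_p(self):
        n, k = 10, 3
        ranking = self._ranking(n)
        labels = {f"e{i:02d}" for i in range(k)}  # ranks 1..k
        res = rank_label_enrichment(ranking, labels, n_perm=20_000, seed=0)
        assert res["statistic"] == pytest.approx((k + 1) / 2)
        # smallest achievable configuration: p near 1/C(n,k) plus smoothing
        assert res["p_permutation"] < 3.0 / 120

    def test_matches_exhaustive_enumeration_n6_k2(self):
        ranking = self._ranking(6)
        labels = {"e00", "e01"}  # observed mean rank 1.5
        res = rank_label_enrichment(ranking, labels, n_perm=100_000, seed=0)
        exact_p = sum(
            1
            for pair in itertools.combinations(range(1, 7), 2)
            if np.mean(pair) <= 1.5
        ) / 15
        assert exact_p == 1 / 15
        assert res["p_permutation"] == pytest.approx(exact_p, abs=0.01)

    def test_null_labelling_p_uniform(self, rng):
        n, k = 20, 5
        ranking = self._ranking(n)
        ids = [f"e{i:02d}" for i in range(n)]
        ps = []
        for _ in range(200):
            labels = set(rng.choice(ids, size=k, replace=False))
            res = rank_label_enrichment(ranking, labels, n_perm=999, seed=rng)
            ps.append(res["p_permutation"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_permutation_and_mannwhitney_agree(self, rng):
        n, k = 60, 12
        ranking = self._ranking(n)
        labels = {f"e{i:02d}" for i in rng.choice(n, size=k, replace=False)}
        res = rank_label_enrichment(ranking, labels, n_perm=50_000, seed=1)
        lo = min(res["p_permutation"], res["p_mannwhitney"])
        hi = max(res["p_permutation"], res["p_mannwhitney"])
        assert hi / lo < 3

    def test_unknown_labels_raise(self):
        ranking = self._ranking(5)
        with pytest.raises(ValueError, match="zz"):
            rank_label_enrichment(ranking, {"zz"}, n_perm=10, seed=0)


class TestMedianLabelRankProfile:
    def test_hand_computed_three_tracks(self):
        layout = GenomeLayout((("chr1", 100),))
        a = WeightTrack.from_intervals(
            layout, [("chr1", 0, 50, 1.0)], TrackLabel("POL2", "", "a")
        )
        b = WeightTrack.from_intervals(
            layout, [("chr1", 0, 40, 1.0)], TrackLabel("POL2", "", "b")
        )
        c = WeightTrack.from_intervals(
            layout, [("chr1", 60, 100, 1.0)], TrackLabel("X", "", "c")
        )
        # a vs b: cos = 40/sqrt(50*40); a vs c: 0; b vs c: 0
        profile = median_label_rank_profile([a, b, c], "POL2")
        med = dict(zip(profile["experiment_id"], profile["median_label_rank"]))
        assert med["a"] == 1  # b ranks first among {b, c}
        assert med["b"] == 1
        # query c: both others are POL2, scores 0 vs 0, tie broken by id -> a, b
        assert med["c"] == 1  # lower median of ranks {1, 2}
        # c (the non-POL2 query with zero overlap) must not sort above a or b
        assert list(profile["experiment_id"][:2]) != ["c", "c"]

    def test_query_without_labelled_others_gets_nan(self):
        layout = GenomeLayout((("chr1", 100),))
        a = WeightTrack.from_intervals(
            layout, [("chr1", 0, 50, 1.0)], TrackLabel("POL2", "", "a")
        )
        c = WeightTrack.from_intervals(
            layout, [("chr1", 60, 100, 1.0)], TrackLabel("X", "", "c")
        )
        profile = median_label_rank_profile([a, c], "POL2")
        row_a = profile[profile["experiment_id"] == "a"]
        assert np.isnan(row_a["median_label_rank"].iloc[0])
        assert profile["experiment_id"].iloc[-1] == "a"  # NaN sorts last

    def test_expression_weighted_query_beats_random_queries(self, compendium):
        query, tracks = compendium
        S = similarity_matrix([query] + tracks)
        profile = median_label_rank_profile([query] + tracks, "POL2", S=S)
        med = dict(zip(profile["experiment_id"], profile["median_label_rank"]))
        random_ids = [t.label.experiment_id for t in tracks if t.label.factor == "RANDOM"]
        assert all(med["QUERY"] < med[r] for r in random_ids)


def test_weighted_dot_symmetric_random_pairs(toy_layout, rng):
    for _ in range(5):
        a = random_track(toy_layout, 15, rng)
        b = random_track(toy_layout, 15, rng)
        assert weighted_dot(a, b) == pytest.approx(weighted_dot(b, a), rel=1e-12)
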