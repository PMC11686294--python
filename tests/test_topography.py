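"""Basins, paths, distances, epistasis squares, one-hot PCA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tfbscape import (
    all_basins,
    basin_of_attraction,
    basin_overlap,
    build_network,
    classify_epistasis,
    enumerate_shortest_paths,
    enumerate_squares,
    epistasis_summary,
    find_peaks,
    make_additive_landscape,
    onehot_pca,
    pairwise_distance_distribution,
    shortest_accessible_path_length,
)
from tfbscape.exceptions import DataError
from tfbscape.topography import Basin, orient_square

from _utils import brute_force_accessible_paths, random_landscape, small_space
from test_synthetic import uniform_weights


def additive_landscape(L, seed):
    sp = small_space(L)
    truth = make_additive_landscape(sp, uniform_weights(sp, np.random.default_rng(seed)))
    return build_network(truth.scores, sp)


class TestBasins:
    def test_path_graph_basin(self, space2):
        land = build_network(pd.Series({"AA": 1.0, "AC": 2.0, "CC": 3.0}), space2)
        b = basin_of_attraction(land, "CC")
        assert b.members == {"AA", "AC"}
        assert b.size == 2 and b.fraction == 1.0

    def test_non_peak_rejected(self, space2):
        land = build_network(pd.Series({"AA": 1.0, "AC": 2.0}), space2)
        with pytest.raises(DataError, match="not a peak"):
            basin_of_attraction(land, "AA")

    @pytest.mark.parametrize("L", [3, 4])
    def test_additive_unique_peak_basin_is_everything(self, L):
        """The single peak of an additive landscape is accessible from every
        non-peak genotype."""
        land = additive_landscape(L, seed=L)
        peaks, _ = find_peaks(land)
        assert len(peaks) == 1
        b = basin_of_attraction(land, peaks[0])
        assert b.size == len(land) - 1
        assert b.fraction == 1.0

    def test_membership_closed_under_uphill_reachability(self):
        land = random_landscape(3, seed=4)
        peaks, _ = find_peaks(land)
        target = max(peaks, key=lambda g: land.scores[land.index[g]])
        b = basin_of_attraction(land, target)
        # every node on an accessible path is itself in the basin:
        # predecessors of members (or of the peak) that can step uphill
        # into the basin must be members too
        member_idx = {land.index[g] for g in b.members} | {land.index[target]}
        for v in list(member_idx):
            for u in land.allowed_in(v):
                if not land.is_peak_[u]:
                    assert str(land.genotypes[u]) in b.members


class TestBasinOverlap:
    def test_jaccard_cases(self):
        mk = lambda members: Basin("P", frozenset(members), 10)
        assert basin_overlap(mk("abc"), mk("abc")) == 1.0
        assert basin_overlap(mk("ab"), mk("cd")) == 0.0
        assert basin_overlap(mk("abc"), mk("bcd")) == 0.5

    def test_both_empty_is_error(self):
        empty = Basin("P", frozenset(), 10)
        with pytest.raises(DataError):
            basin_overlap(empty, empty)


class TestAccessiblePaths:
    def test_adjacent_downhill_neighbor(self, space2):
        land = build_network(pd.Series({"AA": 1.0, "AC": 2.0}), space2)
        assert shortest_accessible_path_length(land, "AA", "AC") == 1

    def test_detour_fixture(self):
        """Both geodesic intermediates are downhill, so the shortest
        accessible path routes each position through a third allele and is
        Hamming distance + 2."""
        sp = small_space(2)
        scores = pd.Series(
            {
                "AA": 1.0,  # src, Hamming distance 2 from the peak CC
                "AC": 0.5,  # geodesic intermediate, downhill
                "CA": 0.6,  # geodesic intermediate, downhill
                "GA": 1.2,  # detour: AA -> GA -> GG -> CG -> CC
                "GG": 1.4,
                "CG": 1.6,
                "CC": 2.0,  # peak
            }
        )
        land = build_network(scores, sp)
        assert shortest_accessible_path_length(land, "AA", "CC") == 4
        assert land.space.hamming("AA", "CC") == 2
        # and the geodesics themselves are counted but inaccessible
        assert enumerate_shortest_paths(land, "AA", "CC") == (2, 0)

    def test_accessible_length_bounds(self):
        land = random_landscape(3, seed=11)
        peaks, _ = find_peaks(land)
        rng = np.random.default_rng(0)
        starts = rng.choice(land.genotypes, 10, replace=False)
        for src in starts:
            for peak in peaks[:5]:
                if src == peak:
                    continue
                acc = shortest_accessible_path_length(land, src, peak)
                if acc is not None:
                    d = land.space.hamming(src, peak)
                    assert acc >= d


class TestShortestPathCensus:
    @pytest.mark.parametrize("L, d", [(3, 2), (3, 3), (4, 4)])
    def test_complete_space_total_is_d_factorial(self, L, d):
        land = additive_landscape(L, seed=d)
        src = "A" * L
        dst = "C" * d + "A" * (L - d)
        n_total, n_acc = enumerate_shortest_paths(land, src, dst)
        assert n_total == math.factorial(d)
        assert 0 <= n_acc <= n_total

    def test_distance_one_single_path(self, space2):
        land = build_network(pd.Series({"AA": 1.0, "AC": 2.0}), space2)
        assert enumerate_shortest_paths(land, "AA", "AC") == (1, 1)

    def test_additive_all_paths_to_global_peak_accessible(self):
        land = additive_landscape(4, seed=1)
        peaks, _ = find_peaks(land)
        peak = peaks[0]
        rng = np.random.default_rng(2)
        for src in rng.choice(land.genotypes, 5, replace=False):
            if src == peak:
                continue
            n_total, n_acc = enumerate_shortest_paths(land, src, peak)
            assert n_total == math.factorial(land.space.hamming(src, peak))
            assert n_acc == n_total

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_explicit_enumeration_oracle(self, seed):
        """DP path counting equals explicit path enumeration on small
        subsampled landscapes."""
        land = random_landscape(3, seed=seed, frac=0.8)
        rng = np.random.default_rng(seed)
        genos = rng.choice(land.genotypes, 6, replace=False)
        checked = 0
        for src, dst in itertools.combinations(genos, 2):
            try:
                got = enumerate_shortest_paths(land, src, dst)
            except DataError:
                continue  # different components
            want = brute_force_accessible_paths(land, src, dst)
            assert got == want
            checked += 1
        assert checked >= 5


class TestPairwiseDistances:
    def test_single_pair(self):
        hist, mean = pairwise_distance_distribution(["AAAA", "AAAT"])
        assert hist.to_dict() == {1: 1}
        assert mean == 1.0

    def test_complete_space_mean_matches_closed_form(self, space2):
        """Over distinct unordered pairs of the complete space the mean
        Hamming distance is (3L/4) * n/(n-1): per position two uniform
        genotypes differ w.p. 3/4, and self-pairs are excluded."""
        hist, mean = pairwise_distance_distribution(space2.all_genotypes())
        assert mean == pytest.approx((2 * 3 / 4) * 16 / 15)
        assert hist.sum() == 16 * 15 // 2

    def test_chunked_equals_direct(self):
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(700)]
        seqs = list(dict.fromkeys(seqs))
        hist, mean = pairwise_distance_distribution(seqs)
        direct = [
            sum(a != b for a, b in zip(x, y))
            for x, y in itertools.combinations(seqs, 2)
        ]
        assert mean == pytest.approx(np.mean(direct))
        assert hist.sum() == len(direct)


class TestEpistasis:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ((0.0, 1.0, 1.0, 2.0), "no_sign"),  # additive
            ((0.0, -1.0, -1.0, 1.0), "reciprocal_sign"),
            ((0.0, -1.0, 0.5, 1.0), "simple_sign"),
            ((0.0, 0.2, 1.5, 2.0), "no_sign"),  # magnitude
        ],
    )
    def test_classification(self, scores, expected):
        assert classify_epistasis(*scores) == expected

    def test_orientation_required(self):
        with pytest.raises(DataError, match="oriented"):
            classify_epistasis(3.0, 1.0, 1.0, 2.0)

    def test_orient_square(self):
        corners = ["AA", "CA", "AC", "CC"]
        scores = [3.0, -1.0, -1.0, 0.0]
        (g, ga, gb, gab), vals = orient_square(corners, scores)
        assert gab == "AA" and g == "CC"
        assert vals == [0.0, -1.0, -1.0, 3.0]
        assert classify_epistasis(*vals) == "reciprocal_sign"

    def test_complete_l2_square_census(self, space2):
        """Square count equals the brute-force 4-cycle census: choose 2
        alleles per position -> C(4,2)^2 = 36 squares for L = 2."""
        land = random_landscape(2, seed=0)
        squares = list(enumerate_squares(land))
        assert len(squares) == 36
        for sq in squares:
            corners = [sq.background, sq.single_a, sq.single_b, sq.double]
            assert len(set(corners)) == 4
            d = land.space.hamming(sq.background, sq.double)
            assert d == 2

    def test_additive_has_no_sign_epistasis(self):
        land = additive_landscape(3, seed=6)
        summary = epistasis_summary(land)
        assert summary["proportions"]["no_sign"] == pytest.approx(1.0)
        assert summary["counts"]["simple_sign"] == 0
        assert summary["counts"]["reciprocal_sign"] == 0

    def test_class_proportions_partition(self):
        land = random_landscape(3, seed=13, frac=0.7)
        summary = epistasis_summary(land)
        assert sum(summary["proportions"].values()) == pytest.approx(1.0)
        assert sum(summary["counts"].values()) == summary["n_squares"]

    def test_multipeaked_complete_landscape_has_reciprocal_sign(self):
        """>= 2 peaks on a complete landscape requires reciprocal sign
        epistasis somewhere."""
        for seed in range(5):
            land = random_landscape(3, seed=seed)
            find_peaks(land)
            if land.n_peaks_ >= 2:
                summary = epistasis_summary(land)
                assert summary["counts"]["reciprocal_sign"] > 0


class TestOneHotPCA:
    def test_two_points_single_axis(self):
        coords, evr = onehot_pca(["AAAA", "CCCC"])
        assert evr[0] == pytest.approx(1.0)
        assert coords.shape[0] == 2

    def test_identical_genotypes_rejected(self):
        with pytest.raises(DataError, match="variance"):
            onehot_pca(["AAAA", "AAAA"])

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(21)
        seqs = list({"".join(rng.choice(list("ACGT"), 6)) for _ in range(60)})
        coords, evr = onehot_pca(seqs)
        assert np.sum(evr) == pytest.approx(1.0, abs=1e-9)
        assert coords.shape == (len(seqs), len(evr))
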