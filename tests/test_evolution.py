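"""Adaptive walk engines, Kimura fixation probabilities, summaries."""

import numpy as np
import pandas as pd
import pytest

from tfbscape import (
    WalkConfig,
    apply_noise_model,
    basin_of_attraction,
    build_network,
    find_peaks,
    greedy_walk,
    kimura_fixation_probability,
    kimura_walk,
    make_additive_landscape,
    noise_sweep,
    run_walks,
    uniform_walk,
    uniform_walk_endpoint_distribution,
    walk_summary,
)
from tfbscape.exceptions import ConfigurationError
from tfbscape.landscape import Landscape

from _utils import random_landscape, small_space
from test_synthetic import uniform_weights


def path_landscape():
    sp = small_space(2)
    return build_network(pd.Series({"AA": 1.0, "AC": 2.0, "CC": 3.0}), sp)


class TestGreedyWalk:
    def test_path_graph(self):
        land = path_landscape()
        res = greedy_walk(land, "AA")
        assert res.trajectory == ["AA", "AC", "CC"]
        assert res.steps == 2
        assert res.selection_coefficients == [1.0, 1.0]

    def test_start_at_peak_zero_steps(self):
        land = path_landscape()
        res = greedy_walk(land, "CC")
        assert res.trajectory == ["CC"] and res.steps == 0

    def test_deterministic_and_strictly_increasing(self):
        land = random_landscape(3, seed=3, frac=0.8)
        find_peaks(land)
        start = str(land.genotypes[~land.is_peak_][0])
        a = greedy_walk(land, start)
        b = greedy_walk(land, start)
        assert a.trajectory == b.trajectory
        scores = [land.scores[land.index[g]] for g in a.trajectory]
        assert np.all(np.diff(scores) > 0)
        assert land.is_peak_[land.index[a.endpoint]]

    def test_lexicographic_tie_break(self):
        sp = small_space(1)
        land = build_network(
            pd.Series({"A": 0.0, "C": 1.0, "T": 1.0, "G": -1.0}), sp
        )
        assert greedy_walk(land, "A").endpoint == "C"  # C < T


class TestUniformWalk:
    def test_single_uphill_neighbor_forced(self):
        land = path_landscape()
        res = uniform_walk(land, "AC", np.random.default_rng(0))
        assert res.trajectory == ["AC", "CC"]

    def test_two_uphill_neighbors_balanced(self):
        sp = small_space(1)
        land = build_network(
            pd.Series({"A": 0.0, "C": 1.0, "T": 1.5, "G": -1.0}), sp
        )
        rng = np.random.default_rng(42)
        first = [uniform_walk(land, "A", rng).trajectory[1] for _ in range(4000)]
        frac_c = np.mean([f == "C" for f in first])
        assert abs(frac_c - 0.5) < 3 * np.sqrt(0.25 / 4000)

    @pytest.mark.parametrize("seed", range(4))
    def test_endpoint_support_equals_basin_reachability(self, seed):
        """A peak receives uniform-walk probability > 0 from g iff g is in
        its basin (exact endpoint DP vs reverse-reachability oracle)."""
        land = random_landscape(3, seed=seed, frac=0.85)
        peaks, _ = find_peaks(land)
        basins = {p: basin_of_attraction(land, p) for p in peaks}
        rng = np.random.default_rng(seed)
        starts = rng.choice(land.genotypes[~land.is_peak_], 12, replace=False)
        for start in starts:
            dist = uniform_walk_endpoint_distribution(land, str(start))
            support = {g for g, p in dist.items() if p > 0}
            reachable = {p for p in peaks if str(start) in basins[p].members}
            assert support == reachable
            assert sum(dist.values()) == pytest.approx(1.0)

    def test_monte_carlo_consistent_with_exact_distribution(self):
        land = random_landscape(2, seed=7)
        find_peaks(land)
        start = str(land.genotypes[~land.is_peak_][0])
        exact = uniform_walk_endpoint_distribution(land, start)
        rng = np.random.default_rng(1)
        ends = [uniform_walk(land, start, rng).endpoint for _ in range(3000)]
        for peak, p in exact.items():
            emp = np.mean([e == peak for e in ends])
            assert abs(emp - p) < 4 * np.sqrt(p * (1 - p) / 3000) + 1e-3


class TestKimuraFixation:
    def test_neutral_limit_is_one_over_N(self):
        for N in (10, 1e4, 1e8):
            assert kimura_fixation_probability(0.0, N) == pytest.approx(
                1 / N, rel=1e-9
            )

    def test_large_N_beneficial(self):
        # denominator saturates at 1: f ~ 1 - e^(-2s)
        f = kimura_fixation_probability(0.01, 1e8)
        assert f == pytest.approx(1 - np.exp(-0.02), rel=1e-9)

    def test_strongly_deleterious_underflows_to_zero(self):
        f = kimura_fixation_probability(-0.1, 1e8)
        assert f == 0.0

    def test_monotone_increasing_in_s(self):
        s = np.linspace(-0.2, 0.2, 401)
        for N in (10, 1e4, 1e8):
            f = kimura_fixation_probability(s, N)
            assert np.all(np.diff(f) >= 0)
            # strictly increasing wherever f has not underflowed to zero
            pos = f > 1e-300
            assert np.all(np.diff(f[pos]) > 0)
            assert np.all(f[s >= 0] > 0)

    def test_large_N_limit_approached_from_above(self):
        """For s > 0, f = (1-e^(-2s))/(1-e^(-2Ns)) >= 1 - e^(-2s), with
        equality in the N -> infinity limit."""
        s = np.linspace(1e-6, 0.5, 100)
        limit = -np.expm1(-2 * s)
        for N in (1e2, 1e4, 1e6):
            f = kimura_fixation_probability(s, N)
            assert np.all(f >= limit - 1e-15)
        f_big = kimura_fixation_probability(s[s >= 1e-3], 1e8)
        np.testing.assert_allclose(f_big, limit[s >= 1e-3], rtol=1e-8)

    def test_small_population_rejected(self):
        with pytest.raises(ConfigurationError):
            kimura_fixation_probability(0.1, 1)


class TestKimuraWalk:
    def test_flat_landscape_fixation_rate(self):
        """All scores equal: every proposal fixes w.p. 1/N, so fixations
        over max_steps average max_steps/N."""
        sp = small_space(2)
        land = build_network(
            pd.Series(1.0, index=sp.all_genotypes()), sp
        )
        N, steps, walks = 50, 400, 200
        cfg = WalkConfig(mode="kimura", population_size=N, max_steps=steps)
        rng = np.random.default_rng(0)
        fixations = [
            kimura_walk(land, "AA", cfg, rng).steps for _ in range(walks)
        ]
        expected = steps / N
        se = np.sqrt(expected / walks)  # ~Poisson
        assert abs(np.mean(fixations) - expected) < 4 * se

    def test_large_N_matches_uniform_endpoints(self):
        """With N = 1e8 deleterious/neutral fixations are essentially
        impossible, so the set of peaks reached matches the uphill-only
        uniform walk support."""
        land = random_landscape(2, seed=5)
        find_peaks(land)
        start = str(land.genotypes[~land.is_peak_][0])
        exact = uniform_walk_endpoint_distribution(land, start)
        cfg = WalkConfig(mode="kimura", population_size=1e8, max_steps=300)
        rng = np.random.default_rng(3)
        ends = set()
        for _ in range(300):
            res = kimura_walk(land, start, cfg, rng)
            if res.visited_peaks:
                ends.add(res.visited_peaks[-1])
        assert ends <= set(exact)

    def test_small_populations_cross_valleys_more(self):
        """Two-peak landscape with a shallow valley: the global peak is
        reached more often at small N (drift crosses the valley)."""
        sp2 = small_space(2)
        scores = pd.Series(
            {"AA": 0.5, "CA": 0.48, "CC": 1.0, "AC": 0.2, "GA": 0.1, "GG": 0.1}
        )
        land = build_network(scores, sp2)
        find_peaks(land)
        reach = {}
        for N in (1e2, 1e5, 1e8):
            cfg = WalkConfig(mode="kimura", population_size=N, max_steps=200)
            rng = np.random.default_rng(11)
            hits = 0
            for _ in range(300):
                res = kimura_walk(land, "AA", cfg, rng)
                hits += "CC" in res.visited_peaks
            reach[N] = hits / 300
        assert reach[1e2] > reach[1e5] >= reach[1e8]

    def test_seeded_reproducibility(self):
        land = random_landscape(2, seed=9)
        cfg = WalkConfig(
            mode="kimura", population_size=100, max_steps=100,
            starts=("sample", 3), walks_per_start=5,
        )
        a = run_walks(land, cfg, seed=4)
        b = run_walks(land, cfg, seed=4)
        assert [r.trajectory for r in a] == [r.trajectory for r in b]


class TestWalkSummary:
    def test_single_peak_landscape_all_high(self):
        sp = small_space(3)
        truth = make_additive_landscape(
            sp, uniform_weights(sp, np.random.default_rng(0))
        )
        scores = truth.scores / truth.scores.max() * 1.2  # peak above 1.0
        land = build_network(scores, sp)
        cfg = WalkConfig(mode="uniform", walks_per_start=2)
        results = run_walks(land, cfg, seed=0)
        summ = walk_summary(results, land, high_peak_threshold=1.0)
        assert summ.frac_end_on_peak == 1.0
        assert summ.frac_reaching_high_peak == 1.0
        assert (summ.per_start["n_distinct_high_peaks"] == 1).all()

    def test_mixed_landscape_rejected(self):
        land_a = path_landscape()
        land_b = random_landscape(3, seed=0)
        res = run_walks(land_a, WalkConfig(mode="greedy"), seed=0)
        with pytest.raises(Exception, match="match"):
            walk_summary(res, land_b)


class TestNoiseSweep:
    def make_noisy_landscape(self, seed=4):
        land = random_landscape(3, seed=seed)
        tau = np.random.default_rng(seed).uniform(0.0, 0.1, len(land))
        return Landscape(land.genotypes, land.scores, land.space, tau=tau)

    def test_scale_zero_reproduces_noise_free(self):
        land = self.make_noisy_landscape()
        cfg = WalkConfig(mode="uniform", walks_per_start=3, starts=("sample", 10))
        table = noise_sweep(land, [0.0], cfg, seed=2)
        base = apply_noise_model(land, scale=0.0)
        assert table.loc[0, "n_peaks"] == base.n_peaks_
        noise_free = build_network(
            pd.Series(land.scores, index=land.genotypes), land.space
        )
        find_peaks(noise_free)
        assert table.loc[0, "n_peaks"] == noise_free.n_peaks_

    def test_peak_count_non_increasing_in_scale(self):
        land = self.make_noisy_landscape()
        cfg = WalkConfig(mode="uniform", walks_per_start=2, starts=("sample", 5))
        table = noise_sweep(land, [0.0, 0.5, 1.0, 1.25, 1.5], cfg, seed=0)
        peaks = table["n_peaks"].to_numpy()
        assert np.all(np.diff(peaks) <= 0)
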