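"""NSGA-II engine: sorting, crowding, restricted mating, full fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lfp2spike as l
from lfp2spike.model import ModelGenome, OperatorSet
from lfp2spike.optimize import (
    FitResult,
    FrontMember,
    GAConfig,
    StructureMismatchError,
    crowding_distance,
    init_population,
    mutate,
    nondominated_sort,
    restricted_mate,
)


def brute_force_front(costs):
    """O(n^2) oracle for the rank-1 non-dominated set."""
    n = len(costs)
    front = []
    for i in range(n):
        if not any(
            l.dominates(costs[j], costs[i]) for j in range(n) if j != i
        ):
            front.append(i)
    return sorted(front)


class TestNondominatedSort:
    def test_all_rank_one(self):
        fronts = nondominated_sort(
            np.array([[0.1, 0.9], [0.9, 0.1], [0.5, 0.5]])
        )
        assert sorted(fronts[0]) == [0, 1, 2]
        assert len(fronts) == 1

    def test_chain_three_fronts(self):
        fronts = nondominated_sort(
            np.array([[0.1, 0.1], [0.2, 0.2], [0.3, 0.3]])
        )
        assert fronts == [[0], [1], [2]]

    def test_duplicates_share_front(self):
        fronts = nondominated_sort(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert sorted(fronts[0]) == [0, 1]

    def test_partition_property(self, rng):
        costs = rng.random((100, 3))
        fronts = nondominated_sort(costs)
        seen = sorted(i for f in fronts for i in f)
        assert seen == list(range(100))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 201))
            costs = np.round(rng.random((n, 3)), 3)
            assert sorted(nondominated_sort(costs)[0]) == brute_force_front(costs)


class TestCrowding:
    def test_two_points_infinite(self):
        d = crowding_distance(np.array([[0.1, 0.9], [0.9, 0.1]]))
        assert np.all(np.isinf(d))

    def test_three_evenly_spaced(self):
        d = crowding_distance(
            np.array([[0.1, 0.9], [0.5, 0.5], [0.9, 0.1]])
        )
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)  # one full normalized gap per objective

    def test_identical_points_zero_interior(self):
        d = crowding_distance(np.tile([0.5, 0.5], (4, 1)))
        assert np.isfinite(d).sum() + np.isinf(d).sum() == 4
        assert np.all(d[np.isfinite(d)] == 0.0)


class TestRestrictedMating:
    def test_identical_parents_identical_child(self, rng):
        g = ModelGenome((1, 2, 0), np.array([0.2, 0.3, 0.5]))
        child = restricted_mate(g, g, rng)
        assert child.structure == g.structure
        np.testing.assert_allclose(child.weights, g.weights)

    def test_structure_mismatch_signalled(self, rng):
        a = ModelGenome((0, 0, 0), np.array([1.0, 0.0, 0.0]))
        b = ModelGenome((1, 0, 0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(StructureMismatchError):
            restricted_mate(a, b, rng)

    def test_one_hot_parents_child_set(self, rng):
        """Children of (1,0,0) x (0,1,0) land on the enumerated outcomes."""
        a = ModelGenome((2, 2, 2), np.array([1.0, 0.0, 0.0]))
        b = ModelGenome((2, 2, 2), np.array([0.0, 1.0, 0.0]))
        seen = set()
        for _ in range(200):
            child = restricted_mate(a, b, rng)
            seen.add(tuple(np.round(child.weights, 6)))
        assert seen <= {(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.5, 0.5, 0.0)}
        assert len(seen) == 3

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_child_on_simplex(self, seed):
        rng = np.random.default_rng(seed)
        w1 = rng.dirichlet(np.ones(3))
        w2 = rng.dirichlet(np.ones(3))
        child = restricted_mate(
            ModelGenome((0, 1, 2), w1), ModelGenome((0, 1, 2), w2), rng
        )
        assert np.all(child.weights >= 0)
        assert child.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestMutation:
    def test_sigma_zero_weights_unchanged(self):
        rng = np.random.default_rng(0)
        cfg = GAConfig(pop_size=4, p_mut=1.0, mut_sigma=0.0)
        g = ModelGenome((0, 0, 0), np.array([0.2, 0.3, 0.5]))
        out = mutate(g, cfg, OperatorSet(), rng)
        np.testing.assert_allclose(out.weights, g.weights)

    def test_structure_mutation_rate(self):
        rng = np.random.default_rng(5)
        cfg = GAConfig(pop_size=4, p_mut=0.1)
        opset = OperatorSet()
        g = ModelGenome((0, 0, 0), np.array([1.0, 0.0, 0.0]))
        flips = 0
        n = 10000
        for _ in range(n):
            out = mutate(g, cfg, opset, rng)
            flips += sum(a != b for a, b in zip(out.structure, g.structure))
        # per-slot switch probability 0.1 -> 0.3 expected switches per draw
        assert flips / (3 * n) == pytest.approx(0.1, abs=0.01)

    def test_post_mutation_simplex(self):
        rng = np.random.default_rng(9)
        cfg = GAConfig(pop_size=4, p_mut=1.0, mut_sigma=0.5)
        g = ModelGenome((0, 0, 0), np.array([0.2, 0.3, 0.5]))
        for _ in range(200):
            g = mutate(g, cfg, OperatorSet(), rng)
            assert np.all(g.weights >= 0)
            assert g.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestInitPopulation:
    def test_deterministic_under_seed(self):
        cfg = GAConfig(pop_size=64, seed=3)
        a = init_population(cfg, OperatorSet())
        b = init_population(cfg, OperatorSet())
        assert all(
            x.structure == y.structure and np.allclose(x.weights, y.weights)
            for x, y in zip(a, b)
        )

    def test_structure_coverage_and_uniformity(self):
        """Population 320 over 64 structures: five per structure on average."""
        from scipy.stats import chisquare

        cfg = GAConfig(pop_size=320, seed=0)
        counts = np.zeros(64)
        for seed in range(100):
            pop = init_population(GAConfig(pop_size=320, seed=seed), OperatorSet())
            for g in pop:
                idx = g.structure[0] * 16 + g.structure[1] * 4 + g.structure[2]
                counts[idx] += 1
        assert counts.sum() == 32000
        _, p = chisquare(counts)
        assert p > 0.01

    def test_weights_on_simplex(self):
        pop = init_population(GAConfig(pop_size=50, seed=1), OperatorSet())
        for g in pop:
            assert np.all(g.weights >= 0)
            assert g.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestFit:
    def test_deterministic_under_seed(self, aligned_data):
        feats, truth = aligned_data
        cfg = GAConfig(pop_size=16, generations=3, seed=21)
        a = l.fit(feats, truth, cfg)
        b = l.fit(feats, truth, cfg)
        assert len(a.val_front) == len(b.val_front)
        for ma, mb in zip(a.val_front, b.val_front):
            assert ma.genome.structure == mb.genome.structure
            np.testing.assert_allclose(ma.genome.weights, mb.genome.weights)
            assert ma.costs == mb.costs

    def test_elitism_non_increasing_minima(self, aligned_data):
        feats, truth = aligned_data
        res = l.fit(feats, truth, GAConfig(pop_size=24, generations=8, seed=2))
        for name in ("sm", "pf", "co"):
            series = [h[f"min_{name}"] for h in res.history]
            assert all(b <= a + 1e-12 for a, b in zip(series, series[1:]))

    def test_co_only_collapses_to_one_hot(self, aligned_data):
        feats, truth = aligned_data
        cfg = GAConfig(pop_size=24, generations=10, seed=4, objectives=("co",))
        res = l.fit(feats, truth, cfg)
        best_co = min(m.costs["co"] for m in res.val_front)
        assert best_co < 0.05

    def test_degenerate_truth_rejected(self, aligned_data):
        feats, _ = aligned_data
        empty = l.BinaryResponse(np.zeros((feats.n_trials, feats.n_bins)))
        with pytest.raises(ValueError):
            l.fit(feats, empty, GAConfig(pop_size=8, generations=1))

    def test_restricted_mating_preserves_structures(self, aligned_data):
        """Every final structure already existed in the stratified start."""
        feats, truth = aligned_data
        cfg = GAConfig(pop_size=16, generations=4, seed=6, p_mut=0.0)
        res = l.fit(feats, truth, cfg)
        init_structs = {
            g.structure for g in init_population(cfg, OperatorSet())
        }
        final_structs = {m.genome.structure for m in res.train_front}
        assert final_structs <= init_structs


class TestAboveChance:
    def _result(self, pfs):
        members = tuple(
            FrontMember(
                ModelGenome((0, 0, 0), np.array([1.0, 0.0, 0.0])),
                {"sm": 0.5, "pf": pf, "co": 0.0},
            )
            for pf in pfs
        )
        return FitResult(members, members, (), ("sm", "pf", "co"))

    def test_mean_minus_std_rule(self):
        assert l.above_chance(self._result([0.5, 0.6]))  # 0.55 - 0.05 < 1
        assert not l.above_chance(self._result([1.5, 1.6, 1.7]))
        assert l.above_chance(self._result([0.99]))  # single member, std 0

    def test_requires_pf(self):
        r = FitResult((), (), (), ("sm",))
        with pytest.raises(ValueError):
            l.above_chance(r)
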