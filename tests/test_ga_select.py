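"""GA feature selection: fitness, operators, and the full driver."""

import numpy as np
import pytest
from scipy import stats

from ipqsar.ga_select import (
    Chromosome,
    GAConfig,
    biased_mutate,
    crossover,
    fitness,
    hyper_bounds,
    run_ga,
)


@pytest.fixture(scope="module")
def planted(small_dataset):
    _, matrix, _, truth, y = small_dataset
    info_idx = frozenset(matrix.feature_ids.index(f) for f in truth.informative_ids)
    return matrix, y, truth, info_idx


small_cfg = GAConfig(population_size=10, generations=6, seed=5)


class TestFitness:
    def test_informative_chromosome_scores_high(self, planted):
        matrix, y, truth, info_idx = planted
        ch = Chromosome(feature_idx=info_idx, hyper=3)
        assert fitness(ch, matrix, y, "gempls") > 0.9

    def test_noise_chromosomes_average_nonpositive(self, planted, rng):
        matrix, y, truth, info_idx = planted
        noise_pool = [
            i for i in np.flatnonzero(~matrix.zero_variance_mask())
            if i not in info_idx
        ]
        values = []
        for _ in range(30):
            idx = frozenset(
                int(i) for i in rng.choice(noise_pool, size=3, replace=False)
            )
            values.append(fitness(Chromosome(idx, hyper=2), matrix, y, "gempls"))
        assert np.mean(values) <= 0.0

    def test_memoized_and_deterministic(self, planted):
        matrix, y, _, info_idx = planted
        ch = Chromosome(feature_idx=info_idx, hyper=2)
        cache = {}
        v1 = fitness(ch, matrix, y, "gempls", cache)
        cache[ch.key()] = sentinel = 0.123456
        assert fitness(ch, matrix, y, "gempls", cache) == sentinel
        assert fitness(ch, matrix, y, "gempls") == v1

    def test_gemknn_fitness_finite(self, planted):
        matrix, y, _, info_idx = planted
        assert np.isfinite(fitness(Chromosome(info_idx, hyper=3), matrix, y,
                                   "gemknn"))


class TestBiasedMutate:
    cfg = GAConfig(population_size=10, generations=1, min_features=1,
                   max_features=50, mutation_rate=1.0)

    def test_zero_mutation_rate_leaves_chromosome_unchanged(self, rng):
        cfg = GAConfig(population_size=10, generations=1, mutation_rate=0.0)
        ch = Chromosome(frozenset({1, 2, 3, 4}), hyper=2)
        out = biased_mutate(ch, np.ones(20), cfg, rng, n_compounds=15)
        assert out.feature_idx == ch.feature_idx and out.hyper == ch.hyper

    def test_uniform_additions_when_all_significance_equal(self, rng):
        """With flat M no feature is favoured: chi-square GOF on added
        features over repeated single-feature additions."""
        M = np.ones(8)
        counts = np.zeros(8)
        cfg = GAConfig(population_size=10, generations=1, min_features=1,
                       max_features=2, mutation_rate=1.0)
        for _ in range(4000):
            # at min size the single mutation event must be an addition
            ch = Chromosome(frozenset({0}), hyper=1)
            out = biased_mutate(ch, M, cfg, rng, n_compounds=15)
            for f in out.feature_idx - {0}:
                counts[f] += 1
        observed = counts[1:]  # feature 0 starts selected
        assert observed.sum() > 500
        chi = stats.chisquare(observed)
        assert chi.pvalue > 0.01

    def test_dominant_significant_feature_always_added(self, rng):
        M = np.zeros(10)
        M[7] = 100.0
        cfg = GAConfig(population_size=10, generations=1, min_features=1,
                       max_features=2, mutation_rate=1.0,
                       significance_threshold=10.0)
        for _ in range(50):
            # at min size the single mutation event must be an addition
            ch = Chromosome(frozenset({0}), hyper=1)
            out = biased_mutate(ch, M, cfg, rng, n_compounds=15)
            assert out.feature_idx - {0} == {7}

    def test_size_bounds_respected(self, rng):
        cfg = GAConfig(population_size=10, generations=1, min_features=3,
                       max_features=6, mutation_rate=1.0)
        M = rng.uniform(0, 20, size=30)
        ch = Chromosome(frozenset({0, 1, 2, 3}), hyper=2)
        for _ in range(200):
            ch = biased_mutate(ch, M, cfg, rng, n_compounds=15)
            assert 3 <= len(ch.feature_idx) <= 6
            lo, hi = hyper_bounds("gempls", 15, len(ch.feature_idx))
            assert lo <= ch.hyper <= hi


class TestCrossover:
    cfg = GAConfig(population_size=10, generations=1, min_features=2,
                   max_features=8)

    def test_identical_parents_give_identical_children(self, rng):
        a = Chromosome(frozenset({1, 2, 3}), hyper=2)
        b = Chromosome(frozenset({1, 2, 3}), hyper=2)
        ca, cb = crossover(a, b, self.cfg, rng)
        assert ca.feature_idx == cb.feature_idx == a.feature_idx

    def test_disjoint_parents_conserve_feature_union(self, rng):
        cfg = GAConfig(population_size=10, generations=1, min_features=1,
                       max_features=20)
        a = Chromosome(frozenset(range(10)), hyper=1)
        b = Chromosome(frozenset(range(10, 20)), hyper=3)
        for _ in range(50):
            ca, cb = crossover(a, b, cfg, rng)
            assert ca.feature_idx | cb.feature_idx == set(range(20))
            assert not (ca.feature_idx & cb.feature_idx)

    def test_repair_enforces_size_bounds(self, rng):
        pool = np.arange(30)
        for _ in range(2000):
            sa = frozenset(rng.choice(pool, size=rng.integers(2, 9),
                                      replace=False).tolist())
            sb = frozenset(rng.choice(pool, size=rng.integers(2, 9),
                                      replace=False).tolist())
            ca, cb = crossover(Chromosome(sa, 1), Chromosome(sb, 2), self.cfg,
                               rng, selectable=pool)
            for c in (ca, cb):
                assert 2 <= len(c.feature_idx) <= 8


class TestRunGA:
    def test_best_fitness_trajectory_non_decreasing(self, planted):
        matrix, y, _, _ = planted
        history = []
        run_ga(matrix, y, "gempls", small_cfg, history=history)
        assert all(b >= a for a, b in zip(history, history[1:]))

    def test_same_seed_reproduces_run(self, planted):
        matrix, y, _, _ = planted
        r1 = run_ga(matrix, y, "gempls", small_cfg)
        r2 = run_ga(matrix, y, "gempls", small_cfg)
        assert r1.feature_ids == r2.feature_ids
        assert r1.hyper == r2.hyper
        assert r1.q2_train == r2.q2_train

    def test_returned_fitness_matches_recomputation(self, planted):
        matrix, y, _, _ = planted
        rec = run_ga(matrix, y, "gempls", small_cfg)
        idx = frozenset(matrix.feature_ids.index(f) for f in rec.feature_ids)
        recomputed = fitness(Chromosome(idx, rec.hyper), matrix, y, "gempls")
        assert recomputed == pytest.approx(rec.q2_train, abs=1e-12)

    def test_beats_all_features_pls_baseline(self, planted):
        """GA-selected subsets outperform a PLS model forced to use every
        feature (LOO q2, same data)."""
        from ipqsar.ga_select import _pls_fit_fn
        from ipqsar.metrics import loo_predict, q2 as q2_fn

        matrix, y, _, _ = planted
        usable = np.flatnonzero(~matrix.zero_variance_mask())
        baseline = q2_fn(loo_predict(_pls_fit_fn(5), matrix.values[:, usable], y))
        rec = run_ga(matrix, y, "gempls", small_cfg)
        assert rec.q2_train > baseline

    def test_insufficient_usable_features_rejected(self, planted, rng):
        from ipqsar.profiles import FeatureMatrix

        constant = FeatureMatrix(
            compound_ids=[f"c{i}" for i in range(10)],
            feature_ids=["f1", "f2", "f3", "f4"],
            values=np.column_stack([np.ones(10)] * 3 + [rng.normal(size=10)]),
            feature_kind="residue",
        )
        with pytest.raises(ValueError, match="usable"):
            run_ga(constant, rng.normal(size=10), "gempls", small_cfg)
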