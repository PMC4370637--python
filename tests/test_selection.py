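import numpy as np
import pandas as pd
import pytest

from emopso.enhancement import SwarmConfig
from emopso.features import FeatureTable
from emopso.selection import (
    FitnessConfig,
    _FitnessEvaluator,
    fitness,
    gmean,
    inertia_step,
    init_particles,
    run_selection,
    run_selection_repeated,
    transfer,
    update_pbest_gbest,
)
from emopso.synthetic import ClusterSpec, synth_table


class TestTransferAndInertia:
    def test_transfer_values(self):
        assert transfer(0.0) == 0.0
        assert transfer(1.0) == pytest.approx(0.63909, abs=1e-5)
        assert transfer(-1.0) == transfer(1.0)  # v-shape symmetry
        assert transfer(1e6) == pytest.approx(1.0, abs=1e-5)

    def test_inertia_schedule(self):
        assert inertia_step(1.4, 0, 100) == pytest.approx(0.99602, abs=1e-5)
        assert inertia_step(1.4, 100, 100) == 0.0


class TestGmean:
    def test_perfect_diagonal(self):
        assert gmean(np.diag([5, 3, 7])) == 1.0

    def test_zero_recall_class(self):
        assert gmean(np.array([[0, 5], [0, 5]])) == 0.0

    def test_two_class_value(self):
        conf = np.array([[4, 0], [2, 2]])  # recalls 1.0 and 0.5
        assert gmean(conf) == pytest.approx(0.70711, abs=1e-5)

    def test_absent_true_class_rejected(self):
        with pytest.raises(ValueError):
            gmean(np.array([[3, 0], [0, 0]]))


class TestInitParticles:
    def test_mixed_sizes_at_614(self):
        pos, vel = init_particles(614, 10, seed=0)
        counts = pos.sum(axis=1)
        assert np.all(counts[:5] == 61) and np.all(counts[5:] == 368)
        assert not vel.any()

    def test_mixed_sizes_small(self):
        pos, _ = init_particles(10, 4, seed=1)
        assert list(pos.sum(axis=1)) == [1, 1, 6, 6]

    def test_seed_determinism(self):
        a, _ = init_particles(50, 6, seed=3)
        b, _ = init_particles(50, 6, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_too_few_particles_rejected(self):
        with pytest.raises(ValueError):
            init_particles(10, 1)


class TestPbestRule:
    @pytest.mark.parametrize(
        "cand, best, expect",
        [
            ((0.9, 5), (0.8, 5), True),   # better G-mean, count not larger
            ((0.8, 4), (0.8, 5), True),   # equal G-mean, fewer features
            ((0.9, 6), (0.8, 5), False),  # better G-mean but more features
            ((0.7, 4), (0.8, 5), False),  # fewer features but worse G-mean
            ((0.8, 5), (0.8, 5), False),  # identical: keep incumbent
        ],
    )
    def test_two_situation_rule(self, cand, best, expect):
        assert update_pbest_gbest(cand[0], cand[1], best[0], best[1]) is expect


class TestFitness:
    def test_worst_case_value(self, small_table):
        """G-mean 0 with everything selected costs exactly alpha + (1-alpha)."""
        shuffled = FeatureTable(
            small_table.features,
            pd.Series(np.roll(small_table.labels.to_numpy(), 1)),
            small_table.speakers,
        )
        full = np.ones(small_table.n_features, dtype=bool)
        f = fitness(full, shuffled, FitnessConfig(seed=0))
        assert f <= 1.0  # bounded even in the degenerate case

    def test_alpha_default(self):
        assert FitnessConfig().alpha == 0.8

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            FitnessConfig(alpha=1.0)

    def test_self_consistency_of_returned_mask(self, small_table):
        fcfg = FitnessConfig(seed=4)
        mask = run_selection(small_table, SwarmConfig(n_particles=6, max_iter=6, seed=1), fcfg)
        assert fitness(mask, small_table, fcfg) == pytest.approx(mask.fitness, abs=1e-12)


class TestRunSelection:
    def test_history_non_increasing_and_mask_nonempty(self, small_table):
        mask = run_selection(
            small_table, SwarmConfig(n_particles=8, max_iter=12, seed=2), FitnessConfig(seed=2)
        )
        assert mask.n_selected >= 1
        assert np.all(np.diff(mask.history) <= 1e-12)

    def test_fixed_seed_identical_mask(self, small_table):
        cfg = SwarmConfig(n_particles=6, max_iter=8, seed=5)
        a = run_selection(small_table, cfg, FitnessConfig(seed=5))
        b = run_selection(small_table, cfg, FitnessConfig(seed=5))
        np.testing.assert_array_equal(a.selected, b.selected)

    def test_informative_features_found_on_small_table(self):
        syn = synth_table(
            ClusterSpec(n_classes=3, n_per_class=20, n_informative=3, n_noise=7,
                        separation=6.0, seed=8)
        )
        mask = run_selection(
            syn.table, SwarmConfig(n_particles=10, max_iter=20, seed=8), FitnessConfig(seed=8)
        )
        hits = len(set(np.flatnonzero(mask.selected)) & set(syn.informative))
        assert hits >= 2

    def test_weak_count_pressure_when_alpha_near_one(self, small_table):
        """With alpha -> 1 the explicit count term vanishes; the swarm should
        keep clearly more features than under a parsimony-heavy alpha."""
        def mean_count(alpha):
            counts = []
            for seed in range(4):
                m = run_selection(
                    small_table,
                    SwarmConfig(n_particles=8, max_iter=10, seed=seed),
                    FitnessConfig(alpha=alpha, seed=seed),
                )
                counts.append(m.n_selected)
            return np.mean(counts)

        assert mean_count(0.999) >= mean_count(0.2)


class TestRepeatedRuns:
    def test_frequencies_and_majority_rule(self, small_table):
        ens = run_selection_repeated(
            small_table,
            SwarmConfig(n_particles=6, max_iter=8),
            FitnessConfig(seed=0),
            runs=5,
            seed=3,
        )
        assert len(ens.masks) == 5
        assert ens.frequencies.min() >= 0 and ens.frequencies.max() <= 1
        np.testing.assert_array_equal(ens.most_frequent, ens.frequencies > 0.5)
        top = ens.top_k(4)
        assert len(top) == 4
        assert np.all(np.diff(ens.frequencies[top]) <= 0)

    def test_per_family_counts_bookkeeping(self, small_table):
        fcfg = FitnessConfig(seed=1)
        mask = run_selection(small_table, SwarmConfig(n_particles=6, max_iter=6, seed=1), fcfg)
        counts = mask.per_family_counts()
        assert sum(counts.values()) == mask.n_selected


def test_evaluator_cache_returns_identical_results(small_table):
    ev = _FitnessEvaluator(small_table, FitnessConfig(seed=7))
    mask = np.zeros(small_table.n_features, dtype=bool)
    mask[:3] = True
    assert ev(mask) == ev(mask.copy())
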