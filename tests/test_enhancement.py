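import numpy as np
import pandas as pd
import pytest

from emopso.enhancement import (
    ClusterModel,
    SwarmConfig,
    WeightVector,
    apply_weights,
    compute_weights,
    fisher_ratio,
    pso_cluster,
)
from emopso.features import FeatureTable
from emopso.synthetic import ClusterSpec, synth_table


def _table(X, labels=None):
    n = len(X)
    return FeatureTable(
        pd.DataFrame(np.asarray(X, float)),
        pd.Series(labels if labels is not None else ["a"] * n),
        pd.Series(["s"] * n),
    )


class TestPsoCluster:
    def test_duplicate_points_degenerate_optimum(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        model = pso_cluster(X, K=1, cfg=SwarmConfig(n_particles=5, max_iter=5, seed=0))
        np.testing.assert_allclose(model.centers[0], [1.0, 2.0])
        assert model.objective == pytest.approx(0.0, abs=1e-12)

    def test_recovers_well_separated_gaussians(self):
        """Centers land within 0.5 sigma of the true means at 10 sigma separation."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mu = np.array([[0.0, 0.0], [10.0, 0.0]])
            # 100 points/cluster keeps the sample centers within ~0.15 sigma
            # of the planted means, so the check exercises the optimizer
            X = np.vstack([mu[0] + rng.standard_normal((100, 2)),
                           mu[1] + rng.standard_normal((100, 2))])
            model = pso_cluster(X, K=2, cfg=SwarmConfig(seed=seed))
            d = np.sort([np.min(np.linalg.norm(model.centers - m, axis=1)) for m in mu])
            assert d[-1] <= 0.5, f"seed {seed}: worst center offset {d[-1]:.3f}"

    def test_fixed_seed_is_bit_identical(self):
        X = np.random.default_rng(1).standard_normal((40, 3))
        cfg = SwarmConfig(n_particles=8, max_iter=15, seed=9)
        a = pso_cluster(X, K=3, cfg=cfg)
        b = pso_cluster(X, K=3, cfg=cfg)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_k_exceeding_distinct_rows_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError):
            pso_cluster(X, K=2)


class TestWeights:
    def test_identity_when_center_mean_matches_data_mean(self):
        X = np.array([[0.0, 2.0], [4.0, 6.0]])  # means (2, 4)
        model = ClusterModel(np.array([[1.0, 3.0], [3.0, 5.0]]), 2, 0.0)
        w = compute_weights(model, X)
        np.testing.assert_allclose(w.weights, 1.0)

    def test_direct_ratio(self):
        X = np.array([[4.0], [4.0]])
        model = ClusterModel(np.array([[2.0]]), 1, 0.0)
        assert compute_weights(model, X).weights[0] == pytest.approx(2.0)

    def test_weights_positive_on_sign_mixed_table(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 6))  # near-zero means: the hostile case
        model = pso_cluster(X, K=2, cfg=SwarmConfig(n_particles=6, max_iter=10, seed=0))
        w = compute_weights(model, X)
        assert np.all(w.weights > 0)
        assert np.all(np.isfinite(w.weights))

    def test_apply_identity_and_column_scaling(self, small_table):
        ones = WeightVector(np.ones(small_table.n_features))
        np.testing.assert_array_equal(apply_weights(small_table, ones).X, small_table.X)
        w = np.ones(small_table.n_features)
        w[3] = 2.0
        out = apply_weights(small_table, WeightVector(w))
        np.testing.assert_allclose(out.X[:, 3], 2.0 * small_table.X[:, 3])
        np.testing.assert_array_equal(out.X[:, :3], small_table.X[:, :3])

    def test_dimension_mismatch_rejected(self, small_table):
        with pytest.raises(ValueError):
            apply_weights(small_table, WeightVector(np.ones(3)))


class TestFisherRatio:
    def test_separation_orders_the_ratio(self):
        lo = synth_table(ClusterSpec(separation=0.5, seed=0)).table
        hi = synth_table(ClusterSpec(separation=8.0, seed=0)).table
        assert fisher_ratio(hi) > fisher_ratio(lo)

    def test_invariant_under_positive_column_scaling(self, small_table):
        rng = np.random.default_rng(0)
        w = WeightVector(rng.uniform(0.5, 2.0, small_table.n_features))
        assert fisher_ratio(apply_weights(small_table, w)) == pytest.approx(
            fisher_ratio(small_table), rel=1e-9
        )


def test_brute_force_small_instance_oracle():
    """On <= 8 points with K=2, the swarm objective comes within 5% of the
    exhaustive best 2-partition (geometric-median centers via Weiszfeld)."""

    def weiszfeld(P, iters=200):
        c = P.mean(axis=0)
        for _ in range(iters):
            d = np.linalg.norm(P - c, axis=1)
            if np.any(d < 1e-12):
                return P[np.argmin(d)]
            wgt = 1.0 / d
            c = (P * wgt[:, None]).sum(axis=0) / wgt.sum()
        return c

    def exhaustive(P):
        n = len(P)
        best = np.inf
        for code in range(1, 2 ** (n - 1)):  # point 0 fixed in the complement
            mask = np.zeros(n, dtype=bool)
            for i in range(n - 1):
                mask[i + 1] = bool((code >> i) & 1)
            obj = 0.0
            for grp in (P[mask], P[~mask]):
                c = weiszfeld(grp)
                obj += np.linalg.norm(grp - c, axis=1).sum()
            best = min(best, obj)
        return best

    ok = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        P = rng.standard_normal((8, 2)) * 2.0
        model = pso_cluster(P, K=2, cfg=SwarmConfig(n_particles=20, max_iter=60, seed=seed))
        if model.objective <= exhaustive(P) * 1.05:
            ok += 1
    assert ok == 10
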