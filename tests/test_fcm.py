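"""Gustafson-Kessel fuzzy C-means: distances, updates, fits, model selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from brainmech import (cluster_covariance, cluster_summary, gk_distance,
                       select_cluster_count, update_centers, update_memberships)
from brainmech.fcm import fit


def three_blobs(seed=0, n_per=100, spread=0.3):
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0, 0], [5.0, 0, 0], [0, 5.0, 5.0]])
    X = np.vstack([rng.normal(c, spread, size=(n_per, 3)) for c in centers])
    labels = np.repeat(np.arange(3), n_per)
    return X, labels


class TestGkDistance:
    def test_zero_at_the_prototype(self):
        assert gk_distance([1.0, 2.0], [1.0, 2.0], np.eye(2)) == 0.0

    def test_identity_covariance_reduces_to_squared_euclidean(self, rng):
        for _ in range(50):
            x, v = rng.normal(size=(2, 4))
            d = gk_distance(x, v, np.eye(4), rho=1.0)
            assert d == pytest.approx(np.sum((x - v) ** 2), abs=1e-12)

    def test_anisotropic_worked_value(self):
        # F = diag(4, 1), rho = 1, x - v = (1, 0):
        # A = (det F)^(1/2) F^-1 = 2 * diag(1/4, 1) so d2 = 0.5
        d = gk_distance([1.0, 0.0], [0.0, 0.0], np.diag([4.0, 1.0]))
        assert d == pytest.approx(0.5, abs=1e-12)

    def test_singular_covariance_is_regularized(self):
        d = gk_distance([1.0, 0.0], [0.0, 0.0], np.diag([1.0, 0.0]))
        assert np.isfinite(d) and d >= 0.0


class TestUpdateMemberships:
    def test_equal_distances_split_membership(self):
        U = update_memberships(np.array([[1.0], [1.0]]), Q=2.0)
        assert np.allclose(U, 0.5)

    def test_zero_distance_takes_full_membership(self):
        U = update_memberships(np.array([[0.0], [5.0]]), Q=2.0)
        assert np.allclose(U[:, 0], [1.0, 0.0])

    def test_one_to_four_distance_ratio(self):
        U = update_memberships(np.array([[1.0], [4.0]]), Q=2.0)
        assert np.allclose(U[:, 0], [0.8, 0.2])

    def test_hard_fuzzifier_rejected(self):
        with pytest.raises(ValueError):
            update_memberships(np.ones((2, 3)), Q=1.0)

    @settings(deadline=None, max_examples=50)
    @given(D=hnp.arrays(float, (3, 8), elements=st.floats(1e-6, 1e6)),
           Q=st.floats(1.1, 5.0))
    def test_columns_always_sum_to_one(self, D, Q):
        U = update_memberships(D, Q)
        assert np.allclose(U.sum(axis=0), 1.0, atol=1e-12)
        assert (U >= 0).all() and (U <= 1).all()


class TestUpdateCenters:
    def test_crisp_memberships_give_cluster_means(self, rng):
        X = rng.normal(size=(10, 2))
        U = np.zeros((2, 10))
        U[0, :4] = 1.0
        U[1, 4:] = 1.0
        V = update_centers(X, U, Q=2.0)
        assert np.allclose(V[0], X[:4].mean(axis=0))
        assert np.allclose(V[1], X[4:].mean(axis=0))

    def test_single_cluster_center_is_global_mean(self, rng):
        X = rng.normal(size=(20, 3))
        V = update_centers(X, np.ones((1, 20)), Q=2.0)
        assert np.allclose(V[0], X.mean(axis=0))

    def test_symmetric_points_with_equal_membership_center_at_midpoint(self):
        X = np.array([[-1.0, 0.0], [1.0, 0.0]])
        V = update_centers(X, np.full((1, 2), 0.5), Q=2.0)
        assert np.allclose(V[0], [0.0, 0.0])


class TestClusterCovariance:
    def test_always_symmetric(self, rng):
        X = rng.normal(size=(50, 3))
        U = rng.uniform(size=(2, 50))
        U /= U.sum(axis=0)
        V = update_centers(X, U, 2.0)
        F = cluster_covariance(X, U, 2.0, V)
        assert np.allclose(F, np.transpose(F, (0, 2, 1)))

    def test_isotropic_cluster_recovers_sigma_squared_identity(self):
        rng = np.random.default_rng(8)
        sigma = 0.7
        X = rng.normal(0, sigma, size=(5000, 2))
        U = np.ones((1, 5000))
        F = cluster_covariance(X, U, 2.0, X.mean(axis=0, keepdims=True))
        assert np.allclose(F[0], sigma ** 2 * np.eye(2), atol=0.05)

    def test_single_point_cluster_is_pure_regularization(self):
        X = np.array([[1.0, 2.0]])
        F = cluster_covariance(X, np.ones((1, 1)), 2.0, X.copy())
        w = np.linalg.eigvalsh(F[0])
        assert w[0] > 0                               # positive definite
        assert w[-1] / w[0] == pytest.approx(1.0)     # isotropic: gamma * I


class TestFit:
    def test_recovers_three_planted_blobs(self):
        X, labels = three_blobs()
        from sklearn.metrics import adjusted_rand_score
        part = fit(X, C=3, seed=4)
        assert adjusted_rand_score(labels, part.hard_labels) > 0.95

    def test_single_cluster_degenerates_to_mean(self, rng):
        X = rng.normal(size=(30, 2))
        part = fit(X, C=1, seed=0)
        assert np.allclose(part.U, 1.0)
        assert np.allclose(part.V[0], X.mean(axis=0), atol=1e-6)

    def test_membership_columns_sum_to_one(self):
        X, _ = three_blobs(seed=2)
        for C, Q, seed in [(2, 2.0, 0), (4, 1.5, 1), (5, 3.0, 2)]:
            part = fit(X, C=C, Q=Q, seed=seed)
            assert np.abs(part.U.sum(axis=0) - 1.0).max() < 1e-12

    def test_seeded_fit_is_reproducible(self):
        X, _ = three_blobs(seed=3)
        a = fit(X, C=3, seed=11)
        b = fit(X, C=3, seed=11)
        assert np.array_equal(a.U, b.U)
        assert a.cost_trace == b.cost_trace

    def test_plain_fcm_cost_never_increases(self, rng):
        for _ in range(20):
            X = rng.normal(size=(rng.integers(20, 60), rng.integers(1, 4)))
            part = fit(X, C=int(rng.integers(2, 5)), seed=int(rng.integers(1 << 16)),
                       gk=False, tol=0.0, max_iter=25)
            J = np.asarray(part.cost_trace)
            assert (np.diff(J) <= 1e-9 * np.abs(J[:-1]) + 1e-12).all()

    def test_gk_cost_final_not_above_initial(self):
        X, _ = three_blobs(seed=5)
        part = fit(X, C=3, seed=6)
        assert part.cost_trace[-1] <= part.cost_trace[0] * (1 + 1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit(np.full((5, 2), np.nan), C=2)
        with pytest.raises(ValueError):
            fit(np.zeros((3, 2)), C=3)


class TestSelectClusterCount:
    def test_selected_count_satisfies_membership_rule(self):
        X, _ = three_blobs(seed=1)
        C, fits = select_cluster_count(X, range(2, 5), seeds=3, seed=0)
        frac = (fits[C].max_memberships > 0.5).mean()
        assert frac >= 0.5

    def test_confidence_diffuses_as_cluster_count_grows(self):
        # a single isotropic blob supports no sharp partition: the mean
        # maximum membership falls steadily as more clusters slice it
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        mean_conf = [fit(X, C=C, seed=1).max_memberships.mean() for C in (2, 4, 6)]
        assert mean_conf[0] > mean_conf[1] > mean_conf[2]

    def test_largest_qualifying_count_is_selected(self):
        X, _ = three_blobs(seed=7, n_per=60)
        C, fits = select_cluster_count(X, range(2, 5), seeds=3, seed=2)
        qualifying = [c for c, p in fits.items()
                      if (p.max_memberships > 0.5).mean() >= 0.5]
        assert C == max(qualifying)

    def test_singleton_range_returns_its_element(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 2))
        C, _ = select_cluster_count(X, [2], seeds=2, seed=0)
        assert C == 2

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            select_cluster_count(np.zeros((10, 2)), [])


def test_cluster_summary_reports_per_cluster_means():
    import pandas as pd
    X, labels = three_blobs(seed=9)
    part = fit(X, C=3, seed=9)
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    summary = cluster_summary(part, df)
    assert len(summary) == 3
    assert summary["n_points"].sum() == len(X)
    # each cluster mean sits near one planted center
    planted = {(0, 0, 0), (5, 0, 0), (0, 5, 5)}
    for _, row in summary.iterrows():
        nearest = min(planted, key=lambda c: np.sum((np.array(c) - row[["a", "b", "c"]].values) ** 2))
        assert np.allclose(row[["a", "b", "c"]].values, nearest, atol=0.2)


def test_partition_json_round_trip(tmp_path):
    X, _ = three_blobs(seed=4, n_per=30)
    part = fit(X, C=2, seed=0)
    path = tmp_path / "part.json"
    part.to_json(path)
    import json
    d = json.loads(path.read_text())
    assert d["C"] == 2 and np.allclose(d["U"], part.U)
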