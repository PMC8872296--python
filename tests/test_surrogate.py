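import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from sklearn.svm import SVR as SkSVR

from metroexposure import blank_grid
from metroexposure.station import CONCOURSE
from metroexposure.surrogate import (SurrogateModel, build_region_map,
                                     kmeans_partition, platform_region_map,
                                     predict_concentration, pso_tune,
                                     r_squared, split_train_test, train_svr)


class TestRSquared:
    def test_perfect_and_null_predictions(self):
        y = np.array([3.0, 5.0, 9.0])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            r_squared([1.0], [1.0])


def _table(X, y):
    return pd.DataFrame({"sim_closed": X[:, 0], "sim_open": X[:, 1],
                         "measured": y, "zone": "half-1"})


class TestKMeans:
    def test_separated_clusters_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal((0, 0), 0.1, (10, 2))
        b = rng.normal((8, 8), 0.1, (10, 2))
        X = np.vstack([a, b])
        y = np.concatenate([np.zeros(10), np.full(10, 10.0)])
        labels = kmeans_partition(_table(X, y), 2, seed=0)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_k_equals_n_gives_zero_wcss(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        labels = kmeans_partition(_table(X, y), 5, seed=0, n_init=20)
        assert len(set(labels)) == 5

    def test_k_above_n_rejected(self):
        X = np.zeros((2, 2))
        with pytest.raises(ValueError):
            kmeans_partition(_table(X, [0.0, 1.0]), 3)

    def test_two_cluster_optimum_matches_brute_force(self):
        """For n = 8, k = 2 Lloyd's best-of-restarts hits the global WCSS."""
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 10, (8, 2))
        y = rng.uniform(0, 10, 8)
        tab = _table(X, y)
        feats = tab[["sim_closed", "sim_open", "measured"]].to_numpy()
        z = (feats - feats.mean(0)) / feats.std(0)

        def wcss(mask):
            out = 0.0
            for sel in (mask, ~mask):
                out += ((z[sel] - z[sel].mean(0)) ** 2).sum()
            return out

        best = min(
            wcss(np.array([i in combo for i in range(8)]))
            for r in range(1, 8)
            for combo in itertools.combinations(range(8), r))
        labels = kmeans_partition(tab, 2, seed=0, n_init=20)
        assert wcss(labels == labels[0]) == pytest.approx(best, rel=1e-9)


class TestSplit:
    @pytest.mark.parametrize("n,n_test,n_train", [(23, 3, 20), (29, 4, 25)])
    def test_split_sizes(self, n, n_test, n_train):
        tab = _table(np.zeros((n, 2)), np.arange(n))
        train, test = split_train_test(tab, n_test, seed=0)
        assert (len(train), len(test)) == (n_train, n_test)

    def test_disjoint_union(self):
        tab = _table(np.arange(20).reshape(10, 2), np.arange(10))
        train, test = split_train_test(tab, 3, seed=2)
        merged = pd.concat([train, test]).sort_values("measured")
        assert merged.measured.tolist() == tab.measured.tolist()

    def test_oversized_test_rejected(self):
        tab = _table(np.zeros((4, 2)), np.arange(4))
        with pytest.raises(ValueError):
            split_train_test(tab, 4, seed=0)


def _svr_primal_objective(model: SurrogateModel, X, y):
    K = np.exp(-model.sigma * ((model.support_vectors[:, None, :]
                                - model.support_vectors[None, :, :]) ** 2
                               ).sum(-1))
    w2 = model.dual_coef @ K @ model.dual_coef
    resid = np.abs(model.predict(X) - y)
    slack = np.maximum(resid - model.epsilon, 0.0).sum()
    return 0.5 * w2 + model.lam * slack


def _svr_dual_oracle(X, y, lam, sigma, epsilon):
    """Dense QP solve of the epsilon-SVR dual (beta = alpha - alpha*)."""
    K = np.exp(-sigma * ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    n = len(y)

    def neg_dual(beta):
        return 0.5 * beta @ K @ beta + epsilon * np.abs(beta).sum() - y @ beta

    cons = [{"type": "eq", "fun": lambda b: b.sum()}]
    res = minimize(neg_dual, np.zeros(n), method="SLSQP",
                   bounds=[(-lam, lam)] * n, constraints=cons,
                   options={"maxiter": 2000, "ftol": 1e-14})
    assert res.success
    return -res.fun


class TestTrainSvr:
    def test_constant_outputs_within_tube(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        model = train_svr(X, np.full(12, 7.0), lam=10.0, sigma=0.5,
                          epsilon=0.1)
        assert np.all(np.abs(model.predict(X) - 7.0) <= 0.1 + 1e-8)

    def test_objective_matches_dense_qp_oracle(self):
        """Strong duality: solver primal equals an SLSQP dual solve."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 2))
        X = (X - X.mean(0)) / X.std(0)
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1]
        lam, sigma, eps = 5.0, 0.8, 0.05
        model = train_svr(X, y, lam, sigma, eps, tol=1e-10)
        primal = _svr_primal_objective(model, X, y)
        dual = _svr_dual_oracle(X, y, lam, sigma, eps)
        assert primal == pytest.approx(dual, rel=1e-5, abs=1e-7)

    def test_duplicated_point_matches_weighted_oracle(self):
        """Duplicating a row equals doubling its loss weight (KKT)."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 2))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, 0] ** 2 - X[:, 1]
        Xd = np.vstack([X, X[:1]])
        yd = np.concatenate([y, y[:1]])
        ours = train_svr(Xd, yd, lam=4.0, sigma=0.6, epsilon=0.05, tol=1e-10)
        sw = np.ones(8)
        sw[0] = 2.0
        oracle = SkSVR(kernel="rbf", C=4.0, gamma=0.6, epsilon=0.05,
                       tol=1e-10)
        # evaluate on the duplicated table's standardized frame
        Z = (Xd - ours.x_mean) / ours.x_scale
        oracle.fit(Z[:8], y, sample_weight=sw)
        grid = rng.normal(size=(20, 2))
        Zg = (grid - ours.x_mean) / ours.x_scale
        np.testing.assert_allclose(ours.predict(grid),
                                   oracle.predict(Zg), atol=1e-6)

    def test_standardization_round_trip_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 2))
        y = X @ [1.0, -2.0] + 0.1 * rng.normal(size=15)
        m1 = train_svr(X, y, 5.0, 0.5, 0.1)
        m2 = train_svr(X * 3.0 + 7.0, y, 5.0, 0.5, 0.1)
        q = rng.normal(size=(10, 2))
        np.testing.assert_allclose(m1.predict(q), m2.predict(q * 3.0 + 7.0),
                                   atol=1e-8)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            train_svr(np.zeros((3, 1)), np.zeros(3), lam=0.0, sigma=1.0)

    def test_json_round_trip(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 2))
        y = X[:, 0] + X[:, 1]
        m = train_svr(X, y, 5.0, 0.5, 0.1, region="A")
        m2 = SurrogateModel.from_dict(m.to_dict())
        q = rng.normal(size=(5, 2))
        np.testing.assert_allclose(m.predict(q), m2.predict(q))


def _rbf_test_problem(seed=0, n_train=24, n_test=30):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-1, 1, (4, 2))
    amps = rng.uniform(1, 3, 4)

    def f(X):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        return np.exp(-1.5 * d2) @ amps

    Xtr = rng.uniform(-1, 1, (n_train, 2))
    Xte = rng.uniform(-1, 1, (n_test, 2))
    return Xtr, f(Xtr), Xte, f(Xte)


class TestPso:
    def test_single_particle_no_iterations_returns_initial(self):
        Xtr, ytr, _, _ = _rbf_test_problem()
        res = pso_tune(Xtr, ytr, swarm=1, iters=0, seed=6, n_repeats=1,
                       n_folds=3)
        assert len(res.history) == 1
        assert res.history[0] == res.score
        assert 1e-2 <= res.lam <= 1e4 and 1e-3 <= res.sigma <= 1e2

    def test_best_score_nondecreasing(self):
        Xtr, ytr, _, _ = _rbf_test_problem(1)
        res = pso_tune(Xtr, ytr, swarm=6, iters=8, seed=2, n_repeats=1,
                       n_folds=3)
        assert all(b >= a for a, b in zip(res.history, res.history[1:]))

    def test_matches_dense_grid_search(self):
        """PSO-tuned model is within 0.02 test R^2 of a log-grid search."""
        from metroexposure.surrogate import _cv_r2

        Xtr, ytr, Xte, yte = _rbf_test_problem(2)
        res = pso_tune(Xtr, ytr, swarm=10, iters=12, seed=3, n_repeats=1,
                       n_folds=3)
        m = train_svr(Xtr, ytr, res.lam, res.sigma, 0.1)
        pso_r2 = r_squared(yte, m.predict(Xte))
        best = (-np.inf, None)
        for ll in np.linspace(-2, 4, 13):
            for ls in np.linspace(-3, 2, 11):
                cv = _cv_r2(Xtr, ytr, 10 ** ll, 10 ** ls, 0.1, 3, [0])
                if cv > best[0]:
                    best = (cv, (10 ** ll, 10 ** ls))
        mg = train_svr(Xtr, ytr, *best[1], 0.1)
        grid_r2 = r_squared(yte, mg.predict(Xte))
        assert pso_r2 >= grid_r2 - 0.02

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            pso_tune(np.zeros((5, 2)), np.zeros(5),
                     bounds_log_lambda=(1.0, 1.0))


class TestRegionRouting:
    def test_single_point_labels_whole_floor(self):
        grid = blank_grid(CONCOURSE, 10, 10, 1.0)
        rmap = build_region_map(grid, np.array([[5.0, 5.0]]), np.array(["A"]))
        assert set(rmap.labels.ravel()) == {"A"}

    def test_cell_on_point_gets_its_label(self):
        grid = blank_grid(CONCOURSE, 10, 10, 1.0)
        pts = np.array([[1.5, 1.5], [8.5, 8.5]])
        rmap = build_region_map(grid, pts, np.array(["A", "B"]))
        assert rmap.region_at(1.5, 1.5) == "A"
        assert rmap.region_at(8.5, 8.5) == "B"

    def test_assignment_matches_nearest_neighbour_oracle(self):
        rng = np.random.default_rng(7)
        grid = blank_grid(CONCOURSE, 12, 9, 1.0)
        pts = rng.uniform(0, 9, (6, 2))
        labels = np.array(list("ABABAB"))
        rmap = build_region_map(grid, pts, labels)
        cx, cy = grid.cell_centers()
        for i, j in [(0, 0), (5, 4), (11, 8), (3, 7)]:
            d = np.hypot(pts[:, 0] - cx[i, j], pts[:, 1] - cy[i, j])
            assert rmap.labels[i, j] == labels[np.argmin(d)]

    def test_no_points_rejected(self):
        grid = blank_grid(CONCOURSE, 4, 4, 1.0)
        with pytest.raises(ValueError):
            build_region_map(grid, np.empty((0, 2)), np.array([]))

    def test_prediction_routing_and_dimension_check(self):
        rng = np.random.default_rng(8)
        Xa = rng.normal(size=(10, 2))
        bank = {
            "A": train_svr(Xa, np.full(10, 30.0), 10.0, 0.5, 0.01),
            "B": train_svr(Xa, np.full(10, 60.0), 10.0, 0.5, 0.01),
        }
        grid = blank_grid(CONCOURSE, 10, 10, 1.0)
        rmap = build_region_map(grid, np.array([[1.0, 1.0], [9.0, 9.0]]),
                                np.array(["A", "B"]))
        assert predict_concentration(bank, rmap, (1.0, 1.0), [0.0, 0.0]) \
            == pytest.approx(30.0, abs=0.5)
        assert predict_concentration(bank, rmap, (9.0, 9.0), [0.0, 0.0]) \
            == pytest.approx(60.0, abs=0.5)
        pmap = platform_region_map(blank_grid("platform", 5, 5, 1.0))
        bank["platform"] = bank["A"]
        with pytest.raises(ValueError):
            predict_concentration(bank, pmap, (1.0, 1.0), [1.0, 2.0, 3.0])
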