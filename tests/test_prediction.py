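"""Cross-validated prediction machinery: folds, deconfounding, training,
tuning, metrics, transfer, and the no-leakage contract."""

import numpy as np
import pytest

from fcintel import synth
from fcintel.prediction import (TrainConfig, apply_deconfounder,
                                cross_validated_predict, fit_deconfounder,
                                fit_full, leakage_audit, make_folds,
                                performance_metrics, train_mlp,
                                transfer_predict, tune_hyperparameters,
                                MLPRegressor)
from fcintel.selection import random_edge_selection


class TestMakeFolds:
    def test_families_unsplit_and_balanced(self, rng):
        fams = np.repeat([f"F{i}" for i in range(10)], 2)
        y = rng.standard_normal(20)
        fa = make_folds(fams, y, n_folds=5, seed=0)
        for f in np.unique(fams):
            assert len(np.unique(fa.fold[fams == f])) == 1
        counts = np.bincount(fa.fold, minlength=5)
        assert np.all(counts == 4)        # 2 families of 2 per fold

    def test_stratification_beats_random_assignment(self, rng):
        fams = np.repeat(np.arange(100), 2)
        y = rng.standard_normal(200) + np.repeat(rng.standard_normal(100), 2)
        sd_strat, sd_rand = [], []
        for s in range(50):
            fa = make_folds(fams, y, 5, seed=s)
            sd_strat.append(np.std([y[fa.fold == f].mean()
                                    for f in range(5)]))
            rr = np.random.default_rng(1000 + s)
            ff = rr.integers(0, 5, 100)[fams]
            sd_rand.append(np.std([y[ff == f].mean() for f in range(5)]))
        assert np.mean(sd_strat) < 0.5 * np.mean(sd_rand)

    def test_single_fold_rejected(self, rng):
        with pytest.raises(ValueError):
            make_folds(np.arange(10), rng.standard_normal(10), n_folds=1)


class TestDeconfounder:
    def test_training_residuals_orthogonal(self, rng):
        x = rng.standard_normal((200, 30))
        c = rng.standard_normal((200, 4))
        y = x[:, 0] + c @ np.array([1.0, -2, 0.5, 3]) + rng.standard_normal(200)
        dec = fit_deconfounder(x, y, c)
        xt, yt = apply_deconfounder(dec, x, y, c)
        for j in range(4):
            assert abs(np.corrcoef(yt, c[:, j])[0, 1]) < 1e-10
        assert yt.mean() == pytest.approx(0, abs=1e-12)
        assert yt.std() == pytest.approx(1, abs=1e-12)
        assert np.allclose(xt.mean(0), 0, atol=1e-10)
        assert np.allclose(xt.std(0), 1, atol=1e-10)

    def test_worked_example_fully_explained_target(self):
        # c = (0,1,2,3), y = (1,3,5,7): y = 1 + 2c exactly -> residuals 0
        c = np.array([[0.0], [1], [2], [3]])
        y = np.array([1.0, 3, 5, 7])
        x = np.eye(4)
        dec = fit_deconfounder(x, y, c, on_zero_variance="keep")
        _, ry = apply_deconfounder(dec, x, y, c)
        assert np.allclose(ry, 0, atol=1e-10)
        with pytest.raises(ValueError, match="fully explained"):
            fit_deconfounder(x, y, c)

    def test_test_equals_train_gives_identical_residuals(self, rng):
        x = rng.standard_normal((50, 5))
        c = rng.standard_normal((50, 2))
        y = rng.standard_normal(50)
        dec = fit_deconfounder(x, y, c)
        a = apply_deconfounder(dec, x, y, c)
        b = apply_deconfounder(dec, x, y, c)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_rank_deficient_confounds_rejected(self, rng):
        c = np.ones((20, 2))
        with pytest.raises(ValueError, match="rank deficient"):
            fit_deconfounder(rng.standard_normal((20, 3)),
                             rng.standard_normal(20), c)

    def test_refuses_mismatched_application(self, rng):
        x = rng.standard_normal((30, 4))
        c = rng.standard_normal((30, 2))
        dec = fit_deconfounder(x, rng.standard_normal(30), c)
        with pytest.raises(ValueError):
            apply_deconfounder(dec, x, np.zeros(30), c[:, :1])
        with pytest.raises(ValueError):
            apply_deconfounder(dec, x[:, :3], np.zeros(30), c)


class TestTrainMlp:
    def _linear_problem(self, seed=0, n=500, p=50, r2=0.7):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, p))
        sig = x[:, :5] @ np.ones(5)
        sig /= sig.std()
        y = np.sqrt(r2) * sig + np.sqrt(1 - r2) * rng.standard_normal(n)
        return x, y

    def test_learns_linear_signal(self):
        x, y = self._linear_problem()
        cfg = TrainConfig(max_epochs=600, patience=60)
        m = train_mlp(x[:320], y[:320], x[320:400], y[320:400],
                      hidden=(50,), config=cfg, seed=3)
        r = np.corrcoef(m.predict(x[400:]), y[400:])[0, 1]
        assert r > 0.6                   # ceiling sqrt(0.7) ~ 0.84

    def test_shuffled_target_gives_null_performance(self):
        rs = []
        for s in range(20):
            rng = np.random.default_rng(s)
            x = rng.standard_normal((200, 30))
            y = rng.standard_normal(200)
            m = train_mlp(x[:120], y[:120], x[120:160], y[120:160],
                          hidden=(10,), config=TrainConfig(max_epochs=100,
                                                           patience=20),
                          seed=s)
            rs.append(np.corrcoef(m.predict(x[160:]), y[160:])[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_early_stopping_fires_on_plateau(self):
        x, y = self._linear_problem(seed=1, r2=0.99)
        cfg = TrainConfig(max_epochs=5000, patience=100)
        m = train_mlp(x[:350], y[:350], x[350:450], y[350:450],
                      hidden=(10,), config=cfg, seed=0)
        assert m.log["stop_reason"] == "early_stop"
        assert m.log["epochs_run"] < 5000
        assert len(m.log["val_history"]) == m.log["epochs_run"]

    def test_divergence_detected(self):
        x, y = self._linear_problem(n=50, p=5)
        cfg = TrainConfig(lr=1e4, max_epochs=50, patience=10)
        with pytest.raises(FloatingPointError):
            train_mlp(x[:40] * 100, y[:40] * 100, x[40:], y[40:],
                      hidden=(10,), config=cfg, seed=0)

    def test_seed_determinism(self):
        x, y = self._linear_problem(n=100, p=10)
        cfg = TrainConfig(max_epochs=50, patience=10)
        m1 = train_mlp(x[:80], y[:80], x[80:], y[80:], (10,), cfg, seed=5)
        m2 = train_mlp(x[:80], y[:80], x[80:], y[80:], (10,), cfg, seed=5)
        assert m1.digest_bytes() == m2.digest_bytes()


class TestTuneHyperparameters:
    def test_singleton_grid_returned(self, rng):
        cfg = TrainConfig(grid=((42,),))
        got = tune_hyperparameters(rng.standard_normal((30, 5)),
                                   rng.standard_normal(30),
                                   np.arange(30), cfg)
        assert got == (42,)

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal((60, 8))
        y = x[:, 0] + 0.5 * rng.standard_normal(60)
        fams = np.arange(60)
        cfg = TrainConfig(grid=((10,), (50,)), max_epochs=60, patience=15)
        a = tune_hyperparameters(x, y, fams, cfg, seed=1)
        b = tune_hyperparameters(x, y, fams, cfg, seed=1)
        assert a == b

    def test_deeper_wins_on_nonlinear_target(self):
        wins = 0
        cfg = TrainConfig(max_epochs=400, patience=50)
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            x = rng.standard_normal((300, 10))
            y = x[:, 0] * x[:, 1] + x[:, 2] ** 2 - 1
            y = (y + 0.3 * rng.standard_normal(300) - y.mean()) / y.std()
            losses = {}
            for hid in [(10,), (50, 50)]:
                m = train_mlp(x[:240], y[:240], x[240:], y[240:],
                              hidden=hid, config=cfg, seed=s)
                losses[hid] = m.log["best_val_loss"]
            wins += losses[(50, 50)] < losses[(10,)]
        assert wins >= 3

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            tune_hyperparameters(rng.standard_normal((20, 3)),
                                 rng.standard_normal(20), np.arange(20),
                                 TrainConfig(grid=()))


class TestPerformanceMetrics:
    def test_perfect_prediction(self, rng):
        y = rng.standard_normal(20)
        m = performance_metrics(y, y.copy())
        assert (m["r"], m["mse"], m["rmse"], m["mae"]) == (1.0, 0, 0, 0)

    def test_anticorrelated(self, rng):
        y = rng.standard_normal(20)
        assert performance_metrics(y, -y)["r"] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        m = performance_metrics(np.array([0.0, 1, 2]), np.array([0.0, 0, 3]))
        assert m["r"] == pytest.approx(0.866, abs=5e-4)
        assert m["mae"] == pytest.approx(1 / 3, abs=1e-12)
        assert m["mse"] == pytest.approx((0 + 0.25 + 0.25) / 3, abs=1e-12)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            performance_metrics(np.ones(5), np.arange(5.0))


class TestCrossValidatedPredict:
    def test_out_of_fold_coverage_and_null(self):
        # zero-signal cohort: mean r within +-0.1 of 0 over 10 fold seeds
        rng = np.random.default_rng(7)
        x = rng.standard_normal((150, 30))
        y = rng.standard_normal(150)
        conf = rng.standard_normal((150, 2))
        fam = np.arange(150) // 2
        cfg = TrainConfig(grid=((10,),), max_epochs=60, patience=15)
        res = cross_validated_predict(x, y, conf, fam, config=cfg,
                                      n_repetitions=10, seed=0)
        assert not np.isnan(res.predictions).any()
        assert abs(res.mean_r) < 0.1

    def test_empty_selection_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            cross_validated_predict(rng.standard_normal((50, 10)),
                                    rng.standard_normal(50),
                                    rng.standard_normal((50, 2)),
                                    np.arange(50),
                                    selection=np.zeros(10, bool))

    def test_monotone_in_effect_size(self):
        # mean r non-decreasing over a 3-point planted effect-size grid
        cfg = TrainConfig(grid=((10,),), max_epochs=100, patience=20)
        means = []
        for beta in (0.0, 0.15, 0.5):
            rs = []
            for s in range(3):
                x, y, _ = synth.planted_features(200, 30, 10, beta=beta,
                                                 seed=s)
                conf = np.random.default_rng(s).standard_normal((200, 2))
                rs.append(cross_validated_predict(
                    x, y, conf, np.arange(200), config=cfg,
                    n_repetitions=1, seed=s).mean_r)
            means.append(np.mean(rs))
        assert means[0] <= means[1] <= means[2]


class TestTransfer:
    def _cohort(self, seed, n=200, p=40, beta=0.35):
        x, y, _ = synth.planted_features(n, p, 15, beta=beta, seed=seed)
        conf = np.random.default_rng(seed + 50).standard_normal((n, 2))
        fams = np.arange(n)
        return x, y, conf, fams

    def test_transfer_to_itself_matches_in_sample(self, tiny_train):
        x, y, conf, fams = self._cohort(0)
        fitted = fit_full(x, y, conf, fams, config=tiny_train, seed=1)
        a = transfer_predict(fitted, x, y, conf)
        b = transfer_predict(fitted, x, y, conf)
        assert np.array_equal(a["predictions"], b["predictions"])
        assert a["r"] > 0.3               # in-sample fit on planted signal

    def test_permuted_target_transfers_at_chance(self, tiny_train):
        x, y, conf, fams = self._cohort(1)
        fitted = fit_full(x, y, conf, fams, config=tiny_train, seed=1)
        x2, y2, conf2, _ = self._cohort(2)
        y_perm = np.random.default_rng(3).permutation(y2)
        out = transfer_predict(fitted, x2, y_perm, conf2)
        assert abs(out["r"]) < 0.2

    def test_performance_pattern_correlates_across_cohorts(self, tiny_train):
        """Two cohorts from the same generator: per-selection performance
        vectors (graded random-edge selections) correlate positively."""
        ks = (4, 8, 16, 24, 32, 40)
        rs = {0: [], 1: []}
        for c, seed in enumerate((10, 20)):
            x, y, conf, fams = self._cohort(seed, n=250)
            for k in ks:
                sel = random_edge_selection(k, 40, seed=99)
                rs[c].append(cross_validated_predict(
                    x, y, conf, fams, selection=sel, config=tiny_train,
                    n_repetitions=1, seed=0).mean_r)
        assert np.corrcoef(rs[0], rs[1])[0, 1] > 0.5


def test_architecture_parameter_count():
    m = MLPRegressor(20, hidden=(10, 5))
    assert m.n_params == 20 * 10 + 10 + 10 * 5 + 5 + 5 * 1 + 1
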