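"""Risk-model contract tests: recovery on known proportional-hazards data,
T-learner independence, determinism, prediction identities, tuning and
serialization."""

import numpy as np
import pytest

from survrec.coxloss import StepFunction
from survrec.models import (FittedRiskModel, NetConfig, fit_balanced_net,
                            fit_t_cph, fit_t_deepsurv, load_model,
                            predict_survival, save_model,
                            tune_hyperparameters)

FAST = NetConfig(shared_layers=(16,), head_layers=(8,), max_iter=300,
                 patience=150, lr=0.01)


def _labels(d):
    return (d["time"], d["event"])


class TestTCph:
    def test_recovers_known_coefficients(self, ph_arm_data):
        m = fit_t_cph(ph_arm_data[0]["X"], _labels(ph_arm_data[0]),
                      ph_arm_data[1]["X"], _labels(ph_arm_data[1]))
        for arm in (0, 1):
            np.testing.assert_allclose(m.linear_coefs[arm], [0.7, -0.3],
                                       atol=0.1)

    def test_constant_covariates_zero_coefficient(self):
        rng = np.random.default_rng(0)
        n = 200
        X = np.ones((n, 2))
        t = rng.exponential(50, n)
        m = fit_t_cph(X, (t, np.ones(n, int)), X, (t, np.ones(n, int)))
        np.testing.assert_array_equal(m.linear_coefs[0], 0.0)

    def test_arm_independence(self, ph_arm_data):
        m1 = fit_t_cph(ph_arm_data[0]["X"], _labels(ph_arm_data[0]),
                       ph_arm_data[1]["X"], _labels(ph_arm_data[1]))
        rng = np.random.default_rng(1)
        X1_garbled = rng.permutation(ph_arm_data[1]["X"])
        m2 = fit_t_cph(ph_arm_data[0]["X"], _labels(ph_arm_data[0]),
                       X1_garbled, _labels(ph_arm_data[1]))
        np.testing.assert_array_equal(m1.linear_coefs[0], m2.linear_coefs[0])
        np.testing.assert_array_equal(m1.baselines[0].values,
                                      m2.baselines[0].values)

    def test_too_few_events_error(self):
        X = np.random.default_rng(0).normal(0, 1, (10, 2))
        t = np.linspace(1, 10, 10)
        with pytest.raises(ValueError, match="events"):
            fit_t_cph(X, (t, np.zeros(10, int)), X, (t, np.ones(10, int)))


class TestTDeepSurv:
    def test_null_effect_data_gives_flat_risks(self):
        rng = np.random.default_rng(2)
        n = 600
        X = rng.normal(0, 1, (n, 3))
        t = rng.exponential(50, n)          # no covariate effect
        e = np.ones(n, int)
        m = fit_t_deepsurv(X, (t, e), X, (t, e), FAST)
        g = m.predict_log_risk(0, X)
        assert np.std(g) < 0.5              # near-constant log-risk

    def test_seeded_determinism(self, ph_arm_data):
        sub = {a: {k: v[:800] for k, v in d.items()}
               for a, d in ph_arm_data.items()}
        runs = []
        for _ in range(2):
            m = fit_t_deepsurv(sub[0]["X"], _labels(sub[0]),
                               sub[1]["X"], _labels(sub[1]), FAST)
            runs.append(m.metadata["arm0_val_loss"])
        assert runs[0] == runs[1]

    def test_concordance_close_to_cph_on_linear_data(self, ph_arm_data):
        from lifelines.utils import concordance_index
        sub = {a: {k: v[:2000] for k, v in d.items()}
               for a, d in ph_arm_data.items()}
        cfg = NetConfig(shared_layers=(16,), head_layers=(8,), max_iter=800,
                        patience=400, lr=0.01)
        md = fit_t_deepsurv(sub[0]["X"], _labels(sub[0]),
                            sub[1]["X"], _labels(sub[1]), cfg)
        mc = fit_t_cph(sub[0]["X"], _labels(sub[0]),
                       sub[1]["X"], _labels(sub[1]))
        ci_d = concordance_index(sub[0]["time"],
                                 -md.predict_log_risk(0, sub[0]["X"]),
                                 sub[0]["event"])
        ci_c = concordance_index(sub[0]["time"],
                                 -mc.predict_log_risk(0, sub[0]["X"]),
                                 sub[0]["event"])
        assert abs(ci_d - ci_c) < 0.02


class TestBalancedNet:
    def test_alpha_zero_identity_encoder_agrees_with_t_learner(self,
                                                               ph_arm_data):
        from survrec.ite import ite_rst
        sub = {a: {k: v[:1500] for k, v in d.items()}
               for a, d in ph_arm_data.items()}
        X = np.vstack([sub[0]["X"], sub[1]["X"]])
        a = np.r_[np.zeros(1500), np.ones(1500)].astype(int)
        t = np.r_[sub[0]["time"], sub[1]["time"]]
        e = np.r_[sub[0]["event"], sub[1]["event"]]
        cfg = NetConfig(shared_layers=(), head_layers=(16,), max_iter=600,
                        patience=300, lr=0.01, seed=4)
        mb = fit_balanced_net(X, a, (t, e), cfg, variant="bites")
        md = fit_t_deepsurv(sub[0]["X"], _labels(sub[0]),
                            sub[1]["X"], _labels(sub[1]),
                            NetConfig(shared_layers=(16,), head_layers=(),
                                      max_iter=600, patience=300, lr=0.01,
                                      seed=4))
        grid = np.arange(0.0, 121.0)
        ite_b = ite_rst(predict_survival(mb, X, grid))
        ite_d = ite_rst(predict_survival(md, X, grid))
        agreement = np.mean(np.sign(ite_b) == np.sign(ite_d))
        assert agreement >= 0.9

    def test_negative_alpha_rejected(self, ph_arm_data):
        X = ph_arm_data[0]["X"][:50]
        with pytest.raises(ValueError):
            fit_balanced_net(X, np.r_[np.zeros(25), np.ones(25)].astype(int),
                             (ph_arm_data[0]["time"][:50],
                              ph_arm_data[0]["event"][:50]),
                             NetConfig(alpha=-1.0), variant="snb")

    def test_seeded_determinism(self, ph_arm_data):
        sub = {a: {k: v[:500] for k, v in d.items()}
               for a, d in ph_arm_data.items()}
        X = np.vstack([sub[0]["X"], sub[1]["X"]])
        a = np.r_[np.zeros(500), np.ones(500)].astype(int)
        t = np.r_[sub[0]["time"], sub[1]["time"]]
        e = np.r_[sub[0]["event"], sub[1]["event"]]
        cfg = NetConfig(shared_layers=(8,), head_layers=(8,), max_iter=150,
                        patience=100, alpha=1.0, seed=7)
        v1 = fit_balanced_net(X, a, (t, e), cfg, "snb").metadata["val_loss"]
        v2 = fit_balanced_net(X, a, (t, e), cfg, "snb").metadata["val_loss"]
        assert v1 == v2


class TestPredictSurvival:
    def _hand_model(self, beta, lam):
        """Linear model with exact exponential baseline H0(t) = lam * t."""
        grid = np.arange(0.0, 121.0)
        baseline = StepFunction(grid, lam * grid)
        return FittedRiskModel(kind="t_cph",
                               baselines={0: baseline, 1: baseline},
                               linear_coefs={0: np.asarray(beta),
                                             1: np.asarray(beta)})

    def test_zero_hazard_gives_unit_survival(self):
        m = self._hand_model([0.5], 0.0)
        curves = predict_survival(m, [[1.0], [2.0]], np.arange(0.0, 121.0))
        np.testing.assert_array_equal(curves.S0, 1.0)

    def test_closed_form_proportional_hazards(self):
        beta, lam = [0.8], 0.01
        m = self._hand_model(beta, lam)
        X = np.array([[0.0], [1.0], [-1.0]])
        grid = np.arange(0.0, 121.0)
        curves = predict_survival(m, X, grid)
        expected = np.exp(-lam * grid[None, :] * np.exp(X @ beta)[:, None])
        np.testing.assert_allclose(curves.S0, expected, atol=1e-6)

    def test_arm_zero_unchanged_by_arm_one_edit(self, ph_arm_data):
        sub = {a: {k: v[:500] for k, v in d.items()}
               for a, d in ph_arm_data.items()}
        m = fit_t_cph(sub[0]["X"], _labels(sub[0]),
                      sub[1]["X"], _labels(sub[1]))
        grid = np.arange(0.0, 121.0)
        before = predict_survival(m, sub[0]["X"][:10], grid).S0.copy()
        m.linear_coefs[1] = m.linear_coefs[1][::-1].copy()
        after = predict_survival(m, sub[0]["X"][:10], grid).S0
        np.testing.assert_array_equal(before, after)

    def test_unsorted_grid_rejected(self, ph_arm_data):
        m = self._hand_model([0.1], 0.01)
        with pytest.raises(ValueError):
            predict_survival(m, [[0.0]], np.array([0.0, 2.0, 1.0]))


class TestTuning:
    def _folds(self, n, k=3, seed=0):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        chunks = np.array_split(perm, k)
        return [(np.setdiff1d(np.arange(n), c), c) for c in chunks]

    def _data(self, n=400):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (n, 2))
        a = (rng.random(n) < 0.5).astype(int)
        lam = 0.02 * np.exp(0.7 * X[:, 0] - 0.3 * a)
        t = rng.exponential(1 / lam)
        return X, a, (t, np.ones(n, int))

    def test_single_point_space(self):
        X, a, y = self._data()
        base = NetConfig(max_iter=60, patience=60)
        cfg = tune_hyperparameters(X, a, y, self._folds(len(X)),
                                   {"lr": [0.02]}, variant="snb",
                                   base_config=base)
        assert cfg.lr == 0.02

    def test_rerun_determinism_random_subsample(self):
        X, a, y = self._data()
        base = NetConfig(max_iter=40, patience=40)
        space = {"lr": [0.3, 0.01, 0.003], "shared_layers": [(4,), (8,)]}
        picks = [tune_hyperparameters(X, a, y, self._folds(len(X)), space,
                                      variant="snb", base_config=base,
                                      n_draws=3, seed=5) for _ in range(2)]
        assert picks[0] == picks[1]

    def test_empty_space_rejected(self):
        X, a, y = self._data(100)
        with pytest.raises(ValueError):
            tune_hyperparameters(X, a, y, self._folds(100), {}, "snb")


def test_save_load_roundtrip(tmp_path, ph_arm_data):
    sub = {a: {k: v[:400] for k, v in d.items()}
           for a, d in ph_arm_data.items()}
    for fit in ("cph", "net"):
        if fit == "cph":
            m = fit_t_cph(sub[0]["X"], _labels(sub[0]),
                          sub[1]["X"], _labels(sub[1]))
        else:
            X = np.vstack([sub[0]["X"], sub[1]["X"]])
            a = np.r_[np.zeros(400), np.ones(400)].astype(int)
            t = np.r_[sub[0]["time"], sub[1]["time"]]
            e = np.r_[sub[0]["event"], sub[1]["event"]]
            m = fit_balanced_net(X, a, (t, e),
                                 NetConfig(shared_layers=(8,),
                                           head_layers=(4,), max_iter=80,
                                           patience=80), "snb")
        path = tmp_path / f"{fit}.json"
        save_model(m, str(path))
        m2 = load_model(str(path))
        grid = np.arange(0.0, 121.0)
        X_test = sub[0]["X"][:20]
        c1 = predict_survival(m, X_test, grid)
        c2 = predict_survival(m2, X_test, grid)
        np.testing.assert_allclose(c1.S0, c2.S0, atol=1e-12)
        np.testing.assert_allclose(c1.S1, c2.S1, atol=1e-12)
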