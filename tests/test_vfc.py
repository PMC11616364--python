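"""Variational feature compressor: KL, loss decomposition, gradients,
training behavior, transform contract and multi-run selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antioxpred import (
    GbtParams,
    InputError,
    VariationalFeatureCompressor,
    VfcConfig,
    gbt_train,
    kl_diag_gaussian,
    select_compressor,
    vfc_fit,
)


def _hand_model(d=4, k=2, lam=0.5, mu0=0.0, sigma0=1.0):
    """A compressor with hand-set parameters: zero hidden weights so the
    heads see a zero hidden vector, mean head emitting ``mu0`` and scale
    head emitting ``sigma0`` through its bias."""
    m = VariationalFeatureCompressor(latent_dim=k, hidden_dims=(3,), lam=lam)
    m.n_features_in_ = d
    m.mean_ = np.zeros(d)
    m.scale_ = np.ones(d)
    m.params_ = {
        "W0": np.zeros((d, 3)),
        "b0": np.zeros(3),
        "Wm": np.zeros((3, k)),
        "bm": np.full(k, mu0),
        "Ws": np.zeros((3, k)),
        # softplus inverse: softplus(log(e^s - 1)) = s
        "bs": np.full(k, np.log(np.expm1(sigma0))),
        "wc": np.zeros(k),
        "bc": np.zeros(1),
    }
    return m


def _separable_data(n=120, d=10, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, d))
    X[:, 0] += 4.0 * y
    return X, y


class TestKl:
    def test_standard_normal_posterior_gives_zero(self):
        assert kl_diag_gaussian(np.zeros((1, 3)), np.ones((1, 3)))[0] == 0.0

    def test_hand_computed_value(self):
        # K=1, mu=1, sigma=2: 0.5*(4 + 1 - 1 - ln 4)
        expected = 0.5 * (4 + 1 - 1 - np.log(4.0))
        assert kl_diag_gaussian([[1.0]], [[2.0]])[0] == pytest.approx(expected)
        assert expected == pytest.approx(1.3069, abs=1e-4)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_nonnegative_everywhere(self, seed):
        rng = np.random.default_rng(seed)
        mu = rng.normal(0, 3, (5, 4))
        sigma = rng.uniform(0.05, 5.0, (5, 4))
        assert np.all(kl_diag_gaussian(mu, sigma) >= 0.0)

    def test_matches_monte_carlo_estimate(self):
        """Closed form within 3 SE of a 1e5-sample Monte-Carlo estimate."""
        rng = np.random.default_rng(42)
        n_mc = 100_000
        for _ in range(20):
            mu = rng.normal(0, 1.5)
            sigma = rng.uniform(0.3, 2.5)
            z = rng.normal(mu, sigma, n_mc)
            # log q(z) - log s(z) under z ~ q
            log_ratio = (
                -0.5 * ((z - mu) / sigma) ** 2 - np.log(sigma)
            ) - (-0.5 * z**2)
            se = log_ratio.std(ddof=1) / np.sqrt(n_mc)
            closed = kl_diag_gaussian([[mu]], [[sigma]])[0]
            assert abs(closed - log_ratio.mean()) < 3 * se


class TestLoss:
    def test_lambda_zero_reduces_to_classification_nll(self, rng):
        m = _hand_model(lam=0.0, mu0=0.7, sigma0=1.3)
        X = rng.normal(size=(6, 4))
        y = rng.integers(0, 2, 6).astype(float)
        eps = rng.standard_normal((6, 2))
        out = m.loss(X, y, eps=eps)
        assert out["total"] == pytest.approx(out["cross_entropy"])
        # zero classifier head -> p = 1/2 for every sample
        assert out["cross_entropy"] == pytest.approx(np.log(2.0))

    def test_standard_normal_posterior_has_zero_kl_component(self, rng):
        m = _hand_model(lam=2.0, mu0=0.0, sigma0=1.0)
        X = rng.normal(size=(5, 4))
        out = m.loss(X, np.ones(5), eps=np.zeros((5, 2)))
        # scale floor of 1e-6 leaves an O(1e-12) residual
        assert out["kl"] == pytest.approx(0.0, abs=1e-9)

    def test_linear_in_lambda_with_fixed_parameters(self, rng):
        X = rng.normal(size=(8, 4))
        y = rng.integers(0, 2, 8).astype(float)
        eps = rng.standard_normal((8, 2))
        outs = {}
        for lam in (0.0, 0.5, 2.0):
            m = _hand_model(lam=lam, mu0=1.1, sigma0=0.6)
            outs[lam] = m.loss(X, y, eps=eps)
        ce, kl = outs[0.0]["cross_entropy"], outs[2.0]["kl"]
        for lam, out in outs.items():
            assert out["total"] == pytest.approx(ce + lam * kl)

    def test_gradients_match_finite_differences(self):
        """Analytic backprop against central finite differences."""
        rng = np.random.default_rng(0)
        m = VariationalFeatureCompressor(latent_dim=3, hidden_dims=(7, 5), lam=0.3)
        d, B = 6, 4
        params = m._init_params(d, rng)
        for k in params:
            params[k] = params[k] + rng.normal(0, 0.1, params[k].shape)
        X = rng.normal(size=(B, d))
        y = rng.integers(0, 2, B).astype(float)
        eps = rng.standard_normal((B, 3))
        _, _, _, grads = m._grads(params, X, y, eps)

        def f():
            ce, kl, _ = m._loss_terms(params, X, y, eps)
            return float(ce.mean() + m.lam * kl.mean())

        for key, analytic in grads.items():
            p = params[key]
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                h = 1e-6
                p[i] += h
                fp = f()
                p[i] -= 2 * h
                fm = f()
                p[i] += h
                num = (fp - fm) / (2 * h)
                assert analytic[i] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestFit:
    def test_fixed_seed_reproduces_parameters(self):
        X, y = _separable_data()
        cfg = dict(latent_dim=4, hidden_dims=(16,), epochs=30, seed=3)
        m1 = VariationalFeatureCompressor(**cfg).fit(X, y)
        m2 = VariationalFeatureCompressor(**cfg).fit(X, y)
        for k in m1.params_:
            np.testing.assert_array_equal(m1.params_[k], m2.params_[k])

    def test_separable_data_beats_chance_nll(self):
        X, y = _separable_data()
        m = VariationalFeatureCompressor(
            latent_dim=4, hidden_dims=(16,), epochs=60, seed=0
        ).fit(X, y)
        assert m.history_["cross_entropy"][-1] < np.log(2.0)
        assert m.history_["total"][-1] <= m.history_["total"][0]

    def test_huge_lambda_collapses_latent_toward_prior(self):
        X, y = _separable_data()
        m = VariationalFeatureCompressor(
            latent_dim=4, hidden_dims=(16,), epochs=300, lam=1000.0, seed=0
        ).fit(X, y)
        baseline = VariationalFeatureCompressor(
            latent_dim=4, hidden_dims=(16,), epochs=300, lam=0.0, seed=0
        ).fit(X, y)
        assert m.history_["kl"][-1] < 0.1
        assert m.history_["kl"][-1] < 0.05 * baseline.history_["kl"][-1]

    def test_single_class_raises(self):
        X, _ = _separable_data()
        with pytest.raises(InputError, match="both classes"):
            VariationalFeatureCompressor(epochs=2).fit(X, np.ones(len(X)))


class TestTransform:
    def test_default_width_is_15_and_deterministic(self):
        X, y = _separable_data(n=80, d=20)
        m = VariationalFeatureCompressor(epochs=10, seed=0).fit(X, y)
        Z1, Z2 = m.transform(X), m.transform(X)
        assert Z1.shape == (80, 15)
        np.testing.assert_array_equal(Z1, Z2)

    def test_rowwise_map(self):
        X, y = _separable_data(n=40, d=8)
        m = VariationalFeatureCompressor(
            latent_dim=3, hidden_dims=(8,), epochs=10, seed=0
        ).fit(X, y)
        Z = m.transform(np.vstack([X, X[:5]]))
        np.testing.assert_array_equal(Z[40:], Z[:5])

    def test_dim_mismatch_raises(self):
        X, y = _separable_data(n=40, d=8)
        m = VariationalFeatureCompressor(
            latent_dim=3, hidden_dims=(8,), epochs=5, seed=0
        ).fit(X, y)
        with pytest.raises(InputError, match="8"):
            m.transform(np.zeros((2, 9)))

    def test_json_round_trip(self, tmp_path):
        X, y = _separable_data(n=40, d=8)
        m = VariationalFeatureCompressor(
            latent_dim=3, hidden_dims=(8,), epochs=5, seed=0
        ).fit(X, y)
        m.to_json(tmp_path / "m.json")
        back = VariationalFeatureCompressor.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.transform(X), m.transform(X))


class TestSelection:
    def _trainer(self, X, y):
        return gbt_train(X, y, GbtParams(n_trees=30, seed=0))

    def test_multi_run_returns_argmax_and_report(self):
        X, y = _separable_data(n=100, d=12, seed=2)
        cfg = VfcConfig(
            input_dim=12, latent_dim=3, hidden_dims=(8,), epochs=15,
            n_runs=3, seed=5,
        )
        model, report = select_compressor(X, y, cfg, self._trainer)
        assert len(report.mccs) == 3
        assert report.best_run == int(np.argmax(report.mccs))
        assert report.seeds == [5, 6, 7]
        assert model.seed == 5 + report.best_run

    def test_single_run_is_returned(self):
        X, y = _separable_data(n=60, d=6, seed=3)
        cfg = VfcConfig(
            input_dim=6, latent_dim=2, hidden_dims=(6,), epochs=10, n_runs=1, seed=1
        )
        model, report = select_compressor(X, y, cfg, self._trainer)
        assert report.best_run == 0 and len(report.mccs) == 1

    def test_information_retained_vs_full_features(self):
        """A classifier on the 15 compressed codes matches one on the full
        473-dim matrix when the label depends on a 3-dim linear factor
        embedded across all coordinates; averaged over three draws to damp
        MCC sampling noise on the test split."""
        diffs = []
        for seed in (7, 8, 9):
            rng = np.random.default_rng(seed)
            n, d, k, n_tr = 1500, 473, 3, 1000
            z = rng.normal(size=(n, k))
            w = rng.normal(size=k)
            y = (z @ w + 0.3 * rng.standard_normal(n) > 0).astype(int)
            A = rng.normal(size=(k, d)) / np.sqrt(k)
            X = z @ A + 0.5 * rng.normal(size=(n, d))
            full = gbt_train(X[:n_tr], y[:n_tr], GbtParams(seed=0))
            mcc_full = _mcc(y[n_tr:], full.predict(X[n_tr:]).astype(int))
            m = VariationalFeatureCompressor(seed=0).fit(X[:n_tr], y[:n_tr])
            lat = gbt_train(m.transform(X[:n_tr]), y[:n_tr], GbtParams(seed=0))
            mcc_lat = _mcc(y[n_tr:], lat.predict(m.transform(X[n_tr:])).astype(int))
            diffs.append(mcc_full - mcc_lat)
        assert np.mean(diffs) <= 0.05


def _mcc(y_true, y_pred):
    from antioxpred import compute_metrics, confusion_from_predictions

    return compute_metrics(confusion_from_predictions(y_true, y_pred)).mcc
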