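"""Confusion metrics, boosted-tree training and k-fold cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.metrics import matthews_corrcoef

from antioxpred import (
    ConfusionCounts,
    GbtParams,
    InputError,
    LabeledDataset,
    PipelineStageConfig,
    SmoteConfig,
    VfcConfig,
    compute_metrics,
    confusion_from_predictions,
    gbt_train,
    kfold_cv,
)

counts_strategy = st.tuples(
    st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
).filter(lambda t: sum(t) > 0)


class TestMetrics:
    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert (r.acc, r.sn, r.sp, r.mcc, r.f1) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_example(self):
        r = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert r.acc == pytest.approx(0.7)
        assert r.sn == pytest.approx(0.6)
        assert r.sp == pytest.approx(0.8)
        assert r.f1 == pytest.approx(2 / 3)
        assert r.mcc == pytest.approx(10 / np.sqrt(600))

    def test_degenerate_denominator_warns_and_returns_zero(self):
        r = compute_metrics(ConfusionCounts(tp=0, fp=2, tn=8, fn=0))
        assert r.sn == 0.0
        assert any("SN" in w for w in r.warnings)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(counts_strategy)
    def test_mcc_symmetries_and_acc_identity(self, t):
        tp, fp, tn, fn = t
        r = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        swapped = compute_metrics(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
        assert r.mcc == pytest.approx(swapped.mcc)
        # label inversion negates MCC
        inverted = compute_metrics(ConfusionCounts(tp=fn, fp=tn, tn=fp, fn=tp))
        assert r.mcc == pytest.approx(-inverted.mcc)
        # ACC = (SN*P + SP*N)/(P+N), valid whenever P and N are nonzero
        P, N = tp + fn, tn + fp
        if P and N:
            assert r.acc == pytest.approx((r.sn * P + r.sp * N) / (P + N))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(counts_strategy)
    def test_mcc_agrees_with_sklearn(self, t):
        tp, fp, tn, fn = t
        y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
        y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
        ours = compute_metrics(confusion_from_predictions(y_true, y_pred)).mcc
        assert ours == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)

    def test_zero_total_raises(self):
        with pytest.raises(InputError):
            compute_metrics(ConfusionCounts(tp=0, fp=0, tn=0, fn=0))


class TestGbt:
    def test_separable_toy_data_fits_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.5, (40, 2)), rng.normal(5, 0.5, (40, 2))])
        y = np.array([0] * 40 + [1] * 40)
        clf = gbt_train(X, y, GbtParams(seed=0))
        assert (clf.predict(X) == y).mean() == 1.0

    def test_pure_noise_accuracy_within_binomial_null(self):
        """Held-out accuracy on label-independent features stays inside the
        central 99.9% of the Binomial(n, 1/2) null."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 10))
        y = rng.integers(0, 2, 200)
        clf = gbt_train(X[:140], y[:140], GbtParams(seed=0))
        correct = int((clf.predict(X[140:]).astype(int) == y[140:]).sum())
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 60, 0.5)
        assert lo <= correct <= hi

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 5))
        y = (X[:, 0] > 0).astype(int)
        p1 = gbt_train(X, y, GbtParams(seed=9)).predict_proba(X)
        p2 = gbt_train(X, y, GbtParams(seed=9)).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_raises(self):
        with pytest.raises(InputError):
            gbt_train(np.zeros((5, 2)), np.ones(5), GbtParams())


def _latent_style_dataset(n=100, d=12, effect=4.0, seed=0, pos_frac=0.35):
    rng = np.random.default_rng(seed)
    n_pos = int(n * pos_frac)
    y = np.array([1] * n_pos + [0] * (n - n_pos))
    X = rng.normal(size=(n, d))
    X[y == 1, :3] += effect
    ids = [str(i) for i in range(n)]
    return LabeledDataset(ids=ids, features=X, labels=y)


def _fast_config(use_vfc=True):
    return PipelineStageConfig(
        smote=SmoteConfig(seed=0),
        vfc=VfcConfig(input_dim=12, latent_dim=4, hidden_dims=(16,), epochs=40, seed=0),
        gbt=GbtParams(n_trees=60, seed=0),
        use_vfc=use_vfc,
    )


class TestKfoldCv:
    def test_averages_are_fold_means_and_fold_count(self):
        ds = _latent_style_dataset()
        rep = kfold_cv(ds, k=5, config=_fast_config(), mode="fold-safe", seed=0)
        assert len(rep.per_fold) == 5
        for attr in ("acc", "sn", "sp", "mcc", "f1"):
            vals = [getattr(r, attr) for r in rep.per_fold]
            assert getattr(rep.averages, attr) == pytest.approx(np.mean(vals))

    def test_stratification_balances_folds(self):
        ds = _latent_style_dataset(n=100, pos_frac=0.3)
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        for _, val_idx in skf.split(ds.features, ds.labels):
            assert val_idx.size == 20
            assert abs(ds.labels[val_idx].sum() - 6) <= 1

    def test_strong_signal_near_perfect_separation(self):
        ds = _latent_style_dataset(effect=8.0)
        rep = kfold_cv(ds, k=5, config=_fast_config(use_vfc=False), mode="fold-safe", seed=0)
        assert rep.averages.acc >= 0.95

    def test_paper_mode_balances_before_split(self):
        ds = _latent_style_dataset(n=80, pos_frac=0.25)
        rep = kfold_cv(ds, k=4, config=_fast_config(use_vfc=False), mode="paper", seed=0)
        # 20 pos + 60 neg -> 120 samples after balancing, 30 per fold
        assert sum(r.counts.total for r in rep.per_fold) == 120

    def test_k_exceeding_n_raises(self):
        ds = _latent_style_dataset(n=20)
        with pytest.raises(InputError):
            kfold_cv(ds, k=30, config=_fast_config())
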