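"""Variational feature compressor (VFC).

The compressor learns a stochastic map from the 473-D feature vector r to a
low-dimensional latent code p by optimizing a variational bound on the
information-bottleneck objective

    max  M(C, P) - lambda * M(R, P),

where C is the class label and M denotes mutual information. With a
variational classifier t(c|p), a diagonal-Gaussian encoder
q(p|r) = N(E(r), diag(D(r)^2)) and a standard-normal prior s(p), the negated
Monte-Carlo bound minimized per batch is

    mean_i [ -log t(c_i | z_i) ]  +  lambda * mean_i KL( q(p|r_i) || s(p) ),

with z_i = E(r_i) + eps * D(r_i), eps ~ N(0, I) (the reparameterization
trick), and the KL term in closed form:

    KL = 1/2 * sum_k ( sigma_k^2 + mu_k^2 - 1 - 2 log sigma_k ).

The encoder is a plain multilayer perceptron with rectified-linear hidden
layers feeding a mean head and a softplus-positive scale head; the
classifier head is affine-plus-logistic on the latent code. Training is
full manual backpropagation with the Adam update rule plus decoupled weight
decay on the weight matrices — the model is small enough that no autodiff
framework is needed. The decay term regularizes the update only; the
reported loss stays the pure variational bound. At transform time the code
is the deterministic posterior mean E(r).

Because weight initialization and latent sampling are stochastic, repeated
fits yield different latent feature sets; :func:`select_compressor` trains
several candidates and keeps the one whose features give the best
validation Matthews correlation under the downstream classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import train_test_split

from .errors import InputError, NumericalError

_SCALE_FLOOR = 1e-6


@dataclass
class VfcConfig:
    """Hyperparameters of the compressor.

    ``lam`` is the information-bottleneck trade-off: 0 reduces training to a
    plain latent classifier; large values collapse the posterior onto the
    prior. The default 1e-3 keeps the compression pressure gentle enough for
    the classification term to dominate early training.
    """

    input_dim: int = 473
    hidden_dims: tuple[int, ...] = (256, 64)
    latent_dim: int = 15
    lam: float = 1e-2
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    n_runs: int = 1
    seed: int = 0
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        self.hidden_dims = tuple(int(h) for h in self.hidden_dims)
        if self.latent_dim < 1:
            raise InputError("latent_dim must be >= 1")
        if self.lam < 0:
            raise InputError("lambda must be non-negative")
        if self.weight_decay < 0:
            raise InputError("weight_decay must be non-negative")
        if self.n_runs < 1:
            raise InputError("n_runs must be >= 1")
        if not (0.0 < self.val_fraction < 1.0):
            raise InputError("val_fraction must lie in (0, 1)")


def kl_diag_gaussian(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Closed-form KL( N(mu, diag(sigma^2)) || N(0, I) ), summed over dims.

    Accepts (n, K) arrays and returns per-row KL values; always >= 0, equal
    to 0 exactly when mu = 0 and sigma = 1.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    if np.any(sigma <= 0):
        raise InputError("sigma must be strictly positive")
    return 0.5 * np.sum(sigma**2 + mu**2 - 1.0 - 2.0 * np.log(sigma), axis=1)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _bce_from_logits(logits: np.ndarray, y: np.ndarray) -> np.ndarray:
    # numerically stable -[y log p + (1-y) log(1-p)]
    return np.maximum(logits, 0.0) - logits * y + np.log1p(np.exp(-np.abs(logits)))


class VariationalFeatureCompressor(TransformerMixin, BaseEstimator):
    """Supervised dimensionality reduction by a variational bottleneck.

    Parameters mirror :class:`VfcConfig`. Fitted attributes carry trailing
    underscores: ``params_`` (weights), ``mean_``/``scale_`` (input
    standardizer, fitted on the training matrix), ``history_`` (per-epoch
    loss, cross-entropy and KL components), ``n_features_in_``.
    """

    def __init__(
        self,
        latent_dim: int = 15,
        hidden_dims: tuple[int, ...] = (256, 64),
        lam: float = 1e-2,
        epochs: int = 200,
        batch_size: int = 64,
        learning_rate: float = 1e-3,
        weight_decay: float = 1e-2,
        seed: int = 0,
    ):
        self.latent_dim = latent_dim
        self.hidden_dims = hidden_dims
        self.lam = lam
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.seed = seed

    # ---------------------------------------------------------------- setup

    def _init_params(self, d: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        dims = [d, *self.hidden_dims]
        params: dict[str, np.ndarray] = {}
        for i in range(len(dims) - 1):
            fan_in = dims[i]
            params[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (dims[i], dims[i + 1]))
            params[f"b{i}"] = np.zeros(dims[i + 1])
        h = dims[-1]
        k = self.latent_dim
        params["Wm"] = rng.normal(0.0, np.sqrt(1.0 / h), (h, k))
        params["bm"] = np.zeros(k)
        params["Ws"] = rng.normal(0.0, np.sqrt(1.0 / h), (h, k))
        # softplus(0.5413) = 1: start with a unit-scale posterior
        params["bs"] = np.full(k, np.log(np.e - 1.0))
        params["wc"] = rng.normal(0.0, np.sqrt(1.0 / k), (k,))
        params["bc"] = np.zeros(1)
        return params

    # -------------------------------------------------------------- forward

    def _encode(self, params: dict[str, np.ndarray], Xs: np.ndarray):
        h = Xs
        acts = []
        n_hidden = len(self.hidden_dims)
        for i in range(n_hidden):
            a = h @ params[f"W{i}"] + params[f"b{i}"]
            h = np.maximum(a, 0.0)
            acts.append((a, h))
        mu = h @ params["Wm"] + params["bm"]
        s_raw = h @ params["Ws"] + params["bs"]
        sigma = _softplus(s_raw) + _SCALE_FLOOR
        return mu, sigma, s_raw, acts

    def _loss_terms(
        self,
        params: dict[str, np.ndarray],
        Xs: np.ndarray,
        y: np.ndarray,
        eps: np.ndarray,
    ):
        mu, sigma, s_raw, acts = self._encode(params, Xs)
        z = mu + eps * sigma
        logits = z @ params["wc"] + params["bc"][0]
        ce = _bce_from_logits(logits, y)
        kl = kl_diag_gaussian(mu, sigma)
        cache = (mu, sigma, s_raw, acts, z, logits)
        return ce, kl, cache

    def loss(
        self,
        X: np.ndarray,
        y: np.ndarray,
        rng: np.random.Generator | None = None,
        eps: np.ndarray | None = None,
    ) -> dict[str, float]:
        """Monte-Carlo bound on a batch: total, cross-entropy and KL parts.

        ``eps`` fixes the latent noise (one draw per sample); otherwise it is
        drawn from ``rng`` (or a fresh generator).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] == 0:
            raise InputError("empty batch")
        Xs = self._standardize(X)
        if eps is None:
            rng = rng if rng is not None else np.random.default_rng()
            eps = rng.standard_normal((X.shape[0], self.latent_dim))
        ce, kl, _ = self._loss_terms(self.params_, Xs, y, eps)
        ce_m, kl_m = float(ce.mean()), float(kl.mean())
        total = ce_m + self.lam * kl_m
        if not np.isfinite(total):
            part = "cross-entropy" if not np.isfinite(ce_m) else "KL"
            raise NumericalError(f"non-finite loss: {part} component diverged")
        return {"total": total, "cross_entropy": ce_m, "kl": kl_m}

    # ------------------------------------------------------------- backward

    def _grads(
        self,
        params: dict[str, np.ndarray],
        Xs: np.ndarray,
        y: np.ndarray,
        eps: np.ndarray,
    ):
        B = Xs.shape[0]
        ce, kl, cache = self._loss_terms(params, Xs, y, eps)
        mu, sigma, s_raw, acts, z, logits = cache
        loss = float(ce.mean() + self.lam * kl.mean())

        g: dict[str, np.ndarray] = {}
        dlogit = (_sigmoid(logits) - y) / B
        g["wc"] = z.T @ dlogit
        g["bc"] = np.array([dlogit.sum()])
        dz = np.outer(dlogit, params["wc"])
        dmu = dz + self.lam * mu / B
        dsigma = dz * eps + self.lam * (sigma - 1.0 / sigma) / B
        ds_raw = dsigma * _sigmoid(s_raw)

        h_last = acts[-1][1] if acts else Xs
        g["Wm"] = h_last.T @ dmu
        g["bm"] = dmu.sum(axis=0)
        g["Ws"] = h_last.T @ ds_raw
        g["bs"] = ds_raw.sum(axis=0)

        dh = dmu @ params["Wm"].T + ds_raw @ params["Ws"].T
        for i in range(len(self.hidden_dims) - 1, -1, -1):
            a_i, _ = acts[i]
            da = dh * (a_i > 0)
            h_prev = acts[i - 1][1] if i > 0 else Xs
            g[f"W{i}"] = h_prev.T @ da
            g[f"b{i}"] = da.sum(axis=0)
            dh = da @ params[f"W{i}"].T
        return loss, float(ce.mean()), float(kl.mean()), g

    # ------------------------------------------------------------------ fit

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_

    def fit(self, X: np.ndarray, y: np.ndarray) -> "VariationalFeatureCompressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise InputError("X must be 2-D with one label per row")
        if len(np.unique(y)) < 2:
            raise InputError("training data must contain both classes")
        n, d = X.shape
        self.n_features_in_ = d
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        self.scale_ = np.where(std > 0, std, 1.0)
        Xs = self._standardize(X)

        rng = np.random.default_rng(self.seed)
        params = self._init_params(d, rng)
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in params.items()}
        beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
        lr = self.learning_rate
        step = 0

        history = {"total": [], "cross_entropy": [], "kl": []}
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            ep_tot = ep_ce = ep_kl = 0.0
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                eps = rng.standard_normal((idx.size, self.latent_dim))
                loss, ce_m, kl_m, grads = self._grads(params, Xs[idx], y[idx], eps)
                if not np.isfinite(loss):
                    raise NumericalError("training loss diverged to non-finite values")
                step += 1
                for key, grad in grads.items():
                    m[key] = beta1 * m[key] + (1 - beta1) * grad
                    v[key] = beta2 * v[key] + (1 - beta2) * grad**2
                    m_hat = m[key] / (1 - beta1**step)
                    v_hat = v[key] / (1 - beta2**step)
                    update = m_hat / (np.sqrt(v_hat) + adam_eps)
                    if key.startswith("W"):
                        # decoupled weight decay on weight matrices only
                        update = update + self.weight_decay * params[key]
                    params[key] = params[key] - lr * update
                ep_tot += loss
                ep_ce += ce_m
                ep_kl += kl_m
                n_batches += 1
            history["total"].append(ep_tot / n_batches)
            history["cross_entropy"].append(ep_ce / n_batches)
            history["kl"].append(ep_kl / n_batches)

        self.params_ = params
        self.history_ = history
        return self

    # ------------------------------------------------------------ transform

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Deterministic latent codes: the posterior means E(r), n x K."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise InputError(
                f"expected {self.n_features_in_} features, got {X.shape}"
            )
        mu, _, _, _ = self._encode(self.params_, self._standardize(X))
        return mu

    def predict_proba_head(self, X: np.ndarray) -> np.ndarray:
        """Class probability from the training-time classifier head."""
        self._check_fitted()
        z = self.transform(X)
        return _sigmoid(z @ self.params_["wc"] + self.params_["bc"][0])

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise InputError("compressor is not fitted")

    # -------------------------------------------------------- serialization

    def to_json(self, path: str | Path) -> None:
        self._check_fitted()
        payload = {
            "config": {
                "latent_dim": self.latent_dim,
                "hidden_dims": list(self.hidden_dims),
                "lam": self.lam,
                "epochs": self.epochs,
                "batch_size": self.batch_size,
                "learning_rate": self.learning_rate,
                "weight_decay": self.weight_decay,
                "seed": self.seed,
            },
            "n_features_in": int(self.n_features_in_),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "params": {k: np.asarray(p).tolist() for k, p in self.params_.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "VariationalFeatureCompressor":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        cfg["hidden_dims"] = tuple(cfg["hidden_dims"])
        model = cls(**cfg)
        model.n_features_in_ = int(payload["n_features_in"])
        model.mean_ = np.asarray(payload["mean"], dtype=float)
        model.scale_ = np.asarray(payload["scale"], dtype=float)
        model.params_ = {
            k: np.asarray(v, dtype=float) for k, v in payload["params"].items()
        }
        model.history_ = {}
        return model


@dataclass
class SelectionReport:
    """Per-candidate validation MCCs from multi-run compressor selection."""

    mccs: list[float]
    best_run: int
    seeds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def vfc_loss(
    X: np.ndarray,
    y: np.ndarray,
    model: VariationalFeatureCompressor,
    rng: np.random.Generator | None = None,
    eps: np.ndarray | None = None,
) -> dict[str, float]:
    """Functional alias for :meth:`VariationalFeatureCompressor.loss`."""
    return model.loss(X, y, rng=rng, eps=eps)


def vfc_fit(X: np.ndarray, y: np.ndarray, config: VfcConfig) -> VariationalFeatureCompressor:
    """Fit a single compressor from a :class:`VfcConfig`."""
    if X.shape[1] != config.input_dim:
        raise InputError(
            f"config expects {config.input_dim} input features, got {X.shape[1]}"
        )
    model = VariationalFeatureCompressor(
        latent_dim=config.latent_dim,
        hidden_dims=config.hidden_dims,
        lam=config.lam,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        weight_decay=config.weight_decay,
        seed=config.seed,
    )
    return model.fit(X, y)


def select_compressor(
    X: np.ndarray,
    y: np.ndarray,
    config: VfcConfig,
    downstream_trainer: Callable[[np.ndarray, np.ndarray], object],
) -> tuple[VariationalFeatureCompressor, SelectionReport]:
    """Train ``config.n_runs`` compressors and keep the best by validation MCC.

    Run r uses seed ``config.seed + r``. Each candidate's latent features are
    scored by fitting ``downstream_trainer`` (any object with fit/predict
    semantics returned from features+labels) on the transformed training
    split and computing the Matthews correlation on the transformed held-out
    split. Ties resolve to the lowest run index.
    """
    from .metrics import confusion_from_predictions, compute_metrics

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=config.val_fraction, stratify=y, random_state=config.seed
    )
    models: list[VariationalFeatureCompressor | None] = []
    mccs: list[float] = []
    seeds: list[int] = []
    for run in range(config.n_runs):
        run_cfg = VfcConfig(**{**asdict(config), "seed": config.seed + run})
        seeds.append(run_cfg.seed)
        try:
            model = vfc_fit(X_tr, y_tr, run_cfg)
        except NumericalError:
            models.append(None)
            mccs.append(-np.inf)
            continue
        clf = downstream_trainer(model.transform(X_tr), y_tr)
        y_pred = np.asarray(clf.predict(model.transform(X_val))).astype(int)
        report = compute_metrics(confusion_from_predictions(y_val, y_pred))
        models.append(model)
        mccs.append(report.mcc)
    if all(m is None for m in models):
        raise NumericalError("all compressor runs diverged")
    best = int(np.argmax(mccs))  # argmax takes the first maximal index
    return models[best], SelectionReport(
        mccs=[float(m) for m in mccs], best_run=best, seeds=seeds
    )
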