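"""Gradient-boosted-tree classification and k-fold cross-validation.

Tree induction is delegated to xgboost configured to the regularized
logistic objective: logistic loss plus gamma * (leaf count) +
lambda/2 * ||leaf weights||^2. Predictions are the accumulated leaf weights
through the logistic link, thresholded at 0.5. Row and column subsampling
(stochastic gradient boosting) is on by default: on small latent datasets
it diversifies split thresholds across trees, which smooths the ensemble
boundary inside wide-margin regions.

``kfold_cv`` runs the full pipeline per fold. Two orderings of SMOTE
relative to the split are supported:

* ``paper`` — the whole dataset is rebalanced once, then split; this mirrors
  the original protocol but lets synthetic points share information with
  validation folds;
* ``fold-safe`` — rebalancing is applied to each training fold only, so
  validation folds contain only original samples. This is the leak-free
  default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .errors import InputError
from .io import LabeledDataset
from .metrics import MetricsReport, compute_metrics, confusion_from_predictions
from .resampling import SmoteConfig, SmoteOversampler
from .vfc import VfcConfig, vfc_fit


@dataclass
class GbtParams:
    """Boosted-ensemble hyperparameters (K trees, shrinkage, penalties)."""

    n_trees: int = 300
    learning_rate: float = 0.1
    max_depth: int = 4
    gamma: float = 0.0
    reg_lambda: float = 1.0
    subsample: float = 0.7
    colsample_bytree: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise InputError("n_trees must be >= 1")
        if self.gamma < 0 or self.reg_lambda < 0:
            raise InputError("regularization penalties must be non-negative")
        if not (0 < self.subsample <= 1) or not (0 < self.colsample_bytree <= 1):
            raise InputError("subsample fractions must lie in (0, 1]")


def gbt_train(features: np.ndarray, labels: np.ndarray, params: GbtParams) -> XGBClassifier:
    """Fit the boosted-tree classifier on (typically latent) features."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise InputError("training data must contain both classes")
    clf = XGBClassifier(
        n_estimators=params.n_trees,
        learning_rate=params.learning_rate,
        max_depth=params.max_depth,
        gamma=params.gamma,
        reg_lambda=params.reg_lambda,
        subsample=params.subsample,
        colsample_bytree=params.colsample_bytree,
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="hist",
        random_state=params.seed,
        n_jobs=1,
    )
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


@dataclass
class CvReport:
    """Per-fold metrics plus their arithmetic means."""

    per_fold: list[MetricsReport]
    averages: MetricsReport
    mode: str = "fold-safe"
    k: int = 5

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "k": self.k,
            "per_fold": [m.to_dict() for m in self.per_fold],
            "averages": self.averages.to_dict(),
        }


@dataclass
class PipelineStageConfig:
    """Everything the per-fold pipeline needs besides the data."""

    smote: SmoteConfig = field(default_factory=SmoteConfig)
    vfc: VfcConfig = field(default_factory=VfcConfig)
    gbt: GbtParams = field(default_factory=GbtParams)
    use_vfc: bool = True


def _mean_report(reports: list[MetricsReport]) -> MetricsReport:
    return MetricsReport(
        acc=float(np.mean([r.acc for r in reports])),
        sn=float(np.mean([r.sn for r in reports])),
        sp=float(np.mean([r.sp for r in reports])),
        mcc=float(np.mean([r.mcc for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
    )


def _fit_fold(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: PipelineStageConfig,
    apply_smote: bool,
) -> MetricsReport:
    if apply_smote:
        sampler = SmoteOversampler(
            m_neighbors=cfg.smote.m_neighbors,
            target_ratio=cfg.smote.target_ratio,
            seed=cfg.smote.seed,
        )
        X_tr, y_tr = sampler.fit_resample(X_tr, y_tr)
    if cfg.use_vfc:
        vfc_cfg = VfcConfig(**{**cfg.vfc.__dict__, "input_dim": X_tr.shape[1]})
        compressor = vfc_fit(X_tr, y_tr, vfc_cfg)
        X_tr_c = compressor.transform(X_tr)
        X_val_c = compressor.transform(X_val)
    else:
        X_tr_c, X_val_c = X_tr, X_val
    clf = gbt_train(X_tr_c, y_tr, cfg.gbt)
    y_pred = clf.predict(X_val_c).astype(int)
    return compute_metrics(confusion_from_predictions(y_val, y_pred))


def kfold_cv(
    dataset: LabeledDataset,
    k: int = 5,
    config: PipelineStageConfig | None = None,
    mode: str = "fold-safe",
    seed: int = 0,
) -> CvReport:
    """Stratified k-fold cross-validation of the full pipeline."""
    if config is None:
        config = PipelineStageConfig()
    if mode not in ("paper", "fold-safe"):
        raise InputError(f"mode must be 'paper' or 'fold-safe', got {mode!r}")
    if k < 2:
        raise InputError("k must be >= 2")
    X, y = dataset.features, dataset.labels
    if k > X.shape[0]:
        raise InputError(f"k={k} exceeds the number of samples {X.shape[0]}")

    if mode == "paper":
        sampler = SmoteOversampler(
            m_neighbors=config.smote.m_neighbors,
            target_ratio=config.smote.target_ratio,
            seed=config.smote.seed,
        )
        X, y = sampler.fit_resample(X, y)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for tr_idx, val_idx in skf.split(X, y):
        per_fold.append(
            _fit_fold(
                X[tr_idx], y[tr_idx], X[val_idx], y[val_idx],
                config, apply_smote=(mode == "fold-safe"),
            )
        )
    return CvReport(per_fold=per_fold, averages=_mean_report(per_fold), mode=mode, k=k)
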