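"""End-to-end train/predict orchestration and the on-disk model bundle.

A bundle is a directory holding the trained compressor (JSON), the boosted
ensemble (xgboost's native JSON), the pipeline configuration and a manifest
recording seeds, a config hash and per-stage sample/feature counts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .config import PipelineConfig
from .errors import InputError
from .evaluate import gbt_train
from .features import extract_dataset, N_FEATURES
from .io import LabeledDataset
from .resampling import smote_oversample
from .vfc import VariationalFeatureCompressor, select_compressor

_BUNDLE_FILES = ("manifest.json", "config.json", "vfc.json", "gbt.json")


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_train(
    pssm_dir: str | Path,
    ss2_dir: str | Path,
    labels_file: str | Path,
    config: PipelineConfig,
    out_dir: str | Path,
) -> Path:
    """Extract -> rebalance -> compress (multi-run select) -> boost; save bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "config_hash": _config_hash(config), "stages": {}}

    try:
        dataset = extract_dataset(
            pssm_dir, ss2_dir, labels_file, bf=config.bf(), motif=config.motif
        )
    except InputError as exc:
        raise InputError(f"stage 'extract' failed: {exc}") from exc
    log["stages"]["extract"] = {
        "n": dataset.n_samples, "d": dataset.n_features,
    }

    balanced = smote_oversample(dataset, config.smote)
    log["stages"]["smote"] = {"n": balanced.n_samples, "d": balanced.n_features}

    compressor, report = select_compressor(
        balanced.features,
        balanced.labels,
        config.vfc,
        downstream_trainer=lambda X, y: gbt_train(X, y, config.gbt),
    )
    latent = compressor.transform(balanced.features)
    log["stages"]["vfc"] = {
        "n": latent.shape[0], "d": latent.shape[1],
        "selection": report.to_dict(),
    }

    clf = gbt_train(latent, balanced.labels, config.gbt)
    log["stages"]["gbt"] = {"n_trees": config.gbt.n_trees}

    compressor.to_json(out_dir / "vfc.json")
    # save via the underlying booster: the sklearn-wrapper save path expects
    # the removed _estimator_type attribute under current scikit-learn
    clf.get_booster().save_model(out_dir / "gbt.json")
    config.to_json(out_dir / "config.json")
    (out_dir / "manifest.json").write_text(json.dumps(log, indent=2))
    return out_dir


def load_bundle(bundle_dir: str | Path) -> tuple[VariationalFeatureCompressor, XGBClassifier, PipelineConfig]:
    bundle_dir = Path(bundle_dir)
    missing = [f for f in _BUNDLE_FILES if not (bundle_dir / f).exists()]
    if missing:
        raise InputError(f"corrupted bundle {bundle_dir}: missing {missing}")
    try:
        compressor = VariationalFeatureCompressor.from_json(bundle_dir / "vfc.json")
        clf = XGBClassifier()
        clf.load_model(bundle_dir / "gbt.json")
        config = PipelineConfig.from_json(bundle_dir / "config.json")
    except (ValueError, KeyError, json.JSONDecodeError) as exc:
        raise InputError(f"corrupted bundle {bundle_dir}: {exc}") from exc
    return compressor, clf, config


def run_predict(
    bundle_dir: str | Path,
    pssm_dir: str | Path,
    ss2_dir: str | Path,
    out_csv: str | Path,
) -> pd.DataFrame:
    """Predict per-id probability and label; writes ``id,prob,label`` CSV."""
    compressor, clf, config = load_bundle(bundle_dir)
    pssm_dir = Path(pssm_dir)
    ids = sorted(p.stem for p in pssm_dir.glob("*.pssm"))
    if not ids:
        df = pd.DataFrame(columns=["id", "prob", "label"])
        df.to_csv(out_csv, index=False)
        return df

    labels_tmp = Path(out_csv).with_suffix(".labels.tmp.csv")
    pd.DataFrame({"id": ids, "label": 0}).to_csv(labels_tmp, index=False)
    try:
        dataset = extract_dataset(
            pssm_dir, ss2_dir, labels_tmp, bf=config.bf(), motif=config.motif
        )
    finally:
        labels_tmp.unlink(missing_ok=True)

    if dataset.n_features != compressor.n_features_in_:
        raise InputError(
            f"feature dimension {dataset.n_features} does not match bundle "
            f"config input_dim {compressor.n_features_in_}"
        )
    latent = compressor.transform(dataset.features)
    prob = clf.predict_proba(latent)[:, 1]
    label = (prob >= 0.5).astype(int)
    df = pd.DataFrame({"id": dataset.ids, "prob": prob, "label": label})
    df.to_csv(out_csv, index=False)
    return df


def predict_dataset(bundle_dir: str | Path, dataset: LabeledDataset) -> np.ndarray:
    """Probability predictions for an already-extracted dataset."""
    compressor, clf, _ = load_bundle(bundle_dir)
    if dataset.n_features != compressor.n_features_in_:
        raise InputError("feature dimension does not match bundle")
    return clf.predict_proba(compressor.transform(dataset.features))[:, 1]
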