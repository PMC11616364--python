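"""Assembly of the full 473-dimensional feature vector and batch extraction.

Ordering: the 440 evolutionary features first (20 PSSM column means, then the
420 weighted n-gram features of the consensus sequence), then the 33
secondary-structure features (6 state-sequence features, 3 global and 24
local probability features). ``BLOCK_MAP`` records the index ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InputError
from .io import (
    CANONICAL_AA,
    LabeledDataset,
    PssmProfile,
    SecondaryStructureTrack,
    read_pssm,
    read_ss2,
)
from .pssm_features import BackgroundFrequencies, pssm_feature_block
from .ss_features import ss_feature_block

#: Total feature dimensionality and its block decomposition.
N_FEATURES = 473
BLOCK_MAP: dict[str, tuple[int, int]] = {
    "pssm_means": (0, 20),
    "ngram": (20, 440),
    "ss_seq": (440, 446),
    "ss_global": (446, 449),
    "ss_local": (449, 473),
}


def feature_names() -> list[str]:
    """Column names f001..f473 used in feature-table CSV headers."""
    return [f"f{i + 1:03d}" for i in range(N_FEATURES)]


@dataclass
class FeatureVector:
    """One protein's ordered 473-value feature vector with its block map."""

    values: np.ndarray
    block_map: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(BLOCK_MAP)
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise InputError(
                f"feature vector must have exactly {N_FEATURES} values, "
                f"got {self.values.shape}"
            )

    def block(self, name: str) -> np.ndarray:
        lo, hi = self.block_map[name]
        return self.values[lo:hi]


def extract_features(
    profile: PssmProfile,
    track: SecondaryStructureTrack,
    bf: BackgroundFrequencies | None = None,
    motif: str = "bab",
) -> FeatureVector:
    """Full 473-D feature vector for one (PSSM, structure-track) pair."""
    if profile.length != track.length:
        raise ConsistencyError(
            f"length mismatch for {profile.record_id!r}: PSSM has "
            f"{profile.length} rows, structure track has {track.length}"
        )
    if profile.record_id != track.record_id:
        raise ConsistencyError(
            f"record id mismatch: PSSM {profile.record_id!r} vs "
            f"structure track {track.record_id!r}"
        )
    pssm_block = pssm_feature_block(profile, bf)
    ss_block = ss_feature_block(track, motif=motif)
    return FeatureVector(values=np.concatenate([pssm_block.combined, ss_block.combined]))


def read_labels(labels_file: str | Path) -> pd.DataFrame:
    """Read a two-column ``id,label`` CSV; labels must be binary."""
    df = pd.read_csv(labels_file, dtype={"id": str})
    if list(df.columns[:2]) != ["id", "label"]:
        raise InputError(f"{labels_file}: labels file must have columns id,label")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise InputError(f"{labels_file}: duplicate ids {dups}")
    if not set(df["label"].unique()) <= {0, 1}:
        raise InputError(f"{labels_file}: labels must be 0 or 1")
    return df


def extract_dataset(
    pssm_dir: str | Path,
    ss2_dir: str | Path,
    labels_file: str | Path,
    bf: BackgroundFrequencies | None = None,
    motif: str = "bab",
) -> LabeledDataset:
    """Batch-extract an n x 473 dataset, rows in labels-file order.

    Expects one ``<id>.pssm`` and one ``<id>.ss2`` file per labelled id;
    all missing files are reported together.
    """
    pssm_dir, ss2_dir = Path(pssm_dir), Path(ss2_dir)
    labels = read_labels(labels_file)
    missing = []
    for rid in labels["id"]:
        if not (pssm_dir / f"{rid}.pssm").exists():
            missing.append(f"{rid}.pssm")
        if not (ss2_dir / f"{rid}.ss2").exists():
            missing.append(f"{rid}.ss2")
    if missing:
        raise InputError(f"missing input files: {', '.join(missing)}")

    rows = np.empty((len(labels), N_FEATURES))
    for k, rid in enumerate(labels["id"]):
        profile = read_pssm(pssm_dir / f"{rid}.pssm", record_id=rid)
        track = read_ss2(ss2_dir / f"{rid}.ss2", record_id=rid)
        rows[k] = extract_features(profile, track, bf=bf, motif=motif).values
    return LabeledDataset(
        ids=labels["id"].tolist(),
        features=rows,
        labels=labels["label"].to_numpy(dtype=int),
        feature_names=feature_names(),
    )
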