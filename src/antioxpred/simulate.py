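"""Synthetic PSSM / secondary-structure / label generator.

Stands in for a real benchmark (profile-search and structure-prediction
outputs over curated positive and negative sequence sets) so the whole
pipeline is exercisable offline. Per record:

* length L uniform on ``length_range`` (minimum 8, the shortest length the
  local structure partition accepts);
* integer PSSM scores from a rounded normal base distribution, clipped to
  ``score_range``; the positive class receives a mean shift of
  ``effect_size`` on a fixed subset of five score columns;
* structure probabilities row-wise Dirichlet, with the positive class's
  helix concentration raised by ``effect_size``; states are the argmax of
  each (rounded-to-file-precision) probability row, so files are internally
  consistent after the round trip;
* the residue sequence is the PSSM consensus under uniform background
  weights, tying sequence composition to the score signal.

At ``effect_size = 0`` the two class-conditional distributions coincide, so
any downstream classifier is at chance. The signal lives in both the
evolutionary and the structural feature blocks, so the compressor must
integrate both modalities to recover it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InputError
from .io import (
    CANONICAL_AA,
    PssmProfile,
    SecondaryStructureTrack,
    write_pssm,
    write_ss2,
)

#: Score columns carrying the class signal (canonical order indices).
SIGNAL_COLUMNS = (0, 4, 9, 14, 19)

#: File precision for structure probabilities (decimal places).
_PROB_DECIMALS = 6


@dataclass
class SimConfig:
    n_pos: int = 30
    n_neg: int = 30
    length_range: tuple[int, int] = (30, 80)
    effect_size: float = 3.0
    score_range: tuple[int, int] = (-10, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise InputError("n_pos and n_neg must be >= 1")
        lo, hi = self.length_range
        if lo < 8 or hi < lo:
            raise InputError("length_range minimum is 8 and must be ordered")
        if self.effect_size < 0:
            raise InputError("effect_size must be non-negative")
        if self.score_range[1] <= self.score_range[0]:
            raise InputError("score_range must be ordered")


def simulate_record(
    cls: int,
    config: SimConfig,
    rng: np.random.Generator,
    record_id: str = "rec",
) -> tuple[PssmProfile, SecondaryStructureTrack]:
    """Draw one synthetic (PSSM profile, structure track) pair."""
    if cls not in (0, 1):
        raise InputError("cls must be 0 or 1")
    lo, hi = config.length_range
    L = int(rng.integers(lo, hi + 1))

    scores = rng.normal(0.0, 2.0, size=(L, 20))
    if cls == 1:
        scores[:, SIGNAL_COLUMNS] += config.effect_size
    scores = np.clip(np.rint(scores), *config.score_range)

    alpha = np.array([3.0, 3.0, 3.0])  # (C, H, E) concentrations
    if cls == 1:
        alpha = alpha + np.array([0.0, config.effect_size, 0.0])
    probs = rng.dirichlet(alpha, size=L)
    probs = np.round(probs, _PROB_DECIMALS)
    probs = probs / probs.sum(axis=1, keepdims=True)
    states = "".join("CHE"[j] for j in np.argmax(probs, axis=1))

    # consensus under uniform background = per-row score argmax
    sequence = "".join(CANONICAL_AA[j] for j in np.argmax(scores, axis=1))

    profile = PssmProfile(record_id=record_id, sequence=sequence, scores=scores)
    track = SecondaryStructureTrack(record_id=record_id, states=states, probs=probs)
    return profile, track


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> Path:
    """Write ``n_pos + n_neg`` record pairs plus a labels CSV under ``out_dir``.

    Layout: ``pssm/<id>.pssm``, ``ss2/<id>.ss2``, ``labels.csv`` — the exact
    dialects the readers accept. Returns ``out_dir``.
    """
    out_dir = Path(out_dir)
    pssm_dir = out_dir / "pssm"
    ss2_dir = out_dir / "ss2"
    pssm_dir.mkdir(parents=True, exist_ok=True)
    ss2_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    labels: list[tuple[str, int]] = []
    order = [1] * config.n_pos + [0] * config.n_neg
    for i, cls in enumerate(order):
        rid = f"s{i + 1:04d}"
        profile, track = simulate_record(cls, config, rng, record_id=rid)
        write_pssm(profile, pssm_dir / f"{rid}.pssm")
        write_ss2(track, ss2_dir / f"{rid}.ss2", sequence=profile.sequence)
        labels.append((rid, cls))

    with open(out_dir / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label"])
        writer.writerows(labels)
    return out_dir
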