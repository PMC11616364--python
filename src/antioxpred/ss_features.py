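"""Secondary-structure features: 33 values per protein.

Six features come from the 3-state sequence itself:

* composition moment vectors D_H, D_E, D_C — the sum of the 1-based sequence
  positions occupied by each state, normalized by L(L-1), so that a protein
  made entirely of one state saturates that state's moment at 1;
* normalized maximum run lengths D_ME = maxE/L and D_MH = maxH/L;
* a fold-architecture motif feature: collapse each maximal helix run to one
  alpha symbol and each strand run to one beta symbol, drop coil entirely,
  and count occurrences of the chosen motif (beta-alpha-beta by default) in
  the fragment string, normalized by L-2.

The remaining 27 come from the L x 3 structure probability matrix (columns
C, H, E): 3 global column means and 24 local ones from an 8-way contiguous
row partition (earlier blocks absorb the remainder when 8 does not divide L).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .io import SecondaryStructureTrack


@dataclass
class SsFeatureBlock:
    seq_feats: np.ndarray      # D_H, D_E, D_C, D_ME, D_MH, D_motif
    global_feats: np.ndarray   # 3 column means (C, H, E)
    local_feats: np.ndarray    # 8 blocks x (C, H, E)

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.seq_feats, self.global_feats, self.local_feats])


def cmv_state_features(states: str) -> np.ndarray:
    """Composition moment vector (D_H, D_E, D_C), 1-based position sums."""
    L = len(states)
    if L < 2:
        raise InputError(f"composition moments need length >= 2, got {L}")
    denom = L * (L - 1)
    out = np.zeros(3)
    for k, state in enumerate("HEC"):
        out[k] = sum(i + 1 for i, s in enumerate(states) if s == state) / denom
    return out


def _max_run(states: str, state: str) -> int:
    best = run = 0
    for s in states:
        run = run + 1 if s == state else 0
        best = max(best, run)
    return best


def max_run_features(states: str) -> np.ndarray:
    """Normalized longest runs (D_ME, D_MH) = (maxE/L, maxH/L)."""
    if not states:
        raise InputError("empty state string")
    L = len(states)
    return np.array([_max_run(states, "E") / L, _max_run(states, "H") / L])


def motif_feature(states: str, motif: str = "bab") -> float:
    """Normalized count of the fold motif in the collapsed fragment string.

    ``motif="bab"`` counts strand-helix-strand; ``"aba"`` helix-strand-helix.
    Overlapping occurrences count.
    """
    L = len(states)
    if L < 3:
        raise InputError(f"motif feature needs length >= 3, got {L}")
    if motif not in ("bab", "aba"):
        raise InputError(f"motif must be 'bab' or 'aba', got {motif!r}")
    collapsed = re.sub("H+", "a", re.sub("E+", "b", states.replace("C", "")))
    pattern = motif
    count = sum(
        1 for i in range(len(collapsed) - 2) if collapsed[i : i + 3] == pattern
    )
    return count / (L - 2)


def global_probability_features(probs: np.ndarray) -> np.ndarray:
    """Column means of the structure probability matrix, (C, H, E) order."""
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise InputError("empty probability matrix")
    return probs.mean(axis=0)


def local_probability_features(probs: np.ndarray) -> np.ndarray:
    """Column means of 8 contiguous row blocks, flattened block-major.

    Blocks differ in size by at most one row; when ``L mod 8 != 0`` the
    earlier blocks take the extra rows.
    """
    probs = np.asarray(probs, dtype=float)
    L = probs.shape[0]
    if L < 8:
        raise InputError(f"local structure features need length >= 8, got {L}")
    blocks = np.array_split(probs, 8, axis=0)
    return np.concatenate([b.mean(axis=0) for b in blocks])


def ss_feature_block(track: SecondaryStructureTrack, motif: str = "bab") -> SsFeatureBlock:
    """All 33 secondary-structure features for one track."""
    if track.length < 8:
        raise InputError(
            f"secondary-structure block needs length >= 8, got {track.length}"
        )
    dh, de, dc = cmv_state_features(track.states)
    dme, dmh = max_run_features(track.states)
    dm = motif_feature(track.states, motif=motif)
    return SsFeatureBlock(
        seq_feats=np.array([dh, de, dc, dme, dmh, dm]),
        global_feats=global_probability_features(track.probs),
        local_feats=local_probability_features(track.probs),
    )
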