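"""Evolutionary (PSSM-derived) features: 440 values per protein.

The block decomposes as

* 20 per-column means of the position-specific scoring matrix — the average
  substitution score toward each amino-acid type over the sequence;
* 420 weighted n-gram composition features of the *consensus sequence*, the
  residue string obtained by keeping, per PSSM row i, the amino acid j
  maximizing the background-weighted transform ``2 ** (score[i, j] * BF[j])``:
  20 monomer frequencies ``O(P_i)/L`` weighted by 20/420 and 400 ordered
  adjacent-pair frequencies ``O(P_i P_j)/L`` weighted by 400/420.

The pair denominator is L (not L - 1) by construction of the weighting
scheme, so the raw pair frequencies sum to (L - 1)/L rather than 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, NumericalError
from .io import CANONICAL_AA, PssmProfile

#: Robinson & Robinson amino-acid background frequencies (canonical order),
#: normalized to sum 1. Any positive 20-vector may be substituted via config.
ROBINSON_FREQUENCIES = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
        0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
        0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
ROBINSON_FREQUENCIES = ROBINSON_FREQUENCIES / ROBINSON_FREQUENCIES.sum()

_AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Positive per-amino-acid weights used in the consensus transform."""

    bf: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.bf, dtype=float)
        object.__setattr__(self, "bf", arr)
        if arr.shape != (20,):
            raise InputError(f"background frequencies must have 20 entries, got {arr.shape}")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise InputError("background frequencies must be finite and positive")

    @classmethod
    def default(cls) -> "BackgroundFrequencies":
        return cls(bf=ROBINSON_FREQUENCIES.copy())

    @classmethod
    def uniform(cls) -> "BackgroundFrequencies":
        return cls(bf=np.full(20, 1.0 / 20.0))


@dataclass
class PssmFeatureBlock:
    d_pssm: np.ndarray    # 20 column means
    d_con: np.ndarray     # 420 weighted n-gram features

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.d_pssm, self.d_con])


def pssm_column_means(profile: PssmProfile) -> np.ndarray:
    """Per-column mean substitution score, canonical amino-acid order."""
    if profile.length < 1:
        raise InputError("empty PSSM profile")
    return profile.scores.mean(axis=0)


def consensus_sequence(
    profile: PssmProfile,
    bf: BackgroundFrequencies | None = None,
) -> str:
    """Consensus residue string from the background-weighted score transform.

    Row i contributes the amino acid maximizing ``2 ** (score[i, j] * bf[j])``;
    ties resolve to the earliest amino acid in canonical alphabetical order
    (numpy argmax takes the first maximal index).
    """
    if profile.length < 1:
        raise InputError("empty PSSM profile")
    if bf is None:
        bf = BackgroundFrequencies.default()
    with np.errstate(over="ignore"):
        transformed = np.exp2(profile.scores * bf.bf[np.newaxis, :])
    if not np.all(np.isfinite(transformed)):
        raise NumericalError(
            "consensus transform 2**(score*BF) overflowed; rescale scores or "
            "background frequencies"
        )
    winners = np.argmax(transformed, axis=1)
    return "".join(CANONICAL_AA[j] for j in winners)


def ngram_features(consensus: str) -> np.ndarray:
    """Weighted 1-gram and 2-gram composition of a consensus sequence.

    Layout: 20 monomer entries ``20 * (O(P_i)/L) / 420`` in canonical order,
    then 400 ordered-pair entries ``400 * (O(P_i P_j)/L) / 420`` row-major
    (first residue of the pair is the row). Pairs are overlapping adjacent
    positions (i, i+1).
    """
    L = len(consensus)
    if L < 2:
        raise InputError(f"n-gram features need length >= 2, got {L}")
    idx = np.array([_AA_INDEX[a] for a in consensus], dtype=int)

    counts1 = np.bincount(idx, minlength=20).astype(float)
    counts2 = np.zeros((20, 20), dtype=float)
    np.add.at(counts2, (idx[:-1], idx[1:]), 1.0)

    d1 = counts1 / L
    d2 = counts2 / L
    return np.concatenate([20.0 * d1 / 420.0, (400.0 * d2 / 420.0).ravel()])


def pssm_feature_block(
    profile: PssmProfile,
    bf: BackgroundFrequencies | None = None,
) -> PssmFeatureBlock:
    """All 440 PSSM-derived features for one profile."""
    if profile.length < 2:
        raise InputError("PSSM feature block needs sequence length >= 2")
    means = pssm_column_means(profile)
    con = consensus_sequence(profile, bf)
    return PssmFeatureBlock(d_pssm=means, d_con=ngram_features(con))
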