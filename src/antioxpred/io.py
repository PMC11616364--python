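"""Readers and writers for the external formats the pipeline touches.

Supported dialects:

* FASTA protein sequences (via Bio.SeqIO);
* PSI-BLAST ASCII position-specific scoring matrices (the ``-out_ascii_pssm``
  layout: header lines, one row per residue with index, residue letter and a
  first block of 20 log-odds columns, optional percentage/information columns,
  trailer);
* PSI-PRED ``.ss2`` secondary-structure tracks (per-row index, residue, state
  letter, then coil/helix/strand probabilities);
* labelled feature tables as CSV with header ``id,label,f001..fNNN``.

Score columns are permuted on read into the canonical alphabetical amino-acid
order ``ACDEFGHIKLMNPQRSTVWY`` so that downstream feature indices are
deterministic regardless of the column order a particular tool emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError

#: Canonical amino-acid ordering used for all internal 20-column matrices.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Letters whose meaning is ambiguous (non-standard/unknown residues);
#: sequences containing any of them are dropped from benchmark construction.
EXCLUDED_LETTERS = frozenset("BXZOUJ")

#: Secondary-structure states: helix, strand, coil.
SS_STATES = "HEC"

#: Column order of the structure probability matrix.
SS_PROB_ORDER = ("C", "H", "E")


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein sequence over the 20 standard amino-acid letters."""

    id: str
    sequence: str


@dataclass
class PssmProfile:
    """A protein's L x 20 position-specific scoring matrix.

    ``scores[i, j]`` is the log-odds score for mutating residue ``i`` of the
    sequence into amino-acid type ``alphabet_order[j]``.
    """

    record_id: str
    sequence: str
    scores: np.ndarray
    alphabet_order: str = CANONICAL_AA

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise FormatError(
                f"PSSM for {self.record_id!r} must be L x 20, got {self.scores.shape}"
            )
        if self.scores.shape[0] != len(self.sequence):
            raise FormatError(
                f"PSSM for {self.record_id!r}: {self.scores.shape[0]} score rows "
                f"but sequence length {len(self.sequence)}"
            )
        if not np.all(np.isfinite(self.scores)):
            raise FormatError(f"PSSM for {self.record_id!r} contains non-finite scores")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SecondaryStructureTrack:
    """Per-residue 3-state secondary structure with state probabilities.

    ``states`` is a string over {H, E, C}; ``probs`` has one row per residue
    with columns ordered (C, H, E) and rows summing to 1.
    """

    record_id: str
    states: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise FormatError(
                f"structure track for {self.record_id!r} must be L x 3, "
                f"got {self.probs.shape}"
            )
        if len(self.states) != self.probs.shape[0]:
            raise FormatError(
                f"structure track for {self.record_id!r}: {len(self.states)} states "
                f"but {self.probs.shape[0]} probability rows"
            )
        bad = set(self.states) - set(SS_STATES)
        if bad:
            raise FormatError(
                f"structure track for {self.record_id!r}: unknown states {sorted(bad)}"
            )
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise FormatError(
                f"structure track for {self.record_id!r}: probabilities outside [0, 1]"
            )
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            i = int(np.argmax(np.abs(sums - 1.0)))
            raise FormatError(
                f"structure track for {self.record_id!r}: row {i + 1} probabilities "
                f"sum to {sums[i]:.6f}, expected 1"
            )

    @property
    def length(self) -> int:
        return len(self.states)


@dataclass
class LabeledDataset:
    """Feature matrix plus binary labels (1 = antioxidant, 0 = negative)."""

    ids: list[str]
    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise FormatError("features must be a 2-D matrix")
        n = self.features.shape[0]
        if len(self.ids) != n or self.labels.shape[0] != n:
            raise FormatError(
                f"inconsistent dataset sizes: {len(self.ids)} ids, "
                f"{n} feature rows, {self.labels.shape[0]} labels"
            )
        if not self.feature_names:
            self.feature_names = default_feature_names(self.features.shape[1])
        elif len(self.feature_names) != self.features.shape[1]:
            raise FormatError("feature_names length does not match feature columns")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def default_feature_names(d: int) -> list[str]:
    width = max(3, len(str(d)))
    return [f"f{i + 1:0{width}d}" for i in range(d)]


# ---------------------------------------------------------------------------
# sequence filtering


def filter_sequences(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Drop sequences containing any ambiguous letter (B, X, Z, O, U, J).

    Order of the surviving records is preserved; nothing is repaired.
    """
    return [r for r in records if not (set(r.sequence) & EXCLUDED_LETTERS)]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file, upper-casing sequences."""
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        if not seq:
            raise FormatError(f"{path}: FASTA record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def read_pssm(path: str | Path, record_id: str | None = None) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM file into canonical column order.

    Only the first 20-column block (the log-odds scores) is used; percentage
    and information columns, when present, are ignored.
    """
    path = Path(path)
    rid = record_id if record_id is not None else path.stem
    lines = path.read_text().splitlines()

    header_cols: list[str] | None = None
    header_lineno = -1
    for lineno, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 20 and all(len(t) == 1 and t.isalpha() for t in toks[:20]):
            header_cols = [t.upper() for t in toks[:20]]
            header_lineno = lineno
            break
    if header_cols is None:
        raise FormatError(f"{path}: no 20-letter PSSM column header found")
    if sorted(header_cols) != sorted(CANONICAL_AA):
        raise FormatError(
            f"{path}: line {header_lineno + 1}: column header is not a "
            f"permutation of the 20 standard amino acids"
        )

    residues: list[str] = []
    rows: list[list[float]] = []
    expected_index = 1
    for lineno in range(header_lineno + 1, len(lines)):
        line = lines[lineno]
        toks = line.split()
        if not toks:
            break  # blank line terminates the matrix block
        if not toks[0].lstrip("-").isdigit():
            break  # trailer (Lambda, K, Standard Ungapped, ...)
        if len(toks) < 22:
            raise FormatError(
                f"{path}: line {lineno + 1}: expected index, residue and 20 "
                f"scores, got {len(toks)} fields"
            )
        idx = int(toks[0])
        if idx != expected_index:
            raise FormatError(
                f"{path}: line {lineno + 1}: residue index {idx}, "
                f"expected {expected_index}"
            )
        residue = toks[1].upper()
        try:
            scores = [float(t) for t in toks[2:22]]
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {lineno + 1}: non-numeric score ({exc})"
            ) from None
        residues.append(residue)
        rows.append(scores)
        expected_index += 1

    if not rows:
        raise FormatError(f"{path}: PSSM contains no score rows")

    raw = np.asarray(rows, dtype=float)
    # permute file columns into canonical order
    perm = [header_cols.index(aa) for aa in CANONICAL_AA]
    scores = raw[:, perm]
    return PssmProfile(record_id=rid, sequence="".join(residues), scores=scores)


def write_pssm(profile: PssmProfile, path: str | Path,
               column_order: str = "ARNDCQEGHILKMFPSTWYV") -> None:
    """Write a profile in the PSI-BLAST ASCII dialect ``read_pssm`` accepts.

    ``column_order`` defaults to the order PSI-BLAST itself emits, exercising
    the canonical-order permutation on the read side.
    """
    if sorted(column_order) != sorted(CANONICAL_AA):
        raise FormatError("column_order must be a permutation of the 20 amino acids")
    inv = [CANONICAL_AA.index(aa) for aa in column_order]
    out = ["", "Last position-specific scoring matrix computed", ""]
    out.append("            " + "  ".join(column_order))
    for i, (res, row) in enumerate(zip(profile.sequence, profile.scores), start=1):
        cells = " ".join(f"{row[j]:3.0f}" for j in inv)
        out.append(f"{i:5d} {res}  {cells}")
    out.append("")
    out.append("                      K         Lambda")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# PSI-PRED .ss2


def read_ss2(path: str | Path, record_id: str | None = None) -> SecondaryStructureTrack:
    """Parse a PSI-PRED ``.ss2`` file.

    Data rows carry: residue index, residue letter, state in {H,E,C}, then the
    coil, helix and strand probabilities, which are stored in (C, H, E) order.
    """
    path = Path(path)
    rid = record_id if record_id is not None else path.stem
    states: list[str] = []
    probs: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        toks = line.split()
        if not toks or toks[0].startswith("#"):
            continue
        if not toks[0].isdigit():
            continue  # header/comment line
        if len(toks) < 6:
            raise FormatError(
                f"{path}: line {lineno}: expected index, residue, state and "
                f"3 probabilities, got {len(toks)} fields"
            )
        state = toks[2].upper()
        if state not in SS_STATES:
            raise FormatError(f"{path}: line {lineno}: unknown state {state!r}")
        try:
            p = [float(toks[3]), float(toks[4]), float(toks[5])]
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {lineno}: non-numeric probability ({exc})"
            ) from None
        if abs(sum(p) - 1.0) > 1e-2:
            raise FormatError(
                f"{path}: line {lineno}: probabilities sum to {sum(p):.4f}, "
                f"expected 1"
            )
        states.append(state)
        probs.append(p)
    if not states:
        raise FormatError(f"{path}: ss2 file contains no data rows")
    arr = np.asarray(probs, dtype=float)
    arr = arr / arr.sum(axis=1, keepdims=True)  # absorb 2-decimal rounding drift
    return SecondaryStructureTrack(record_id=rid, states="".join(states), probs=arr)


def write_ss2(track: SecondaryStructureTrack, path: str | Path,
              sequence: str | None = None) -> None:
    """Write a track in the PSI-PRED ``.ss2`` dialect ``read_ss2`` accepts."""
    seq = sequence if sequence is not None else "A" * track.length
    lines = ["# PSIPRED VFORMAT (antioxpred synthetic)", ""]
    for i in range(track.length):
        c, h, e = track.probs[i]
        lines.append(
            f"{i + 1:4d} {seq[i]} {track.states[i]}  {c:8.6f} {h:8.6f} {e:8.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(dataset: LabeledDataset, path: str | Path) -> None:
    """Write a dataset as CSV with header ``id,label,f001..``."""
    df = pd.DataFrame(dataset.features, columns=dataset.feature_names)
    df.insert(0, "label", dataset.labels)
    df.insert(0, "id", dataset.ids)
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path,
                       expected_dim: int | None = None) -> LabeledDataset:
    """Read a CSV feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, dtype={"id": str})
    if list(df.columns[:2]) != ["id", "label"]:
        raise FormatError(f"{path}: feature table must start with id,label columns")
    feat_cols = list(df.columns[2:])
    if expected_dim is not None and len(feat_cols) != expected_dim:
        raise FormatError(
            f"{path}: expected {expected_dim} feature columns, found {len(feat_cols)}"
        )
    features = (
        df[feat_cols].to_numpy(dtype=float)
        if feat_cols
        else np.empty((len(df), 0))
    )
    return LabeledDataset(
        ids=df["id"].tolist(),
        features=features,
        labels=df["label"].to_numpy(dtype=int),
        feature_names=feat_cols,
    )
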