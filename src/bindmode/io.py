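"""Input/output for the formats the package touches.

Sequences come in as multi-record FASTA; per-residue disorder scores as a
three-column TSV (position, residue, score; 1-based, header line); model
parameters as JSON; per-residue binding-mode profiles go out as a TSV with
fixed 6-decimal precision so repeated runs are byte-identical.

All coordinates are 1-based and inclusive on both ends, matching
crystallographic residue numbering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)


class SequenceError(ValueError):
    """Malformed or policy-violating sequence input."""


class ScoreTableError(ValueError):
    """Malformed per-residue score table."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with 1-based positions.

    Parameters
    ----------
    id : str
        Free-text identifier (FASTA header up to first whitespace).
    residues : str
        Upper-case amino-acid string. Under the default ``map`` policy,
        nonstandard letters have been mapped to ``X``; windows touching an
        ``X`` are excluded from feature computation downstream.
    """

    id: str
    residues: str

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")

    def slice(self, start: int, end: int) -> str:
        """Residues in the 1-based inclusive interval [start, end]."""
        return self.residues[start - 1 : end]


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder scores in [0, 1] for one sequence."""

    sequence_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 1 or scores.size == 0:
            raise ScoreTableError("scores must be a non-empty 1-D array")
        if np.any(~np.isfinite(scores)) or scores.min() < 0 or scores.max() > 1:
            raise ScoreTableError(
                f"disorder scores for {self.sequence_id!r} must lie in [0, 1]"
            )

    def __len__(self) -> int:
        return int(self.scores.size)

    def mean_over(self, positions: Iterable[int]) -> float:
        """Mean score over 1-based positions."""
        idx = np.fromiter((p - 1 for p in positions), dtype=int)
        return float(self.scores[idx].mean())


def sanitize_residues(raw: str, *, policy: str = "map", record_id: str = "?") -> str:
    """Apply the nonstandard-residue policy to a raw sequence string.

    ``map`` (default) rewrites any letter outside the 20 standard codes to
    ``X``; ``reject`` raises, naming the first offending position.
    """
    seq = raw.upper()
    if policy not in ("map", "reject"):
        raise ValueError(f"unknown residue policy {policy!r}")
    bad = [i for i, c in enumerate(seq) if c not in _STANDARD_SET]
    if not bad:
        return seq
    if policy == "reject":
        i = bad[0]
        raise SequenceError(
            f"record {record_id!r}: illegal residue {seq[i]!r} at position {i + 1}"
        )
    out = list(seq)
    for i in bad:
        out[i] = "X"
    return "".join(out)


def read_fasta(path: str | Path, *, policy: str = "map") -> list[ProteinSequence]:
    """Read a multi-record FASTA file, preserving record order.

    Raises on an empty file, on duplicate identifiers, and (under the
    ``reject`` policy) on letters outside the 20-letter alphabet.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    seen: set[str] = set()
    out: list[ProteinSequence] = []
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = sanitize_residues(str(rec.seq), policy=policy, record_id=rec.id)
        out.append(ProteinSequence(id=rec.id, residues=residues))
    return out


def write_fasta(sequences: Sequence[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n{seq.residues}\n")


def read_score_table(
    path: str | Path, *, sequence: ProteinSequence | None = None
) -> DisorderProfile:
    """Read a per-residue disorder-score TSV (position, residue, score).

    Positions must be 1-based, contiguous and start at 1; scores in [0, 1].
    If ``sequence`` is given, residue letters are cross-checked against it.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"position", "residue", "score"}
    if not required.issubset(df.columns):
        raise ScoreTableError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    if len(df) == 0:
        raise ScoreTableError(f"{path}: empty score table")
    pos = df["position"].to_numpy()
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(pos, expected):
        first_bad = int(expected[pos != expected][0]) if len(pos) == len(expected) else len(df)
        raise ScoreTableError(
            f"{path}: positions must be contiguous 1..n (first problem near row {first_bad})"
        )
    scores = df["score"].to_numpy(dtype=float)
    bad = np.where((scores < 0) | (scores > 1) | ~np.isfinite(scores))[0]
    if bad.size:
        row = int(bad[0])
        raise ScoreTableError(
            f"{path}: score {scores[row]} at position {row + 1} outside [0, 1]"
        )
    seq_id = sequence.id if sequence is not None else Path(path).stem
    if sequence is not None:
        letters = "".join(df["residue"].astype(str))
        if letters != sequence.residues:
            raise ScoreTableError(
                f"{path}: residue column does not match sequence {sequence.id!r}"
            )
    return DisorderProfile(sequence_id=seq_id, scores=scores)


def write_score_table(
    seq: ProteinSequence, profile: DisorderProfile, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("position\tresidue\tscore\n")
        for i, (aa, s) in enumerate(zip(seq.residues, profile.scores), start=1):
            fh.write(f"{i}\t{aa}\t{s:.6f}\n")


# --- profile table -----------------------------------------------------------

PROFILE_COLUMNS = [
    "sequence_id",
    "position",
    "residue",
    "n_windows",
    "p_do",
    "p_dd",
    "entropy_bits",
    "landscape_class",
]


def write_profile_table(profiles: Iterable, path: str | Path) -> None:
    """Write per-residue binding-mode profiles as a deterministic TSV.

    One row per residue, 6-decimal fixed precision, rows ordered by
    (sequence id, position): re-writing the same profiles yields a
    byte-identical file. Residues without a computable window carry ``NA``.
    """
    rows = sorted(profiles, key=lambda p: (p.sequence_id, p.position))
    with open(path, "w") as fh:
        fh.write("\t".join(PROFILE_COLUMNS) + "\n")
        for p in rows:
            if p.n_windows == 0:
                vals = ["NA", "NA", "NA", "NA"]
            else:
                vals = [
                    f"{p.p_do:.6f}",
                    f"{p.p_dd:.6f}",
                    f"{p.entropy_bits:.6f}",
                    p.landscape_class,
                ]
            fh.write(
                f"{p.sequence_id}\t{p.position}\t{p.residue}\t{p.n_windows}\t"
                + "\t".join(vals)
                + "\n"
            )


def read_profile_table(path: str | Path) -> pd.DataFrame:
    """Read a profile TSV back into a DataFrame (numeric columns parsed)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])


# --- model-parameter JSON ----------------------------------------------------


def read_model_json(path: str | Path) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    for key in ("lambda1", "lambda2", "lambda3", "gamma"):
        if key not in data:
            raise ValueError(f"model file {path} missing field {key!r}")
    return data


def write_model_json(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")
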