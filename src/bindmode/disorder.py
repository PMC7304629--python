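"""Per-residue disorder-score providers.

The binding-mode predictor consumes one disorder score in [0, 1] per
residue. In practice these come from a dedicated disorder predictor run
externally and loaded through :func:`bindmode.io.read_score_table`; this
module additionally ships a built-in charge/hydropathy fallback so the full
pipeline runs with no external tool.

The fallback computes, on a sliding window, the mean Kyte–Doolittle
hydropathy rescaled to [0, 1] and the absolute mean net charge, combines
them into an unfoldability index u = 2.785·⟨H⟩ − |⟨q⟩| − 1.151, and maps it
to a disorder score 0.5 − u clipped to [0, 1]. Hydrophobic uncharged
stretches therefore score low (ordered), charged hydrophilic stretches high
(disordered). It is a coarse stand-in, not a replacement for a trained
disorder predictor, and benchmark-quality runs should inject external
scores.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .features import KYTE_DOOLITTLE
from .io import DisorderProfile, ProteinSequence

logger = logging.getLogger(__name__)

#: Net charge per residue at neutral pH (side chains only).
RESIDUE_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}


class ProfileMismatchError(ValueError):
    """Sequence and disorder profile do not belong together."""


def _sliding_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; truncated (not padded) at the termini."""
    n = values.size
    half = window // 2
    cumsum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cumsum[hi] - cumsum[lo]) / (hi - lo)


def builtin_disorder(
    seq: ProteinSequence, window: int = 21
) -> DisorderProfile:
    """Charge/hydropathy fallback disorder score, one value per residue.

    Parameters
    ----------
    seq : ProteinSequence
        Query sequence; ``X`` residues contribute neutral hydropathy (0)
        and zero charge.
    window : int
        Odd smoothing window length, >= 3. A window longer than the
        sequence falls back to the whole-sequence mean (with a warning).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if window > seq.n:
        warnings.warn(
            f"smoothing window {window} exceeds sequence length {seq.n}; "
            "using whole-sequence mean",
            stacklevel=2,
        )
        window = seq.n if seq.n % 2 == 1 else seq.n - 1
        window = max(window, 1)
    kd = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq.residues])
    q = np.array([RESIDUE_CHARGE.get(aa, 0.0) for aa in seq.residues])
    h_norm = (_sliding_mean(kd, window) + 4.5) / 9.0
    q_mean = _sliding_mean(q, window)
    unfoldability = 2.785 * h_norm - np.abs(q_mean) - 1.151
    scores = np.clip(0.5 - unfoldability, 0.0, 1.0)
    return DisorderProfile(sequence_id=seq.id, scores=scores)


def attach_scores(
    seq: ProteinSequence,
    profile: DisorderProfile,
    *,
    allow_id_mismatch: bool = False,
) -> tuple[ProteinSequence, DisorderProfile]:
    """Validate that a disorder profile belongs to a sequence.

    Returns the validated pair used by feature computation. Lengths must
    match; identifiers must match unless ``allow_id_mismatch`` is set, in
    which case a warning is logged.
    """
    if len(profile) != seq.n:
        raise ProfileMismatchError(
            f"sequence {seq.id!r} has {seq.n} residues but profile "
            f"{profile.sequence_id!r} has {len(profile)} scores"
        )
    if profile.sequence_id != seq.id:
        if not allow_id_mismatch:
            raise ProfileMismatchError(
                f"profile id {profile.sequence_id!r} does not match sequence "
                f"id {seq.id!r} (pass allow_id_mismatch=True to override)"
            )
        logger.warning(
            "attaching profile %r to sequence %r despite id mismatch",
            profile.sequence_id,
            seq.id,
        )
    return seq, profile
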