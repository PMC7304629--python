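"""Per-residue binding-mode profiles.

For each residue A_i, every candidate binding window of length 5-9 that
contains it is scored and converted to a disorder-to-order probability
p_DO(R_i); the residue-level p_DO(A_i) is the median of that set, with
p_DD(A_i) = 1 - p_DO(A_i). The set is also binned into binding modes to
yield the residue's Shannon entropy and its landscape class.

Windows whose features cannot be computed (nonstandard residues, no
flanking context) are dropped rather than imputed; ``n_windows`` records
the survivors, and residues with none are emitted with missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .disorder import attach_scores
from .entropy import (
    LandscapeThresholds,
    DEFAULT_THRESHOLDS,
    bin_frequencies,
    classify_landscape,
    shannon_entropy,
)
from .features import (
    FeatureConfig,
    WindowFeatureError,
    bias_features,
    enumerate_windows,
)
from .io import DisorderProfile, ProteinSequence
from .scoring import ModelParams, pdo_from_score, score_region

logger = logging.getLogger(__name__)


class NoComputableWindowError(ValueError):
    """No window around this residue has computable features."""


@dataclass(frozen=True)
class ResidueBindingProfile:
    """Predicted binding-mode summary for one residue."""

    sequence_id: str
    position: int
    residue: str
    window_pdos: tuple[float, ...]
    p_do: float
    p_dd: float
    entropy_bits: float
    landscape_class: str

    @property
    def n_windows(self) -> int:
        return len(self.window_pdos)


def window_pdo_set(
    seq: ProteinSequence,
    i: int,
    profile: DisorderProfile,
    params: ModelParams,
) -> list[float]:
    """p_DO(R_i) for every computable window containing residue i.

    Values follow window-enumeration order (by length, then start).
    Windows skipped for feature errors are logged; if none survives,
    :class:`NoComputableWindowError` is raised.
    """
    pdos, skipped = _window_pdos(seq, i, profile, params)
    if skipped:
        logger.debug(
            "%s position %d: skipped %d of %d windows",
            seq.id,
            i,
            len(skipped),
            len(skipped) + len(pdos),
        )
    if not pdos:
        raise NoComputableWindowError(
            f"no computable binding window around {seq.id!r} position {i}"
        )
    return pdos


def _window_pdos(seq, i, profile, params):
    config = params.feature_config
    pdos: list[float] = []
    skipped = []
    for window in enumerate_windows(i, seq.n, config.min_len, config.max_len):
        try:
            feats = bias_features(window, seq, profile, config)
        except WindowFeatureError as exc:
            skipped.append((window, str(exc)))
            continue
        pdos.append(pdo_from_score(score_region(feats, params)))
    return pdos, skipped


def residue_pdo(window_pdos) -> float:
    """Residue-level p_DO: the sample median of the window probabilities.

    For an even count this is the midpoint of the two central order
    statistics. p_DD follows as 1 - p_DO.
    """
    values = np.asarray(window_pdos, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take the median of an empty probability set")
    return float(np.median(values))


def profile_sequence(
    seq: ProteinSequence,
    profile: DisorderProfile,
    params: ModelParams,
    thresholds: LandscapeThresholds = DEFAULT_THRESHOLDS,
    *,
    allow_id_mismatch: bool = False,
) -> list[ResidueBindingProfile]:
    """Per-residue binding-mode profiles for a whole sequence.

    Deterministic: identical inputs produce identical output. Residues
    with no computable window get ``n_windows = 0`` and NaN summaries.
    """
    seq, profile = attach_scores(
        seq, profile, allow_id_mismatch=allow_id_mismatch
    )
    out: list[ResidueBindingProfile] = []
    for i in range(1, seq.n + 1):
        pdos, _ = _window_pdos(seq, i, profile, params)
        if not pdos:
            logger.warning(
                "%s position %d: no computable window; emitting missing values",
                seq.id,
                i,
            )
            out.append(
                ResidueBindingProfile(
                    sequence_id=seq.id,
                    position=i,
                    residue=seq.residues[i - 1],
                    window_pdos=(),
                    p_do=float("nan"),
                    p_dd=float("nan"),
                    entropy_bits=float("nan"),
                    landscape_class="NA",
                )
            )
            continue
        p_do = residue_pdo(pdos)
        p_dd = 1.0 - p_do
        ent = shannon_entropy(bin_frequencies(pdos))
        out.append(
            ResidueBindingProfile(
                sequence_id=seq.id,
                position=i,
                residue=seq.residues[i - 1],
                window_pdos=tuple(pdos),
                p_do=p_do,
                p_dd=p_dd,
                entropy_bits=ent,
                landscape_class=classify_landscape(p_dd, ent, thresholds),
            )
        )
    return out
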