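"""Candidate binding windows and region-vs-flank bias features.

Around every residue A_i all candidate binding windows of length 5-9 that
contain it are enumerated (35 for a residue far from both termini). Each
window R is compared against its up-to-20-residue flanking segments Fl on
three axes:

* ``delta_id`` — mean disorder score of the window minus the pooled flank
  mean (local bias in disorder propensity, ΔID),
* ``delta_a``  — amino-acid composition bias (ΔA), by default the
  difference in mean TOP-IDP disorder propensity between window and
  flanks; an L1 distance between composition vectors is selectable,
* ``delta_h``  — mean Kyte-Doolittle hydropathy difference (ΔH).

Ordering of a bound region is promoted when the window is locally more
hydrophobic / less disorder-prone than its context, which is exactly what
these differences measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

from .io import DisorderProfile, ProteinSequence, STANDARD_AA

#: Kyte & Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: TOP-IDP disorder propensity scale (higher = more disorder-promoting).
TOP_IDP = {
    "W": -0.884, "F": -0.697, "Y": -0.510, "I": -0.486, "M": -0.397,
    "L": -0.326, "V": -0.121, "N": 0.007, "C": 0.020, "T": 0.059,
    "A": 0.060, "G": 0.166, "R": 0.180, "D": 0.192, "H": 0.303,
    "Q": 0.318, "S": 0.341, "K": 0.586, "E": 0.736, "P": 0.987,
}

DEFAULT_MIN_LEN = 5
DEFAULT_MAX_LEN = 9
DEFAULT_FLANK_LEN = 20


class WindowFeatureError(ValueError):
    """A window's features cannot be computed (X residues, empty flanks)."""


@dataclass(frozen=True)
class BindingWindow:
    """A candidate binding region: 1-based [start, start+length-1]."""

    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class FlankContext:
    """Flanking intervals of a window; ``None`` side means empty at a terminus."""

    left: tuple[int, int] | None
    right: tuple[int, int] | None

    def positions(self) -> Iterator[int]:
        if self.left is not None:
            yield from range(self.left[0], self.left[1] + 1)
        if self.right is not None:
            yield from range(self.right[0], self.right[1] + 1)


@dataclass(frozen=True)
class BiasFeatures:
    """The (ΔID, ΔA, ΔH) triple for one window against its flanks."""

    delta_id: float
    delta_a: float
    delta_h: float

    def as_array(self) -> np.ndarray:
        return np.array([self.delta_id, self.delta_a, self.delta_h])


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction settings; stored in model files so trained
    parameters can never be applied to differently-computed features."""

    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN
    flank_len: int = DEFAULT_FLANK_LEN
    composition_statistic: str = "topidp"  # or "l1"
    hydropathy_scale: str = "kyte-doolittle"
    disorder_source: str = "unspecified"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


def enumerate_windows(
    i: int,
    n: int,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[BindingWindow]:
    """All windows of each length in [min_len, max_len] containing position i.

    Windows lie entirely within [1, n] and come out sorted by
    (length, start). An interior residue of a long sequence has
    sum(L for L in 5..9) = 35 windows; residue 1 or n has exactly one
    window per length.
    """
    if not 1 <= i <= n:
        raise ValueError(f"position {i} outside sequence [1, {n}]")
    windows: list[BindingWindow] = []
    for length in range(min_len, max_len + 1):
        if length > n:
            continue
        lo = max(1, i - length + 1)
        hi = min(i, n - length + 1)
        for start in range(lo, hi + 1):
            windows.append(BindingWindow(start=start, length=length))
    return windows


def flank_of(
    window: BindingWindow, n: int, flank_len: int = DEFAULT_FLANK_LEN
) -> FlankContext:
    """The up-to-``flank_len``-residue segments on each side of a window.

    Flanks are truncated at the termini; a window abutting a terminus keeps
    only the other side. A window spanning the whole sequence (both flanks
    empty) is rejected: there is no context to compare against.
    """
    if window.start < 1 or window.end > n:
        raise ValueError(f"window [{window.start},{window.end}] outside [1,{n}]")
    left = (max(1, window.start - flank_len), window.start - 1)
    right = (window.end + 1, min(n, window.end + flank_len))
    left_ctx = left if left[1] >= left[0] else None
    right_ctx = right if right[1] >= right[0] else None
    if left_ctx is None and right_ctx is None:
        raise WindowFeatureError(
            f"window [{window.start},{window.end}] spans the whole sequence; "
            "no flanking context exists"
        )
    return FlankContext(left=left_ctx, right=right_ctx)


def _mean_scale(residues: str, scale: dict[str, float]) -> float:
    return float(np.mean([scale[aa] for aa in residues]))


def _composition_vector(residues: str) -> np.ndarray:
    counts = np.array([residues.count(aa) for aa in STANDARD_AA], dtype=float)
    return counts / counts.sum()


def bias_features(
    window: BindingWindow,
    seq: ProteinSequence,
    profile: DisorderProfile,
    config: FeatureConfig = FeatureConfig(),
) -> BiasFeatures:
    """Compute (ΔID, ΔA, ΔH) for one window.

    Flank residues from both sides are pooled into a single mean, so a
    truncated flank contributes in proportion to the residues it actually
    has. Windows or flanks containing ``X`` cannot be scored on the
    composition scales and are rejected with :class:`WindowFeatureError`.
    """
    flanks = flank_of(window, seq.n, config.flank_len)
    region_res = seq.slice(window.start, window.end)
    flank_pos = list(flanks.positions())
    flank_res = "".join(seq.residues[p - 1] for p in flank_pos)
    if "X" in region_res or "X" in flank_res:
        raise WindowFeatureError(
            f"window [{window.start},{window.end}] or its flanks contain "
            "nonstandard (X) residues"
        )
    delta_id = profile.mean_over(window.positions()) - profile.mean_over(flank_pos)
    delta_h = _mean_scale(region_res, KYTE_DOOLITTLE) - _mean_scale(
        flank_res, KYTE_DOOLITTLE
    )
    if config.composition_statistic == "topidp":
        delta_a = _mean_scale(region_res, TOP_IDP) - _mean_scale(flank_res, TOP_IDP)
    elif config.composition_statistic == "l1":
        delta_a = float(
            np.abs(
                _composition_vector(region_res) - _composition_vector(flank_res)
            ).sum()
        )
    else:
        raise ValueError(
            f"unknown composition statistic {config.composition_statistic!r}"
        )
    return BiasFeatures(delta_id=float(delta_id), delta_a=delta_a, delta_h=delta_h)
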