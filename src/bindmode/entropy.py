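"""Binding-mode frequencies, Shannon entropy and landscape classification.

Each residue carries up to 35 window-level disorder-to-order probabilities
p_DO(R). These are binned into ten 0.1-wide intervals over [0, 1] — each
bin a distinct "binding mode" — and the Shannon entropy (base 2) of the
bin frequencies quantifies how many modes the residue can sample:
0 bits for a residue locked into one mode, up to log2(10) ≈ 3.32 bits for
a residue whose candidate windows spread over all ten modes.

A residue is then placed on the two-dimensional (p_DD, S) landscape:
low-entropy residues commit to folding (disorder-to-order) or to staying
disordered (disorder-to-disorder) when they bind, while high-entropy
residues are context-dependent — polymorphic, conditionally folding, or
disordered-binding depending on how disordered their bound state tends to
be. Points outside the five named boxes belong to the continuum between
these archetypes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
import math
from pathlib import Path

import numpy as np

N_BINS = 10
MAX_ENTROPY_BITS = math.log2(N_BINS)


@dataclass(frozen=True)
class ModeDistribution:
    """Histogram of window probabilities over ten 0.1-wide bins.

    Bins are half-open [0.0,0.1), ..., [0.8,0.9) with the final bin
    [0.9,1.0] closed so that p_DO = 1 is representable.
    """

    counts: np.ndarray
    n: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, N_BINS + 1)


def bin_frequencies(window_pdos, n_bins: int = N_BINS) -> ModeDistribution:
    """Bin window-level p_DO values into 0.1-wide binding-mode intervals."""
    values = np.asarray(window_pdos, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bin an empty probability set")
    if values.min() < 0.0 or values.max() > 1.0:
        raise ValueError("window probabilities must lie in [0, 1]")
    idx = np.minimum(np.floor(values * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return ModeDistribution(counts=counts, n=int(values.size))


def shannon_entropy(dist: ModeDistribution) -> float:
    """Shannon entropy (bits) of the binding-mode frequencies.

    Empty bins contribute nothing (0·log2 0 ≡ 0); the result lies in
    [0, log2 10].
    """
    f = dist.frequencies
    nz = f[f > 0]
    return float(-(nz * np.log2(nz)).sum())


# --- landscape classification ------------------------------------------------

DISORDER_TO_ORDER = "disorder-to-order"
DISORDER_TO_DISORDER = "disorder-to-disorder"
POLYMORPHIC = "polymorphic"
CONDITIONAL_FOLDING = "conditional-folding"
DISORDERED_BINDING = "disordered-binding"
CONTINUUM = "continuum"

LANDSCAPE_LABELS = (
    DISORDER_TO_ORDER,
    DISORDER_TO_DISORDER,
    POLYMORPHIC,
    CONDITIONAL_FOLDING,
    DISORDERED_BINDING,
    CONTINUUM,
)


@dataclass(frozen=True)
class LandscapeThresholds:
    """Boundaries of the five named boxes on the (p_DD, S) landscape.

    Defaults follow the published boxes: the ordered/disordered corners
    require S < 1.8 bits, the three context-dependent boxes require
    S > 2.25 bits; boundary inclusivity mirrors the printed inequalities
    (strict < on entropy, mixture of < and <= on p_DD).
    """

    low_entropy: float = 1.8
    high_entropy: float = 2.25
    do_pdd_max: float = 0.25          # DO box: p_DD < 0.25
    dd_pdd_min: float = 0.65          # DD box: p_DD > 0.65
    polymorphic_pdd_max: float = 0.25  # p_DD <= 0.25
    conditional_pdd_max: float = 0.45  # 0.25 < p_DD <= 0.45
    disordered_binding_pdd_max: float = 0.75  # 0.45 < p_DD <= 0.75

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, path: str | Path) -> "LandscapeThresholds":
        with open(path) as fh:
            d = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


DEFAULT_THRESHOLDS = LandscapeThresholds()


def classify_landscape(
    p_dd: float,
    entropy_bits: float,
    thresholds: LandscapeThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Assign a residue to one region of the (p_DD, S) landscape.

    Every (p_dd, entropy) point receives exactly one label; points in none
    of the five named boxes (including the 1.8 <= S <= 2.25 band) fall in
    the ``continuum``.
    """
    if not 0.0 <= p_dd <= 1.0:
        raise ValueError(f"p_dd must be in [0, 1], got {p_dd}")
    if entropy_bits < 0.0:
        raise ValueError(f"entropy must be non-negative, got {entropy_bits}")
    t = thresholds
    if entropy_bits < t.low_entropy:
        if p_dd < t.do_pdd_max:
            return DISORDER_TO_ORDER
        if p_dd > t.dd_pdd_min:
            return DISORDER_TO_DISORDER
        return CONTINUUM
    if entropy_bits > t.high_entropy:
        if p_dd <= t.polymorphic_pdd_max:
            return POLYMORPHIC
        if p_dd <= t.conditional_pdd_max:
            return CONDITIONAL_FOLDING
        if p_dd <= t.disordered_binding_pdd_max:
            return DISORDERED_BINDING
        return CONTINUUM
    return CONTINUUM
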