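"""Synthetic data for exercising every stage of the pipeline offline.

Three generators, each a pure function of (spec, seed):

* labelled feature vectors drawn under a known logistic model, for testing
  parameter recovery and classifier sanity;
* protein sequences with engineered local composition / hydropathy /
  disorder biases inside designated "binding regions" relative to their
  flanks, for testing the feature and profiling stages end to end;
* minimal toy coordinate files (idealised extended backbones) realising a
  per-structure observed/missing plan with designed interface contacts,
  for testing the curation rules.

These emulate the statistical structure the method assumes — not real
proteome composition, real disorder predictors, or real 3-D geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .curation import DDR, DOR, CDR
from .features import KYTE_DOOLITTLE, BiasFeatures
from .io import DisorderProfile, ProteinSequence, STANDARD_AA
from .scoring import ModelParams, TrainingExample, pdo_from_score, score_region


@dataclass(frozen=True)
class SimulationSpec:
    """Generating model for labelled feature vectors.

    Features are independent normals (one mean/sd pair per feature);
    labels are Bernoulli with probability logistic(S_F) under the true
    coefficients. Defaults put the features on the scales the real biases
    live on: disorder differences within about +/-0.3, composition-propensity
    differences within about +/-0.3, hydropathy differences of a couple of
    Kyte-Doolittle units.
    """

    lambda1: float = 2.0
    lambda2: float = -1.0
    lambda3: float = 0.5
    gamma: float = -0.3
    means: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sds: tuple[float, float, float] = (0.3, 0.3, 1.5)
    #: optional 3x3 feature correlation matrix (rows as tuples);
    #: None = independent features
    correlation: tuple | None = None
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("feature standard deviations must be positive")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
                raise ValueError("correlation must be a symmetric 3x3 matrix")
            if np.linalg.eigvalsh(corr).min() < -1e-10:
                raise ValueError("correlation matrix must be positive semidefinite")

    @property
    def true_params(self) -> ModelParams:
        return ModelParams(
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            lambda3=self.lambda3,
            gamma=self.gamma,
        )


def simulate_training_set(spec: SimulationSpec) -> list[TrainingExample]:
    """Draw labelled region features under the spec's logistic model."""
    rng = np.random.default_rng(spec.seed)
    if spec.correlation is None:
        feats = rng.normal(loc=spec.means, scale=spec.sds, size=(spec.n, 3))
    else:
        corr = np.asarray(spec.correlation, dtype=float)
        cov = corr * np.outer(spec.sds, spec.sds)
        feats = rng.multivariate_normal(spec.means, cov, size=spec.n)
    params = spec.true_params
    examples = []
    for k in range(spec.n):
        f = BiasFeatures(*feats[k])
        p = pdo_from_score(score_region(f, params))
        label = int(rng.random() < p)
        examples.append(TrainingExample(features=f, label=label, region_id=f"sim{k}"))
    return examples


def expected_prevalence(spec: SimulationSpec, n_grid: int = 201) -> float:
    """E[label] under the spec by Gauss-Hermite-free numeric integration.

    The linear score is itself normal with mean m = lambda.mu + gamma and
    variance v = sum (lambda_j sd_j)^2, so the prevalence is the integral
    of logistic(s) against N(m, v)."""
    lam = np.array([spec.lambda1, spec.lambda2, spec.lambda3])
    m = float(lam @ np.array(spec.means) + spec.gamma)
    if spec.correlation is None:
        v = float(((lam * np.array(spec.sds)) ** 2).sum())
    else:
        cov = np.asarray(spec.correlation) * np.outer(spec.sds, spec.sds)
        v = float(lam @ cov @ lam)
    if v == 0:
        return float(pdo_from_score(m))
    s = np.linspace(m - 8 * np.sqrt(v), m + 8 * np.sqrt(v), n_grid)
    dens = np.exp(-((s - m) ** 2) / (2 * v)) / np.sqrt(2 * np.pi * v)
    return float(np.trapezoid(np.asarray(pdo_from_score(s)) * dens, s))


# --- designed sequences ------------------------------------------------------

#: Hydrophobic, order-promoting residues and hydrophilic, disorder-promoting
#: ones; used to steer region composition toward a hydropathy target.
_HYDROPHOBIC = "ILVFM"
_HYDROPHILIC = "DEKNQS"


@dataclass(frozen=True)
class RegionDesign:
    """One engineered region: interval plus target biases vs its flanks."""

    start: int
    end: int
    hydropathy_bias: float = 0.0
    disorder_bias: float = 0.0
    composition_skew: float = 0.0  # in [-1, 1]: + toward hydrophilic set

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SequenceDesign:
    """Blueprint for a synthetic sequence with designed binding regions."""

    length: int
    regions: tuple[RegionDesign, ...] = ()
    seed: int = 0
    baseline_disorder: float = 0.5

    def __post_init__(self) -> None:
        prev_end = 0
        for r in self.regions:
            if r.length < 5:
                raise ValueError("designed regions must be >= 5 residues")
            if r.start <= prev_end or r.end > self.length:
                raise ValueError("regions must be in-bounds and non-overlapping")
            if abs(r.hydropathy_bias) > 8.0:
                raise ValueError("hydropathy bias outside the achievable range")
            prev_end = r.end


def _draw_with_mean_kd(
    rng: np.random.Generator, length: int, target_mean: float, tol: float = 0.2
) -> str:
    """Sample residues whose mean Kyte-Doolittle value hits a target.

    Rejection sampling from an exponentially tilted composition; keeps the
    best draw if the tolerance is not met within the retry budget.
    """
    aas = np.array(list(STANDARD_AA))
    kd = np.array([KYTE_DOOLITTLE[a] for a in aas])
    lo, hi = -6.0, 6.0
    # bisect the tilt so that the tilted mean matches the target
    for _ in range(60):
        mid = (lo + hi) / 2
        w = np.exp(mid * kd / 4.5)
        mean = float((w * kd).sum() / w.sum())
        if mean < target_mean:
            lo = mid
        else:
            hi = mid
    w = np.exp(((lo + hi) / 2) * kd / 4.5)
    w = w / w.sum()
    best, best_err = None, np.inf
    for _ in range(200):
        draw = rng.choice(aas, size=length, p=w)
        err = abs(np.mean([KYTE_DOOLITTLE[a] for a in draw]) - target_mean)
        if err < best_err:
            best, best_err = draw, err
        if err <= tol:
            break
    return "".join(best)


def synth_sequence(
    design: SequenceDesign,
) -> tuple[ProteinSequence, DisorderProfile, list[dict]]:
    """Generate (sequence, disorder profile, truth table) from a design.

    Background residues come from a flat 20-letter composition; each
    designed region is drawn to achieve its requested mean hydropathy
    shift (within ~0.2 Kyte-Doolittle units) and optional composition
    skew. The disorder profile is the baseline plus the requested region
    bias, clipped to [0, 1]. The truth table records, per region, the
    realised region-vs-flank deltas for assertions.
    """
    rng = np.random.default_rng(design.seed)
    aas = np.array(list(STANDARD_AA))
    residues = list(rng.choice(aas, size=design.length))
    scores = np.full(design.length, design.baseline_disorder, dtype=float)

    background_kd = float(np.mean([KYTE_DOOLITTLE[a] for a in STANDARD_AA]))
    truth: list[dict] = []
    for region in design.regions:
        target = background_kd + region.hydropathy_bias
        if abs(region.composition_skew) > 0:
            pool = _HYDROPHILIC if region.composition_skew > 0 else _HYDROPHOBIC
            k = int(round(abs(region.composition_skew) * region.length))
            chosen = list(_draw_with_mean_kd(rng, region.length, target))
            idx = rng.choice(region.length, size=min(k, region.length), replace=False)
            for j in idx:
                chosen[j] = str(rng.choice(list(pool)))
        else:
            chosen = list(_draw_with_mean_kd(rng, region.length, target))
        residues[region.start - 1 : region.end] = chosen
        scores[region.start - 1 : region.end] = np.clip(
            design.baseline_disorder + region.disorder_bias, 0.0, 1.0
        )

    seq = ProteinSequence(id=f"synth-{design.seed}", residues="".join(residues))
    profile = DisorderProfile(sequence_id=seq.id, scores=np.clip(scores, 0, 1))

    for region in design.regions:
        fl_lo = max(1, region.start - 20)
        fl_hi = min(design.length, region.end + 20)
        flank_pos = [
            p
            for p in range(fl_lo, fl_hi + 1)
            if p < region.start or p > region.end
        ]
        region_res = seq.slice(region.start, region.end)
        flank_res = "".join(seq.residues[p - 1] for p in flank_pos)
        truth.append(
            {
                "start": region.start,
                "end": region.end,
                "target_hydropathy_bias": region.hydropathy_bias,
                "target_disorder_bias": region.disorder_bias,
                "realised_delta_h": float(
                    np.mean([KYTE_DOOLITTLE[a] for a in region_res])
                    - np.mean([KYTE_DOOLITTLE[a] for a in flank_res])
                ),
                "realised_delta_id": float(
                    profile.mean_over(range(region.start, region.end + 1))
                    - profile.mean_over(flank_pos)
                ),
            }
        )
    return seq, profile, truth


# --- toy structures ----------------------------------------------------------

CA_SPACING = 3.8
CONTACT_DISTANCE = 4.0


@dataclass(frozen=True)
class StructurePlan:
    """O/M states for one structure, plus the designed contact residue.

    ``states`` covers the declared sequence; ``contact_position`` (for
    complexes) is the chain-A residue the partner chain is placed next to,
    at 4.0 A — inside the 4.5 A interface rule by construction.
    """

    name: str
    states: str
    is_complex: bool = False
    contact_position: int | None = None


def _add_backbone(chain: gemmi.Chain, position: int, aa_name: str, x0: float = 0.0):
    res = gemmi.Residue()
    res.name = aa_name
    res.seqid = gemmi.SeqId(position, " ")
    x = x0 + CA_SPACING * position
    for name, dz in (("N", -0.7), ("CA", 0.0), ("C", 0.7)):
        atom = gemmi.Atom()
        atom.name = name
        atom.element = gemmi.Element("N" if name == "N" else "C")
        atom.pos = gemmi.Position(x, 0.0, dz)
        atom.occ = 1.0
        atom.b_iso = 20.0
        res.add_atom(atom)
    chain.add_residue(res)


def _three_letter(aa: str) -> str:
    table = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    }
    return table.get(aa, "GLY")


def synth_structure_file(
    seq: ProteinSequence, plan: StructurePlan, out_dir: str | Path
) -> Path:
    """Write one toy PDB file realising an O/M plan.

    Chain A holds the observed residues of ``seq`` on an idealised
    extended backbone; a complex gets a short partner chain B whose first
    residue sits 4.2 A from the designated contact residue's backbone
    (within the 4.5 A interface cutoff for that residue only).
    """
    if len(plan.states) != seq.n:
        raise ValueError("plan states must cover the declared sequence")
    st = gemmi.Structure()
    st.name = plan.name
    st.resolution = 2.0
    model = gemmi.Model("1")
    chain_a = gemmi.Chain("A")
    for i, (aa, state) in enumerate(zip(seq.residues, plan.states), start=1):
        if state == "O":
            _add_backbone(chain_a, i, _three_letter(aa))
    model.add_chain(chain_a)
    if plan.is_complex:
        chain_b = gemmi.Chain("B")
        cx = CA_SPACING * (plan.contact_position or (seq.n + 5))
        for k in range(5):
            res = gemmi.Residue()
            res.name = "GLY"
            res.seqid = gemmi.SeqId(k + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(cx, 4.2 + CA_SPACING * k, 0.0)
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
            chain_b.add_residue(res)
        model.add_chain(chain_b)
    st.add_model(model)
    st.setup_entities()
    out = Path(out_dir) / f"{plan.name}.pdb"
    st.write_pdb(str(out))
    return out


def synth_structures(
    seq: ProteinSequence,
    plans: list[StructurePlan],
    out_dir: str | Path,
) -> list[Path]:
    """Write a monomer+complexes fixture set; one file per plan."""
    return [synth_structure_file(seq, plan, out_dir) for plan in plans]


def curation_fixture(
    kind: str, *, seed: int = 0, length: int = 40
) -> tuple[ProteinSequence, tuple[int, int], list[StructurePlan], str]:
    """A ready-made curation scenario with its expected label.

    ``kind`` is one of ``DOR``, ``DDR``, ``CDR``. The designed region is
    residues 16-25, disordered (missing) in the monomer; complexes differ
    in whether the region is modelled and contacted per the target rule.
    """
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(list(STANDARD_AA), size=length))
    seq = ProteinSequence(id=f"fixture-{kind}-{seed}", residues=residues)
    region = (16, 25)
    mono = "O" * 15 + "M" * 10 + "O" * (length - 25)
    region_ordered = "O" * length
    region_missing = mono
    if kind == DOR:
        plans = [
            StructurePlan("monomer", mono),
            StructurePlan("cplx1", region_ordered, is_complex=True, contact_position=20),
            StructurePlan("cplx2", region_ordered, is_complex=True, contact_position=18),
        ]
        truth = DOR
    elif kind == DDR:
        plans = [
            StructurePlan("monomer", mono),
            StructurePlan("cplx1", region_missing, is_complex=True, contact_position=5),
            StructurePlan("cplx2", region_missing, is_complex=True, contact_position=30),
        ]
        truth = DDR
    elif kind == CDR:
        plans = [
            StructurePlan("monomer", mono),
            StructurePlan("cplx1", region_ordered, is_complex=True, contact_position=20),
            StructurePlan("cplx2", region_missing, is_complex=True, contact_position=5),
        ]
        truth = CDR
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return seq, region, plans, truth
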