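"""Dataset curation from monomer and complex structures.

Training regions are derived from crystal structures: residues modelled in
the coordinates are taken as ordered (O), residues missing from the model
as disordered (M). A region that is disordered in the monomeric structure
is classified by how it behaves across all known complexes:

* **DOR** (disorder-to-order region) — at least 5 consecutive residues are
  observed in *every* complex and at least one region residue mediates an
  inter-molecular contact (any heavy atom within 4.5 A of a different
  chain; homotypic contacts count);
* **DDR** (disorder-to-disorder region) — the region stays missing in the
  monomer and in every complex;
* **CDR** (context-dependent region) — at least 5 consecutive residues are
  observed ordered in some complex (with an interface contact in that
  ordered form) and missing in another.

Anything else is left ``unclassified`` with its evidence retained so the
label can be re-derived and audited. Terminal missing runs are flagged as
potential truncation artefacts and excluded from DDR/CDR evidence unless
the caller overrides.

Structures are read with gemmi; both PDB and mmCIF are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi

MIN_REGION_LEN = 5
INTERFACE_CUTOFF = 4.5
RESOLUTION_CUTOFF = 3.0

DOR = "DOR"
CDR = "CDR"
DDR = "DDR"
UNCLASSIFIED = "unclassified"


class CurationError(ValueError):
    """Structure cannot be curated as requested."""


@dataclass(frozen=True)
class ResidueObservation:
    """Per-residue O(bserved)/M(issing) states over a declared sequence.

    ``terminal_missing`` marks the leading/trailing M runs, which may be
    construct-truncation artefacts rather than genuine disorder.
    ``nonstandard`` flags positions modelled as chemically modified or
    non-standard residues.
    """

    sequence_id: str
    states: str
    resolution: float | None = None
    nonstandard: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if set(self.states) - {"O", "M"}:
            raise CurationError("states must contain only 'O' and 'M'")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def terminal_missing(self) -> frozenset[int]:
        """1-based positions in the leading or trailing M run."""
        n = len(self.states)
        out: set[int] = set()
        for i in range(n):
            if self.states[i] != "M":
                break
            out.add(i + 1)
        for i in range(n - 1, -1, -1):
            if self.states[i] != "M":
                break
            out.add(i + 1)
        return frozenset(out)


@dataclass(frozen=True)
class RegionAnnotation:
    """A curated region with its label and the evidence it rests on."""

    sequence_id: str
    start: int
    end: int
    label: str
    evidence: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _is_standard(residue: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(residue.name)
    return bool(info and info.is_standard() and info.is_amino_acid())


def _has_heavy_atom(residue: gemmi.Residue) -> bool:
    return any(atom.element.name != "H" for atom in residue)


def read_structure(path: str | Path) -> gemmi.Structure:
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def residue_order_states(
    structure: str | Path | gemmi.Structure,
    chain_id: str,
    declared_sequence: str,
    *,
    enforce_resolution: bool = False,
    max_resolution: float = RESOLUTION_CUTOFF,
) -> ResidueObservation:
    """Assign O/M per residue of ``declared_sequence`` from one chain.

    A residue is O when any of its non-hydrogen atoms is modelled, M
    otherwise. Mapping is by author residue numbering against the declared
    full-length sequence; when the numbering does not fit (out-of-range or
    letter mismatches), the modelled stretch is located by exact substring
    alignment instead. With ``enforce_resolution``, structures determined
    worse than ``max_resolution`` Angstrom are rejected.
    """
    st = (
        structure
        if isinstance(structure, gemmi.Structure)
        else read_structure(structure)
    )
    resolution = st.resolution if st.resolution > 0 else None
    if enforce_resolution and (resolution is None or resolution > max_resolution):
        raise CurationError(
            f"{st.name}: resolution {resolution} worse than {max_resolution} A"
        )
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise CurationError(f"chain {chain_id!r} not found in {st.name}")

    n = len(declared_sequence)
    observed: list[tuple[int | None, str, bool]] = []  # (author num, letter, standard)
    for residue in chain:
        if not _has_heavy_atom(residue):
            continue
        info = gemmi.find_tabulated_residue(residue.name)
        if info is None or not info.is_amino_acid():
            continue
        letter = gemmi.find_tabulated_residue(residue.name).one_letter_code.upper()
        observed.append((residue.seqid.num, letter, _is_standard(residue)))
    if not observed:
        raise CurationError(f"chain {chain_id!r} of {st.name} has no amino acids")

    mapping = _map_by_numbering(observed, declared_sequence)
    if mapping is None:
        mapping = _map_by_alignment(observed, declared_sequence)
    if mapping is None:
        raise CurationError(
            f"cannot map chain {chain_id!r} of {st.name} onto the declared "
            f"{n}-residue sequence (numbering and substring alignment both fail)"
        )

    states = ["M"] * n
    nonstandard: set[int] = set()
    for (num, letter, standard), pos in zip(observed, mapping):
        states[pos - 1] = "O"
        if not standard:
            nonstandard.add(pos)
    return ResidueObservation(
        sequence_id=chain_id,
        states="".join(states),
        resolution=resolution,
        nonstandard=frozenset(nonstandard),
    )


def _map_by_numbering(observed, declared_sequence) -> list[int] | None:
    n = len(declared_sequence)
    mapping = []
    for num, letter, _ in observed:
        if num is None or not 1 <= num <= n:
            return None
        if letter != "X" and declared_sequence[num - 1] != letter:
            return None
        mapping.append(num)
    return mapping


def _map_by_alignment(observed, declared_sequence) -> list[int] | None:
    """Exact substring match of the modelled residue string; assumes one
    contiguous modelled stretch (adequate for construct-style chains)."""
    modelled = "".join(letter for _, letter, _ in observed)
    idx = declared_sequence.find(modelled)
    if idx < 0:
        return None
    return [idx + 1 + k for k in range(len(modelled))]


def disordered_segments(
    obs: ResidueObservation, min_len: int = MIN_REGION_LEN
) -> list[tuple[int, int]]:
    """Maximal runs of missing residues of length >= min_len, by start."""
    segments: list[tuple[int, int]] = []
    start = None
    for i, state in enumerate(obs.states + "O", start=1):
        if state == "M" and start is None:
            start = i
        elif state == "O" and start is not None:
            if i - start >= min_len:
                segments.append((start, i - 1))
            start = None
    return segments


def interface_residues(
    structure: str | Path | gemmi.Structure,
    chain_id: str,
    cutoff: float = INTERFACE_CUTOFF,
) -> set[int]:
    """Author seq-ids of residues of ``chain_id`` within ``cutoff`` A of
    any other chain (heavy atoms only; homotypic chain pairs count)."""
    st = (
        structure
        if isinstance(structure, gemmi.Structure)
        else read_structure(structure)
    )
    model = st[0]
    if len(model) < 2:
        raise CurationError(
            f"{st.name}: interface detection needs >= 2 chains, found {len(model)}"
        )
    chain = model.find_chain(chain_id)
    if chain is None:
        raise CurationError(f"chain {chain_id!r} not found in {st.name}")

    # non-periodic search: contacts across symmetry images are out of scope
    ns = gemmi.NeighborSearch(model, gemmi.UnitCell(), max(cutoff + 1.0, 5.0)).populate()
    contacts: set[int] = set()
    for residue in chain:
        for atom in residue:
            if atom.element.name == "H":
                continue
            for mark in ns.find_atoms(atom.pos, "\0", radius=cutoff):
                cra = mark.to_cra(model)
                if cra.chain.name == chain_id:
                    continue
                if cra.atom.element.name == "H":
                    continue
                if atom.pos.dist(cra.atom.pos) <= cutoff:
                    contacts.add(residue.seqid.num)
                    break
            else:
                continue
            break
    return contacts


def _has_run(states: str, char: str, min_len: int) -> bool:
    run = 0
    for s in states:
        run = run + 1 if s == char else 0
        if run >= min_len:
            return True
    return False


def classify_region(
    region: tuple[int, int],
    monomer_obs: ResidueObservation,
    complex_obs_list: list[ResidueObservation],
    interface_sets: list[set[int]],
    *,
    min_len: int = MIN_REGION_LEN,
    exclude_terminal_artifacts: bool = True,
    sequence_id: str = "",
) -> RegionAnnotation:
    """Label a monomer-disordered region as DOR, CDR, DDR or unclassified.

    ``complex_obs_list`` and ``interface_sets`` are parallel: one O/M
    observation and one interface-residue set per complex structure.
    The label is a pure function of the stored evidence (same-length
    permutations of the complex list give the same label).
    """
    start, end = region
    if end - start + 1 < min_len:
        raise CurationError(f"region [{start},{end}] shorter than {min_len} residues")
    if not complex_obs_list:
        raise CurationError("at least one complex observation is required")
    if len(complex_obs_list) != len(interface_sets):
        raise CurationError("one interface set per complex is required")
    mono_states = monomer_obs.states[start - 1 : end]
    if "O" in mono_states:
        raise CurationError(
            f"region [{start},{end}] is not disordered in the monomer"
        )

    region_positions = set(range(start, end + 1))
    ordered_with_contact = []  # complex has >=5 consecutive O and an interface residue
    ordered_runs = []          # complex has >=5 consecutive O in the region
    missing_runs = []          # complex has >=5 consecutive (non-artifact) M
    all_missing = []
    for obs, iface in zip(complex_obs_list, interface_sets):
        states = obs.states[start - 1 : end]
        has_o = _has_run(states, "O", min_len)
        m_states = states
        if exclude_terminal_artifacts:
            term = obs.terminal_missing
            m_states = "".join(
                "O" if (p in term and s == "M") else s
                for p, s in zip(range(start, end + 1), states)
            )
        has_m = _has_run(m_states, "M", min_len)
        fully_missing = set(states) == {"M"} and (
            not exclude_terminal_artifacts
            or not region_positions <= obs.terminal_missing
        )
        contact = bool(region_positions & iface)
        ordered_runs.append(has_o)
        ordered_with_contact.append(has_o and contact)
        missing_runs.append(has_m)
        all_missing.append(fully_missing)

    evidence = {
        "monomer_states": mono_states,
        "complex_states": [o.states[start - 1 : end] for o in complex_obs_list],
        "interface_contact": [
            sorted(region_positions & s) for s in interface_sets
        ],
        "structures": [o.sequence_id for o in complex_obs_list],
        "n_complexes": len(complex_obs_list),
    }

    if all(ordered_runs) and any(ordered_with_contact):
        label = DOR
    elif all(all_missing):
        label = DDR
    elif any(ordered_with_contact) and any(missing_runs):
        label = CDR
    else:
        label = UNCLASSIFIED
    return RegionAnnotation(
        sequence_id=sequence_id or monomer_obs.sequence_id,
        start=start,
        end=end,
        label=label,
        evidence=evidence,
    )
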