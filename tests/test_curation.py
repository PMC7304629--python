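"""Structure-derived O/M assignment and region classification."""

import numpy as np
import pytest

from bindmode.curation import (
    CDR,
    DDR,
    DOR,
    UNCLASSIFIED,
    CurationError,
    ResidueObservation,
    classify_region,
    disordered_segments,
    interface_residues,
    residue_order_states,
)
from bindmode.io import ProteinSequence
from bindmode.simulate import (
    StructurePlan,
    curation_fixture,
    synth_structure_file,
    synth_structures,
)


@pytest.fixture
def seq40():
    rng = np.random.default_rng(1)
    return ProteinSequence("s40", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40)))


class TestResidueOrderStates:
    def test_truncated_construct_tail_missing(self, seq40, tmp_path):
        seq60 = ProteinSequence("s60", seq40.residues + "G" * 20)
        plan = StructurePlan("trunc", "O" * 40 + "M" * 20)
        path = synth_structure_file(seq60, plan, tmp_path)
        obs = residue_order_states(path, "A", seq60.residues)
        assert obs.states == "O" * 40 + "M" * 20
        assert set(obs.terminal_missing) == set(range(41, 61))

    def test_fully_modelled_chain_all_observed(self, seq40, tmp_path):
        path = synth_structure_file(seq40, StructurePlan("full", "O" * 40), tmp_path)
        obs = residue_order_states(path, "A", seq40.residues)
        assert obs.states == "O" * 40

    def test_internal_gap_missing_exactly(self, seq40, tmp_path):
        states = "O" * 9 + "M" * 11 + "O" * 20  # unmodelled 10-20
        path = synth_structure_file(seq40, StructurePlan("gap", states), tmp_path)
        obs = residue_order_states(path, "A", seq40.residues)
        assert obs.states == states
        assert obs.terminal_missing == frozenset()

    def test_missing_chain_rejected(self, seq40, tmp_path):
        path = synth_structure_file(seq40, StructurePlan("full", "O" * 40), tmp_path)
        with pytest.raises(CurationError, match="chain"):
            residue_order_states(path, "Q", seq40.residues)

    def test_idempotent(self, seq40, tmp_path):
        states = "M" * 5 + "O" * 30 + "M" * 5
        path = synth_structure_file(seq40, StructurePlan("x", states), tmp_path)
        a = residue_order_states(path, "A", seq40.residues)
        b = residue_order_states(path, "A", seq40.residues)
        assert a.states == b.states


class TestDisorderedSegments:
    def _obs(self, states):
        return ResidueObservation(sequence_id="s", states=states)

    def test_short_run_excluded(self):
        assert disordered_segments(self._obs("O" * 5 + "M" * 4 + "O" * 5)) == []

    def test_minimum_length_run_included(self):
        obs = self._obs("O" * 5 + "M" * 5 + "O" * 5)
        assert disordered_segments(obs) == [(6, 10)]

    def test_multiple_runs_in_order(self):
        obs = self._obs("M" * 6 + "O" * 4 + "M" * 8 + "O" * 2)
        assert disordered_segments(obs) == [(1, 6), (11, 18)]


class TestInterfaceResidues:
    def test_contact_at_4A_detected(self, seq40, tmp_path):
        plan = StructurePlan("c", "O" * 40, is_complex=True, contact_position=20)
        path = synth_structure_file(seq40, plan, tmp_path)
        assert interface_residues(path, "A") == {20}

    def test_no_contact_beyond_cutoff(self, seq40, tmp_path):
        plan = StructurePlan("c", "O" * 40, is_complex=True, contact_position=20)
        path = synth_structure_file(seq40, plan, tmp_path)
        # tighten the cutoff below the 4.2 A designed distance: nothing left
        assert interface_residues(path, "A", cutoff=4.0) == set()

    def test_single_chain_rejected(self, seq40, tmp_path):
        path = synth_structure_file(seq40, StructurePlan("m", "O" * 40), tmp_path)
        with pytest.raises(CurationError, match="2 chains"):
            interface_residues(path, "A")

    def test_partner_chain_symmetric_view(self, seq40, tmp_path):
        plan = StructurePlan("c", "O" * 40, is_complex=True, contact_position=20)
        path = synth_structure_file(seq40, plan, tmp_path)
        assert interface_residues(path, "B") == {1}


class TestClassifyRegion:
    @pytest.mark.parametrize("kind", [DOR, DDR, CDR])
    def test_fixture_truth_table(self, kind, tmp_path):
        seq, region, plans, truth = curation_fixture(kind)
        paths = synth_structures(seq, plans, tmp_path)
        mono = residue_order_states(paths[0], "A", seq.residues)
        cobs = [residue_order_states(p, "A", seq.residues) for p in paths[1:]]
        iface = [interface_residues(p, "A") for p in paths[1:]]
        ann = classify_region(region, mono, cobs, iface)
        assert ann.label == truth

    def test_dor_without_interface_contact_not_dor(self, tmp_path):
        """Ordered in all complexes but never touching the partner:
        fails the interface requirement, so not a DOR call."""
        seq, region, plans, _ = curation_fixture(DOR)
        plans = [plans[0]] + [
            StructurePlan(p.name, p.states, is_complex=True, contact_position=35)
            for p in plans[1:]
        ]
        paths = synth_structures(seq, plans, tmp_path)
        mono = residue_order_states(paths[0], "A", seq.residues)
        cobs = [residue_order_states(p, "A", seq.residues) for p in paths[1:]]
        iface = [interface_residues(p, "A") for p in paths[1:]]
        ann = classify_region(region, mono, cobs, iface)
        assert ann.label == UNCLASSIFIED

    def test_complex_order_permutation_invariant(self, tmp_path):
        seq, region, plans, truth = curation_fixture(CDR)
        paths = synth_structures(seq, plans, tmp_path)
        mono = residue_order_states(paths[0], "A", seq.residues)
        cobs = [residue_order_states(p, "A", seq.residues) for p in paths[1:]]
        iface = [interface_residues(p, "A") for p in paths[1:]]
        forward = classify_region(region, mono, cobs, iface)
        backward = classify_region(region, mono, cobs[::-1], iface[::-1])
        assert forward.label == backward.label == truth

    def test_label_rederivable_from_evidence(self, tmp_path):
        """Audit property: the stored evidence alone reproduces the label."""
        seq, region, plans, truth = curation_fixture(DOR)
        paths = synth_structures(seq, plans, tmp_path)
        mono = residue_order_states(paths[0], "A", seq.residues)
        cobs = [residue_order_states(p, "A", seq.residues) for p in paths[1:]]
        iface = [interface_residues(p, "A") for p in paths[1:]]
        ann = classify_region(region, mono, cobs, iface)
        ev = ann.evidence
        # rebuild observations from the evidence strings and re-classify
        start, end = region
        n = seq.n
        mono2 = ResidueObservation("m", "O" * (start - 1) + ev["monomer_states"] + "O" * (n - end))
        cobs2 = [
            ResidueObservation(name, "O" * (start - 1) + s + "O" * (n - end))
            for name, s in zip(ev["structures"], ev["complex_states"])
        ]
        iface2 = [set(c) for c in ev["interface_contact"]]
        ann2 = classify_region(region, mono2, cobs2, iface2)
        assert ann2.label == ann.label == truth

    def test_region_ordered_in_monomer_rejected(self):
        mono = ResidueObservation("m", "O" * 40)
        with pytest.raises(CurationError, match="not disordered"):
            classify_region((10, 20), mono, [mono], [set()])

    def test_no_complexes_rejected(self):
        mono = ResidueObservation("m", "M" * 40)
        with pytest.raises(CurationError, match="complex"):
            classify_region((10, 20), mono, [], [])
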