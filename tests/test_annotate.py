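"""Pi-helix re-marking rules, bulges, label reduction, oracle equivalence."""

from __future__ import annotations

import numpy as np
import pytest

from pihelix.annotate import (
    AnnotationParams,
    annotate_chain,
    annotate_structure,
    assign_bulges,
    assign_pi_helices,
    pi_bond_runs,
    reduce_8_to_4,
    segments_from_labels,
)
from pihelix.hbond import HBond

from _oracles import literal_pi_annotation, reduce_map
from conftest import make_fake_chain, random_annotation_instance


def helical_chain(n):
    return make_fake_chain(n, phi=[None] + [-63.0] * (n - 1), psi=[-45.0] * (n - 1) + [None])


class TestPiBondRuns:
    def test_consecutive_acceptors_grouped(self):
        bonds = [HBond(a + 5, a, -2.5) for a in (3, 4, 5, 9)]
        runs = pi_bond_runs(bonds)
        assert [[b.acceptor_idx for b in run] for run in runs] == [[3, 4, 5], [9]]

    def test_no_pi_bonds_empty(self):
        assert pi_bond_runs([HBond(8, 4, -2.5)]) == []

    def test_alternative_resolution_gates_membership(self):
        # donor 9 has a stronger i->i+4 alternative: its pi bond is discarded
        bonds = [HBond(9, 4, -2.0), HBond(9, 5, -2.6), HBond(10, 5, -2.5)]
        runs = pi_bond_runs(bonds)
        assert [[b.acceptor_idx for b in run] for run in runs] == [[5]]

    def test_ideal_pi_14mer_has_nine_bond_run(self, pi14):
        from pihelix.hbond import find_hbonds

        runs = pi_bond_runs(find_hbonds(pi14), pi14)
        assert len(runs) == 1
        assert len(runs[0]) == 9


class TestAssignPiHelices:
    def test_two_bond_run_marks_exactly_seven_residues(self):
        chain = helical_chain(20)
        bonds = [HBond(11, 6, -2.5), HBond(12, 7, -1.8)]
        ann = assign_pi_helices(chain, bonds, "C" * 20)
        segs = [s for s in ann.segments if s[0] == "I"]
        assert segs == [("I", 6, 12)]
        assert ann.labels4.count("I") == 7

    def test_energy_gate_requires_one_strong_bond(self):
        chain = helical_chain(20)
        bonds = [HBond(11, 6, -1.9), HBond(12, 7, -1.8)]
        ann = assign_pi_helices(chain, bonds, "C" * 20)
        assert "I" not in ann.labels4

    def test_dihedral_window_vetoes_the_range(self):
        phi = [None] + [-63.0] * 19
        psi = [-45.0] * 19 + [None]
        phi[9] = 60.0  # one spanned residue outside the helical region
        chain = make_fake_chain(20, phi=phi, psi=psi)
        bonds = [HBond(11, 6, -2.5), HBond(12, 7, -2.4)]
        ann = assign_pi_helices(chain, bonds, "C" * 20)
        assert "I" not in ann.labels4

    def test_single_bond_never_canonical(self):
        chain = helical_chain(20)
        ann = assign_pi_helices(chain, [HBond(11, 6, -3.0)], "C" * 20)
        assert "I" not in ann.labels4

    def test_existing_I_labels_erased(self):
        chain = helical_chain(10)
        ann = assign_pi_helices(chain, [], "CCIIIIICCC")
        assert ann.labels8 == "CCCCCCCCCC"

    def test_remarking_overrides_prior_labels(self):
        chain = helical_chain(20)
        bonds = [HBond(11, 6, -2.5), HBond(12, 7, -2.4)]
        ann = assign_pi_helices(chain, bonds, "HHHHHHHHHHHHHHHHHHHH")
        assert ann.labels8[6:13] == "IIIIIII"
        assert ann.labels8[:6] == "HHHHHH"

    def test_terminal_undefined_dihedrals_pass(self):
        # pi run right at the chain start: phi of residue 0 is undefined
        chain = helical_chain(12)
        bonds = [HBond(5, 0, -2.5), HBond(6, 1, -2.0)]
        ann = assign_pi_helices(chain, bonds, "C" * 12)
        assert ann.labels4[:7] == "IIIIIII"

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            assign_pi_helices(helical_chain(10), [], "C" * 9)


class TestAssignBulges:
    def test_isolated_strong_bond_makes_six_residue_bulge(self):
        chain = helical_chain(20)
        assert assign_bulges(chain, [HBond(11, 6, -2.0)]) == [(6, 11)]

    def test_weak_bond_is_not_a_bulge(self):
        chain = helical_chain(20)
        assert assign_bulges(chain, [HBond(11, 6, -1.5)]) == []

    def test_two_bond_run_is_not_a_bulge(self):
        chain = helical_chain(20)
        bonds = [HBond(11, 6, -2.5), HBond(12, 7, -2.4)]
        assert assign_bulges(chain, bonds) == []


class TestReduce:
    @pytest.mark.parametrize(
        "l8,l4",
        [("G", "H"), ("H", "H"), ("E", "E"), ("B", "E"), ("S", "C"), ("T", "C"), ("C", "C"), ("I", "I")],
    )
    def test_reduction_map(self, l8, l4):
        assert reduce_8_to_4(l8) == l4

    def test_unknown_letter_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            reduce_8_to_4("HZX")


class TestEndToEnd:
    def test_pi_fixture_single_I_segment(self, pi12):
        ann = annotate_chain(pi12)
        i_segs = [s for s in ann.segments if s[0] == "I"]
        assert len(i_segs) == 1
        assert i_segs[0][1] == 0 and i_segs[0][2] == 11

    def test_alpha_and_threeten_have_no_pi(self, alpha12, threeten12):
        assert "I" not in annotate_chain(alpha12).labels4
        assert "I" not in annotate_chain(threeten12).labels4

    def test_annotate_structure_from_file(self, tmp_path, pi12):
        from pihelix.structure_io import write_pdb

        path = tmp_path / "pi.pdb"
        write_pdb([pi12], path)
        anns = annotate_structure(path)
        assert set(anns) == {"A"}
        assert anns["A"].labels4 == "I" * 12

    def test_dssp_file_mode(self, tmp_path):
        from pihelix.structure_io import DsspRecord, write_dssp

        n = 16
        recs = []
        for i in range(n):
            nh_o = [(None, 0.0), (None, 0.0)]
            if 7 <= i <= 8:  # donors i accept from i-5: acceptors 2,3
                nh_o[0] = (i - 5, -2.5)
            recs.append(
                DsspRecord(
                    chain_id="A", res_seq=i + 1, aa="A", label8="H",
                    nh_o=tuple(nh_o), o_nh=((None, 0.0), (None, 0.0)),
                    phi=None if i == 0 else -63.0, psi=None if i == n - 1 else -45.0,
                )
            )
        path = tmp_path / "x.dssp"
        write_dssp(recs, path)
        anns = annotate_structure(None, mode="dssp_file", dssp_path=path)
        assert anns["A"].labels8[2:9] == "IIIIIII"
        assert anns["A"].labels4 == "HH" + "IIIIIII" + "HHHHHHH"


class TestProperties:
    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            phi, psi, raw_bonds, labels8 = random_annotation_instance(rng)
            chain = make_fake_chain(30, phi=phi, psi=psi)
            bonds = [HBond(d, a, e) for d, a, e in raw_bonds]
            ann = assign_pi_helices(chain, bonds, labels8)
            bulges = assign_bulges(chain, bonds)
            want8, want_bulges = literal_pi_annotation(30, raw_bonds, phi, psi, labels8)
            assert ann.labels8 == want8
            assert ann.labels4 == reduce_map(want8)
            assert bulges == want_bulges

    def test_energy_gate_monotonicity(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            phi, psi, raw_bonds, labels8 = random_annotation_instance(rng)
            chain = make_fake_chain(30, phi=phi, psi=psi)
            bonds = [HBond(d, a, e) for d, a, e in raw_bonds]
            tight = assign_pi_helices(chain, bonds, labels8, AnnotationParams(energy_gate=-2.5))
            loose = assign_pi_helices(chain, bonds, labels8, AnnotationParams(energy_gate=-1.5))
            tight_I = {i for i, c in enumerate(tight.labels8) if c == "I"}
            loose_I = {i for i, c in enumerate(loose.labels8) if c == "I"}
            assert tight_I <= loose_I

    def test_segment_length_is_bonds_plus_five(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            phi, psi, raw_bonds, labels8 = random_annotation_instance(rng)
            chain = make_fake_chain(30, phi=phi, psi=psi)
            bonds = [HBond(d, a, e) for d, a, e in raw_bonds]
            ann = assign_pi_helices(chain, bonds, "C" * 30)
            for typ, s, e in ann.segments:
                if typ == "I":
                    assert e - s + 1 >= 7

    def test_idempotence(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            phi, psi, raw_bonds, labels8 = random_annotation_instance(rng)
            chain = make_fake_chain(30, phi=phi, psi=psi)
            bonds = [HBond(d, a, e) for d, a, e in raw_bonds]
            once = assign_pi_helices(chain, bonds, labels8)
            twice = assign_pi_helices(chain, bonds, once.labels8)
            assert twice.labels8 == once.labels8

    def test_segments_are_maximal_runs(self):
        labels = "CCIIIIIIIHHEEC"
        segs = segments_from_labels(labels)
        rebuilt = "".join(t * (e - s + 1) for t, s, e in segs)
        assert rebuilt == labels
        for (t1, _, e1), (t2, s2, _) in zip(segs, segs[1:]):
            assert t1 != t2 and s2 == e1 + 1
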