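"""Contact/clash classification, radii assignment and H-bond geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcbsr.errors import ConfigurationError
from lcbsr.fixtures import make_random_pose, make_toy_receptor, FixtureSpec, PosePrescription
from lcbsr.interactions import (
    InteractionParams,
    assign_radii,
    classify_pair,
    detect_hbonds,
    enumerate_pose_interactions,
    pair_overlap,
)
from lcbsr.structures import Receptor

from _oracle import oracle_pose_record
from conftest import make_atom, make_pose, simple_key


class TestPairOverlap:
    def test_exact_vdw_touching_gives_zero(self):
        a = make_atom(1, "C", (0, 0, 0), radius=1.70)
        b = make_atom(2, "N", (3.25, 0, 0), radius=1.55)
        assert pair_overlap(a, b) == pytest.approx(0.0)

    def test_contact_boundary_value(self):
        # r_i + r_j = 3.25, distance 3.65 -> overlap -0.40
        a = make_atom(1, "C", (0, 0, 0), radius=1.70)
        b = make_atom(2, "N", (3.65, 0, 0), radius=1.55)
        assert pair_overlap(a, b) == pytest.approx(-0.40)

    def test_symmetric_in_arguments(self):
        a = make_atom(1, "C", (1.0, -2.0, 0.5), radius=1.70)
        b = make_atom(2, "O", (3.0, 1.0, -1.0), radius=1.52)
        assert pair_overlap(a, b) == pytest.approx(pair_overlap(b, a))

    def test_unassigned_radius_raises(self):
        a = make_atom(1, "C", (0, 0, 0), radius=1.70)
        b = make_atom(2, "N", (3.0, 0, 0))
        with pytest.raises(ConfigurationError):
            pair_overlap(a, b)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "distance,expected",
        [
            (2.40, "clash"),    # overlap exactly 1.0: inclusive
            (2.50, "contact"),  # overlap 0.9, below clash threshold
            (3.80, "contact"),  # overlap exactly -0.4: inclusive
            (3.81, "none"),     # overlap -0.41: just outside
        ],
    )
    def test_boundaries(self, distance, expected, params):
        a = make_atom(1, "C", (0, 0, 0), radius=1.70)
        b = make_atom(2, "C", (distance, 0, 0), radius=1.70)
        assert classify_pair(a, b, params) == expected

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            InteractionParams(contact_cutoff=1.5, clash_cutoff=1.0)
        with pytest.raises(ConfigurationError):
            InteractionParams(hbond_angle_max=95.0)


class TestAssignRadii:
    def test_carbon_gets_bundled_bondi_value(self):
        key = simple_key()
        rec = Receptor([make_atom(1, "C", (0, 0, 0), residue_key=key)])
        assign_radii(rec)
        assert rec.atoms[0].vdw_radius == pytest.approx(1.70)

    def test_unknown_element_uses_default_with_warning(self):
        key = simple_key()
        rec = Receptor([make_atom(1, "unknown", (0, 0, 0), residue_key=key)])
        with pytest.warns(UserWarning, match="unknown"):
            assign_radii(rec, default_radius=1.5)
        assert rec.atoms[0].vdw_radius == pytest.approx(1.5)

    def test_missing_element_without_default_raises(self):
        key = simple_key()
        rec = Receptor([make_atom(1, "S", (0, 0, 0), residue_key=key)])
        with pytest.raises(ConfigurationError, match="S"):
            assign_radii(rec, radii_table={"C": 1.70})


class TestDetectHbonds:
    def _receptor_with_acceptor(self, acceptor_coords):
        # a remote hydrogen makes the receptor explicitly protonated, so its
        # O (with no bonded H) is an acceptor only, never a fallback donor
        key = simple_key()
        acceptor = make_atom(10, "O", acceptor_coords, radius=1.52,
                             name="O", residue_key=key)
        remote_h = make_atom(11, "H", np.asarray(acceptor_coords) + 50.0,
                             radius=1.20, name="H", residue_key=key)
        return Receptor([acceptor, remote_h])

    def test_collinear_geometry_accepted(self, params):
        rec = self._receptor_with_acceptor((2.9, 0, 0))
        donor = make_atom(1, "N", (0, 0, 0), radius=1.55)
        hydrogen = make_atom(2, "H", (1.0, 0, 0), radius=1.20)
        pose = make_pose([donor, hydrogen])
        bonds = detect_hbonds(pose, rec, params)
        assert len(bonds) == 1
        assert bonds[0].da_distance == pytest.approx(2.9)
        assert bonds[0].hda_angle == pytest.approx(0.0)

    def test_perpendicular_hydrogen_rejected(self, params):
        # acceptor at 90 degrees from the N-H bond: distance ok, angle not
        rec = self._receptor_with_acceptor((0, 3.4, 0))
        donor = make_atom(1, "N", (0, 0, 0), radius=1.55)
        hydrogen = make_atom(2, "H", (1.0, 0, 0), radius=1.20)
        pose = make_pose([donor, hydrogen])
        assert detect_hbonds(pose, rec, params) == []

    def test_distance_cutoff_rejected(self, params):
        rec = self._receptor_with_acceptor((3.6, 0, 0))
        donor = make_atom(1, "N", (0, 0, 0), radius=1.55)
        hydrogen = make_atom(2, "H", (1.0, 0, 0), radius=1.20)
        pose = make_pose([donor, hydrogen])
        assert detect_hbonds(pose, rec, params) == []

    def test_no_explicit_hydrogens_falls_back_to_distance(self, params):
        # polar-H-merged ligand: distance criterion alone, hda_angle absent
        rec = self._receptor_with_acceptor((3.2, 0, 0))
        donor = make_atom(1, "N", (0, 0, 0), radius=1.55)
        pose = make_pose([donor])
        bonds = [b for b in detect_hbonds(pose, rec, params) if b.donor is donor]
        assert len(bonds) == 1
        assert bonds[0].hydrogen is None and bonds[0].hda_angle is None

    def test_carbon_never_participates(self, params):
        rec = self._receptor_with_acceptor((2.9, 0, 0))
        pose = make_pose([make_atom(1, "C", (0, 0, 0), radius=1.70)])
        assert detect_hbonds(pose, rec, params) == []


class TestEnumeratePoseInteractions:
    def _two_residue_receptor(self):
        key_a, key_b = simple_key(1), simple_key(2, resname="GLY")
        atoms = [
            make_atom(1, "C", (0, 0, 0), radius=1.70, residue_key=key_a),
            make_atom(2, "C", (0, 0, 30), radius=1.70, residue_key=key_a),
            make_atom(3, "C", (30, 0, 0), radius=1.70, residue_key=key_b),
        ]
        return Receptor(atoms), key_a, key_b

    def test_prescribed_contacts_and_clash(self, params):
        rec, key_a, key_b = self._two_residue_receptor()
        lig = [
            make_atom(1, "C", (3.1, 0, 0), radius=1.70),    # contact with A atom 1
            make_atom(2, "C", (0, 3.1, 30), radius=1.70),   # contact with A atom 2
            make_atom(3, "C", (32.0, 0, 0), radius=1.70),   # clash with B (overlap 1.4)
        ]
        record = enumerate_pose_interactions(make_pose(lig), rec, params)
        assert record.contacts == {key_a: 2}
        assert record.clashes == {key_b: 1}
        assert record.clashing_residues == {key_b}

    def test_faraway_ligand_counts_nothing(self, params):
        rec, *_ = self._two_residue_receptor()
        lig = [make_atom(1, "C", (100, 100, 100), radius=1.70)]
        record = enumerate_pose_interactions(make_pose(lig), rec, params)
        assert not record.contacts and not record.clashes and not record.hbonds

    def test_receptor_atom_order_invariance(self, params, demo_receptor, demo_ensembles):
        pose = demo_ensembles[0].poses[0]
        baseline = enumerate_pose_interactions(pose, demo_receptor, params)
        shuffled = Receptor(list(reversed(demo_receptor.atoms)))
        record = enumerate_pose_interactions(pose, shuffled, params)
        assert record.contacts == baseline.contacts
        assert record.clashes == baseline.clashes
        assert record.hbonds == baseline.hbonds

    def test_clash_not_double_counted_as_contact(self, params):
        rec, key_a, _ = self._two_residue_receptor()
        lig = [make_atom(1, "C", (2.0, 0, 0), radius=1.70)]  # overlap 1.4
        record = enumerate_pose_interactions(make_pose(lig), rec, params)
        assert record.clashes == {key_a: 1}
        assert key_a not in record.contacts

    def test_clash_also_contact_flag(self):
        rec, key_a, _ = self._two_residue_receptor()
        lig = [make_atom(1, "C", (2.0, 0, 0), radius=1.70)]
        params = InteractionParams(clash_also_contact=True)
        record = enumerate_pose_interactions(make_pose(lig), rec, params)
        assert record.contacts == {key_a: 1} and record.clashes == {key_a: 1}


class TestOracleEquivalence:
    """The k-d-tree path must match the exhaustive double loop exactly."""

    @pytest.mark.parametrize("seed", range(25))
    def test_random_geometry_matches_bruteforce(self, seed, params):
        rng = np.random.default_rng(seed)
        spec = FixtureSpec(
            n_residues=int(rng.integers(3, 11)),
            poses=(PosePrescription(binding_energy=-5.0),),
            seed=seed,
        )
        rec = assign_radii(make_toy_receptor(spec))
        pose = make_random_pose(rec, int(rng.integers(20, 51)), rng)
        assign_radii(pose)
        record = enumerate_pose_interactions(pose, rec, params)
        contacts, clashes, hbonds, clashing = oracle_pose_record(pose, rec, params)
        assert record.contacts == contacts
        assert record.clashes == clashes
        assert record.hbonds == hbonds
        assert record.clashing_residues == clashing

    def test_hydrogen_exclusion_matches_bruteforce(self):
        params = InteractionParams(include_hydrogens_in_contacts=False)
        rng = np.random.default_rng(7)
        spec = FixtureSpec(
            n_residues=4, poses=(PosePrescription(binding_energy=-5.0),), seed=7
        )
        rec = assign_radii(make_toy_receptor(spec))
        pose = assign_radii(make_random_pose(rec, 30, rng))
        record = enumerate_pose_interactions(pose, rec, params)
        contacts, clashes, hbonds, clashing = oracle_pose_record(pose, rec, params)
        assert (record.contacts, record.clashes, record.hbonds) == (
            contacts, clashes, hbonds)


class TestProperties:
    @given(
        distance=st.floats(min_value=0.5, max_value=6.0),
        low_clash=st.floats(min_value=0.2, max_value=1.0),
        high_clash=st.floats(min_value=1.0, max_value=2.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_raising_clash_cutoff_never_adds_clashes(
        self, distance, low_clash, high_clash
    ):
        a = make_atom(1, "C", (0, 0, 0), radius=1.70)
        b = make_atom(2, "C", (distance, 0, 0), radius=1.70)
        lo = classify_pair(a, b, InteractionParams(clash_cutoff=low_clash))
        hi = classify_pair(a, b, InteractionParams(clash_cutoff=high_clash))
        if hi == "clash":
            assert lo == "clash"

    @given(
        distance=st.floats(min_value=0.5, max_value=6.0),
        wide=st.floats(min_value=-1.5, max_value=-0.4),
    )
    @settings(max_examples=50, deadline=None)
    def test_widening_contact_cutoff_never_loses_contacts(self, distance, wide):
        a = make_atom(1, "C", (0, 0, 0), radius=1.70)
        b = make_atom(2, "C", (distance, 0, 0), radius=1.70)
        narrow_cls = classify_pair(a, b, InteractionParams())
        wide_cls = classify_pair(a, b, InteractionParams(contact_cutoff=wide))
        if narrow_cls == "contact":
            assert wide_cls in ("contact", "clash")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_cotransform_leaves_counts_unchanged(self, seed, params):
        rng = np.random.default_rng(seed)
        spec = FixtureSpec(
            n_residues=4, poses=(PosePrescription(binding_energy=-5.0),), seed=seed
        )
        rec = assign_radii(make_toy_receptor(spec))
        pose = assign_radii(make_random_pose(rec, 25, rng))
        before = enumerate_pose_interactions(pose, rec, params)
        before_hb = len(detect_hbonds(pose, rec, params))

        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.uniform(-40, 40, size=3)
        for atom in list(rec.atoms) + list(pose.atoms):
            atom.coords = q @ atom.coords + shift
        after = enumerate_pose_interactions(pose, rec, params)
        assert after.contacts == before.contacts
        assert after.clashes == before.clashes
        assert after.hbonds == before.hbonds
        assert len(detect_hbonds(pose, rec, params)) == before_hb
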