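"""Structure and convergence diagnostics: dRMS, CRMSD, H-bonds, secondary
structure, folded counts, melting curves, density maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from foldscale import analysis, fixtures
from foldscale.analysis import (
    NativeContactSet,
    assign_ss,
    count_native_hbonds,
    crmsd,
    density_map,
    detect_backbone_hbonds,
    drms,
    folded_count_series,
    is_folded,
    melting_curve,
    native_contacts,
    native_hbond_pattern,
    plateau_sweep,
    ss_propagation,
)
from foldscale.io_formats import AtomRecord, Frame, Structure, Trajectory


def rigid_transform(s: Structure, rotation, translation) -> Structure:
    atoms = [
        AtomRecord(a.atom_name, a.residue_index, a.residue_name,
                   rotation @ a.coords + translation)
        for a in s.atoms
    ]
    return Structure(atoms, id=s.id)


class TestNativeContacts:
    def test_matches_brute_force_enumeration(self, hairpin16, backbone_contacts):
        sel = [a for a in hairpin16.atoms if a.atom_name in ("N", "CA", "C", "O")]
        expected = set()
        for i in range(len(sel)):
            for j in range(i + 1, len(sel)):
                if abs(sel[i].residue_index - sel[j].residue_index) <= 2:
                    continue
                if np.linalg.norm(sel[i].coords - sel[j].coords) <= 4.5:
                    expected.add(
                        (
                            (sel[i].residue_index, sel[i].atom_name),
                            (sel[j].residue_index, sel[j].atom_name),
                        )
                    )
        got = {(c[0], c[1]) for c in backbone_contacts.contacts}
        assert got == expected
        assert backbone_contacts.n_bb == len(expected)

    def test_sequence_separation_rule(self):
        """Residues i and i+2 at 3 Å are excluded by |i-j| > 2."""
        atoms = []
        for ri, x in ((1, 0.0), (2, 40.0), (3, 3.0)):
            atoms.append(AtomRecord("CA", ri, "ALA", np.array([x, 0.0, 0.0])))
        ncs = native_contacts(Structure(atoms), atom_names=("CA",))
        assert ncs.n_bb == 0

    def test_distant_structure_has_no_contacts(self, extended16):
        ncs = native_contacts(extended16, cutoff=4.5, atom_names=("CA",))
        assert ncs.n_bb == 0


class TestDRMS:
    def test_native_is_zero(self, hairpin16, backbone_contacts):
        assert drms(hairpin16, backbone_contacts) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, hairpin16, backbone_contacts, rng):
        rot = Rotation.from_euler("zyx", [90, 30, -45], degrees=True).as_matrix()
        moved = rigid_transform(hairpin16, rot, np.array([10.0, -3.0, 7.0]))
        assert drms(moved, backbone_contacts) == pytest.approx(0.0, abs=1e-9)

    def test_two_contact_hand_value(self):
        """(r - r0) of +0.3 and -0.4 Å: sqrt((0.09 + 0.16)/2) = 0.353553..."""
        atoms = [
            AtomRecord("CA", 1, "ALA", np.array([0.0, 0.0, 0.0])),
            AtomRecord("CA", 4, "ALA", np.array([4.0, 0.0, 0.0])),
            AtomRecord("CA", 8, "ALA", np.array([0.0, 6.0, 0.0])),
        ]
        s = Structure(atoms)
        ncs = NativeContactSet(
            contacts=(
                ((1, "CA"), (4, "CA"), 3.7),  # candidate r = 4.0 -> +0.3
                ((1, "CA"), (8, "CA"), 6.4),  # candidate r = 6.0 -> -0.4
            ),
            cutoff=7.0,
        )
        assert drms(s, ncs) == pytest.approx(np.sqrt((0.09 + 0.16) / 2), abs=1e-12)
        assert drms(s, ncs) == pytest.approx(0.3535533905932738, abs=1e-12)

    def test_brute_force_oracle_on_50_decoys(self, hairpin16, backbone_contacts):
        for seed in range(50):
            decoy = fixtures.perturb_structure(hairpin16, 1.0, seed=seed)
            brute = np.sqrt(
                np.mean(
                    [
                        (
                            np.linalg.norm(
                                decoy.atom(*c[0]).coords - decoy.atom(*c[1]).coords
                            )
                            - c[2]
                        )
                        ** 2
                        for c in backbone_contacts.contacts
                    ]
                )
            )
            assert drms(decoy, backbone_contacts) == pytest.approx(brute, abs=1e-12)

    def test_empty_contact_set_is_an_error(self, hairpin16):
        with pytest.raises(ValueError, match="undefined"):
            drms(hairpin16, NativeContactSet(contacts=(), cutoff=4.5))


class TestIsFolded:
    def test_native_folded_at_any_positive_threshold(self, hairpin16, backbone_contacts):
        assert is_folded(hairpin16, backbone_contacts, threshold=1e-6)

    def test_extended_not_folded(self, extended16, hairpin16, backbone_contacts):
        assert not is_folded(extended16, backbone_contacts)

    def test_boundary_is_strict(self, hairpin16, backbone_contacts):
        value = drms(hairpin16, backbone_contacts)
        assert not is_folded(hairpin16, backbone_contacts, threshold=value)


class TestCRMSD:
    def test_identity_is_zero(self, hairpin16):
        assert crmsd(hairpin16, hairpin16) == pytest.approx(0.0, abs=1e-12)

    def test_superposition_removes_rigid_motion(self, hairpin16):
        rot = Rotation.from_euler("xyz", [17, -40, 113], degrees=True).as_matrix()
        moved = rigid_transform(hairpin16, rot, np.array([-5.0, 2.0, 30.0]))
        assert crmsd(moved, hairpin16) == pytest.approx(0.0, abs=1e-10)

    def test_matches_quaternion_oracle(self, hairpin16, rng):
        """scipy's quaternion-based align_vectors as the independent
        superposition method."""
        decoy = fixtures.perturb_structure(hairpin16, 1.5, seed=8)
        p = decoy.ca_coords()
        q = hairpin16.ca_coords()
        rot, _ = Rotation.align_vectors(q - q.mean(axis=0), p - p.mean(axis=0))
        aligned = rot.apply(p - p.mean(axis=0)) + q.mean(axis=0)
        oracle = np.sqrt(np.mean(np.sum((aligned - q) ** 2, axis=1)))
        assert crmsd(decoy, hairpin16) == pytest.approx(oracle, abs=1e-9)

    def test_ca_count_mismatch_rejected(self, hairpin16):
        with pytest.raises(ValueError, match="mismatch"):
            crmsd(fixtures.make_extended_chain(8), hairpin16)


class TestHydrogenBonds:
    def test_extended_chain_has_none(self, extended16):
        assert detect_backbone_hbonds(extended16) == []

    def test_hairpin_ladder_regression(self, hairpin16):
        bonds = detect_backbone_hbonds(hairpin16)
        assert len(bonds) == 7  # frozen construction value
        assert all(b.energy < -0.5 for b in bonds)
        assert all(abs(b.donor - b.acceptor) >= 2 for b in bonds)

    def test_helix_is_i_to_i_minus_4(self):
        helix = fixtures.make_ideal_helix(14)
        bonds = detect_backbone_hbonds(helix)
        assert len(bonds) >= 8
        assert {b.donor - b.acceptor for b in bonds} == {4}

    def test_count_native_full_on_native(self, hairpin16):
        pattern = native_hbond_pattern(hairpin16)
        assert count_native_hbonds(hairpin16, pattern) == len(pattern)

    def test_count_native_zero_on_extended(self, hairpin16, extended16):
        pattern = native_hbond_pattern(hairpin16)
        assert count_native_hbonds(extended16, pattern) == 0

    def test_single_broken_bond_decrements_count(self, hairpin16):
        """Targeted decoy: displacing one acceptor carbonyl breaks exactly
        its bond."""
        pattern = native_hbond_pattern(hairpin16)
        # (16 -> 1): displace residue 1's O away from donor 16's N-H
        atoms = [
            AtomRecord(a.atom_name, a.residue_index, a.residue_name,
                       a.coords + np.array([0.0, 0.0, 3.0])
                       if (a.residue_index == 1 and a.atom_name == "O")
                       else a.coords)
            for a in hairpin16.atoms
        ]
        decoy = Structure(atoms).validate()
        assert count_native_hbonds(decoy, pattern) == len(pattern) - 1

    def test_empty_pattern_rejected(self, hairpin16):
        with pytest.raises(ValueError):
            count_native_hbonds(hairpin16, [])

    def test_missing_backbone_atoms_rejected(self, hairpin16):
        stripped = Structure(
            [a for a in hairpin16.atoms if not (a.residue_index == 7 and a.atom_name == "O")]
        )
        with pytest.raises(ValueError, match="lacks backbone"):
            detect_backbone_hbonds(stripped)


class TestSecondaryStructure:
    def test_helix_interior_h(self):
        helix = fixtures.make_ideal_helix(14)
        code = assign_ss(helix)
        interior = [r for r in helix.residue_indices[3:-3]]
        assert all(code[r] == "H" for r in interior)

    def test_extended_all_coil(self, extended16):
        assert set(assign_ss(extended16).values()) == {"C"}

    def test_propagation_single_frame(self, hairpin16):
        t = Trajectory([Frame(hairpin16, energy=None, step=0, temperature=300.0)])
        m = ss_propagation(t)
        code = assign_ss(hairpin16)
        assert m.codes.shape == (16, 1)
        assert list(m.codes[:, 0]) == [code[r] for r in hairpin16.residue_indices]

    def test_constant_trajectory_constant_columns(self, hairpin16):
        frames = [
            Frame(hairpin16, energy=None, step=k, temperature=300.0) for k in range(4)
        ]
        m = ss_propagation(Trajectory(frames))
        assert m.codes.shape == (16, 4)
        assert all((m.codes[:, 0] == m.codes[:, k]).all() for k in range(4))

    def test_topology_drift_rejected(self, hairpin16):
        other = fixtures.make_extended_chain(8)
        frames = [
            Frame(hairpin16, energy=None, step=0, temperature=300.0),
            Frame(other, energy=None, step=1, temperature=300.0),
        ]
        with pytest.raises(ValueError, match="drift"):
            ss_propagation(Trajectory(frames))


class TestFoldedCountsAndMelting:
    def _result(self, states_per_slot, temperatures=None):
        from foldscale.remd import REMDResult

        n_slots = len(states_per_slot)
        n_rec = len(states_per_slot[0])
        return REMDResult(
            temperatures=np.asarray(temperatures or np.linspace(300, 400, n_slots)),
            record_sweeps=np.arange(1, n_rec + 1),
            slot_states=[list(s) for s in states_per_slot],
            slot_energies=np.zeros((n_slots, n_rec)),
            walker_slots=np.tile(np.arange(n_slots), (n_rec, 1)),
        ).validate()

    def test_all_native_slots_count_full(self, hairpin16, ca_contacts):
        folded_fn = analysis.make_drms_folded_fn(
            ca_contacts, hairpin16.residue_indices
        )
        native_ca = hairpin16.ca_coords()
        result = self._result([[native_ca] * 5] * 4)
        _, counts = folded_count_series(result, folded_fn)
        np.testing.assert_array_equal(counts, 4)

    def test_all_extended_slots_count_zero(self, hairpin16, extended16, ca_contacts):
        folded_fn = analysis.make_drms_folded_fn(ca_contacts, hairpin16.residue_indices)
        ext_ca = extended16.ca_coords()
        result = self._result([[ext_ca] * 5] * 4)
        _, counts = folded_count_series(result, folded_fn)
        np.testing.assert_array_equal(counts, 0)

    def test_mixed_assignment_matches_hand_count(self, hairpin16, extended16, ca_contacts):
        folded_fn = analysis.make_drms_folded_fn(ca_contacts, hairpin16.residue_indices)
        nat, ext = hairpin16.ca_coords(), extended16.ca_coords()
        result = self._result([[nat, ext, nat], [ext, ext, nat], [nat, nat, nat]])
        _, counts = folded_count_series(result, folded_fn)
        np.testing.assert_array_equal(counts, [2, 1, 3])

    def test_melting_fraction_bounds_and_all_folded(self, hairpin16, ca_contacts):
        folded_fn = analysis.make_drms_folded_fn(ca_contacts, hairpin16.residue_indices)
        nat = hairpin16.ca_coords()
        result = self._result([[nat] * 30] * 3)
        curve = melting_curve(result, folded_fn, window=(0, 31), block=5, seed=1)
        np.testing.assert_array_equal(curve.fractions, 1.0)

    def test_empty_window_rejected(self, hairpin16, ca_contacts):
        folded_fn = analysis.make_drms_folded_fn(ca_contacts, hairpin16.residue_indices)
        result = self._result([[hairpin16.ca_coords()] * 5] * 2)
        with pytest.raises(ValueError, match="window"):
            melting_curve(result, folded_fn, window=(100, 200))

    def test_plateau_detection_on_synthetic_series(self):
        sweeps = np.arange(0, 1000, 10)
        counts = np.where(sweeps < 300, 0, 5)
        assert plateau_sweep(sweeps, counts) == 300
        flat = np.full_like(sweeps, 5)
        assert plateau_sweep(sweeps, flat) == 0


class TestDensityMap:
    def _traj(self, structures, energies):
        frames = [
            Frame(s, energy=float(e), step=k, temperature=300.0)
            for k, (s, e) in enumerate(zip(structures, energies))
        ]
        return Trajectory(frames)

    def test_counts_conserved(self, hairpin16):
        t = self._traj([hairpin16] * 7, np.arange(7.0))
        counts, _, _ = density_map(t, hairpin16, bins=5)
        assert counts.sum() == 7

    def test_identical_frames_occupy_single_cell(self, hairpin16):
        t = self._traj([hairpin16] * 5, [2.0] * 5)
        counts, _, _ = density_map(t, hairpin16, bins=4)
        assert (counts > 0).sum() == 1
        assert counts.max() == 5

    def test_two_state_trajectory_shows_two_basins(self, hairpin16, extended16):
        """Alternating folded/unfolded frames produce occupied cells both
        below 3 Å and above 4 Å CRMSD."""
        structures = [hairpin16, extended16] * 10
        energies = [-20.0, 0.0] * 10
        t = self._traj(structures, energies)
        counts, _, r_edges = density_map(t, hairpin16, bins=10)
        centers = 0.5 * (r_edges[:-1] + r_edges[1:])
        occupancy = counts.sum(axis=0)
        assert occupancy[centers < 3.0].sum() > 0
        assert occupancy[centers > 4.0].sum() > 0

    def test_missing_energy_rejected(self, hairpin16):
        t = Trajectory([Frame(hairpin16, energy=None, step=0, temperature=300.0)])
        with pytest.raises(ValueError, match="energy"):
            density_map(t, hairpin16)


@settings(derandomize=True, max_examples=25)
@given(
    angles=st.tuples(*[st.floats(min_value=-180, max_value=180)] * 3),
    shift=st.tuples(*[st.floats(min_value=-50, max_value=50)] * 3),
)
def test_drms_and_crmsd_rigid_invariance_property(angles, shift):
    """Any proper rigid motion leaves both metrics at zero."""
    s = fixtures.make_ideal_hairpin(8)
    ncs = native_contacts(s, cutoff=8.0, atom_names=("CA",))
    rot = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
    moved = rigid_transform(s, rot, np.array(shift))
    assert drms(moved, ncs) < 1e-8
    assert crmsd(moved, s) < 1e-8
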