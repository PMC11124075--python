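"""Geometric descriptors: frame basis, signed distance, orientation, tilt,
circularity, hydrogen bonds, and binding-mode classification."""

import numpy as np
import pytest

from cyclobind import (
    AtomRecord,
    CDBuildParams,
    GeometryError,
    HBondCriteria,
    MolecularStructure,
    SelectionSpec,
    build_cd,
    build_frame_basis,
    circularity,
    classify_mode,
    count_hbonds,
    describe_frame,
    dopo_like_guest,
    guest_orientation,
    place_guest,
    signed_com_distance,
    tilt_angles,
)
from conftest import random_rotation


class TestFrameBasis:
    def test_canonical_pose(self, beta_cd):
        structure, topology = beta_cd
        basis = build_frame_basis(structure, topology)
        assert np.allclose(basis.origin, 0.0, atol=1e-8)
        assert np.allclose(basis.z_axis, [0.0, 0.0, 1.0], atol=1e-8)
        # right-handed orthonormal frame
        frame = np.column_stack([basis.x_axis, basis.y_axis, basis.z_axis])
        assert np.allclose(frame.T @ frame, np.eye(3), atol=1e-10)
        assert np.linalg.det(frame) == pytest.approx(1.0, abs=1e-10)

    def test_rotated_pose_oracle(self, beta_cd, rng):
        """Oracle: the rotated basis must equal R applied to the canonical one."""
        structure, topology = beta_cd
        R = random_rotation(rng)
        t = rng.normal(size=3) * 10.0
        basis = build_frame_basis(structure.transformed(R, t), topology)
        assert np.allclose(basis.z_axis, R @ [0.0, 0.0, 1.0], atol=1e-8)
        canonical = build_frame_basis(structure, topology)
        assert np.allclose(basis.x_axis, R @ canonical.x_axis, atol=1e-8)
        assert np.allclose(basis.origin, R @ canonical.origin + t, atol=1e-8)

    def test_sign_rule_flips_with_rims(self, beta_cd):
        """Primary rim below the plane -> z points down."""
        structure, topology = beta_cd
        flipped = structure.transformed(rotation=np.diag([1.0, -1.0, -1.0]))
        basis = build_frame_basis(flipped, topology)
        assert np.allclose(basis.z_axis, [0.0, 0.0, -1.0], atol=1e-8)

    def test_collinear_oxygens_rejected(self, beta_cd):
        structure, topology = beta_cd
        atoms = [AtomRecord(a.serial, a.name, a.residue_name, a.residue_index,
                            a.element, np.array([float(a.serial), 0.0, 0.0]))
                 for a in structure.atoms]
        with pytest.raises(GeometryError):
            build_frame_basis(MolecularStructure(atoms), topology)


class TestSignedDistance:
    @pytest.mark.parametrize("d", [3.0, -3.0, 0.0])
    def test_axial_placement(self, beta_cd, guest, d):
        structure, topology = beta_cd
        g, vec = guest
        cx, sel = place_guest(structure, topology, g, vec, d_signed=d, theta=0.0)
        basis = build_frame_basis(cx, topology)
        assert signed_com_distance(cx, topology, sel, basis) == pytest.approx(
            d, abs=1e-8)

    def test_sign_matches_rim_distance_oracle(self, beta_cd, guest, rng):
        """d > 0 iff the guest COM is strictly closer to the P-rim oxygen centroid."""
        structure, topology = beta_cd
        g, vec = guest
        for d in rng.uniform(-8.0, 8.0, size=12):
            cx, sel = place_guest(structure, topology, g, vec,
                                  d_signed=float(d), theta=30.0)
            basis = build_frame_basis(cx, topology)
            com = cx.com(sel.guest)
            d_p = np.linalg.norm(com - cx.centroid(topology.prim_serials))
            d_s = np.linalg.norm(com - cx.centroid(topology.sec_serials))
            value = signed_com_distance(cx, topology, sel, basis)
            assert (value > 0) == (d_p < d_s) or value == 0


class TestOrientation:
    @pytest.mark.parametrize("theta", [0.0, 90.0, 180.0, 25.0, 151.8])
    def test_injected_angle_recovered(self, beta_cd, guest, theta):
        structure, topology = beta_cd
        g, vec = guest
        cx, sel = place_guest(structure, topology, g, vec, d_signed=0.5,
                              theta=theta, azimuth=33.0)
        basis = build_frame_basis(cx, topology)
        assert guest_orientation(cx, sel, basis) == pytest.approx(theta, abs=1e-6)

    def test_zero_length_vector_rejected(self, beta_cd):
        structure, topology = beta_cd
        atoms = list(structure.atoms)
        atoms.append(AtomRecord(9001, "X1", "GST", 50, "C", np.array([0.0, 0.0, 1.0])))
        atoms.append(AtomRecord(9002, "X2", "GST", 50, "C", np.array([0.0, 0.0, 1.0])))
        s = MolecularStructure(atoms)
        sel = SelectionSpec(host=set(int(x) for x in structure.serials),
                            guest={9001, 9002}, guest_vector=(9001, 9002))
        basis = build_frame_basis(s, topology)
        with pytest.raises(GeometryError):
            guest_orientation(s, sel, basis)


class TestTilt:
    @pytest.mark.parametrize("tau", [77.0, 80.0, 88.0])
    def test_uniform_tilt_recovered(self, tau):
        structure, topology = build_cd(CDBuildParams(n_units=7, tilt_deg=tau))
        basis = build_frame_basis(structure, topology)
        per_unit, mean = tilt_angles(structure, topology, basis)
        assert mean == pytest.approx(tau, abs=1e-6)
        assert np.allclose(per_unit, tau, atol=1e-6)

    def test_above_90_leans_secondary_rim_inward(self):
        structure, topology = build_cd(CDBuildParams(n_units=7, tilt_deg=95.0))
        basis = build_frame_basis(structure, topology)
        _, mean = tilt_angles(structure, topology, basis)
        assert mean == pytest.approx(95.0, abs=1e-6)


class TestCircularity:
    def test_regular_ring_is_circular(self, beta_cd, beta_cd_basis):
        structure, topology = beta_cd
        assert circularity(structure, topology, beta_cd_basis) == pytest.approx(
            1.0, abs=1e-10)

    @pytest.mark.parametrize("ell", [0.8, 0.95])
    def test_elliptical_cavity(self, ell):
        """Oracle: points on an ellipse at equal parameter angles have a
        projected covariance with eigenvalues (a^2/2, (ell*a)^2/2)."""
        structure, topology = build_cd(CDBuildParams(n_units=7, ellipticity=ell))
        basis = build_frame_basis(structure, topology)
        assert circularity(structure, topology, basis) == pytest.approx(
            ell, abs=1e-6)

    def test_rigid_motion_invariance(self, rng):
        structure, topology = build_cd(CDBuildParams(n_units=7, ellipticity=0.9))
        basis = build_frame_basis(structure, topology)
        ref = circularity(structure, topology, basis)
        moved = structure.transformed(random_rotation(rng), rng.normal(size=3))
        basis2 = build_frame_basis(moved, topology)
        assert circularity(moved, topology, basis2) == pytest.approx(ref, abs=1e-10)


def _hbond_fixture(da_distance, hda_angle_deg):
    """Host hydroxyl O-H donating to a guest acceptor O."""
    theta = np.radians(hda_angle_deg)
    h_pos = np.array([0.96 * np.cos(theta), 0.96 * np.sin(theta), 0.0])
    atoms = [
        AtomRecord(1, "O2", "GLC", 1, "O", np.zeros(3)),           # donor
        AtomRecord(2, "HO2", "GLC", 1, "H", h_pos),                # its H
        AtomRecord(3, "O1", "DPO", 9, "O", np.array([da_distance, 0.0, 0.0])),
        AtomRecord(4, "P1", "DPO", 9, "P", np.array([da_distance + 1.5, 0.0, 0.0])),
    ]
    s = MolecularStructure(atoms)
    sel = SelectionSpec(host={1, 2}, guest={3, 4}, guest_vector=(4, 3))
    return s, sel


class TestHBonds:
    def test_collinear_pair_counted(self):
        s, sel = _hbond_fixture(2.8, 0.0)
        assert count_hbonds(s, sel) == 1

    def test_distance_cutoff(self):
        s, sel = _hbond_fixture(4.0, 0.0)
        assert count_hbonds(s, sel) == 0

    def test_angle_cutoff(self):
        s, sel = _hbond_fixture(2.8, 45.0)
        assert count_hbonds(s, sel) == 0

    def test_criteria_are_tunable(self):
        s, sel = _hbond_fixture(2.8, 45.0)
        assert count_hbonds(s, sel, HBondCriteria(max_da_distance=3.5,
                                                  max_angle=60.0)) == 1

    def test_no_hydrogens_is_an_error(self, beta_cd, guest):
        structure, topology = beta_cd
        g, vec = guest
        cx, sel = place_guest(structure, topology, g, vec, d_signed=0.0, theta=0.0)
        with pytest.raises(GeometryError, match="hydrogen"):
            count_hbonds(cx, sel)


class TestClassifyMode:
    @pytest.mark.parametrize("d,theta,expected", [
        (-1.0, 20.0, "BS"),      # beta-CD MD preference
        (8.5, 45.0, "UNBOUND"),  # dissociated peak
        (1.2, 151.8, "BP"),      # gamma-CD docking pose
        (-4.3, 27.3, "BS"),      # alpha-CD docking pose
        (0.0, 90.0, "BP"),       # documented tie-break at exactly 90 deg
        (-7.0, 10.0, "UNBOUND"),
        (6.5, 89.9, "BS"),       # exactly at the cutoff is still bound
    ])
    def test_reference_cases(self, d, theta, expected):
        assert classify_mode(d, theta) == expected

    def test_exhaustive_grid_is_total(self):
        d_grid = np.linspace(-12.0, 12.0, 49)
        t_grid = np.linspace(0.0, 180.0, 37)
        labels = {classify_mode(d, t) for d in d_grid for t in t_grid}
        assert labels == {"BS", "BP", "UNBOUND"}
        for d in d_grid:
            for t in t_grid:
                m = classify_mode(d, t)
                if abs(d) > 6.5:
                    assert m == "UNBOUND"
                else:
                    assert m == ("BS" if t < 90.0 else "BP")


class TestDescribeFrame:
    @pytest.mark.parametrize("d,theta,mode", [
        (-1.5, 25.0, "BS"),
        (1.2, 152.0, "BP"),
        (8.5, 45.0, "UNBOUND"),
    ])
    def test_composite_recovery(self, beta_cd, guest, d, theta, mode):
        structure, topology = beta_cd
        g, vec = guest
        cx, sel = place_guest(structure, topology, g, vec, d_signed=d,
                              theta=theta, azimuth=120.0)
        desc = describe_frame(cx, topology, sel)
        assert desc.d_signed == pytest.approx(d, abs=1e-6)
        assert desc.theta == pytest.approx(theta, abs=1e-6)
        assert desc.tau_mean == pytest.approx(80.0, abs=1e-6)
        assert desc.circularity == pytest.approx(1.0, abs=1e-6)
        assert desc.mode == mode
        assert desc.n_hbonds is None

    def test_rigid_motion_invariance_of_all_descriptors(self, beta_cd, guest, rng):
        structure, topology = beta_cd
        g, vec = guest
        cx, sel = place_guest(structure, topology, g, vec, d_signed=-2.0,
                              theta=40.0, azimuth=75.0)
        ref = describe_frame(cx, topology, sel)
        for _ in range(3):
            moved = cx.transformed(random_rotation(rng), rng.normal(size=3) * 20.0)
            got = describe_frame(moved, topology, sel)
            assert got.d_signed == pytest.approx(ref.d_signed, abs=1e-8)
            assert got.theta == pytest.approx(ref.theta, abs=1e-8)
            assert got.tau_mean == pytest.approx(ref.tau_mean, abs=1e-8)
            assert got.circularity == pytest.approx(ref.circularity, abs=1e-8)
            assert got.mode == ref.mode
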