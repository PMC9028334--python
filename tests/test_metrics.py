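"""Structural observables: H-bonds, distances, pore radius, RDF, dipoles,
membrane potential, bond-vector angles."""

import numpy as np
import pytest

from poreflux.metrics import (
    HBondCriterion,
    bond_vector_angle,
    dipole_moment,
    hydrogen_bonds,
    membrane_potential,
    min_distance,
    pore_radius_profile,
    potential_from_density,
    rdf,
)
from poreflux.permeation import PoreGeometry
from poreflux.trajio import AtomMeta, Selection

from conftest import make_trajectory


def hbond_system(acceptor_positions):
    """Donor N at origin-ish with H along +x; acceptor O moved per frame."""
    n_frames = len(acceptor_positions)
    coords = np.zeros((n_frames, 3, 3))
    coords[:, 0] = [10.0, 10.0, 10.0]  # donor N
    coords[:, 1] = [11.0, 10.0, 10.0]  # its hydrogen
    coords[:, 2] = np.asarray(acceptor_positions) + np.array([10.0, 10.0, 10.0])
    atoms = [
        AtomMeta("N", "ASN", 1),
        AtomMeta("HN", "ASN", 1),
        AtomMeta("O", "DEX", 2),
    ]
    return make_trajectory(coords, (30.0, 30.0, 30.0), atoms=atoms)


class TestHydrogenBonds:
    def test_planted_geometries_match_hand_enumeration(self):
        """5-frame fixture: bond iff distance ≤ 3.5 Å and H–D–A angle ≤ 30°."""
        a = 3.4
        positions = [
            (a, 0, 0),                                  # 3.4 Å, 0° → bond
            (3.6, 0, 0),                                # too far → none
            (0, a, 0),                                  # 90° → none
            (a * np.cos(np.deg2rad(20)), a * np.sin(np.deg2rad(20)), 0),  # 20° → bond
            (1.7, 0, 0),                                # short, 0° → bond
        ]
        traj = hbond_system(positions)
        counts, pairs = hydrogen_bonds(
            traj, Selection("don", [0]), Selection("acc", [2])
        )
        assert list(counts) == [1, 0, 0, 1, 1]
        assert pairs[0] == [(0, 2)]

    def test_donor_without_hydrogen_rejected(self):
        traj = hbond_system([(3.0, 0, 0)])
        with pytest.raises(ValueError, match="hydrogen"):
            hydrogen_bonds(traj, Selection("don", [2]), Selection("acc", [0]))

    def test_angle_cutoff_configurable(self):
        traj = hbond_system([(3.4 * np.cos(np.deg2rad(20)), 3.4 * np.sin(np.deg2rad(20)), 0)])
        crit = HBondCriterion(max_hda_angle=10.0)
        counts, _ = hydrogen_bonds(traj, Selection("d", [0]), Selection("a", [2]), crit)
        assert counts[0] == 0


class TestMinDistance:
    def test_identical_groups_zero(self, gas_trajectory):
        sel = Selection("s", np.arange(5))
        assert np.all(min_distance(gas_trajectory, sel, sel) == 0.0)

    def test_direct_distance(self):
        coords = np.array([[[0, 0, 0], [0, 0, 5.0]]])
        traj = make_trajectory(coords, (100.0, 100.0, 100.0))
        assert min_distance(traj, Selection("a", [0]), Selection("b", [1]))[0] == 5.0

    def test_minimum_image(self):
        coords = np.array([[[0, 0, 1.0], [0, 0, 99.0]]])
        traj = make_trajectory(coords, (100.0, 100.0, 100.0))
        assert min_distance(traj, Selection("a", [0]), Selection("b", [1]))[0] == pytest.approx(2.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        coords = rng.random((3, 8, 3)) * 50
        traj = make_trajectory(coords, (50.0, 50.0, 50.0))
        a, b = Selection("a", np.arange(4)), Selection("b", np.arange(4, 8))
        ref = min_distance(traj, a, b)
        shifted = make_trajectory(coords + 13.7, (50.0, 50.0, 50.0))
        assert np.allclose(min_distance(shifted, a, b), ref, atol=1e-9)


class TestPoreRadius:
    def test_single_atom_arithmetic(self):
        atoms = [AtomMeta("CA", "ALA", 1, vdw_radius=1.5)]
        coords = np.array([[[14.0, 10.0, 20.0]]])  # lateral distance 4 from axis
        traj = make_trajectory(coords, (20.0, 20.0, 60.0), atoms=atoms)
        geom = PoreGeometry(center=(10.0, 10.0), radius=5.0, z_lo=19.0, z_hi=21.0)
        _, prof = pore_radius_profile(traj, Selection("p", [0]), geom, slice_width=2.0)
        assert prof[0] == pytest.approx(2.5)

    def test_empty_selection_all_masked(self, pore_geometry, gas_trajectory):
        _, prof = pore_radius_profile(
            gas_trajectory, Selection("none", np.array([], int)), pore_geometry
        )
        assert np.all(np.isnan(prof))

    def test_cylinder_of_atoms_uniform_profile(self):
        """Ring of vdW-1.4 atoms at lateral distance 6 → open radius 4.6."""
        n_ring, n_slices = 12, 10
        zs = np.linspace(20.5, 29.5, n_slices)
        pos = []
        for z in zs:
            for k in range(n_ring):
                th = 2 * np.pi * k / n_ring
                pos.append([15 + 6 * np.cos(th), 15 + 6 * np.sin(th), z])
        coords = np.array([pos])
        atoms = [
            AtomMeta("CA", "ALA", i + 1, vdw_radius=1.4) for i in range(len(pos))
        ]
        traj = make_trajectory(coords, (30.0, 30.0, 60.0), atoms=atoms)
        geom = PoreGeometry(center=(15.0, 15.0), radius=8.0, z_lo=20.0, z_hi=30.0)
        _, prof = pore_radius_profile(
            traj, Selection("p", np.arange(len(pos))), geom, slice_width=1.0
        )
        assert np.allclose(prof, 4.6)


class TestRdf:
    def test_single_pair_single_bin(self):
        coords = np.array([[[10.0, 10, 10], [15.0, 10, 10]]])
        traj = make_trajectory(coords, (40.0, 40.0, 40.0))
        res = rdf(traj, Selection("r", [0]), Selection("t", [1]), r_max=8.0, bin_width=0.5)
        nz = np.nonzero(res.g)[0]
        assert len(nz) == 1
        assert res.r_edges[nz[0]] <= 5.0 < res.r_edges[nz[0] + 1]

    def test_poisson_gas_converges_to_one(self):
        rng = np.random.default_rng(8)
        n_ref, n_tgt, n_frames = 100, 1000, 20
        coords = rng.random((n_frames, n_ref + n_tgt, 3)) * 20.0
        traj = make_trajectory(coords, (20.0, 20.0, 20.0))
        res = rdf(
            traj,
            Selection("ref", np.arange(n_ref)),
            Selection("tgt", np.arange(n_ref, n_ref + n_tgt)),
            r_max=8.0,
            bin_width=0.5,
        )
        assert np.max(np.abs(res.g[2:] - 1.0)) < 0.05

    def test_normalization_integrates_to_n_target(self):
        rng = np.random.default_rng(9)
        coords = rng.random((10, 220, 3)) * 12.0
        traj = make_trajectory(coords, (12.0, 12.0, 12.0))
        tgt = Selection("t", np.arange(20, 220))
        res = rdf(traj, Selection("r", np.arange(20)), tgt, r_max=5.8, bin_width=0.2)
        shell = 4 / 3 * np.pi * (res.r_edges[1:] ** 3 - res.r_edges[:-1] ** 3)
        integral = np.sum(res.g * shell) * len(tgt) / 12.0**3
        expected = len(tgt) * (4 / 3 * np.pi * 5.8**3) / 12.0**3
        assert integral == pytest.approx(expected, rel=0.05)

    def test_r_max_beyond_half_box_rejected(self, gas_trajectory):
        with pytest.raises(ValueError, match="half"):
            rdf(
                gas_trajectory,
                Selection("r", [0]),
                Selection("t", [1]),
                r_max=15.0,
            )


class TestDipole:
    def charge_pair(self, rvec):
        atoms = [
            AtomMeta("P", "LIG", 1, partial_charge=1.0),
            AtomMeta("M", "LIG", 1, partial_charge=-1.0),
        ]
        coords = np.zeros((1, 2, 3))
        coords[0, 0] = np.array([25.0, 25.0, 25.0]) + np.asarray(rvec)
        coords[0, 1] = [25.0, 25.0, 25.0]
        return make_trajectory(coords, (50.0, 50.0, 50.0), atoms=atoms)

    def test_unit_separation_along_z(self):
        traj = self.charge_pair([0, 0, 1.0])
        s = dipole_moment(traj, Selection("all", [0, 1]))
        assert s.magnitude[0] == pytest.approx(4.80320425)
        assert s.angle_to_z[0] == pytest.approx(0.0)

    def test_rotation_maps_angle(self):
        # the same dipole along +x is 90° from z
        s = dipole_moment(self.charge_pair([1.0, 0, 0]), Selection("all", [0, 1]))
        assert s.angle_to_z[0] == pytest.approx(90.0)

    def test_point_charges_coincident_zero(self):
        traj = self.charge_pair([0.0, 0, 0])
        s = dipole_moment(traj, Selection("all", [0, 1]))
        assert s.magnitude[0] == 0.0
        assert np.isnan(s.angle_to_z[0])

    def test_missing_charges_listed(self):
        atoms = [AtomMeta("X", "LIG", 1), AtomMeta("Y", "LIG", 1, partial_charge=1.0)]
        traj = make_trajectory(np.zeros((1, 2, 3)) + 5, (10.0, 10.0, 10.0), atoms=atoms)
        with pytest.raises(ValueError, match="without partial charges: \\[0\\]"):
            dipole_moment(traj, Selection("all", [0, 1]))


class TestMembranePotential:
    def sheet_system(self, q, flip=False):
        """10×10 point charges per sheet at z = 30 and 70 in a 100 Å box."""
        xs = np.linspace(2.5, 47.5, 10)
        pos, charges = [], []
        for zq, sgn in ((30.0, 1.0), (70.0, -1.0)):
            for x in xs:
                for y in xs:
                    pos.append([x, y, zq])
                    charges.append(sgn * q * (-1 if flip else 1))
        atoms = [
            AtomMeta("Q", "SHT", i + 1, partial_charge=c)
            for i, c in enumerate(charges)
        ]
        coords = np.array([pos])
        return make_trajectory(coords, (50.0, 50.0, 100.0), atoms=atoms)

    def test_zero_charges_zero_potential(self):
        traj = self.sheet_system(0.0)
        prof = membrane_potential(traj)
        assert np.allclose(prof.potential, 0.0)

    def test_two_sheet_plateau_matches_parallel_plate(self):
        from poreflux.synthetic import parallel_plate_delta_v

        q = 0.05
        traj = self.sheet_system(q)
        prof = membrane_potential(traj, slice_width=1.0)
        sigma = 100 * q / (50.0 * 50.0)
        expected = parallel_plate_delta_v(sigma, 40.0)
        measured = abs(prof.potential[-1] - prof.potential[0])
        assert measured == pytest.approx(expected, rel=0.01)

    def test_linearity_sign_flip(self):
        a = membrane_potential(self.sheet_system(0.05)).potential
        b = membrane_potential(self.sheet_system(0.05, flip=True)).potential
        assert np.allclose(a, -b)

    def test_potential_from_density_zero(self):
        phi = potential_from_density(np.linspace(0, 10, 11), np.zeros(10))
        assert np.allclose(phi, 0.0)


class TestBondVectorAngle:
    @pytest.mark.parametrize(
        "vec,angle", [((0, 0, 1.0), 0.0), ((1.0, 0, 0), 90.0), ((0, 0, -1.0), 180.0)]
    )
    def test_cardinal_directions(self, vec, angle):
        coords = np.zeros((1, 2, 3))
        coords[0, 0] = [25.0, 25.0, 25.0]
        coords[0, 1] = np.array([25.0, 25.0, 25.0]) + np.asarray(vec)
        traj = make_trajectory(coords, (50.0, 50.0, 50.0))
        assert bond_vector_angle(traj, 0, 1)[0] == pytest.approx(angle)

    def test_coincident_atoms_masked(self):
        coords = np.zeros((1, 2, 3)) + 25.0
        traj = make_trajectory(coords, (50.0, 50.0, 50.0))
        assert np.isnan(bond_vector_angle(traj, 0, 1)[0])

    def test_identical_atom_rejected(self):
        coords = np.zeros((1, 2, 3)) + 25.0
        traj = make_trajectory(coords, (50.0, 50.0, 50.0))
        with pytest.raises(ValueError, match="distinct"):
            bond_vector_angle(traj, 1, 1)
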