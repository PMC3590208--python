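"""Generalized Born solvation: closed-form limits, oracles, reranking."""

import numpy as np
import pytest

from fftdock.fftscore import Pose
from fftdock.gbrerank import (COULOMB, BornRadii, GBParams, SolvationModel,
                              born_radii, gcav_gvdw, gpol, rerank)
from fftdock.molio import Atom, Molecule, detect_surface_atoms
from fftdock.spatial import surface_quadrature


def _ion(charge=1.0, radius=2.0):
    mol = Molecule([Atom(serial=1, name="CA", residue_name="GLY",
                         residue_seq=1, chain_id="A", position=np.zeros(3),
                         radius=radius, charge=charge)])
    return detect_surface_atoms(mol)


def _cluster(rng, n=40, box=6.0):
    atoms = [Atom(serial=i + 1, name="CA", residue_name="ALA",
                  residue_seq=i + 1, chain_id="A",
                  position=rng.uniform(-box, box, 3), radius=1.7,
                  charge=float(rng.uniform(-0.5, 0.5)))
             for i in range(n)]
    return detect_surface_atoms(Molecule(atoms))


class TestBornRadii:
    def test_single_sphere_recovers_radius(self, params):
        mol = _ion(radius=2.0)
        quad = surface_quadrature(mol, density=6.0, params=params, probe=0.0)
        born = born_radii(mol.coords, mol.radii, quad)
        assert born.radii[0] == pytest.approx(2.0, rel=0.03)

    def test_buried_atom_larger_radius(self, params, rng):
        mol = _cluster(rng, n=60, box=5.0)
        quad = surface_quadrature(mol, density=2.0, params=params, probe=0.0)
        born = born_radii(mol.coords, mol.radii, quad)
        center = np.argmin(np.linalg.norm(mol.coords, axis=1))
        d = np.linalg.norm(mol.coords, axis=1)
        peripheral = np.argmax(d)
        assert born.radii[center] > born.radii[peripheral]

    def test_refinement_convergence(self, params):
        # compact lattice blob: smooth surface, so the Coulomb-field
        # integral converges cleanly under quadrature refinement
        ax = np.arange(-3.0, 3.1, 2.0)
        pts = np.array(np.meshgrid(ax, ax, ax)).reshape(3, -1).T
        atoms = [Atom(serial=i + 1, name="CA", residue_name="ALA",
                      residue_seq=i + 1, chain_id="A", position=p,
                      radius=1.8, charge=0.0) for i, p in enumerate(pts)]
        mol = detect_surface_atoms(Molecule(atoms))
        q1 = surface_quadrature(mol, density=4.0, params=params, probe=0.0)
        q2 = surface_quadrature(mol, density=8.0, params=params, probe=0.0)
        r1 = born_radii(mol.coords, mol.radii, q1).radii
        r2 = born_radii(mol.coords, mol.radii, q2).radii
        assert np.all(np.abs(r1 - r2) / r2 < 0.05)


class TestGpol:
    def test_single_ion_matches_born_formula(self):
        q, radius = 1.0, 2.0
        born = BornRadii(np.array([radius]))
        got = gpol(np.zeros((1, 3)), [q], born, eps_in=1.0, eps_out=80.0)
        want = -0.5 * (1 - 1 / 80.0) * COULOMB * q * q / radius
        assert got == pytest.approx(want, rel=1e-12)

    def test_zero_charges_zero_energy(self, rng):
        coords = rng.uniform(-5, 5, (20, 3))
        born = BornRadii(np.full(20, 2.0))
        assert gpol(coords, np.zeros(20), born) == 0.0

    @pytest.mark.parametrize("eps_tol", [1e-2, 1e-3])
    def test_approximation_within_tolerance(self, rng, eps_tol):
        n = 500
        coords = rng.uniform(-25, 25, (n, 3))
        charges = rng.uniform(-0.8, 0.8, n)
        born = BornRadii(rng.uniform(1.5, 4.0, n))
        exact = gpol(coords, charges, born, eps_tol=0.0)
        approx = gpol(coords, charges, born, eps_tol=eps_tol)
        assert abs(approx - exact) / abs(exact) <= eps_tol


class TestCavityAndDispersion:
    def test_unit_sphere_volume_and_area(self, params):
        r, probe = 1.7, 1.4
        mol = _ion(radius=r)
        quad = surface_quadrature(mol, density=6.0, params=params, probe=probe)
        gcav, _ = gcav_gvdw(["C"], quad, params, np.zeros((1, 3)))
        r_acc = r + probe
        vol = 4.0 / 3.0 * np.pi * r_acc ** 3
        area = 4.0 * np.pi * r_acc ** 2
        p = params.solvation["pressure"]
        gamma = params.solvation["gamma"]
        assert gcav == pytest.approx(p * vol + gamma * area, rel=0.02)

    def test_buried_atoms_no_dispersion(self, params):
        # 3x3x3 tight cluster: the center atom has zero SASA
        ax = np.arange(-2.0, 2.1, 2.0)
        pts = np.array(np.meshgrid(ax, ax, ax)).reshape(3, -1).T
        atoms = [Atom(serial=i + 1, name="CA", residue_name="ALA",
                      residue_seq=i + 1, chain_id="A", position=p,
                      radius=1.8, charge=0.0) for i, p in enumerate(pts)]
        mol = detect_surface_atoms(Molecule(atoms))
        quad = surface_quadrature(mol, density=3.0, params=params, probe=1.4)
        center = int(np.argmin(np.linalg.norm(pts, axis=1)))
        sasa = np.zeros(len(pts))
        np.add.at(sasa, quad.parents, quad.areas)
        assert sasa[center] == 0.0

    def test_cavity_grows_with_added_surface_atom(self, params, rng):
        mol = _cluster(rng, n=20, box=4.0)
        quad = surface_quadrature(mol, density=2.0, params=params)
        g1, _ = gcav_gvdw(["C"] * len(mol), quad, params, mol.coords)
        grown = Molecule(mol.atoms + [Atom(
            serial=99, name="CA", residue_name="ALA", residue_seq=99,
            chain_id="A", position=np.array([8.0, 0, 0]), radius=1.7,
            charge=0.0)])
        grown = detect_surface_atoms(grown)
        quad2 = surface_quadrature(grown, density=2.0, params=params)
        g2, _ = gcav_gvdw(["C"] * len(grown), quad2, params, grown.coords)
        assert g2 > g1


@pytest.fixture(scope="module")
def model(prepared_pair):
    rec, lig, _ = prepared_pair
    return SolvationModel(rec, lig, gb=GBParams(quad_density=1.0))


class TestDeltaGsol:
    def test_delta_vanishes_at_large_separation(self, model):
        far = Pose(rotation_index=0, translation=np.array([200.0, 0.0, 0.0]))
        energy = model.delta_gsol(far)
        assert abs(energy.delta) < 0.5

    def test_contact_pose_nonzero_delta(self, model):
        energy = model.delta_gsol(Pose(rotation_index=0,
                                       translation=np.zeros(3)))
        assert abs(energy.delta) > 0.5

    def test_frame_invariance(self, prepared_pair):
        rec, lig, _ = prepared_pair
        pose = Pose(rotation_index=0, translation=np.zeros(3))
        e1 = SolvationModel(rec, lig).delta_gsol(pose).delta
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        shift = np.array([7.0, -2.0, 3.0])
        rec_m = rec.transformed(rot, shift, center=np.zeros(3))
        lig_m = lig.transformed(rot, shift, center=np.zeros(3))
        e2 = SolvationModel(rec_m, lig_m).delta_gsol(pose).delta
        # surface sampling directions are fixed in the lab frame, so the
        # invariance holds to quadrature orientation noise, not exactly
        assert e2 == pytest.approx(e1, rel=0.05)

    def test_burying_opposite_charges_lowers_gpol_vs_sum(self, params):
        # +q and -q spheres in contact: complex Gpol above the sum of the
        # isolated-ion energies (screening is lost on burial), checked
        # against the exact pairwise expression
        a = _ion(charge=1.0, radius=2.0)
        b = _ion(charge=-1.0, radius=2.0)
        for atom in b.atoms:
            atom.position = np.array([4.2, 0.0, 0.0])
        b.invalidate()
        b = detect_surface_atoms(b)
        model = SolvationModel(a, b, gb=GBParams(quad_density=4.0))
        energy = model.delta_gsol(Pose(rotation_index=0,
                                       translation=np.zeros(3)))
        d = 4.2
        r1 = r2 = 2.0
        f = np.sqrt(d * d + r1 * r2 * np.exp(-d * d / (4 * r1 * r2)))
        pref = -0.5 * (1 - 1 / 80.0) * COULOMB
        want_cross = pref * 2 * (1.0 * -1.0) / f
        want_self = pref * (1.0 / r1 + 1.0 / r2)
        got = energy.gpol["AB"]
        assert got == pytest.approx(want_self + want_cross, rel=0.1)
        assert energy.gpol["AB"] - energy.gpol["A"] - energy.gpol["B"] > 0


class TestRerank:
    def _fake_poses(self):
        return [Pose(rotation_index=0, translation=np.array([200.0, 0, 0]),
                     total=10.0, rank=1),
                Pose(rotation_index=0, translation=np.zeros(3), total=9.0,
                     rank=2),
                Pose(rotation_index=0, translation=np.array([0, 300.0, 0]),
                     total=8.0, rank=3)]

    def test_top_n_zero_identity(self, prepared_pair):
        rec, lig, _ = prepared_pair
        model = SolvationModel(rec, lig)
        poses = self._fake_poses()
        out = rerank(poses, model, top_n=0)
        assert [p.rank for p in out] == [1, 2, 3]
        assert all("dGsol" not in p.scores for p in out)

    def test_complementary_pose_ranks_first(self, prepared_pair):
        """The pocket contact (buried complementary charges) beats the
        far-away pose once solvation change is the criterion."""
        rec, lig, _ = prepared_pair
        model = SolvationModel(rec, lig)
        out = rerank(self._fake_poses(), model, top_n=2)
        assert np.linalg.norm(out[0].translation) < 1.0
        assert out[0].scores["dGbind"] < out[1].scores["dGbind"]

    def test_rerank_is_permutation(self, prepared_pair):
        rec, lig, _ = prepared_pair
        model = SolvationModel(rec, lig)
        poses = self._fake_poses()
        out = rerank(poses, model, top_n=2)
        assert sorted(tuple(p.translation) for p in out) == \
            sorted(tuple(p.translation) for p in poses)
        # tail keeps its original relative order
        assert tuple(out[2].translation) == (0.0, 300.0, 0.0)
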