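"""FFT scoring: smearing, sparse/banded transforms, correlation oracle,
skin/core weighting, search contract."""

import numpy as np
import pytest
from scipy import fft as sp_fft

from fftdock.fftscore import (DockParams, GridSpec, ball_occupancy,
                              cross_correlate, curvature_factor,
                              forward_fft_sparse, inverse_fft_banded,
                              make_grid_spec, prepare_receptor, sc_weights,
                              score_rotation, search, smear_atoms,
                              wrap_indices)
from fftdock.molio import Atom, Molecule
from fftdock.rotsamp import Rotation, sample_rotations


def direct_correlation(f, g):
    """Brute-force C(t) = sum_x f(x) g(x - t) with circular indexing."""
    n = f.shape[0]
    out = np.zeros_like(f, dtype=complex)
    for tx in range(n):
        for ty in range(n):
            for tz in range(n):
                shifted = np.roll(g, (tx, ty, tz), axis=(0, 1, 2))
                out[tx, ty, tz] = np.sum(f * shifted)
    return out


def small_spec(n=8, h=1.0):
    return GridSpec(origin=np.zeros(3), spacing=h, dim=n)


class TestSmearAtoms:
    def test_maximum_at_nearest_node(self):
        spec = small_spec(12, 1.0)
        field = smear_atoms(np.array([[5.2, 5.0, 5.0]]), np.array([1.0]),
                            np.array([1.0]), spec)
        assert np.unravel_index(np.argmax(field), field.shape) == (5, 5, 5)

    def test_total_mass_matches_gaussian_integral(self, rng):
        spec = GridSpec(origin=np.full(3, -12.0), spacing=1.0, dim=24)
        pos = rng.uniform(-4, 4, (50, 3))
        w = rng.uniform(0.5, 2.0, 50)
        sig = rng.uniform(1.0, 1.6, 50)
        field = smear_atoms(pos, w, sig, spec)
        expect = np.sum(w * (2 * np.pi * sig ** 2) ** 1.5)
        assert field.sum() * spec.spacing ** 3 == pytest.approx(expect, rel=0.01)

    def test_linearity(self):
        spec = small_spec(10)
        p1 = np.array([[3.0, 3.0, 3.0]])
        p2 = np.array([[6.0, 6.0, 6.0]])
        both = smear_atoms(np.vstack([p1, p2]), np.ones(2), np.ones(2), spec)
        sep = smear_atoms(p1, [1.0], [1.0], spec) + \
            smear_atoms(p2, [1.0], [1.0], spec)
        np.testing.assert_allclose(both, sep, atol=1e-12)

    def test_atom_outside_grid_raises(self):
        spec = small_spec(8)
        with pytest.raises(ValueError, match="outside grid"):
            smear_atoms(np.array([[20.0, 0, 0]]), [1.0], [1.0], spec)


class TestSparseBandedFFT:
    def test_sparse_forward_equals_dense(self, rng):
        field = np.zeros((16, 16, 16), dtype=complex)
        # occupy half the planes only
        field[3:8] = rng.normal(size=(5, 16, 16)) \
            + 1j * rng.normal(size=(5, 16, 16))
        np.testing.assert_allclose(forward_fft_sparse(field),
                                   sp_fft.fftn(field), atol=1e-9)

    def test_banded_inverse_full_band_equals_dense(self, rng):
        spec = rng.normal(size=(8, 8, 8)) + 1j * rng.normal(size=(8, 8, 8))
        band = np.ones((8, 8, 8), dtype=bool)
        np.testing.assert_allclose(inverse_fft_banded(spec, band),
                                   sp_fft.ifftn(spec), atol=1e-12)

    def test_banded_inverse_restriction(self, rng):
        spec = rng.normal(size=(8, 8, 8)) + 0j
        band = rng.random((8, 8, 8)) > 0.6
        out = inverse_fft_banded(spec, band)
        dense = sp_fft.ifftn(spec)
        np.testing.assert_allclose(out[band], dense[band], atol=1e-12)
        assert np.all(out[~band] == 0)


class TestCorrelationOracle:
    @pytest.mark.parametrize("kind", ["complex", "real"])
    def test_fft_equals_direct(self, rng, kind):
        """Master oracle: FFT correlation == brute-force correlation."""
        n = 8
        if kind == "complex":
            f = rng.normal(size=(n,) * 3) + 1j * rng.random((n,) * 3)
            g = rng.normal(size=(n,) * 3) + 1j * rng.random((n,) * 3)
        else:
            f = rng.normal(size=(n,) * 3).astype(complex)
            g = rng.normal(size=(n,) * 3).astype(complex)
        got = cross_correlate(sp_fft.fftn(f), g)
        want = direct_correlation(f, g)
        np.testing.assert_allclose(got, want, atol=1e-8)


class TestScWeights:
    def test_flat_boundary_occupancy_half(self):
        # dense half-space z <= 0: a ball probe centered on the boundary
        # sees occupancy 1/2, so the curvature factor is exactly 1
        ax = np.arange(-8.0, 8.1, 1.0)
        # atom radius 1.0, topmost layer at z = -1, so the vdW surface of
        # the half-space is the z = 0 plane
        pts = np.array(np.meshgrid(ax, ax, np.arange(-7.0, -0.9, 1.0))
                       ).reshape(3, -1).T
        occ = ball_occupancy(pts, np.full(len(pts), 1.0),
                             np.array([0.0, 0.0, 0.0]), r_probe=3.0)
        assert occ == pytest.approx(0.5, abs=0.08)
        assert curvature_factor(0.5, kappa=1.0) == 1.0

    def test_traditional_mode_constant_weights(self, prepared_pair):
        rec, lig, _ = prepared_pair
        w_rec, w_lig = sc_weights(rec, lig, mode="traditional")
        pseudo = np.array([a.role == "pseudo_skin" for a in rec.atoms])
        assert np.allclose(w_rec[pseudo].real, w_rec[pseudo].real[0])
        core = ~pseudo
        assert np.allclose(w_rec[core].imag, w_rec[core].imag[0])

    def test_deepest_core_atom_hits_cap(self):
        # big solid lattice: center atom is deepest and reaches the cap
        ax = np.arange(-9, 9.1, 2.2)
        pts = np.array(np.meshgrid(ax, ax, ax)).reshape(3, -1).T
        atoms = [Atom(serial=i + 1, name="CA", residue_name="ALA",
                      residue_seq=i + 1, chain_id="A", position=p,
                      radius=1.6, charge=0.0) for i, p in enumerate(pts)]
        from fftdock.molio import detect_surface_atoms
        rec = detect_surface_atoms(Molecule(atoms))
        for a in rec.atoms:
            a.role = "core"
        lig = detect_surface_atoms(Molecule([Atom(
            serial=1, name="CA", residue_name="ALA", residue_seq=1,
            chain_id="L", position=np.array([50.0, 0, 0]), radius=1.6,
            charge=0.0)]))
        lig.atoms[0].role = "skin"
        p = DockParams()
        w_rec, _ = sc_weights(rec, lig, mode="improved", params=p)
        center = int(np.argmin(np.linalg.norm(pts, axis=1)))
        assert w_rec[center].imag == pytest.approx(p.w_core * p.depth_cap)


class TestScoreRotationAndSearch:
    def test_zero_ligand_charge_zero_el(self, prepared_pair):
        rec, lig, _ = prepared_pair
        lig0 = lig.copy()
        for a in lig0.atoms:
            a.charge = 0.0
        lig0.invalidate()
        pre = prepare_receptor(rec, lig0, DockParams(grid_dim=32))
        res = score_rotation(pre, Rotation(np.eye(3), 0))
        np.testing.assert_allclose(res["EL"], 0.0, atol=1e-12)

    def test_band_fraction_below_half(self, prepared_pair):
        rec, lig, _ = prepared_pair
        pre = prepare_receptor(rec, lig, DockParams(grid_dim=32))
        assert pre.band_t.mean() < 0.5

    def test_native_beats_offset_pose(self, prepared_pair):
        """Shape channel prefers the pocket over a 6 A offset."""
        rec, lig, _ = prepared_pair
        pre = prepare_receptor(rec, lig, DockParams(grid_dim=32))
        res = score_rotation(pre, Rotation(np.eye(3), 0))
        spec = pre.spec
        center_world = spec.origin + (spec.dim // 2) * spec.spacing
        base = center_world - pre.lig_center
        disp = base + wrap_indices(res["t"], spec.dim) * spec.spacing
        dmag = np.linalg.norm(disp, axis=1)
        pocket_sc = res["SC"][dmag <= 2.5].max()
        off_mask = np.abs(dmag - 6.0) < 1.0
        assert pocket_sc > res["SC"][off_mask].max()

    def test_search_sorted_and_complete(self, prepared_pair):
        rec, lig, _ = prepared_pair
        rots = sample_rotations(120.0)
        params = DockParams(grid_dim=32, k_retain=10 ** 9)
        poses = search(rec, lig, rots, params)
        totals = [p.total for p in poses]
        assert all(a >= b for a, b in zip(totals, totals[1:]))
        assert [p.rank for p in poses] == list(range(1, len(poses) + 1))
        # k larger than available scores -> everything returned
        pre = prepare_receptor(rec, lig, params)
        expected = len(rots) * int(pre.band_t.sum())
        assert len(poses) == expected

    def test_grid_spec_contains_both_spheres(self, prepared_pair):
        rec, lig, _ = prepared_pair
        spec = make_grid_spec(rec, lig, 1.2)
        from fftdock.fftscore import ligand_radius
        c = rec.geometric_center
        r_a = np.max(np.linalg.norm(rec.coords - c, axis=1) + rec.radii)
        assert spec.extent >= 2 * r_a + 2 * ligand_radius(lig)
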