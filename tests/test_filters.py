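"""Knowledge-based filters vs brute-force oracles; complex typing."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from fftdock.cdr import detect_complex_type, identify_cdrs, \
    surface_glycine_fraction
from fftdock.fftscore import Pose
from fftdock.filters import (ACTION_NONE, ACTION_PENALIZE, ACTION_REWARD,
                             FilterConfig, FilterContext, apply_filters,
                             area_filter, antibody_filter, clash_filter,
                             count_clashes, find_gly_motifs, glycine_filter,
                             interface_quadrature, ip_filter,
                             lennard_jones_energy, lj_filter,
                             rr_contact_filter)
from fftdock.molio import detect_surface_atoms
from fftdock.params import NONPOLAR_RESIDUES, POLAR_RESIDUES
from fftdock.synthkit import make_sequence_fixture, molecule_from_chains


@pytest.fixture(scope="module")
def ctx(prepared_pair, params):
    rec, lig, _ = prepared_pair
    return FilterContext(receptor=rec, ligand=lig, params=params,
                         config=FilterConfig(), complex_type="other")


NATIVE = Pose(rotation_index=0, translation=np.zeros(3))
FAR = Pose(rotation_index=0, translation=np.array([80.0, 0.0, 0.0]))


class TestIpFilter:
    def test_no_interface_penalized(self, ctx):
        verdict = ip_filter(ctx, FAR)
        assert verdict.raw_value == 0.0
        assert verdict.action == ACTION_PENALIZE

    def test_native_contact_not_penalized(self, ctx):
        assert ip_filter(ctx, NATIVE).action != ACTION_PENALIZE

    def test_value_matches_brute_force(self, ctx):
        """I from the octree/grid path equals an O(n^2) double loop."""
        cfg = ctx.config
        mask_a, qb, mask_b = interface_quadrature(ctx, NATIVE)
        qa = ctx.quad_rec
        d = cdist(qa.positions, qb.positions)
        brute_a = d.min(axis=1) < cfg.interface_cutoff
        brute_b = d.min(axis=0) < cfg.interface_cutoff
        np.testing.assert_array_equal(mask_a, brute_a)
        np.testing.assert_array_equal(mask_b, brute_b)
        contrib = np.concatenate([qa.areas[brute_a] * qa.labels[brute_a],
                                  qb.areas[brute_b] * qb.labels[brute_b]])
        want = contrib[contrib > 0].sum() + cfg.ip_beta * contrib[contrib < 0].sum()
        assert ip_filter(ctx, NATIVE).raw_value == pytest.approx(want)


class TestRrContactFilter:
    def test_separated_molecules_penalized(self, ctx):
        verdict = rr_contact_filter(ctx, FAR)
        assert verdict.action == ACTION_PENALIZE

    def test_all_preferred_contacts_never_penalized(self, prepared_pair,
                                                    params):
        rec, lig, _ = prepared_pair
        # TRP-TRP contacts have positive preference in the bundled matrix
        rec_t = rec.copy()
        lig_t = lig.copy()
        for a in rec_t.atoms + lig_t.atoms:
            a.residue_name = "TRP"
        c = FilterContext(receptor=rec_t, ligand=lig_t, params=params,
                          config=FilterConfig())
        assert rr_contact_filter(c, NATIVE).action != ACTION_PENALIZE

    def test_contact_list_matches_brute(self, ctx):
        from fftdock.filters import _cb_coords
        cb_a, _ = _cb_coords(ctx.receptor)
        cb_b, _ = _cb_coords(ctx.ligand)
        d = cdist(cb_a, cb_b)
        n_brute = int((d < ctx.config.contact_dist).sum())
        from fftdock.spatial import close_pairs
        assert len(close_pairs(cb_a, cb_b, ctx.config.contact_dist)) == n_brute


class TestLjFilter:
    def test_equilibrium_pair_energy(self, params):
        eps, rstar = params.lj_of("C")
        e = lennard_jones_energy(np.zeros((1, 3)), ["C"],
                                 np.array([[rstar, 0, 0]]), ["C"],
                                 params, softening=1.0)
        assert e == pytest.approx(-eps, rel=1e-9)

    def test_matches_brute_double_sum(self, params, rng):
        a = rng.uniform(0, 12, (150, 3))
        b = rng.uniform(6, 18, (150, 3))
        ea = ["C"] * 150
        eb = ["N"] * 150
        got = lennard_jones_energy(a, ea, b, eb, params, softening=0.7,
                                   cutoff=12.0)
        eps = np.sqrt(params.lj_of("C")[0] * params.lj_of("N")[0])
        rstar = 0.5 * (params.lj_of("C")[1] + params.lj_of("N")[1])
        d = cdist(a, b)
        mask = d < 12.0
        dm = np.maximum(d[mask], 1e-6)
        want = np.sum(0.7 * eps * rstar ** 12 / dm ** 12
                      - 2 * eps * rstar ** 6 / dm ** 6)
        assert got == pytest.approx(want, rel=1e-6)

    def test_interpenetrating_pose_penalized(self, ctx):
        # drive the plug deep into the receptor core
        buried = Pose(rotation_index=0, translation=np.array([0.0, 0.0, -7.0]))
        assert lj_filter(ctx, buried).action == ACTION_PENALIZE

    def test_native_not_penalized(self, ctx):
        assert lj_filter(ctx, NATIVE).action == ACTION_NONE


class TestClashFilter:
    def test_disjoint_no_clash(self, ctx):
        v = clash_filter(ctx, FAR)
        assert v.raw_value == 0 and v.action == ACTION_NONE

    def test_counts_match_brute(self, rng):
        a = rng.uniform(0, 10, (300, 3))
        b = rng.uniform(5, 15, (300, 3))
        ra = rng.uniform(1.4, 1.9, 300)
        rb = rng.uniform(1.4, 1.9, 300)
        factor = 0.7
        got = count_clashes(a, ra, b, rb, factor)
        d = cdist(a, b)
        want = int((d < factor * (ra[:, None] + rb[None, :])).sum())
        assert got == want

    def test_monotone_in_clash_factor(self, rng):
        a = rng.uniform(0, 8, (100, 3))
        b = rng.uniform(4, 12, (100, 3))
        ra = np.full(100, 1.7)
        counts = [count_clashes(a, ra, b, ra, f)
                  for f in (0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts)


class TestAreaFilter:
    def test_no_interface_penalized(self, ctx):
        v = area_filter(ctx, FAR)
        assert v.raw_value == 0.0 and v.action == ACTION_PENALIZE

    def test_area_matches_brute_selection(self, ctx):
        cfg = ctx.config
        mask_a, qb, mask_b = interface_quadrature(ctx, NATIVE)
        d = cdist(ctx.quad_rec.positions, qb.positions)
        want = ctx.quad_rec.areas[d.min(axis=1) < cfg.interface_cutoff].sum() \
            + qb.areas[d.min(axis=0) < cfg.interface_cutoff].sum()
        assert area_filter(ctx, NATIVE).raw_value == pytest.approx(want)

    def test_area_nonincreasing_with_separation(self, ctx):
        areas = [area_filter(ctx, Pose(rotation_index=0,
                                       translation=np.array([0.0, 0.0, z]))
                             ).raw_value
                 for z in (0.0, 2.0, 4.0, 8.0, 16.0)]
        assert all(a >= b - 1e-9 for a, b in zip(areas, areas[1:]))


class TestGlycineFilter:
    def test_gsa_matches_motif(self):
        assert find_gly_motifs("GSA") == [0]

    def test_no_glycine_no_motifs(self):
        assert find_gly_motifs("ASTVAL" * 10) == []

    def test_motif_count_matches_regex_scan(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        seq = "".join(rng.choice(aa, 200))
        want = []
        for i in range(198):
            a, b, c = seq[i], seq[i + 1], seq[i + 2]
            if (a == "G" and b in POLAR_RESIDUES and c in NONPOLAR_RESIDUES) \
                    or (a in NONPOLAR_RESIDUES and b in POLAR_RESIDUES
                        and c == "G"):
                want.append(i)
        assert find_gly_motifs(seq) == want

    def test_interface_motifs_rewarded(self, prepared_pair, params):
        rec, lig, _ = prepared_pair  # fixture motif includes SER/GLY/ALA runs
        c = FilterContext(receptor=rec, ligand=lig, params=params,
                          config=FilterConfig(), complex_type="enzyme")
        v = glycine_filter(c, NATIVE)
        assert v.action in (ACTION_REWARD, ACTION_PENALIZE)
        far = glycine_filter(c, FAR)
        assert far.action == ACTION_PENALIZE


class TestCdrAndComplexType:
    def test_antibody_fixture_yields_six_loops(self):
        chains = make_sequence_fixture("antibody_like", seed=7)
        cdr = identify_cdrs(chains)
        assert cdr is not None
        assert set(cdr.loops) == {"L1", "L2", "L3", "H1", "H2", "H3"}

    def test_random_sequence_no_cdrs(self):
        assert identify_cdrs(make_sequence_fixture("random", seed=7)) is None

    def test_heavy_only_camelid_style_not_recognized(self):
        chains = make_sequence_fixture("antibody_like", seed=7)
        assert identify_cdrs({"H": chains["H"]}) is None

    def test_enzyme_rule_thresholds(self):
        enz = detect_surface_atoms(molecule_from_chains(
            make_sequence_fixture("enzyme_like", seed=7)))
        other = detect_surface_atoms(molecule_from_chains(
            make_sequence_fixture("random", seed=7)))
        assert surface_glycine_fraction(enz) >= 0.08
        assert len(enz.residues()) >= 200
        assert detect_complex_type(enz, other) == "enzyme"

    def test_short_chain_fails_length_test(self):
        # 150 residues with plenty of glycine is still 'other'
        seq = {"X": ("G" + "AST"[0:2]) * 50}
        mol = detect_surface_atoms(molecule_from_chains(seq))
        assert detect_complex_type(mol, mol) == "other"

    def test_antibody_precedence_over_enzyme(self):
        ab = detect_surface_atoms(molecule_from_chains(
            make_sequence_fixture("antibody_like", seed=7)))
        enz = detect_surface_atoms(molecule_from_chains(
            make_sequence_fixture("enzyme_like", seed=7)))
        assert detect_complex_type(ab, enz) == "antibody"


@pytest.fixture(scope="module")
def ab_ctx(params):
    chains = make_sequence_fixture("antibody_like", seed=7)
    ab = detect_surface_atoms(molecule_from_chains(chains, seed=1))
    ag = detect_surface_atoms(molecule_from_chains({"G": "ASTV" * 10},
                                                   seed=2))
    return FilterContext(receptor=ab, ligand=ag, params=params,
                         config=FilterConfig(), complex_type="antibody")


class TestAntibodyFilter:
    def test_cdr_found(self, ab_ctx):
        assert ab_ctx.cdr is not None

    def test_no_contact_pose_penalized(self, ab_ctx):
        v = antibody_filter(ab_ctx, Pose(rotation_index=0,
                                         translation=np.array([500.0, 0, 0])))
        assert v.action == ACTION_PENALIZE

    def test_counts_match_brute(self, ab_ctx):
        cfg = ab_ctx.config
        pose = Pose(rotation_index=0, translation=np.zeros(3))
        v = antibody_filter(ab_ctx, pose)
        # brute force the minimum regional count
        ab = ab_ctx.receptor
        ag_coords = ab_ctx.posed_ligand_coords(pose)[ab_ctx.ligand.real_mask]
        residues = ab.residues()
        chain_res = {}
        for ridx, (rkey, _) in enumerate(residues):
            chain_res.setdefault(rkey[0], []).append(ridx)
        counts = []
        for loops in (("L1", "H1"), ("L3",), ("H3",)):
            atom_idx = []
            for chain, posn in ab_ctx.cdr.residues_of(*loops):
                ridxs = chain_res.get(chain, [])
                if posn < len(ridxs):
                    atom_idx.extend(residues[ridxs[posn]][1])
            if not atom_idx:
                counts.append(0)
                continue
            d = cdist(ab.coords[atom_idx], ag_coords)
            counts.append(int((d.min(axis=0) < cfg.contact_neighborhood).sum()))
        assert v.raw_value == pytest.approx(min(counts))


class TestApplyFilters:
    def _poses(self):
        return [Pose(rotation_index=0, translation=np.zeros(3), total=10.0,
                     rank=1),
                Pose(rotation_index=0, translation=np.array([80.0, 0, 0]),
                     total=5.0, rank=2)]

    def test_all_disabled_identity(self, ctx):
        out = apply_filters(self._poses(), ctx, enabled=())
        assert [p.total for p in out] == [10.0, 5.0]

    def test_penalized_pose_never_rises(self, ctx):
        poses = [Pose(rotation_index=0, translation=np.zeros(3), total=10.0,
                      rank=1),
                 Pose(rotation_index=0, translation=np.array([80.0, 0, 0]),
                      total=10.0, rank=2)]
        out = apply_filters(poses, ctx)
        # the far pose collects penalties and cannot outrank the contact pose
        far = next(p for p in out if p.translation[0] > 50)
        near = next(p for p in out if p.translation[0] < 50)
        assert near.rank < far.rank

    def test_only_top_window_touched(self, ctx, rng):
        cfg = FilterConfig(n_filter=2)
        small_ctx = FilterContext(receptor=ctx.receptor, ligand=ctx.ligand,
                                  params=ctx.params, config=cfg,
                                  quad_rec=ctx.quad_rec, quad_lig=ctx.quad_lig)
        poses = [Pose(rotation_index=0,
                      translation=np.array([100.0 + 10 * i, 0, 0]),
                      total=10.0 - i, rank=i + 1) for i in range(6)]
        out = apply_filters(poses, small_ctx)
        # tail poses keep their relative order and totals
        tail = out[2:]
        assert [p.total for p in tail] == [8.0, 7.0, 6.0, 5.0]

    def test_deterministic_and_idempotent_shape(self, ctx):
        out1 = apply_filters(self._poses(), ctx)
        out2 = apply_filters(self._poses(), ctx)
        assert [(p.rank, p.total) for p in out1] == \
            [(p.rank, p.total) for p in out2]
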