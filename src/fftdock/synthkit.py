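"""Deterministic toy receptor/ligand fixtures with known native poses.

``make_pocket_plug`` builds a spherical receptor with a hemispherical
cavity and a complementary plug ligand already sitting in the cavity (so
the native pose is the identity), with planted opposite charges across
the interface and residue names drawn from a configurable motif.  These
are not physically realistic decoys - they are geometry with just enough
chemistry attached to exercise every scoring channel and filter.

``make_sequence_fixture`` emits chain sequences that, by construction,
trigger (antibody-like), satisfy (enzyme-like) or miss (random) the
complex-type detection rules.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fftscore import Pose
from .molio import Atom, Molecule, write_pqr
from .params import ONE_TO_THREE

#: residue motif cycled over fixture atoms so propensity/contact/glycine
#: machinery sees a spread of residue types
DEFAULT_MOTIF = ("TRP", "SER", "GLY", "ALA", "ASP", "LEU", "THR", "ARG")

_FILLER = "ASTVEQDNHLRY"  # no C/W/G/F/K: cannot fake CDR anchors


def _lattice(radius: float, spacing: float) -> np.ndarray:
    n = int(np.ceil(radius / spacing))
    ax = spacing * np.arange(-n, n + 1)
    pts = np.array(np.meshgrid(ax, ax, ax)).reshape(3, -1).T
    return pts[np.linalg.norm(pts, axis=1) <= radius]


def _mk_atoms(points: np.ndarray, charges: np.ndarray, radii: np.ndarray,
              chain: str, motif, serial0: int = 1) -> list[Atom]:
    atoms = []
    for k, (p, q, r) in enumerate(zip(points, charges, radii)):
        atoms.append(Atom(
            serial=serial0 + k, name="CA",
            residue_name=motif[k % len(motif)], residue_seq=k + 1,
            chain_id=chain, position=p, radius=float(r), charge=float(q)))
    return atoms


def make_pocket_plug(seed: int = 7, n_atoms: int = 120,
                     pocket_depth: float = 4.5,
                     charge_motif: tuple[str, ...] = DEFAULT_MOTIF,
                     charge: float = 0.4, gap: float = 1.0,
                     ) -> tuple[Molecule, Molecule, Pose]:
    """Pocket-and-plug fixture: receptor, ligand (in native placement) and
    the native pose (identity rotation, zero translation).

    The plug (a small lattice ball half-buried in the receptor sphere) is
    built first; the receptor cavity is then carved as the inflated plug,
    so the two van der Waals surfaces are complementary with a controlled
    native gap of ``gap`` Angstrom.  ``n_atoms`` sets the approximate
    receptor atom budget (it fixes the receptor radius at the lattice
    density); ``pocket_depth`` controls how deep the plug center sits
    below the receptor surface.
    """
    rng = np.random.default_rng(seed)
    spacing = 2.5
    r_rec = (3.0 * n_atoms * spacing ** 3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    plug_center = np.array([0.0, 0.0, r_rec + 3.0 - pocket_depth])
    # asymmetric plug: an ellipsoid with an off-axis bump, so only the
    # native orientation fits the complementary cavity (a spherical plug
    # would score equally under every rotation)
    ax = 2.0 * np.arange(-3, 4)
    cand = np.array(np.meshgrid(ax, ax, ax)).reshape(3, -1).T
    semi = np.array([4.2, 2.6, 2.6])
    ell = cand[np.sum((cand / semi) ** 2, axis=1) <= 1.0]
    bump = cand[np.linalg.norm(cand - np.array([2.0, 2.0, 1.6]), axis=1) <= 1.8]
    plug_pts = np.unique(np.vstack([ell, bump]), axis=0) + plug_center
    lig_radii = rng.uniform(1.5, 1.9, len(plug_pts))

    pts = _lattice(r_rec, spacing)
    rec_radii_all = rng.uniform(1.5, 1.9, len(pts))
    # carve: drop receptor atoms whose sphere comes within `gap` of any
    # plug-atom sphere
    d = np.linalg.norm(pts[:, None, :] - plug_pts[None, :, :], axis=2)
    clearance = rec_radii_all[:, None] + lig_radii[None, :] + gap
    keep = np.all(d >= clearance, axis=1)
    rec_pts = pts[keep]
    rec_radii = rec_radii_all[keep]

    rec_q = rng.uniform(-0.1, 0.1, len(rec_pts))
    lig_q = rng.uniform(-0.1, 0.1, len(plug_pts))
    # planted charge pairs across the interface: cavity lining positive,
    # buried plug half negative
    lining = np.min(np.linalg.norm(
        rec_pts[:, None, :] - plug_pts[None, :, :], axis=2), axis=1) < 6.0
    rec_q[lining] = charge
    tip = plug_pts[:, 2] < plug_center[2] + 0.5
    lig_q[tip] = -charge
    # neutralize each molecule (proteins carry little net charge; monopole
    # terms would otherwise dominate every electrostatic limit)
    rec_q -= rec_q.mean()
    lig_q -= lig_q.mean()

    receptor = Molecule(_mk_atoms(rec_pts, rec_q, rec_radii, "R", charge_motif),
                        label="receptor")
    ligand = Molecule(_mk_atoms(plug_pts, lig_q, lig_radii, "L", charge_motif),
                      label="ligand")
    native = Pose(rotation_index=0, translation=np.zeros(3))
    return receptor, ligand, native


def write_fixture(receptor: Molecule, ligand: Molecule, native: Pose,
                  outdir: str | Path) -> dict[str, Path]:
    """Persist a fixture as PQR files plus a JSON native-pose sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"receptor": outdir / "receptor.pqr",
             "ligand": outdir / "ligand.pqr",
             "native": outdir / "native_pose.json"}
    write_pqr(receptor, paths["receptor"])
    write_pqr(ligand, paths["ligand"])
    with open(paths["native"], "w") as fh:
        json.dump({"rotation_index": native.rotation_index,
                   "rotation": np.eye(3).ravel().tolist(),
                   "translation": native.translation.tolist()}, fh, indent=1)
    return paths


# ---------------------------------------------------------------------------
# Sequence fixtures for complex-type detection
# ---------------------------------------------------------------------------

def _fill(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_FILLER), size=max(n, 0)))


def _light_chain(rng: np.random.Generator) -> str:
    seq = _fill(rng, 17) + "C"              # L1 anchor Cys
    seq += _fill(rng, 12) + "W"             # L1 (12) ends before Trp
    seq += _fill(rng, 15)                   # framework to L2
    seq += _fill(rng, 7)                    # L2
    seq += _fill(rng, 25) + "C" + _fill(rng, 1)   # L3 anchor Cys + 1
    seq += _fill(rng, 9) + "FGAG"           # L3 (9) + FGxG
    seq += _fill(rng, 8)
    return seq


def _heavy_chain(rng: np.random.Generator) -> str:
    seq = _fill(rng, 20) + "C"              # H1 anchor Cys
    seq += _fill(rng, 3)                    # H1 starts Cys+4
    seq += _fill(rng, 10) + "W"             # H1 (10) ends before Trp
    seq += _fill(rng, 14)                   # framework to H2
    seq += _fill(rng, 17) + "KLT"           # H2 (17) + K/R framework triplet
    seq += _fill(rng, 24) + "C" + _fill(rng, 2)   # H3 anchor Cys + 2
    seq += _fill(rng, 8) + "WGQG"           # H3 (8) + WGxG
    seq += _fill(rng, 10)
    return seq


def make_sequence_fixture(kind: str, seed: int = 7) -> dict[str, str]:
    """Chain sequences for complex-type detection fixtures.

    * ``antibody_like``: light + heavy chains embedding all six CDR anchors.
    * ``enzyme_like``: a single >= 200-residue chain with >= 8% glycine.
    * ``random``: 150 uniform residues (no anchors, too short for enzyme).
    """
    rng = np.random.default_rng(seed)
    if kind == "antibody_like":
        return {"L": _light_chain(rng), "H": _heavy_chain(rng)}
    if kind == "enzyme_like":
        seq = []
        for i in range(210):
            seq.append("G" if i % 8 == 0 else rng.choice(list(_FILLER)))
        return {"E": "".join(seq)}
    if kind == "random":
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        return {"X": "".join(rng.choice(aa, size=150))}
    raise ValueError(f"unknown fixture kind {kind!r}")


def molecule_from_chains(chains: dict[str, str], seed: int = 0) -> Molecule:
    """CA-trace toy molecule realizing the given chain sequences.

    Residues are laid out on a jittered helix, so essentially every
    residue is solvent-exposed; enough structure for the surface-fraction
    and contact rules, not a protein fold.
    """
    rng = np.random.default_rng(seed)
    atoms = []
    serial = 1
    offset = np.zeros(3)
    for chain_id, seq in chains.items():
        for i, one in enumerate(seq):
            theta = 2.0 * np.pi * i / 3.6
            pos = offset + np.array([
                8.0 * np.cos(theta), 8.0 * np.sin(theta), 1.5 * i]) \
                + rng.normal(0.0, 0.25, 3)
            atoms.append(Atom(
                serial=serial, name="CA",
                residue_name=ONE_TO_THREE.get(one, "GLY"),
                residue_seq=i + 1, chain_id=chain_id, position=pos,
                radius=1.7, charge=0.0))
            serial += 1
        offset = offset + np.array([40.0, 0.0, 0.0])
    return Molecule(atoms, label="seqfixture")
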