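"""Solvation-energy rescoring of docking poses (GBSA model).

The solvation free energy of a solute is modeled as

    Gsol = Gcav + Gvdw + Gpol

with a pressure-volume plus surface-tension cavity term, a per-atom
SASA-weighted solute-solvent dispersion term, and a Generalized Born
polarization term

    Gpol = -1/2 (1/eps_in - 1/eps_out) sum_ij q_i q_j / f_GB(r_ij, R_i, R_j)

using the Still interpolation f_GB = sqrt(r^2 + Ri Rj exp(-r^2/(4 Ri Rj))).
Effective Born radii come from the Coulomb-field surface-integral
approximation evaluated on the molecular-surface quadrature.  Poses are
rescored by the solvation change on binding,
dGsol = Gsol(AB) - Gsol(A) - Gsol(B), combined with the direct
intra-complex Coulomb interaction; complementary buried interfaces
(desolvating apolar surface, pairing opposite charges) give the most
negative binding term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fftscore import Pose
from .molio import Molecule, ROLE_PSEUDO
from .params import ParamTable, load_params
from .spatial import QuadratureSet, surface_quadrature

COULOMB = 332.06  # kcal A / (mol e^2)


@dataclass
class GBParams:
    eps_in: float = 1.0
    eps_out: float = 80.0
    eps_tol: float = 1e-3        # relative accuracy of the Gpol approximation
    quad_density: float = 1.0    # Born-radius quadrature, points / A^2
    sasa_probe: float = 1.4      # probe for the SASA/volume quadrature, A
    born_probe: float = 0.0      # Born radii integrate the vdW surface


@dataclass
class BornRadii:
    radii: np.ndarray  # per real atom, A


@dataclass
class EnergyBreakdown:
    """Per-component solvation energies (kcal/mol) for A, B and AB.

    ``delta`` is the solvation change on binding, dGsol.  ``binding``
    adds the direct intra-complex Coulomb interaction (in eps_in), the
    standard GBSA electrostatic treatment: pure dGsol alone rewards
    burying like charges and penalizes salt bridges, because Born
    self-energies scale with the square of the local net charge.
    """

    gpol: dict[str, float] = field(default_factory=dict)
    gcav: dict[str, float] = field(default_factory=dict)
    gvdw: dict[str, float] = field(default_factory=dict)
    coulomb_ab: float = 0.0  # direct A-B Coulomb interaction, kcal/mol

    def gsol(self, key: str) -> float:
        return self.gpol[key] + self.gcav[key] + self.gvdw[key]

    @property
    def delta(self) -> float:
        return self.gsol("AB") - self.gsol("A") - self.gsol("B")

    @property
    def binding(self) -> float:
        return self.delta + self.coulomb_ab


def born_radii(coords: np.ndarray, radii: np.ndarray,
               quad: QuadratureSet) -> BornRadii:
    """Effective Born radii via the Coulomb-field surface integral.

    1/R_i = (1/4pi) sum_k a_k ((x_k - c_i) . n_k) / |x_k - c_i|^4,
    floored at the intrinsic atomic radius.  Quadrature points coincident
    with an atom center are skipped.
    """
    coords = np.asarray(coords).reshape(-1, 3)
    n = len(coords)
    inv = np.zeros(n)
    for i in range(n):
        d = quad.positions - coords[i]
        r2 = np.sum(d * d, axis=1)
        ok = r2 > 1e-12
        dots = np.sum(d[ok] * quad.normals[ok], axis=1)
        inv[i] = np.sum(quad.areas[ok] * dots / r2[ok] ** 2) / (4.0 * np.pi)
    with np.errstate(divide="ignore"):
        r_eff = np.where(inv > 0, 1.0 / np.maximum(inv, 1e-12), 1e3)
    # floor at the intrinsic radius, cap to keep degenerate integrals finite
    return BornRadii(np.minimum(np.maximum(r_eff, np.asarray(radii)), 1e3))


def gpol(coords: np.ndarray, charges: np.ndarray, born: BornRadii,
         eps_in: float = 1.0, eps_out: float = 80.0,
         eps_tol: float = 0.0) -> float:
    """Generalized Born polarization energy (kcal/mol), self-terms included.

    With ``eps_tol > 0`` pairs beyond an analytically chosen distance use
    the Coulomb limit f_GB -> r, keeping the relative error of the total
    within the tolerance; ``eps_tol = 0`` evaluates the exact double sum.
    """
    coords = np.asarray(coords).reshape(-1, 3)
    q = np.asarray(charges, dtype=float)
    r_eff = born.radii
    pref = -0.5 * (1.0 / eps_in - 1.0 / eps_out) * COULOMB
    n = len(q)
    if n == 0 or not np.any(q):
        return 0.0
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    rr = r_eff[:, None] * r_eff[None, :]
    if eps_tol > 0:
        # f_GB -> r beyond r_far: rel. error of 1/f vs 1/r is bounded by
        # RiRj/(2 r^2), kept <= eps_tol/10 at r_far
        rmax = float(np.max(r_eff[np.isfinite(r_eff)], initial=1.0))
        r_far = max(rmax * np.sqrt(max(5.0 / eps_tol, 1.0)), 2.0 * rmax)
        far = d > r_far
        f = np.where(far, np.maximum(d, 1e-12),
                     np.sqrt(d * d + rr * np.exp(-np.minimum(
                         d * d / (4.0 * rr), 50.0))))
    else:
        f = np.sqrt(d * d + rr * np.exp(-np.minimum(d * d / (4.0 * rr), 50.0)))
    return float(pref * np.sum(q[:, None] * q[None, :] / f))


def gcav_gvdw(mol_elements: list[str], quad: QuadratureSet,
              params: ParamTable, atom_coords: np.ndarray
              ) -> tuple[float, float]:
    """Cavity and solute-solvent dispersion terms from the SAS quadrature.

    Gcav = p*V + gamma*SASA.  The volume uses the spherical-sector form of
    the divergence theorem, V = (1/3) sum_k a_k (x_k - c_parent) . n_k:
    anchoring each patch to its own atom center keeps the estimate exactly
    translation/rotation invariant and exactly additive for separated
    molecules (the naive sum a_k x_k . n_k amplifies quadrature
    non-closure by the distance to the origin).  Gvdw = sum_i sigma_i
    SASA_i with per-element solvation parameters; buried atoms (zero
    SASA) contribute nothing.
    """
    solv = params.solvation
    p = solv.get("pressure", 0.008)
    gamma = solv.get("gamma", 0.0072)
    atom_coords = np.asarray(atom_coords).reshape(-1, 3)
    rel = quad.positions - atom_coords[quad.parents]
    volume = float(np.sum(quad.areas * np.sum(rel * quad.normals, axis=1))
                   / 3.0)
    sasa_total = quad.total_area
    gcav = p * volume + gamma * sasa_total
    sasa_per_atom = np.zeros(len(atom_coords))
    np.add.at(sasa_per_atom, quad.parents, quad.areas)
    sigma = np.array([solv.get(e, 0.0) for e in mol_elements])
    gvdw = float(np.sum(sigma * sasa_per_atom))
    return gcav, gvdw


@dataclass
class _Component:
    coords: np.ndarray
    radii: np.ndarray
    charges: np.ndarray
    elements: list[str]
    gpol: float
    gcav: float
    gvdw: float


def _component_energy(mol: Molecule, params: ParamTable,
                      gb: GBParams) -> _Component:
    real = mol.real_mask
    coords = mol.coords[real]
    radii = mol.radii[real]
    charges = mol.charges[real]
    elements = [a.element for a, m in zip(mol.atoms, real) if m]
    sub = _submol(mol)
    quad_sas = surface_quadrature(sub, gb.quad_density, params,
                                  probe=gb.sasa_probe)
    quad_vdw = surface_quadrature(sub, gb.quad_density, params,
                                  probe=gb.born_probe)
    born = born_radii(coords, radii, quad_vdw)
    g_cav, g_vdw = gcav_gvdw(elements, quad_sas, params, coords)
    return _Component(
        coords=coords, radii=radii, charges=charges, elements=elements,
        gpol=gpol(coords, charges, born, gb.eps_in, gb.eps_out, gb.eps_tol),
        gcav=g_cav, gvdw=g_vdw)


def _submol(mol: Molecule) -> Molecule:
    """Molecule restricted to real atoms (pseudo skin stripped)."""
    real_atoms = [a for a in mol.atoms if a.role != ROLE_PSEUDO]
    m = Molecule([a for a in real_atoms], label=mol.label)
    return m.copy()


class SolvationModel:
    """Precomputes component energies and scores posed complexes."""

    def __init__(self, receptor: Molecule, ligand: Molecule,
                 params: ParamTable | None = None,
                 gb: GBParams | None = None):
        self.params = params or load_params()
        self.gb = gb or GBParams()
        self.receptor = _submol(receptor)
        self.ligand = _submol(ligand)
        self._a = _component_energy(self.receptor, self.params, self.gb)
        self._b = _component_energy(self.ligand, self.params, self.gb)
        self._lig_center = self.ligand.geometric_center

    def delta_gsol(self, pose: Pose,
                   rotation: np.ndarray | None = None) -> EnergyBreakdown:
        """Fresh quadrature and Born radii on the posed union AB."""
        rot = np.eye(3) if rotation is None else np.asarray(rotation)
        posed = self.ligand.transformed(rot, pose.translation,
                                        center=self._lig_center)
        combined = Molecule(self.receptor.copy().atoms + posed.atoms,
                            label="complex")
        coords = combined.coords
        radii = combined.radii
        charges = combined.charges
        elements = [a.element for a in combined.atoms]
        quad_sas = surface_quadrature(combined, self.gb.quad_density,
                                      self.params, probe=self.gb.sasa_probe)
        quad_vdw = surface_quadrature(combined, self.gb.quad_density,
                                      self.params, probe=self.gb.born_probe)
        born = born_radii(coords, radii, quad_vdw)
        g_pol = gpol(coords, charges, born, self.gb.eps_in, self.gb.eps_out,
                     self.gb.eps_tol)
        g_cav, g_vdw = gcav_gvdw(elements, quad_sas, self.params, coords)
        n_a = len(self.receptor)
        d_ab = np.linalg.norm(coords[:n_a, None, :] - coords[None, n_a:, :],
                              axis=2)
        coul = float(COULOMB / self.gb.eps_in
                     * np.sum(charges[:n_a, None] * charges[None, n_a:]
                              / np.maximum(d_ab, 0.5)))
        return EnergyBreakdown(
            gpol={"A": self._a.gpol, "B": self._b.gpol, "AB": g_pol},
            gcav={"A": self._a.gcav, "B": self._b.gcav, "AB": g_cav},
            gvdw={"A": self._a.gvdw, "B": self._b.gvdw, "AB": g_vdw},
            coulomb_ab=coul)


def rerank(poses: list[Pose], model: SolvationModel, top_n: int,
           rotations=None, task_runner=None) -> list[Pose]:
    """Re-sort the top ``top_n`` poses by solvation-aware binding energy
    (dGsol plus the screened intra-complex Coulomb term), ascending.

    The remainder keeps its original relative order after the reranked
    block; every pose keeps its original scores, with the solvation
    change recorded under the ``dGsol`` score key and the ranking
    criterion under ``dGbind``.
    """
    if top_n <= 0:
        return [p.copy() for p in poses]
    rotmap = {r.index: r.matrix for r in rotations} if rotations else {}
    head = [p.copy() for p in poses[:top_n]]
    tail = [p.copy() for p in poses[top_n:]]

    def eval_pose(pose: Pose) -> Pose:
        energy = model.delta_gsol(pose, rotmap.get(pose.rotation_index))
        pose.scores["dGsol"] = energy.delta
        pose.scores["dGbind"] = energy.binding
        pose.scores["Gpol_AB"] = energy.gpol["AB"]
        pose.scores["Gcav_AB"] = energy.gcav["AB"]
        pose.scores["Gvdw_AB"] = energy.gvdw["AB"]
        return pose

    runner = task_runner or (lambda fn, items: [fn(x) for x in items])
    head = runner(eval_pose, head)
    order = sorted(range(len(head)),
                   key=lambda i: (head[i].scores["dGbind"], i))
    head = [head[i] for i in order]
    out = head + tail
    for rank, p in enumerate(out, start=1):
        p.rank = rank
    return out
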