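"""Knowledge-based soft filters applied to the top-ranked docking poses.

Each filter inspects the interface of a pose and issues a verdict:
reward, leave alone, or penalize.  Penalties are soft - a fraction of the
score magnitude - so a pose failing one test can still survive if every
other signal is strong.  Geometric quantities (contacts, clashes, areas,
interface points) are computed with the packing-grid / octree machinery
from :mod:`fftdock.spatial`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cdr import CdrRegions, identify_cdrs
from .fftscore import Pose
from .molio import Molecule
from .params import (NONPOLAR_RESIDUES, POLAR_RESIDUES, ParamTable,
                     THREE_TO_ONE)
from .spatial import QuadratureSet, close_pairs, surface_quadrature

ACTION_REWARD = "reward"
ACTION_NONE = "none"
ACTION_PENALIZE = "penalize"


@dataclass
class FilterVerdict:
    name: str
    raw_value: float
    action: str
    amount: float  # fraction of |score| to add (reward) or subtract

    def __post_init__(self):
        if self.action == ACTION_NONE:
            self.amount = 0.0


@dataclass
class FilterConfig:
    """Thresholds and penalty fractions for all seven filters.

    The trained thresholds of the original protocol are unpublished;
    these defaults are documented placeholders, all overridable.
    """

    penalty_fraction: float = 0.3    # score reduction per triggered filter
    reward_fraction: float = 0.1

    interface_cutoff: float = 3.0    # quad-point interface distance, A
    ip_beta: float = 1.0             # weight of the negative propensity sums
    ip_t_lo: float = 5.0             # penalize poses with I below this
    ip_t_hi: float = 150.0           # reward poses with I above this

    contact_dist: float = 6.0        # C-beta contact distance, A
    ratio_lo: float = 0.5            # allowed S+/|S-| range
    ratio_hi: float = 1e9
    ratio_eps: float = 1e-6

    lj_softening: float = 0.5        # repulsive-term scaling (unbound inputs)
    lj_cutoff: float = 12.0

    clash_factor: float = 0.6        # clash if d < factor * (r_i + r_j)
    clash_max: int = 5

    area_lo: float = 100.0           # allowed interface area range, A^2
    area_hi: float = 5000.0

    gly_threshold: int = 1           # min G-X-Y / Y-X-G motifs at interface
    gly_weight: float = 0.02         # reward fraction per motif
    contact_neighborhood: float = 5.0   # atom contact distance for motifs/CDRs

    cdr_min_contacts: tuple[int, int, int] = (1, 1, 1)  # L1/H1, L3, H3
    cdr_max_contacts: int = 10**9

    n_filter: int = 2000             # poses the filter stage touches
    quad_density: float = 1.0        # quadrature points per A^2


@dataclass
class FilterContext:
    """Prepared inputs shared by all filters for one receptor/ligand pair."""

    receptor: Molecule
    ligand: Molecule
    params: ParamTable
    config: FilterConfig
    complex_type: str = "other"
    quad_rec: QuadratureSet | None = None
    quad_lig: QuadratureSet | None = None
    cdr: CdrRegions | None = None
    _cache: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.quad_rec is None:
            self.quad_rec = surface_quadrature(
                self.receptor, self.config.quad_density, self.params)
        if self.quad_lig is None:
            self.quad_lig = surface_quadrature(
                self.ligand, self.config.quad_density, self.params)
        if self.cdr is None and self.complex_type == "antibody":
            self.cdr = identify_cdrs(self.receptor.chains) or \
                identify_cdrs(self.ligand.chains)

    def posed_ligand_coords(self, pose: Pose) -> np.ndarray:
        c = self.ligand.geometric_center
        # rotation matrices are stored per pose by the pipeline; fall back
        # to identity when a pose carries no rotation matrix
        rot = self._cache.get("rotations", {}).get(pose.rotation_index)
        coords = self.ligand.coords
        if rot is not None:
            coords = (coords - c) @ rot.T + c
        return coords + pose.translation

    def set_rotations(self, rotations) -> None:
        self._cache["rotations"] = {r.index: r.matrix for r in rotations}


# ---------------------------------------------------------------------------
# Interface extraction helpers
# ---------------------------------------------------------------------------

def _interface_quad_masks(pos_a: np.ndarray, pos_b: np.ndarray,
                          cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Masks of A points near B points and vice versa (one pair pass)."""
    mask_a = np.zeros(len(pos_a), dtype=bool)
    mask_b = np.zeros(len(pos_b), dtype=bool)
    if len(pos_a) and len(pos_b):
        pairs = close_pairs(pos_a, pos_b, cutoff)
        if len(pairs):
            mask_a[np.unique(pairs[:, 0])] = True
            mask_b[np.unique(pairs[:, 1])] = True
    return mask_a, mask_b


def interface_quadrature(ctx: FilterContext, pose: Pose
                         ) -> tuple[np.ndarray, QuadratureSet, np.ndarray]:
    """Interface masks for both molecules' quadrature sets at a pose.

    Cached per pose so the propensity and area filters share the work.
    """
    key = ("iface", pose.rotation_index, pose.translation.tobytes())
    if key in ctx._cache:
        return ctx._cache[key]
    rot = ctx._cache.get("rotations", {}).get(pose.rotation_index)
    c = ctx.ligand.geometric_center
    qb = ctx.quad_lig.transformed(
        rot if rot is not None else np.eye(3), c, pose.translation)
    mask_a, mask_b = _interface_quad_masks(ctx.quad_rec.positions,
                                           qb.positions,
                                           ctx.config.interface_cutoff)
    ctx._cache[key] = (mask_a, qb, mask_b)
    if len(ctx._cache) > 4096:  # bounded: drop oldest pose entries
        for k in list(ctx._cache)[:1024]:
            if isinstance(k, tuple) and k and k[0] == "iface":
                ctx._cache.pop(k, None)
    return ctx._cache[key]


# ---------------------------------------------------------------------------
# The seven filters
# ---------------------------------------------------------------------------

def ip_filter(ctx: FilterContext, pose: Pose) -> FilterVerdict:
    """Interface-propensity filter.

    I = (P_A + P_B) + beta * (N_A + N_B) where P/N sum the positive and
    negative area-weighted propensity contributions a_k * l_k of the
    interface quadrature points of each molecule.
    """
    cfg = ctx.config
    mask_a, qb, mask_b = interface_quadrature(ctx, pose)
    contrib_a = ctx.quad_rec.areas[mask_a] * ctx.quad_rec.labels[mask_a]
    contrib_b = qb.areas[mask_b] * qb.labels[mask_b]
    pos_sum = contrib_a[contrib_a > 0].sum() + contrib_b[contrib_b > 0].sum()
    neg_sum = contrib_a[contrib_a < 0].sum() + contrib_b[contrib_b < 0].sum()
    value = float(pos_sum + cfg.ip_beta * neg_sum)
    if value < cfg.ip_t_lo:
        return FilterVerdict("ip", value, ACTION_PENALIZE, cfg.penalty_fraction)
    if value > cfg.ip_t_hi:
        return FilterVerdict("ip", value, ACTION_REWARD, cfg.reward_fraction)
    return FilterVerdict("ip", value, ACTION_NONE, 0.0)


def _cb_coords(mol: Molecule) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Contact-atom coordinate per residue: C-beta, C-alpha for glycine or
    single-atom residues, else an ideal tetrahedral C-beta from N/CA/C."""
    coords, resnames = [], []
    for key, idx in mol.residues():
        by_name = {mol.atoms[i].name.upper(): i for i in idx}
        resname = mol.atoms[idx[0]].residue_name.upper()
        if "CB" in by_name:
            c = mol.atoms[by_name["CB"]].position
        elif {"N", "CA", "C"} <= by_name.keys() and resname != "GLY":
            n = mol.atoms[by_name["N"]].position
            ca = mol.atoms[by_name["CA"]].position
            cc = mol.atoms[by_name["C"]].position
            # ideal tetrahedral reconstruction
            b1 = ca - n
            b2 = ca - cc
            bis = b1 / np.linalg.norm(b1) + b2 / np.linalg.norm(b2)
            bis /= np.linalg.norm(bis)
            perp = np.cross(b1, b2)
            perp /= max(np.linalg.norm(perp), 1e-9)
            d = bis * np.cos(0.95) + perp * np.sin(0.95)
            c = ca + 1.53 * d
        elif "CA" in by_name:
            c = mol.atoms[by_name["CA"]].position
        else:
            c = mol.atoms[idx[0]].position
        coords.append(c)
        resnames.append((key[0], resname))
    return np.array(coords).reshape(-1, 3), resnames


def rr_contact_filter(ctx: FilterContext, pose: Pose) -> FilterVerdict:
    """Residue-residue contact-preference filter.

    Residues are in contact if their C-beta atoms (C-alpha for Gly) are
    closer than the contact distance; the pose is penalized when the
    ratio of preferred (S+) to avoided (S-) contact weight falls outside
    the configured range, or when there are no contacts at all.
    """
    cfg = ctx.config
    cb_a, res_a = _cb_coords(ctx.receptor)
    key = "cb_lig"
    if key not in ctx._cache:
        ctx._cache[key] = _cb_coords(ctx.ligand)
    cb_b0, res_b = ctx._cache[key]
    rot = ctx._cache.get("rotations", {}).get(pose.rotation_index)
    c = ctx.ligand.geometric_center
    cb_b = ((cb_b0 - c) @ rot.T + c if rot is not None else cb_b0) \
        + pose.translation
    pairs = close_pairs(cb_a, cb_b, cfg.contact_dist)
    if not len(pairs):
        return FilterVerdict("rr_contact", 0.0, ACTION_PENALIZE,
                             cfg.penalty_fraction)
    s_pos = s_neg = 0.0
    for i, j in pairs:
        e = ctx.params.contact_pref_of(res_a[i][1], res_b[j][1])
        if e > 0:
            s_pos += e
        else:
            s_neg += e
    if s_neg == 0.0:
        ratio = np.inf  # all-preferred contacts count as in range
        in_range = True
    else:
        ratio = s_pos / max(abs(s_neg), cfg.ratio_eps)
        in_range = cfg.ratio_lo <= ratio <= cfg.ratio_hi
    if in_range:
        return FilterVerdict("rr_contact", float(min(ratio, 1e12)), ACTION_NONE, 0.0)
    return FilterVerdict("rr_contact", float(min(ratio, 1e12)),
                         ACTION_PENALIZE, cfg.penalty_fraction)


def lennard_jones_energy(coords_a, elements_a, coords_b, elements_b,
                         params: ParamTable, softening: float = 1.0,
                         cutoff: float = 12.0) -> float:
    """Softened 12-6 energy between two atom sets (kcal/mol).

    Lorentz-Berthelot combination of per-class well depths and contact
    distances; the repulsive A_ij term is scaled by ``softening`` to allow
    soft clashes in unbound docking.
    """
    pairs = close_pairs(np.asarray(coords_a), np.asarray(coords_b), cutoff)
    if not len(pairs):
        return 0.0
    eps_a = np.array([params.lj_of(e)[0] for e in elements_a])
    rs_a = np.array([params.lj_of(e)[1] for e in elements_a])
    eps_b = np.array([params.lj_of(e)[0] for e in elements_b])
    rs_b = np.array([params.lj_of(e)[1] for e in elements_b])
    i, j = pairs[:, 0], pairs[:, 1]
    eps = np.sqrt(eps_a[i] * eps_b[j])
    rstar = 0.5 * (rs_a[i] + rs_b[j])  # r* of the mixed pair
    d = np.linalg.norm(np.asarray(coords_a)[i] - np.asarray(coords_b)[j], axis=1)
    d = np.maximum(d, 1e-6)
    a_ij = eps * rstar ** 12 * softening
    b_ij = 2.0 * eps * rstar ** 6
    return float(np.sum(a_ij / d ** 12 - b_ij / d ** 6))


def lj_filter(ctx: FilterContext, pose: Pose) -> FilterVerdict:
    """Penalize poses with positive (repulsive) Lennard-Jones energy."""
    cfg = ctx.config
    coords_b = ctx.posed_ligand_coords(pose)
    real_a = ctx.receptor.real_mask
    real_b = ctx.ligand.real_mask
    e = lennard_jones_energy(
        ctx.receptor.coords[real_a],
        [a.element for a, m in zip(ctx.receptor.atoms, real_a) if m],
        coords_b[real_b],
        [a.element for a, m in zip(ctx.ligand.atoms, real_b) if m],
        ctx.params, softening=cfg.lj_softening, cutoff=cfg.lj_cutoff)
    if e > 0:
        return FilterVerdict("lj", e, ACTION_PENALIZE, cfg.penalty_fraction)
    return FilterVerdict("lj", e, ACTION_NONE, 0.0)


def count_clashes(coords_a, radii_a, coords_b, radii_b,
                  clash_factor: float) -> int:
    """Atom pairs with center distance < clash_factor * (r_i + r_j)."""
    rmax = float(np.max(radii_a) + np.max(radii_b)) * clash_factor
    pairs = close_pairs(np.asarray(coords_a), np.asarray(coords_b), rmax)
    if not len(pairs):
        return 0
    i, j = pairs[:, 0], pairs[:, 1]
    d = np.linalg.norm(np.asarray(coords_a)[i] - np.asarray(coords_b)[j], axis=1)
    return int(np.sum(d < clash_factor * (np.asarray(radii_a)[i]
                                          + np.asarray(radii_b)[j])))


def clash_filter(ctx: FilterContext, pose: Pose) -> FilterVerdict:
    """Penalize poses with more steric clashes than the allowance."""
    cfg = ctx.config
    real_a = ctx.receptor.real_mask
    real_b = ctx.ligand.real_mask
    n = count_clashes(ctx.receptor.coords[real_a], ctx.receptor.radii[real_a],
                      ctx.posed_ligand_coords(pose)[real_b],
                      ctx.ligand.radii[real_b], cfg.clash_factor)
    if n > cfg.clash_max:
        return FilterVerdict("clash", n, ACTION_PENALIZE, cfg.penalty_fraction)
    return FilterVerdict("clash", n, ACTION_NONE, 0.0)


def area_filter(ctx: FilterContext, pose: Pose) -> FilterVerdict:
    """Penalize interfaces whose buried quadrature area is out of range."""
    cfg = ctx.config
    mask_a, qb, mask_b = interface_quadrature(ctx, pose)
    area = float(ctx.quad_rec.areas[mask_a].sum() + qb.areas[mask_b].sum())
    if cfg.area_lo <= area <= cfg.area_hi:
        return FilterVerdict("area", area, ACTION_NONE, 0.0)
    return FilterVerdict("area", area, ACTION_PENALIZE, cfg.penalty_fraction)


def find_gly_motifs(sequence: str) -> list[int]:
    """Start indices of G-X-Y / Y-X-G tripeptides (X polar, Y non-polar)."""
    hits = []
    for i in range(len(sequence) - 2):
        a, b, c = sequence[i:i + 3]
        if a == "G" and b in POLAR_RESIDUES and c in NONPOLAR_RESIDUES:
            hits.append(i)
        elif a in NONPOLAR_RESIDUES and b in POLAR_RESIDUES and c == "G":
            hits.append(i)
    return hits


def glycine_filter(ctx: FilterContext, pose: Pose,
                   enzyme: Molecule | None = None) -> FilterVerdict:
    """Enzyme active-site glycine filter.

    Surface G-X-Y / Y-X-G tripeptides of the enzyme are marked; the pose
    is rewarded in proportion to how many of them sit at the interface
    and penalized when fewer than the threshold do.
    """
    cfg = ctx.config
    enzyme = enzyme or ctx.receptor
    other_is_ligand = enzyme is ctx.receptor
    # enumerate surface motif residues once
    key = f"gly_motifs_{id(enzyme)}"
    if key not in ctx._cache:
        motifs = []
        residues = enzyme.residues()
        surf = enzyme.surface_mask
        by_chain: dict[str, list[int]] = {}
        for ridx, (rkey, aidx) in enumerate(residues):
            by_chain.setdefault(rkey[0], []).append(ridx)
        for chain, ridxs in by_chain.items():
            seq = "".join(THREE_TO_ONE.get(
                enzyme.atoms[residues[r][1][0]].residue_name.upper(), "X")
                for r in ridxs)
            for start in find_gly_motifs(seq):
                tri = [ridxs[start], ridxs[start + 1], ridxs[start + 2]]
                if any(surf[i] for r in tri for i in residues[r][1]):
                    motifs.append([i for r in tri for i in residues[r][1]])
        ctx._cache[key] = motifs
    motifs = ctx._cache[key]
    if not motifs:
        return FilterVerdict("glycine", 0.0, ACTION_PENALIZE,
                             cfg.penalty_fraction)
    if other_is_ligand:
        other_coords = ctx.posed_ligand_coords(pose)[ctx.ligand.real_mask]
    else:
        other_coords = ctx.receptor.coords[ctx.receptor.real_mask]
    motif_atoms = sorted({i for atom_idx in motifs for i in atom_idx})
    pairs = close_pairs(enzyme.coords[motif_atoms], other_coords,
                        cfg.contact_neighborhood)
    touched = {motif_atoms[i] for i in np.unique(pairs[:, 0])} if len(pairs) else set()
    count = sum(1 for atom_idx in motifs if any(i in touched for i in atom_idx))
    if count < cfg.gly_threshold:
        return FilterVerdict("glycine", count, ACTION_PENALIZE,
                             cfg.penalty_fraction)
    return FilterVerdict("glycine", count, ACTION_REWARD,
                         cfg.gly_weight * count)


def antibody_filter(ctx: FilterContext, pose: Pose) -> FilterVerdict:
    """Antibody-antigen contact filter.

    Counts antigen atoms in the close neighborhood of CDR-L1/H1, CDR-L3
    and CDR-H3; each of the three regions must show a contact count
    within its configured native range (default: at least one each).
    """
    cfg = ctx.config
    if ctx.cdr is None:
        return FilterVerdict("antibody", 0.0, ACTION_NONE, 0.0)
    antibody_is_receptor = identify_cdrs(ctx.receptor.chains) is not None
    antibody = ctx.receptor if antibody_is_receptor else ctx.ligand
    if antibody_is_receptor:
        antigen_coords = ctx.posed_ligand_coords(pose)[ctx.ligand.real_mask]
        ab_coords = antibody.coords
    else:
        antigen_coords = ctx.receptor.coords[ctx.receptor.real_mask]
        ab_coords = ctx.posed_ligand_coords(pose)

    residues = antibody.residues()
    chain_res: dict[str, list[int]] = {}
    for ridx, (rkey, _) in enumerate(residues):
        chain_res.setdefault(rkey[0], []).append(ridx)

    def region_atoms(*loop_names: str) -> np.ndarray:
        idx = []
        for chain, pos in ctx.cdr.residues_of(*loop_names):
            ridxs = chain_res.get(chain, [])
            if pos < len(ridxs):
                idx.extend(residues[ridxs[pos]][1])
        return np.array(idx, dtype=int)

    counts = []
    for loops in (("L1", "H1"), ("L3",), ("H3",)):
        atoms = region_atoms(*loops)
        if not len(atoms):
            counts.append(0)
            continue
        pairs = close_pairs(ab_coords[atoms], antigen_coords,
                            cfg.contact_neighborhood)
        counts.append(len(np.unique(pairs[:, 1])) if len(pairs) else 0)
    lo = cfg.cdr_min_contacts
    ok = all(lo[k] <= counts[k] <= cfg.cdr_max_contacts for k in range(3))
    value = float(min(counts))
    if ok:
        return FilterVerdict("antibody", value, ACTION_NONE, 0.0)
    return FilterVerdict("antibody", value, ACTION_PENALIZE,
                         cfg.penalty_fraction)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

ALWAYS_ON = ("ip", "rr_contact", "lj", "clash", "area")


def apply_filters(poses: list[Pose], ctx: FilterContext,
                  enabled: tuple[str, ...] | None = None,
                  task_runner=None) -> list[Pose]:
    """Run the active filters on the top ``n_filter`` poses and re-sort.

    Glycine and antibody filters join in only for their complex types.
    Verdicts are recorded in each pose's penalty list; rewards add and
    penalties subtract the verdict fraction of the score magnitude.
    The poses below the filter window keep their relative order.
    """
    cfg = ctx.config
    if enabled is None:
        enabled = ALWAYS_ON
        if ctx.complex_type == "enzyme":
            enabled = enabled + ("glycine",)
        elif ctx.complex_type == "antibody" and ctx.cdr is not None:
            enabled = enabled + ("antibody",)
    fns = {"ip": ip_filter, "rr_contact": rr_contact_filter, "lj": lj_filter,
           "clash": clash_filter, "area": area_filter,
           "glycine": glycine_filter, "antibody": antibody_filter}
    head = [p.copy() for p in poses[:cfg.n_filter]]
    tail = [p.copy() for p in poses[cfg.n_filter:]]

    def eval_pose(pose: Pose) -> Pose:
        for name in enabled:
            verdict = fns[name](ctx, pose)
            if verdict.action == ACTION_PENALIZE:
                amount = verdict.amount * abs(pose.total)
                pose.total -= amount
                pose.penalties.append((name, amount))
            elif verdict.action == ACTION_REWARD:
                amount = verdict.amount * abs(pose.total)
                pose.total += amount
                pose.penalties.append((name, -amount))
        return pose

    runner = task_runner or (lambda fn, items: [fn(x) for x in items])
    head = runner(eval_pose, head)
    head.sort(key=lambda p: (-p.total, p.rotation_index, tuple(p.translation)))
    out = head + tail
    for rank, p in enumerate(out, start=1):
        p.rank = rank
    return out
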