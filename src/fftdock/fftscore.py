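"""FFT-accelerated exhaustive translational scoring of docking poses.

For every sampled rotation of the ligand, three affinity channels are
evaluated over the whole translational grid with one forward and one
inverse FFT per channel:

* **SC** - double-skin shape complementarity.  Skin atoms carry positive
  real weights and core atoms positive imaginary weights, so the real part
  of the complex correlation is (skin-skin - core-core) overlap and the
  imaginary part counts skin-core clashes, which enter the score with a
  small negative weight.
* **EL** - Gaussian-smeared charges of the ligand correlated against the
  receptor's electric potential computed with a distance-dependent
  dielectric (eps = 4r, clamped below 1 A).
* **IP** - interface propensity: the receptor's skin-band indicator
  correlated with a per-atom propensity field on the ligand skin; poses
  whose skin-overlap volume is below a threshold get a fixed
  small-interface penalty instead.

Input-plane sparsity (2D transforms of all-zero planes are skipped) and
output band masking (only translations that can produce molecular contact
are scored) keep the transforms cheap without changing any value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as sp_fft

from ._sphere import ball_points
from .molio import ROLE_PSEUDO, ROLE_SKIN, Molecule
from .params import load_params
from .rotsamp import Rotation
from .spatial import PackingGrid

_GAUSS_TRUNC = np.sqrt(2.0 * np.log(1e4))  # radius/sigma where the factor hits 1e-4


@dataclass(frozen=True)
class GridSpec:
    """Cubic FFT grid: world = origin + index * spacing, 0-based indices."""

    origin: np.ndarray
    spacing: float
    dim: int

    def __post_init__(self):
        object.__setattr__(self, "origin",
                           np.asarray(self.origin, dtype=float).reshape(3))

    @property
    def extent(self) -> float:
        return self.dim * self.spacing

    def world(self, index: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(index) * self.spacing

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ax = self.origin[:, None] + self.spacing * np.arange(self.dim)[None, :]
        return ax[0], ax[1], ax[2]


@dataclass
class ChannelGrid:
    """A complex scalar field on the FFT grid for one affinity channel."""

    spec: GridSpec
    values: np.ndarray
    channel: str  # SC | EL | IP


@dataclass
class Pose:
    """A (rotation, translation) placement of the ligand with its scores.

    ``translation`` is the displacement of the ligand geometric center
    from its input position, in Angstrom.
    """

    rotation_index: int
    translation: np.ndarray
    scores: dict[str, float] = field(default_factory=dict)
    penalties: list[tuple[str, float]] = field(default_factory=list)
    total: float = 0.0
    rank: int = 0

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def copy(self) -> "Pose":
        return replace(self, translation=self.translation.copy(),
                       scores=dict(self.scores), penalties=list(self.penalties))


@dataclass
class DockParams:
    """Scoring parameters; per-complex-type presets in :data:`TYPE_PRESETS`."""

    spacing: float = 1.2          # grid spacing h, A
    w_skin: float = 1.0           # real skin weight
    w_core: float = 9.0           # imaginary core weight
    lambda_sc: float = 1.0        # skin-core clash weight (x w_skin); per
                                  # overlapping pair this stays well below
                                  # the core-core weight w_core^2
    kappa: float = 1.0            # curvature weighting strength
    r_curv: float = 3.0           # curvature probe ball radius, A
    depth_slope: float = 0.5      # core depth weighting slope, 1/A
    depth_cap: float = 2.5        # core depth factor cap
    sigma_radius_factor: float = 0.5  # skin/core smear sigma = factor * radius
    clamp_dist: float = 1.0       # dielectric clamp distance, A
    ip_overlap_min: float = 1.0   # small-interface threshold (smeared
                                  # skin-overlap integral, grid units)
    ip_penalty: float = -1.0      # IP channel value for tiny interfaces
    w_sc: float = 1.0
    w_el: float = 0.3
    w_ip: float = 0.3
    k_retain: int = 0             # 0 -> max(4 * n_rot, 20000)
    n_filter: int = 2000          # poses passed to the filter stage
    skin_mode: str = "improved"
    grid_dim: int = 0             # 0 -> auto-size; else fixed N (must fit)


TYPE_PRESETS: dict[str, dict[str, float]] = {
    # channel weights per complex type (antibody A/AB, enzyme E, other O);
    # documented calibration defaults, overridable in config
    "A": {"w_sc": 1.0, "w_el": 0.3, "w_ip": 0.4},
    "E": {"w_sc": 1.0, "w_el": 0.4, "w_ip": 0.2},
    "O": {"w_sc": 1.0, "w_el": 0.3, "w_ip": 0.3},
}


def params_for_type(complex_type: str, base: DockParams | None = None) -> DockParams:
    p = base or DockParams()
    preset = TYPE_PRESETS.get(complex_type.upper(), TYPE_PRESETS["O"])
    return replace(p, **preset)


# ---------------------------------------------------------------------------
# Grid construction and smearing
# ---------------------------------------------------------------------------

def ligand_radius(ligand: Molecule) -> float:
    """Largest distance from the ligand geometric center to an atom."""
    c = ligand.geometric_center
    real = ligand.real_mask
    return float(np.max(np.linalg.norm(ligand.coords[real] - c, axis=1)
                        + ligand.radii[real]))


def make_grid_spec(receptor: Molecule, ligand: Molecule, spacing: float,
                   margin: float = 1.0) -> GridSpec:
    """Grid large enough to hold the receptor sphere and the ligand sphere
    side by side (so no contacting translation is lost to wraparound)."""
    c_a = receptor.geometric_center
    r_a = float(np.max(np.linalg.norm(receptor.coords - c_a, axis=1)
                       + receptor.radii))
    r_b = ligand_radius(ligand)
    need = 2.0 * (r_a + r_b) + 2.0 * margin
    dim = int(np.ceil(need / spacing))
    dim += dim % 2  # even size
    origin = c_a - 0.5 * dim * spacing
    return GridSpec(origin=origin, spacing=spacing, dim=dim)


def smear_atoms(positions: np.ndarray, weights: np.ndarray,
                sigmas: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Sum of Gaussians w_i * exp(-||x - c_i||^2 / (2 sigma_i^2)) on the grid.

    Truncated where the Gaussian factor drops below 1e-4.  Raises if an
    atom center lies outside the grid.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    weights = np.asarray(weights)
    sigmas = np.asarray(sigmas, dtype=float)
    if np.any(sigmas <= 0):
        raise ValueError("sigmas must be positive")
    out = np.zeros((spec.dim,) * 3,
                   dtype=complex if np.iscomplexobj(weights) else float)
    h = spec.spacing
    n = spec.dim
    rel = (positions - spec.origin) / h
    if np.any(rel < 0) or np.any(rel >= n):
        raise ValueError("atom outside grid bounds; enlarge the grid")
    for (cx, cy, cz), w, sig in zip(rel, weights, sigmas):
        cut = _GAUSS_TRUNC * sig / h
        lo = np.maximum(np.ceil([cx - cut, cy - cut, cz - cut]), 0).astype(int)
        hi = np.minimum(np.floor([cx + cut, cy + cut, cz + cut]),
                        n - 1).astype(int)
        if np.any(lo > hi):
            continue
        ax = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
        d2 = ((ax[0] - cx)[:, None, None] ** 2
              + (ax[1] - cy)[None, :, None] ** 2
              + (ax[2] - cz)[None, None, :] ** 2) * h * h
        g = np.exp(-d2 / (2.0 * sig * sig))
        g[g < 1e-4] = 0.0
        out[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += w * g
    return out


# ---------------------------------------------------------------------------
# Skin/core weighting
# ---------------------------------------------------------------------------

def ball_occupancy(coords: np.ndarray, radii: np.ndarray, center: np.ndarray,
                   r_probe: float, n_shells: int = 5, per_shell: int = 24,
                   grid: PackingGrid | None = None) -> float:
    """Fraction of a probe ball at ``center`` lying inside the molecule.

    0.5 on a flat boundary, < 0.5 outside convex bumps, > 0.5 in concave
    pockets.  Pass a prebuilt ``grid`` over ``coords`` to amortize the
    index across many probes.
    """
    pts = center + r_probe * ball_points(n_shells, per_shell)
    rmax = float(radii.max())
    if grid is None:
        grid = PackingGrid(coords, cell_size=max(rmax, 1.0) * 2)
    inside = 0
    for p in pts:
        near = grid.neighbors_within(p, rmax + 1e-9)
        if len(near) and np.any(np.linalg.norm(coords[near] - p, axis=1)
                                < radii[near]):
            inside += 1
    return inside / len(pts)


def curvature_factor(occ: float, kappa: float) -> float:
    """Skin weight multiplier 1 + kappa * (0.5 - occ): rewards skin atoms
    over convex regions of the receptor (pockets on the *ligand* side)."""
    return 1.0 + kappa * (0.5 - occ)


def _depths(mol: Molecule) -> np.ndarray:
    """Approximate burial depth of each real atom: distance to the nearest
    surface-atom center (0 for surface atoms)."""
    coords = mol.coords
    surf = mol.surface_mask & mol.real_mask
    if not surf.any():
        return np.zeros(len(mol))
    surf_pts = coords[surf]
    grid = PackingGrid(surf_pts, cell_size=5.0)
    depths = np.zeros(len(mol))
    for i in np.nonzero(mol.real_mask)[0]:
        if surf[i]:
            continue
        d = 5.0
        near = grid.neighbors_within(coords[i], d)
        while not len(near) and d < 1e3:
            d *= 2.0
            near = grid.neighbors_within(coords[i], d)
        if len(near):
            depths[i] = float(np.min(np.linalg.norm(surf_pts[near] - coords[i],
                                                    axis=1)))
    return depths


def sc_weights(receptor: Molecule, ligand: Molecule, mode: str = "improved",
               params: DockParams | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom complex shape-complementarity weights for both molecules.

    Real part: skin weight (curvature-modulated on the receptor in
    improved mode); imaginary part: core weight (depth-modulated in
    improved mode).
    """
    params = params or DockParams()
    w_rec = np.zeros(len(receptor), dtype=complex)
    real = receptor.real_mask
    rc, rr = receptor.coords[real], receptor.radii[real]
    rec_depth = _depths(receptor)
    occ_grid = PackingGrid(rc, cell_size=max(float(rr.max()), 1.0) * 2)
    for i, a in enumerate(receptor.atoms):
        if a.role == ROLE_PSEUDO:
            if mode == "improved":
                occ = ball_occupancy(rc, rr, a.position, params.r_curv,
                                     grid=occ_grid)
                w_rec[i] = params.w_skin * curvature_factor(occ, params.kappa)
            else:
                w_rec[i] = params.w_skin
        else:
            fac = (min(1.0 + params.depth_slope * rec_depth[i], params.depth_cap)
                   if mode == "improved" else 1.0)
            w_rec[i] = 1j * params.w_core * fac

    w_lig = np.zeros(len(ligand), dtype=complex)
    lig_depth = _depths(ligand)
    for i, a in enumerate(ligand.atoms):
        if a.role == ROLE_SKIN:
            w_lig[i] = params.w_skin
        else:
            fac = (min(1.0 + params.depth_slope * lig_depth[i], params.depth_cap)
                   if mode == "improved" else 1.0)
            w_lig[i] = 1j * params.w_core * fac
    return w_rec, w_lig


# ---------------------------------------------------------------------------
# Sparse/banded FFTs and correlation
# ---------------------------------------------------------------------------

def forward_fft_sparse(fieldarr: np.ndarray) -> np.ndarray:
    """3D forward FFT skipping 2D transforms of all-zero planes.

    Numerically identical to the dense transform (the plane skip only
    applies where a plane's max |value| is exactly 0).
    """
    n = fieldarr.shape[0]
    out = np.zeros(fieldarr.shape, dtype=complex)
    nonzero = [i for i in range(n) if np.any(fieldarr[i])]
    for i in nonzero:
        out[i] = sp_fft.fft2(fieldarr[i])
    return sp_fft.fft(out, axis=0)


def inverse_fft_banded(spectrum: np.ndarray, band: np.ndarray | None = None
                       ) -> np.ndarray:
    """3D inverse FFT evaluated only on planes that intersect the band.

    With ``band=None`` (or an all-true band) this equals the dense inverse
    transform; outside the band the result is zeroed.
    """
    tmp = sp_fft.ifft(spectrum, axis=0)
    out = np.zeros(spectrum.shape, dtype=complex)
    if band is None:
        for i in range(spectrum.shape[0]):
            out[i] = sp_fft.ifft2(tmp[i])
        return out
    for i in range(spectrum.shape[0]):
        if band[i].any():
            plane = sp_fft.ifft2(tmp[i])
            out[i][band[i]] = plane[band[i]]
    return out


def cross_correlate(spectrum_a: np.ndarray, fieldarr_b: np.ndarray,
                    band: np.ndarray | None = None) -> np.ndarray:
    """C(t) = sum_x f_A(x) * g_B(x - t) for all grid translations t.

    ``spectrum_a`` is the precomputed forward FFT of f_A; one forward and
    one inverse transform are spent per call.
    """
    g_neg_spec = np.conj(forward_fft_sparse(np.conj(fieldarr_b)))
    return inverse_fft_banded(spectrum_a * g_neg_spec, band)


def compute_band(receptor: Molecule, spec: GridSpec, r_b: float,
                 margin: float = 1.0) -> np.ndarray:
    """Translational band: nodes where a ligand-center sphere of radius
    ``r_b`` can touch the receptor.  Computed by convolving the receptor
    occupancy with a ball kernel via a single FFT pair."""
    occ = np.zeros((spec.dim,) * 3)
    h = spec.spacing
    n = spec.dim
    rel = (receptor.coords - spec.origin) / h
    for (cx, cy, cz), rad in zip(rel, receptor.radii + margin):
        cut = rad / h
        lo = np.maximum(np.ceil([cx - cut, cy - cut, cz - cut]), 0).astype(int)
        hi = np.minimum(np.floor([cx + cut, cy + cut, cz + cut]), n - 1).astype(int)
        if np.any(lo > hi):
            continue
        ax = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
        d2 = ((ax[0] - cx)[:, None, None] ** 2
              + (ax[1] - cy)[None, :, None] ** 2
              + (ax[2] - cz)[None, None, :] ** 2) * h * h
        occ[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += (d2 < rad * rad)
    # ball kernel with minimum-image (circular) distances
    idx = np.arange(n)
    half = ((idx + n // 2) % n) - n // 2
    d2 = (half[:, None, None] ** 2 + half[None, :, None] ** 2
          + half[None, None, :] ** 2) * h * h
    kernel = (d2 <= r_b * r_b).astype(float)
    conv = sp_fft.ifftn(sp_fft.fftn(occ) * sp_fft.fftn(kernel)).real
    return conv > 0.5


# ---------------------------------------------------------------------------
# Per-rotation scoring and global search
# ---------------------------------------------------------------------------

@dataclass
class ReceptorSpectra:
    """Everything precomputed about the stationary receptor."""

    spec: GridSpec
    sc: np.ndarray        # forward FFT of the complex skin/core field
    el: np.ndarray        # forward FFT of the potential grid
    ip: np.ndarray        # forward FFT of the skin-band indicator field
    band_t: np.ndarray    # translation-index band mask
    band_world: np.ndarray
    lig_center: np.ndarray
    lig_sc_weights: np.ndarray
    lig_charges: np.ndarray
    lig_lp: np.ndarray
    lig_skin_mask: np.ndarray
    lig_coords: np.ndarray
    sigma_occ: np.ndarray
    sigma_charge: np.ndarray
    params: DockParams


def receptor_potential(receptor: Molecule, spec: GridSpec,
                       params: DockParams) -> np.ndarray:
    """Receptor electric potential on the grid from its smeared charges,
    with distance-dependent dielectric eps(r) = 4r clamped below
    ``clamp_dist`` (potential kernel 1 / (4 max(r, clamp)^2))."""
    real = receptor.real_mask
    sig = receptor.radii[real] / 2.0
    # normalized Gaussians: each atom's grid mass (* h^3) equals its charge
    w = receptor.charges[real] / (2.0 * np.pi * sig ** 2) ** 1.5
    rho = smear_atoms(receptor.coords[real], w, sig, spec)
    h = spec.spacing
    n = spec.dim
    idx = np.arange(n)
    half = ((idx + n // 2) % n) - n // 2
    d2 = (half[:, None, None] ** 2 + half[None, :, None] ** 2
          + half[None, None, :] ** 2) * h * h
    r = np.sqrt(d2)
    kernel = 1.0 / (4.0 * np.maximum(r, params.clamp_dist) ** 2)
    phi = sp_fft.ifftn(sp_fft.fftn(rho) * sp_fft.fftn(kernel)).real * h ** 3
    return phi


def prepare_receptor(receptor: Molecule, ligand: Molecule,
                     params: DockParams) -> ReceptorSpectra:
    """Precompute the receptor channel grids, their spectra and the band."""
    spec = make_grid_spec(receptor, ligand, params.spacing)
    if params.grid_dim:
        if params.grid_dim < spec.dim:
            raise ValueError(
                f"grid_dim={params.grid_dim} too small; need >= {spec.dim}")
        c_a = receptor.geometric_center
        spec = GridSpec(origin=c_a - 0.5 * params.grid_dim * params.spacing,
                        spacing=params.spacing, dim=params.grid_dim)
    w_rec, w_lig = sc_weights(receptor, ligand, params.skin_mode, params)
    sig_rec = np.maximum(params.sigma_radius_factor * receptor.radii, 1e-3)
    sc_field = smear_atoms(receptor.coords, w_rec, sig_rec, spec)
    phi = receptor_potential(receptor, spec, params)
    pseudo = ~receptor.real_mask
    ip_field = smear_atoms(receptor.coords[pseudo], np.ones(pseudo.sum()),
                           sig_rec[pseudo], spec)
    r_b = ligand_radius(ligand)
    band_world = compute_band(receptor, spec, r_b)
    n = spec.dim
    band_t = np.roll(band_world, shift=(-(n // 2),) * 3, axis=(0, 1, 2))

    lig_real = ligand.real_mask
    lp = np.zeros(len(ligand))
    tbl = load_params()
    for i, a in enumerate(ligand.atoms):
        lp[i] = tbl.propensity_of(a.residue_name)
    skin_mask = np.array([a.role == ROLE_SKIN for a in ligand.atoms])
    return ReceptorSpectra(
        spec=spec,
        sc=forward_fft_sparse(sc_field),
        el=forward_fft_sparse(phi.astype(complex)),
        ip=forward_fft_sparse(ip_field.astype(complex)),
        band_t=band_t,
        band_world=band_world,
        lig_center=ligand.geometric_center,
        lig_sc_weights=w_lig,
        lig_charges=ligand.charges * lig_real,
        lig_lp=lp,
        lig_skin_mask=skin_mask,
        lig_coords=ligand.coords,
        sigma_occ=np.maximum(params.sigma_radius_factor * ligand.radii, 1e-3),
        sigma_charge=np.maximum(ligand.radii / 2.0, 1e-3),
        params=params,
    )


def wrap_indices(t: np.ndarray, n: int) -> np.ndarray:
    """Map 0..N-1 circular translation indices to signed offsets."""
    return ((t + n // 2) % n) - n // 2


def score_rotation(pre: ReceptorSpectra, rot: Rotation
                   ) -> dict[str, np.ndarray]:
    """Score every in-band translation for one ligand rotation.

    Returns in-band arrays: integer translation triples ``t`` plus SC, EL,
    IP and the weighted total.
    """
    spec = pre.spec
    p = pre.params
    center_world = spec.origin + (spec.dim // 2) * spec.spacing
    pos = (pre.lig_coords - pre.lig_center) @ rot.matrix.T + center_world

    sig_occ = pre.sigma_occ
    sc_field = smear_atoms(pos, pre.lig_sc_weights, sig_occ, spec)
    # normalized Gaussians so each atom's smeared mass equals its charge
    el_w = pre.lig_charges / (2.0 * np.pi * pre.sigma_charge ** 2) ** 1.5
    el_field = smear_atoms(pos, el_w, pre.sigma_charge, spec)
    skin = pre.lig_skin_mask
    ip_field = smear_atoms(pos[skin],
                           pre.lig_lp[skin] + 1j * np.ones(skin.sum()),
                           sig_occ[skin], spec)

    band = pre.band_t
    corr_sc = cross_correlate(pre.sc, sc_field, band)
    corr_el = cross_correlate(pre.el, el_field, band)
    corr_ip = cross_correlate(pre.ip, ip_field, band)

    tidx = np.argwhere(band)
    sel = tuple(tidx.T)
    sc = corr_sc.real[sel] - p.lambda_sc * p.w_skin * corr_sc.imag[sel]
    el = -corr_el.real[sel]
    ip = corr_ip.real[sel]
    overlap = corr_ip.imag[sel] * spec.spacing ** 3
    ip = np.where(overlap < p.ip_overlap_min, p.ip_penalty, ip)
    total = p.w_sc * sc + p.w_el * el + p.w_ip * ip
    return {"t": tidx, "SC": sc, "EL": el, "IP": ip, "total": total}


def _pose_from_row(pre: ReceptorSpectra, rot_index: int, t: np.ndarray,
                   sc: float, el: float, ip: float, total: float) -> Pose:
    spec = pre.spec
    center_world = spec.origin + (spec.dim // 2) * spec.spacing
    disp = (center_world + wrap_indices(t, spec.dim) * spec.spacing
            - pre.lig_center)
    return Pose(rotation_index=rot_index, translation=disp,
                scores={"SC": float(sc), "EL": float(el), "IP": float(ip)},
                total=float(total))


def search(receptor: Molecule, ligand: Molecule, rotations: list[Rotation],
           params: DockParams | None = None,
           pre: ReceptorSpectra | None = None,
           task_runner=None) -> list[Pose]:
    """Exhaustive 6D search: all rotations x all in-band translations.

    Returns the top ``k_retain`` poses globally ranked by the weighted
    channel total, deterministically tie-broken by (rotation index,
    lexicographic translation).
    """
    params = params or DockParams()
    pre = pre or prepare_receptor(receptor, ligand, params)
    k_retain = params.k_retain or max(4 * len(rotations), 20000)

    def one(rot: Rotation):
        res = score_rotation(pre, rot)
        m = len(res["total"])
        k = min(k_retain, m)
        if k < m:
            part = np.argpartition(-res["total"], k - 1)[:k]
        else:
            part = np.arange(m)
        return (np.full(len(part), rot.index), res["t"][part],
                res["SC"][part], res["EL"][part], res["IP"][part],
                res["total"][part])

    runner = task_runner or (lambda fn, items: [fn(x) for x in items])
    chunks = runner(one, rotations)

    rot_idx = np.concatenate([c[0] for c in chunks])
    ts = np.vstack([c[1] for c in chunks])
    scs = np.concatenate([c[2] for c in chunks])
    els = np.concatenate([c[3] for c in chunks])
    ips = np.concatenate([c[4] for c in chunks])
    totals = np.concatenate([c[5] for c in chunks])

    order = np.lexsort((ts[:, 2], ts[:, 1], ts[:, 0], rot_idx, -totals))
    order = order[:k_retain]
    poses = []
    for rank, j in enumerate(order, start=1):
        pose = _pose_from_row(pre, int(rot_idx[j]), ts[j],
                              scs[j], els[j], ips[j], totals[j])
        pose.rank = rank
        poses.append(pose)
    return poses
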