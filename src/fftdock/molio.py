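"""Molecular structure I/O, surface detection and skin/core preparation.

Docking treats the larger molecule (the receptor) as stationary.  Its
"grown skin" is a shell of chargeless pseudo-atoms sampled above the van
der Waals surface; the moving ligand's skin is its layer of surface atoms
(one layer in the traditional scheme, two in the improved scheme where the
receptor skin additionally floats at a stand-off distance so the two van
der Waals surfaces never need to touch for a perfect skin-skin overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._sphere import sphere_points
from .params import THREE_TO_ONE, ParamTable, element_of, load_params
from .spatial import PackingGrid

ROLE_CORE = "core"
ROLE_SKIN = "skin"
ROLE_PSEUDO = "pseudo_skin"

BACKBONE_NAMES = {"N", "CA", "C", "O"}


class PQRParseError(ValueError):
    """Raised for malformed PQR/PDB records; carries the line number."""


@dataclass
class Atom:
    serial: int
    name: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    radius: float
    charge: float
    role: str = ROLE_CORE
    is_surface: bool = False
    insertion_code: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite position")
        if self.radius <= 0:
            raise ValueError(f"atom {self.serial}: radius must be positive")
        if self.role == ROLE_PSEUDO and self.charge != 0.0:
            raise ValueError("pseudo-skin atoms must be chargeless")

    @property
    def element(self) -> str:
        return element_of(self.name)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)


class Molecule:
    """An ordered atom collection with chain sequences and cached arrays."""

    def __init__(self, atoms: list[Atom], label: str = ""):
        if not atoms:
            raise ValueError("empty molecule")
        self.atoms = list(atoms)
        self.label = label
        self._cache: dict[str, np.ndarray] = {}

    # -- cached array views ------------------------------------------------
    def _arr(self, key: str, build) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = build()
        return self._cache[key]

    @property
    def coords(self) -> np.ndarray:
        return self._arr("coords", lambda: np.array([a.position for a in self.atoms]))

    @property
    def radii(self) -> np.ndarray:
        return self._arr("radii", lambda: np.array([a.radius for a in self.atoms]))

    @property
    def charges(self) -> np.ndarray:
        return self._arr("charges", lambda: np.array([a.charge for a in self.atoms]))

    @property
    def real_mask(self) -> np.ndarray:
        return self._arr("real", lambda: np.array(
            [a.role != ROLE_PSEUDO for a in self.atoms], dtype=bool))

    @property
    def surface_mask(self) -> np.ndarray:
        return np.array([a.is_surface for a in self.atoms], dtype=bool)

    def invalidate(self) -> None:
        self._cache.clear()

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def geometric_center(self) -> np.ndarray:
        """Unweighted mean position of the real (non-pseudo) atoms."""
        return self.coords[self.real_mask].mean(axis=0)

    @property
    def chains(self) -> dict[str, str]:
        """chain id -> one-letter residue sequence, in order of appearance."""
        seqs: dict[str, str] = {}
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            if a.role == ROLE_PSEUDO:
                continue
            key = a.residue_key
            if key in seen:
                continue
            seen.add(key)
            seqs[a.chain_id] = seqs.get(a.chain_id, "") + \
                THREE_TO_ONE.get(a.residue_name.upper(), "X")
        return seqs

    def residues(self) -> list[tuple[tuple[str, int, str], list[int]]]:
        """Residues (in order of appearance) with their atom indices."""
        order: list[tuple[str, int, str]] = []
        groups: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            if a.role == ROLE_PSEUDO:
                continue
            key = a.residue_key
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(i)
        return [(k, groups[k]) for k in order]

    def copy(self) -> "Molecule":
        return Molecule([replace(a, position=a.position.copy())
                         for a in self.atoms], label=self.label)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    center: np.ndarray | None = None) -> "Molecule":
        """Rigidly transform: rotate about ``center`` (default: geometric
        center), then translate."""
        c = self.geometric_center if center is None else np.asarray(center)
        new = self.copy()
        pos = (self.coords - c) @ np.asarray(rotation).T + c + np.asarray(translation)
        for a, p in zip(new.atoms, pos):
            a.position = p
        return new


# ---------------------------------------------------------------------------
# PQR / PDB reading and writing
# ---------------------------------------------------------------------------

def _parse_pqr_fields(fields: list[str], lineno: int) -> Atom:
    # Whitespace PQR dialects: with chain id (11 cols) or without (10 cols).
    if len(fields) < 10:
        raise PQRParseError(
            f"line {lineno}: expected at least 10 whitespace-separated fields "
            f"(missing charge/radius column?), got {len(fields)}")
    serial = int(fields[1])
    name = fields[2]
    resname = fields[3]
    # decide whether fields[4] is a chain id or a residue number
    def _int_prefix(tok: str) -> tuple[int, str]:
        sign = 1
        body = tok
        if body and body[0] in "+-":
            sign = -1 if body[0] == "-" else 1
            body = body[1:]
        digits = ""
        for ch in body:
            if ch.isdigit():
                digits += ch
            else:
                break
        if not digits:
            raise ValueError(tok)
        return sign * int(digits), body[len(digits):]

    try:
        resseq, icode = _int_prefix(fields[4])
        chain = ""
        rest = fields[5:]
    except ValueError:
        chain = fields[4]
        try:
            resseq, icode = _int_prefix(fields[5])
        except ValueError as exc:
            raise PQRParseError(
                f"line {lineno}: cannot parse residue number {fields[5]!r}") from exc
        rest = fields[6:]
    if len(rest) < 5:
        raise PQRParseError(
            f"line {lineno}: missing coordinate/charge/radius columns")
    try:
        x, y, z, charge, radius = (float(v) for v in rest[:5])
    except ValueError as exc:
        raise PQRParseError(
            f"line {lineno}: non-numeric coordinate/charge/radius field") from exc
    if radius <= 0:
        raise PQRParseError(f"line {lineno}: non-positive radius {radius}")
    return Atom(serial=serial, name=name, residue_name=resname,
                residue_seq=resseq, chain_id=chain or "A",
                position=np.array([x, y, z]), radius=radius, charge=charge,
                insertion_code=icode)


def read_pqr(path: str | Path, label: str = "") -> Molecule:
    """Read a whitespace-delimited PQR file (both PDB2PQR flavors)."""
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            atoms.append(_parse_pqr_fields(rec, lineno))
    if not atoms:
        raise PQRParseError(f"{path}: no ATOM/HETATM records found")
    return Molecule(_dedupe_altloc(atoms), label=label or Path(path).stem)


def write_pqr(mol: Molecule, path: str | Path,
              include_pseudo: bool = False) -> None:
    """Write the molecule in whitespace-PQR format (chain-id flavor)."""
    with open(path, "w") as fh:
        for a in mol.atoms:
            if a.role == ROLE_PSEUDO and not include_pseudo:
                continue
            fh.write(
                f"ATOM {a.serial} {a.name} {a.residue_name} {a.chain_id} "
                f"{a.residue_seq}{a.insertion_code} "
                f"{a.position[0]:.3f} {a.position[1]:.3f} {a.position[2]:.3f} "
                f"{a.charge:.4f} {a.radius:.4f}\n")
        fh.write("END\n")


def _dedupe_altloc(atoms: list[Atom]) -> list[Atom]:
    # PQR output normally has altLocs resolved already; keep first occurrence
    # of a duplicated (residue, atom-name) as the documented tie-break.
    seen: set[tuple[str, int, str, str]] = set()
    out = []
    for a in atoms:
        key = (*a.residue_key, a.name)
        if key in seen:
            continue
        seen.add(key)
        out.append(a)
    return out


def read_pdb(path: str | Path, params: ParamTable | None = None,
             label: str = "") -> Molecule:
    """Fallback reader for plain PDB: bundled per-element radii, zero charges.

    PQR produced by a proper charge/radius assigner is the supported input
    path; this fallback only enables shape-driven runs and emits a warning.
    """
    from Bio.PDB import PDBParser  # established parser for the fixed-column format

    params = params or load_params()
    warnings.warn("PDB input: assigning bundled per-element radii and zero "
                  "charges; use PQR input for charged runs", stacklevel=2)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("mol", str(path))
    atoms: list[Atom] = []
    serial = 0
    model = next(iter(structure))
    for chain in model:
        for residue in chain:
            het, resseq, icode = residue.id
            if het.strip():
                continue
            best: dict[str, object] = {}
            for atom in residue:
                # altLoc: highest occupancy wins, first on tie
                prev = best.get(atom.get_name())
                if prev is not None and (prev.get_occupancy() or 1.0) >= (atom.get_occupancy() or 1.0):
                    continue
                best[atom.get_name()] = atom
            for name in sorted(best):
                atom = best[name]
                serial += 1
                el = element_of(name)
                atoms.append(Atom(
                    serial=serial, name=name, residue_name=residue.get_resname(),
                    residue_seq=int(resseq), chain_id=chain.id.strip() or "A",
                    position=np.array(atom.get_coord(), dtype=float),
                    radius=params.vdw_radius.get(el, 1.7),
                    charge=params.default_charge.get(el, 0.0),
                    insertion_code=icode.strip()))
    if not atoms:
        raise PQRParseError(f"{path}: no usable ATOM records")
    return Molecule(atoms, label=label or Path(path).stem)


def read_structure(path: str | Path, label: str = "") -> Molecule:
    """Dispatch on extension: .pqr -> PQR, otherwise PDB fallback."""
    p = Path(path)
    if p.suffix.lower() == ".pqr":
        return read_pqr(p, label=label)
    return read_pdb(p, label=label)


# ---------------------------------------------------------------------------
# Surface detection and skin/core construction
# ---------------------------------------------------------------------------

def detect_surface_atoms(mol: Molecule, probe_radius: float = 1.4,
                         n_points: int = 128) -> Molecule:
    """Mark atoms whose solvent-accessible sphere has exposed area.

    Sphere-point accessibility test: an atom is surface if any of the
    ``n_points`` samples on its accessible sphere (radius + probe) lies
    outside every neighbor's accessible sphere.  Returns a new molecule.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    new = mol.copy()
    coords, radii = new.coords, new.radii
    real = new.real_mask
    idx = np.nonzero(real)[0]
    rmax = float(radii[idx].max())
    grid = PackingGrid(coords[idx], cell_size=2.0 * (rmax + probe_radius))
    unit = sphere_points(n_points)
    for i in idx:
        pts = coords[i] + (radii[i] + probe_radius) * unit
        neigh = idx[grid.neighbors_within(coords[i], 2.0 * (rmax + probe_radius))]
        neigh = neigh[neigh != i]
        if len(neigh) == 0:
            exposed = True
        else:
            d2 = np.sum((pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2)
            lim = (radii[neigh] + probe_radius) ** 2
            exposed = bool(np.any(np.all(d2 >= lim[None, :] - 1e-12, axis=1)))
        new.atoms[i].is_surface = exposed
    new.invalidate()
    return new


@dataclass
class SkinParams:
    """Geometry of the grown receptor skin and the ligand skin layers."""

    d_float: float = 1.0       # stand-off of the floating receptor skin, A
    r_skin: float = 1.1        # pseudo skin-atom radius, A
    d_layer2: float = 3.0      # second ligand skin layer depth, A
    probe: float = 1.4         # solvent probe for surface detection, A
    sample_density: float = 1.0   # pseudo-atom sampling, points / A^2
    merge_dist: float = 1.0    # pseudo-atom de-duplication distance, A


def grow_pseudo_skin(receptor: Molecule, offset: float, r_skin: float,
                     density: float = 1.0, merge_dist: float = 1.0) -> list[Atom]:
    """Sample pseudo-atoms on the offset surface shell of the receptor.

    Per-atom sphere point sets at radius ``r_i + offset``; points inside
    any inflated neighbor sphere are discarded, then points closer than
    ``merge_dist`` are merged keeping the earlier-generated one.
    """
    coords, radii = receptor.coords, receptor.radii
    real = receptor.real_mask
    idx = np.nonzero(real & receptor.surface_mask)[0]
    if not len(idx):
        idx = np.nonzero(real)[0]
    rmax = float(radii[real].max())
    grid = PackingGrid(coords[real], cell_size=2.0 * (rmax + offset) + 1e-9)
    real_idx = np.nonzero(real)[0]
    candidates: list[np.ndarray] = []
    for i in idx:
        r_shell = radii[i] + offset
        npts = max(int(np.ceil(density * 4 * np.pi * r_shell ** 2)), 8)
        pts = coords[i] + r_shell * sphere_points(npts)
        neigh = real_idx[grid.neighbors_within(coords[i], 2.0 * (rmax + offset))]
        neigh = neigh[neigh != i]
        if len(neigh):
            d2 = np.sum((pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2)
            lim = (radii[neigh] + offset) ** 2
            pts = pts[~np.any(d2 < lim[None, :] - 1e-9, axis=1)]
        if len(pts):
            candidates.append(pts)
    if not candidates:
        raise ValueError("degenerate geometry: empty grown skin")
    pts = np.vstack(candidates)
    # deterministic greedy merge in generation order
    kept_grid: dict[tuple[int, int, int], list[np.ndarray]] = {}
    cell = merge_dist
    kept: list[np.ndarray] = []
    for p in pts:
        ci = tuple(int(v) for v in np.floor(p / cell))
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    for q in kept_grid.get((ci[0] + di, ci[1] + dj, ci[2] + dk), ()):
                        if np.sum((p - q) ** 2) < merge_dist ** 2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            kept.append(p)
            kept_grid.setdefault(ci, []).append(p)
    base_serial = max(a.serial for a in receptor.atoms)
    return [Atom(serial=base_serial + 1 + k, name="PS", residue_name="PSD",
                 residue_seq=k + 1, chain_id="~", position=p,
                 radius=r_skin, charge=0.0, role=ROLE_PSEUDO)
            for k, p in enumerate(kept)]


def build_skin_core(receptor: Molecule, ligand: Molecule,
                    mode: str = "improved",
                    params: SkinParams | None = None) -> tuple[Molecule, Molecule]:
    """Label skin/core regions and grow the receptor pseudo-atom skin.

    ``traditional``: the pseudo-skin shell starts at the receptor vdW
    surface and the ligand skin is its single layer of surface atoms.
    ``improved``: the shell floats ``d_float`` above the vdW surface and
    the ligand skin is a double layer (surface atoms plus atoms within
    ``d_layer2`` of one).
    """
    if mode not in ("traditional", "improved"):
        raise ValueError(f"unknown skin mode {mode!r}")
    params = params or SkinParams()
    if not receptor.surface_mask.any():
        receptor = detect_surface_atoms(receptor, params.probe)
    if not ligand.surface_mask.any():
        ligand = detect_surface_atoms(ligand, params.probe)

    rec = receptor.copy()
    for a in rec.atoms:
        if a.role != ROLE_PSEUDO:
            a.role = ROLE_CORE
    rec.atoms = [a for a in rec.atoms if a.role != ROLE_PSEUDO]
    offset = params.d_float if mode == "improved" else 0.0
    pseudo = grow_pseudo_skin(rec, offset=offset, r_skin=params.r_skin,
                              density=params.sample_density,
                              merge_dist=params.merge_dist)
    rec.atoms.extend(pseudo)
    rec.invalidate()

    lig = ligand.copy()
    surf = lig.surface_mask
    skin = surf.copy()
    if mode == "improved" and surf.any():
        grid = PackingGrid(lig.coords[surf], cell_size=params.d_layer2)
        surf_idx = np.nonzero(surf)[0]
        for i in range(len(lig)):
            if skin[i]:
                continue
            near = grid.neighbors_within(lig.coords[i], params.d_layer2)
            if len(near):
                skin[i] = True
        del surf_idx
    if not skin.any():
        raise ValueError("degenerate geometry: empty ligand skin")
    for i, a in enumerate(lig.atoms):
        a.role = ROLE_SKIN if skin[i] else ROLE_CORE
    lig.invalidate()
    return rec, lig
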