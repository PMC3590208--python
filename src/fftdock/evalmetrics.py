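"""Evaluation of predicted poses against a native complex.

The receptor stays in a fixed frame throughout the search, so a predicted
ligand placement is compared with the native one directly, with no
superposition: the interface RMSD (IRMSD) is the root-mean-square
deviation of the ligand's native-interface backbone atoms, a *hit* is a
pose with IRMSD <= 5 A, and fnat is the fraction of native
residue-residue contacts recovered.  Pose quality classes follow the
CAPRI convention combining fnat and IRMSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fftscore import Pose
from .molio import BACKBONE_NAMES, Molecule
from .spatial import Octree, PackingGrid, interface_pairs

HIT_IRMSD = 5.0
HIT_RANGES = ((1, 1), (1, 10), (1, 50), (1, 100), (1, 500), (1, 1000))


@dataclass
class EvalResult:
    irmsd: float
    fnat: float
    capri: str
    is_hit: bool


def interface_backbone_set(receptor: Molecule, ligand_native: Molecule,
                           cutoff: float = 10.0) -> np.ndarray:
    """Indices of native-interface ligand backbone atoms.

    A ligand atom is on the interface if its center lies within ``cutoff``
    of any receptor atom center in the native pose; only backbone atoms
    (N, CA, C, O) enter the IRMSD set.
    """
    real_r = receptor.real_mask
    real_l = ligand_native.real_mask
    bb = np.array([a.name.upper() in BACKBONE_NAMES for a in ligand_native.atoms])
    cand = np.nonzero(real_l & bb)[0]
    if not len(cand):
        return np.empty(0, dtype=int)
    grid = PackingGrid(receptor.coords[real_r], cell_size=cutoff)
    out = [i for i in cand
           if len(grid.neighbors_within(ligand_native.coords[i], cutoff))]
    return np.array(out, dtype=int)


def _posed_coords(ligand: Molecule, pose: Pose,
                  rotation: np.ndarray | None) -> np.ndarray:
    c = ligand.geometric_center
    coords = ligand.coords
    if rotation is not None:
        coords = (coords - c) @ np.asarray(rotation).T + c
    return coords + pose.translation


def irmsd(pose: Pose, ligand_native: Molecule, iface: np.ndarray,
          rotation: np.ndarray | None = None) -> float:
    """Interface RMSD of a pose against the native ligand placement."""
    if not len(iface):
        raise ValueError("empty native interface set")
    posed = _posed_coords(ligand_native, pose, rotation)
    d2 = np.sum((posed[iface] - ligand_native.coords[iface]) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))


def residue_contacts(receptor: Molecule, ligand_coords: np.ndarray,
                     ligand: Molecule, cutoff: float) -> set[tuple]:
    """Residue-level contact set: any-atom distance below the cutoff."""
    real_r = receptor.real_mask
    real_l = ligand.real_mask
    idx_r = np.nonzero(real_r)[0]
    idx_l = np.nonzero(real_l)[0]
    pairs = interface_pairs(Octree(receptor.coords[idx_r]),
                            Octree(ligand_coords[idx_l]), cutoff)
    contacts = set()
    for i, j in pairs:
        ra = receptor.atoms[idx_r[i]]
        rb = ligand.atoms[idx_l[j]]
        contacts.add((ra.residue_key, rb.residue_key))
    return contacts


def fnat(pose: Pose, receptor: Molecule, ligand_native: Molecule,
         contact_cutoff: float = 5.0,
         rotation: np.ndarray | None = None) -> float:
    """Fraction of native residue-residue contacts present in the pose."""
    native = residue_contacts(receptor, ligand_native.coords, ligand_native,
                              contact_cutoff)
    if not native:
        raise ValueError("native complex has no residue contacts")
    posed = residue_contacts(receptor,
                             _posed_coords(ligand_native, pose, rotation),
                             ligand_native, contact_cutoff)
    return len(native & posed) / len(native)


def capri_class(irmsd_value: float, fnat_value: float,
                lrmsd_proxy: float | None = None) -> str:
    """CAPRI quality class from fnat and interface RMSD."""
    if fnat_value >= 0.5 and irmsd_value <= 1.0:
        return "high"
    if fnat_value >= 0.3 and irmsd_value <= 2.0:
        return "medium"
    if fnat_value >= 0.1 and irmsd_value <= 4.0:
        return "acceptable"
    return "incorrect"


def evaluate_pose(pose: Pose, receptor: Molecule, ligand_native: Molecule,
                  iface: np.ndarray | None = None,
                  rotation: np.ndarray | None = None,
                  contact_cutoff: float = 5.0) -> EvalResult:
    if iface is None:
        iface = interface_backbone_set(receptor, ligand_native)
    rms = irmsd(pose, ligand_native, iface, rotation)
    fn = fnat(pose, receptor, ligand_native, contact_cutoff, rotation)
    return EvalResult(irmsd=rms, fnat=fn, capri=capri_class(rms, fn),
                      is_hit=rms <= HIT_IRMSD)


@dataclass
class ComplexSummary:
    top_hit_rank: int | None
    top_hit_irmsd: float | None
    best_hit_rank: int | None
    best_hit_irmsd: float | None


def rank_stats(irmsds_per_complex: dict[str, list[float]],
               max_rank: int = 1000) -> dict:
    """Hit-rank statistics over a set of complexes.

    Input: ranked IRMSD lists (index 0 = rank 1).  Output: per-complex
    top/best hit summaries, counts of complexes whose top hit falls in
    the standard rank ranges, and the rate-of-success curve
    H(k)/H(max_rank) where H(k) counts all hits at rank <= k.
    """
    per_complex: dict[str, ComplexSummary] = {}
    hit_counts = np.zeros(max_rank, dtype=int)
    for name, values in irmsds_per_complex.items():
        values = list(values)[:max_rank]
        hits = [(rank0 + 1, v) for rank0, v in enumerate(values)
                if v <= HIT_IRMSD]
        if hits:
            top = hits[0]
            best = min(hits, key=lambda rv: (rv[1], rv[0]))
            per_complex[name] = ComplexSummary(top[0], top[1], best[0], best[1])
            for rank, _ in hits:
                hit_counts[rank - 1] += 1
        else:
            per_complex[name] = ComplexSummary(None, None, None, None)
    range_counts = {}
    for lo, hi in HIT_RANGES:
        range_counts[(lo, hi)] = sum(
            1 for s in per_complex.values()
            if s.top_hit_rank is not None and lo <= s.top_hit_rank <= hi)
    cumulative = np.cumsum(hit_counts)
    total = cumulative[-1]
    rate = cumulative / total if total else np.zeros(max_rank)
    return {"per_complex": per_complex, "range_counts": range_counts,
            "rate_of_success": rate, "total_hits": int(total)}
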