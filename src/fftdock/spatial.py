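"""Spatial indices (uniform packing grid, octree) and molecular surface
quadrature.

The packing grid is a uniform-cell spatial hash giving near-constant-time
fixed-radius neighbor queries; the octree is an adaptive subdivision used
for dual-tree interface extraction.  Surface quadrature decomposes the
solvent-accessible surface into per-atom patches: every surviving sphere
sample point represents a patch whose weight is its share of the exposed
area, so patch weights sum to the molecule's accessible area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterator

import numpy as np
from scipy.spatial.distance import cdist

from ._sphere import sphere_points

if TYPE_CHECKING:  # pragma: no cover
    from .molio import Molecule
    from .params import ParamTable


class PackingGrid:
    """Uniform-cell spatial hash over a fixed point set.

    Cell index of a point is ``floor(coordinate / cell_size)`` per
    component; each point lives in exactly one cell.
    """

    def __init__(self, points: np.ndarray, cell_size: float):
        if cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.points = np.asarray(points, dtype=float).reshape(-1, 3)
        self.cell_size = float(cell_size)
        self.cells: dict[tuple[int, int, int], np.ndarray] = {}
        if len(self.points):
            idx = np.floor(self.points / self.cell_size).astype(np.int64)
            order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
            sorted_idx = idx[order]
            change = np.any(np.diff(sorted_idx, axis=0) != 0, axis=1)
            starts = np.concatenate([[0], np.nonzero(change)[0] + 1, [len(order)]])
            for a, b in zip(starts[:-1], starts[1:]):
                key = tuple(int(v) for v in sorted_idx[a])
                self.cells[key] = order[a:b]

    def __len__(self) -> int:
        return len(self.points)

    def neighbors_within(self, q, d: float) -> np.ndarray:
        """Indices of points with ``||p - q|| < d`` (strict inequality)."""
        if d <= 0:
            raise ValueError("query radius must be positive")
        if not len(self.points):
            return np.empty(0, dtype=np.int64)
        q = np.asarray(q, dtype=float)
        lo = np.floor((q - d) / self.cell_size).astype(np.int64)
        hi = np.floor((q + d) / self.cell_size).astype(np.int64)
        hits: list[np.ndarray] = []
        for i in range(lo[0], hi[0] + 1):
            for j in range(lo[1], hi[1] + 1):
                for k in range(lo[2], hi[2] + 1):
                    cand = self.cells.get((i, j, k))
                    if cand is None:
                        continue
                    dist2 = np.sum((self.points[cand] - q) ** 2, axis=1)
                    hits.append(cand[dist2 < d * d])
        if not hits:
            return np.empty(0, dtype=np.int64)
        return np.sort(np.concatenate(hits))


def neighbors_within(grid: PackingGrid, q, d: float) -> np.ndarray:
    """Functional alias for :meth:`PackingGrid.neighbors_within`."""
    return grid.neighbors_within(q, d)


@dataclass
class _OctNode:
    origin: np.ndarray
    edge: float
    indices: np.ndarray
    children: list["_OctNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Octree:
    """Adaptive octree over a point set.

    A node is split while it holds more than ``leaf_cap`` points, up to
    ``depth_cap`` levels; every point ends up in exactly one leaf.
    """

    def __init__(self, points: np.ndarray, leaf_cap: int = 32, depth_cap: int = 12):
        self.points = np.asarray(points, dtype=float).reshape(-1, 3)
        self.leaf_cap = int(leaf_cap)
        self.depth_cap = int(depth_cap)
        if len(self.points):
            lo = self.points.min(axis=0)
            hi = self.points.max(axis=0)
            edge = float(max(np.max(hi - lo), 1e-9)) * (1 + 1e-9)
        else:
            lo, edge = np.zeros(3), 1.0
        self.root = _OctNode(np.asarray(lo, dtype=float), edge,
                             np.arange(len(self.points), dtype=np.int64))
        self._split(self.root, 0)

    def _split(self, node: _OctNode, depth: int) -> None:
        if len(node.indices) <= self.leaf_cap or depth >= self.depth_cap:
            return
        half = node.edge / 2.0
        mid = node.origin + half
        pts = self.points[node.indices]
        octant = ((pts[:, 0] >= mid[0]).astype(int)
                  | ((pts[:, 1] >= mid[1]).astype(int) << 1)
                  | ((pts[:, 2] >= mid[2]).astype(int) << 2))
        for o in range(8):
            sub = node.indices[octant == o]
            if not len(sub):
                continue
            off = np.array([o & 1, (o >> 1) & 1, (o >> 2) & 1], dtype=float)
            child = _OctNode(node.origin + off * half, half, sub)
            node.children.append(child)
            self._split(child, depth + 1)
        node.indices = np.empty(0, dtype=np.int64)

    def leaves(self) -> Iterator[_OctNode]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                yield n
            else:
                stack.extend(n.children)


def _box_min_dist(a: _OctNode, b: _OctNode) -> float:
    lo_a, hi_a = a.origin, a.origin + a.edge
    lo_b, hi_b = b.origin, b.origin + b.edge
    gap = np.maximum(0.0, np.maximum(lo_a - hi_b, lo_b - hi_a))
    return float(np.linalg.norm(gap))


def close_pairs(points_a: np.ndarray, points_b: np.ndarray,
                cutoff: float, max_brute: int = 1_000_000) -> np.ndarray:
    """All (i, j) with ``||a_i - b_j|| < cutoff``, dispatching on size.

    Small inputs use a blocked vectorized distance matrix; large inputs
    build octrees and run the dual-tree traversal of
    :func:`interface_pairs`.  Both return identical pair sets.
    """
    points_a = np.asarray(points_a, dtype=float).reshape(-1, 3)
    points_b = np.asarray(points_b, dtype=float).reshape(-1, 3)
    if not len(points_a) or not len(points_b):
        return np.empty((0, 2), dtype=np.int64)
    if len(points_a) * len(points_b) > max_brute:
        return interface_pairs(Octree(points_a), Octree(points_b), cutoff)
    d = cdist(points_a, points_b)
    ii, jj = np.nonzero(d < cutoff)
    return np.column_stack([ii, jj]).astype(np.int64)


def interface_pairs(tree_a: Octree, tree_b: Octree, cutoff: float) -> np.ndarray:
    """All point pairs (i in A, j in B) with ``||a_i - b_j|| < cutoff``.

    Dual-tree traversal prunes leaf pairs whose cube separation exceeds
    the cutoff; surviving A-leaf points are resolved against a packing
    grid over B's points.  Returns an (m, 2) int array sorted
    lexicographically.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not len(tree_a.points) or not len(tree_b.points):
        return np.empty((0, 2), dtype=np.int64)
    close_a: set[int] = set()
    candidate_a: list[np.ndarray] = []
    stack = [(tree_a.root, tree_b.root)]
    seen: list[tuple[int, np.ndarray]] = []
    while stack:
        na, nb = stack.pop()
        if _box_min_dist(na, nb) > cutoff:
            continue
        if na.is_leaf and nb.is_leaf:
            key = id(na)
            if key not in close_a:
                close_a.add(key)
                candidate_a.append(na.indices)
            continue
        # descend the larger box first
        if not na.is_leaf and (nb.is_leaf or na.edge >= nb.edge):
            stack.extend((c, nb) for c in na.children)
        else:
            stack.extend((na, c) for c in nb.children)
    del seen
    if not candidate_a:
        return np.empty((0, 2), dtype=np.int64)
    grid_b = PackingGrid(tree_b.points, cell_size=cutoff)
    a_idx = np.unique(np.concatenate(candidate_a))
    pairs: list[np.ndarray] = []
    for i in a_idx:
        js = grid_b.neighbors_within(tree_a.points[i], cutoff)
        if len(js):
            pairs.append(np.column_stack([np.full(len(js), i, dtype=np.int64), js]))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    out = np.vstack(pairs)
    return out[np.lexsort((out[:, 1], out[:, 0]))]


@dataclass
class QuadPoint:
    """One surface quadrature point: a patch representative."""

    position: np.ndarray
    normal: np.ndarray
    area: float
    propensity: float
    parent_atom: int


class QuadratureSet:
    """Vectorized collection of surface quadrature points."""

    def __init__(self, positions, normals, areas, labels, parents):
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        self.normals = np.asarray(normals, dtype=float).reshape(-1, 3)
        self.areas = np.asarray(areas, dtype=float)
        self.labels = np.asarray(labels, dtype=float)
        self.parents = np.asarray(parents, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.areas)

    def __getitem__(self, i: int) -> QuadPoint:
        return QuadPoint(self.positions[i], self.normals[i],
                         float(self.areas[i]), float(self.labels[i]),
                         int(self.parents[i]))

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def transformed(self, rotation: np.ndarray, center: np.ndarray,
                    translation: np.ndarray) -> "QuadratureSet":
        """Rigidly move the point set (rotate about ``center``, then shift)."""
        pos = (self.positions - center) @ rotation.T + center + translation
        nrm = self.normals @ rotation.T
        return QuadratureSet(pos, nrm, self.areas.copy(), self.labels.copy(),
                             self.parents.copy())

    def to_array(self) -> np.ndarray:
        """Tabular export: x y z nx ny nz area label atom."""
        return np.column_stack([self.positions, self.normals,
                                self.areas, self.labels,
                                self.parents.astype(float)])


def surface_quadrature(mol: "Molecule", density: float,
                       params: "ParamTable | None" = None,
                       probe: float = 1.4, r_label: float = 4.0) -> QuadratureSet:
    """Sample weighted quadrature points from the accessible surface.

    Each atom's accessible sphere (radius ``r_i + probe``) is covered with
    ~``density`` points per square Angstrom; points buried inside a
    neighbor's accessible sphere are discarded, and every survivor carries
    an equal share of its sphere's area, so the patch weights of an atom
    sum to its exposed area.  Points are labeled with the mean interface
    propensity of residues owning atoms within ``r_label``.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    coords = mol.coords
    radii = mol.radii
    real = mol.real_mask  # pseudo-atoms carry no surface
    n = len(coords)
    rmax = float(radii[real].max()) if real.any() else 1.0
    grid = PackingGrid(coords[real], cell_size=2.0 * (rmax + probe))
    real_idx = np.nonzero(real)[0]

    if params is not None:
        lp_atom = np.array([params.propensity_of(a.residue_name) for a in mol.atoms])
    else:
        lp_atom = np.zeros(n)
    label_grid = PackingGrid(coords[real], cell_size=max(r_label, 1e-6))

    positions, normals, areas, labels, parents = [], [], [], [], []
    for i in real_idx:
        r_acc = radii[i] + probe
        sphere_area = 4.0 * np.pi * r_acc * r_acc
        npts = max(int(np.ceil(density * sphere_area)), 8)
        pts = coords[i] + r_acc * sphere_points(npts)
        neigh = grid.neighbors_within(coords[i], 2.0 * (rmax + probe))
        neigh = real_idx[neigh]
        neigh = neigh[neigh != i]
        keep = np.ones(npts, dtype=bool)
        if len(neigh):
            d2 = np.sum((pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2)
            lim = (radii[neigh] + probe) ** 2
            keep = ~np.any(d2 < lim[None, :] - 1e-12, axis=1)
        if not keep.any():
            continue
        kept = pts[keep]
        patch = sphere_area / npts
        # label: mean propensity of atoms within r_label of each point;
        # candidates restricted to atoms near this atom's sphere
        cand = real_idx[label_grid.neighbors_within(coords[i], r_acc + r_label + 1e-9)]
        d2lab = np.sum((kept[:, None, :] - coords[cand][None, :, :]) ** 2, axis=2)
        mask = d2lab < r_label * r_label
        counts = mask.sum(axis=1)
        sums = mask @ lp_atom[cand]
        labs = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        positions.append(kept)
        normals.append((kept - coords[i]) / r_acc)
        areas.append(np.full(len(kept), patch))
        labels.append(labs)
        parents.append(np.full(len(kept), i, dtype=np.int64))
    if not positions:
        return QuadratureSet(np.empty((0, 3)), np.empty((0, 3)),
                             np.empty(0), np.empty(0),
                             np.empty(0, dtype=np.int64))
    return QuadratureSet(np.vstack(positions), np.vstack(normals),
                         np.concatenate(areas), np.concatenate(labels),
                         np.concatenate(parents))
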