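"""Proximity clustering of docking poses.

Poses whose ligand geometric centers crowd around a better-scoring pose
are penalized so the top of the ranked list stays diverse; all but the
best-scoring pose of a cluster receive a reduction.  Neighbor counting
always uses the original (pre-penalty) scores, and poses are processed
sequentially in rank order, so the result is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fftscore import Pose
from .spatial import PackingGrid


@dataclass
class ClusterParams:
    """Three-tier penalty rule.

    A pose with ``m`` better-or-equal-scoring neighbors within ``radius``
    is reduced by ``p1`` if m >= n1, else ``p2`` if m >= n2, else ``p3``
    if m >= n3 (fractions of the current score magnitude).  The lowest
    tier defaults to n3 = 1 so that every pose but the best of a cluster
    is penalized.
    """

    radius: float = 5.0
    counts: tuple[int, int, int] = (8, 4, 1)        # n1 > n2 > n3
    penalties: tuple[float, float, float] = (0.95, 0.9, 0.85)  # p1 > p2 > p3


def proximity_cluster(poses: list[Pose], ligand_center: np.ndarray,
                      params: ClusterParams | None = None) -> list[Pose]:
    """Penalize poses similar to better-scoring poses, then re-sort.

    ``ligand_center`` is the input ligand geometric center; a pose's
    cluster position is that center displaced by the pose translation.
    The number of poses is unchanged - only the ordering moves.
    """
    params = params or ClusterParams()
    totals = np.array([p.total for p in poses])
    if np.any(np.diff(totals) > 1e-9):
        raise ValueError("poses must be sorted by total score, descending")
    if not poses:
        return []
    centers = np.asarray(ligand_center) + np.array([p.translation for p in poses])
    grid = PackingGrid(centers, cell_size=params.radius)
    n1, n2, n3 = params.counts
    p1, p2, p3 = params.penalties
    out = []
    for i, pose in enumerate(poses):
        neigh = grid.neighbors_within(centers[i], params.radius)
        # better-or-equal original score, excluding the pose itself;
        # ties broken by rank so exactly one member of an exact tie is free
        m = int(np.sum((totals[neigh] > totals[i])
                       | ((totals[neigh] == totals[i]) & (neigh < i))))
        frac = 0.0
        if m >= n1:
            frac = p1
        elif m >= n2:
            frac = p2
        elif m >= n3:
            frac = p3
        new = pose.copy()
        if frac > 0.0:
            amount = frac * abs(new.total)
            new.total -= amount
            new.penalties.append(("cluster", amount))
        out.append(new)
    out.sort(key=lambda p: (-p.total, p.rotation_index, tuple(p.translation)))
    for rank, p in enumerate(out, start=1):
        p.rank = rank
    return out
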