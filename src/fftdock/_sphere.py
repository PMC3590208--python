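"""Deterministic point sets on spheres and balls (Fibonacci spirals)."""

from __future__ import annotations

import numpy as np

_GOLDEN = np.pi * (3.0 - np.sqrt(5.0))  # golden angle, rad


def sphere_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors on S2 (Fibonacci spiral), (n, 3).

    Deterministic; point 0 is the north pole for n == 1, and the spiral
    runs pole to pole otherwise.
    """
    n = max(int(n), 1)
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = _GOLDEN * k
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def ball_points(n_shells: int = 4, per_shell: int = 16) -> np.ndarray:
    """Deterministic sample of the unit ball with near-uniform density.

    Shell radii follow the cube-root spacing so each shell represents an
    equal-volume slab; used for local occupancy (curvature) probes.
    """
    pts = [np.zeros((1, 3))]
    for i in range(n_shells):
        r = ((i + 0.5) / n_shells) ** (1.0 / 3.0)
        pts.append(r * sphere_points(per_shell))
    return np.vstack(pts)
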