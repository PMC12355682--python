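"""Shrake–Rupley solvent-accessible surface area.

Each atom is inflated by the probe radius and covered with a
deterministic golden-spiral point set; points inside any neighbouring
inflated sphere are occluded.  SASA_i = accessible fraction × 4π(R_i +
probe)².  Deterministic for a fixed point count and invariant under
rigid motions of the whole system (the point set is generated in a
fixed frame, so invariance holds to sampling tolerance only).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .constants import VDW_RADII

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960


def golden_spiral_points(n: int) -> np.ndarray:
    """n roughly uniform unit-sphere points (deterministic)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley(
    positions: np.ndarray,
    elements: list[str],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom SASA (Å²)."""
    radii = dict(radii or VDW_RADII)
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    r = np.array([radii.get(e.upper(), 1.7) + probe_radius for e in elements])
    sphere = golden_spiral_points(n_points)
    tree = cKDTree(positions)
    out = np.zeros(len(positions))
    max_r = r.max()
    for i in range(len(positions)):
        pts = positions[i] + r[i] * sphere
        neighbors = [j for j in tree.query_ball_point(positions[i], r[i] + max_r)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - positions[j], axis=1)
            accessible &= d >= r[j]
        out[i] = accessible.mean() * 4.0 * np.pi * r[i] ** 2
    return out
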