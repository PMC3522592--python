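"""Small geometry helpers shared by hydrogen building and fixtures."""
from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def any_perpendicular(v: np.ndarray) -> np.ndarray:
    """Deterministic unit vector orthogonal to v."""
    v = unit(v)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(v @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, ref))


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D bonded to C given internal coordinates.

    ``angle`` is the B-C-D angle and ``dihedral`` the A-B-C-D torsion.
    """
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = unit(c - b)
    try:
        n = unit(np.cross(b - a, bc))
    except ValueError:
        n = any_perpendicular(bc)
    m = np.cross(n, bc)
    d = bond * (-np.cos(ang) * bc +
                np.sin(ang) * (np.cos(dih) * m + np.sin(dih) * n))
    return c + d


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about a unit axis (Rodrigues)."""
    axis = unit(axis)
    t = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)
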