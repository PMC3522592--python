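"""Scan coordinate frame and exact rigid-body pose transforms.

The scan axis (local +x) is the principal axis of the mobile body — the
eigenvector of its gyration tensor with the largest eigenvalue — sign-fixed
to point from the fixed body toward the mobile body.  For an immunoglobulin
variable-domain dimer this is the long axis orthogonal to the binding plane,
so translating along +x separates the partners and rotating about it sweeps
the docking orientation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._geom import rotation_about_axis, unit
from .errors import GeometryError
from .structure_io import ParameterizedStructure, ResidueId

__all__ = ["ScanFrame", "Pose", "compute_scan_frame", "apply_pose",
           "min_interbody_distance"]

# relative eigenvalue gap below which the principal axis is ambiguous
_DEGENERACY_TOL = 1e-8


@dataclass(frozen=True)
class ScanFrame:
    """Right-handed orthonormal frame anchored at the mobile-body centroid."""
    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        for a in (self.x_axis, self.y_axis, self.z_axis):
            if abs(np.linalg.norm(a) - 1) > 1e-10:
                raise GeometryError("frame axis not unit length")
        if abs(self.x_axis @ self.y_axis) > 1e-10 or \
           abs(self.x_axis @ self.z_axis) > 1e-10 or \
           abs(self.y_axis @ self.z_axis) > 1e-10:
            raise GeometryError("frame axes not orthogonal")


@dataclass(frozen=True)
class Pose:
    """Separation along +x (Å) and right-handed rotation about x (degrees),
    relative to the native position."""
    separation: float = 0.0
    angle: float = 0.0

    def __post_init__(self):
        a = normalize_angle(self.angle)
        object.__setattr__(self, "angle", a)

    def transform(self, frame: ScanFrame) -> tuple[np.ndarray, np.ndarray]:
        """(R, t) acting on mobile atoms as x -> R (x - origin) + origin + t."""
        rot = rotation_about_axis(frame.x_axis, self.angle)
        return rot, self.separation * frame.x_axis


def normalize_angle(angle: float) -> float:
    """Map an angle in degrees to (-180, 180]."""
    a = float(angle) % 360.0
    if a > 180.0:
        a -= 360.0
    return a


def _centroids(structure: ParameterizedStructure):
    mob = structure.is_mobile
    if not mob.any() or mob.all():
        raise GeometryError("both bodies must be non-empty")
    return (structure.positions[mob].mean(axis=0),
            structure.positions[~mob].mean(axis=0))


def compute_scan_frame(structure: ParameterizedStructure,
                       axis_mode: str = "gyration-max") -> ScanFrame:
    """Deterministic scan frame from the mobile body.

    ``gyration-max`` takes the largest-eigenvalue eigenvector of the mobile
    body's (unweighted) gyration tensor; ``centroid-line`` falls back to the
    normalized centroid-difference vector.
    """
    c_mob, c_fix = _centroids(structure)
    sep = c_mob - c_fix
    if np.linalg.norm(sep) < 1e-9:
        raise GeometryError("coincident body centroids; axis sign undefined")
    if axis_mode == "centroid-line":
        x = unit(sep)
    elif axis_mode == "gyration-max":
        rel = structure.positions[structure.is_mobile] - c_mob
        gyr = rel.T @ rel / len(rel)
        evals, evecs = np.linalg.eigh(gyr)
        scale = max(evals[-1], 1e-12)
        if (evals[-1] - evals[-2]) / scale < _DEGENERACY_TOL:
            raise GeometryError(
                "gyration tensor has no unique largest principal axis; "
                "use axis_mode='centroid-line'")
        x = evecs[:, -1]
        if x @ sep < 0:
            x = -x
    else:
        raise GeometryError(f"unknown axis_mode {axis_mode!r}")
    # y: global +z projected off x; fall back to +y when nearly parallel
    ref = np.array([0.0, 0.0, 1.0])
    if abs(x @ ref) > 1.0 - 1e-6:
        ref = np.array([0.0, 1.0, 0.0])
    y = unit(ref - (ref @ x) * x)
    z = np.cross(x, y)
    return ScanFrame(origin=c_mob, x_axis=x, y_axis=y, z_axis=z)


def apply_pose(structure: ParameterizedStructure, frame: ScanFrame,
               pose: Pose) -> ParameterizedStructure:
    """Rigidly transform the mobile body: rotate about the axis through the
    frame origin along x, then translate by ``separation`` along +x."""
    rot, t = pose.transform(frame)
    pos = structure.positions.copy()
    mob = structure.is_mobile
    pos[mob] = (pos[mob] - frame.origin) @ rot.T + frame.origin + t
    return structure.with_positions(pos)


def min_interbody_distance(structure: ParameterizedStructure,
                           ) -> tuple[float, tuple[ResidueId, ResidueId]]:
    """Smallest mobile-fixed atom distance and the owning residue pair."""
    mob = structure.is_mobile
    if not mob.any() or mob.all():
        raise GeometryError("both bodies must be non-empty")
    mpos = structure.positions[mob]
    fpos = structure.positions[~mob]
    tree = cKDTree(fpos)
    dist, j = tree.query(mpos, k=1)
    i = int(np.argmin(dist))
    mob_idx = np.flatnonzero(mob)[i]
    fix_idx = np.flatnonzero(~mob)[int(j[i])]
    return float(dist[i]), (structure.residue_ids[mob_idx],
                            structure.residue_ids[fix_idx])
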