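"""Scan orchestration: rotation profiles, landscapes, rigid pulling,
clash masking and minima detection.

The default protocol mirrors a long-range docking-orientation scan: the
mobile body is translated 8 Å away from the fixed body along the scan axis
and rotated in 5° steps through a full revolution; each pose is scored by
the inter-body polar energy (shifted Coulomb + GB cross terms, Born radii
re-estimated at every pose).  Poses whose closest residue pair clashes
sterically are masked.  Minima are classified into a primary minimum (the
deepest local minimum within ±90° of the native orientation) and a
secondary one (outside that window, i.e. toward the opposed orientation).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decomposition import polar_shares
from .energy import (EnergyModel, born_radii, coulomb_energy,
                     gb_polar_energy, lj_energy, lj_residue_pair_energy,
                     sasa)
from .errors import ConfigurationError, DegenerateProfileError
from .rigid_geometry import (Pose, ScanFrame, apply_pose,
                             min_interbody_distance, normalize_angle)
from .structure_io import ParameterizedStructure

__all__ = ["RotationProfile", "MinimaReport", "PullingProfile",
           "rotation_profile", "group_profiles", "clash_check",
           "find_minima", "landscape", "pulling_profile", "scan_angles"]

PRIMARY_HALF_WINDOW = 90.0  # degrees; primary window is (-90, 90)


def scan_angles(step: float = 5.0) -> np.ndarray:
    """Angle grid in degrees: full revolution, normalized to (-180, 180],
    ascending, 0 present."""
    n = int(round(360.0 / step))
    if abs(n * step - 360.0) > 1e-9:
        raise ConfigurationError(f"step {step} does not divide 360")
    return np.sort(np.array([normalize_angle(k * step) for k in range(n)]))


@dataclass
class RotationProfile:
    """Inter-body polar energy versus rotation angle at fixed separation.

    ``energy`` is reported relative to the unmasked minimum (NaN at masked
    poses); ``reference_zero`` restores absolute values."""
    separation: float
    angles: np.ndarray
    energy: np.ndarray
    clash_mask: np.ndarray
    reference_zero: float

    @property
    def n_poses(self) -> int:
        return len(self.angles)

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.clash_mask

    @property
    def raw_energy(self) -> np.ndarray:
        return self.energy + self.reference_zero

    @property
    def amplitude(self) -> float:
        e = self.energy[self.unmasked]
        return float(e.max() - e.min())


@dataclass(frozen=True)
class MinimaReport:
    """Primary/secondary minimum classification of a rotation profile."""
    primary_minimum: float | None
    secondary_minimum: float | None
    energy_difference: float | None  # E(secondary) - E(primary)
    primary_is_global: bool
    amplitude: float
    local_minima: tuple = field(default_factory=tuple)  # (angle, energy)


@dataclass
class PullingProfile:
    """Full effective interaction energy along a translation away from the
    bound pose."""
    displacements: np.ndarray
    full_energy: np.ndarray
    barrier_position: float | None
    barrier_height: float | None   # barrier - plateau
    well_depth: float              # plateau - E(0)
    components: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# clash masking
# ---------------------------------------------------------------------------

def clash_check(structure: ParameterizedStructure,
                model: EnergyModel) -> bool:
    """True when the pose clashes: the closest inter-body residue pair has a
    repulsive LJ energy above threshold, or any atom pair is closer than the
    hard distance floor."""
    dmin, (rid_m, rid_f) = min_interbody_distance(structure)
    if dmin < model.clash_distance_floor:
        return True
    if dmin > model.cutoff:
        return False
    pair_lj = lj_residue_pair_energy(structure, model, rid_m, rid_f)
    return pair_lj > model.clash_lj_threshold


# ---------------------------------------------------------------------------
# rotation profiles
# ---------------------------------------------------------------------------

def _pose_polar_energy(posed, model) -> float:
    radii = born_radii(posed, model)
    return (coulomb_energy(posed, model, interbody_only=True)
            + gb_polar_energy(posed, model, radii, interbody_only=True))


def rotation_profile(structure: ParameterizedStructure, model: EnergyModel,
                     frame: ScanFrame, separation: float = 8.0,
                     step: float = 5.0) -> RotationProfile:
    """Rotate the translated mobile body through 360° and record the
    inter-body polar energy per pose (NaN where the clash mask fires)."""
    angles = scan_angles(step)
    energy = np.full(len(angles), np.nan)
    mask = np.zeros(len(angles), dtype=bool)
    for t, ang in enumerate(angles):
        posed = apply_pose(structure, frame, Pose(separation, float(ang)))
        if clash_check(posed, model):
            mask[t] = True
            continue
        energy[t] = _pose_polar_energy(posed, model)
    if mask.all():
        raise DegenerateProfileError(
            f"all {len(angles)} poses at separation {separation} A clash")
    ref = float(np.nanmin(energy))
    return RotationProfile(separation=separation, angles=angles,
                           energy=energy - ref, clash_mask=mask,
                           reference_zero=ref)


def group_profiles(structure: ParameterizedStructure, model: EnergyModel,
                   frame: ScanFrame, groups: dict[str, np.ndarray],
                   separation: float = 8.0, step: float = 5.0,
                   ) -> tuple[RotationProfile, dict[str, np.ndarray]]:
    """System rotation profile plus per-group polar-share vectors.

    ``groups`` maps a label to a boolean atom mask; each vector W_sel[t] is
    the summed inter-body (coulomb + GB) share of the selection at pose t,
    index-aligned with the system profile (NaN at masked poses).  Group
    vectors are absolute (not offset to the profile minimum).
    """
    for label, m in groups.items():
        if not np.asarray(m).any():
            raise ConfigurationError(f"group {label!r} selects no atoms")
    angles = scan_angles(step)
    energy = np.full(len(angles), np.nan)
    mask = np.zeros(len(angles), dtype=bool)
    vectors = {g: np.full(len(angles), np.nan) for g in groups}
    for t, ang in enumerate(angles):
        posed = apply_pose(structure, frame, Pose(separation, float(ang)))
        if clash_check(posed, model):
            mask[t] = True
            continue
        radii = born_radii(posed, model)
        shares = polar_shares(posed, model, radii, interbody_only=True)
        energy[t] = shares.sum()
        for g, m in groups.items():
            vectors[g][t] = shares[np.asarray(m, dtype=bool)].sum()
    if mask.all():
        raise DegenerateProfileError("all poses clash")
    ref = float(np.nanmin(energy))
    profile = RotationProfile(separation=separation, angles=angles,
                              energy=energy - ref, clash_mask=mask,
                              reference_zero=ref)
    return profile, vectors


# ---------------------------------------------------------------------------
# minima detection
# ---------------------------------------------------------------------------

def _circular_local_minima(angles, energy, mask):
    """Local minima over unmasked poses on the circle; plateaus collapse to
    the member with the smallest |angle|."""
    idx = np.flatnonzero(~mask)
    n = len(idx)
    if n < 3:
        return []
    vals = energy[idx]
    # group circularly-consecutive equal values into runs
    runs, visited = [], set()
    for k in range(n):
        if k in visited:
            continue
        run = [k]
        visited.add(k)
        j = (k + 1) % n
        while j != k and vals[j] == vals[k]:
            run.append(j)
            visited.add(j)
            j = (j + 1) % n
        j = (k - 1) % n
        while j != k and vals[j] == vals[k] and j not in visited:
            run.insert(0, j)
            visited.add(j)
            j = (j - 1) % n
        runs.append(run)
    minima = []
    for run in runs:
        if len(run) == n:  # flat profile: no local structure
            continue
        before = vals[(run[0] - 1) % n]
        after = vals[(run[-1] + 1) % n]
        if before > vals[run[0]] and after > vals[run[0]]:
            best = min(run, key=lambda kk: (abs(angles[idx[kk]]), kk))
            minima.append(idx[best])
    return [(float(angles[i]), float(energy[i])) for i in sorted(set(minima))]


def find_minima(profile: RotationProfile) -> MinimaReport:
    """Classify local minima into primary (within ±90° of native) and
    secondary (outside), each the deepest in its window."""
    if int(profile.unmasked.sum()) < 8:
        raise DegenerateProfileError("fewer than 8 unmasked poses")
    minima = _circular_local_minima(profile.angles, profile.energy,
                                    profile.clash_mask)
    inside = [m for m in minima if abs(m[0]) < PRIMARY_HALF_WINDOW]
    outside = [m for m in minima if abs(m[0]) >= PRIMARY_HALF_WINDOW]
    primary = min(inside, key=lambda m: (m[1], abs(m[0]))) if inside else None
    secondary = min(outside, key=lambda m: (m[1], abs(abs(m[0]) - 180.0))) \
        if outside else None
    diff = None
    if primary is not None and secondary is not None:
        diff = secondary[1] - primary[1]
    e_unmasked = profile.energy[profile.unmasked]
    global_min = float(e_unmasked.min())
    is_global = primary is not None and primary[1] <= global_min + 1e-9
    return MinimaReport(
        primary_minimum=None if primary is None else primary[0],
        secondary_minimum=None if secondary is None else secondary[0],
        energy_difference=diff,
        primary_is_global=is_global,
        amplitude=profile.amplitude,
        local_minima=tuple(minima))


# ---------------------------------------------------------------------------
# landscape and pulling
# ---------------------------------------------------------------------------

def landscape(structure, model, frame, separations,
              step: float = 5.0) -> list[RotationProfile | None]:
    """One rotation profile per separation; a row whose every pose clashes
    yields None instead of aborting the rest."""
    if any(s < 0 for s in separations):
        raise ConfigurationError("separations must be non-negative")
    rows = []
    for s in separations:
        try:
            rows.append(rotation_profile(structure, model, frame,
                                         separation=float(s), step=step))
        except DegenerateProfileError:
            rows.append(None)
    return rows


def _isolated_reference(structure, model):
    """GB and SASA of the two bodies at infinite separation."""
    mob = structure.is_mobile
    gb_ref = 0.0
    sasa_ref = 0.0
    for m in (mob, ~mob):
        idx = np.flatnonzero(m)
        body = _subset(structure, idx)
        gb_ref += gb_polar_energy(body, model)
        sasa_ref += sasa(body, model)
    return gb_ref, sasa_ref


def _subset(structure, idx):
    return ParameterizedStructure(
        serials=structure.serials[idx],
        names=[structure.names[i] for i in idx],
        resnames=[structure.resnames[i] for i in idx],
        residue_ids=[structure.residue_ids[i] for i in idx],
        positions=structure.positions[idx],
        charges=structure.charges[idx],
        lj_epsilon=structure.lj_epsilon[idx],
        lj_rmin_half=structure.lj_rmin_half[idx],
        intrinsic_radius=structure.intrinsic_radius[idx],
        hct_scale=structure.hct_scale[idx],
        is_mobile=structure.is_mobile[idx],
        subgroup=structure.subgroup[idx],
        built_h=structure.built_h[idx],
        provenance=structure.provenance)


def pulling_profile(structure: ParameterizedStructure, model: EnergyModel,
                    frame: ScanFrame, max_displacement: float = 40.0,
                    step: float = 0.1, include_sasa: bool = True,
                    barrier_tolerance: float = 0.05,
                    displacements: np.ndarray | None = None,
                    ) -> PullingProfile:
    """Full effective interaction energy along +x from the bound pose.

    Per displacement: inter-body shifted Coulomb + LJ, the change in total
    GB solvation relative to the isolated bodies (which includes mutual
    desolvation through the per-pose Born radii), and optionally the change
    in the gamma*SASA non-polar term.  A clash at displacement 0 (native
    contact) is tolerated; negative displacements are rejected.
    """
    if displacements is None:
        displacements = np.arange(0.0, max_displacement + 0.5 * step, step)
    displacements = np.asarray(displacements, dtype=float)
    if (displacements < 0).any():
        raise ConfigurationError("negative displacements rejected")
    gb_ref, sasa_ref = _isolated_reference(structure, model)
    energies = np.empty(len(displacements))
    comp = {"coulomb": np.empty(len(displacements)),
            "gb": np.empty(len(displacements)),
            "lj": np.empty(len(displacements)),
            "nonpolar": np.zeros(len(displacements))}
    for t, d in enumerate(displacements):
        posed = apply_pose(structure, frame, Pose(float(d), 0.0))
        radii = born_radii(posed, model)
        comp["coulomb"][t] = coulomb_energy(posed, model,
                                            interbody_only=True)
        comp["gb"][t] = gb_polar_energy(posed, model, radii) - gb_ref
        comp["lj"][t] = lj_energy(posed, model, interbody_only=True)
        if include_sasa:
            comp["nonpolar"][t] = model.sasa_gamma * (
                sasa(posed, model) - sasa_ref)
        energies[t] = (comp["coulomb"][t] + comp["gb"][t] + comp["lj"][t]
                       + comp["nonpolar"][t])
    plateau = float(energies[-1])
    well_depth = plateau - float(energies[0])
    kmax = int(np.argmax(energies))
    barrier_pos = barrier_height = None
    if 0 < kmax < len(energies) - 1 and \
            energies[kmax] > plateau + barrier_tolerance and \
            energies[kmax] > energies[0] + barrier_tolerance:
        barrier_pos = float(displacements[kmax])
        barrier_height = float(energies[kmax] - plateau)
    return PullingProfile(displacements=displacements, full_energy=energies,
                          barrier_position=barrier_pos,
                          barrier_height=barrier_height,
                          well_depth=well_depth, components=comp)
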