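"""Synthetic two-body complexes with known ground truth, written as valid
PDB files.

Every fixture is built from real amino-acid residues (ALA/GLY/ASP/LYS) at
idealized heavy-atom geometry so the bundled parameter table applies without
any special-case path; hydrogens are rebuilt on load like for any other
structure.  The mobile body always carries a neutral "stalk" of residues
extended along +x so its gyration-defined principal axis is the scan axis.

Fixtures:

* ``charge_ridge`` — complementary rings of charged residues facing each
  other across the interface; the construction places the polar-energy
  optimum at a requested rotation angle (an idealized version of the ring
  of charged interface residues that steers an approaching receptor).
* ``c2_dimer`` — a mobile body with exact two-fold symmetry about the scan
  axis, the negative control whose rotation profile must be 180°-periodic.
* ``mini_complex`` — a small general-purpose complex with MHC-, peptide-
  and CDR-labeled residues for end-to-end runs.
* ``barrier_complex`` — short-range attraction plus longer-range dipolar
  repulsion, so the pulling profile exhibits a binding barrier.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from ._geom import nerf, rotation_about_axis
from .structure_io import BodyAssignment, ParameterizedStructure, load_complex

__all__ = ["FixtureResult", "make_charge_ridge", "make_c2_dimer",
           "make_mini_complex", "make_barrier_complex", "load_fixture",
           "FIXTURE_MAKERS"]


@dataclass(frozen=True)
class FixtureResult:
    name: str
    pdb_path: Path
    assignment_path: Path
    truth_path: Path
    truth: dict


# ---------------------------------------------------------------------------
# idealized residue geometry (heavy atoms, local frame centered on centroid)
# ---------------------------------------------------------------------------

def _residue_heavy_coords(resname: str, cter: bool = False):
    n = np.array([-0.572, 1.343, 0.0])
    ca = np.zeros(3)
    c = np.array([1.52, 0.0, 0.0])
    coords = {"N": n, "CA": ca, "C": c,
              "O": nerf(n, ca, c, 1.23, 121.0, 0.0)}
    if cter:
        coords["OXT"] = nerf(n, ca, c, 1.25, 121.0, 180.0)
    if resname != "GLY":
        coords["CB"] = nerf(c, n, ca, 1.53, 110.5, -122.0)
    if resname == "ASP":
        cb = coords["CB"]
        cg = nerf(n, ca, cb, 1.52, 113.0, 180.0)
        coords["CG"] = cg
        coords["OD1"] = nerf(ca, cb, cg, 1.25, 119.0, 0.0)
        coords["OD2"] = nerf(ca, cb, cg, 1.25, 119.0, 180.0)
    elif resname == "LYS":
        cb = coords["CB"]
        cg = nerf(n, ca, cb, 1.52, 113.0, 180.0)
        cd = nerf(ca, cb, cg, 1.52, 111.0, 180.0)
        ce = nerf(cb, cg, cd, 1.52, 111.0, 180.0)
        nz = nerf(cg, cd, ce, 1.49, 111.0, 180.0)
        coords.update(CG=cg, CD=cd, CE=ce, NZ=nz)
    elif resname not in ("ALA", "GLY"):
        raise ValueError(f"fixture residue {resname!r} not supported")
    centroid = np.mean(list(coords.values()), axis=0)
    return {k: v - centroid for k, v in coords.items()}


def _place(resname: str, rotation: np.ndarray, translation: np.ndarray,
           cter: bool = False, mirror_yz: bool = False):
    """Placed heavy-atom dict; ``mirror_yz`` applies the exact two-fold
    rotation diag(1,-1,-1) AFTER placement (bitwise-symmetric partner)."""
    out = {}
    for name, p in _residue_heavy_coords(resname, cter=cter).items():
        q = rotation @ p + translation
        if mirror_yz:
            q = q * np.array([1.0, -1.0, -1.0])
        out[name] = q
    return out


_TIP_ATOMS = {"ASP": ("OD1", "OD2"), "LYS": ("NZ",), "ALA": ("CB",),
              "GLY": ("CA",)}


def _align(u: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector u onto unit vector d."""
    u = u / np.linalg.norm(u)
    d = d / np.linalg.norm(d)
    axis = np.cross(u, d)
    s = np.linalg.norm(axis)
    c = u @ d
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        from ._geom import any_perpendicular
        return rotation_about_axis(any_perpendicular(u), 180.0)
    return rotation_about_axis(axis, np.degrees(np.arctan2(s, c)))


def _place_tip(resname: str, tip_point: np.ndarray, direction: np.ndarray,
               spin_deg: float = 0.0, cter: bool = False):
    """Place a residue so its charged-group tip sits at ``tip_point`` and
    points along ``direction`` (the backbone trails the other way)."""
    coords = _residue_heavy_coords(resname, cter=cter)
    tip_local = np.mean([coords[a] for a in _TIP_ATOMS[resname]], axis=0)
    q = rotation_about_axis(direction, spin_deg) @ _align(tip_local,
                                                          direction)
    t = np.asarray(tip_point, dtype=float) - q @ tip_local
    return {name: q @ p + t for name, p in coords.items()}


def _write_pdb(path: Path, chains):
    """chains: list of (chain_id, [(resname, {atom: pos}), ...])."""
    serial = 0
    with open(path, "w") as fh:
        for chain_id, residues in chains:
            for resseq, (resname, coords) in enumerate(residues, start=1):
                for name, pos in coords.items():
                    serial += 1
                    field = name if len(name) == 4 else " " + name
                    fh.write(
                        f"ATOM  {serial:5d} {field:<4s} {resname:<3s} "
                        f"{chain_id}{resseq:4d}    "
                        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                        f"  1.00  0.00          {name[0]:>2s}\n")
            fh.write("TER\n")
        fh.write("END\n")


def _emit(out_dir, name, chains, assignment_cfg, truth) -> FixtureResult:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb = out_dir / f"{name}.pdb"
    _write_pdb(pdb, chains)
    apath = out_dir / f"{name}_assignment.yaml"
    with open(apath, "w") as fh:
        yaml.safe_dump(assignment_cfg, fh, sort_keys=True)
    tpath = out_dir / f"{name}_truth.json"
    with open(tpath, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return FixtureResult(name, pdb, apath, tpath, truth)


def load_fixture(result: FixtureResult
                 ) -> tuple[ParameterizedStructure, BodyAssignment]:
    assignment = BodyAssignment.from_yaml(result.assignment_path)
    return load_complex(result.pdb_path, assignment), assignment


def _stalk(x_positions, radius=3.2, resname="ALA", tilt=30.0):
    """C2-symmetric pairs of neutral residues strung along +x."""
    residues = []
    for k, x in enumerate(x_positions):
        rot = rotation_about_axis(np.array([1.0, 0.0, 0.0]), tilt * k)
        t = np.array([x, radius, 0.0])
        placed = _place(resname, rot, t)
        residues.append((resname, placed))
        residues.append((resname, {n: p * np.array([1.0, -1.0, -1.0])
                                   for n, p in placed.items()}))
    return residues


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_charge_ridge(seed: int, out_dir, n_charges: int = 6,
                      optimum_angle: float = 0.0, ring_radius: float = 8.0,
                      tip_overlap: float = 2.0) -> FixtureResult:
    """Complementary charged rings; polar optimum at ``optimum_angle``.

    The fixed body carries a ring of LYS side chains pointing toward the
    mobile body, with a single ASP at site 0; the mobile ring is the charge
    complement (ASP everywhere, LYS at site 0), its tips reaching
    ``tip_overlap`` Å past the fixed tip plane in the bound pose (side
    chains interdigitate, as at a real interface), and rotated by
    -optimum_angle so that the scan recovers the optimum at the requested
    angle.
    """
    if n_charges < 2:
        raise ValueError("n_charges must be >= 2")
    rng = np.random.default_rng(seed)
    xhat = np.array([1.0, 0.0, 0.0])
    step = 360.0 / n_charges

    def ring(x0, special, default, offset_deg, direction, jitter):
        # reference residue at site 0, copies rotated about the scan axis
        residues = []
        for k in range(n_charges):
            phi = k * step + offset_deg
            rot = rotation_about_axis(xhat, phi)
            resname = special if k == 0 else default
            ref = _place_tip(resname,
                             np.array([x0, ring_radius + jitter[k], 0.0]),
                             direction)
            residues.append((resname,
                             {n: rot @ p for n, p in ref.items()}))
        return residues

    jit_f = rng.uniform(-0.15, 0.15, n_charges)
    jit_m = rng.uniform(-0.15, 0.15, n_charges)
    fixed = ring(0.0, "ASP", "LYS", 0.0, np.array([1.0, 0.0, 0.0]), jit_f)
    mobile = ring(-tip_overlap, "LYS", "ASP", -optimum_angle,
                  np.array([-1.0, 0.0, 0.0]), jit_m)
    mobile += _stalk([8.0, 14.0, 20.0])
    cfg = {"bodies": {"A": "MOBILE", "B": "FIXED"},
           "subgroups": {"B": "MHC"},
           "options": {"neutral_termini": True}}
    truth = {"name": "charge_ridge", "seed": int(seed),
             "n_charges": int(n_charges),
             "optimum_angle_deg": float(optimum_angle),
             "ring_radius_A": float(ring_radius),
             "tip_overlap_A": float(tip_overlap)}
    return _emit(out_dir, "charge_ridge", [("A", mobile), ("B", fixed)],
                 cfg, truth)


def make_c2_dimer(seed: int, out_dir) -> FixtureResult:
    """Mobile body with exact C2 symmetry about the scan axis (the
    homodimer negative control): its rotation profile must have period
    180° and equal-depth primary/secondary minima."""
    rng = np.random.default_rng(seed)
    xhat = np.array([1.0, 0.0, 0.0])
    minus_x = np.array([-1.0, 0.0, 0.0])
    mobile = []
    # charged tips reach toward the fixed body so the profile has signal
    tips = [("LYS", 0.5, 5.0, 1.0, 20.0), ("ASP", 3.0, 4.5, -1.0, 140.0)]
    for resname, x, y, z, spin in tips:
        tip = np.array([x, y, z]) + rng.uniform(-0.1, 0.1, 3)
        placed = _place_tip(resname, tip, minus_x, spin_deg=spin)
        mobile.append((resname, placed))
        mobile.append((resname, {n: p * np.array([1.0, -1.0, -1.0])
                                 for n, p in placed.items()}))
    # neutral arms extended along +x dominate the gyration tensor
    arms = [("ALA", 14.0, 4.5, -1.5, 65.0), ("ALA", 22.0, 3.5, 1.0, 200.0),
            ("ALA", 30.0, 4.0, 0.0, 280.0)]
    for resname, x, y, z, spin in arms:
        t = np.array([x, y, z]) + rng.uniform(-0.1, 0.1, 3)
        placed = _place(resname, rotation_about_axis(xhat, spin), t)
        mobile.append((resname, placed))
        mobile.append((resname, {n: p * np.array([1.0, -1.0, -1.0])
                                 for n, p in placed.items()}))
    fixed = [("ASP", _place("ASP", np.eye(3), np.array([-2.0, 3.0, 1.0]))),
             ("ALA", _place("ALA", rotation_about_axis(xhat, 80.0),
                            np.array([-2.0, -4.0, 2.0]))),
             ("LYS", _place("LYS", rotation_about_axis(xhat, 160.0),
                            np.array([-4.0, 0.0, -3.0])))]
    cfg = {"bodies": {"A": "MOBILE", "B": "FIXED"},
           "subgroups": {"B": "MHC"},
           "options": {"neutral_termini": True}}
    truth = {"name": "c2_dimer", "seed": int(seed), "period_deg": 180.0}
    return _emit(out_dir, "c2_dimer", [("A", mobile), ("B", fixed)],
                 cfg, truth)


def make_mini_complex(seed: int, out_dir) -> FixtureResult:
    """Small general-purpose complex: a 6-residue mobile chain (with CDR
    labels), a 4-residue MHC-like fixed chain and a 2-residue peptide
    chain.  Net-neutral bodies; runs the full pipeline in seconds."""
    rng = np.random.default_rng(seed)
    xhat = np.array([1.0, 0.0, 0.0])
    minus_x = np.array([-1.0, 0.0, 0.0])
    # four binding-loop residues reach toward the interface (CDR-like),
    # two framework residues extend along +x to set the principal axis
    loop_spec = [("ALA", 2.0, 1.5, 0.0), ("ASP", 2.5, -2.0, 1.0),
                 ("ALA", 3.0, 3.5, -2.0), ("LYS", 3.5, -1.0, -3.8)]
    mobile = []
    for k, (resname, x, y, z) in enumerate(loop_spec):
        tip = np.array([x, y, z]) + rng.uniform(-0.2, 0.2, 3)
        mobile.append((resname, _place_tip(resname, tip, minus_x,
                                           spin_deg=30.0 * k)))
    frame_spec = [("ALA", 13.0, 2.0, 0.5), ("GLY", 20.0, -2.0, 1.0)]
    for k, (resname, x, y, z) in enumerate(frame_spec):
        t = np.array([x, y, z]) + rng.uniform(-0.2, 0.2, 3)
        mobile.append((resname, _place(
            resname, rotation_about_axis(xhat, 45.0 + 70.0 * k), t,
            cter=k == len(frame_spec) - 1)))
    fixed_spec = [("GLY", -10.0), ("LYS", -3.5), ("ALA", 3.5),
                  ("ASP", 10.0)]
    fixed = []
    for k, (resname, y) in enumerate(fixed_spec):
        tip = np.array([0.5, y, 0.0]) + rng.uniform(-0.2, 0.2, 3)
        fixed.append((resname, _place_tip(
            resname, tip, xhat, spin_deg=70.0 * k,
            cter=k == len(fixed_spec) - 1)))
    peptide = [("ALA", _place_tip("ALA",
                                  np.array([1.0, -1.5, 4.5])
                                  + rng.uniform(-0.2, 0.2, 3), xhat)),
               ("ALA", _place_tip("ALA",
                                  np.array([1.0, 1.5, -4.5])
                                  + rng.uniform(-0.2, 0.2, 3), xhat,
                                  spin_deg=120.0, cter=True))]
    cfg = {"bodies": {"A": "MOBILE", "B": "FIXED", "C": "FIXED"},
           "subgroups": {"B": "MHC", "C": "PEPTIDE"},
           "cdr_ranges": {"A": {"CDR3": [1, 2], "CDR1": [3, 3],
                                "CDR2": [4, 4]}},
           "options": {"neutral_termini": False}}
    truth = {"name": "mini_complex", "seed": int(seed),
             "n_mobile_residues": len(mobile),
             "n_fixed_residues": len(fixed_spec) + len(peptide)}
    return _emit(out_dir, "mini_complex",
                 [("A", mobile), ("B", fixed), ("C", peptide)], cfg, truth)


def make_barrier_complex(seed: int, out_dir, bridge_gap: float = 3.2,
                         dipole_span: float = 6.0) -> FixtureResult:
    """Staircase salt-bridge fixture: the closest inter-body contact is an
    opposite-charge pair (short-range attraction, buried on association)
    while the secondary like-charge pairs and the mutual desolvation repel
    at longer range, so the pulling profile shows a binding barrier."""
    rng = np.random.default_rng(seed)
    xhat = np.array([1.0, 0.0, 0.0])
    plus_x = np.array([1.0, 0.0, 0.0])
    minus_x = np.array([-1.0, 0.0, 0.0])

    def j():
        return rng.uniform(-0.1, 0.1, 3)

    # a ladder of salt bridges: fixed tips alternate ASP/LYS up the y axis,
    # mobile tips carry the complement one rung up, so each mobile tip
    # forms a bridge straight across while its diagonal neighbors repel
    fixed, mobile = [], []
    rungs = ["ASP", "LYS", "ASP", "LYS"]
    for k, resname in enumerate(rungs):
        fixed.append((resname, _place_tip(
            resname, np.array([0.0, dipole_span * k, 0.0]) + j(),
            plus_x, spin_deg=40.0 * k)))
    complement = {"ASP": "LYS", "LYS": "ASP"}
    for k, resname in enumerate(rungs[1:], start=1):
        mobile.append((complement[resname], _place_tip(
            complement[resname],
            np.array([bridge_gap, dipole_span * k, 0.0]) + j(),
            minus_x, spin_deg=180.0 + 40.0 * k)))
    for k in range(3):
        mobile.append(("ALA", _place(
            "ALA", rotation_about_axis(xhat, 45.0 * k),
            np.array([bridge_gap + 7.0 + 6.0 * k, dipole_span, 0.0])
            + j())))
    cfg = {"bodies": {"A": "MOBILE", "B": "FIXED"},
           "subgroups": {"B": "MHC"},
           "options": {"neutral_termini": True}}
    truth = {"name": "barrier_complex", "seed": int(seed),
             "bridge_gap_A": float(bridge_gap),
             "dipole_span_A": float(dipole_span)}
    return _emit(out_dir, "barrier_complex", [("A", mobile), ("B", fixed)],
                 cfg, truth)


FIXTURE_MAKERS = {
    "charge_ridge": make_charge_ridge,
    "c2_dimer": make_c2_dimer,
    "mini_complex": make_mini_complex,
    "barrier_complex": make_barrier_complex,
}
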