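"""Idealized placement of hydrogens missing from the input coordinates.

Partial charges live on hydrogens too, so the energy model needs them; when
a PDB file carries only heavy atoms the hydrogens are rebuilt from the
template connectivity at idealized geometry.  Placement is purely local:
tetrahedral/trigonal completion against the already-placed neighbors, with
staggered torsions for rotatable hydrogens.  The positions are deterministic
functions of the heavy-atom coordinates.
"""
from __future__ import annotations

import numpy as np

from ._geom import any_perpendicular, nerf, rotation_about_axis, unit
from .errors import ParameterizationError
from .params import ResidueTemplate

# X-H bond length by element of the parent heavy atom
_BOND = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}
_TET = 109.47  # idealized tetrahedral angle, degrees


def place_missing_hydrogens(template: ResidueTemplate,
                            coords: dict[str, np.ndarray],
                            prev_c: np.ndarray | None = None,
                            ignore_missing_parents: bool = False,
                            ) -> dict[str, np.ndarray]:
    """Return {hydrogen name: position} for template hydrogens absent
    from ``coords``.  ``prev_c`` is the carbonyl carbon of the preceding
    residue (used for the backbone amide hydrogen)."""
    missing: dict[str, list[str]] = {}
    for atom in template.atoms:
        if atom.element != "H" or atom.name in coords:
            continue
        bonded = template.bonded_to(atom.name)
        if len(bonded) != 1:
            raise ParameterizationError(
                f"hydrogen {atom.name} has {len(bonded)} bonds in template")
        missing.setdefault(bonded[0], []).append(atom.name)

    out: dict[str, np.ndarray] = {}
    for parent, hnames in missing.items():
        if parent not in coords:
            if ignore_missing_parents:
                continue
            raise ParameterizationError(
                f"cannot build {hnames}: parent atom {parent} missing")
        out.update(_place_on_parent(template, parent, hnames, coords, prev_c))
    return out


def _known_neighbors(template, parent, coords, prev_c):
    pos = [coords[n] for n in template.bonded_to(parent) if n in coords]
    names = [n for n in template.bonded_to(parent) if n in coords]
    if parent == "N" and prev_c is not None \
            and np.linalg.norm(prev_c - coords["N"]) < 1.8:
        pos.append(prev_c)
        names.append("-C")
    return names, pos


def _reference(template, parent, nbr_name, coords, prev_c):
    """An atom bonded to ``nbr_name`` other than ``parent`` (torsion ref)."""
    if nbr_name == "-C":
        return None
    for cand in template.bonded_to(nbr_name):
        if cand != parent and cand in coords:
            return coords[cand]
    if nbr_name == "N" and prev_c is not None:
        return prev_c
    return None


def _place_on_parent(template, parent, hnames, coords, prev_c):
    x = coords[parent]
    elem = parent[0]
    L = _BOND.get(elem, 1.09)
    nbr_names, nbrs = _known_neighbors(template, parent, coords, prev_c)
    n_h = len(hnames)
    out = {}
    if not nbrs:
        raise ParameterizationError(
            f"no placed neighbor of {parent} to orient hydrogens")

    if n_h == 1 and len(nbrs) >= 2:
        vec = -sum(unit(p - x) for p in nbrs)
        if np.linalg.norm(vec) < 1e-6:
            vec = any_perpendicular(nbrs[0] - x)
        out[hnames[0]] = x + L * unit(vec)
    elif n_h == 2 and len(nbrs) >= 2:
        u1, u2 = unit(nbrs[0] - x), unit(nbrs[1] - x)
        b = -unit(u1 + u2)
        c = unit(np.cross(u1, u2))
        half = np.deg2rad(_TET / 2)
        out[hnames[0]] = x + L * (b * np.cos(half) + c * np.sin(half))
        out[hnames[1]] = x + L * (b * np.cos(half) - c * np.sin(half))
    elif n_h == 2 and len(nbrs) == 1:
        # sp2 amide/guanidinium pair, in the plane of the reference atom
        n = nbrs[0]
        u = unit(n - x)
        ref = _reference(template, parent, nbr_names[0], coords, prev_c)
        v = any_perpendicular(u) if ref is None else _inplane(u, n, ref)
        s = np.sqrt(3.0) / 2
        out[hnames[0]] = x + L * (-0.5 * u + s * v)
        out[hnames[1]] = x + L * (-0.5 * u - s * v)
    elif n_h in (1, 3) and len(nbrs) == 1:
        # rotatable: anti to the reference, staggered triplet for methyls
        n = nbrs[0]
        ref = _reference(template, parent, nbr_names[0], coords, prev_c)
        if ref is None:
            ref = n + any_perpendicular(x - n)
        first = nerf(ref, n, x, L, _TET, 180.0)
        out[hnames[0]] = first
        if n_h == 3:
            axis = unit(x - n)
            for name, ang in zip(hnames[1:], (120.0, -120.0)):
                out[name] = x + rotation_about_axis(axis, ang) @ (first - x)
    else:
        raise ParameterizationError(
            f"unsupported hydrogen pattern on {parent}: "
            f"{n_h} H, {len(nbrs)} placed neighbors")
    return out


def _inplane(u, n, ref):
    r = ref - n
    v = r - (r @ u) * u
    if np.linalg.norm(v) < 1e-6:
        return any_perpendicular(u)
    return unit(v)
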