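"""Bundled force-field parameter table.

The package ships a single CHARMM-style all-atom protein residue-template
table (``data/residue_templates.json``): partial charges and Lennard-Jones
types per atom, covalent bonds (used to place missing hydrogens), and the
terminal patches.  Charges derive from the CHARMM22 protein topology mapped
onto PDB v3.3 atom names; intrinsic radii are Bondi-style element radii used
to seed Born-radius estimation; descreening scale factors are the standard
element-wise values of pairwise-descreening GB models.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .errors import ParameterizationError

__all__ = ["AtomTemplate", "ResidueTemplate", "ParameterTable", "load_table"]


@dataclass(frozen=True)
class AtomTemplate:
    name: str
    type: str
    charge: float
    element: str
    lj_epsilon: float
    lj_rmin_half: float
    intrinsic_radius: float
    hct_scale: float


@dataclass(frozen=True)
class ResidueTemplate:
    name: str
    formal_charge: float
    atoms: tuple[AtomTemplate, ...]
    bonds: tuple[tuple[str, str], ...]

    @property
    def atom_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.atoms)

    def atom(self, name: str) -> AtomTemplate:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    def bonded_to(self, name: str) -> tuple[str, ...]:
        out = []
        for a, b in self.bonds:
            if a == name:
                out.append(b)
            elif b == name:
                out.append(a)
        return tuple(out)


def _element(name: str) -> str:
    return name[0]


class ParameterTable:
    """Residue templates plus terminal patches."""

    def __init__(self, raw: dict):
        self.version: str = raw["version"]
        self._types = raw["atom_types"]
        self._radii = raw["element_radii"]
        self._scale = raw["hct_scale"]
        self.residues: dict[str, ResidueTemplate] = {}
        for rname, rdat in raw["residues"].items():
            self.residues[rname] = self._build(rname, rdat["formal_charge"],
                                               rdat["atoms"], rdat["bonds"])
        self._patches = raw["patches"]

    def _atom(self, name: str, atype: str, charge: float) -> AtomTemplate:
        el = _element(name)
        eps, rmin = self._types[atype]
        return AtomTemplate(name, atype, charge, el, eps, rmin,
                            self._radii[el], self._scale[el])

    def _build(self, rname, formal, atoms, bonds) -> ResidueTemplate:
        return ResidueTemplate(
            rname, formal,
            tuple(self._atom(n, t, q) for n, t, q in atoms),
            tuple((a, b) for a, b in bonds))

    def residue(self, resname: str) -> ResidueTemplate:
        try:
            return self.residues[resname]
        except KeyError:
            raise ParameterizationError(
                f"no residue template for {resname!r}") from None

    def patched(self, resname: str, *, nter: bool = False,
                cter: bool = False) -> ResidueTemplate:
        """Residue template with terminal patches applied."""
        tpl = self.residue(resname)
        if nter:
            if resname == "PRO":
                raise ParameterizationError(
                    "N-terminal proline patch is not supported")
            tpl = self._apply(tpl, "GLYP" if resname == "GLY" else "NTER")
        if cter:
            tpl = self._apply(tpl, "CTER")
        return tpl

    def _apply(self, tpl: ResidueTemplate, pname: str) -> ResidueTemplate:
        p = self._patches[pname]
        removed = set(p["remove"])
        mods = {m[0]: (m[1], m[2]) for m in p["modify"]}
        atoms = []
        for a in tpl.atoms:
            if a.name in removed:
                continue
            if a.name in mods:
                t, q = mods[a.name]
                atoms.append(self._atom(a.name, t, q))
            else:
                atoms.append(a)
        for n, t, q in p["add"]:
            atoms.append(self._atom(n, t, q))
        bonds = [b for b in tpl.bonds
                 if b[0] not in removed and b[1] not in removed]
        bonds += [(a, b) for a, b in p["add_bonds"]]
        return ResidueTemplate(tpl.name, tpl.formal_charge +
                               p["formal_charge_delta"],
                               tuple(atoms), tuple(bonds))


@lru_cache(maxsize=1)
def load_table() -> ParameterTable:
    with resources.files("orientscan.data").joinpath(
            "residue_templates.json").open() as fh:
        return ParameterTable(json.load(fh))
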