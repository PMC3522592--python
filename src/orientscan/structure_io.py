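"""Reading two-body complexes from PDB files and attaching parameters.

A complex is split into a MOBILE body (the receptor being scanned, e.g. the
TCR variable domains) and a FIXED body (e.g. peptide-MHC), chain by chain.
Residues are further labeled with sub-groups (MHC, PEPTIDE, B2M on the fixed
side; CDR1/CDR2/CDR3/FRAMEWORK on the mobile side) used by the energy
decomposition.  Every atom is matched against the bundled residue-template
table; unmatched residues or missing heavy atoms are hard errors, missing
hydrogens are rebuilt at idealized positions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
import yaml

from .errors import ConfigurationError, ParameterizationError
from .hydrogens import place_missing_hydrogens
from .params import ParameterTable, load_table

log = logging.getLogger(__name__)

MOBILE, FIXED = "MOBILE", "FIXED"
SUBGROUPS = ("MHC", "PEPTIDE", "B2M", "CDR1", "CDR2", "CDR3", "FRAMEWORK")
ResidueId = tuple[str, int, str]  # chain id, residue number, insertion code


@dataclass(frozen=True)
class Atom:
    """One parameterized atom."""
    serial: int
    name: str
    residue_name: str
    residue_id: ResidueId
    position: np.ndarray
    charge: float
    lj_epsilon: float
    lj_rmin_half: float
    intrinsic_radius: float


@dataclass
class BodyAssignment:
    """Chain-to-body mapping plus sub-group annotations.

    ``subgroup_of_chain`` labels fixed-body chains (MHC / PEPTIDE / B2M);
    ``cdr_ranges`` maps mobile chains to {loop name: [lo, hi] residue-number
    intervals}.  ``subgroup_of_residue`` holds explicit residue-level
    overrides and is also where resolved labels end up after loading.
    """
    body_of_chain: dict[str, str]
    subgroup_of_chain: dict[str, str] = field(default_factory=dict)
    cdr_ranges: dict[str, dict[str, list]] = field(default_factory=dict)
    subgroup_of_residue: dict[ResidueId, str] = field(default_factory=dict)
    neutral_termini: bool = False
    allow_missing: bool = False

    def __post_init__(self):
        for ch, body in self.body_of_chain.items():
            if body not in (MOBILE, FIXED):
                raise ConfigurationError(
                    f"chain {ch!r}: body must be MOBILE or FIXED, got {body!r}")
        for ch, grp in self.subgroup_of_chain.items():
            if grp not in ("MHC", "PEPTIDE", "B2M"):
                raise ConfigurationError(
                    f"chain {ch!r}: fixed-chain sub-group must be "
                    f"MHC/PEPTIDE/B2M, got {grp!r}")
            if self.body_of_chain.get(ch) != FIXED:
                raise ConfigurationError(
                    f"sub-group {grp} assigned to non-fixed chain {ch!r}")

    @classmethod
    def from_config(cls, cfg: dict) -> "BodyAssignment":
        opts = cfg.get("options", {})
        return cls(body_of_chain={str(k): str(v).upper()
                                  for k, v in cfg["bodies"].items()},
                   subgroup_of_chain={str(k): str(v).upper()
                                      for k, v in cfg.get("subgroups", {}).items()},
                   cdr_ranges={str(k): v for k, v in
                               cfg.get("cdr_ranges", {}).items()},
                   neutral_termini=bool(opts.get("neutral_termini", False)),
                   allow_missing=bool(opts.get("allow_missing", False)))

    @classmethod
    def from_yaml(cls, path) -> "BodyAssignment":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


class ParameterizedStructure:
    """Atoms of a two-body complex with charges, LJ parameters and labels.

    Data are stored column-wise in numpy arrays; :meth:`atom` materializes a
    single :class:`Atom` view when object access is more convenient.
    """

    def __init__(self, *, serials, names, resnames, residue_ids, positions,
                 charges, lj_epsilon, lj_rmin_half, intrinsic_radius,
                 hct_scale, is_mobile, subgroup, built_h, provenance):
        self.serials = np.asarray(serials, dtype=int)
        self.names = list(names)
        self.resnames = list(resnames)
        self.residue_ids: list[ResidueId] = list(residue_ids)
        self.positions = np.asarray(positions, dtype=float)
        self.charges = np.asarray(charges, dtype=float)
        self.lj_epsilon = np.asarray(lj_epsilon, dtype=float)
        self.lj_rmin_half = np.asarray(lj_rmin_half, dtype=float)
        self.intrinsic_radius = np.asarray(intrinsic_radius, dtype=float)
        self.hct_scale = np.asarray(hct_scale, dtype=float)
        self.is_mobile = np.asarray(is_mobile, dtype=bool)
        self.subgroup = np.asarray(subgroup, dtype=object)
        self.built_h = np.asarray(built_h, dtype=bool)
        self.provenance = dict(provenance)
        if not np.isfinite(self.positions).all():
            raise ParameterizationError("non-finite coordinates")

    # -- basic introspection -------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return self.n_atoms

    def atom(self, i: int) -> Atom:
        return Atom(int(self.serials[i]), self.names[i], self.resnames[i],
                    self.residue_ids[i], self.positions[i].copy(),
                    float(self.charges[i]), float(self.lj_epsilon[i]),
                    float(self.lj_rmin_half[i]),
                    float(self.intrinsic_radius[i]))

    def __iter__(self):
        return (self.atom(i) for i in range(self.n_atoms))

    def net_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def mobile_mask(self) -> np.ndarray:
        return self.is_mobile

    def atom_indices_of_residues(self, residues) -> np.ndarray:
        wanted = set(residues)
        return np.array([i for i, rid in enumerate(self.residue_ids)
                         if rid in wanted], dtype=int)

    def unique_residues(self) -> list[ResidueId]:
        seen, out = set(), []
        for rid in self.residue_ids:
            if rid not in seen:
                seen.add(rid)
                out.append(rid)
        return out

    def group_mask(self, group: str) -> np.ndarray:
        return self.subgroup == group

    # -- copies --------------------------------------------------------
    def copy(self) -> "ParameterizedStructure":
        return ParameterizedStructure(
            serials=self.serials.copy(), names=list(self.names),
            resnames=list(self.resnames), residue_ids=list(self.residue_ids),
            positions=self.positions.copy(), charges=self.charges.copy(),
            lj_epsilon=self.lj_epsilon.copy(),
            lj_rmin_half=self.lj_rmin_half.copy(),
            intrinsic_radius=self.intrinsic_radius.copy(),
            hct_scale=self.hct_scale.copy(), is_mobile=self.is_mobile.copy(),
            subgroup=self.subgroup.copy(), built_h=self.built_h.copy(),
            provenance=self.provenance)

    def with_positions(self, positions: np.ndarray) -> "ParameterizedStructure":
        s = self.copy()
        s.positions = np.array(positions, dtype=float)
        return s


def _iter_pdb_residues(pdb_path, chains):
    """Yield (chain, resname, resseq, icode, [(name, pos, altloc)]) for ATOM
    records of the requested chains, first model only."""
    st = gemmi.read_structure(str(pdb_path), merge_chain_parts=True)
    st.setup_entities()
    if len(st) == 0:
        raise ConfigurationError(f"no model in {pdb_path}")
    model = st[0]
    present = set()
    for chain in model:
        present.add(chain.name)
        if chain.name not in chains:
            continue
        for residue in chain:
            if residue.het_flag != "A":  # HETATM: ligands, waters, ions
                log.info("dropping HETATM residue %s %s", chain.name,
                         residue.name)
                continue
            atoms = []
            for at in residue:
                if at.altloc not in ("", "A", "\0"):
                    continue
                atoms.append((at.name, np.array([at.pos.x, at.pos.y, at.pos.z])))
            yield (chain.name, residue.name, residue.seqid.num,
                   residue.seqid.icode.strip(), atoms)
    missing = set(chains) - present
    if missing:
        raise ConfigurationError(
            f"chains {sorted(missing)} named in the assignment are absent "
            f"from {pdb_path}")
    ignored = present - set(chains)
    if ignored:
        log.info("chains %s present in file but not assigned; excluded",
                 sorted(ignored))


def load_complex(pdb_path, assignment: BodyAssignment,
                 table: ParameterTable | None = None) -> ParameterizedStructure:
    """Read ATOM records of the assigned chains and parameterize them.

    Raises :class:`ConfigurationError` for missing chains and
    :class:`ParameterizationError` for residues without a template or with
    missing heavy atoms (unless ``assignment.allow_missing``).
    """
    table = table or load_table()
    chains = set(assignment.body_of_chain)
    residues = list(_iter_pdb_residues(pdb_path, chains))
    if not residues:
        raise ConfigurationError(f"no assigned ATOM records in {pdb_path}")

    # group per chain to find true termini
    by_chain: dict[str, list[int]] = {}
    for idx, r in enumerate(residues):
        by_chain.setdefault(r[0], []).append(idx)

    cols = {k: [] for k in ("serials", "names", "resnames", "residue_ids",
                            "positions", "charges", "lj_epsilon",
                            "lj_rmin_half", "intrinsic_radius", "hct_scale",
                            "is_mobile", "subgroup", "built_h")}
    serial = 0
    expected_formal = 0.0
    charge_delta = 0.0
    for ch, idxs in by_chain.items():
        body = assignment.body_of_chain[ch]
        prev_c = None
        for k, idx in enumerate(idxs):
            _, resname, resseq, icode, atoms = residues[idx]
            rid: ResidueId = (ch, resseq, icode)
            nter = (k == 0) and not assignment.neutral_termini
            cter = (k == len(idxs) - 1) and not assignment.neutral_termini
            tpl = table.patched(resname, nter=nter, cter=cter)
            coords = {}
            for name, pos in atoms:
                if name == "OXT" and not cter:
                    raise ParameterizationError(
                        f"{rid}: OXT present but residue is not a "
                        "C-terminus under the neutral-termini option")
                if name not in tpl.atom_names:
                    raise ParameterizationError(
                        f"{rid} {resname}: atom {name!r} not in template")
                coords[name] = pos
            heavy_missing = [a.name for a in tpl.atoms
                             if a.element != "H" and a.name not in coords]
            if heavy_missing:
                if not assignment.allow_missing:
                    raise ParameterizationError(
                        f"{rid} {resname}: missing heavy atoms "
                        f"{heavy_missing} (rebuilding is not attempted)")
                dq = sum(tpl.atom(n).charge for n in heavy_missing)
                charge_delta -= dq
                log.warning("%s %s: missing heavy atoms %s; their charges "
                            "(%+.3f e) are dropped", rid, resname,
                            heavy_missing, dq)
            built = place_missing_hydrogens(
                tpl, coords, prev_c,
                ignore_missing_parents=assignment.allow_missing)
            # drop hydrogens that ride on missing heavy atoms
            placeable = {**coords, **built}
            expected_formal += tpl.formal_charge
            sub = _subgroup_for(assignment, body, ch, rid)
            for a in tpl.atoms:
                if a.name not in placeable:
                    # dropped atom (missing heavy under allow_missing, or a
                    # hydrogen riding on one); heavy charges were already
                    # subtracted above
                    if a.element == "H":
                        charge_delta -= a.charge
                    continue
                serial += 1
                cols["serials"].append(serial)
                cols["names"].append(a.name)
                cols["resnames"].append(resname)
                cols["residue_ids"].append(rid)
                cols["positions"].append(placeable[a.name])
                cols["charges"].append(a.charge)
                cols["lj_epsilon"].append(a.lj_epsilon)
                cols["lj_rmin_half"].append(a.lj_rmin_half)
                cols["intrinsic_radius"].append(a.intrinsic_radius)
                cols["hct_scale"].append(a.hct_scale)
                cols["is_mobile"].append(body == MOBILE)
                cols["subgroup"].append(sub)
                cols["built_h"].append(a.name in built)
            prev_c = coords.get("C")

    structure = ParameterizedStructure(
        **cols, provenance={"source": str(pdb_path),
                            "table_version": table.version})
    total = structure.net_charge()
    if abs(total - (expected_formal + charge_delta)) > 1e-6:
        raise ParameterizationError(
            f"net charge {total:.6f} e does not match the template sum "
            f"{expected_formal + charge_delta:.6f} e")
    if assignment.cdr_ranges:
        structure = assign_subgroups_from_ranges(structure,
                                                 assignment.cdr_ranges)
    return structure


def _subgroup_for(assignment, body, chain, rid):
    if rid in assignment.subgroup_of_residue:
        return assignment.subgroup_of_residue[rid]
    if body == MOBILE:
        return "FRAMEWORK"
    return assignment.subgroup_of_chain.get(chain, "MHC")


def assign_subgroups_from_ranges(structure: ParameterizedStructure,
                                 cdr_ranges: dict[str, dict[str, list]],
                                 ) -> ParameterizedStructure:
    """Label mobile-body residues inside the given residue-number intervals
    as CDR1/CDR2/CDR3; other mobile residues stay FRAMEWORK."""
    intervals = []  # (chain, lo, hi, loop)
    for ch, loops in cdr_ranges.items():
        for loop, rng in loops.items():
            if loop.upper() not in ("CDR1", "CDR2", "CDR3"):
                raise ConfigurationError(f"unknown CDR loop name {loop!r}")
            spans = rng if rng and isinstance(rng[0], (list, tuple)) else [rng]
            for lo, hi in spans:
                intervals.append((ch, int(lo), int(hi), loop.upper()))
    for i, (ch, lo, hi, loop) in enumerate(intervals):
        if lo > hi:
            raise ConfigurationError(f"{loop} interval [{lo},{hi}] inverted")
        for ch2, lo2, hi2, loop2 in intervals[i + 1:]:
            if ch == ch2 and lo <= hi2 and lo2 <= hi and loop != loop2:
                raise ConfigurationError(
                    f"overlapping intervals {loop}[{lo},{hi}] and "
                    f"{loop2}[{lo2},{hi2}] on chain {ch}")
    chain_res = {(rid[0], rid[1]) for rid in structure.residue_ids}
    for ch, lo, hi, loop in intervals:
        if not any(c == ch and lo <= num <= hi for c, num in chain_res):
            raise ConfigurationError(
                f"{loop} interval [{lo},{hi}] matches no residue of "
                f"chain {ch!r}")
    out = structure.copy()
    for i, rid in enumerate(out.residue_ids):
        if not out.is_mobile[i]:
            continue
        label = "FRAMEWORK"
        for ch, lo, hi, loop in intervals:
            if rid[0] == ch and lo <= rid[1] <= hi:
                label = loop
                break
        out.subgroup[i] = label
    return out


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_pdb(structure: ParameterizedStructure, path) -> None:
    """Write ATOM records (PDB v3.3 fixed columns)."""
    with open(path, "w") as fh:
        for i in range(structure.n_atoms):
            name = structure.names[i]
            field = name if (len(name) == 4 or name[0].isdigit()) \
                else " " + name
            ch, resseq, icode = structure.residue_ids[i]
            x, y, z = structure.positions[i]
            fh.write(
                f"ATOM  {structure.serials[i]:5d} {field:<4s} "
                f"{structure.resnames[i]:<3s} {ch[:1]:1s}{resseq:4d}"
                f"{(icode or ' '):1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}\n")
        fh.write("END\n")


def write_annotation_tsv(structure: ParameterizedStructure, path) -> None:
    """Sidecar table: serial, chain, residue, subgroup, charge, radius."""
    with open(path, "w") as fh:
        fh.write("serial\tchain\tresid\tname\tbody\tsubgroup\tcharge_e"
                 "\tintrinsic_radius_A\n")
        for i in range(structure.n_atoms):
            ch, num, icode = structure.residue_ids[i]
            body = MOBILE if structure.is_mobile[i] else FIXED
            fh.write(f"{structure.serials[i]}\t{ch}\t{num}{icode}\t"
                     f"{structure.names[i]}\t{body}\t{structure.subgroup[i]}"
                     f"\t{structure.charges[i]:.6f}\t"
                     f"{structure.intrinsic_radius[i]:.3f}\n")
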