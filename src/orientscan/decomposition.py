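"""Per-atom decomposition of the polar energy and sub-group aggregation.

Each pair energy is split half-and-half between its two atoms (the standard
MM-GBSA decomposition convention), so atom shares sum exactly to the total;
GB self terms belong entirely to their atom.  Sub-group vectors are computed
from inter-body shares only: intra-body pair energies are invariant under
rigid motion of a body and would only add a constant to a rotation profile.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import (EnergyModel, born_radii, coulomb_pair_matrix,
                     gb_pair_matrix)
from .errors import ConfigurationError
from .structure_io import ParameterizedStructure

__all__ = ["AtomContribution", "decompose_coulomb", "decompose_gb",
           "polar_shares", "group_polar_energy", "exclude_residues"]


@dataclass(frozen=True)
class AtomContribution:
    serial: int
    coulomb_share: float
    gb_share: float


def _cross_weight(structure, interbody_only: bool) -> np.ndarray:
    """Pair weight matrix: 1 for counted pairs, 0 otherwise (full matrix,
    both (i,j) and (j,i) present -- the half-share convention divides by 2)."""
    n = structure.n_atoms
    w = np.ones((n, n))
    np.fill_diagonal(w, 0.0)
    if interbody_only:
        mob = structure.is_mobile
        w *= (mob[:, None] ^ mob[None, :])
    return w


def decompose_coulomb(structure, model: EnergyModel,
                      interbody_only: bool = False) -> np.ndarray:
    """Per-atom Coulomb shares; shares sum to ``coulomb_energy``."""
    e = coulomb_pair_matrix(structure, model)
    w = _cross_weight(structure, interbody_only)
    return 0.5 * (e * w).sum(axis=1)


def decompose_gb(structure, model: EnergyModel,
                 radii: np.ndarray | None = None,
                 interbody_only: bool = False) -> np.ndarray:
    """Per-atom GB shares (self term included unless ``interbody_only``);
    shares sum to ``gb_polar_energy`` under the same flag."""
    if radii is None:
        radii = born_radii(structure, model)
    e = gb_pair_matrix(structure, model, radii)
    w = _cross_weight(structure, interbody_only)
    shares = 0.5 * (e * w).sum(axis=1)
    if not interbody_only:
        # self term: appears once in the half double sum, entirely atom i's
        shares = shares + 0.5 * np.diag(e)
    return shares


def atom_contributions(structure, model: EnergyModel,
                       radii: np.ndarray | None = None,
                       interbody_only: bool = False) -> list[AtomContribution]:
    cs = decompose_coulomb(structure, model, interbody_only)
    gs = decompose_gb(structure, model, radii, interbody_only)
    return [AtomContribution(int(structure.serials[i]), float(cs[i]),
                             float(gs[i]))
            for i in range(structure.n_atoms)]


def polar_shares(structure, model: EnergyModel,
                 radii: np.ndarray | None = None,
                 interbody_only: bool = True) -> np.ndarray:
    """coulomb_share + gb_share per atom."""
    return (decompose_coulomb(structure, model, interbody_only)
            + decompose_gb(structure, model, radii, interbody_only))


def group_polar_energy(structure, model: EnergyModel, atom_mask: np.ndarray,
                       radii: np.ndarray | None = None,
                       interbody_only: bool = True) -> float:
    """Polar energy share of an atom selection at the current pose."""
    if not np.asarray(atom_mask).any():
        raise ConfigurationError("empty atom selection")
    shares = polar_shares(structure, model, radii, interbody_only)
    return float(shares[np.asarray(atom_mask, dtype=bool)].sum())


def standard_groups(structure: ParameterizedStructure,
                    ) -> dict[str, np.ndarray]:
    """The four canonical sub-groups: MHC (with β2-microglobulin), peptide,
    CDR3, and CDR12 — the whole mobile body minus CDR3 (i.e. "the receptor
    without CDR3", which bundles CDR1, CDR2 and the framework).  Together
    they partition the system; empty groups are dropped."""
    sub = structure.subgroup
    mob = structure.is_mobile
    cand = {
        "MHC": ~mob & ((sub == "MHC") | (sub == "B2M")),
        "PEPTIDE": ~mob & (sub == "PEPTIDE"),
        "CDR3": mob & (sub == "CDR3"),
        "CDR12": mob & (sub != "CDR3"),
    }
    return {k: v for k, v in cand.items() if v.any()}


def group_profile(structure, model: EnergyModel, frame, group_mask,
                  separation: float = 8.0, step: float = 5.0):
    """Rotation-profile energy vector of one atom selection (W_sel),
    index-aligned with the system profile.  Returns (profile, vector)."""
    from .scan import group_profiles  # deferred: scan builds on this module
    profile, vecs = group_profiles(structure, model, frame,
                                   {"sel": group_mask},
                                   separation=separation, step=step)
    return profile, vecs["sel"]


def exclude_residues(structure: ParameterizedStructure,
                     residues) -> ParameterizedStructure:
    """Copy of the structure with the listed residues' charges zeroed.

    Geometry and LJ parameters are untouched, so clash masking is unchanged;
    only the polar terms lose those residues' contributions.
    """
    residues = list(residues)
    known = set(structure.residue_ids)
    unknown = [r for r in residues if r not in known]
    if unknown:
        raise ConfigurationError(f"unknown residues: {unknown}")
    out = structure.copy()
    idx = structure.atom_indices_of_residues(residues)
    out.charges[idx] = 0.0
    return out
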