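"""Energy terms: shifted Coulomb, Generalized-Born polar solvation with
pluggable Born radii, Lennard-Jones, and a SASA-proportional non-polar term.

The polar model is the classic two-dielectric continuum: charges interact in
vacuo through a shifted Coulomb potential (CHARMM energy-shift form, 12 Å
cutoff) and the solvent response is approximated by the Generalized Born
formula with the canonical Still interpolation

    f_GB(r, Ri, Rj) = sqrt(r^2 + Ri Rj exp(-r^2 / (4 Ri Rj)))

over per-atom Born radii.  Radii default to a Hawkins-Cramer-Truhlar-style
analytic pairwise-descreening estimate seeded from element radii; a
fixed-intrinsic mode (no descreening) and externally supplied radii are also
available.  All terms are strictly pairwise, hence exactly invariant under
global rigid motion of the whole system.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import SingularityError, UndefinedRadiusError

__all__ = ["EnergyModel", "coulomb_energy", "born_radii",
           "born_radius_from_engine", "gb_polar_energy", "lj_energy",
           "sasa", "sasa_nonpolar", "EnergyBreakdown", "energy_breakdown"]

COULOMB_K = 332.0716  # kcal*A/(mol*e^2)
_MIN_R = 1e-6         # overlap threshold, A
_MAX_BORN = 1000.0    # cap for fully buried atoms, A


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the effective-energy model."""
    eps_protein: float = 1.0
    eps_solvent: float = 80.0
    coulomb_constant: float = COULOMB_K
    cutoff: float = 12.0          # Coulomb shift / LJ switch-off, A
    lj_switch_on: float = 10.0    # LJ switch-on, A
    gb_radii_method: str = "pairwise_descreening"
    gb_pair_shift: bool = True    # shift GB pair terms like Coulomb
    external_radii: tuple | None = None
    hct_offset: float = 0.0       # subtracted from intrinsic radii, A
    sasa_gamma: float = 0.015     # kcal/(mol*A^2)
    probe_radius: float = 1.4     # A
    sasa_n_points: int = 256
    clash_lj_threshold: float = 10.0  # kcal/mol, residue-pair LJ
    clash_distance_floor: float = 1.0  # A

    def __post_init__(self):
        if not (self.eps_solvent > self.eps_protein >= 1.0):
            raise ValueError("require eps_solvent > eps_protein >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def tau(self) -> float:
        return self.coulomb_constant * (1.0 / self.eps_protein
                                        - 1.0 / self.eps_solvent)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Grouped energy terms, kcal/mol."""
    coulomb: float
    gb_polar: float
    lj: float
    sasa_nonpolar: float

    @property
    def polar_total(self) -> float:
        return self.coulomb + self.gb_polar

    @property
    def full_total(self) -> float:
        return self.polar_total + self.lj + self.sasa_nonpolar


# ---------------------------------------------------------------------------
# pair scaffolding
# ---------------------------------------------------------------------------

def _distance_matrix(structure) -> np.ndarray:
    p = structure.positions
    d = p[:, None, :] - p[None, :, :]
    return np.sqrt((d * d).sum(-1))


def _pair_mask(structure, interbody_only: bool) -> np.ndarray:
    """Boolean (N, N) mask of unordered pairs counted once (upper triangle)."""
    n = structure.n_atoms
    mask = np.triu(np.ones((n, n), dtype=bool), k=1)
    if interbody_only:
        mob = structure.is_mobile
        cross = mob[:, None] ^ mob[None, :]
        mask &= cross
    return mask


def _check_overlaps(r, mask):
    bad = mask & (r < _MIN_R)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise SingularityError(
            f"atoms {i} and {j} overlap (r = {r[i, j]:.2e} A)")


def coulomb_shift(r: np.ndarray, cutoff: float) -> np.ndarray:
    """CHARMM energy-shift factor S(r) = (1 - (r/rc)^2)^2, zero beyond rc."""
    s = (1.0 - (r / cutoff) ** 2) ** 2
    return np.where(r <= cutoff, s, 0.0)


# ---------------------------------------------------------------------------
# Coulomb
# ---------------------------------------------------------------------------

def coulomb_pair_matrix(structure, model: EnergyModel) -> np.ndarray:
    """Symmetric matrix of pair Coulomb energies (zero diagonal)."""
    r = _distance_matrix(structure)
    np.fill_diagonal(r, np.inf)
    q = structure.charges
    e = (model.coulomb_constant / model.eps_protein) \
        * q[:, None] * q[None, :] / r * coulomb_shift(r, model.cutoff)
    return e


def coulomb_energy(structure, model: EnergyModel,
                   interbody_only: bool = False) -> float:
    """Shifted-Coulomb energy, kcal/mol, summed over unordered pairs."""
    r = _distance_matrix(structure)
    mask = _pair_mask(structure, interbody_only)
    _check_overlaps(r, mask)
    np.fill_diagonal(r, np.inf)
    e = coulomb_pair_matrix(structure, model)
    return float(e[mask].sum())


# ---------------------------------------------------------------------------
# Born radii
# ---------------------------------------------------------------------------

def born_radii(structure, model: EnergyModel) -> np.ndarray:
    """Per-atom Born radii (Å) by the configured estimator.

    ``pairwise_descreening``: HCT analytic integral over scaled neighbor
    spheres.  ``fixed_intrinsic``: the intrinsic radii unchanged.
    ``external``: radii supplied on the model.  An isolated atom always
    recovers its intrinsic radius.
    """
    method = model.gb_radii_method
    rho = structure.intrinsic_radius - model.hct_offset
    if (rho <= 0).any():
        raise ValueError("non-positive reduced intrinsic radius")
    if method == "fixed_intrinsic":
        return structure.intrinsic_radius.astype(float).copy()
    if method == "external":
        if model.external_radii is None:
            raise ValueError("external radii requested but none supplied")
        radii = np.asarray(model.external_radii, dtype=float)
        if radii.shape != (structure.n_atoms,):
            raise ValueError("external radii length mismatch")
        return radii.copy()
    if method != "pairwise_descreening":
        raise ValueError(f"unknown gb_radii_method {method!r}")

    r = _distance_matrix(structure)
    n = structure.n_atoms
    sr = (structure.hct_scale * rho)[None, :]       # scaled descreener radius
    rho_i = rho[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        U = 1.0 / (r + sr)
        L = 1.0 / np.maximum(rho_i, np.abs(r - sr))
        integral = 0.5 * (L - U
                          + 0.25 * (r - sr ** 2 / r) * (U ** 2 - L ** 2)
                          + 0.5 / r * np.log(U / L))
        # atom i fully inside the descreening sphere of j
        inside = sr - r > rho_i
        integral = np.where(inside,
                            integral + 2.0 * (1.0 / rho_i - L), integral)
        # no contribution when sphere j is engulfed by rho_i
        integral = np.where(r + sr <= rho_i, 0.0, integral)
    np.fill_diagonal(integral, 0.0)
    inv = 1.0 / rho - integral.sum(axis=1)
    radii = np.where(inv > 1.0 / _MAX_BORN, 1.0 / np.maximum(inv, 1e-12),
                     _MAX_BORN)
    return radii


def gb_pair_matrix(structure, model: EnergyModel,
                   radii: np.ndarray) -> np.ndarray:
    """Matrix of -tau * qi qj / f_GB including the diagonal self terms.

    With ``model.gb_pair_shift`` (the default) the off-diagonal pair terms
    are attenuated by the same energy-shift factor as the Coulomb term, so
    that the screened pair interaction  qi qj (k/r - tau/f_GB) S(r)  keeps a
    physical sign at every distance and vanishes smoothly at the cutoff;
    self terms are never truncated.
    """
    if (np.asarray(radii) <= 0).any():
        raise ValueError("non-positive Born radius")
    r = _distance_matrix(structure)
    rr = radii[:, None] * radii[None, :]
    f = np.sqrt(r ** 2 + rr * np.exp(-r ** 2 / (4.0 * rr)))
    q = structure.charges
    e = -model.tau * q[:, None] * q[None, :] / f
    if model.gb_pair_shift:
        sw = coulomb_shift(r, model.cutoff)
        np.fill_diagonal(sw, 1.0)
        e = e * sw
    return e


def gb_polar_energy(structure, model: EnergyModel,
                    radii: np.ndarray | None = None,
                    interbody_only: bool = False) -> float:
    """Generalized-Born polar solvation energy, kcal/mol.

    The full energy is the half double sum including self terms; with
    ``interbody_only`` it reduces to the mobile-fixed cross terms (each
    unordered cross pair counted once, no self terms).
    """
    if radii is None:
        radii = born_radii(structure, model)
    e = gb_pair_matrix(structure, model, radii)
    if interbody_only:
        mob = structure.is_mobile
        return float(e[np.ix_(mob, ~mob)].sum())
    return float(0.5 * e.sum())


def born_radius_from_engine(structure, model: EnergyModel, atom_index: int,
                            radii: np.ndarray | None = None) -> float:
    """Operational Born radius of one atom: charge the system with only that
    atom's charge, take the engine's solvation energy dG_i, and invert the
    Born formula  R_i = -tau * q_i^2 / (2 dG_i)."""
    q = structure.charges[atom_index]
    if q == 0.0:
        raise UndefinedRadiusError(
            f"atom {atom_index} has zero charge; Born radius undefined")
    solo = structure.copy()
    solo.charges = np.zeros_like(solo.charges)
    solo.charges[atom_index] = q
    if radii is None:
        radii = born_radii(structure, model)
    dg = gb_polar_energy(solo, model, radii=radii)
    return float(-model.tau * q * q / (2.0 * dg))


# ---------------------------------------------------------------------------
# Lennard-Jones
# ---------------------------------------------------------------------------

def lj_switch(r: np.ndarray, r_on: float, r_off: float) -> np.ndarray:
    """CHARMM switching function: 1 below r_on, 0 beyond r_off."""
    denom = (r_off ** 2 - r_on ** 2) ** 3
    sw = ((r_off ** 2 - r ** 2) ** 2
          * (r_off ** 2 + 2.0 * r ** 2 - 3.0 * r_on ** 2)) / denom
    out = np.where(r <= r_on, 1.0, sw)
    return np.where(r >= r_off, 0.0, out)


def lj_pair_matrix(structure, model: EnergyModel) -> np.ndarray:
    """Symmetric matrix of switched 12-6 pair energies (zero diagonal)."""
    r = _distance_matrix(structure)
    np.fill_diagonal(r, np.inf)
    eps = np.sqrt(structure.lj_epsilon[:, None]
                  * structure.lj_epsilon[None, :])
    rmin = structure.lj_rmin_half[:, None] + structure.lj_rmin_half[None, :]
    x6 = (rmin / r) ** 6
    e = eps * (x6 * x6 - 2.0 * x6) * lj_switch(r, model.lj_switch_on,
                                               model.cutoff)
    return e


def lj_energy(structure, model: EnergyModel,
              interbody_only: bool = False) -> float:
    """Lennard-Jones 12-6 energy with Lorentz-Berthelot combination and a
    [switch_on, cutoff] switching window, kcal/mol."""
    r = _distance_matrix(structure)
    mask = _pair_mask(structure, interbody_only)
    _check_overlaps(r, mask)
    e = lj_pair_matrix(structure, model)
    return float(e[mask].sum())


def lj_residue_pair_energy(structure, model: EnergyModel,
                           rid_a, rid_b) -> float:
    """Switched LJ energy between the atoms of two residues (clash probe)."""
    ia = structure.atom_indices_of_residues([rid_a])
    ib = structure.atom_indices_of_residues([rid_b])
    e = lj_pair_matrix(structure, model)
    return float(e[np.ix_(ia, ib)].sum())


# ---------------------------------------------------------------------------
# SASA non-polar term
# ---------------------------------------------------------------------------

def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def _canonical_positions(positions: np.ndarray) -> np.ndarray:
    """Express coordinates in a body-fixed principal-axis frame so the
    sphere-point sampling (and hence SASA) is invariant under global rigid
    motion of the input."""
    c = positions.mean(axis=0)
    rel = positions - c
    if len(rel) < 3:
        return rel
    cov = rel.T @ rel
    _, evecs = np.linalg.eigh(cov)
    axes = evecs[:, ::-1]
    for k in range(2):
        proj = rel @ axes[:, k]
        skew = (proj ** 3).sum()
        if abs(skew) < 1e-9:  # symmetric direction: orient by extreme atom
            skew = proj[np.argmax(np.abs(proj))]
        if skew < 0:
            axes[:, k] = -axes[:, k]
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    return rel @ axes


def sasa(structure, model: EnergyModel,
         indices: np.ndarray | None = None) -> float:
    """Solvent-accessible surface area (Å^2) of a subset (default: all) by
    Shrake-Rupley sampling on a fixed golden-spiral point set."""
    if indices is None:
        indices = np.arange(structure.n_atoms)
    pos = _canonical_positions(structure.positions[indices])
    radii = structure.intrinsic_radius[indices] + model.probe_radius
    pts = _golden_spiral(model.sasa_n_points)
    tree = cKDTree(pos)
    rmax = radii.max()
    area = 0.0
    for i in range(len(pos)):
        sphere = pos[i] + radii[i] * pts
        nbrs = [j for j in tree.query_ball_point(pos[i], radii[i] + rmax)
                if j != i]
        exposed = np.ones(len(pts), dtype=bool)
        for j in nbrs:
            d2 = ((sphere - pos[j]) ** 2).sum(axis=1)
            exposed &= d2 > radii[j] ** 2
        area += 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    return float(area)


def sasa_nonpolar(structure, model: EnergyModel,
                  indices: np.ndarray | None = None) -> float:
    """gamma * SASA, kcal/mol."""
    return model.sasa_gamma * sasa(structure, model, indices)


# ---------------------------------------------------------------------------
# combined
# ---------------------------------------------------------------------------

def energy_breakdown(structure, model: EnergyModel,
                     interbody_only: bool = False,
                     radii: np.ndarray | None = None) -> EnergyBreakdown:
    if radii is None:
        radii = born_radii(structure, model)
    return EnergyBreakdown(
        coulomb=coulomb_energy(structure, model, interbody_only),
        gb_polar=gb_polar_energy(structure, model, radii, interbody_only),
        lj=lj_energy(structure, model, interbody_only),
        sasa_nonpolar=sasa_nonpolar(structure, model))
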