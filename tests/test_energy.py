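"""Energy-term unit tests against closed forms and brute-force oracles."""
import math

import numpy as np
import pytest
from conftest import build_structure, random_charged_structure

from orientscan.energy import (COULOMB_K, EnergyModel, born_radii,
                               born_radius_from_engine, coulomb_energy,
                               gb_polar_energy, lj_energy, sasa,
                               sasa_nonpolar)
from orientscan.errors import SingularityError, UndefinedRadiusError

TAU = COULOMB_K * (1 - 1 / 80)


# ---------------------------------------------------------------------------
# independent scalar-loop oracles (deliberately naive)
# ---------------------------------------------------------------------------

def shift(r, rc):
    return (1 - (r / rc) ** 2) ** 2 if r <= rc else 0.0


def brute_coulomb(st, m, interbody=False):
    total = 0.0
    for i in range(st.n_atoms):
        for j in range(i + 1, st.n_atoms):
            if interbody and st.is_mobile[i] == st.is_mobile[j]:
                continue
            r = math.dist(st.positions[i], st.positions[j])
            total += (m.coulomb_constant / m.eps_protein * st.charges[i]
                      * st.charges[j] / r * shift(r, m.cutoff))
    return total


def brute_lj(st, m, interbody=False):
    def sw(r):
        on, off = m.lj_switch_on, m.cutoff
        if r <= on:
            return 1.0
        if r >= off:
            return 0.0
        return ((off ** 2 - r ** 2) ** 2 * (off ** 2 + 2 * r ** 2
                - 3 * on ** 2)) / (off ** 2 - on ** 2) ** 3

    total = 0.0
    for i in range(st.n_atoms):
        for j in range(i + 1, st.n_atoms):
            if interbody and st.is_mobile[i] == st.is_mobile[j]:
                continue
            r = math.dist(st.positions[i], st.positions[j])
            eps = math.sqrt(st.lj_epsilon[i] * st.lj_epsilon[j])
            rmin = st.lj_rmin_half[i] + st.lj_rmin_half[j]
            x6 = (rmin / r) ** 6
            total += eps * (x6 * x6 - 2 * x6) * sw(r)
    return total


def brute_gb(st, m, radii):
    tau = m.coulomb_constant * (1 / m.eps_protein - 1 / m.eps_solvent)
    total = 0.0
    for i in range(st.n_atoms):
        for j in range(st.n_atoms):
            r = math.dist(st.positions[i], st.positions[j])
            f = math.sqrt(r * r + radii[i] * radii[j]
                          * math.exp(-r * r / (4 * radii[i] * radii[j])))
            s = 1.0 if i == j else (shift(r, m.cutoff)
                                    if m.gb_pair_shift else 1.0)
            total += -0.5 * tau * st.charges[i] * st.charges[j] / f * s
    return total


def brute_hct(st, offset=0.0):
    """Independent pairwise-descreening integral (scalar form)."""
    n = st.n_atoms
    out = np.empty(n)
    for i in range(n):
        rho = st.intrinsic_radius[i] - offset
        acc = 0.0
        for j in range(n):
            if j == i:
                continue
            r = math.dist(st.positions[i], st.positions[j])
            sr = st.hct_scale[j] * (st.intrinsic_radius[j] - offset)
            if rho >= r + sr:
                continue
            L = 1.0 / max(rho, abs(r - sr))
            U = 1.0 / (r + sr)
            term = 0.5 * (L - U + 0.25 * (r - sr * sr / r)
                          * (U * U - L * L) + 0.5 / r * math.log(U / L))
            if rho < sr - r:
                term += 2.0 * (1.0 / rho - L)
            acc += term
        inv = 1.0 / rho - acc
        out[i] = 1.0 / inv if inv > 1e-3 else 1000.0
    return out


# ---------------------------------------------------------------------------
# Coulomb
# ---------------------------------------------------------------------------

class TestCoulomb:
    def test_shift_reaches_zero_at_cutoff(self, model):
        st = build_structure([[0, 0, 0], [12.0, 0, 0]], charges=[1, -1])
        assert coulomb_energy(st, model) == 0.0

    def test_hand_evaluated_pair(self, model):
        st = build_structure([[0, 0, 0], [3.32, 0, 0]], charges=[1, -1])
        expected = COULOMB_K * (-1.0) / 3.32 * (1 - (3.32 / 12) ** 2) ** 2
        assert coulomb_energy(st, model) == pytest.approx(expected,
                                                          abs=1e-10)
        assert expected == pytest.approx(-85.3, abs=0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, model, seed):
        st = random_charged_structure(np.random.default_rng(seed))
        assert coulomb_energy(st, model) == pytest.approx(
            brute_coulomb(st, model), abs=1e-10)
        assert coulomb_energy(st, model, interbody_only=True) == \
            pytest.approx(brute_coulomb(st, model, True), abs=1e-10)

    def test_overlapping_atoms_raise(self, model):
        st = build_structure([[0, 0, 0], [0, 0, 1e-9]], charges=[1, 1])
        with pytest.raises(SingularityError):
            coulomb_energy(st, model)


# ---------------------------------------------------------------------------
# Born radii
# ---------------------------------------------------------------------------

class TestBornRadii:
    def test_isolated_atom_recovers_intrinsic(self, model):
        st = build_structure([[0, 0, 0]], charges=[1.0],
                             intrinsic_radius=[1.5])
        assert born_radii(st, model)[0] == pytest.approx(1.5, abs=1e-12)

    def test_burial_increases_radius(self, model):
        center = [[0.0, 0.0, 0.0]]
        shell = [[2.8 * x, 2.8 * y, 2.8 * z]
                 for x, y, z in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                 (0, -1, 0), (0, 0, 1), (0, 0, -1)]]
        st = build_structure(center + shell)
        buried = born_radii(st, model)[0]
        iso = st.intrinsic_radius[0]
        assert buried > iso

    def test_five_atom_line_matches_independent_integral(self, model):
        pos = [[2.1 * k, 0, 0] for k in range(5)]
        st = build_structure(pos, intrinsic_radius=[1.3, 1.6, 1.5, 1.4, 1.7],
                             hct_scale=[0.85, 0.72, 0.79, 0.85, 0.96])
        np.testing.assert_allclose(born_radii(st, model), brute_hct(st),
                                   rtol=0, atol=1e-12)

    def test_radii_never_below_intrinsic_floor(self, model):
        rng = np.random.default_rng(11)
        st = random_charged_structure(rng, n=30, box=5.0)
        radii = born_radii(st, model)
        assert np.all(radii >= 0.8 * st.intrinsic_radius)
        assert np.all(np.isfinite(radii))

    def test_fixed_intrinsic_mode(self):
        m = EnergyModel(gb_radii_method="fixed_intrinsic")
        st = build_structure([[0, 0, 0], [2, 0, 0]],
                             intrinsic_radius=[1.4, 1.9])
        np.testing.assert_array_equal(born_radii(st, m), [1.4, 1.9])

    def test_external_mode(self):
        st = build_structure([[0, 0, 0], [2, 0, 0]])
        m = EnergyModel(gb_radii_method="external",
                        external_radii=(2.2, 3.3))
        np.testing.assert_array_equal(born_radii(st, m), [2.2, 3.3])


class TestBornRadiusFromEngine:
    def test_single_ion_round_trip(self, model):
        st = build_structure([[0, 0, 0]], charges=[1.0],
                             intrinsic_radius=[2.0])
        assert born_radius_from_engine(st, model, 0) == pytest.approx(
            2.0, abs=1e-12)

    def test_round_trip_on_random_system(self, model):
        st = random_charged_structure(np.random.default_rng(2), n=10)
        radii = born_radii(st, model)
        for i in range(st.n_atoms):
            got = born_radius_from_engine(st, model, i)
            assert got == pytest.approx(radii[i], abs=1e-9)

    def test_zero_charge_atom_raises(self, model):
        st = build_structure([[0, 0, 0]], charges=[0.0])
        with pytest.raises(UndefinedRadiusError):
            born_radius_from_engine(st, model, 0)


# ---------------------------------------------------------------------------
# GB polar energy
# ---------------------------------------------------------------------------

class TestGBPolar:
    def test_born_ion_closed_form(self, model):
        st = build_structure([[0, 0, 0]], charges=[1.0],
                             intrinsic_radius=[2.0])
        expected = -TAU / 2 / 2.0
        assert gb_polar_energy(st, model) == pytest.approx(expected,
                                                           abs=1e-9)
        assert expected == pytest.approx(-81.98, abs=0.01)

    def test_zero_charges_zero_energy(self, model):
        st = build_structure(np.random.default_rng(0).uniform(0, 5, (6, 3)))
        assert gb_polar_energy(st, model) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, model, seed):
        st = random_charged_structure(np.random.default_rng(100 + seed),
                                      n=15)
        radii = born_radii(st, model)
        assert gb_polar_energy(st, model, radii) == pytest.approx(
            brute_gb(st, model, radii), abs=1e-10)

    def test_self_term_sum_is_negative_and_exact(self, model):
        st = random_charged_structure(np.random.default_rng(3), n=12)
        radii = born_radii(st, model)
        self_sum = float(np.sum(-TAU * st.charges ** 2 / (2 * radii)))
        assert self_sum < 0
        solo = st.copy()
        # with all atoms infinitely apart, only self terms remain
        solo.positions = solo.positions + np.arange(12)[:, None] * 500.0
        assert gb_polar_energy(solo, model, radii) == pytest.approx(
            self_sum, abs=1e-8)

    def test_nonpositive_radius_raises(self, model):
        st = build_structure([[0, 0, 0]], charges=[1.0])
        with pytest.raises(ValueError):
            gb_polar_energy(st, model, radii=np.array([-1.0]))

    def test_interbody_polar_vanishes_far_away(self, model):
        st = random_charged_structure(np.random.default_rng(4), n=10)

        def inter_at(sep):
            moved = st.copy()
            moved.positions = moved.positions.copy()
            moved.positions[moved.is_mobile] += np.array([sep + 30, 0, 0])
            radii = born_radii(moved, model)
            return abs(coulomb_energy(moved, model, True)
                       + gb_polar_energy(moved, model, radii, True))

        vals = [inter_at(s) for s in (0.0, 10.0, 20.0, 40.0)]
        assert vals[-1] == 0.0
        assert all(a >= b for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# Lennard-Jones
# ---------------------------------------------------------------------------

class TestLJ:
    def test_minimum_depth_at_rmin(self, model):
        st = build_structure([[0, 0, 0], [3.4, 0, 0]], lj_epsilon=[0.2, 0.2],
                             lj_rmin_half=[1.7, 1.7])
        assert lj_energy(st, model) == pytest.approx(-0.2, abs=1e-12)

    def test_zero_beyond_cutoff(self, model):
        st = build_structure([[0, 0, 0], [12.5, 0, 0]])
        assert lj_energy(st, model) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, model, seed):
        st = random_charged_structure(np.random.default_rng(200 + seed))
        assert lj_energy(st, model) == pytest.approx(brute_lj(st, model),
                                                     abs=1e-10)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

class TestSasa:
    def test_single_sphere_closed_form(self, model):
        st = build_structure([[0, 0, 0]], intrinsic_radius=[1.8])
        exact = 4 * np.pi * (1.8 + 1.4) ** 2
        assert sasa(st, model) == pytest.approx(exact, rel=0.005)

    def test_far_spheres_additive(self, model):
        st = build_structure([[0, 0, 0], [50, 0, 0]],
                             intrinsic_radius=[1.5, 1.9])
        lone1 = build_structure([[0, 0, 0]], intrinsic_radius=[1.5])
        lone2 = build_structure([[0, 0, 0]], intrinsic_radius=[1.9])
        assert sasa(st, model) == pytest.approx(
            sasa(lone1, model) + sasa(lone2, model), rel=1e-9)

    def test_caged_atom_is_buried(self, model):
        # a tight shell of large spheres swallows the central atom
        phi = (1 + 5 ** 0.5) / 2
        verts = []
        for a in (-1, 1):
            for b in (-phi, phi):
                verts += [(0, a, b), (a, b, 0), (b, 0, a)]
        verts = 1.9 * np.array(verts) / np.linalg.norm(verts[0])
        st = build_structure(np.vstack([[0, 0, 0], verts]),
                             intrinsic_radius=[1.2] + [2.0] * 12)
        per_atom_area = []
        m = model
        for i in range(st.n_atoms):
            pass  # central-atom burial checked via subtraction below
        cage = build_structure(verts, intrinsic_radius=[2.0] * 12)
        assert sasa(st, m) == pytest.approx(sasa(cage, m), rel=1e-6)

    def test_nonpolar_is_gamma_times_area(self, model):
        st = build_structure([[0, 0, 0]], intrinsic_radius=[1.5])
        assert sasa_nonpolar(st, model) == pytest.approx(
            model.sasa_gamma * sasa(st, model), abs=1e-12)


# ---------------------------------------------------------------------------
# rigid-motion invariance (pairwise terms are exactly invariant; SASA is
# sampled in a body-fixed frame so it is too)
# ---------------------------------------------------------------------------

def test_rigid_invariance_of_all_terms(mini, model):
    # the reported terms: inter-body Coulomb/LJ, full GB, SASA non-polar
    from scipy.spatial.transform import Rotation

    st = mini["structure"]
    radii0 = born_radii(st, model)
    ref = {
        "coulomb": coulomb_energy(st, model, interbody_only=True),
        "gb": gb_polar_energy(st, model, radii0),
        "gb_inter": gb_polar_energy(st, model, radii0, interbody_only=True),
        "lj": lj_energy(st, model, interbody_only=True),
        "sasa": sasa_nonpolar(st, model),
    }
    rng = np.random.default_rng(42)
    for _ in range(5):
        rot = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-20, 20, 3)
        moved = st.with_positions(st.positions @ rot.T + t)
        radii = born_radii(moved, model)
        assert coulomb_energy(moved, model, interbody_only=True) == \
            pytest.approx(ref["coulomb"], abs=1e-9)
        assert gb_polar_energy(moved, model, radii) == pytest.approx(
            ref["gb"], abs=1e-9)
        assert gb_polar_energy(moved, model, radii, interbody_only=True) \
            == pytest.approx(ref["gb_inter"], abs=1e-9)
        assert lj_energy(moved, model, interbody_only=True) == \
            pytest.approx(ref["lj"], abs=1e-9)
        assert sasa_nonpolar(moved, model) == pytest.approx(
            ref["sasa"], abs=1e-9)
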