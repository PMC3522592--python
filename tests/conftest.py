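import numpy as np
import pytest

from orientscan.energy import EnergyModel
from orientscan.fixtures import (make_barrier_complex, make_c2_dimer,
                                 make_charge_ridge, make_mini_complex,
                                 load_fixture)
from orientscan.rigid_geometry import compute_scan_frame
from orientscan.structure_io import ParameterizedStructure


def build_structure(positions, charges=None, mobile=None, *, lj_epsilon=None,
                    lj_rmin_half=None, intrinsic_radius=None, hct_scale=None,
                    residue_ids=None, subgroup=None):
    """Bare-bones ParameterizedStructure for point-charge style tests."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)

    def arr(x, default):
        if x is None:
            return np.full(n, default, dtype=float)
        return np.asarray(x, dtype=float)

    if mobile is None:
        mobile = np.zeros(n, dtype=bool)
    if residue_ids is None:
        residue_ids = [("A" if m else "B", i + 1, "")
                       for i, m in enumerate(mobile)]
    if subgroup is None:
        subgroup = ["FRAMEWORK" if m else "MHC" for m in mobile]
    return ParameterizedStructure(
        serials=np.arange(1, n + 1), names=["X"] * n, resnames=["UNK"] * n,
        residue_ids=residue_ids, positions=positions,
        charges=arr(charges, 0.0), lj_epsilon=arr(lj_epsilon, 0.1),
        lj_rmin_half=arr(lj_rmin_half, 1.7),
        intrinsic_radius=arr(intrinsic_radius, 1.5),
        hct_scale=arr(hct_scale, 0.8), is_mobile=np.asarray(mobile, bool),
        subgroup=subgroup, built_h=np.zeros(n, bool),
        provenance={"source": "synthetic", "table_version": "test"})


@pytest.fixture(scope="session")
def structure_factory():
    return build_structure


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture(scope="session")
def mini(tmp_path_factory):
    res = make_mini_complex(1, tmp_path_factory.mktemp("mini"))
    structure, assignment = load_fixture(res)
    frame = compute_scan_frame(structure)
    return {"result": res, "structure": structure,
            "assignment": assignment, "frame": frame}


@pytest.fixture(scope="session")
def ridge(tmp_path_factory):
    res = make_charge_ridge(3, tmp_path_factory.mktemp("ridge"),
                            optimum_angle=0.0)
    structure, assignment = load_fixture(res)
    frame = compute_scan_frame(structure)
    return {"result": res, "structure": structure,
            "assignment": assignment, "frame": frame}


@pytest.fixture(scope="session")
def c2(tmp_path_factory):
    res = make_c2_dimer(5, tmp_path_factory.mktemp("c2"))
    structure, assignment = load_fixture(res)
    frame = compute_scan_frame(structure)
    return {"result": res, "structure": structure,
            "assignment": assignment, "frame": frame}


@pytest.fixture(scope="session")
def barrier(tmp_path_factory):
    res = make_barrier_complex(7, tmp_path_factory.mktemp("barrier"))
    structure, assignment = load_fixture(res)
    frame = compute_scan_frame(structure)
    return {"result": res, "structure": structure,
            "assignment": assignment, "frame": frame}


def random_charged_structure(rng, n=20, box=9.0, split=True,
                             min_dist=2.8):
    """Well-separated random atoms (no steric overlap) with random
    charges; rejection sampling keeps every pair at least min_dist apart."""
    pts = []
    while len(pts) < n:
        cand = rng.uniform(-box, box, 3)
        if all(np.linalg.norm(cand - p) >= min_dist for p in pts):
            pts.append(cand)
    pos = np.array(pts)
    charges = rng.uniform(-1.0, 1.0, n)
    mobile = np.zeros(n, dtype=bool)
    if split:
        mobile[: n // 2] = True
    eps = rng.uniform(0.02, 0.3, n)
    rmin = rng.uniform(1.2, 2.2, n)
    radii = rng.uniform(1.2, 2.0, n)
    return build_structure(pos, charges, mobile, lj_epsilon=eps,
                           lj_rmin_half=rmin, intrinsic_radius=radii)
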