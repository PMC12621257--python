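"""Superposition RMSE and coordination-sphere bond-error metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import benchkit as bk
from benchkit.errors import (
    BondDetectionError,
    CorrespondenceError,
    IllPosedSuperpositionError,
)
from benchkit.synthetic import random_rigid_motion


def brute_force_rmse(comp, ref):
    """Independent oracle: numerically minimize RMSE over Euler angles + translation."""
    a = comp.coords - comp.coords.mean(axis=0)
    b = ref.coords - ref.coords.mean(axis=0)

    def objective(p):
        r = Rotation.from_euler("zyx", p[:3]).as_matrix()
        diff = a @ r.T + p[3:] - b
        return np.sqrt(np.mean(np.sum(diff**2, axis=1)))

    best = np.inf
    for angles in itertools.product([0.0, 1.2, 2.4, 4.0, 5.2], repeat=3):
        res = minimize(objective, x0=np.array(list(angles) + [0.0, 0.0, 0.0]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        best = min(best, res.fun)
    return best


class TestSuperposeRMSE:
    def test_identical_structures_zero(self, octahedron):
        assert bk.superpose_rmse(octahedron, octahedron) <= 1e-10

    def test_rigid_motion_invariance(self, octahedron):
        rot, t = random_rigid_motion(seed=42)
        moved = octahedron.transformed(rot, t)
        assert bk.superpose_rmse(moved, octahedron) <= 1e-8

    def test_matches_brute_force_on_displaced_toy(self):
        rng = np.random.default_rng(17)
        base = bk.MolecularStructure(
            ("Fe", "N", "N", "O"),
            np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2.0]]),
            metal_index=0,
        )
        coords = base.coords.copy()
        coords[1] += np.array([0.3, 0.0, 0.0])
        rot, t = random_rigid_motion(seed=18)
        comp = bk.MolecularStructure(base.elements, coords, 0).transformed(rot, t)
        rmse = bk.superpose_rmse(comp, base)
        assert rmse == pytest.approx(brute_force_rmse(comp, base), abs=1e-4)
        # third route: scipy's align_vectors
        r, rssd = Rotation.align_vectors(
            base.coords - base.coords.mean(axis=0),
            comp.coords - comp.coords.mean(axis=0),
        )
        assert rmse == pytest.approx(rssd / np.sqrt(base.n_atoms), abs=1e-8)

    def test_symmetry(self, octahedron):
        rng = np.random.default_rng(3)
        comp = bk.MolecularStructure(
            octahedron.elements,
            octahedron.coords + rng.normal(scale=0.1, size=octahedron.coords.shape),
            0,
        )
        assert bk.superpose_rmse(comp, octahedron) == pytest.approx(
            bk.superpose_rmse(octahedron, comp), abs=1e-10
        )

    def test_joint_rigid_motion_invariance(self, octahedron):
        rng = np.random.default_rng(4)
        comp = bk.MolecularStructure(
            octahedron.elements,
            octahedron.coords + rng.normal(scale=0.05, size=octahedron.coords.shape),
            0,
        )
        r0 = bk.superpose_rmse(comp, octahedron)
        rot, t = random_rigid_motion(seed=7)
        assert bk.superpose_rmse(
            comp.transformed(rot, t), octahedron.transformed(rot, t)
        ) == pytest.approx(r0, abs=1e-9)

    def test_hydrogens_excluded(self, octahedron):
        # a wildly displaced H must not change the RMSE
        with_h = bk.MolecularStructure(
            octahedron.elements + ("H",),
            np.vstack([octahedron.coords, [5.0, 5.0, 5.0]]),
            0,
        )
        moved_h = bk.MolecularStructure(
            octahedron.elements + ("H",),
            np.vstack([octahedron.coords, [-9.0, 3.0, 0.0]]),
            0,
        )
        assert bk.superpose_rmse(moved_h, with_h) <= 1e-10

    def test_element_mismatch_rejected(self, octahedron):
        other = bk.MolecularStructure(
            ("Fe",) + ("O",) * 6, octahedron.coords.copy(), 0
        )
        with pytest.raises(CorrespondenceError):
            bk.superpose_rmse(other, octahedron)

    def test_collinear_ill_posed(self):
        line = bk.MolecularStructure(
            ("Fe", "N", "N"), np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2.0]]), 0
        )
        with pytest.raises(IllPosedSuperpositionError):
            bk.superpose_rmse(line, line)


class TestDetectMetalBonds:
    def test_octahedral_six_bonds(self, octahedron):
        bonds = bk.detect_metal_bonds(octahedron)
        assert bonds.n == 6

    def test_pulled_ligand_excluded(self, octahedron):
        coords = octahedron.coords.copy()
        coords[1] = [3.5, 0.0, 0.0]
        s = bk.MolecularStructure(octahedron.elements, coords, 0)
        assert bk.detect_metal_bonds(s, tolerance=1.3).n == 5

    def test_close_hydrogen_never_bonded(self, octahedron):
        s = bk.MolecularStructure(
            octahedron.elements + ("H",),
            np.vstack([octahedron.coords, [1.6, 0, 0]]),
            0,
        )
        bonds = bk.detect_metal_bonds(s)
        assert all(s.elements[j] != "H" for _, j in bonds.pairs)

    def test_empty_detection_raises(self):
        far = bk.MolecularStructure(
            ("Fe", "N"), np.array([[0, 0, 0], [0, 0, 9.0]]), 0
        )
        with pytest.raises(BondDetectionError):
            bk.detect_metal_bonds(far)


class TestBondErrors:
    def test_uniform_elongation(self, octahedron):
        scenario = bk.StructureScenario(octahedron, (0.02,) * 6, jitter=0.0, seed=1)
        comp, ref = bk.gen_structure_pair(scenario)
        errs = bk.bond_errors(comp, ref, bk.detect_metal_bonds(ref))
        assert errs.mue == pytest.approx(0.02, abs=1e-10)
        assert errs.mse == pytest.approx(0.02, abs=1e-10)

    def test_cancellation(self, octahedron):
        scenario = bk.StructureScenario(
            octahedron, (0.02, 0.02, 0.02, -0.02, -0.02, -0.02), jitter=0.0, seed=1
        )
        comp, ref = bk.gen_structure_pair(scenario)
        errs = bk.bond_errors(comp, ref, bk.detect_metal_bonds(ref))
        assert errs.mue == pytest.approx(0.02, abs=1e-10)
        assert errs.mse == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_two_bond_case(self):
        ref = bk.MolecularStructure(
            ("Fe", "N", "N"),
            np.array([[0, 0, 0], [2.00, 0, 0], [0, 2.10, 0]]),
            0,
        )
        comp = bk.MolecularStructure(
            ("Fe", "N", "N"),
            np.array([[0, 0, 0], [2.05, 0, 0], [0, 2.00, 0]]),
            0,
        )
        errs = bk.bond_errors(comp, ref, bk.detect_metal_bonds(ref))
        np.testing.assert_allclose(errs.per_bond, [0.05, -0.10], atol=1e-10)
        assert errs.mue == pytest.approx(0.075)
        assert errs.mse == pytest.approx(-0.025)

    def test_superposition_independent(self, octahedron):
        scenario = bk.StructureScenario(octahedron, (0.05, -0.1, 0, 0, 0, 0), jitter=0.0, seed=2)
        comp, ref = bk.gen_structure_pair(scenario)
        bonds = bk.detect_metal_bonds(ref)
        e0 = bk.bond_errors(comp, ref, bonds)
        rot, t = random_rigid_motion(seed=99)
        e1 = bk.bond_errors(comp.transformed(rot, t), ref, bonds)
        np.testing.assert_allclose(e1.per_bond, e0.per_bond, atol=1e-10)

    @given(st.lists(st.floats(-0.2, 0.2), min_size=2, max_size=8))
    def test_mue_dominates_abs_mse(self, deltas):
        arr = np.asarray(deltas)
        errs = bk.StructureErrors(
            mue=float(np.abs(arr).mean()), mse=float(arr.mean()), per_bond=tuple(arr)
        )
        assert errs.mue >= abs(errs.mse) - 1e-12
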