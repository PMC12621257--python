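"""Geometry-error metrics between computed and reference structures.

Two complementary views of geometric accuracy:

* **Superposition RMSE** — the root-mean-square Cartesian deviation after
  optimal rigid-body superposition (Kabsch alignment, proper rotations
  only), a whole-molecule measure that is sensitive to conformational
  freedom of peripheral ligand atoms.
* **Metal-ligand bond errors** — mean unsigned error (MUE) and mean signed
  error (MSE) over the bonds of the coordination sphere, i.e. the
  distances from the metal to each directly coordinated non-hydrogen
  atom. The MSE's sign exposes systematic over- or under-estimation of
  bond lengths.

Hydrogen atoms are excluded throughout: their positions are poorly
determined by conventional X-ray diffraction. Atom correspondence is
positional (index by index after hydrogen filtering) and guarded by a
strict element-sequence check; misordered inputs fail loudly rather than
being silently re-matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    BondDetectionError,
    CorrespondenceError,
    IllPosedSuperpositionError,
    InputError,
)
from .spectra_io import MolecularStructure

__all__ = [
    "COVALENT_RADII",
    "BondSet",
    "StructureErrors",
    "superpose",
    "superpose_rmse",
    "detect_metal_bonds",
    "bond_errors",
    "compare_structures",
]

#: Single-bond covalent radii in angstrom (Cordero et al. 2008 compilation,
#: high-spin values for Mn/Fe/Co). Pinned here so bond detection never
#: drifts with an external dependency.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.61, "Fe": 1.52, "Co": 1.50, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Y": 1.90, "Zr": 1.75, "Nb": 1.64, "Mo": 1.54,
    "Tc": 1.47, "Ru": 1.46, "Rh": 1.42, "Pd": 1.39, "Ag": 1.45, "Cd": 1.44,
    "In": 1.42, "Sn": 1.39, "Sb": 1.39, "Te": 1.38, "I": 1.39, "Xe": 1.40,
}

#: Default multiplier on the covalent-radius sum for bond detection.
DEFAULT_BOND_TOLERANCE = 1.3


@dataclass(frozen=True)
class BondSet:
    """Metal-ligand bonds as (metal_index, ligand_index) pairs.

    Detected on the reference structure; the same index pairs are then
    measured in the computed structure, so both sets of distances refer to
    the same chemical bonds.
    """

    pairs: tuple[tuple[int, int], ...]
    elements: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if len(self.pairs) < 1:
            raise InputError("a bond set needs at least one bond")
        if len(set(self.pairs)) != len(self.pairs):
            raise InputError("duplicate bonds in bond set")
        if len(self.elements) != len(self.pairs):
            raise InputError("elements/pairs length mismatch")
        if any(x == "H" for _, x in self.elements):
            raise InputError("hydrogen atoms cannot be coordination-sphere bonds")

    @property
    def n(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class StructureErrors:
    """Geometry-error bundle for one computed-vs-reference comparison (angstrom)."""

    mue: float
    mse: float
    per_bond: tuple[float, ...]
    rmse: float | None = None

    def __post_init__(self):
        if self.per_bond:
            pb = np.asarray(self.per_bond)
            if abs(self.mue - np.abs(pb).mean()) > 1e-9 or abs(self.mse - pb.mean()) > 1e-9:
                raise InputError("mue/mse inconsistent with per-bond errors")


def _heavy_atoms(structure: MolecularStructure) -> tuple[tuple[str, ...], np.ndarray]:
    keep = [i for i, el in enumerate(structure.elements) if el != "H"]
    return tuple(structure.elements[i] for i in keep), structure.coords[keep]


def _kabsch_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centred ``moving`` onto centred ``target``."""
    h = moving.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])  # forbid reflections
    return vt.T @ diag @ u.T


def superpose(
    comp: MolecularStructure, ref: MolecularStructure, exclude_h: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares superposition of ``comp`` onto ``ref``.

    Returns ``(comp_coords_aligned, ref_coords)`` for the retained atoms.
    Correspondence is positional; the element sequences (after optional
    hydrogen exclusion) must match exactly.
    """
    if exclude_h:
        els_c, xyz_c = _heavy_atoms(comp)
        els_r, xyz_r = _heavy_atoms(ref)
    else:
        els_c, xyz_c = comp.elements, comp.coords
        els_r, xyz_r = ref.elements, ref.coords
    if els_c != els_r:
        raise CorrespondenceError(
            f"element sequences differ: {els_c[:6]}... vs {els_r[:6]}..."
        )
    n = len(els_c)
    if n < 3:
        raise IllPosedSuperpositionError(f"need >=3 atoms, got {n}")
    cc = xyz_c - xyz_c.mean(axis=0)
    cr = xyz_r - xyz_r.mean(axis=0)
    if np.linalg.matrix_rank(cr, tol=1e-8) < 2:
        raise IllPosedSuperpositionError("reference atoms are collinear")
    rot = _kabsch_rotation(cc, cr)
    return cc @ rot.T + xyz_r.mean(axis=0), xyz_r


def superpose_rmse(
    comp: MolecularStructure, ref: MolecularStructure, exclude_h: bool = True
) -> float:
    """Minimal RMSE (angstrom) over all rigid motions of ``comp`` onto ``ref``.

    RMSE = sqrt( (1/N) sum_i |r_i^comp - r_i^ref|^2 ) evaluated on the
    optimally superposed coordinates.
    """
    aligned, target = superpose(comp, ref, exclude_h=exclude_h)
    return float(np.sqrt(np.mean(np.sum((aligned - target) ** 2, axis=1))))


def detect_metal_bonds(
    structure: MolecularStructure, tolerance: float = DEFAULT_BOND_TOLERANCE
) -> BondSet:
    """Find the coordination sphere of the metal centre by a distance cutoff.

    A non-hydrogen atom X is bonded to the metal M when
    ``d(M, X) <= tolerance * (r_cov(M) + r_cov(X))``. Unknown elements fall
    back to a generic 1.5 angstrom radius.
    """
    m = structure.metal_index
    metal_el = structure.elements[m]
    r_metal = COVALENT_RADII.get(metal_el, 1.5)
    dists = np.linalg.norm(structure.coords - structure.coords[m], axis=1)
    pairs, elements = [], []
    for i, el in enumerate(structure.elements):
        if i == m or el == "H":
            continue
        if dists[i] <= tolerance * (r_metal + COVALENT_RADII.get(el, 1.5)):
            pairs.append((m, i))
            elements.append((metal_el, el))
    if not pairs:
        raise BondDetectionError(
            f"no {metal_el}-X bonds within tolerance {tolerance}; "
            "check the geometry or raise the tolerance"
        )
    return BondSet(tuple(pairs), tuple(elements))


def bond_errors(
    comp: MolecularStructure, ref: MolecularStructure, bonds: BondSet
) -> StructureErrors:
    """Per-bond signed errors plus their MUE and MSE.

    ``per_bond[i] = R_i(comp) - R_i(ref)``; MUE is the mean absolute value,
    MSE the mean signed value. Distances only — no superposition involved.
    """
    for _, j in bonds.pairs:
        if j >= comp.n_atoms or j >= ref.n_atoms:
            raise InputError(f"bond index {j} out of range")
    per = []
    for m, j in bonds.pairs:
        r_comp = float(np.linalg.norm(comp.coords[j] - comp.coords[m]))
        r_ref = float(np.linalg.norm(ref.coords[j] - ref.coords[m]))
        per.append(r_comp - r_ref)
    per_arr = np.asarray(per)
    return StructureErrors(
        mue=float(np.abs(per_arr).mean()),
        mse=float(per_arr.mean()),
        per_bond=tuple(per),
    )


def compare_structures(
    comp: MolecularStructure,
    ref: MolecularStructure,
    tolerance: float = DEFAULT_BOND_TOLERANCE,
    bonds: BondSet | None = None,
) -> StructureErrors:
    """Full comparison: superposition RMSE plus coordination-sphere MUE/MSE.

    Bonds are detected on the reference structure unless an explicit
    ``bonds`` override is given (the override is the source of truth when
    the coordination sphere is known).
    """
    if bonds is None:
        bonds = detect_metal_bonds(ref, tolerance=tolerance)
    be = bond_errors(comp, ref, bonds)
    rmse = superpose_rmse(comp, ref, exclude_h=True)
    return StructureErrors(mue=be.mue, mse=be.mse, per_bond=be.per_bond, rmse=rmse)
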