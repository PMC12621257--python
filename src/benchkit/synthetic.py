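"""Synthetic benchmark inputs with known ground truth.

Real benchmark inputs — digitized experimental UV-vis spectra, vertical
excitation tables from time-dependent calculations, and crystallographic
reference geometries — are expensive to obtain and carry no ground truth.
Every generator here is a pure function of its seed and parameters and
records the truth it was built from, so each pipeline stage can be tested
closed-loop: the expected shift, width, MUE and MSE are known before the
analysis runs.

What is emulated (and what is not): stick spectra have tens of transitions
with a few dominant bands (log-uniform strengths over two decades);
pseudo-experimental spectra are broadened sticks plus multiplicative
relative noise, mimicking digitization error that scales with the signal;
structure pairs differ by per-bond stretches, optional Cartesian jitter
and a rigid motion. None of these carry vibronic structure, solvent-
dependent band shapes, or the conformational freedom of real ligands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .broadening import BroadeningParams, broaden
from .constants import DEFAULT_SPACING_EV
from .errors import DegenerateSpectrumError, InputError
from .spectra_io import (
    MolecularStructure,
    Spectrum,
    StickSpectrum,
    write_stick_spectrum,
    write_xyz,
)
from .structures import detect_metal_bonds

__all__ = [
    "SpectrumScenario",
    "StructureScenario",
    "gen_sticks",
    "gen_experimental",
    "gen_structure_pair",
    "gen_octahedral_toy",
    "random_rigid_motion",
    "simulate_benchmark",
]


@dataclass(frozen=True)
class SpectrumScenario:
    """Ground truth for one pseudo-experimental spectrum."""

    sticks_true: StickSpectrum
    delta_true: float
    sigma_true: float
    window: tuple[float, float]
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (-1.5 <= self.delta_true <= 1.5):
            raise InputError("delta_true outside [-1.5, 1.5] eV")
        if not (0 < self.sigma_true <= 0.5):
            raise InputError("sigma_true outside (0, 0.5] eV")
        if self.noise_level < 0:
            raise InputError("noise_level must be non-negative")


@dataclass(frozen=True)
class StructureScenario:
    """Ground truth for one computed-vs-reference structure pair."""

    base: MolecularStructure
    bond_deltas: tuple[float, ...]
    jitter: float = 0.0
    seed: int = 0
    rigid: tuple[np.ndarray, np.ndarray] | None = None  # (rotation, translation)


def gen_sticks(
    n_transitions: int,
    energy_range: tuple[float, float] = (1.4, 6.2),
    strength_law: str = "log-uniform",
    seed: int = 0,
    label: str = "synthetic",
) -> StickSpectrum:
    """Draw a stick spectrum with ``n_transitions`` transitions.

    Energies are uniform over ``energy_range``; strengths follow the chosen
    law — the default log-uniform over two decades gives the realistic
    situation where a few bands dominate the spectrum.
    """
    lo, hi = energy_range
    if not (0 < lo < hi):
        raise InputError(f"invalid energy range {energy_range}")
    if n_transitions < 1:
        raise InputError("need at least one transition")
    rng = np.random.default_rng(seed)
    energies = rng.uniform(lo, hi, size=n_transitions)
    if strength_law == "log-uniform":
        strengths = 10.0 ** rng.uniform(-2.0, 0.0, size=n_transitions)
    elif strength_law == "uniform":
        strengths = rng.uniform(0.0, 1.0, size=n_transitions)
    else:
        raise InputError(f"unknown strength law {strength_law!r}")
    return StickSpectrum(energies, strengths, label=label)


def gen_experimental(
    scenario: SpectrumScenario, spacing: float = DEFAULT_SPACING_EV
) -> Spectrum:
    """Pseudo-experimental spectrum: broadened truth plus multiplicative noise.

    Each grid value is multiplied by ``1 + noise_level * u`` with ``u``
    drawn uniform on [-1, 1] from the scenario seed; negatives are clipped
    and the result re-normalized so the carrier invariants hold.
    """
    e1, e2 = scenario.window
    n = int(np.floor((e2 - e1) / spacing + 1e-9)) + 1
    grid = e1 + spacing * np.arange(n)
    params = BroadeningParams(scenario.delta_true, scenario.sigma_true)
    clean = broaden(scenario.sticks_true, params, grid).intensities
    if scenario.noise_level > 0:
        rng = np.random.default_rng(scenario.seed)
        u = rng.uniform(-1.0, 1.0, size=clean.size)
        noisy = np.clip(clean * (1.0 + scenario.noise_level * u), 0.0, None)
    else:
        noisy = clean
    peak = noisy.max()
    if peak <= 0:
        raise DegenerateSpectrumError("noisy spectrum vanished")
    return Spectrum(grid, noisy / peak, window=(e1, e2), provenance="synthetic")


def random_rigid_motion(seed: int, translation_scale: float = 5.0):
    """A seeded proper rotation (QR-based, det fixed to +1) and translation."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))  # make decomposition unique
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-translation_scale, translation_scale, size=3)
    return q, t


def gen_structure_pair(
    scenario: StructureScenario,
) -> tuple[MolecularStructure, MolecularStructure]:
    """Build a (computed-like, reference-like) structure pair.

    The reference is the scenario base. The computed copy stretches each
    metal-ligand bond along its bond vector by the corresponding entry of
    ``bond_deltas`` (detection order on the base), adds seeded isotropic
    jitter to atoms outside the coordination sphere, and finally applies a
    rigid motion. With zero jitter the ground-truth MUE and MSE are exactly
    the mean absolute and mean signed ``bond_deltas``.
    """
    base = scenario.base
    bonds = detect_metal_bonds(base)
    if len(scenario.bond_deltas) != bonds.n:
        raise InputError(
            f"bond_deltas has {len(scenario.bond_deltas)} entries "
            f"but the base structure has {bonds.n} metal-ligand bonds"
        )
    coords = base.coords.copy()
    m = base.metal_index
    bonded = {j for _, j in bonds.pairs}
    for (mi, j), dr in zip(bonds.pairs, scenario.bond_deltas):
        vec = coords[j] - coords[mi]
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise InputError("zero-length metal-ligand bond in base structure")
        coords[j] = coords[j] + dr * vec / norm
    if scenario.jitter > 0:
        rng = np.random.default_rng(scenario.seed)
        noise = rng.normal(scale=scenario.jitter, size=coords.shape)
        for i in range(base.n_atoms):
            if i == m or i in bonded:
                noise[i] = 0.0
        coords = coords + noise
    computed = MolecularStructure(base.elements, coords, m, label=base.label + "_computed")
    rigid = scenario.rigid if scenario.rigid is not None else random_rigid_motion(scenario.seed)
    computed = computed.transformed(*rigid)
    reference = MolecularStructure(base.elements, base.coords.copy(), m, label=base.label + "_reference")
    return computed, reference


_TETRAHEDRON = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3.0)
_OCTAHEDRON = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float
)
_TRIGONAL_BIPYRAMID = np.array(
    [
        [0, 0, 1],
        [0, 0, -1],
        [1, 0, 0],
        [-0.5, np.sqrt(3) / 2, 0],
        [-0.5, -np.sqrt(3) / 2, 0],
    ]
)


def gen_octahedral_toy(
    bond_length: float = 2.0,
    n_ligands: int = 6,
    metal: str = "Fe",
    ligand: str = "N",
    label: str = "toy",
) -> MolecularStructure:
    """Ideal coordination polyhedron: metal at the origin, donors at vertices.

    Supports coordination numbers 4 (tetrahedron), 5 (trigonal bipyramid)
    and 6 (octahedron) — the geometries typical of mononuclear iron
    complexes.
    """
    if bond_length <= 0:
        raise InputError("bond_length must be positive")
    vertices = {4: _TETRAHEDRON, 5: _TRIGONAL_BIPYRAMID, 6: _OCTAHEDRON}.get(n_ligands)
    if vertices is None:
        raise InputError(f"unsupported coordination number {n_ligands} (use 4, 5 or 6)")
    coords = np.vstack([[0.0, 0.0, 0.0], bond_length * vertices])
    elements = (metal,) + (ligand,) * n_ligands
    return MolecularStructure(elements, coords, metal_index=0, label=label)


# ---------------------------------------------------------------------------
# Full simulated benchmark (files + manifest + ground-truth sidecar)
# ---------------------------------------------------------------------------

#: Per-method systematic excitation-energy bias (eV) used by the simulator.
#: A stick placed at E_i + bias needs delta = bias to land back on E_i, so
#: the pipeline should recover approximately the bias itself as delta_opt.
_DEFAULT_METHOD_BIASES = (-0.25, 0.10, 0.40, -0.60, 0.80, -0.05, 0.55, -0.90)
#: Per-method systematic bond-length bias (angstrom), the MSE ground truth.
_DEFAULT_BOND_BIASES = (0.02, -0.015, 0.04, -0.05, 0.01, 0.03, -0.02, 0.05)


def simulate_benchmark(
    out_dir: str | Path,
    n_compounds: int = 4,
    n_methods: int = 3,
    seed: int = 0,
    n_transitions: int = 40,
    noise_level: float = 0.03,
    spacing: float = DEFAULT_SPACING_EV,
) -> Path:
    """Emit a complete simulated benchmark ready for ``run_benchmark``.

    Per compound: a pseudo-experimental spectrum (two-column eV text), a
    reference XYZ; per compound x method: a stick spectrum whose energies
    carry the method's systematic bias plus scatter, and a computed XYZ
    with stretched bonds and jitter. A ``ground_truth.csv`` sidecar records
    every true parameter. Returns the manifest path.
    """
    if n_methods > len(_DEFAULT_METHOD_BIASES):
        raise InputError(f"at most {len(_DEFAULT_METHOD_BIASES)} methods supported")
    out = Path(out_dir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    (out / "sticks").mkdir(exist_ok=True)
    (out / "structures").mkdir(exist_ok=True)
    master = np.random.default_rng(seed)

    compounds, methods = [], []
    truth_rows = ["compound,method,delta_true,sigma_true,mse_true,mue_true"]
    method_ids = [f"M{k+1}" for k in range(n_methods)]
    method_data: dict[str, dict] = {mid: {} for mid in method_ids}

    for c in range(n_compounds):
        cid = f"C{c+1}"
        crng = np.random.default_rng(master.integers(2**31))
        window = (1.5, 5.5)
        sigma_exp = float(crng.uniform(0.08, 0.30))
        sticks_true = gen_sticks(
            n_transitions, (window[0] + 0.3, window[1] - 0.3),
            seed=int(crng.integers(2**31)), label=cid,
        )
        scenario = SpectrumScenario(
            sticks_true, delta_true=0.0, sigma_true=sigma_exp, window=window,
            noise_level=noise_level, seed=int(crng.integers(2**31)),
        )
        exp = gen_experimental(scenario, spacing=spacing)
        # the manifest window must match the emitted grid extent exactly,
        # otherwise conditioning would reject the (slightly shorter) grid
        window = (float(exp.energies[0]), float(exp.energies[-1]))
        spec_path = out / "spectra" / f"{cid}_exp.txt"
        with open(spec_path, "w") as fh:
            fh.write("# energy_eV intensity\n")
            for e, y in zip(exp.energies, exp.intensities):
                fh.write(f"{e:.10g} {y:.10g}\n")

        n_lig = int(crng.choice([4, 5, 6]))
        base = gen_octahedral_toy(
            bond_length=float(crng.uniform(1.9, 2.2)), n_ligands=n_lig, label=cid
        )
        ref_path = out / "structures" / f"{cid}_ref.xyz"
        write_xyz(base, ref_path, comment=f"{cid} reference")

        compounds.append(
            {
                "id": cid,
                "window_ev": [float(window[0]), float(window[1])],
                "experimental_spectrum": str(spec_path.relative_to(out)),
                "spectrum_units": "eV",
                "reference_structure": str(ref_path.relative_to(out)),
                "solvent": "water",
            }
        )

        for k, mid in enumerate(method_ids):
            mrng = np.random.default_rng(master.integers(2**31))
            bias = _DEFAULT_METHOD_BIASES[k]
            scatter = mrng.normal(scale=0.03, size=len(sticks_true))
            energies = np.clip(sticks_true.energies + bias + scatter, 0.2, None)
            f_jit = sticks_true.strengths * np.exp(mrng.normal(scale=0.10, size=len(sticks_true)))
            method_sticks = StickSpectrum(energies, f_jit, label=f"{cid}_{mid}")
            sticks_path = out / "sticks" / f"{cid}_{mid}.txt"
            write_stick_spectrum(method_sticks, sticks_path)

            bond_bias = _DEFAULT_BOND_BIASES[k]
            deltas = tuple(bond_bias + mrng.normal(scale=0.01, size=n_lig))
            struct_scenario = StructureScenario(
                base=base, bond_deltas=deltas, jitter=0.01,
                seed=int(mrng.integers(2**31)),
            )
            computed, _ = gen_structure_pair(struct_scenario)
            comp_path = out / "structures" / f"{cid}_{mid}.xyz"
            write_xyz(computed, comp_path, comment=f"{cid} {mid}")

            method_data[mid][cid] = {
                "sticks": str(sticks_path.relative_to(out)),
                "structure": str(comp_path.relative_to(out)),
            }
            darr = np.asarray(deltas)
            truth_rows.append(
                f"{cid},{mid},{bias:.6f},{sigma_exp:.6f},"
                f"{darr.mean():.6f},{np.abs(darr).mean():.6f}"
            )

    for mid in method_ids:
        methods.append({"id": mid, "data": method_data[mid]})

    manifest = {
        "spacing_ev": float(spacing),
        "bond_tolerance": 1.3,
        "compounds": compounds,
        "methods": methods,
    }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    (out / "ground_truth.csv").write_text("\n".join(truth_rows) + "\n")
    return manifest_path
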