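"""Reading, unit conversion and conditioning of spectra and structures.

This module owns the data carriers of the pipeline — raw digitized spectra,
conditioned spectra on a uniform energy grid, stick spectra of vertical
transitions, and Cartesian molecular structures — together with every unit
conversion between the wavelength and energy domains.

Conventions
-----------
* Wavelengths in nm, photon energies in eV, coordinates in angstrom.
* Converting a spectrum from wavelength to energy applies the Jacobian
  rescaling ``I(E) = I(lambda) * lambda^2 / hc`` so that integrated band
  areas are preserved (``dlambda = (lambda^2/hc) dE``).
* Conditioned spectra live on a uniform grid, are clipped to be
  non-negative and max-normalized to one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .constants import DEFAULT_SPACING_EV, HC_EV_NM
from .errors import (
    DegenerateSpectrumError,
    InputError,
    MetalAmbiguityError,
    SpectrumParseError,
    WindowError,
    XYZFormatError,
)

__all__ = [
    "RawSpectrum",
    "Spectrum",
    "StickSpectrum",
    "MolecularStructure",
    "read_xy_spectrum",
    "wavelength_to_energy",
    "energy_to_wavelength",
    "condition",
    "read_stick_spectrum",
    "read_xyz",
    "write_xyz",
    "savgol_smoother",
]

Provenance = Literal["experimental", "computed", "synthetic"]

#: Elements accepted as an auto-detected metal centre (d-block symbols).
TRANSITION_METALS = frozenset(
    "Sc Ti V Cr Mn Fe Co Ni Cu Zn "
    "Y Zr Nb Mo Tc Ru Rh Pd Ag Cd "
    "Hf Ta W Re Os Ir Pt Au Hg".split()
)


# ---------------------------------------------------------------------------
# Data carriers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RawSpectrum:
    """A digitized spectrum: strictly increasing abscissa vs intensity.

    The abscissa may be wavelength (nm) or energy (eV) depending on where
    the object sits in the conversion chain; ``domain`` records which.
    """

    abscissa: np.ndarray
    intensity: np.ndarray
    label: str = ""
    domain: Literal["wavelength", "energy"] = "wavelength"

    def __post_init__(self):
        a = np.asarray(self.abscissa, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "abscissa", a)
        object.__setattr__(self, "intensity", y)
        if a.ndim != 1 or y.ndim != 1 or a.size != y.size:
            raise InputError("abscissa and intensity must be 1-D of equal length")
        if a.size < 2:
            raise InputError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(a)) or not np.all(np.isfinite(y)):
            raise InputError("spectrum values must be finite")
        if not np.all(np.diff(a) > 0):
            raise InputError("abscissa must be strictly increasing")

    def __len__(self) -> int:
        return int(self.abscissa.size)


@dataclass(frozen=True)
class Spectrum:
    """A conditioned absorption profile on a uniform energy grid.

    Invariants: constant grid spacing (to 1e-9 eV), non-negative intensities
    with maximum one, and every grid point inside ``window``.
    """

    energies: np.ndarray
    intensities: np.ndarray
    window: tuple[float, float]
    provenance: Provenance = "experimental"
    label: str = ""

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "intensities", y)
        if e.size != y.size or e.size < 2:
            raise InputError("energies/intensities must match and have >=2 points")
        steps = np.diff(e)
        if not np.all(steps > 0):
            raise InputError("energy grid must be strictly increasing")
        if np.ptp(steps) > 1e-9:
            raise InputError("energy grid must be uniform to 1e-9 eV")
        if np.any(y < 0):
            raise InputError("intensities must be non-negative")
        ymax = y.max()
        if ymax > 0 and abs(ymax - 1.0) > 1e-9:
            raise InputError("intensities must be max-normalized to 1")
        lo, hi = self.window
        if e[0] < lo - 1e-9 or e[-1] > hi + 1e-9:
            raise InputError("grid extends outside the declared window")

    @property
    def spacing(self) -> float:
        return float(self.energies[1] - self.energies[0])

    def __len__(self) -> int:
        return int(self.energies.size)


@dataclass(frozen=True)
class StickSpectrum:
    """Vertical transitions of one compound/method: (E_i [eV], f_i) pairs.

    Transitions are stored sorted by ascending energy. Zero-strength rows
    are retained (they contribute nothing to the broadened band shape).
    """

    energies: np.ndarray
    strengths: np.ndarray
    label: str = ""

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        f = np.asarray(self.strengths, dtype=float)
        if e.ndim != 1 or f.ndim != 1 or e.size != f.size:
            raise InputError("energies and strengths must be 1-D of equal length")
        if e.size < 1:
            raise InputError("a stick spectrum needs at least one transition")
        if np.any(e <= 0):
            raise InputError("transition energies must be positive")
        if np.any(f < 0):
            raise InputError("oscillator strengths must be non-negative")
        order = np.argsort(e, kind="stable")
        object.__setattr__(self, "energies", e[order])
        object.__setattr__(self, "strengths", f[order])

    @property
    def usable(self) -> bool:
        """True if at least one transition carries intensity."""
        return bool(np.any(self.strengths > 0))

    def shifted(self, shift: float) -> "StickSpectrum":
        """Return a copy with all transition energies moved by ``shift`` eV."""
        return StickSpectrum(self.energies + shift, self.strengths, self.label)

    def __len__(self) -> int:
        return int(self.energies.size)


@dataclass(frozen=True)
class MolecularStructure:
    """Element symbols plus Cartesian coordinates with a metal centre."""

    elements: tuple[str, ...]
    coords: np.ndarray
    metal_index: int
    label: str = ""

    def __post_init__(self):
        xyz = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", xyz)
        object.__setattr__(self, "elements", tuple(self.elements))
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise InputError("coords must have shape (n_atoms, 3)")
        if len(self.elements) != xyz.shape[0]:
            raise InputError("elements and coords lengths differ")
        if not np.all(np.isfinite(xyz)):
            raise InputError("coordinates must be finite")
        if not (0 <= self.metal_index < len(self.elements)):
            raise InputError(f"metal_index {self.metal_index} out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def metal(self) -> str:
        return self.elements[self.metal_index]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MolecularStructure":
        """Apply a rigid motion ``x -> R x + t`` to every atom."""
        rotation = np.asarray(rotation, dtype=float)
        if rotation.shape != (3, 3) or abs(np.linalg.det(rotation) - 1.0) > 1e-8:
            raise InputError("rotation must be a proper 3x3 rotation matrix")
        new = self.coords @ rotation.T + np.asarray(translation, dtype=float)
        return replace(self, coords=new)


# ---------------------------------------------------------------------------
# Spectrum file IO and unit conversion
# ---------------------------------------------------------------------------

_SPLIT_RE = re.compile(r"[,\s;]+")


def _parse_two_columns(path: str | Path, delimiter: str | None = None):
    """Yield (line_number, col1, col2) for every data row of a text table."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split(delimiter) if delimiter else _SPLIT_RE.split(text)
            if len(parts) < 2:
                raise SpectrumParseError(f"expected >=2 columns, got {text!r}", lineno)
            try:
                rows.append((lineno, float(parts[0]), float(parts[1])))
            except ValueError:
                raise SpectrumParseError(f"non-numeric value in {text!r}", lineno) from None
    return rows


def read_xy_spectrum(
    path: str | Path,
    delimiter: str | None = None,
    label: str | None = None,
    domain: Literal["wavelength", "energy"] = "wavelength",
) -> RawSpectrum:
    """Read a two-column XY spectrum from delimited text.

    Lines may carry ``#`` comments; the default delimiter accepts any mix of
    whitespace, commas and semicolons. Rows are sorted to a strictly
    increasing abscissa and rows sharing an abscissa value are averaged.
    """
    rows = _parse_two_columns(path, delimiter)
    if len(rows) < 2:
        raise InputError(f"{path}: need at least 2 data points, got {len(rows)}")
    x = np.array([r[1] for r in rows])
    y = np.array([r[2] for r in rows])
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    # average duplicated abscissa values
    ux, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    if ux.size != x.size:
        sums = np.zeros(ux.size)
        np.add.at(sums, inverse, y)
        x, y = ux, sums / counts
    return RawSpectrum(x, y, label=label or str(path), domain=domain)


def wavelength_to_energy(raw: RawSpectrum, hc: float = HC_EV_NM) -> RawSpectrum:
    """Convert a wavelength-domain spectrum to the energy domain.

    Applies ``E = hc/lambda`` to the abscissa and the Jacobian factor
    ``lambda^2/hc`` to the intensity so band areas are preserved; the output
    is sorted ascending in energy.
    """
    if raw.domain != "wavelength":
        raise InputError("spectrum is not in the wavelength domain")
    lam = raw.abscissa
    if np.any(lam <= 0):
        raise InputError("wavelengths must be positive")
    energies = hc / lam
    intensities = raw.intensity * lam**2 / hc
    return RawSpectrum(energies[::-1], intensities[::-1], label=raw.label, domain="energy")


def energy_to_wavelength(raw: RawSpectrum, hc: float = HC_EV_NM) -> RawSpectrum:
    """Inverse of :func:`wavelength_to_energy` (round-trips to 1e-9 relative)."""
    if raw.domain != "energy":
        raise InputError("spectrum is not in the energy domain")
    e = raw.abscissa
    if np.any(e <= 0):
        raise InputError("energies must be positive")
    lam = hc / e
    intensities = raw.intensity * e**2 / hc
    return RawSpectrum(lam[::-1], intensities[::-1], label=raw.label, domain="wavelength")


def savgol_smoother(window_length: int = 9, polyorder: int = 3) -> Callable[[np.ndarray], np.ndarray]:
    """Moving-window polynomial (Savitzky-Golay) smoother factory.

    The window shrinks automatically (keeping it odd and > polyorder) when a
    spectrum has fewer points than ``window_length``.
    """

    def smooth(y: np.ndarray) -> np.ndarray:
        n = y.size
        w = min(window_length, n if n % 2 == 1 else n - 1)
        if w <= polyorder:
            return y.copy()
        return savgol_filter(y, window_length=w, polyorder=polyorder)

    return smooth


#: Default conditioning smoother (window 9 points, cubic).
DEFAULT_SMOOTHER = savgol_smoother(9, 3)


def condition(
    raw: RawSpectrum,
    window: tuple[float, float],
    spacing: float = DEFAULT_SPACING_EV,
    smoothing: Callable[[np.ndarray], np.ndarray] | None = DEFAULT_SMOOTHER,
    interpolation: Literal["linear", "cubic"] = "linear",
    provenance: Provenance = "experimental",
) -> Spectrum:
    """Smooth, resample and normalize an energy-domain spectrum.

    The output grid starts at ``window[0]`` and steps by ``spacing`` up to
    ``window[1]``. Smoothing (pass ``None`` to disable) is applied on the
    original sampling before interpolation; negative values are clipped to
    zero and the result is max-normalized.
    """
    if raw.domain != "energy":
        raise InputError("condition() expects an energy-domain spectrum")
    e1, e2 = float(window[0]), float(window[1])
    if not (e1 < e2):
        raise WindowError(f"invalid window ({e1}, {e2})")
    if spacing <= 0:
        raise InputError("spacing must be positive")
    if e1 < raw.abscissa[0] - 1e-9 or e2 > raw.abscissa[-1] + 1e-9:
        raise WindowError(
            f"window ({e1:.4f}, {e2:.4f}) eV outside data range "
            f"({raw.abscissa[0]:.4f}, {raw.abscissa[-1]:.4f}) eV"
        )
    y = raw.intensity
    if smoothing is not None:
        y = smoothing(y)
    n = int(np.floor((e2 - e1) / spacing + 1e-9)) + 1
    grid = e1 + spacing * np.arange(n)
    if interpolation == "linear":
        vals = np.interp(grid, raw.abscissa, y)
    elif interpolation == "cubic":
        from scipy.interpolate import CubicSpline

        vals = CubicSpline(raw.abscissa, y)(grid)
    else:
        raise InputError(f"unknown interpolation {interpolation!r}")
    vals = np.clip(vals, 0.0, None)
    peak = vals.max()
    if peak <= 0:
        raise DegenerateSpectrumError("conditioned spectrum is identically zero")
    return Spectrum(grid, vals / peak, window=(e1, e2), provenance=provenance, label=raw.label)


def read_stick_spectrum(path: str | Path, label: str | None = None) -> StickSpectrum:
    """Read a stick spectrum from two-column text: energy (eV), strength.

    Zero-strength rows are retained; negative strengths or non-positive
    energies are rejected. Rows are stored sorted by ascending energy.
    """
    rows = _parse_two_columns(path)
    if not rows:
        raise InputError(f"{path}: no transitions found")
    for lineno, e, f in rows:
        if e <= 0:
            raise SpectrumParseError(f"non-positive transition energy {e}", lineno)
        if f < 0:
            raise SpectrumParseError(f"negative oscillator strength {f}", lineno)
    return StickSpectrum(
        np.array([r[1] for r in rows]),
        np.array([r[2] for r in rows]),
        label=label or str(path),
    )


def write_stick_spectrum(sticks: StickSpectrum, path: str | Path) -> None:
    """Write a stick spectrum as two-column text (eV, oscillator strength)."""
    with open(path, "w") as fh:
        fh.write("# energy_eV oscillator_strength\n")
        for e, f in zip(sticks.energies, sticks.strengths):
            fh.write(f"{e:.10g} {f:.10g}\n")


# ---------------------------------------------------------------------------
# XYZ structures
# ---------------------------------------------------------------------------


def read_xyz(path: str | Path, metal_index: int | None = None, label: str | None = None) -> MolecularStructure:
    """Read a standard XYZ file (count line, comment, element x y z rows).

    The metal centre is auto-detected as the unique transition-metal symbol
    unless ``metal_index`` overrides it; zero or multiple candidates without
    an override raise :class:`MetalAmbiguityError`.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZFormatError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZFormatError(f"{path}: first line must be the atom count") from None
    body = [ln for ln in lines[2 : 2 + count]]
    atom_rows = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < count or len(atom_rows) != count:
        raise XYZFormatError(
            f"{path}: count line says {count} atoms but {len(atom_rows)} atom rows found"
        )
    elements, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise XYZFormatError(f"{path}: malformed atom row {ln!r}")
        elements.append(parts[0].capitalize())
        try:
            coords.append([float(v) for v in parts[1:4]])
        except ValueError:
            raise XYZFormatError(f"{path}: non-numeric coordinate in {ln!r}") from None
    if metal_index is None:
        candidates = [i for i, el in enumerate(elements) if el in TRANSITION_METALS]
        if len(candidates) != 1:
            raise MetalAmbiguityError(
                f"{path}: {len(candidates)} metal candidates "
                f"({[elements[i] for i in candidates]}); pass metal_index explicitly"
            )
        metal_index = candidates[0]
    return MolecularStructure(tuple(elements), np.array(coords), metal_index, label=label or str(path))


def write_xyz(structure: MolecularStructure, path: str | Path, comment: str = "") -> None:
    """Write a structure as a standard XYZ file."""
    with open(path, "w") as fh:
        fh.write(f"{structure.n_atoms}\n{comment}\n")
        for el, (x, y, z) in zip(structure.elements, structure.coords):
            fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")
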