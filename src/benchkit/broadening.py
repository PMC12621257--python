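"""Gaussian broadening of stick spectra.

A computed band shape is modelled as a sum of Gaussians, one per vertical
transition, sharing a single width sigma and a single energy shift delta::

    I(E) = N * sum_i f_i * exp(-(E - E_i + delta)^2 / (2 sigma^2))

with N chosen so the maximum over the evaluation grid is one. The sign
convention places each stick's band at ``E_i - delta``: a positive shift
moves the whole spectrum to lower energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import FWHM_PER_SIGMA
from .errors import DegenerateSpectrumError, InputError
from .spectra_io import Spectrum, StickSpectrum

__all__ = ["BroadeningParams", "broaden", "fwhm_from_sigma", "sigma_from_fwhm"]


@dataclass(frozen=True)
class BroadeningParams:
    """Shift delta (eV) and Gaussian width sigma (eV) applied to all sticks."""

    delta: float
    sigma: float

    def __post_init__(self):
        if not np.isfinite(self.delta):
            raise InputError("delta must be finite")
        if not (self.sigma > 0) or not np.isfinite(self.sigma):
            raise InputError(f"sigma must be positive, got {self.sigma}")

    @property
    def fwhm(self) -> float:
        return fwhm_from_sigma(self.sigma)


def fwhm_from_sigma(sigma: float) -> float:
    """Full width at half maximum of a Gaussian of width sigma: 2*sqrt(2 ln 2)*sigma."""
    if sigma <= 0:
        raise InputError(f"sigma must be positive, got {sigma}")
    return FWHM_PER_SIGMA * sigma


def sigma_from_fwhm(fwhm: float) -> float:
    """Gaussian width corresponding to a full width at half maximum."""
    if fwhm <= 0:
        raise InputError(f"fwhm must be positive, got {fwhm}")
    return fwhm / FWHM_PER_SIGMA


def broaden(
    sticks: StickSpectrum,
    params: BroadeningParams,
    grid: np.ndarray,
    label: str | None = None,
) -> Spectrum:
    """Evaluate the shifted-Gaussian band shape of ``sticks`` on ``grid``.

    The grid must be uniform and ascending (normally the experimental grid
    restricted to the comparison window, so the similarity integrand is
    pointwise aligned). The normalization constant is recomputed for every
    parameter pair — it depends on both delta and sigma. Sticks whose
    shifted centres fall outside the grid still contribute their tails.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise InputError("grid must be 1-D with at least 2 points")
    if not sticks.usable:
        raise DegenerateSpectrumError("all oscillator strengths are zero")
    # (n_grid, n_sticks) displacement table; fine for tens of transitions
    arg = grid[:, None] - sticks.energies[None, :] + params.delta
    profile = np.exp(-0.5 * (arg / params.sigma) ** 2) @ sticks.strengths
    peak = profile.max()
    if peak <= 0:
        raise DegenerateSpectrumError("broadened spectrum vanishes on this grid")
    return Spectrum(
        grid,
        profile / peak,
        window=(float(grid[0]), float(grid[-1])),
        provenance="computed",
        label=label if label is not None else sticks.label,
    )


def broadened_profile(
    sticks: StickSpectrum, delta: float, sigma: float, grid: np.ndarray
) -> np.ndarray:
    """Unwrapped max-normalized profile (no Spectrum validation).

    Hot path for the similarity optimizer: identical arithmetic to
    :func:`broaden` but returns the bare array.
    """
    arg = grid[:, None] - sticks.energies[None, :] + delta
    profile = np.exp(-0.5 * (arg / sigma) ** 2) @ sticks.strengths
    peak = profile.max()
    if peak <= 0:
        raise DegenerateSpectrumError("broadened spectrum vanishes on this grid")
    return profile / peak
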