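"""Cosine-similarity scoring of computed vs experimental spectra.

The similarity between two non-negative spectra on a shared energy window
[E1, E2] is the normalized inner product

    S = int I_exp * I_comp dE / sqrt(int I_exp^2 dE * int I_comp^2 dE)

with each integral evaluated by composite Simpson quadrature on the shared
uniform grid. S lies in [0, 1]: 1 for identical band shapes (scale
invariant), 0 for non-overlapping bands.

For a stick spectrum, S is maximized over the energy shift delta and the
Gaussian width sigma inside a rectangular constraint box (by default
delta in [-1.5, 1.5] eV, sigma in (0, 0.5] eV) with the Nelder-Mead
simplex, restarted from a deterministic 3x3 grid of initial points. The
box is enforced by evaluating at the clipped point plus a quadratic
penalty on the excursion, which preserves simplex behaviour near the
boundary. Ties between restarts are broken by higher S, then smaller
|delta|, then smaller sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .broadening import broadened_profile, fwhm_from_sigma
from .errors import DegenerateSpectrumError, GridMismatchError, InputError
from .spectra_io import Spectrum, StickSpectrum

__all__ = ["SimilarityResult", "similarity", "optimize_similarity", "DEFAULT_BOUNDS"]

#: Constraint box for (delta, sigma) in eV. The sigma lower bound is kept
#: strictly positive (a zero width is singular in the band-shape model).
DEFAULT_BOUNDS: tuple[tuple[float, float], tuple[float, float]] = ((-1.5, 1.5), (0.005, 0.5))

_PENALTY_WEIGHT = 10.0
_TIE_TOL = 1e-9


def simpson_quadrature(y: np.ndarray, dx: float) -> float:
    """Composite Simpson integral on a uniform grid.

    Simpson's rule needs an even number of intervals; with an odd count the
    final interval is integrated by the trapezoid rule (a one-interval
    correction of order dx^3, negligible at the grid spacings used here).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        raise InputError("need at least 2 points to integrate")
    if n == 2:
        return float(0.5 * dx * (y[0] + y[1]))
    m = n if n % 2 == 1 else n - 1  # largest odd point count => even intervals
    core = dx / 3.0 * (y[0] + y[m - 1] + 4.0 * y[1:m:2].sum() + 2.0 * y[2 : m - 1 : 2].sum())
    tail = 0.0 if m == n else 0.5 * dx * (y[-2] + y[-1])
    return float(core + tail)


def _cosine(a: np.ndarray, b: np.ndarray, dx: float) -> float:
    num = simpson_quadrature(a * b, dx)
    da = simpson_quadrature(a * a, dx)
    db = simpson_quadrature(b * b, dx)
    if da <= 0 or db <= 0:
        raise DegenerateSpectrumError("identically-zero spectrum in similarity")
    return float(np.clip(num / np.sqrt(da * db), 0.0, 1.0))


def similarity(exp: Spectrum, comp: Spectrum) -> float:
    """Cosine similarity of two spectra on the identical energy grid."""
    if len(exp) != len(comp) or not np.allclose(exp.energies, comp.energies, atol=1e-9, rtol=0):
        raise GridMismatchError("spectra are not on the identical energy grid")
    return _cosine(exp.intensities, comp.intensities, exp.spacing)


@dataclass(frozen=True)
class SimilarityResult:
    """Outcome of the shift/broadening optimization for one comparison.

    ``delta_opt`` follows the band-shape model's sign convention (a positive
    delta moves computed bands to lower energy); the apparent displacement of
    the bands on the energy axis is ``-delta_opt``.
    """

    s_max: float
    delta_opt: float
    sigma_opt: float
    window: tuple[float, float]
    converged: bool
    n_iterations: int
    n_restarts: int

    @property
    def fwhm_opt(self) -> float:
        return fwhm_from_sigma(self.sigma_opt)

    @property
    def abs_shift(self) -> float:
        return abs(self.delta_opt)

    @property
    def apparent_shift(self) -> float:
        """Band displacement on the energy axis (eV): -delta_opt."""
        return -self.delta_opt


def _make_objective(exp: Spectrum, sticks: StickSpectrum, bounds):
    grid = exp.energies
    dx = exp.spacing
    iexp = exp.intensities
    (dlo, dhi), (slo, shi) = bounds

    def raw_similarity(delta: float, sigma: float) -> float:
        return _cosine(iexp, broadened_profile(sticks, delta, sigma, grid), dx)

    def penalized(p: np.ndarray) -> float:
        d = float(np.clip(p[0], dlo, dhi))
        s = float(np.clip(p[1], slo, shi))
        excursion = (p[0] - d) ** 2 + (p[1] - s) ** 2
        return -raw_similarity(d, s) + _PENALTY_WEIGHT * excursion

    return raw_similarity, penalized


def _better(cand: tuple[float, float, float], best: tuple[float, float, float]) -> bool:
    """Tie-break: higher S, then smaller |delta|, then smaller sigma."""
    s, d, sig = cand
    bs, bd, bsig = best
    if s > bs + _TIE_TOL:
        return True
    if s < bs - _TIE_TOL:
        return False
    if abs(d) < abs(bd) - _TIE_TOL:
        return True
    if abs(d) > abs(bd) + _TIE_TOL:
        return False
    return sig < bsig - _TIE_TOL


def optimize_similarity(
    exp: Spectrum,
    sticks: StickSpectrum,
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    n_starts: tuple[int, int] = (3, 3),
    xatol: float = 1e-6,
    fatol: float = 1e-6,
    max_iter: int = 500,
) -> SimilarityResult:
    """Maximize the spectral similarity over (delta, sigma) within ``bounds``.

    Runs Nelder-Mead from an ``n_starts`` grid of interior starting points
    (fractions 1/(n+1) .. n/(n+1) of each box edge — no randomness) and
    returns the best point seen across all restarts and their starting
    values. Non-convergence on every restart is reported through the
    ``converged`` flag rather than an exception.
    """
    if not sticks.usable:
        raise DegenerateSpectrumError("all oscillator strengths are zero")
    (dlo, dhi), (slo, shi) = bounds
    if not (dlo < dhi and 0 < slo < shi):
        raise InputError(f"invalid bounds {bounds}")
    raw_similarity, penalized = _make_objective(exp, sticks, bounds)

    nd, ns = n_starts
    deltas0 = dlo + (dhi - dlo) * (np.arange(1, nd + 1) / (nd + 1))
    sigmas0 = slo + (shi - slo) * (np.arange(1, ns + 1) / (ns + 1))

    best: tuple[float, float, float] | None = None
    any_converged = False
    total_iter = 0
    restarts = 0
    for d0 in deltas0:
        for s0 in sigmas0:
            restarts += 1
            start = (raw_similarity(d0, s0), float(d0), float(s0))
            if best is None or _better(start, best):
                best = start
            res = minimize(
                penalized,
                x0=np.array([d0, s0]),
                method="Nelder-Mead",
                options={"xatol": xatol, "fatol": fatol, "maxiter": max_iter},
            )
            total_iter += int(res.nit)
            any_converged = any_converged or bool(res.success)
            d = float(np.clip(res.x[0], dlo, dhi))
            s = float(np.clip(res.x[1], slo, shi))
            cand = (raw_similarity(d, s), d, s)
            if _better(cand, best):
                best = cand

    s_best, d_best, sig_best = best
    return SimilarityResult(
        s_max=s_best,
        delta_opt=d_best,
        sigma_opt=sig_best,
        window=exp.window,
        converged=any_converged,
        n_iterations=total_iter,
        n_restarts=restarts,
    )


def grid_scan_similarity(
    exp: Spectrum,
    sticks: StickSpectrum,
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    delta_step: float = 0.01,
    sigma_step: float = 0.005,
) -> tuple[float, float, float]:
    """Exhaustive (delta, sigma) scan; returns (S, delta, sigma) at the best node.

    Brute-force reference for the simplex optimizer — slow but assumption
    free.
    """
    raw_similarity, _ = _make_objective(exp, sticks, bounds)
    (dlo, dhi), (slo, shi) = bounds
    deltas = np.arange(dlo, dhi + delta_step / 2, delta_step)
    sigmas = np.arange(slo, shi + sigma_step / 2, sigma_step)
    best = (-1.0, 0.0, 0.0)
    for d in deltas:
        for s in sigmas:
            val = raw_similarity(float(d), float(s))
            if val > best[0]:
                best = (val, float(d), float(s))
    return best
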