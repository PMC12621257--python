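"""Physical constants and unit conversions.

Single source of truth for every wavelength/energy/wavenumber conversion in
the package, so that windows, grid spacings and Jacobian factors can never
drift apart between modules.
"""

import math

#: hc in eV*nm (CODATA-consistent). E[eV] = HC_EV_NM / lambda[nm].
HC_EV_NM: float = 1239.841984

#: hc in eV*cm; E[eV] = HC_EV_CM * wavenumber[cm^-1].
HC_EV_CM: float = HC_EV_NM * 1e-7

#: The canonical resampling interval: 100 cm^-1 expressed in eV (~0.0124 eV).
DEFAULT_SPACING_EV: float = 100.0 * HC_EV_CM

#: FWHM of a Gaussian divided by its standard deviation: 2*sqrt(2*ln 2) ~ 2.355.
FWHM_PER_SIGMA: float = 2.0 * math.sqrt(2.0 * math.log(2.0))


def wavenumber_to_ev(wavenumber_cm: float) -> float:
    """Convert a wavenumber in cm^-1 to photon energy in eV."""
    return HC_EV_CM * wavenumber_cm


def nm_to_ev(wavelength_nm: float) -> float:
    """Convert a wavelength in nm to photon energy in eV."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    return HC_EV_NM / wavelength_nm


def ev_to_nm(energy_ev: float) -> float:
    """Convert a photon energy in eV to wavelength in nm."""
    if energy_ev <= 0:
        raise ValueError(f"energy must be positive, got {energy_ev}")
    return HC_EV_NM / energy_ev
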