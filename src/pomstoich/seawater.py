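"""One-atmosphere seawater density (EOS-80).

Implements the Millero & Poisson (1981) international one-atmosphere
equation of state, which is accurate to a few parts in 10^6 over oceanic
temperature/salinity ranges — far below the precision any layer-depth
criterion needs.  The potential density anomaly sigma-t is ``rho(S, T) -
1000`` evaluated at surface pressure; the thermal-expansion term used by
the mixed-layer criterion is obtained by centred finite difference so it
stays consistent with whatever density formula is in use.
"""

from __future__ import annotations

import numpy as np

__all__ = ["density", "sigma_t", "dsigma_dt"]


def density(salinity, temperature):
    """Seawater density rho(S, T) at 0 dbar, kg m^-3.

    Parameters
    ----------
    salinity : array_like
        Practical salinity (dimensionless, PSS-78).
    temperature : array_like
        Temperature, deg C (treated as potential temperature at surface
        pressure; the distinction is negligible at 0 dbar).
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    # pure-water part (Bigg 1967, as adopted by EOS-80)
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        8.24493e-1
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return rho_w + a * s + b * s**1.5 + c * s**2


def sigma_t(salinity, temperature):
    """Potential density anomaly sigma-t = rho(S, T) - 1000, kg m^-3."""
    return density(salinity, temperature) - 1000.0


def dsigma_dt(salinity, temperature, dt: float = 0.1):
    """d(sigma-t)/dT by centred finite difference, kg m^-3 degC^-1.

    Negative in normal oceanic conditions (warming lightens seawater).
    ``dt`` is the half-step temperature perturbation.
    """
    t = np.asarray(temperature, dtype=float)
    return (sigma_t(salinity, t + dt) - sigma_t(salinity, t - dt)) / (2.0 * dt)


def dsigma_ds(salinity, temperature, ds: float = 0.01):
    """d(sigma-t)/dS by centred finite difference, kg m^-3 (psu)^-1."""
    s = np.asarray(salinity, dtype=float)
    return (sigma_t(s + ds, temperature) - sigma_t(s - ds, temperature)) / (2.0 * ds)
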