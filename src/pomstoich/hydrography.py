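"""Hydrographic diagnostics from CTD/nutrient profiles.

Derives, per station: nutricline depth (first crossing of a nitrate
threshold), mixed layer depth (density criterion with a thermal-expansion
scaled temperature step), isothermal layer depth, barrier layer thickness,
corrected underway SST, latitudinal region labels for the eastern Indian
Ocean transect, and the SST-nutricline correlation.

Sign conventions: the mixed-layer criterion is a density *increase* of
``delta_t * |d(sigma)/dT|`` from the surface, and the isothermal-layer
criterion a temperature *decrease* of ``delta_t`` — the conventional
reading of the layer-depth definitions (the criterion sign is
configurable via ``sign``).  All crossings are found by scanning from the
surface and linearly interpolating within the first bracketing pair of
sampled depths; crossings are never bridged across vertical data gaps
wider than ``max_gap`` metres.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import seawater

__all__ = [
    "Profile",
    "LayerDepths",
    "Region",
    "InsufficientDataError",
    "derive_nutricline",
    "derive_mld",
    "derive_itl",
    "derive_blt",
    "derive_layer_depths",
    "correct_sst",
    "classify_region",
    "sst_nutricline_correlation",
]

#: Region latitude bounds (degrees north, half-open on the north side
#: except the final BoB bound): SIO gyre [-31, -12), EqIO [-12, 5),
#: BoB [5, 19].
SIO_SOUTH, SIO_NORTH = -31.0, -12.0
EQIO_NORTH = 5.0
BOB_NORTH = 19.0

#: Underway (Hydro Lab) temperature -> SST polynomial coefficients.
SST_CORRECTION_COEFFS = (0.001424, 0.950053, 0.048227)


class InsufficientDataError(ValueError):
    """A profile lacks the samples an operation needs."""


class Region(str, enum.Enum):
    """Latitudinal regions of the eastern Indian Ocean transect."""

    SIO_GYRE = "SIO_GYRE"
    EQIO = "EQIO"
    BOB = "BOB"
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class Profile:
    """One station's depth-resolved hydrography and nitrate.

    ``depth`` is metres, positive down and strictly increasing;
    ``sigma_t`` is the potential density anomaly (kg m^-3); ``nitrate``
    is micromolar.  ``sigma_t`` may be omitted, in which case it is
    computed from temperature and salinity with the built-in EOS.
    """

    station_id: str
    latitude: float
    longitude: float
    depth: np.ndarray
    temperature: np.ndarray
    salinity: np.ndarray
    sigma_t: np.ndarray | None = None
    nitrate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.salinity = np.asarray(self.salinity, dtype=float)
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError(f"{self.station_id}: depth must be strictly increasing")
        n = self.depth.size
        for name in ("temperature", "salinity"):
            if getattr(self, name).size != n:
                raise ValueError(f"{self.station_id}: {name} length mismatch")
        if self.sigma_t is None:
            self.sigma_t = seawater.sigma_t(self.salinity, self.temperature)
        else:
            self.sigma_t = np.asarray(self.sigma_t, dtype=float)
            if self.sigma_t.size != n:
                raise ValueError(f"{self.station_id}: sigma_t length mismatch")
        if self.nitrate is not None:
            self.nitrate = np.asarray(self.nitrate, dtype=float)
            if self.nitrate.size != n:
                raise ValueError(f"{self.station_id}: nitrate length mismatch")
            if np.any(self.nitrate[np.isfinite(self.nitrate)] < 0):
                raise ValueError(f"{self.station_id}: negative nitrate")


@dataclass
class LayerDepths:
    """Mixed-layer, isothermal-layer and barrier-layer diagnostics (m).

    ``blt = itl - mld`` when both are defined; a negative value marks a
    compensated layer (density-mixed deeper than temperature-mixed) and
    is reported, not clipped.  ``dsigma_dt`` is the surface thermal
    expansion term used in the density criterion, kg m^-3 degC^-1.
    """

    mld: float | None
    itl: float | None
    blt: float | None
    delta_t: float = 0.5
    dsigma_dt: float = field(default=np.nan)

    @property
    def is_compensated(self) -> bool:
        return self.blt is not None and self.blt < 0


def _first_crossing(
    depth: np.ndarray,
    values: np.ndarray,
    target: float,
    direction: str,
    max_gap: float = 50.0,
) -> float | None:
    """Shallowest depth at which ``values`` crosses ``target``.

    ``direction`` is ``"up"`` (value rises through target with depth) or
    ``"down"``.  Scans from the surface, interpolates linearly within the
    first bracketing pair, and refuses to bridge gaps wider than
    ``max_gap`` m between valid samples.  Returns None when the target is
    never reached (a flagged-undefined outcome, not an error).
    """
    ok = np.isfinite(values)
    d, v = depth[ok], values[ok]
    if v.size < 2:
        raise InsufficientDataError("need at least 2 valid samples")
    if direction == "down":
        v = -v
        target = -target
    if v[0] >= target:
        return float(d[0])
    for i in range(v.size - 1):
        if v[i] < target <= v[i + 1]:
            if d[i + 1] - d[i] > max_gap:
                return None
            frac = (target - v[i]) / (v[i + 1] - v[i])
            return float(d[i] + frac * (d[i + 1] - d[i]))
    return None


def derive_nutricline(
    profile: Profile, threshold: float = 1.0, max_gap: float = 50.0
) -> float | None:
    """Nutricline depth: shallowest depth where nitrate reaches ``threshold`` uM.

    Linear interpolation between the first bracketing pair scanning from
    the surface; if surface nitrate already exceeds the threshold the
    shallowest sampled depth is returned; None when nitrate never reaches
    the threshold.
    """
    if profile.nitrate is None or np.sum(np.isfinite(profile.nitrate)) < 2:
        raise InsufficientDataError(
            f"{profile.station_id}: <2 nitrate values, cannot derive nutricline"
        )
    return _first_crossing(profile.depth, profile.nitrate, threshold, "up", max_gap)


def derive_mld(
    profile: Profile,
    delta_t: float = 0.5,
    max_gap: float = 50.0,
    sign: float = 1.0,
    dt_fd: float = 0.1,
) -> float | None:
    """Mixed layer depth from the density criterion.

    Depth h where sigma_t(h) = sigma_t(0) + delta_t * |d(sigma)/dT|, the
    thermal expansion term evaluated at surface temperature and salinity
    by finite difference (half-step ``dt_fd`` degC).  ``sign=-1`` flips to
    a density-decrease criterion for sensitivity checks.
    """
    if not (np.isfinite(profile.sigma_t[0]) and np.isfinite(profile.temperature[0])):
        raise InsufficientDataError(f"{profile.station_id}: missing surface values")
    dsdt = seawater.dsigma_dt(profile.salinity[0], profile.temperature[0], dt=dt_fd)
    target = profile.sigma_t[0] + sign * delta_t * abs(float(dsdt))
    direction = "up" if sign > 0 else "down"
    d = _first_crossing(profile.depth[1:], profile.sigma_t[1:], target, direction, max_gap)
    return d


def derive_itl(
    profile: Profile, delta_t: float = 0.5, max_gap: float = 50.0, sign: float = -1.0
) -> float | None:
    """Isothermal layer depth: temperature departs delta_t degC from the surface.

    Applied as a 0.5 degC *decrease* by default (``sign=-1``); in-situ
    temperature is used.
    """
    if not np.isfinite(profile.temperature[0]):
        raise InsufficientDataError(f"{profile.station_id}: missing surface temperature")
    target = profile.temperature[0] + sign * delta_t
    direction = "down" if sign < 0 else "up"
    return _first_crossing(
        profile.depth[1:], profile.temperature[1:], target, direction, max_gap
    )


def derive_blt(itl: float | None, mld: float | None) -> float | None:
    """Barrier layer thickness BLT = ITL - MLD; None if either is undefined.

    Negative values (compensated layers) are returned as-is.
    """
    if itl is None or mld is None:
        return None
    return itl - mld


def derive_layer_depths(
    profile: Profile, delta_t: float = 0.5, max_gap: float = 50.0
) -> LayerDepths:
    """Convenience wrapper deriving MLD, ITL and BLT together."""
    mld = derive_mld(profile, delta_t=delta_t, max_gap=max_gap)
    itl = derive_itl(profile, delta_t=delta_t, max_gap=max_gap)
    dsdt = float(
        seawater.dsigma_dt(profile.salinity[0], profile.temperature[0], dt=0.1)
    )
    return LayerDepths(
        mld=mld, itl=itl, blt=derive_blt(itl, mld), delta_t=delta_t, dsigma_dt=dsdt
    )


def correct_sst(hlt):
    """Correct underway Hydro Lab temperature (HLT) to estimated SST (degC).

    Quadratic calibration ``0.001424*HLT^2 + 0.950053*HLT + 0.048227``,
    evaluated exactly as printed.  Inputs outside the plausible ocean
    range (-2..40 degC) trigger a warning but are still evaluated.
    """
    h = np.asarray(hlt, dtype=float)
    if np.any((h < -2.0) | (h > 40.0)):
        warnings.warn("HLT outside plausible ocean range (-2..40 degC)", stacklevel=2)
    a, b, c = SST_CORRECTION_COEFFS
    out = a * h**2 + b * h + c
    return float(out) if np.ndim(hlt) == 0 else out


def classify_region(latitude):
    """Assign transect region labels from latitude alone.

    SIO gyre [-31, -12), EqIO [-12, 5), BoB [5, 19]; OTHER outside.  The
    gyre's northern cutoff is 12 S (not 10 S) because of uncertainty in
    the gyre / Indonesian-throughflow transition.
    """
    lat = np.asarray(latitude, dtype=float)
    scalar = lat.ndim == 0
    lat = np.atleast_1d(lat)
    out = np.empty(lat.shape, dtype=object)
    out.fill(Region.OTHER)
    out[(lat >= SIO_SOUTH) & (lat < SIO_NORTH)] = Region.SIO_GYRE
    out[(lat >= SIO_NORTH) & (lat < EQIO_NORTH)] = Region.EQIO
    out[(lat >= EQIO_NORTH) & (lat <= BOB_NORTH)] = Region.BOB
    return out[0] if scalar else out


def sst_nutricline_correlation(sst, znut) -> float:
    """Pearson r between SST and nutricline depth over paired stations.

    Missing values in either series drop the pair.
    """
    s = np.asarray(sst, dtype=float)
    z = np.asarray(znut, dtype=float)
    ok = np.isfinite(s) & np.isfinite(z)
    if ok.sum() < 3:
        raise InsufficientDataError("need >=3 paired stations for a correlation")
    return float(stats.pearsonr(s[ok], z[ok]).statistic)
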