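"""Synthetic meridional cruise generator with known ground truth.

Emulates the structure of an eastern Indian Ocean underway transect
(roughly 31 S to 19 N along ~95 E): a ship steams north at constant
speed sampling POM triplicates, while station-level truth is built from

* piecewise-linear latitudinal SST and nutricline-depth maps with the
  observed negative SST-nutricline coupling (warm water over a shallow
  nutricline in the north, cool water over a deep nutricline in the
  gyre),
* POM baselines responding linearly to nutricline depth (or,
  alternatively, to SST), so environment-model fits have a known slope,
* a 24-h sinusoidal diel modulation with region-dependent fractional
  amplitude (smallest in the gyre) and per-element peak local hours
  (POC and POP peaking near dusk, PON in the early morning),
* multiplicative lognormal triplicate noise with a configured CV.

Every configured quantity is recorded in a :class:`SyntheticTruth`
before noise is applied, so each downstream stage (nutricline
derivation, diel fitting, environment-model slopes) has a
parameter-recovery oracle.  Identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from . import seawater
from .hydrography import Profile, Region, classify_region
from .stoichiometry import UnderwaySample, local_solar_hour

__all__ = [
    "CruiseConfig",
    "SyntheticTruth",
    "ConfigError",
    "generate_transect",
    "generate_profiles",
    "make_blt_profile",
    "samples_to_frame",
    "profiles_to_frame",
]


class ConfigError(ValueError):
    """Invalid cruise configuration."""


#: Default latitudinal maps: (latitude degN, value) knots.  SST rises
#: northward from the cool gyre into the warm equatorial band and Bay of
#: Bengal; the nutricline is deepest (129 m) in the gyre and shoals to
#: ~61-62 m in the north, giving the negative SST-nutricline coupling.
DEFAULT_SST_KNOTS = (
    (-31.0, 20.5), (-12.0, 28.5), (-10.0, 30.3), (0.0, 30.9),
    (5.0, 30.5), (19.0, 30.8),
)
DEFAULT_ZNUT_KNOTS = (
    (-31.0, 110.0), (-20.0, 129.0), (-12.0, 95.0), (-10.0, 62.0),
    (5.0, 61.0), (19.0, 61.0),
)

#: POM baseline response to the driver (default nutricline depth, m):
#: value = intercept + slope * driver.  Units: POC, PON uM; POP nM.
#: Chosen so regional mean ratios land near observed basin values
#: (gyre C:P ~150 and C:N ~7.6 falling to ~127 / ~7.1 in the north).
DEFAULT_POM_RESPONSE = {
    "poc": (3.4, -0.008),
    "pon": (0.502, -0.0015),
    "pop": (29.7, -0.112),
}

#: Fractional diel amplitudes per region per element; smallest in the
#: gyre, with POC cycling hardest.
DEFAULT_DIEL_AMPLITUDES = {
    "SIO_GYRE": {"poc": 0.04, "pon": 0.012, "pop": 0.016},
    "EQIO": {"poc": 0.08, "pon": 0.024, "pop": 0.032},
    "BOB": {"poc": 0.08, "pon": 0.024, "pop": 0.032},
    "OTHER": {"poc": 0.0, "pon": 0.0, "pop": 0.0},
}

#: Peak local solar hour per element: POC and POP near dusk, PON in the
#: small hours.
DEFAULT_DIEL_PHASES = {"poc": 18.0, "pon": 3.0, "pop": 18.0}

ELEMENTS = ("poc", "pon", "pop")


@dataclass
class CruiseConfig:
    """Ground-truth recipe for one synthetic cruise."""

    lat_start: float = -31.0
    lat_end: float = 19.0
    n_stations: int = 238
    ship_speed: float = 0.0703       # degrees latitude per hour northward
    longitude: float = 95.0
    start_time_utc: datetime = field(
        default_factory=lambda: datetime(2016, 3, 15, 0, 0, 0)
    )
    sst_profile: tuple = DEFAULT_SST_KNOTS
    znut_profile: tuple = DEFAULT_ZNUT_KNOTS
    pom_response: dict = field(default_factory=lambda: dict(DEFAULT_POM_RESPONSE))
    pom_driver: str = "znut"         # "znut" or "sst"
    diel_amplitudes: dict = field(
        default_factory=lambda: {r: dict(v) for r, v in DEFAULT_DIEL_AMPLITUDES.items()}
    )
    diel_phases: dict = field(default_factory=lambda: dict(DEFAULT_DIEL_PHASES))
    noise_cv: float = 0.05
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lat_start >= self.lat_end:
            raise ConfigError("lat_start must be south of lat_end")
        if self.n_stations < 8:
            raise ConfigError("n_stations must be >= 8")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.ship_speed <= 0:
            raise ConfigError("ship_speed must be > 0")
        if self.pom_driver not in ("znut", "sst"):
            raise ConfigError("pom_driver must be 'znut' or 'sst'")
        for name, knots in (("sst_profile", self.sst_profile),
                            ("znut_profile", self.znut_profile)):
            lats = [k[0] for k in knots]
            if min(lats) > self.lat_start or max(lats) < self.lat_end:
                raise ConfigError(
                    f"{name} knots must cover [{self.lat_start}, {self.lat_end}]"
                )

    def _interp(self, knots, lats: np.ndarray) -> np.ndarray:
        pts = sorted(knots)
        return np.interp(lats, [p[0] for p in pts], [p[1] for p in pts])

    def sst_at(self, lats) -> np.ndarray:
        return self._interp(self.sst_profile, np.asarray(lats, dtype=float))

    def znut_at(self, lats) -> np.ndarray:
        return self._interp(self.znut_profile, np.asarray(lats, dtype=float))


@dataclass
class SyntheticTruth:
    """Everything the generator knew before noise was added."""

    latitude: np.ndarray
    tot_hrs: np.ndarray
    local_hour: np.ndarray
    region: list
    sst_true: np.ndarray
    znut_true: np.ndarray
    baseline: dict          # element -> noise-free baseline (no diel)
    truth: dict             # element -> noise-free value incl. diel
    diel_fractional: dict   # region -> element -> configured fraction
    diel_amplitude_abs: dict  # region -> element -> fraction * regional mean baseline
    diel_peak_hour: dict    # element -> configured peak local hour
    slope_vs_znut: dict     # element -> least-squares slope of baseline on znut
    slope_vs_sst: dict
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = asdict(self)
        for key in ("latitude", "tot_hrs", "local_hour", "sst_true", "znut_true"):
            d[key] = np.asarray(d[key]).tolist()
        d["region"] = [str(r) for r in d["region"]]
        for key in ("baseline", "truth"):
            d[key] = {k: np.asarray(v).tolist() for k, v in d[key].items()}
        return d


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and coefficient of
    variation ``cv`` (exactly 1 when cv == 0)."""
    s2 = np.log1p(cv**2)
    s = np.sqrt(s2)
    return np.exp(rng.normal(-s2 / 2.0, s, size)) if cv > 0 else np.ones(size)


def generate_transect(config: CruiseConfig) -> tuple[list[UnderwaySample], SyntheticTruth]:
    """Generate the underway POM samples and their ground truth.

    Stations are ordered south to north with monotonically increasing
    timestamps set by the constant ship speed; each station carries
    ``n_replicates`` replicate values per element, drawn as
    truth * (1 + lognormal noise) at the configured CV.
    """
    rng = np.random.default_rng(config.seed)
    lats = np.linspace(config.lat_start, config.lat_end, config.n_stations)
    tot_hrs = (lats - config.lat_start) / config.ship_speed
    times = [config.start_time_utc + timedelta(hours=float(h)) for h in tot_hrs]
    local = np.array(
        [local_solar_hour(t, config.longitude) for t in times]
    )
    regions = [classify_region(lat) for lat in lats]
    sst = config.sst_at(lats)
    znut = config.znut_at(lats)
    driver = znut if config.pom_driver == "znut" else sst

    omega = 2.0 * np.pi / 24.0
    baseline, truth = {}, {}
    frac_amp = {r: dict(v) for r, v in config.diel_amplitudes.items()}
    for elem in ELEMENTS:
        b0, b1 = config.pom_response[elem]
        base = b0 + b1 * driver
        if np.any(base <= 0):
            raise ConfigError(f"{elem} baseline non-positive under this response")
        amp = np.array(
            [frac_amp.get(str(r), {}).get(elem, 0.0) for r in regions]
        )
        peak = config.diel_phases[elem]
        diel = 1.0 + amp * np.cos(omega * (local - peak))
        baseline[elem] = base
        truth[elem] = base * diel

    # absolute diel amplitudes: fraction times the regional mean baseline
    amp_abs: dict[str, dict[str, float]] = {}
    for reg in frac_amp:
        mask = np.array([str(r) == reg for r in regions])
        amp_abs[reg] = {
            elem: (
                float(frac_amp[reg][elem] * baseline[elem][mask].mean())
                if mask.any() else np.nan
            )
            for elem in ELEMENTS
        }

    slope_znut = {
        elem: float(np.polyfit(znut, baseline[elem], 1)[0]) for elem in ELEMENTS
    }
    slope_sst = {
        elem: float(np.polyfit(sst, baseline[elem], 1)[0]) for elem in ELEMENTS
    }

    samples = []
    n_rep = config.n_replicates
    for i in range(config.n_stations):
        reps = {}
        for elem in ELEMENTS:
            factors = _lognormal_factors(rng, config.noise_cv, n_rep)
            reps[elem] = truth[elem][i] * factors
        samples.append(
            UnderwaySample(
                station_id=f"S{i + 1:03d}",
                latitude=float(lats[i]),
                longitude=config.longitude,
                time_utc=times[i],
                poc_reps=reps["poc"],
                pon_reps=reps["pon"],
                pop_reps=reps["pop"],
                local_hour=float(local[i]),
            )
        )

    truth_obj = SyntheticTruth(
        latitude=lats,
        tot_hrs=tot_hrs,
        local_hour=local,
        region=regions,
        sst_true=sst,
        znut_true=znut,
        baseline=baseline,
        truth=truth,
        diel_fractional=frac_amp,
        diel_amplitude_abs=amp_abs,
        diel_peak_hour=dict(config.diel_phases),
        slope_vs_znut=slope_znut,
        slope_vs_sst=slope_sst,
        seed=config.seed,
    )
    return samples, truth_obj


def generate_profiles(
    config: CruiseConfig,
    depths: np.ndarray | None = None,
    salinity_stratified: bool = False,
    station_stride: int = 1,
) -> list[Profile]:
    """Depth-resolved T/S/sigma-t/nitrate profiles embedding the truth.

    Nitrate crosses 1 uM exactly at the configured nutricline depth
    (linear ramp of 0.1 uM/m through the nutricline, floored near the
    surface), temperature is mixed to 40 m then decreases at 0.08 degC/m,
    and sigma-t (from the built-in EOS) increases with depth.  With
    ``salinity_stratified`` a fresh surface lens adds a salinity gradient
    that makes the density-mixed layer shallower than the isothermal
    layer, producing a positive barrier layer thickness.
    """
    if depths is None:
        depths = np.arange(0.0, 302.5, 2.5)
    depths = np.asarray(depths, dtype=float)
    lats = np.linspace(config.lat_start, config.lat_end, config.n_stations)
    lats = lats[::station_stride]
    profiles = []
    for i, lat in enumerate(lats):
        sst = float(config.sst_at(lat))
        znut = float(config.znut_at(lat))
        temp = np.where(depths <= 40.0, sst, sst - 0.08 * (depths - 40.0))
        temp = np.maximum(temp, 4.0)
        if salinity_stratified:
            sal = 33.5 + 0.02 * depths
        else:
            sal = np.full_like(depths, 35.2)
        no3 = np.maximum(0.05, 1.0 + 0.1 * (depths - znut))
        profiles.append(
            Profile(
                station_id=f"P{i + 1:03d}",
                latitude=float(lat),
                longitude=config.longitude,
                depth=depths,
                temperature=temp,
                salinity=sal,
                nitrate=no3,
            )
        )
    return profiles


def make_blt_profile(
    sst: float = 29.0,
    s0: float = 33.5,
    mld: float = 40.0,
    itl: float = 60.0,
    depths: np.ndarray | None = None,
    delta_t: float = 0.5,
) -> tuple[Profile, dict]:
    """Construct a salinity-stratified profile with known MLD and ITL.

    Temperature is uniform down to ``itl - 5`` m, then falls at
    0.1 degC/m so it crosses ``sst - delta_t`` exactly at ``itl``.  A
    linear salinity gradient is sized (via the surface haline and
    thermal expansion terms of the EOS) so the density criterion is met
    at ``mld``; requires ``mld < itl - 5``.  Returns the profile and the
    analytic truth dict.
    """
    if not mld < itl - 5.0:
        raise ValueError("need mld < itl - 5 so the crossings are separable")
    if depths is None:
        depths = np.arange(0.0, 202.5, 2.5)
    depths = np.asarray(depths, dtype=float)
    dsdt = abs(float(seawater.dsigma_dt(s0, sst, dt=0.1)))
    dsds = float(seawater.dsigma_ds(s0, sst))
    grad_s = delta_t * dsdt / (dsds * mld)
    sal = s0 + grad_s * depths
    t_knee = itl - delta_t / 0.1
    temp = np.where(depths <= t_knee, sst, sst - 0.1 * (depths - t_knee))
    profile = Profile(
        station_id="BLT",
        latitude=10.0,
        longitude=90.0,
        depth=depths,
        temperature=temp,
        salinity=sal,
    )
    return profile, {"mld": mld, "itl": itl, "blt": itl - mld}


def samples_to_frame(samples: list[UnderwaySample]) -> pd.DataFrame:
    """Tidy long-format underway table (one row per station x replicate)."""
    rows = []
    for s in samples:
        n = max(s.poc_reps.size, s.pon_reps.size, s.pop_reps.size)
        for r in range(n):
            rows.append(
                {
                    "station_id": s.station_id,
                    "lat": s.latitude,
                    "lon": s.longitude,
                    "time_utc": s.time_utc.isoformat(),
                    "rep_id": r + 1,
                    "poc_uM": s.poc_reps[r] if r < s.poc_reps.size else np.nan,
                    "pon_uM": s.pon_reps[r] if r < s.pon_reps.size else np.nan,
                    "pop_nM": s.pop_reps[r] if r < s.pop_reps.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def profiles_to_frame(profiles: list[Profile]) -> pd.DataFrame:
    """Tidy long-format profile table (one row per station x depth)."""
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "station_id": p.station_id,
                    "lat": p.latitude,
                    "lon": p.longitude,
                    "depth_m": p.depth,
                    "temp_C": p.temperature,
                    "sal": p.salinity,
                    "sigma_t": p.sigma_t,
                    "no3_uM": p.nitrate,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
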