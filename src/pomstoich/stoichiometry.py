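"""Elemental ratios of particulate organic matter with pooled uncertainties.

Each underway station carries analytical triplicates of POC and PON (uM)
and POP (nM).  The ratio conventions are deliberately asymmetric, echoing
how the filters are analysed: every filter measured for both POC and PON
yields a per-filter C:N ratio, so C:N is the mean of per-filter ratios
with the population standard deviation of those ratios; C:P and N:P are
ratios of the mean concentrations, with uncertainties propagated in
relative-error quadrature from the replicate standard deviations:

    sigma_NP = (N/P) * sqrt((sigma_N/N)^2 + (sigma_P/P)^2)
    sigma_CP = (C/P) * sqrt((sigma_C/C)^2 + (sigma_P/P)^2)

POP is converted nM -> uM before any ratio is formed.  Standard
deviations use the population convention (denominator n) by default,
configurable through ``ddof``.  A uniform ratio-of-means mode exists for
sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np

__all__ = [
    "UnderwaySample",
    "RatioRecord",
    "DetectionLimits",
    "qc_filter",
    "compute_ratios",
    "local_solar_hour",
]

log = logging.getLogger(__name__)


def local_solar_hour(time_utc: datetime, longitude: float) -> float:
    """Local solar hour in [0, 24): UTC hour + longitude / 15.

    Solar time is the physically meaningful clock for day/night cycles;
    15 degrees of longitude correspond to one hour.
    """
    utc_h = time_utc.hour + time_utc.minute / 60.0 + time_utc.second / 3600.0
    return (utc_h + longitude / 15.0) % 24.0


@dataclass
class UnderwaySample:
    """One station's position, time and POM replicate measurements."""

    station_id: str
    latitude: float
    longitude: float
    time_utc: datetime
    poc_reps: np.ndarray  # uM
    pon_reps: np.ndarray  # uM
    pop_reps: np.ndarray  # nM
    local_hour: float | None = None

    def __post_init__(self) -> None:
        for name in ("poc_reps", "pon_reps", "pop_reps"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.local_hour is None:
            self.local_hour = local_solar_hour(self.time_utc, self.longitude)


@dataclass
class DetectionLimits:
    """Analytical detection windows used for replicate-level QC.

    POC and PON bounds are the dry-combustion protocol's detection range
    in seawater (uM); the POP floor is the ash-hydrolysis assay detection
    limit (nM), with no meaningful upper bound.
    """

    poc: tuple[float, float] = (0.43, 43.13)
    pon: tuple[float, float] = (0.037, 7.39)
    pop: tuple[float, float] = (0.1, np.inf)


@dataclass
class RatioRecord:
    """Molar elemental ratios and pooled standard deviations for a station.

    ``p_ave`` is in uM (converted from the nM replicates).
    """

    station_id: str
    cn_mean: float
    cn_sigma: float
    cp_mean: float
    cp_sigma: float
    np_mean: float
    np_sigma: float
    c_ave: float
    n_ave: float
    p_ave: float
    n_reps: dict = field(default_factory=dict)


def qc_filter(
    sample: UnderwaySample, limits: DetectionLimits | None = None
) -> UnderwaySample | None:
    """Drop replicates outside the detection ranges.

    Returns a new sample with the surviving replicates, or None (with a
    logged reason) when any element is left with no replicate.
    """
    limits = limits or DetectionLimits()
    kept = {}
    for name, (lo, hi) in (
        ("poc_reps", limits.poc),
        ("pon_reps", limits.pon),
        ("pop_reps", limits.pop),
    ):
        reps = getattr(sample, name)
        ok = np.isfinite(reps) & (reps >= lo) & (reps <= hi)
        n_dropped = int(reps.size - ok.sum())
        if n_dropped:
            log.info(
                "%s: dropped %d %s replicate(s) outside [%g, %g]",
                sample.station_id, n_dropped, name[:3].upper(), lo, hi,
            )
        kept[name] = reps[ok]
    empty = [k[:3].upper() for k, v in kept.items() if v.size == 0]
    if empty:
        log.warning(
            "%s: rejected — no surviving replicate for %s",
            sample.station_id, ", ".join(empty),
        )
        return None
    return replace(sample, **kept)


def _pop_sd(x: np.ndarray, ddof: int) -> float:
    if x.size <= ddof:
        return 0.0
    return float(np.std(x, ddof=ddof))


def compute_ratios(
    sample: UnderwaySample, ddof: int = 0, mode: str = "per_filter_cn"
) -> RatioRecord:
    """Compute C:N, C:P and N:P with pooled standard deviations.

    ``mode="per_filter_cn"`` (default) pairs POC/PON replicates by filter
    for C:N; ``mode="ratio_of_means"`` treats all three ratios uniformly
    as ratios of mean concentrations with quadrature sigmas.
    """
    c = sample.poc_reps
    n = sample.pon_reps
    p_um = sample.pop_reps / 1000.0  # nM -> uM
    c_ave, n_ave, p_ave = float(np.mean(c)), float(np.mean(n)), float(np.mean(p_um))
    if min(c_ave, n_ave, p_ave) <= 0:
        raise ValueError(f"{sample.station_id}: non-positive mean concentration")

    sig_c, sig_n, sig_p = _pop_sd(c, ddof), _pop_sd(n, ddof), _pop_sd(p_um, ddof)

    if mode == "per_filter_cn":
        k = min(c.size, n.size)
        cn_i = c[:k] / n[:k]
        cn_mean = float(np.mean(cn_i))
        cn_sigma = _pop_sd(cn_i, ddof)
    elif mode == "ratio_of_means":
        cn_mean = c_ave / n_ave
        cn_sigma = cn_mean * float(
            np.sqrt((sig_c / c_ave) ** 2 + (sig_n / n_ave) ** 2)
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    cp_mean = c_ave / p_ave
    np_mean = n_ave / p_ave
    cp_sigma = cp_mean * float(np.sqrt((sig_c / c_ave) ** 2 + (sig_p / p_ave) ** 2))
    np_sigma = np_mean * float(np.sqrt((sig_n / n_ave) ** 2 + (sig_p / p_ave) ** 2))

    return RatioRecord(
        station_id=sample.station_id,
        cn_mean=cn_mean,
        cn_sigma=cn_sigma,
        cp_mean=cp_mean,
        cp_sigma=cp_sigma,
        np_mean=np_mean,
        np_sigma=np_sigma,
        c_ave=c_ave,
        n_ave=n_ave,
        p_ave=p_ave,
        n_reps={"poc": int(c.size), "pon": int(n.size), "pop": int(p_um.size)},
    )
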