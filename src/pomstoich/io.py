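"""Tidy-CSV readers/writers and run metadata.

The canonical interchange formats are tidy long-format CSVs:

* underway table: station_id, lat, lon, time_utc, rep_id, poc_uM,
  pon_uM, pop_nM (one row per station x replicate);
* profile table: station_id, lat, lon, depth_m, temp_C, sal, sigma_t,
  no3_uM (one row per station x depth);
* global POM database: lat, lon, depth_m, poc_uM, pon_uM, pop_nM,
  temp_C, znut_m;
* climatology grid: lat, lon, znut_m, po4_uM.

Output CSVs carry a commented metadata header (# key: value) recording
the package version, seed and a hash of the configuration, so every
product is traceable to the run that made it.  For real GO-SHIP bottle
files in the CCHDO "exchange" dialect, ``EXCHANGE_COLUMN_MAP`` documents
the column mapping into the profile table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hydrography import Profile
from .stoichiometry import UnderwaySample

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_underway",
    "read_profiles",
    "read_global_pom",
    "read_climatology",
    "write_csv",
    "read_csv",
    "write_truth_json",
    "EXCHANGE_COLUMN_MAP",
]

#: Mapping from CCHDO bottle-exchange column names to the profile table,
#: for converting real hydrographic data into the canonical dialect.
EXCHANGE_COLUMN_MAP = {
    "STNNBR": "station_id",
    "LATITUDE": "lat",
    "LONGITUDE": "lon",
    "CTDPRS": "depth_m",   # decibar ~ metre near the surface
    "CTDTMP": "temp_C",
    "CTDSAL": "sal",
    "NITRAT": "no3_uM",
}


@dataclass
class PipelineConfig:
    """Thresholds, sampler settings and paths for one pipeline run."""

    underway_path: str | None = None
    profiles_path: str | None = None
    output_dir: str = "pomstoich_out"
    nutricline_threshold: float = 1.0   # uM nitrate
    delta_t: float = 0.5                # degC layer criterion
    gyre_znut_threshold: float = 150.0  # m
    smoothing_window: int = 8
    mh_chains: int = 4
    mh_steps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nutricline_threshold", "delta_t", "gyre_znut_threshold",
                     "smoothing_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _metadata_header(config: PipelineConfig | None, seed: int | None) -> list[str]:
    from . import __version__

    lines = [f"# pomstoich_version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config.hash()}")
    return lines


def write_csv(
    df: pd.DataFrame,
    path: str | Path,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> None:
    """Write a CSV with a commented metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _metadata_header(config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV, ignoring commented metadata headers."""
    return pd.read_csv(path, comment="#")


def write_truth_json(truth, path: str | Path) -> None:
    """Write a synthetic-truth sidecar as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1)


def read_underway(path: str | Path) -> list[UnderwaySample]:
    """Read the tidy underway table into validated station samples.

    Rows with non-positive concentrations are rejected (and logged);
    duplicated (station, rep_id) pairs are an error; the local solar
    hour is computed from the UTC timestamp and longitude.
    """
    df = read_csv(path)
    required = {"station_id", "lat", "lon", "time_utc", "rep_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"underway table missing columns: {sorted(missing)}")
    if df.duplicated(subset=["station_id", "rep_id"]).any():
        raise ValueError("duplicated (station_id, rep_id) rows in underway table")

    samples = []
    for sid, grp in df.groupby("station_id", sort=False):
        reps = {}
        for col, elem in (("poc_uM", "poc"), ("pon_uM", "pon"), ("pop_nM", "pop")):
            vals = grp[col].to_numpy(dtype=float)
            bad = np.isfinite(vals) & (vals <= 0)
            if bad.any():
                log.warning(
                    "%s: rejected %d non-positive %s replicate(s)",
                    sid, int(bad.sum()), elem.upper(),
                )
                vals = vals[~bad]
            reps[elem] = vals[np.isfinite(vals)]
        samples.append(
            UnderwaySample(
                station_id=str(sid),
                latitude=float(grp["lat"].iloc[0]),
                longitude=float(grp["lon"].iloc[0]),
                time_utc=datetime.fromisoformat(str(grp["time_utc"].iloc[0])),
                poc_reps=reps["poc"],
                pon_reps=reps["pon"],
                pop_reps=reps["pop"],
            )
        )
    return samples


def read_profiles(path: str | Path) -> list[Profile]:
    """Read the tidy profile table into validated Profile objects."""
    df = read_csv(path)
    profiles = []
    for sid, grp in df.groupby("station_id", sort=False):
        grp = grp.sort_values("depth_m")
        profiles.append(
            Profile(
                station_id=str(sid),
                latitude=float(grp["lat"].iloc[0]),
                longitude=float(grp["lon"].iloc[0]),
                depth=grp["depth_m"].to_numpy(dtype=float),
                temperature=grp["temp_C"].to_numpy(dtype=float),
                salinity=grp["sal"].to_numpy(dtype=float),
                sigma_t=(
                    grp["sigma_t"].to_numpy(dtype=float)
                    if "sigma_t" in grp.columns else None
                ),
                nitrate=(
                    grp["no3_uM"].to_numpy(dtype=float)
                    if "no3_uM" in grp.columns else None
                ),
            )
        )
    return profiles


def read_global_pom(path: str | Path) -> pd.DataFrame:
    """Read the global POM database table (tidy CSV)."""
    df = read_csv(path)
    required = {"lat", "lon", "depth_m", "poc_uM", "pon_uM", "pop_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"global POM table missing columns: {sorted(missing)}")
    return df


def read_climatology(path: str | Path) -> pd.DataFrame:
    """Read the gridded climatology table (lat, lon, znut_m, po4_uM)."""
    df = read_csv(path)
    if "znut_m" not in df.columns:
        raise ValueError("climatology table must have a znut_m column")
    return df
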