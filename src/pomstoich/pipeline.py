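"""End-to-end pipeline: hydrography -> stoichiometry -> diel -> models -> regional.

``run_pipeline`` consumes underway samples and profiles (from files or
passed in-memory, e.g. straight from the synthetic generator), derives
per-station hydrographic diagnostics, elemental ratios with pooled
uncertainties, diel residual fits per region, sinusoid + environment
model fits for each POM variable against SST and nutricline depth, and
regional summary/ANOVA tables.  Every output CSV carries the package
version, seed and config hash; a fixed seed makes reruns byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diel as diel_mod
from . import hydrography as hydro
from . import io as io_mod
from . import regional as regional_mod
from . import stoichiometry as stoich
from .models import EnvHarmonicModel, compare_predictors

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "station_table", "hydrography_table"]

RATIO_VARS = ["poc", "pon", "pop", "cp", "cn", "np_ratio"]


def hydrography_table(profiles, config: io_mod.PipelineConfig) -> pd.DataFrame:
    """Per-station nutricline/MLD/ITL/BLT diagnostics plus region label."""
    rows = []
    for p in profiles:
        znut = hydro.derive_nutricline(p, threshold=config.nutricline_threshold)
        layers = hydro.derive_layer_depths(p, delta_t=config.delta_t)
        rows.append(
            {
                "station_id": p.station_id,
                "lat": p.latitude,
                "lon": p.longitude,
                "surface_temp_C": float(p.temperature[0]),
                "znut_m": np.nan if znut is None else znut,
                "mld_m": np.nan if layers.mld is None else layers.mld,
                "itl_m": np.nan if layers.itl is None else layers.itl,
                "blt_m": np.nan if layers.blt is None else layers.blt,
                "region": str(hydro.classify_region(p.latitude)),
            }
        )
    return pd.DataFrame(rows)


def station_table(samples, hydro_df: pd.DataFrame | None = None) -> pd.DataFrame:
    """QC'd per-station ratio table with time base and region labels.

    When a hydrography table is available, nutricline depth and surface
    temperature are interpolated onto station latitudes to serve as
    environmental predictors.
    """
    t0 = min(s.time_utc for s in samples)
    rows = []
    for s in sorted(samples, key=lambda s: s.time_utc):
        qc = stoich.qc_filter(s)
        if qc is None:
            continue
        rec = stoich.compute_ratios(qc)
        rows.append(
            {
                "station_id": s.station_id,
                "lat": s.latitude,
                "lon": s.longitude,
                "tot_hrs": (s.time_utc - t0).total_seconds() / 3600.0,
                "local_hour": s.local_hour,
                "region": str(hydro.classify_region(s.latitude)),
                "poc": rec.c_ave,
                "pon": rec.n_ave,
                "pop": rec.p_ave * 1000.0,  # report POP back in nM
                "cn": rec.cn_mean,
                "cn_sigma": rec.cn_sigma,
                "cp": rec.cp_mean,
                "cp_sigma": rec.cp_sigma,
                "np_ratio": rec.np_mean,
                "np_sigma": rec.np_sigma,
            }
        )
    df = pd.DataFrame(rows)
    if hydro_df is not None and not hydro_df.empty:
        h = hydro_df.sort_values("lat")
        ok = h["znut_m"].notna()
        df["znut_m"] = np.interp(df["lat"], h.loc[ok, "lat"], h.loc[ok, "znut_m"])
        df["sst_C"] = hydro.correct_sst(
            np.interp(df["lat"], h["lat"], h["surface_temp_C"])
        )
    return df


def _diel_products(df: pd.DataFrame, window: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residual series and per-region diel fits for every POM variable."""
    df = df.sort_values("tot_hrs").reset_index(drop=True)
    resid_df = df[["station_id", "lat", "tot_hrs", "local_hour", "region"]].copy()
    fits = []
    for var in RATIO_VARS:
        smoothed = diel_mod.moving_average(df[var].to_numpy(), window=window)
        res = diel_mod.residuals(df[var].to_numpy(), smoothed)
        resid_df[f"{var}_smoothed"] = smoothed
        resid_df[f"{var}_residual"] = res
        for region, grp in resid_df.groupby("region", sort=False):
            try:
                fit = diel_mod.fit_diel_sine(
                    grp["local_hour"], grp[f"{var}_residual"],
                    variable=var, region=str(region),
                )
            except (ValueError, np.linalg.LinAlgError) as err:
                log.warning("diel fit skipped for %s/%s: %s", var, region, err)
                continue
            fits.append(
                {
                    "variable": var,
                    "region": str(region),
                    "amplitude": fit.amplitude,
                    "phase_rad": fit.phase,
                    "peak_local_hour": fit.peak_local_hour,
                    "daily_range": fit.daily_range,
                    "rmse": fit.rmse,
                    "n": fit.n_points,
                }
            )
    return resid_df, pd.DataFrame(fits)


def _env_fits(df: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    fits = []
    for var in RATIO_VARS:
        for pred in predictors:
            try:
                fit = EnvHarmonicModel.from_dataframe(
                    df, variable=var, predictor=pred
                ).fit()
            except ValueError as err:
                log.warning("env fit skipped for %s ~ %s: %s", var, pred, err)
                continue
            fits.append(fit)
    return pd.DataFrame(
        [
            {
                "variable": f.variable,
                "predictor": f.predictor,
                "p1_amplitude": f.p1,
                "p2_phase_rad": f.p2,
                "p3_intercept": f.p3,
                "p4_slope": f.p4,
                "rmse": f.rmse,
                "r2": f.r2,
                "n": f.n,
            }
            for f in fits
        ]
    ), fits


def run_pipeline(
    config: io_mod.PipelineConfig,
    samples=None,
    profiles=None,
    write: bool = True,
) -> dict:
    """Execute the full pipeline and (optionally) write the output bundle.

    Inputs come from ``config`` paths unless ``samples``/``profiles``
    are given directly.  Returns a dict of DataFrames:
    hydrography, stations, residuals, diel_fits, env_fits,
    predictor_comparison, regional_summary, regional_anova.
    """
    if samples is None:
        if config.underway_path is None:
            raise FileNotFoundError("no underway input: set underway_path")
        samples = io_mod.read_underway(config.underway_path)
    if profiles is None and config.profiles_path is not None:
        profiles = io_mod.read_profiles(config.profiles_path)

    bundle: dict[str, pd.DataFrame] = {}
    hydro_df = (
        hydrography_table(profiles, config) if profiles else pd.DataFrame()
    )
    bundle["hydrography"] = hydro_df

    stations = station_table(samples, hydro_df if not hydro_df.empty else None)
    bundle["stations"] = stations

    resid_df, diel_fits = _diel_products(stations, config.smoothing_window)
    bundle["residuals"] = resid_df
    bundle["diel_fits"] = diel_fits

    predictors = [p for p in ("sst_C", "znut_m") if p in stations.columns]
    if predictors:
        env_df, env_fit_objs = _env_fits(stations, predictors)
        bundle["env_fits"] = env_df
        if env_fit_objs:
            bundle["predictor_comparison"] = compare_predictors(env_fit_objs)

    summary = regional_mod.regional_summary(
        stations[stations["region"] != "OTHER"], RATIO_VARS
    )
    bundle["regional_summary"] = summary
    anova_rows = []
    for var in RATIO_VARS:
        try:
            res = regional_mod.regional_anova(
                stations[stations["region"] != "OTHER"], var
            )
        except ValueError as err:
            log.warning("ANOVA skipped for %s: %s", var, err)
            continue
        for _, row in res["pairwise"].iterrows():
            anova_rows.append(
                {
                    "variable": var,
                    "f_stat": res["f_stat"],
                    "p_overall": res["p_value"],
                    "region_a": row["region_a"],
                    "region_b": row["region_b"],
                    "p_pairwise": row["p_value"],
                    "stars": row["stars"],
                }
            )
    bundle["regional_anova"] = pd.DataFrame(anova_rows)

    if write:
        out = Path(config.output_dir)
        for name, df in bundle.items():
            if isinstance(df, pd.DataFrame) and not df.empty:
                io_mod.write_csv(df, out / f"{name}.csv", config=config,
                                 seed=config.seed)
    return bundle
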