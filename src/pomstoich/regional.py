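"""Regional summaries, significance tests, and subtropical-gyre comparisons.

Regional statistics summarise POM concentrations and ratios per transect
region (SIO gyre, EqIO, BoB) and test for differences with a one-way
ANOVA followed by Holm-corrected pairwise Welch t-tests, star-encoded at
p < 0.05 / 0.01 / 0.001.

For the global comparison, the five subtropical gyres are delimited by
longitude blocks and a nutricline-depth criterion (> 150 m) applied to a
climatology grid; per-gyre medians are expressed as anomalies relative
to the cross-gyre mean (the unweighted mean of gyre medians, so the
anomalies of fully reported variables sum to zero).  Sign tables of
Metropolis-Hastings posterior slopes on max-normalised inputs support
the basin-vs-global comparison (e.g. the temperature slope flipping sign
between the Indian Ocean and the global database).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import MHConfig, mh_linear_slope

log = logging.getLogger(__name__)

__all__ = [
    "GYRE_LONGITUDE_BLOCKS",
    "regional_summary",
    "regional_anova",
    "select_gyres",
    "gyre_anomalies",
    "slope_sign_comparison",
    "filter_surface",
    "stars",
]

#: Longitude blocks (west edge, east edge, degrees east in [-180, 180))
#: delimiting each subtropical gyre; blocks crossing the antimeridian
#: (North and South Pacific) wrap.
GYRE_LONGITUDE_BLOCKS: dict[str, tuple[float, float]] = {
    "North Atlantic": (-90.0, -5.0),
    "North Pacific": (120.0, -100.0),
    "South Atlantic": (-60.0, 10.0),
    "South Pacific": (150.0, -60.0),
    "South Indian": (30.0, 150.0),
}


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.minimum(1.0, np.maximum.accumulate((m - np.arange(m)) * p[order]))
    out = np.empty(m)
    out[order] = adj
    return out


def stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def regional_summary(
    df: pd.DataFrame, variables: list[str], region_col: str = "region"
) -> pd.DataFrame:
    """Per-region mean/median/SD/n for the given variables.

    Station-level values (per-station ratios or concentrations) are
    aggregated, i.e. a regional mean ratio is the mean of per-station
    ratios.
    """
    rows = []
    for region, grp in df.groupby(region_col, sort=False):
        for v in variables:
            vals = grp[v].dropna()
            rows.append(
                {
                    "region": str(region),
                    "variable": v,
                    "mean": vals.mean(),
                    "median": vals.median(),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


def regional_anova(
    df: pd.DataFrame,
    variable: str,
    region_col: str = "region",
    method: str = "holm-welch",
) -> dict:
    """One-way ANOVA across regions plus pairwise post-hoc comparisons.

    Regions with fewer than 2 observations are excluded with a warning.
    Post-hoc pairwise comparisons are Welch t-tests with Holm correction
    (robust to unequal variances); ``method="tukey"`` switches to Tukey
    HSD.  Returns the overall ANOVA F/p and a pairwise table with star
    encoding.
    """
    groups = {}
    for region, grp in df.groupby(region_col, sort=False):
        vals = grp[variable].dropna().to_numpy()
        if vals.size < 2:
            log.warning("region %s excluded from ANOVA (n=%d < 2)", region, vals.size)
            continue
        groups[str(region)] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 regions with n >= 2")

    names = list(groups)
    f_stat, p_overall = stats.f_oneway(*groups.values())

    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    if method == "tukey":
        res = stats.tukey_hsd(*groups.values())
        pvals = [res.pvalue[names.index(a), names.index(b)] for a, b in pairs]
    elif method == "holm-welch":
        raw = [
            stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue
            for a, b in pairs
        ]
        pvals = holm_adjust(raw)
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")

    pairwise = pd.DataFrame(
        {
            "region_a": [a for a, _ in pairs],
            "region_b": [b for _, b in pairs],
            "p_value": pvals,
            "stars": [stars(p) for p in pvals],
        }
    )
    return {
        "variable": variable,
        "f_stat": float(f_stat),
        "p_value": float(p_overall),
        "stars": stars(float(p_overall)),
        "pairwise": pairwise,
    }


def _wrap_lon(lon: np.ndarray) -> np.ndarray:
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def _in_block(lon: np.ndarray, west: float, east: float) -> np.ndarray:
    lon = _wrap_lon(lon)
    if west <= east:
        return (lon >= west) & (lon < east)
    return (lon >= west) | (lon < east)  # wraps the antimeridian


def select_gyres(
    climatology: pd.DataFrame,
    blocks: dict[str, tuple[float, float]] | None = None,
    znut_threshold: float = 150.0,
    lon_col: str = "lon",
    lat_col: str = "lat",
    znut_col: str = "znut_m",
) -> dict[str, np.ndarray]:
    """Boolean masks of climatology grid cells belonging to each gyre.

    A cell belongs to a gyre when its nutricline depth exceeds
    ``znut_threshold`` (default 150 m) and its longitude falls in the
    gyre's block; blocks named "North ..."/"South ..." are additionally
    restricted to their hemisphere when a latitude column is present
    (the Pacific blocks overlap in longitude).  Selection is a pure
    per-cell predicate: idempotent and independent of grid ordering.
    """
    blocks = blocks or GYRE_LONGITUDE_BLOCKS
    deep = climatology[znut_col].to_numpy(dtype=float) > znut_threshold
    lon = climatology[lon_col].to_numpy(dtype=float)
    lat = (
        climatology[lat_col].to_numpy(dtype=float)
        if lat_col in climatology.columns else None
    )
    masks = {}
    for name, (w, e) in blocks.items():
        m = deep & _in_block(lon, w, e)
        if lat is not None:
            if name.startswith("North"):
                m &= lat > 0
            elif name.startswith("South"):
                m &= lat < 0
        masks[name] = m
    return masks


def gyre_anomalies(
    df: pd.DataFrame,
    variables: list[str],
    gyre_col: str = "gyre",
    center: str = "median",
) -> pd.DataFrame:
    """Per-gyre central values and anomalies relative to the cross-gyre mean.

    The cross-gyre mean is the unweighted mean of the per-gyre central
    values (median by default, ``center="mean"`` for the alternative)
    over the gyres that report the variable; gyres with no data for a
    variable are flagged missing with NaN anomaly.  When every gyre
    reports, the anomalies sum to zero by construction.
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    gyres = list(dict.fromkeys(df[gyre_col]))
    rows = []
    for v in variables:
        centers = {}
        for g in gyres:
            vals = df.loc[df[gyre_col] == g, v].dropna()
            centers[g] = getattr(vals, center)() if len(vals) else np.nan
        avail = [c for c in centers.values() if np.isfinite(c)]
        cross = float(np.mean(avail)) if avail else np.nan
        for g in gyres:
            c = centers[g]
            rows.append(
                {
                    "gyre": g,
                    "variable": v,
                    center: c,
                    "cross_gyre_mean": cross,
                    "anomaly": c - cross if np.isfinite(c) else np.nan,
                    "missing": not np.isfinite(c),
                }
            )
    return pd.DataFrame(rows)


def filter_surface(df: pd.DataFrame, max_depth: float = 30.0,
                   depth_col: str = "depth_m") -> pd.DataFrame:
    """Restrict observations to the near-surface layer (top 30 m)."""
    return df[df[depth_col] <= max_depth]


def slope_sign_comparison(
    datasets: dict[str, pd.DataFrame],
    variables: list[str],
    predictors: list[str],
    config: MHConfig | None = None,
) -> pd.DataFrame:
    """Posterior slope signs per dataset x variable x predictor.

    Each slope is the Metropolis-Hastings posterior mean on
    max-normalised inputs; the table records its sign, 95% interval and
    whether the interval excludes zero — enough to read off sign flips
    between e.g. the Indian Ocean transect and the global database.
    """
    cfg = config or MHConfig()
    rows = []
    for ds_name, df in datasets.items():
        for v in variables:
            for p in predictors:
                sub = df[[v, p]].dropna()
                post = mh_linear_slope(sub[p], sub[v], config=cfg)
                lo, hi = post.slope_ci95
                rows.append(
                    {
                        "dataset": ds_name,
                        "variable": v,
                        "predictor": p,
                        "slope_norm": post.slope_mean,
                        "sign": post.slope_sign,
                        "ci_lo": lo,
                        "ci_hi": hi,
                        "excludes_zero": (lo > 0) or (hi < 0),
                    }
                )
    return pd.DataFrame(rows)


def detect_sign_flips(table: pd.DataFrame) -> pd.DataFrame:
    """Variable x predictor pairs whose slope sign differs across datasets."""
    flips = []
    for (v, p), grp in table.groupby(["variable", "predictor"]):
        signs = set(grp["sign"])
        if len(signs - {0}) > 1:
            flips.append({"variable": v, "predictor": p,
                          "signs": dict(zip(grp["dataset"], grp["sign"]))})
    return pd.DataFrame(flips)
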