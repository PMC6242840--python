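"""Diel (24-hour) cycle extraction from underway transect series.

The transect trend is removed with an 8-sample moving average (the first
and last few positions average over fewer points); residuals from that
smooth carry the day/night signal, which is quantified per region by a
fixed-period sinusoid

    r(t) = A * sin(2*pi*t/24 + phi)

fitted by exact least squares in the linear basis {sin, cos}.  The fit is
exposed statsmodels-style: ``DielSineModel(hour, values).fit()`` returns
a ``DielFit`` results object carrying amplitude, phase, the analytically
derived peak local hour, RMSE, and a ``summary()``.

The daily range of a variable is the peak-to-trough of the fitted
sinusoid (2A).  A per-day biomass accumulation proxy is the daily POC
residual range normalised by the day's smoothed mean POC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "moving_average",
    "residuals",
    "DielSineModel",
    "DielFit",
    "fit_diel_sine",
    "daily_range",
    "poc_accumulation_proxy",
    "plot_diel_residuals",
]

OMEGA = 2.0 * np.pi / 24.0  # fixed diel angular frequency, rad / hour


def moving_average(series, window: int = 8) -> np.ndarray:
    """Centred ``window``-sample moving average with truncated edges.

    For the default window of 8, position i averages samples i-4 .. i+3;
    near the edges the window truncates to the available points, so the
    first and last few positions are averaged over fewer than 8 samples.
    Missing values are ignored within each window.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must have at least 2 points")
    half = window // 2
    out = np.empty(x.size)
    for i in range(x.size):
        lo = max(0, i - half)
        hi = min(x.size, i + window - half)
        w = x[lo:hi]
        w = w[np.isfinite(w)]
        out[i] = np.mean(w) if w.size else np.nan
    return out


def residuals(series, smoothed, orientation: str = "data_minus_smoothed") -> np.ndarray:
    """Residuals between observations and the smoothed transect trend.

    Default orientation is observation minus smooth; ``"smoothed_minus_
    data"`` flips the sign (amplitudes are invariant to the choice).
    """
    s = np.asarray(series, dtype=float)
    m = np.asarray(smoothed, dtype=float)
    if s.shape != m.shape:
        raise ValueError("series and smoothed must align")
    r = s - m
    if orientation == "smoothed_minus_data":
        r = -r
    elif orientation != "data_minus_smoothed":
        raise ValueError(f"unknown orientation {orientation!r}")
    return r


@dataclass
class DielFit:
    """Results of a fixed-24-h sinusoid fit.

    ``amplitude`` is in the units of the fitted variable and always
    non-negative; ``phase`` (radians, wrapped to (-pi, pi]) and
    ``peak_local_hour`` describe the same timing:
    peak = ((pi/2 - phase) / omega) mod 24.
    """

    amplitude: float
    phase: float
    peak_local_hour: float
    n_points: int
    rmse: float
    period_hours: float = 24.0
    variable: str = ""
    region: str = ""

    @property
    def daily_range(self) -> float:
        """Peak-to-trough excursion over one cycle, 2A."""
        return 2.0 * self.amplitude

    def predict(self, hour) -> np.ndarray:
        t = np.asarray(hour, dtype=float)
        return self.amplitude * np.sin(OMEGA * t + self.phase)

    def summary(self) -> str:
        lines = [
            f"Diel sinusoid fit{' — ' + self.variable if self.variable else ''}"
            f"{' (' + self.region + ')' if self.region else ''}",
            f"  period          24.00 h (fixed)",
            f"  amplitude       {self.amplitude:.6g}",
            f"  phase           {self.phase:+.4f} rad",
            f"  peak local hour {self.peak_local_hour:05.2f}",
            f"  daily range     {self.daily_range:.6g}",
            f"  rmse            {self.rmse:.6g}   n = {self.n_points}",
        ]
        return "\n".join(lines)


class DielSineModel:
    """Least-squares sinusoid with fixed 24-h period on residual series.

    Parameters
    ----------
    hour : array_like
        Local solar hour of each observation (any real number; only the
        value mod 24 matters).
    values : array_like
        Residual values in the variable's units.
    variable, region : str, optional
        Labels carried through to the results object.
    """

    def __init__(self, hour, values, variable: str = "", region: str = ""):
        hour = np.asarray(hour, dtype=float)
        values = np.asarray(values, dtype=float)
        ok = np.isfinite(hour) & np.isfinite(values)
        self.hour = hour[ok]
        self.values = values[ok]
        self.variable = variable
        self.region = region
        if self.hour.size < 6:
            raise ValueError("need at least 6 points for a diel fit")
        span = np.ptp(self.hour % 24.0)
        if span < 12.0:
            raise ValueError(
                f"local-time coverage spans only {span:.1f} h (<12 h); "
                "the diel fit would be poorly constrained"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str,
                       hour_col: str = "local_hour", **kw) -> "DielSineModel":
        return cls(df[hour_col].to_numpy(), df[value_col].to_numpy(), **kw)

    def fit(self) -> DielFit:
        t = self.hour
        X = np.column_stack([np.sin(OMEGA * t), np.cos(OMEGA * t)])
        # guard against degenerate time coverage (all points at one hour)
        if np.linalg.matrix_rank(X) < 2:
            raise np.linalg.LinAlgError("ill-conditioned diel design (degenerate hours)")
        coef, *_ = np.linalg.lstsq(X, self.values, rcond=None)
        a, b = coef
        amplitude = float(np.hypot(a, b))
        phase = float(np.arctan2(b, a))
        peak = ((np.pi / 2.0 - phase) / OMEGA) % 24.0
        resid = self.values - X @ coef
        rmse = float(np.sqrt(np.mean(resid**2)))
        return DielFit(
            amplitude=amplitude,
            phase=phase,
            peak_local_hour=float(peak),
            n_points=int(t.size),
            rmse=rmse,
            variable=self.variable,
            region=self.region,
        )


def fit_diel_sine(hour, values, variable: str = "", region: str = "") -> DielFit:
    """Functional wrapper: fit the fixed-24-h sinusoid to a residual series."""
    return DielSineModel(hour, values, variable=variable, region=region).fit()


def daily_range(fit: DielFit) -> float:
    """Daily peak-to-trough range implied by a diel fit (2A)."""
    return fit.daily_range


def plot_diel_residuals(hour, values, fit: DielFit | None = None, ax=None,
                        label: str | None = None, night=(18.0, 6.0)):
    """Scatter residuals against local hour with the fitted sinusoid.

    Shades local nighttime (default 18:00-06:00).  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.axvspan(0.0, night[1], color="0.85", zorder=0)
    ax.axvspan(night[0], 24.0, color="0.85", zorder=0)
    ax.scatter(np.asarray(hour) % 24.0, values, s=12, alpha=0.7, label=label)
    if fit is not None:
        grid = np.linspace(0, 24, 241)
        ax.plot(grid, fit.predict(grid), lw=1.5,
                label=f"A={fit.amplitude:.3g}, peak {fit.peak_local_hour:.1f} h")
    ax.set_xlim(0, 24)
    ax.set_xticks([0, 6, 12, 18, 24])
    ax.set_xlabel("local solar hour")
    ax.set_ylabel(f"{fit.variable or 'residual'}" if fit else "residual")
    if label or fit:
        ax.legend(frameon=False, fontsize=8)
    return ax


def poc_accumulation_proxy(
    local_day, poc_residual, poc_smoothed
) -> pd.DataFrame:
    """Per-day normalised POC accumulation proxy.

    For each local day (boundaries at local midnight), the proxy is the
    range (max - min) of the POC residuals that day divided by the day's
    mean smoothed POC.  For a clean sinusoid of amplitude A about a
    smoothed mean M this is 2A/M; a flat day gives 0.
    """
    df = pd.DataFrame(
        {
            "local_day": np.asarray(local_day),
            "residual": np.asarray(poc_residual, dtype=float),
            "smoothed": np.asarray(poc_smoothed, dtype=float),
        }
    ).dropna()
    if df.empty:
        raise ValueError("no valid observations for accumulation proxy")

    def _one(g: pd.DataFrame) -> pd.Series:
        rng = g["residual"].max() - g["residual"].min()
        mean_poc = g["smoothed"].mean()
        return pd.Series(
            {
                "range": rng,
                "mean_poc": mean_poc,
                "proxy": rng / mean_poc if mean_poc > 0 else np.nan,
                "n": len(g),
            }
        )

    out = df.groupby("local_day", sort=True).apply(_one, include_groups=False)
    return out.reset_index()
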