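"""Environment + diel models for POM variables, and Bayesian slope estimation.

Two model families:

1. ``EnvHarmonicModel`` — the sinusoid-plus-environment model

       y = p1 * sin(TotHrs * 2*pi/24 + p2) + p3 + p4 * x

   where y is a POM concentration or elemental ratio, TotHrs the
   cumulative cruise hours from the first station, and x an
   environmental predictor (SST, nutricline depth, or MLD).  Although
   the amplitude/phase pair makes the model look nonlinear, the
   reparameterisation p1*sin(wt+p2) = a*sin(wt) + b*cos(wt) makes it an
   ordinary linear least-squares problem; p1 = sqrt(a^2+b^2) >= 0 and
   p2 = atan2(b, a) wrapped to (-pi, pi] are recovered exactly.
   Competing predictors are compared by RMSE and R^2, with near-ties
   flagged as statistically indistinguishable.

2. ``BayesLinearModel`` — simple linear regression y ~ Normal(a + b*x,
   sigma) sampled with a random-walk Metropolis-Hastings algorithm.
   Inputs are normalised by their maxima (so slopes from datasets with
   different units/scales are comparable); priors are Normal(0, 10^2) on
   intercept and slope and half-Normal(1) on sigma; the proposal scale
   adapts during burn-in toward ~30% acceptance.  ``fit`` runs several
   chains and returns a results object with posterior draws, the
   posterior-mean slope, a central 95% interval, and a de-normalisation
   helper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OMEGA = 2.0 * np.pi / 24.0

__all__ = [
    "EnvModelFit",
    "EnvHarmonicModel",
    "fit_env_model",
    "compare_predictors",
    "regional_restriction_fit",
    "MHConfig",
    "SlopePosterior",
    "BayesLinearModel",
    "mh_linear_slope",
]


# ---------------------------------------------------------------------------
# sinusoid + environmental predictor
# ---------------------------------------------------------------------------

@dataclass
class EnvModelFit:
    """Fitted parameters of the sinusoid + environment model.

    p1: diel amplitude (variable units, >= 0); p2: phase, radians in
    (-pi, pi]; p3: intercept; p4: slope on the environmental predictor.
    """

    variable: str
    predictor: str
    p1: float
    p2: float
    p3: float
    p4: float
    rmse: float
    r2: float
    n: int
    bse: np.ndarray | None = None

    @property
    def params(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4])

    def predict(self, tot_hrs, x) -> np.ndarray:
        t = np.asarray(tot_hrs, dtype=float)
        xx = np.asarray(x, dtype=float)
        return self.p1 * np.sin(OMEGA * t + self.p2) + self.p3 + self.p4 * xx

    def summary(self) -> str:
        lines = [
            f"Sinusoid + environment fit: {self.variable or 'y'} ~ "
            f"sin(24 h) + {self.predictor or 'x'}",
            f"  p1 (amplitude)  {self.p1:.6g}",
            f"  p2 (phase)      {self.p2:+.4f} rad",
            f"  p3 (intercept)  {self.p3:.6g}",
            f"  p4 (slope)      {self.p4:.6g}",
            f"  rmse {self.rmse:.6g}   R^2 {self.r2:.4f}   n {self.n}",
        ]
        return "\n".join(lines)


class EnvHarmonicModel:
    """Least-squares model y = p1*sin(w*t + p2) + p3 + p4*x, w = 2*pi/24.

    Parameters
    ----------
    y : array_like
        Response (POM concentration or ratio).
    tot_hrs : array_like
        Cumulative cruise hours; the origin is the first station's
        timestamp (the phase p2 is defined relative to it).
    x : array_like
        Environmental predictor (SST degC, nutricline depth m, or MLD m).
    """

    def __init__(self, y, tot_hrs, x, variable: str = "", predictor: str = ""):
        y = np.asarray(y, dtype=float)
        t = np.asarray(tot_hrs, dtype=float)
        xx = np.asarray(x, dtype=float)
        ok = np.isfinite(y) & np.isfinite(t) & np.isfinite(xx)
        self.y, self.tot_hrs, self.x = y[ok], t[ok], xx[ok]
        self.variable, self.predictor = variable, predictor
        if self.y.size < 8:
            raise ValueError("need at least 8 paired observations")
        if np.ptp(self.tot_hrs) < 24.0:
            raise ValueError("time base must span at least 24 h")
        if np.ptp(self.x) <= 1e-12 * max(1.0, np.abs(self.x).max()):
            raise ValueError(
                f"predictor {predictor or 'x'!r} is constant; slope p4 undefined"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, variable: str, predictor: str,
                       time_col: str = "tot_hrs") -> "EnvHarmonicModel":
        return cls(df[variable], df[time_col], df[predictor],
                   variable=variable, predictor=predictor)

    def fit(self) -> EnvModelFit:
        t, x, y = self.tot_hrs, self.x, self.y
        X = np.column_stack(
            [np.sin(OMEGA * t), np.cos(OMEGA * t), np.ones_like(t), x]
        )
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        a, b, p3, p4 = coef
        p1 = float(np.hypot(a, b))
        p2 = float(np.arctan2(b, a))
        if p2 <= -np.pi:  # wrap to (-pi, pi]
            p2 += 2.0 * np.pi
        resid = y - X @ coef
        rss = float(resid @ resid)
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        rmse = float(np.sqrt(rss / y.size))
        dof = max(y.size - 4, 1)
        sigma2 = rss / dof
        try:
            cov = sigma2 * np.linalg.inv(X.T @ X)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:  # pragma: no cover
            bse = None
        return EnvModelFit(
            variable=self.variable, predictor=self.predictor,
            p1=p1, p2=p2, p3=float(p3), p4=float(p4),
            rmse=rmse, r2=max(r2, 0.0), n=int(y.size), bse=bse,
        )


def fit_env_model(y, tot_hrs, x, variable: str = "", predictor: str = "") -> EnvModelFit:
    """Functional wrapper around :class:`EnvHarmonicModel`."""
    return EnvHarmonicModel(y, tot_hrs, x, variable=variable, predictor=predictor).fit()


def compare_predictors(fits: list[EnvModelFit], tie_frac: float = 0.01) -> pd.DataFrame:
    """Rank competing predictor fits of the same variable by RMSE.

    Fits whose RMSE is within ``tie_frac`` (fractional) of the best are
    flagged indistinguishable — the situation where diel + temperature
    and diel + nutricline depth explain the data equally well.
    """
    if not fits:
        raise ValueError("no fits to compare")
    rows = []
    for grp_var in sorted({f.variable for f in fits}):
        grp = [f for f in fits if f.variable == grp_var]
        best = min(f.rmse for f in grp)
        for f in sorted(grp, key=lambda f: f.rmse):
            rows.append(
                {
                    "variable": f.variable,
                    "predictor": f.predictor,
                    "rmse": f.rmse,
                    "r2": f.r2,
                    "n": f.n,
                    "best": f.rmse == best,
                    "tied_with_best": f.rmse <= best * (1.0 + tie_frac),
                }
            )
    return pd.DataFrame(rows)


def regional_restriction_fit(
    df: pd.DataFrame,
    variable: str,
    predictor: str,
    lat_cutoff: float = 5.0,
    lat_col: str = "latitude",
    time_col: str = "tot_hrs",
) -> EnvModelFit:
    """Refit the sinusoid + environment model south of a latitude cutoff.

    Used to gauge the influence of the Bay of Bengal (north of 5 N) on
    basin-wide fits.  An empty subset raises.
    """
    sub = df[df[lat_col] < lat_cutoff]
    if sub.empty:
        raise ValueError(f"no stations south of {lat_cutoff} degN")
    return EnvHarmonicModel.from_dataframe(
        sub, variable=variable, predictor=predictor, time_col=time_col
    ).fit()


# ---------------------------------------------------------------------------
# Metropolis-Hastings Bayesian linear regression
# ---------------------------------------------------------------------------

@dataclass
class MHConfig:
    """Sampler settings for the random-walk Metropolis-Hastings regression."""

    chains: int = 4
    steps: int = 10_000
    burn_frac: float = 0.5
    target_accept: float = 0.30
    prior_sd: float = 10.0       # Normal(0, prior_sd^2) on intercept & slope
    sigma_prior_scale: float = 1.0  # half-Normal scale on sigma
    seed: int = 0


@dataclass
class SlopePosterior:
    """Posterior draws and summaries for the normalised-scale regression.

    Slope and intercept are on the max-normalised scale (x/max(x),
    y/max(y)); ``denormalize_slope`` converts back to raw units.
    """

    samples: np.ndarray            # (n_draws, 3): intercept, slope, sigma
    chain_samples: np.ndarray      # (n_chains, n_draws_per_chain, 3)
    slope_mean: float
    slope_ci95: tuple[float, float]
    intercept_mean: float
    acceptance_rate: float
    x_max: float
    y_max: float
    seed: int
    sigma_fixed: float | None = None

    @property
    def slope_sd(self) -> float:
        return float(np.std(self.samples[:, 1], ddof=1))

    @property
    def slope_sign(self) -> int:
        return int(np.sign(self.slope_mean))

    def prob_slope_negative(self) -> float:
        return float(np.mean(self.samples[:, 1] < 0.0))

    def denormalize_slope(self, slope: float | None = None) -> float:
        """Convert a normalised-scale slope back to raw y-per-x units."""
        s = self.slope_mean if slope is None else slope
        return s * self.y_max / self.x_max

    def summary(self) -> str:
        lo, hi = self.slope_ci95
        return "\n".join(
            [
                "Bayesian linear regression (random-walk Metropolis-Hastings)",
                f"  draws {self.samples.shape[0]}   acceptance {self.acceptance_rate:.2f}",
                f"  slope (normalised)  {self.slope_mean:+.4f}  "
                f"95% CI [{lo:+.4f}, {hi:+.4f}]",
                f"  slope (raw units)   {self.denormalize_slope():+.6g}",
                f"  intercept (norm.)   {self.intercept_mean:+.4f}",
                f"  P(slope < 0)        {self.prob_slope_negative():.3f}",
            ]
        )


class BayesLinearModel:
    """y ~ Normal(alpha + beta * x, sigma) with max-normalised inputs.

    Parameters
    ----------
    x, y : array_like
        Paired observations; both are divided by their maxima before
        sampling (zero or non-finite maxima raise).
    normalize : bool
        Disable to sample on the raw scale.
    sigma : float, optional
        If given, the noise SD is held fixed (known-sigma model) and
        only intercept and slope are sampled.
    """

    def __init__(self, x, y, normalize: bool = True, sigma: float | None = None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3:
            raise ValueError("need at least 3 paired observations")
        if np.ptp(x) == 0:
            raise ValueError("x is constant; slope unidentified")
        if normalize:
            self.x_max = float(np.max(np.abs(x)))
            self.y_max = float(np.max(np.abs(y)))
            if self.x_max == 0 or self.y_max == 0:
                raise ValueError("zero maximum; cannot max-normalise")
        else:
            self.x_max = self.y_max = 1.0
        self.x = x / self.x_max
        self.y = y / self.y_max
        self.sigma_fixed = sigma

    # log posterior, vectorised over a (k, 3) state matrix
    def _log_post(self, theta: np.ndarray, cfg: MHConfig) -> np.ndarray:
        alpha, beta, sigma = theta[:, 0], theta[:, 1], theta[:, 2]
        lp = np.full(theta.shape[0], -np.inf)
        ok = sigma > 0
        if not np.any(ok):
            return lp
        a, b, s = alpha[ok], beta[ok], sigma[ok]
        resid = self.y[None, :] - (a[:, None] + b[:, None] * self.x[None, :])
        n = self.y.size
        loglik = -n * np.log(s) - 0.5 * np.sum(resid**2, axis=1) / s**2
        logprior = -(a**2 + b**2) / (2.0 * cfg.prior_sd**2)
        if self.sigma_fixed is None:
            logprior = logprior - s**2 / (2.0 * cfg.sigma_prior_scale**2)
        lp[ok] = loglik + logprior
        return lp

    def fit(self, config: MHConfig | None = None, **kw) -> SlopePosterior:
        cfg = config or MHConfig(**kw)
        rng = np.random.default_rng(cfg.seed)
        k = cfg.chains
        n_burn = int(cfg.steps * cfg.burn_frac)

        # overdispersed starts around the least-squares solution
        A = np.column_stack([np.ones_like(self.x), self.x])
        ols, *_ = np.linalg.lstsq(A, self.y, rcond=None)
        resid_sd = float(np.std(self.y - A @ ols)) or 0.1
        theta = np.empty((k, 3))
        theta[:, 0] = ols[0] + rng.normal(0, 0.5, k)
        theta[:, 1] = ols[1] + rng.normal(0, 0.5, k)
        if self.sigma_fixed is None:
            theta[:, 2] = resid_sd * np.exp(rng.normal(0, 0.3, k))
        else:
            theta[:, 2] = self.sigma_fixed

        scale = np.full(k, max(resid_sd, 1e-3))
        lp = self._log_post(theta, cfg)
        n_par = 2 if self.sigma_fixed is not None else 3
        kept = []
        accepted_post = 0
        proposed_post = 0
        acc_window = np.zeros(k)
        window = 200

        for step in range(cfg.steps):
            prop = theta.copy()
            prop[:, :n_par] += rng.normal(0, 1, (k, n_par)) * scale[:, None]
            lp_prop = self._log_post(prop, cfg)
            accept = np.log(rng.random(k)) < (lp_prop - lp)
            theta[accept] = prop[accept]
            lp[accept] = lp_prop[accept]
            acc_window += accept

            if step < n_burn:
                if (step + 1) % window == 0:
                    rate = acc_window / window
                    scale *= np.exp(rate - cfg.target_accept)
                    acc_window[:] = 0.0
            else:
                accepted_post += int(accept.sum())
                proposed_post += k
                kept.append(theta.copy())

        chain_samples = np.stack(kept, axis=1)  # (n_chains, draws, 3)
        samples = chain_samples.reshape(-1, 3)
        slope = samples[:, 1]
        lo, hi = np.percentile(slope, [2.5, 97.5])
        return SlopePosterior(
            samples=samples,
            chain_samples=chain_samples,
            slope_mean=float(slope.mean()),
            slope_ci95=(float(lo), float(hi)),
            intercept_mean=float(samples[:, 0].mean()),
            acceptance_rate=accepted_post / proposed_post,
            x_max=self.x_max,
            y_max=self.y_max,
            seed=cfg.seed,
            sigma_fixed=self.sigma_fixed,
        )


def mh_linear_slope(
    x, y, config: MHConfig | None = None, normalize: bool = True,
    sigma: float | None = None, **kw
) -> SlopePosterior:
    """Functional wrapper around :class:`BayesLinearModel`."""
    return BayesLinearModel(x, y, normalize=normalize, sigma=sigma).fit(config, **kw)
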