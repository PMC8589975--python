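"""Elevational/long-term trend models for hatching and snowmelt dates.

Linear mixed models of the form

    response ~ elev + elev^2 + year + elev:year + (1 | year)

are fitted by REML for three responses (mean hatching date, meltstart,
meltend).  Uncertainty is propagated by directly simulating from the joint
posterior of the parameters under flat coefficient priors and p(sigma)
proportional to 1/sigma: the residual variance is drawn from the implied
scaled inverse-chi-square and the coefficients from the conditional
multivariate normal, with the among-year variance held at its REML
estimate.  This is the classical "sim" shortcut; it is fast and adequate
for prediction bands.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

logger = logging.getLogger(__name__)

#: reference elevation (m asl): the species' density optimum, used to
#: centre the elevation axis
REFERENCE_ELEVATION_M = 2450.0


@dataclass
class TrendFit:
    response: str
    coef: np.ndarray                # (5,) intercept, elev, elev2, year, exy
    coef_names: list[str]
    cov: np.ndarray                 # covariance of coef at sigma = sigma_hat
    sigma_resid: float
    sigma_year: float
    df_resid: int
    centers: dict[str, float]       # centering/scaling constants
    scales: dict[str, float]
    singular: bool = False


@dataclass
class TrendPosterior:
    fit: TrendFit
    coef_draws: np.ndarray          # (n_draws, 5)
    sigma_draws: np.ndarray         # (n_draws,)

    @property
    def n_draws(self) -> int:
        return len(self.sigma_draws)


def _design(elev: np.ndarray, year: np.ndarray, centers, scales) -> np.ndarray:
    ze = (elev - centers["elevation"]) / scales["elevation"]
    zy = (year - centers["year"]) / scales["year"]
    return np.column_stack([np.ones_like(ze), ze, ze ** 2, zy, ze * zy])


def fit_trend(data: pd.DataFrame, response: str,
              elevation_col: str = "elevation",
              year_col: str = "year") -> TrendFit:
    """REML fit of the quadratic-elevation x year trend model.

    ``data`` needs the response column plus elevation and year.  Elevation
    is centred at 2450 m and scaled by its SD; year is centred mid-study
    and scaled by its SD.  A singular random-effect fit falls back to
    ordinary least squares with a warning.
    """
    need = {response, elevation_col, year_col}
    if not need.issubset(data.columns):
        raise KeyError(f"data missing columns {need - set(data.columns)}")
    df = data.dropna(subset=list(need))
    if len(df) < 10:
        raise ValueError("need at least 10 observations")
    year = df[year_col].to_numpy(dtype=float)
    if len(np.unique(year)) < 2:
        raise ValueError("need at least 2 distinct years")
    elev = df[elevation_col].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    centers = {"elevation": REFERENCE_ELEVATION_M, "year": float(year.mean())}
    scales = {"elevation": float(np.std(elev, ddof=1)),
              "year": max(float(np.std(year, ddof=1)), 1e-12)}
    X = _design(elev, year, centers, scales)
    names = ["intercept", "elevation", "elevation2", "year", "elevation_year"]

    singular = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = MixedLM(y, X, groups=year.astype(int))
            res = mod.fit(reml=True, method="lbfgs")
        sigma_year = float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0)))
        sigma = float(np.sqrt(res.scale))
        coef = np.asarray(res.fe_params, dtype=float)
        cov = np.asarray(res.cov_params())[:5, :5]
        if not np.all(np.isfinite(cov)) or sigma_year < 1e-8:
            raise np.linalg.LinAlgError("singular random-effect fit")
    except Exception as exc:  # singular / non-converged -> OLS fallback
        logger.warning("mixed-model fit failed (%s); falling back to OLS",
                       exc)
        singular = True
        ols = sm.OLS(y, X).fit()
        coef = np.asarray(ols.params)
        cov = np.asarray(ols.cov_params())
        sigma = float(np.sqrt(ols.mse_resid))
        sigma_year = 0.0
    return TrendFit(response, coef, names, cov, sigma, sigma_year,
                    len(df) - X.shape[1], centers, scales, singular)


def simulate_posterior(fit: TrendFit, n_draws: int = 10_000,
                       seed: int | None = None) -> TrendPosterior:
    """Joint posterior draws under flat priors.

    sigma^2 is drawn from df * sigma_hat^2 / chi2(df) (the posterior under
    p(sigma) ~ 1/sigma) and the coefficients from the conditional normal
    N(beta_hat, cov * sigma^2 / sigma_hat^2).
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    rng = np.random.default_rng(seed)
    df = max(fit.df_resid, 1)
    sigma2 = df * fit.sigma_resid ** 2 / rng.chisquare(df, n_draws)
    L = np.linalg.cholesky(fit.cov + 1e-12 * np.eye(len(fit.coef)))
    z = rng.standard_normal((n_draws, len(fit.coef)))
    scale = np.sqrt(sigma2 / max(fit.sigma_resid ** 2, 1e-300))
    coef = fit.coef[None, :] + (z @ L.T) * scale[:, None]
    return TrendPosterior(fit, coef, np.sqrt(sigma2))


def trend_surfaces(posterior: TrendPosterior, elevations: np.ndarray,
                   years: np.ndarray,
                   data_range: tuple[float, float] | None = None,
                   ) -> pd.DataFrame:
    """Posterior mean and 95% bands of the predicted date surface.

    One row per (elevation, year) combination with the posterior mean and
    the 2.5/97.5% quantiles of the linear predictor.  Elevations outside
    ``data_range`` (when given) are flagged ``extrapolated``.
    """
    fit = posterior.fit
    rows = []
    for yr in np.atleast_1d(years):
        X = _design(np.asarray(elevations, dtype=float),
                    np.full(len(np.atleast_1d(elevations)), float(yr)),
                    fit.centers, fit.scales)
        pred = posterior.coef_draws @ X.T      # (n_draws, n_elev)
        lo, hi = np.percentile(pred, [2.5, 97.5], axis=0)
        for i, e in enumerate(np.atleast_1d(elevations)):
            extrap = (data_range is not None
                      and not data_range[0] <= e <= data_range[1])
            rows.append((float(e), float(yr), float(pred[:, i].mean()),
                         float(lo[i]), float(hi[i]), extrap))
    return pd.DataFrame(rows, columns=["elevation", "year", "mean",
                                       "lower", "upper", "extrapolated"])
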