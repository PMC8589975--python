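"""Hierarchical Bayesian measurement-error models for hatching dates.

Two models share a backbone.  The *spatiotemporal* model regresses the
latent true hatching date of brood *i* on region intercepts, standardized
elevation (linear + quadratic), mean observer day, year, and an
elevation x year interaction, with a year random effect.  The
*environmental* model adds winter intensity, spring precipitation,
snowmelt initiation and spring temperature.

Measurement error enters twice.  The observed interval midpoint is
modelled as h_obs_i ~ Normal(h_i, w_i / 4), where w_i is the hatching
interval width, so the true date falls inside the interval with ~95%
probability.  Covariates measured with sub-grid / location uncertainty
(elevation, temperature, precipitation) are latent with
z_i ~ Normal(z_obs_i, sd_i) on the standardized scale; latent elevation
propagates through both the linear and quadratic terms.

Priors: region intercepts ~ Normal(overall mean hatching date, 50 d);
standardized coefficients ~ Normal(0, 5); year effects Normal(0,
sigma_year) with sigma_year ~ half-Cauchy(5); residual sigma ~
half-Cauchy(20).

Sampling is a blocked Gibbs scheme: conjugate normal blocks for the latent
hatch dates, the coefficient vector, the year effects and the linear
latent covariates; an inverse-gamma draw for the residual variance after
parameter expansion of its half-Cauchy prior; a slice-sampling step for
the among-year SD on its marginal conditional (year effects integrated
out, which avoids the slow centred-parameterization coupling); and a
vectorised Metropolis-within-Gibbs step for latent elevation, which
enters the predictor quadratically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "HierPriors", "HierData", "HierPosterior", "build_model_data",
    "fit_hier", "convergence_report", "unstandardize", "coefficient_table",
    "posterior_predictive_check", "partial_effect_curves",
    "prior_mass_in_breeding_season",
]

SPATIOTEMPORAL = ("elevation", "elevation2", "observer_day", "year",
                  "elevation_year")
ENVIRONMENTAL = SPATIOTEMPORAL + ("winter", "precipitation", "meltstart",
                                  "temperature")

#: reference MCMC size of the full-scale analysis; effective-sample gates
#: scale proportionally when fewer draws are kept
REFERENCE_KEPT_DRAWS = 30_000
REFERENCE_MIN_ESS = 1500.0


@dataclass(frozen=True)
class HierPriors:
    intercept_mean: float          # overall mean hatching date (day-of-year)
    intercept_sd: float = 50.0
    beta_sd: float = 5.0
    sigma_scale: float = 20.0      # half-Cauchy scale, residual SD
    sigma_year_scale: float = 5.0  # half-Cauchy scale, among-year SD

    def __post_init__(self) -> None:
        for v in (self.intercept_sd, self.beta_sd, self.sigma_scale,
                  self.sigma_year_scale):
            if v <= 0:
                raise ValueError("prior scales must be positive")


def prior_mass_in_breeding_season(intercept_mean: float = 175.0,
                                  intercept_sd: float = 50.0,
                                  season: tuple[float, float] = (121.0, 243.0),
                                  ) -> float:
    """Prior probability that the intercept falls in the breeding season.

    Defaults: Normal(Jun 24, 50 d) against May 1 - Aug 31.
    """
    lo, hi = season
    return float(stats.norm.cdf(hi, intercept_mean, intercept_sd)
                 - stats.norm.cdf(lo, intercept_mean, intercept_sd))


@dataclass
class HierData:
    """Standardized model inputs with per-row measurement SDs."""

    model: str                       # 'spatiotemporal' | 'environmental'
    h_obs: np.ndarray                # interval midpoints (day-of-year)
    h_sd: np.ndarray                 # interval width / 4
    region_idx: np.ndarray
    region_labels: list[str]
    year_idx: np.ndarray
    year_labels: np.ndarray
    z_obs: dict[str, np.ndarray]     # standardized observed covariates
    z_sd: dict[str, np.ndarray]      # standardized measurement SDs (0 = exact)
    scales: dict[str, tuple[float, float]]   # raw (center, sd) per predictor
    predictors: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.predictors = (ENVIRONMENTAL if self.model == "environmental"
                           else SPATIOTEMPORAL)

    @property
    def n(self) -> int:
        return len(self.h_obs)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def n_years(self) -> int:
        return len(self.year_labels)


_RAW_COLS = {
    "elevation": ("elevation_mean", "elevation_sd"),
    "observer_day": ("observer_day", None),
    "year": ("year", None),
    "winter": ("winter_intensity", None),
    "precipitation": ("precipitation_mean", "precipitation_sd"),
    "meltstart": ("meltstart", None),
    "temperature": ("temperature_mean", "temperature_sd"),
}


def build_model_data(df: pd.DataFrame, model: str = "spatiotemporal",
                     ) -> HierData:
    """Standardize a brood table into :class:`HierData`.

    Required columns: ``hatch_mean``, ``hatch_width``, ``region``, ``year``,
    ``elevation_mean``, ``elevation_sd``, ``observer_day``; the
    environmental model additionally needs ``winter_intensity``,
    ``temperature_mean``/``_sd``, ``precipitation_mean``/``_sd`` and
    ``meltstart``.  Numeric predictors are centred and scaled by the
    empirical SD of the observed means; measurement SDs are divided by the
    same scale.  Rows with missing values are dropped with a log message.
    """
    if model not in ("spatiotemporal", "environmental"):
        raise ValueError(f"unknown model {model!r}")
    base = ["elevation", "observer_day", "year"]
    extra = (["winter", "precipitation", "meltstart", "temperature"]
             if model == "environmental" else [])
    cols = ["hatch_mean", "hatch_width", "region"]
    for p in base + extra:
        mean_col, sd_col = _RAW_COLS[p]
        cols.append(mean_col)
        if sd_col:
            cols.append(sd_col)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"model {model!r} requires missing columns {missing}")
    sub = df.dropna(subset=cols)
    if len(sub) < len(df):
        logger.info("dropping %d broods with incomplete data",
                    len(df) - len(sub))
    if len(sub) < 10:
        raise ValueError("too few complete broods")

    regions = sorted(sub["region"].unique())
    region_idx = sub["region"].map({r: i for i, r in enumerate(regions)})
    years = np.sort(sub["year"].unique())
    year_idx = sub["year"].map({y: i for i, y in enumerate(years)})

    z_obs: dict[str, np.ndarray] = {}
    z_sd: dict[str, np.ndarray] = {}
    scales: dict[str, tuple[float, float]] = {}
    for p in base + extra:
        mean_col, sd_col = _RAW_COLS[p]
        v = sub[mean_col].to_numpy(dtype=float)
        center, scale = float(v.mean()), float(np.std(v, ddof=1))
        if scale <= 0:
            raise ValueError(f"predictor {p} has zero variance")
        scales[p] = (center, scale)
        z_obs[p] = (v - center) / scale
        if sd_col:
            z_sd[p] = sub[sd_col].to_numpy(dtype=float) / scale
        else:
            z_sd[p] = np.zeros(len(sub))
    return HierData(
        model=model,
        h_obs=sub["hatch_mean"].to_numpy(dtype=float),
        h_sd=sub["hatch_width"].to_numpy(dtype=float) / 4.0,
        region_idx=region_idx.to_numpy(),
        region_labels=list(regions),
        year_idx=year_idx.to_numpy(),
        year_labels=years,
        z_obs=z_obs, z_sd=z_sd, scales=scales,
    )


@dataclass
class HierPosterior:
    data: HierData
    priors: HierPriors
    alpha: np.ndarray        # (chains, kept, n_regions)
    beta: np.ndarray         # (chains, kept, p)
    sigma: np.ndarray        # (chains, kept)
    sigma_year: np.ndarray   # (chains, kept)
    gamma: np.ndarray        # (chains, kept, n_years)
    h_latent: np.ndarray     # (chains, kept, n)
    accept_elev: float       # MH acceptance rate for latent elevation
    seed: int

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_kept(self) -> int:
        return self.alpha.shape[1]

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, "h_latent" if name == "h" else name)
        return arr.reshape(-1, *arr.shape[2:])

    def param_dict(self) -> dict[str, np.ndarray]:
        """Model parameters (chains, draws, ...) for diagnostics."""
        return {"alpha": self.alpha, "beta": self.beta, "sigma": self.sigma,
                "sigma_year": self.sigma_year, "gamma": self.gamma}

    def summary(self) -> pd.DataFrame:
        rows = []
        names = ([f"alpha[{r}]" for r in self.data.region_labels]
                 + [f"beta[{p}]" for p in self.data.predictors]
                 + ["sigma", "sigma_year"])
        draws = np.concatenate(
            [self.flat("alpha"), self.flat("beta"),
             self.flat("sigma")[:, None], self.flat("sigma_year")[:, None]],
            axis=1)
        for j, name in enumerate(names):
            d = draws[:, j]
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append((name, d.mean(), d.std(ddof=1), lo, hi))
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd",
                                           "q2.5", "q97.5"])


# ---------------------------------------------------------------------------
# sampler

def _slice_sample_scale(x0: float, logf, rng: np.random.Generator,
                        width: float = 1.0, max_steps: int = 50) -> float:
    """One slice-sampling update of a positive scalar (stepping out)."""
    ly = logf(x0) + np.log(rng.random())
    lo = x0 - width * rng.random()
    hi = lo + width
    j = int(max_steps * rng.random())
    k = max_steps - 1 - j
    while j > 0 and lo > 0 and logf(lo) > ly:
        lo -= width
        j -= 1
    while k > 0 and logf(hi) > ly:
        hi += width
        k -= 1
    lo = max(lo, 0.0)
    for _ in range(100):
        x1 = lo + (hi - lo) * rng.random()
        if logf(x1) > ly:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0

def _design(data: HierData, z_elev, z_temp, z_precip) -> np.ndarray:
    cols = []
    for p in data.predictors:
        if p == "elevation":
            cols.append(z_elev)
        elif p == "elevation2":
            cols.append(z_elev ** 2)
        elif p == "elevation_year":
            cols.append(z_elev * data.z_obs["year"])
        elif p == "temperature":
            cols.append(z_temp)
        elif p == "precipitation":
            cols.append(z_precip)
        else:
            cols.append(data.z_obs[p])
    return np.column_stack(cols)


def _run_chain(data: HierData, priors: HierPriors, n_iter: int, warmup: int,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
    n, R = data.n, data.n_regions
    p = len(data.predictors)
    q = R + p
    ny = data.n_years
    A = np.zeros((n, R))
    A[np.arange(n), data.region_idx] = 1.0
    yearix = data.year_idx
    env = data.model == "environmental"

    sE = data.z_sd["elevation"]
    elev_free = sE > 0
    zE = data.z_obs["elevation"] + np.where(elev_free,
                                            rng.normal(0, 1, n) * sE, 0.0)
    if env:
        sT = data.z_sd["temperature"]
        sP = data.z_sd["precipitation"]
        zT = data.z_obs["temperature"].copy()
        zP = data.z_obs["precipitation"].copy()
    else:
        zT = zP = None

    h_fixed = data.h_sd <= 0
    h = data.h_obs.copy()

    # overdispersed initial values
    alpha = np.full(R, priors.intercept_mean) + rng.normal(0, 3, R)
    beta = rng.normal(0, 0.5, p)
    sigma2 = float(np.var(data.h_obs, ddof=1)) * rng.uniform(0.5, 2.0)
    sigma2_year = rng.uniform(0.5, 4.0)
    a_sig = 1.0
    gamma = rng.normal(0, 1.0, ny)

    prior_prec = np.concatenate([
        np.full(R, 1.0 / priors.intercept_sd ** 2),
        np.full(p, 1.0 / priors.beta_sd ** 2)])
    prior_mean_full = np.concatenate([np.full(R, priors.intercept_mean),
                                      np.zeros(p + ny)])
    Z = np.zeros((n, ny))
    Z[np.arange(n), yearix] = 1.0

    ib = {name: i for i, name in enumerate(data.predictors)}
    kept = n_iter - warmup
    out = {
        "alpha": np.empty((kept, R)), "beta": np.empty((kept, p)),
        "sigma": np.empty(kept), "sigma_year": np.empty(kept),
        "gamma": np.empty((kept, ny)), "h": np.empty((kept, n)),
    }
    n_prop = 0
    n_acc = 0
    step = np.where(elev_free, 1.2 * np.maximum(sE, 1e-6), 0.0)
    ny_counts = np.bincount(yearix, minlength=ny).astype(float)

    for it in range(n_iter):
        X = _design(data, zE, zT, zP)
        mu = A @ alpha + X @ beta + gamma[yearix]

        # latent hatch dates (conjugate; fixed where interval width is 0)
        prec = 1.0 / sigma2 + np.where(h_fixed, 0.0, 1.0 / np.where(
            h_fixed, 1.0, data.h_sd ** 2))
        mean = (mu / sigma2 + np.where(h_fixed, 0.0, data.h_obs / np.where(
            h_fixed, 1.0, data.h_sd ** 2))) / prec
        h = np.where(h_fixed, data.h_obs,
                     mean + rng.standard_normal(n) / np.sqrt(prec))

        # among-year SD first, with the year effects integrated out of its
        # conditional (partially collapsed Gibbs: gamma is redrawn below)
        r = h - A @ alpha - X @ beta
        sums = np.bincount(yearix, weights=r, minlength=ny)
        active = ny_counts > 0
        rbar = np.where(active, sums / np.maximum(ny_counts, 1), 0.0)[active]
        nact = ny_counts[active]
        s2 = sigma2
        A_y = priors.sigma_year_scale

        def _lf_sy(s):
            if s <= 0:
                return -np.inf
            v = s2 / nact + s * s
            return (-0.5 * float(np.sum(np.log(v) + rbar ** 2 / v))
                    - np.log1p((s / A_y) ** 2))

        sy = _slice_sample_scale(np.sqrt(sigma2_year), _lf_sy, rng)
        sigma2_year = sy * sy

        # coefficients and year effects in one joint Gaussian block --
        # the year covariate is constant within years, so updating beta
        # and gamma separately would mix slowly along their ridge
        D = np.concatenate([A, X, Z], axis=1)
        P = (D.T @ D) / sigma2
        prior_prec_full = np.concatenate(
            [prior_prec, np.full(ny, 1.0 / sigma2_year)])
        P[np.diag_indices(q + ny)] += prior_prec_full
        b = D.T @ h / sigma2 + prior_prec_full * prior_mean_full
        L = np.linalg.cholesky(P)
        m = np.linalg.solve(L.T, np.linalg.solve(L, b))
        theta = m + np.linalg.solve(L.T, rng.standard_normal(q + ny))
        alpha, beta, gamma = theta[:R], theta[R:q], theta[q:]
        lin = A @ alpha + X @ beta

        # residual SD: half-Cauchy via inverse-gamma parameter expansion
        eps = h - lin - gamma[yearix]
        sigma2 = stats.invgamma.rvs(
            (n + 1) / 2.0, scale=1.0 / a_sig + 0.5 * float(eps @ eps),
            random_state=rng)
        a_sig = stats.invgamma.rvs(
            1.0, scale=1.0 / priors.sigma_scale ** 2 + 1.0 / sigma2,
            random_state=rng)

        # latent elevation: Metropolis step (enters linearly + quadratically)
        if np.any(elev_free):
            base = A @ alpha + gamma[yearix]
            for name in data.predictors:
                if name not in ("elevation", "elevation2", "elevation_year"):
                    base = base + beta[ib[name]] * X[:, ib[name]]
            zy = data.z_obs["year"]
            be = beta[ib["elevation"]]
            be2 = beta[ib["elevation2"]]
            bxy = (beta[ib["elevation_year"]]
                   if "elevation_year" in ib else 0.0)

            def _lp(z):
                muz = base + be * z + be2 * z * z + bxy * z * zy
                prior = -0.5 * ((z - data.z_obs["elevation"])
                                / np.where(elev_free, sE, 1.0)) ** 2
                like = -0.5 * (h - muz) ** 2 / sigma2
                return prior + like

            prop = zE + step * rng.standard_normal(n)
            logr = _lp(prop) - _lp(zE)
            acc = (np.log(rng.random(n)) < logr) & elev_free
            zE = np.where(acc, prop, zE)
            n_prop += int(elev_free.sum())
            n_acc += int(acc.sum())

        # latent temperature / precipitation (conjugate, linear entry)
        if env:
            X = _design(data, zE, zT, zP)
            mu_all = A @ alpha + X @ beta + gamma[yearix]
            for nm, zcur, s in (("temperature", zT, sT),
                                ("precipitation", zP, sP)):
                free = s > 0
                if not np.any(free):
                    continue
                bcol = beta[ib[nm]]
                resid_ex = h - (mu_all - bcol * zcur)
                lprec = 1.0 / np.where(free, s, 1.0) ** 2
                cprec = lprec + bcol ** 2 / sigma2
                cmean = (data.z_obs[nm] * lprec
                         + bcol * resid_ex / sigma2) / cprec
                znew = np.where(
                    free, cmean + rng.standard_normal(n) / np.sqrt(cprec),
                    zcur)
                mu_all = mu_all + bcol * (znew - zcur)
                if nm == "temperature":
                    zT = znew
                else:
                    zP = znew

        if it >= warmup:
            k = it - warmup
            out["alpha"][k] = alpha
            out["beta"][k] = beta
            out["sigma"][k] = np.sqrt(sigma2)
            out["sigma_year"][k] = np.sqrt(sigma2_year)
            out["gamma"][k] = gamma
            out["h"][k] = h
    out["accept"] = np.array([n_acc / max(n_prop, 1)])
    return out


def fit_hier(data: HierData, priors: HierPriors | None = None,
             chains: int = 4, n_iter: int = 2000,
             warmup: int | None = None, seed: int = 0) -> HierPosterior:
    """Fit a hierarchical model by blocked Gibbs sampling.

    ``n_iter`` counts total iterations per chain; the second half is kept
    unless ``warmup`` says otherwise.  Six chains of 10,000 reproduce the
    full-scale analysis; the default 4 x 2000 is desk-scale.
    """
    if priors is None:
        priors = HierPriors(intercept_mean=float(data.h_obs.mean()))
    if warmup is None:
        warmup = n_iter // 2
    if not 0 < warmup < n_iter:
        raise ValueError("warmup must be in (0, n_iter)")
    ss = np.random.SeedSequence([seed, 777])
    child = ss.spawn(chains)
    results = [_run_chain(data, priors, n_iter, warmup,
                          np.random.default_rng(child[c]))
               for c in range(chains)]
    stack = {k: np.stack([r[k] for r in results])
             for k in ("alpha", "beta", "sigma", "sigma_year", "gamma", "h")}
    acc = float(np.mean([r["accept"][0] for r in results]))
    return HierPosterior(data, priors, stack["alpha"], stack["beta"],
                         stack["sigma"], stack["sigma_year"], stack["gamma"],
                         stack["h"], acc, seed)


# ---------------------------------------------------------------------------
# convergence

def convergence_report(posterior: HierPosterior,
                       rhat_max: float = 1.01,
                       mcse_frac_max: float = 0.05,
                       min_ess_reference: float = REFERENCE_MIN_ESS,
                       ) -> pd.DataFrame:
    """Per-parameter split-R-hat, ESS and MCSE gates.

    The ESS gate scales proportionally with the number of kept draws
    relative to the full-scale 6 x 5000 reference; the MCSE gate requires
    the Monte Carlo SE of the posterior mean to stay below 5% of the
    posterior SD.  Raises on a single chain, where R-hat is unavailable.
    """
    import arviz as az

    if posterior.n_chains < 2:
        raise ValueError("convergence assessment needs at least 2 chains")
    total_kept = posterior.n_chains * posterior.n_kept
    min_ess = min_ess_reference * total_kept / REFERENCE_KEPT_DRAWS
    idata = az.from_dict(posterior=posterior.param_dict())
    # classic split potential-scale-reduction, the definition the original
    # analysis tooling reported
    rhat = az.rhat(idata, method="split")
    ess = az.ess(idata)
    mcse = az.mcse(idata)
    rows = []
    for var in ("alpha", "beta", "sigma", "sigma_year", "gamma"):
        r = np.atleast_1d(rhat[var].values)
        e = np.atleast_1d(ess[var].values)
        m = np.atleast_1d(mcse[var].values)
        draws = posterior.flat(var)
        if draws.ndim == 1:
            draws = draws[:, None]
        sd = draws.std(axis=0, ddof=1)
        for j in range(len(r)):
            frac = m[j] / sd[j] if sd[j] > 0 else 0.0
            rows.append((f"{var}[{j}]" if len(r) > 1 else var,
                         float(r[j]), float(e[j]), float(frac),
                         bool(r[j] < rhat_max and e[j] > min_ess
                              and frac < mcse_frac_max)))
    rep = pd.DataFrame(rows, columns=["parameter", "rhat", "ess",
                                      "mcse_frac", "ok"])
    rep.attrs["min_ess"] = min_ess
    rep.attrs["passed"] = bool(rep["ok"].all())
    if not rep.attrs["passed"]:
        bad = rep.loc[~rep["ok"], "parameter"].tolist()
        logger.warning("convergence gates failed for: %s", bad)
    return rep


# ---------------------------------------------------------------------------
# reporting helpers

def unstandardize(beta_std: float, raw_sd: float,
                  report_unit_factor: float = 1.0) -> float:
    """Standardized effect (days per SD) to days per reporting unit.

    ``beta_unstd = beta_std / raw_sd * report_unit_factor`` -- e.g. factor
    100 for "per 100 m", 10 for "per decade", 7 for "per week".  A
    per-(mm/day) precipitation coefficient converts to per-100-mm with
    ``factor = 100 / window_length_days``.
    """
    if raw_sd <= 0:
        raise ValueError("raw_sd must be positive")
    return beta_std / raw_sd * report_unit_factor


#: reporting-unit factors per predictor: (factor, unit label); precipitation
#: is handled separately because its factor depends on the window length
REPORT_UNITS = {
    "elevation": (100.0, "per 100 m"),
    "elevation2": (100.0, "per 100 m"),
    "observer_day": (1.0, "per day"),
    "year": (10.0, "per decade"),
    "winter": (1.0, "per PC unit"),
    "meltstart": (7.0, "per week"),
    "temperature": (1.0, "per deg C"),
}


def coefficient_table(posterior: HierPosterior,
                      raw_sds: dict[str, float] | None = None,
                      precip_window_days: int | None = None) -> pd.DataFrame:
    """Standardized and unstandardized coefficient report.

    ``raw_sds`` defaults to the scales stored in the model data; the
    precipitation column, measured in mm/day, is reported per 100 mm of
    window total when ``precip_window_days`` is given.  The interaction
    term is reported per 100 m per decade.
    """
    data = posterior.data
    if raw_sds is None:
        raw_sds = {k: v[1] for k, v in data.scales.items()}
    beta = posterior.flat("beta")
    alpha = posterior.flat("alpha")
    rows = []
    for j, r in enumerate(data.region_labels):
        d = alpha[:, j]
        lo, hi = np.percentile(d, [2.5, 97.5])
        rows.append((f"region[{r}]", d.mean(), d.std(ddof=1), lo, hi,
                     d.mean(), "day-of-year"))
    for j, p in enumerate(data.predictors):
        d = beta[:, j]
        lo, hi = np.percentile(d, [2.5, 97.5])
        if p == "elevation_year":
            sd = raw_sds["elevation"] * raw_sds["year"]
            factor, unit = 1000.0, "per 100 m per decade"
        elif p == "precipitation":
            sd = raw_sds["precipitation"]
            if precip_window_days:
                factor, unit = 100.0 / precip_window_days, "per 100 mm"
            else:
                factor, unit = 1.0, "per mm/day"
        else:
            sd = raw_sds["elevation" if p == "elevation2" else p]
            factor, unit = REPORT_UNITS[p]
        rows.append((p, d.mean(), d.std(ddof=1), lo, hi,
                     unstandardize(float(d.mean()), sd, factor), unit))
    for name in ("sigma", "sigma_year"):
        d = posterior.flat(name)
        lo, hi = np.percentile(d, [2.5, 97.5])
        rows.append((name, d.mean(), d.std(ddof=1), lo, hi, d.mean(),
                     "days"))
    return pd.DataFrame(rows, columns=["parameter", "std_mean", "std_sd",
                                       "q2.5", "q97.5", "unstd", "unit"])


def posterior_predictive_check(posterior: HierPosterior, n_rep: int = 200,
                               seed: int = 0) -> pd.DataFrame:
    """Observed vs replicated summary statistics with tail probabilities.

    Replicated datasets are drawn from the fitted observation model
    (latent regression + residual + interval-width measurement noise) at
    posterior draws; tail probability is the fraction of replicates whose
    statistic exceeds the observed one.  Values near 0 or 1 flag misfit.
    """
    rng = np.random.default_rng(seed)
    data = posterior.data
    total = posterior.n_chains * posterior.n_kept
    take = rng.choice(total, size=min(n_rep, total), replace=False)
    alpha = posterior.flat("alpha")[take]
    beta = posterior.flat("beta")[take]
    sigma = posterior.flat("sigma")[take]
    gamma = posterior.flat("gamma")[take]
    X = _design(data, data.z_obs["elevation"],
                data.z_obs.get("temperature"),
                data.z_obs.get("precipitation"))
    A = np.zeros((data.n, data.n_regions))
    A[np.arange(data.n), data.region_idx] = 1.0
    stats_fn = {
        "mean": np.mean,
        "sd": lambda v: np.std(v, ddof=1),
        "q10": lambda v: np.quantile(v, 0.10),
        "q90": lambda v: np.quantile(v, 0.90),
    }
    obs = {k: float(f(data.h_obs)) for k, f in stats_fn.items()}
    reps = {k: [] for k in stats_fn}
    for d in range(len(take)):
        mu = A @ alpha[d] + X @ beta[d] + gamma[d][data.year_idx]
        h = mu + rng.normal(0, sigma[d], data.n)
        y = h + rng.normal(0, 1, data.n) * data.h_sd
        for k, f in stats_fn.items():
            reps[k].append(float(f(y)))
    rows = []
    for k in stats_fn:
        r = np.array(reps[k])
        rows.append((k, obs[k], r.mean(), r.std(ddof=1),
                     float(np.mean(r >= obs[k]))))
    return pd.DataFrame(rows, columns=["statistic", "observed", "rep_mean",
                                       "rep_sd", "tail_prob"])


def partial_effect_curves(posterior: HierPosterior, variable: str,
                          n_grid: int = 50) -> pd.DataFrame:
    """Predicted hatching date over one predictor, others at their means.

    The curve is evaluated on the observed range of the predictor (raw
    units) with the average region intercept and all other standardized
    covariates at 0; bands are 2.5/97.5% posterior quantiles.
    """
    data = posterior.data
    if variable not in data.predictors:
        raise KeyError(f"{variable!r} not a predictor of model {data.model}")
    j = data.predictors.index(variable)
    zobs = data.z_obs[variable if variable != "elevation2" else "elevation"]
    zgrid = np.linspace(zobs.min(), zobs.max(), n_grid)
    alpha = posterior.flat("alpha").mean(axis=1)      # average region
    beta = posterior.flat("beta")
    pred = alpha[:, None] + beta[:, j][:, None] * zgrid[None, :]
    if variable == "elevation" and "elevation2" in data.predictors:
        j2 = data.predictors.index("elevation2")
        pred = pred + beta[:, j2][:, None] * (zgrid ** 2)[None, :]
    center, scale = data.scales.get(
        variable if variable != "elevation2" else "elevation", (0.0, 1.0))
    lo, hi = np.percentile(pred, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "value": center + scale * zgrid, "z": zgrid,
        "mean": pred.mean(axis=0), "lower": lo, "upper": hi,
    })
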