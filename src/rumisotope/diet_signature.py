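"""Diet-to-methane isotope relationship for ruminants.

A linear regression delta13C_CH4 = slope * delta13C_diet + intercept is
fitted to paired literature observations of diet and enteric-methane
signatures, propagating the stated per-point uncertainties by a Monte
Carlo perturb-and-refit scheme.  The fitted line is applied to national
delta13C_diet series and the national signatures are flux-weighted into a
global delta13C of ruminant enteric methane.

The slope of the empirical line is close to 1, so it is compatible with a
single kinetic fractionation during rumen fermentation,
delta13C_CH4 ~= delta13C_diet - eps, with eps the (positive) isotopic
discrimination of methanogenesis; both the exact first-order-kinetics form
and its linearization are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .isotope_diet import co2_adjustment


class RegressionError(ValueError):
    pass


@dataclass
class RegressionModel:
    """Fitted diet -> CH4 signature line with uncertainty.

    ``slope``/``intercept`` are the reported coefficients (Monte Carlo
    ensemble means for the perturb-and-refit method, plain OLS estimates
    otherwise); ``se_slope``/``se_intercept`` the corresponding standard
    errors; ``r_squared`` always refers to the central (unperturbed) OLS
    fit; ``cov`` is the 2x2 (intercept, slope) parameter covariance.
    """

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r_squared: float
    cov: np.ndarray
    method: str
    n_obs: int
    central_slope: float = field(default=np.nan)
    central_intercept: float = field(default=np.nan)

    def predict(self, delta13c_diet):
        return predict_delta13c_ch4(self, delta13c_diet)


def adjust_observation_diet_delta(
    observations: pd.DataFrame, co2_series: pd.Series
) -> pd.DataFrame:
    """Shift composition-derived diet signatures to their measurement year.

    Observations whose diet delta13C was computed from a feed-composition
    mixture of the 2012-referenced category signatures are shifted by the
    CO2-trend adjustment of the measurement year; directly reported diet
    signatures pass through unchanged.  Requires columns
    ``delta13c_diet, provenance, year`` where provenance is ``direct`` or
    ``composition``.
    """
    for col in ("delta13c_diet", "provenance", "year"):
        if col not in observations.columns:
            raise RegressionError(f"observations missing column {col!r}")
    out = observations.copy()
    comp = out["provenance"] == "composition"
    if comp.any():
        years = out.loc[comp, "year"]
        if years.isna().any():
            raise RegressionError("composition-derived observation without a measurement year")
        shift = co2_adjustment(years.to_numpy(dtype=int), co2_series)
        out.loc[comp, "delta13c_diet"] = out.loc[comp, "delta13c_diet"] + shift
    return out


def _central_ols(x: np.ndarray, y: np.ndarray):
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return res


def fit_diet_ch4_regression(
    observations: pd.DataFrame,
    n_draws: int = 2000,
    seed: int = 0,
    method: str = "mc",
) -> RegressionModel:
    """Fit the delta13C_diet -> delta13C_CH4 line.

    Parameters
    ----------
    observations : DataFrame
        Columns ``delta13c_diet, diet_sd, delta13c_ch4, ch4_sd`` (permil).
    n_draws : int
        Monte Carlo ensemble size for the perturb-and-refit estimator.
    seed : int
        RNG seed; the fit is deterministic under a fixed seed.
    method : str
        ``"mc"`` (default): both coordinates of every point are perturbed by
        their stated uncertainties, an OLS line is fitted to each perturbed
        replicate, and the ensemble mean/sd give the coefficients and their
        standard errors.  ``"ols"``: plain OLS on the central values with
        analytic standard errors.

    Notes
    -----
    The coefficient of determination always refers to the central OLS fit.
    Degenerate spread in delta13c_diet raises.
    """
    for col in ("delta13c_diet", "delta13c_ch4"):
        if col not in observations.columns:
            raise RegressionError(f"observations missing column {col!r}")
    x = observations["delta13c_diet"].to_numpy(dtype=float)
    y = observations["delta13c_ch4"].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise RegressionError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise RegressionError("degenerate spread in delta13c_diet")

    central = _central_ols(x, y)
    r2 = float(central.rsquared)

    if method == "ols":
        return RegressionModel(
            slope=float(central.params[1]),
            intercept=float(central.params[0]),
            se_slope=float(central.bse[1]),
            se_intercept=float(central.bse[0]),
            r_squared=r2,
            cov=np.asarray(central.cov_params()),
            method="ols",
            n_obs=n,
            central_slope=float(central.params[1]),
            central_intercept=float(central.params[0]),
        )
    if method != "mc":
        raise RegressionError(f"unknown fit method {method!r}")

    sx = observations.get("diet_sd", pd.Series(np.zeros(n))).to_numpy(dtype=float)
    sy = observations.get("ch4_sd", pd.Series(np.zeros(n))).to_numpy(dtype=float)
    if (sx < 0).any() or (sy < 0).any():
        raise RegressionError("per-point uncertainties must be non-negative")

    rng = np.random.default_rng(seed)
    xs = x + rng.standard_normal((n_draws, n)) * sx
    ys = y + rng.standard_normal((n_draws, n)) * sy
    # closed-form OLS per draw, vectorised over the ensemble axis
    xm = xs.mean(axis=1, keepdims=True)
    ym = ys.mean(axis=1, keepdims=True)
    sxx = ((xs - xm) ** 2).sum(axis=1)
    sxy = ((xs - xm) * (ys - ym)).sum(axis=1)
    slopes = sxy / sxx
    intercepts = ym[:, 0] - slopes * xm[:, 0]

    params = np.column_stack([intercepts, slopes])
    cov = np.cov(params, rowvar=False)
    return RegressionModel(
        slope=float(slopes.mean()),
        intercept=float(intercepts.mean()),
        se_slope=float(slopes.std(ddof=1)),
        se_intercept=float(intercepts.std(ddof=1)),
        r_squared=r2,
        cov=cov,
        method="mc",
        n_obs=n,
        central_slope=float(central.params[1]),
        central_intercept=float(central.params[0]),
    )


def predict_delta13c_ch4(model: RegressionModel, delta13c_diet):
    """Apply the fitted line: slope * delta13C_diet + intercept (permil)."""
    x = np.asarray(delta13c_diet, dtype=float)
    out = model.slope * x + model.intercept
    return float(out) if out.ndim == 0 else out


def prediction_interval(model: RegressionModel, delta13c_diet, z: float = 1.96):
    """Parameter-uncertainty band around the fitted line (permil).

    Returns (lo, hi) at +/- z standard deviations from the parameter
    covariance; residual scatter is not included.
    """
    x = np.atleast_1d(np.asarray(delta13c_diet, dtype=float))
    design = np.column_stack([np.ones_like(x), x])
    var = np.einsum("ij,jk,ik->i", design, model.cov, design)
    centre = model.slope * x + model.intercept
    half = z * np.sqrt(var)
    return centre - half, centre + half


def epsilon_forms(delta13c_diet, epsilon):
    """Exact and linearized fractionation forms (permil in, permil out).

    With alpha = R_diet / R_CH4 = 1 + eps (eps a positive dimensionless
    fraction for normal discrimination), the exact first-order-kinetics
    relation is

        delta_CH4 = (delta_diet/1000 - eps) / (1 + eps) * 1000

    and its linearization is delta_CH4 = delta_diet - 1000 * eps.  The two
    differ by eps * (eps - delta_diet/1000) / (1 + eps), i.e. second order
    in the small quantities eps and delta_diet/1000.
    """
    d = np.asarray(delta13c_diet, dtype=float) / 1000.0
    eps = np.asarray(epsilon, dtype=float)
    if (np.abs(eps) >= 0.1).any():
        raise RegressionError("epsilon must satisfy |eps| < 0.1 (dimensionless)")
    if (1.0 + eps == 0).any():
        raise RegressionError("1 + eps must not vanish")
    exact = (d - eps) / (1.0 + eps) * 1000.0
    linear = (d - eps) * 1000.0
    if exact.ndim == 0:
        return float(exact), float(linear)
    return exact, linear


def flux_weighted_signature(flux, delta13c):
    """Flux-weighted mean signature: sum(F * delta) / sum(F) (permil).

    Weights are scale invariant; an all-zero flux vector raises.
    """
    f = np.asarray(flux, dtype=float)
    d = np.asarray(delta13c, dtype=float)
    if f.shape != d.shape:
        raise RegressionError("flux and delta13c must be aligned")
    if (f < 0).any():
        raise RegressionError("fluxes must be non-negative")
    total = f.sum()
    if total == 0:
        raise RegressionError("all fluxes are zero; weighted signature undefined")
    return float((f * d).sum() / total)
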