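"""Monte Carlo propagation of parameter uncertainty through the pipeline.

One ensemble member = one joint draw of the uncertain parameters (feed
digestibilities and their REMs, the methane conversion factor Y_m, the four
feed-category delta13C signatures, and the diet-to-CH4 regression
coefficients), held fixed across all countries and years of that member:
the parameter uncertainties behave as systematic, not per-country, errors.
95 % confidence intervals are the empirical 2.5/97.5 percentiles of the
ensemble.

95 % confidence intervals stated for input parameters are converted to
Gaussian standard deviations via sd = (hi - lo) / 3.92.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diet_signature import RegressionModel
from .isotope_diet import IsotopeParams, co2_adjustment
from .ruminant_energy import E_GE_FEED, rem


class MonteCarloError(ValueError):
    pass


@dataclass(frozen=True)
class MCConfig:
    """Ensemble size, seed and the parameter distributions.

    Defaults: f_DE,concentrates ~ N(0.80, 0.1/3.92) truncated to (0.3, 0.9);
    f_DE for grass and stover+occasional ~ N(0.55, 0.2/3.92), same
    truncation; Y_m ~ N(0.065, 0.01/1.96) truncated positive; feed-category
    signatures Gaussian with their stated one-sigma uncertainties.
    """

    n_ensemble: int = 1000
    seed: int = 0
    f_de_concentrates: tuple[float, float] = (0.80, 0.1 / 3.92)
    f_de_grass: tuple[float, float] = (0.55, 0.2 / 3.92)
    f_de_so: tuple[float, float] = (0.55, 0.2 / 3.92)
    y_m: tuple[float, float] = (0.065, 0.01 / 1.96)
    f_de_bounds: tuple[float, float] = (0.3, 0.9)
    isotope_params: IsotopeParams = field(default_factory=IsotopeParams)

    def __post_init__(self):
        if self.n_ensemble < 2:
            raise MonteCarloError("n_ensemble must be at least 2")
        for name in ("f_de_concentrates", "f_de_grass", "f_de_so", "y_m"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise MonteCarloError(f"negative sd for {name}")
        lo, hi = self.f_de_bounds
        if not 0 < lo < hi < 1:
            raise MonteCarloError("f_de_bounds must satisfy 0 < lo < hi < 1")


@dataclass
class ParameterDraws:
    """Joint parameter draws; arrays of length n_ensemble."""

    f_de_concentrates: np.ndarray
    f_de_grass: np.ndarray
    f_de_so: np.ndarray
    y_m: np.ndarray
    d_c3_concentrates: np.ndarray
    d_c3_grass_other: np.ndarray
    d_c4_concentrates: np.ndarray
    d_c4_grass_other: np.ndarray
    slope: np.ndarray
    intercept: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y_m)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, lo: float, hi: float
) -> np.ndarray:
    """Rejection-sampled truncated normal; degenerates to the mean at sd=0."""
    if sd == 0:
        if not lo < mean < hi:
            raise MonteCarloError(f"central value {mean} outside truncation ({lo}, {hi})")
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = (out <= lo) | (out >= hi)
    tries = 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
        tries += 1
        if tries > 1000:
            raise MonteCarloError("truncated-normal rejection sampling failed to converge")
    return out


def sample_parameters(
    config: MCConfig, regression: RegressionModel | None = None
) -> ParameterDraws:
    """Draw the joint parameter ensemble (deterministic under the seed).

    Regression coefficients are drawn from the fitted model's parameter
    covariance when a model is given, else held at the central estimates of
    the model (or at slope 0.91, intercept -43.49 permil with zero spread
    when no model is supplied).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_ensemble
    lo, hi = config.f_de_bounds
    iso = config.isotope_params

    draws = dict(
        f_de_concentrates=_truncated_normal(rng, *config.f_de_concentrates, n, lo, hi),
        f_de_grass=_truncated_normal(rng, *config.f_de_grass, n, lo, hi),
        f_de_so=_truncated_normal(rng, *config.f_de_so, n, lo, hi),
        y_m=_truncated_normal(rng, *config.y_m, n, 0.0, 0.15),
        d_c3_concentrates=rng.normal(iso.d_c3_concentrates, iso.sd_c3_concentrates, n),
        d_c3_grass_other=rng.normal(iso.d_c3_grass_other, iso.sd_c3_grass_other, n),
        d_c4_concentrates=rng.normal(iso.d_c4_concentrates, iso.sd_c4_concentrates, n),
        d_c4_grass_other=rng.normal(iso.d_c4_grass_other, iso.sd_c4_grass_other, n),
    )
    if regression is not None:
        cov = np.asarray(regression.cov)
        if cov.shape != (2, 2) or not np.all(np.isfinite(cov)):
            raise MonteCarloError("regression model lacks a usable 2x2 covariance")
        coef = rng.multivariate_normal(
            [regression.intercept, regression.slope], cov, size=n, method="cholesky"
        )
        draws["intercept"], draws["slope"] = coef[:, 0], coef[:, 1]
    else:
        draws["slope"] = np.full(n, 0.91)
        draws["intercept"] = np.full(n, -43.49)
    return ParameterDraws(**draws)


def run_ensemble(
    me: np.ndarray,
    q_concentrates: np.ndarray,
    q_c4_concentrates: np.ndarray,
    q_grass: np.ndarray,
    c4_grass_fraction: np.ndarray,
    co2_delta: np.ndarray,
    draws: ParameterDraws,
    e_ge: float = E_GE_FEED,
    e_ch4: float = 55.65,
    max_failure_fraction: float = 0.05,
) -> dict[str, np.ndarray]:
    """Propagate the parameter ensemble through the pipeline core.

    Inputs are aligned country-year arrays (length m): the ME requirement
    (MJ), concentrate residual and its C4 part (kg DM), grass quantity
    (kg DM), country C4 grass fraction, and the per-year CO2-trend
    adjustment (permil).  Per ensemble member the stover+occasional
    quantity solves the energy balance with that member's digestibilities
    (REM recomputed per draw), the diet basket is assembled, delta13C_diet
    mixed, Tier-2 emissions computed, and the regression applied.

    Returns arrays of shape (n_kept, m) under keys ``q_so``,
    ``delta13c_diet``, ``f_ch4`` and ``delta13c_ch4``, plus a boolean
    ``clamped`` mask of members-by-rows where a negative energy-balance
    solution was clamped to zero (flagged, not a failure).  Members
    producing non-finite output are excluded and counted under
    ``n_failed``; more than ``max_failure_fraction`` failed members aborts.
    """
    me = np.asarray(me, dtype=float)[None, :]
    q_c = np.asarray(q_concentrates, dtype=float)[None, :]
    q_c4c = np.asarray(q_c4_concentrates, dtype=float)[None, :]
    q_g = np.asarray(q_grass, dtype=float)[None, :]
    c4g = np.asarray(c4_grass_fraction, dtype=float)[None, :]
    co2 = np.asarray(co2_delta, dtype=float)[None, :]

    f_conc = draws.f_de_concentrates[:, None]
    f_grass = draws.f_de_grass[:, None]
    f_so = draws.f_de_so[:, None]

    coef_conc = e_ge * f_conc * rem(f_conc)
    coef_grass = e_ge * f_grass * rem(f_grass)
    coef_so = e_ge * f_so * rem(f_so)

    q_so = (me - q_c * coef_conc - q_g * coef_grass) / coef_so
    clamped = q_so < 0
    q_so = np.where(clamped, 0.0, q_so)

    q_c3c = q_c - q_c4c
    q_c4_other = (q_g + q_so) * c4g
    q_c3_other = (q_g + q_so) * (1.0 - c4g)
    total = q_c + q_g + q_so
    delta_diet = (
        q_c3c * draws.d_c3_concentrates[:, None]
        + q_c4c * draws.d_c4_concentrates[:, None]
        + q_c3_other * draws.d_c3_grass_other[:, None]
        + q_c4_other * draws.d_c4_grass_other[:, None]
    ) / total + co2

    ge = total * e_ge
    f_ch4 = ge * draws.y_m[:, None] / (e_ch4 * 1e9)
    delta_ch4 = draws.slope[:, None] * delta_diet + draws.intercept[:, None]

    # members producing non-finite output anywhere are excluded and counted;
    # clamped energy-balance rows are legitimate (flagged) and kept
    finite = (
        np.isfinite(q_so).all(axis=1)
        & np.isfinite(delta_diet).all(axis=1)
        & np.isfinite(f_ch4).all(axis=1)
        & np.isfinite(delta_ch4).all(axis=1)
    )
    n_failed = int((~finite).sum())
    if n_failed > max_failure_fraction * len(finite):
        raise MonteCarloError(
            f"{n_failed} of {len(finite)} ensemble members failed; "
            "inputs and parameter ranges are inconsistent"
        )
    return {
        "q_so": q_so[finite],
        "delta13c_diet": delta_diet[finite],
        "f_ch4": f_ch4[finite],
        "delta13c_ch4": delta_ch4[finite],
        "clamped": clamped[finite],
        "n_failed": n_failed,
    }


def summarize(ensemble: np.ndarray, axis: int = 0) -> dict[str, np.ndarray]:
    """Ensemble mean, sd and empirical 95 % interval along ``axis``."""
    lo, hi = np.percentile(ensemble, [2.5, 97.5], axis=axis)
    return {
        "mean": ensemble.mean(axis=axis),
        "sd": ensemble.std(axis=axis, ddof=1),
        "ci_lo": lo,
        "ci_hi": hi,
    }


def ensemble_from_tables(
    supply: pd.DataFrame,
    requirements: pd.DataFrame,
    me_series: pd.DataFrame,
    grass_use: pd.DataFrame,
    co2_series: pd.Series,
    draws: ParameterDraws,
) -> dict[str, np.ndarray]:
    """Run the ensemble from the pipeline's observable input tables.

    Allocates the supply, splits the ruminant residual into C3/C4, aligns
    the ME and grass tables and the CO2 adjustment, then calls
    :func:`run_ensemble`.  Returns the per-draw arrays plus
    ``countries``/``years`` row labels.
    """
    from . import feed_allocation as fa

    alloc = fa.allocate_concentrates(supply, requirements)
    conc = fa.split_ruminant_concentrates_c3c4(alloc, supply)
    merged = (
        me_series.merge(conc, on=["country", "year"], validate="1:1")
        .merge(grass_use, on=["country", "year"], validate="1:1")
        .sort_values(["country", "year"])
        .reset_index(drop=True)
    )
    co2 = co2_adjustment(merged["year"].to_numpy(), co2_series)
    out = run_ensemble(
        merged["me_mj"].to_numpy(),
        merged["q_concentrates"].to_numpy(),
        merged["q_c4_concentrates"].to_numpy(),
        merged["q_grass"].to_numpy(),
        merged["c4_grass_fraction"].to_numpy(),
        co2,
        draws,
    )
    out["countries"] = merged["country"].to_numpy()
    out["years"] = merged["year"].to_numpy()
    return out


def ensemble_from_world(world, draws: ParameterDraws) -> dict[str, np.ndarray]:
    """Run the ensemble on a synthetic world's observable inputs."""
    return ensemble_from_tables(
        world.supply,
        world.truth.requirements,
        world.me_series,
        world.grass_use,
        world.co2_series,
        draws,
    )
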