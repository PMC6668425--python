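"""Carbon isotope signature of the ruminant diet.

delta13C_diet of a country-year is the dry-matter-weighted mean of four
feed-category signatures (C3 concentrates, C3 grass/other, C4 concentrates,
C4 grass/other; all referenced to the year 2012), plus an adjustment for
the declining delta13C of atmospheric CO2, which plants incorporate in the
year they grow (no time lag is assumed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ruminant_energy import BASKET_POOLS


class IsotopeError(ValueError):
    pass


@dataclass(frozen=True)
class IsotopeParams:
    """Feed-category delta13C signatures (permil vs VPDB, year-2012 reference).

    The +/- uncertainties are treated as one standard deviation for Monte
    Carlo sampling.  ``apply_co2_adjustment`` toggles the atmospheric-CO2
    trend adjustment.
    """

    d_c3_concentrates: float = -25.10
    sd_c3_concentrates: float = 2.27
    d_c3_grass_other: float = -28.25
    sd_c3_grass_other: float = 1.68
    d_c4_concentrates: float = -12.24
    sd_c4_concentrates: float = 0.34
    d_c4_grass_other: float = -13.3
    sd_c4_grass_other: float = 1.1
    apply_co2_adjustment: bool = True

    def __post_init__(self):
        for name in (
            "d_c3_concentrates",
            "d_c3_grass_other",
            "d_c4_concentrates",
            "d_c4_grass_other",
        ):
            v = getattr(self, name)
            if not -40.0 < v < 0.0:
                raise IsotopeError(f"{name} = {v} outside the plausible (-40, 0) permil band")
        for name in (
            "sd_c3_concentrates",
            "sd_c3_grass_other",
            "sd_c4_concentrates",
            "sd_c4_grass_other",
        ):
            if getattr(self, name) <= 0:
                raise IsotopeError(f"{name} must be positive")


def co2_adjustment(year, series: pd.Series, reference_year: int = 2012):
    """CO2-trend adjustment Delta (permil): delta13C_CO2(year) - delta13C_CO2(2012).

    ``series`` maps year -> delta13C of atmospheric CO2 (permil vs VPDB).
    Scalar or array ``year`` accepted; missing years raise.
    """
    years = np.atleast_1d(np.asarray(year))
    missing = [int(y) for y in np.unique(years) if y not in series.index]
    if missing:
        raise IsotopeError(f"years {missing} missing from the delta13C_CO2 series")
    if reference_year not in series.index:
        raise IsotopeError(f"reference year {reference_year} missing from the delta13C_CO2 series")
    delta = series.loc[years].to_numpy(dtype=float) - float(series.loc[reference_year])
    return float(delta[0]) if np.ndim(year) == 0 else delta


def diet_delta13c(
    basket: pd.DataFrame,
    params: IsotopeParams | None = None,
    co2_series: pd.Series | None = None,
) -> pd.Series:
    """delta13C of the diet per country-year (permil vs VPDB).

    ``basket`` carries the six diet pools plus ``year`` (and ``country``).
    The mixture is formed with the four category signatures; when
    ``params.apply_co2_adjustment`` and a CO2 series are given, the
    year-specific adjustment is added.  Empty baskets (zero total) raise.
    """
    params = IsotopeParams() if params is None else params
    missing = [c for c in BASKET_POOLS if c not in basket.columns]
    if missing:
        raise IsotopeError(f"basket missing pools {missing}")
    pools = basket[list(BASKET_POOLS)].to_numpy(dtype=float)
    if (pools < 0).any():
        raise IsotopeError("basket pools must be non-negative")
    total = pools.sum(axis=1)
    if (total <= 0).any():
        bad = basket.loc[total <= 0, ["country", "year"]].head(3).to_dict("records")
        raise IsotopeError(f"empty diet basket for {bad}")

    weighted = (
        pools[:, 0] * params.d_c3_concentrates
        + pools[:, 1] * params.d_c4_concentrates
        + (pools[:, 2] + pools[:, 4]) * params.d_c3_grass_other
        + (pools[:, 3] + pools[:, 5]) * params.d_c4_grass_other
    )
    delta = weighted / total
    if params.apply_co2_adjustment and co2_series is not None:
        delta = delta + co2_adjustment(basket["year"].to_numpy(), co2_series)
    return pd.Series(delta, index=basket.index, name="delta13c_diet")
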