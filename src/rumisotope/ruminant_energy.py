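"""Ruminant energy budget: close the metabolizable-energy balance.

The national metabolizable-energy (ME) requirement of the ruminant herd is
met by three feed classes: concentrates (the residual from the feed model),
grazed grass, and "other feeds" (crop stover and occasional/scavenged
biomass, s+o).  Given ME, concentrate and grass quantities, the s+o
quantity is the solution of a linear energy balance

    ME = Q_so * E_GE * f_DE,so * REM(f_DE,so)
       + Q_conc * E_GE * f_DE,conc * REM(f_DE,conc)
       + Q_grass * E_GE * f_DE,grass * REM(f_DE,grass)

where E_GE = 18.45 MJ per kg dry matter is the mean gross-energy density of
feed, f_DE is the digestible fraction of gross energy of each feed class,
and REM (the fraction of digestible energy available for maintenance)
follows the IPCC (2006) national-inventory relation

    REM = 1.123 - 4.092e-3 DE + 1.126e-5 DE^2 - 25.4 / DE,   DE = 100 f_DE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Mean gross-energy density of feed dry matter, MJ per kg DM.
E_GE_FEED = 18.45


class EnergyBalanceError(ValueError):
    """Raised for inputs outside the validity of the energy balance."""


def rem(f_de):
    """Fraction of digestible energy available for maintenance (REM).

    Parameters
    ----------
    f_de : float or array
        Digestible fraction of gross energy, as a fraction in [0.3, 0.9]
        (the validity envelope enforced here).

    Returns
    -------
    REM as a fraction in (0, 1), same shape as the input.
    """
    arr = np.asarray(f_de, dtype=float)
    if (arr < 0.3).any() or (arr > 0.9).any():
        raise EnergyBalanceError(f"f_DE outside the validity envelope [0.3, 0.9]: {f_de!r}")
    de = 100.0 * arr
    out = 1.123 - 4.092e-3 * de + 1.126e-5 * de**2 - 25.4 / de
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EnergyParams:
    """Central digestibility parameters of the three ruminant feed classes.

    Concentrate digestibility is 0.80 (95 % CI 0.75-0.85); grass and
    stover+occasional share the medium-quality-forage value 0.55
    (95 % CI 0.45-0.65).
    """

    e_ge: float = E_GE_FEED
    f_de_concentrates: float = 0.80
    f_de_grass: float = 0.55
    f_de_so: float = 0.55

    @property
    def rem_concentrates(self):
        return rem(self.f_de_concentrates)

    @property
    def rem_grass(self):
        return rem(self.f_de_grass)

    @property
    def rem_so(self):
        return rem(self.f_de_so)

    def me_coefficient(self, feed_class: str):
        """MJ of maintenance-available ME per kg DM of a feed class."""
        f_de = {
            "concentrates": self.f_de_concentrates,
            "grass": self.f_de_grass,
            "so": self.f_de_so,
        }[feed_class]
        return self.e_ge * f_de * rem(f_de)


def solve_other_feeds(me, q_concentrates, q_grass, params: EnergyParams | None = None):
    """Solve the ME balance for the stover+occasional quantity Q_so (kg DM).

    Negative solutions (ME already exceeded by concentrates + grass) are
    clamped to zero and flagged; they indicate inconsistent inputs rather
    than a physical diet.

    Returns
    -------
    (q_so, clamped) : arrays (or scalars) of the solved quantity and a
    boolean flag marking clamped entries.
    """
    params = EnergyParams() if params is None else params
    me = np.asarray(me, dtype=float)
    q_c = np.asarray(q_concentrates, dtype=float)
    q_g = np.asarray(q_grass, dtype=float)
    if (me < 0).any() or (q_c < 0).any() or (q_g < 0).any():
        raise EnergyBalanceError("ME and feed quantities must be non-negative")

    supplied = q_c * params.me_coefficient("concentrates") + q_g * params.me_coefficient("grass")
    q_so = (me - supplied) / params.me_coefficient("so")
    clamped = q_so < 0
    q_so = np.where(clamped, 0.0, q_so)
    if q_so.ndim == 0:
        return float(q_so), bool(clamped)
    return q_so, clamped


def me_balance(q_so, q_concentrates, q_grass, params: EnergyParams | None = None):
    """Evaluate the right-hand side of the ME balance (MJ) for a solved basket."""
    params = EnergyParams() if params is None else params
    return (
        np.asarray(q_so, dtype=float) * params.me_coefficient("so")
        + np.asarray(q_concentrates, dtype=float) * params.me_coefficient("concentrates")
        + np.asarray(q_grass, dtype=float) * params.me_coefficient("grass")
    )


def aggregate_c3c4_fractions(grid: pd.DataFrame) -> pd.DataFrame:
    """Country-level C4 grass fraction from gridded fractions and grass use.

    Parameters
    ----------
    grid : DataFrame
        One row per grid cell with columns ``country, c4_fraction,
        grass_use``; the country fraction is the grass-use-weighted mean of
        the cell fractions.

    Returns
    -------
    DataFrame with columns ``country, c4_grass_fraction, flagged``;
    countries with zero total grass use receive a flagged neutral 0 and a
    warning.
    """
    for col in ("country", "c4_fraction", "grass_use"):
        if col not in grid.columns:
            raise EnergyBalanceError(f"grid table missing column {col!r}")
    if ((grid["c4_fraction"] < 0) | (grid["c4_fraction"] > 1)).any():
        raise EnergyBalanceError("grid C4 fractions must lie in [0, 1]")
    if (grid["grass_use"] < 0).any():
        raise EnergyBalanceError("grid grass use must be non-negative")

    rows = []
    for country, sub in grid.groupby("country", sort=True):
        total = sub["grass_use"].sum()
        if total == 0:
            warnings.warn(
                f"country {country!r} has zero grass use; C4 fraction undefined, set to 0",
                stacklevel=2,
            )
            rows.append({"country": country, "c4_grass_fraction": 0.0, "flagged": True})
        else:
            frac = float((sub["c4_fraction"] * sub["grass_use"]).sum() / total)
            rows.append({"country": country, "c4_grass_fraction": frac, "flagged": False})
    return pd.DataFrame(rows)


BASKET_POOLS = (
    "q_c3_concentrates",
    "q_c4_concentrates",
    "q_c3_grass",
    "q_c4_grass",
    "q_c3_so",
    "q_c4_so",
)


def assemble_diet_basket(
    concentrates: pd.DataFrame,
    grass: pd.DataFrame,
    q_so,
) -> pd.DataFrame:
    """Assemble the six-pool ruminant diet basket.

    Parameters
    ----------
    concentrates : DataFrame
        Columns ``country, year, q_c3_concentrates, q_c4_concentrates``
        (from :func:`rumisotope.feed_allocation.split_ruminant_concentrates_c3c4`).
    grass : DataFrame
        Columns ``country, year, q_grass, c4_grass_fraction``.
    q_so : array-like
        Stover+occasional quantity aligned with the merged rows; split into
        C3/C4 with the same ratio as the country's grass.

    Returns
    -------
    DataFrame with ``country, year`` and the six pools (kg DM); pool sums
    conserve the inputs exactly.
    """
    merged = concentrates.merge(grass, on=["country", "year"], validate="1:1")
    q_so = np.asarray(q_so, dtype=float)
    if len(q_so) != len(merged):
        raise EnergyBalanceError("q_so length does not match country-year rows")
    frac = merged["c4_grass_fraction"].to_numpy()
    if ((frac < 0) | (frac > 1)).any():
        raise EnergyBalanceError("c4_grass_fraction outside [0, 1]")
    q_grass = merged["q_grass"].to_numpy()
    if (q_grass < 0).any() or (q_so < 0).any():
        raise EnergyBalanceError("grass and s+o quantities must be non-negative")

    return pd.DataFrame(
        {
            "country": merged["country"],
            "year": merged["year"],
            "q_c3_concentrates": merged["q_c3_concentrates"],
            "q_c4_concentrates": merged["q_c4_concentrates"],
            "q_c3_grass": q_grass * (1.0 - frac),
            "q_c4_grass": q_grass * frac,
            "q_c3_so": q_so * (1.0 - frac),
            "q_c4_so": q_so * frac,
        }
    )
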