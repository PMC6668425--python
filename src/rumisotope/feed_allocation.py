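"""Simple feed model: split concentrate feed commodities between monogastrics and ruminants.

Country-by-year commodity supply (seven feed groups: maize, other cereals,
oilseeds, cakes of oilseeds, brans, pulses, others) is allocated in priority
to poultry-meat and egg production, then to pigs, according to feed
conversion ratios (FCR), dressing percentages and a farming-intensity
fraction (the share of production raised on commodity feed rather than
backyard scavenging).  Ruminants receive, as a residual, all maize, other
cereals, oilseeds, cakes, brans and "others" not consumed by poultry and
pigs; leftover pulses are not fed to ruminants.  The ruminant residual is
finally split into C4 concentrates (maize + millet + sorghum + sugarcane)
and C3 concentrates (everything else).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: The seven concentrate feed-commodity groups (kg dry matter).
FEED_GROUPS = ("maize", "other_cereals", "oilseeds", "cakes", "brans", "pulses", "others")

#: Groups whose residual (after poultry and pigs) is fed to ruminants.
#: Pulses left over after the monogastric allocation are not fed to ruminants.
RUMINANT_GROUPS = ("maize", "other_cereals", "oilseeds", "cakes", "brans", "others")

POULTRY_MEAT_SPECIES = ("chickens", "ducks", "geese", "turkeys", "other_birds")
LAYING_SPECIES = ("laying_hens", "laying_other")

#: Dressing percentage: carcass weight as a fraction of live weight.
DRESSING_FRACTION = {"poultry": 0.70, "pig": 0.60}


class AllocationError(ValueError):
    """Raised for invalid inputs to the feed model."""


# ---------------------------------------------------------------------------
# Feed conversion ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FCRSchedule:
    """Linear-in-time feed conversion ratio for one animal product.

    Parameters
    ----------
    base : float
        FCR at ``anchor_year`` for developed countries,
        kg dry matter per kg live-weight gain (or per kg eggs).
    anchor_year : int
        Year at which ``base`` applies.
    rate : float
        Annual change of the FCR (negative: efficiency improves).
    developing_multiplier : float
        Multiplier applied for developing countries (default 1.2,
        i.e. 20 % higher FCR than developed countries).
    floor_fraction : float
        The extrapolated FCR is floored at this fraction of ``base``
        so it can never become non-positive.
    """

    base: float
    anchor_year: int
    rate: float
    developing_multiplier: float = 1.2
    floor_fraction: float = 0.5

    def at(self, year: int, status: str = "developed") -> float:
        fcr = self.base + self.rate * (year - self.anchor_year)
        fcr = max(fcr, self.floor_fraction * self.base)
        if status == "developing":
            fcr *= self.developing_multiplier
        elif status != "developed":
            raise AllocationError(f"unknown development status {status!r}")
        return fcr


#: Default schedules: broiler-performance-derived poultry FCR (1.95 kg DM in
#: 2005, improving by 0.01 per year; the same schedule is used for eggs) and
#: a pig FCR of 3.28 kg DM per kg live-weight gain in 1995 improving by
#: 0.015 per year.
DEFAULT_FCR_SCHEDULES: dict[str, FCRSchedule] = {
    "poultry": FCRSchedule(base=1.95, anchor_year=2005, rate=-0.01),
    "eggs": FCRSchedule(base=1.95, anchor_year=2005, rate=-0.01),
    "pig": FCRSchedule(base=3.28, anchor_year=1995, rate=-0.015),
}


def fcr_at(
    species: str,
    year: int,
    status: str = "developed",
    schedules: Mapping[str, FCRSchedule] | None = None,
) -> float:
    """Feed conversion ratio for ``species`` in ``year``.

    ``species`` is one of ``poultry``, ``eggs``, ``pig``.
    """
    schedules = DEFAULT_FCR_SCHEDULES if schedules is None else schedules
    try:
        schedule = schedules[species]
    except KeyError:
        raise AllocationError(f"unknown species {species!r}") from None
    return schedule.at(year, status)


# ---------------------------------------------------------------------------
# Farming intensity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FarmingIntensity:
    """Fraction of monogastric production raised on commodity feed.

    Developed countries hold their year-2000 anchor fraction constant over
    1961-2012.  Developing countries follow a logistic intensification curve
    that passes exactly through the year-2000 anchor, asymptotes at ``cap``
    (0.95), and is shaped so that the 1961 intensity equals
    ``ratio_1961`` times the 2000 anchor.
    """

    anchor: float
    status: str = "developed"
    cap: float = 0.95
    ratio_1961: float = 0.4

    def __post_init__(self):
        if not 0.0 <= self.anchor <= 1.0:
            raise AllocationError(f"intensity anchor {self.anchor} outside [0, 1]")
        if self.status == "developing" and self.anchor >= self.cap:
            raise AllocationError(
                f"developing-country anchor {self.anchor} must lie below the cap {self.cap}"
            )
        if not 0.0 < self.ratio_1961 < 1.0:
            raise AllocationError("ratio_1961 must be in (0, 1)")

    def _logistic_rate(self) -> float:
        # Closed form from f(2000) = anchor and f(1961) = ratio_1961 * anchor
        # for a logistic with asymptote `cap`.
        a, r, cap = self.anchor, self.ratio_1961, self.cap
        return math.log((cap - r * a) / (r * (cap - a))) / (2000 - 1961)

    def at(self, year: int) -> float:
        if self.status == "developed":
            return self.anchor
        if self.anchor == 0.0:
            return 0.0
        k = self._logistic_rate()
        a, cap = self.anchor, self.cap
        midpoint = 2000 + math.log(cap / a - 1.0) / k if a != cap else 2000.0
        return cap / (1.0 + math.exp(-k * (year - midpoint)))


def farming_intensity_at(
    anchor: float, year: int, status: str = "developed", cap: float = 0.95, ratio_1961: float = 0.4
) -> float:
    """Farming intensity in ``year`` for a country with the given 2000 anchor."""
    return FarmingIntensity(anchor, status, cap=cap, ratio_1961=ratio_1961).at(year)


# ---------------------------------------------------------------------------
# Live weights and feed requirements
# ---------------------------------------------------------------------------

def live_weight_totals(production: pd.DataFrame) -> pd.DataFrame:
    """Total live weight (or egg mass) per species group and country-year.

    Parameters
    ----------
    production : DataFrame
        Long table with columns ``country, year, species, n_head,
        yield_kg_per_head``.  Poultry and pig yields are carcass weight per
        head; laying yields are kg eggs per head.

    Returns
    -------
    DataFrame with columns ``country, year, weight_poultry, weight_pig,
    weight_egg`` (kg).  Carcass weights are converted to live weight with
    dressing fractions of 0.70 (poultry) and 0.60 (pigs); egg mass carries
    no dressing conversion.
    """
    required = {"country", "year", "species", "n_head", "yield_kg_per_head"}
    missing = required - set(production.columns)
    if missing:
        raise AllocationError(f"production table missing columns {sorted(missing)}")
    if (production["n_head"] < 0).any() or (production["yield_kg_per_head"] < 0).any():
        raise AllocationError("negative head count or yield in production table")

    prod = production.copy()
    prod["mass"] = prod["n_head"] * prod["yield_kg_per_head"]

    def group_of(species: str) -> str:
        if species in POULTRY_MEAT_SPECIES:
            return "poultry"
        if species in LAYING_SPECIES:
            return "egg"
        if species == "pig":
            return "pig"
        raise AllocationError(f"unknown species {species!r} in production table")

    prod["group"] = prod["species"].map(group_of)
    wide = (
        prod.pivot_table(index=["country", "year"], columns="group", values="mass", aggfunc="sum")
        .reindex(columns=["poultry", "pig", "egg"], fill_value=0.0)
        .fillna(0.0)
    )
    wide["poultry"] /= DRESSING_FRACTION["poultry"]
    wide["pig"] /= DRESSING_FRACTION["pig"]
    wide.columns = ["weight_poultry", "weight_pig", "weight_egg"]
    return wide.reset_index()


def feed_requirement(weight, fcr, f_intensity):
    """Commodity feed requirement Q = Weight x FCR x f_intensity (kg DM).

    A zero intensity describes pure backyard production, which consumes no
    feed commodities.  Accepts scalars or aligned arrays.
    """
    weight = np.asarray(weight, dtype=float)
    fcr = np.asarray(fcr, dtype=float)
    f_intensity = np.asarray(f_intensity, dtype=float)
    if (weight < 0).any() or (fcr < 0).any() or (f_intensity < 0).any():
        raise AllocationError("feed_requirement inputs must be non-negative")
    out = weight * fcr * f_intensity
    return float(out) if out.ndim == 0 else out


def compute_requirements(
    production: pd.DataFrame,
    statuses: Mapping[str, str],
    intensity_anchors: Mapping[str, float],
    schedules: Mapping[str, FCRSchedule] | None = None,
    cap: float = 0.95,
    ratio_1961: float = 0.4,
) -> pd.DataFrame:
    """Per country-year commodity requirements of poultry meat, eggs and pigs.

    Combines :func:`live_weight_totals`, :func:`fcr_at` and
    :func:`farming_intensity_at`.  Returns a DataFrame with columns
    ``country, year, q_poultry, q_eggs, q_pig`` (kg DM).
    """
    weights = live_weight_totals(production)
    intens = {
        c: FarmingIntensity(intensity_anchors[c], statuses[c], cap=cap, ratio_1961=ratio_1961)
        for c in weights["country"].unique()
    }
    rows = []
    for row in weights.itertuples(index=False):
        status = statuses[row.country]
        f_int = intens[row.country].at(row.year)
        rows.append(
            {
                "country": row.country,
                "year": row.year,
                "q_poultry": feed_requirement(
                    row.weight_poultry, fcr_at("poultry", row.year, status, schedules), f_int
                ),
                "q_eggs": feed_requirement(
                    row.weight_egg, fcr_at("eggs", row.year, status, schedules), f_int
                ),
                "q_pig": feed_requirement(
                    row.weight_pig, fcr_at("pig", row.year, status, schedules), f_int
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Allocation
# ---------------------------------------------------------------------------

#: Which commodity groups each monogastric product draws from, as fixed
#: proportions of its total requirement.  This default table is a synthetic
#: stand-in calibrated to a cereal/cake/bran-dominated compound-feed recipe;
#: real applications should supply a country- or system-specific table.
DEFAULT_COMPOSITION_SHARES: dict[str, dict[str, float]] = {
    "poultry": {"maize": 0.35, "other_cereals": 0.30, "cakes": 0.18, "brans": 0.10, "pulses": 0.07},
    "eggs": {"maize": 0.35, "other_cereals": 0.30, "cakes": 0.18, "brans": 0.10, "pulses": 0.07},
    "pig": {"maize": 0.30, "other_cereals": 0.32, "cakes": 0.14, "brans": 0.16, "pulses": 0.08},
}


def _validate_shares(shares: Mapping[str, Mapping[str, float]]) -> None:
    for species, table in shares.items():
        unknown = set(table) - set(FEED_GROUPS)
        if unknown:
            raise AllocationError(f"unknown feed groups {sorted(unknown)} for {species}")
        total = sum(table.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise AllocationError(f"composition shares for {species} sum to {total}, not 1")
        if any(v < 0 for v in table.values()):
            raise AllocationError(f"negative composition share for {species}")


@dataclass
class FeedAllocationResult:
    """Outcome of the priority allocation.

    ``allocations`` is a tidy DataFrame with one row per
    (country, year, group) carrying the supply of the group and its split
    between poultry, eggs, pigs, the ruminant residual and unused leftover
    (pulses only), plus shortfall flags per priority tier.
    ``shortfalls`` lists the country-year-groups where a tier's demand
    exceeded the remaining supply and was scaled pro-rata.
    """

    allocations: pd.DataFrame
    shortfalls: pd.DataFrame

    def ruminant_totals(self) -> pd.DataFrame:
        """Total ruminant concentrate residual per country-year (kg DM)."""
        sub = self.allocations[self.allocations["group"].isin(RUMINANT_GROUPS)]
        out = sub.groupby(["country", "year"], as_index=False)["ruminant"].sum()
        return out.rename(columns={"ruminant": "q_concentrates"})


def allocate_concentrates(
    supply: pd.DataFrame,
    requirements: pd.DataFrame,
    shares: Mapping[str, Mapping[str, float]] | None = None,
) -> FeedAllocationResult:
    """Allocate the commodity supply: poultry + eggs first, then pigs, residual to ruminants.

    Parameters
    ----------
    supply : DataFrame
        One row per country-year with a column per feed group (kg DM);
        may carry extra columns (e.g. sub-shares) which are ignored here.
    requirements : DataFrame
        Columns ``country, year, q_poultry, q_eggs, q_pig`` (kg DM).
    shares : nested mapping, optional
        Species -> group -> proportion tables; defaults to
        :data:`DEFAULT_COMPOSITION_SHARES`.

    Tier 1 (poultry meat + eggs) and tier 2 (pigs) each draw from the groups
    according to their composition shares.  When a tier's demand for a group
    exceeds what is left, the tier is served pro-rata within that group and a
    shortfall record is emitted; the residual can therefore never go
    negative.  Conservation holds exactly per group:
    poultry + eggs + pig + ruminant + unused == supply.
    """
    shares = DEFAULT_COMPOSITION_SHARES if shares is None else shares
    _validate_shares(shares)
    for g in FEED_GROUPS:
        if g not in supply.columns:
            raise AllocationError(f"supply table missing group column {g!r}")
        if (supply[g] < 0).any():
            raise AllocationError(f"negative supply in group {g!r}")

    merged = supply.merge(requirements, on=["country", "year"], how="left", validate="1:1")
    if merged[["q_poultry", "q_eggs", "q_pig"]].isna().any().any():
        raise AllocationError("requirements missing for some country-years in supply")

    records = []
    shortfall_rows = []
    for row in merged.itertuples(index=False):
        for g in FEED_GROUPS:
            avail = getattr(row, g)
            d_poultry = row.q_poultry * shares["poultry"].get(g, 0.0)
            d_eggs = row.q_eggs * shares["eggs"].get(g, 0.0)
            d1 = d_poultry + d_eggs
            factor1 = 1.0 if d1 <= avail or d1 == 0 else avail / d1
            a_poultry, a_eggs = d_poultry * factor1, d_eggs * factor1
            remaining = avail - a_poultry - a_eggs

            d_pig = row.q_pig * shares["pig"].get(g, 0.0)
            factor2 = 1.0 if d_pig <= remaining or d_pig == 0 else remaining / d_pig
            a_pig = d_pig * factor2
            remaining -= a_pig

            if g in RUMINANT_GROUPS:
                ruminant, unused = remaining, 0.0
            else:
                ruminant, unused = 0.0, remaining

            rec = {
                "country": row.country,
                "year": row.year,
                "group": g,
                "supply": avail,
                "poultry": a_poultry,
                "eggs": a_eggs,
                "pig": a_pig,
                "ruminant": ruminant,
                "unused": unused,
                "shortfall_tier1": factor1 < 1.0,
                "shortfall_tier2": factor2 < 1.0,
            }
            records.append(rec)
            if factor1 < 1.0 or factor2 < 1.0:
                shortfall_rows.append(
                    {
                        "country": row.country,
                        "year": row.year,
                        "group": g,
                        "tier1_factor": factor1,
                        "tier2_factor": factor2,
                    }
                )

    allocations = pd.DataFrame.from_records(records)
    shortfalls = pd.DataFrame.from_records(
        shortfall_rows, columns=["country", "year", "group", "tier1_factor", "tier2_factor"]
    )
    return FeedAllocationResult(allocations=allocations, shortfalls=shortfalls)


def split_ruminant_concentrates_c3c4(
    result: FeedAllocationResult, supply: pd.DataFrame
) -> pd.DataFrame:
    """Split the ruminant concentrate residual into C4 and C3 parts.

    C4 concentrates are maize plus the millet+sorghum part of "other
    cereals" plus the sugarcane part of "others"; the sub-shares (columns
    ``millet_sorghum_share`` and ``sugarcane_share`` of ``supply``) are held
    at their pre-allocation values.  Returns a DataFrame with columns
    ``country, year, q_concentrates, q_c4_concentrates, q_c3_concentrates``.
    """
    for col in ("millet_sorghum_share", "sugarcane_share"):
        if col not in supply.columns:
            raise AllocationError(f"supply table missing sub-share column {col!r}")
        bad = (supply[col] < 0) | (supply[col] > 1)
        if bad.any():
            raise AllocationError(f"sub-share {col!r} outside [0, 1]")

    wide = (
        result.allocations.pivot_table(
            index=["country", "year"], columns="group", values="ruminant", aggfunc="sum"
        )
        .reindex(columns=list(FEED_GROUPS), fill_value=0.0)
        .reset_index()
    )
    wide = wide.merge(
        supply[["country", "year", "millet_sorghum_share", "sugarcane_share"]],
        on=["country", "year"],
        validate="1:1",
    )
    total = wide[list(RUMINANT_GROUPS)].sum(axis=1)
    q_c4 = (
        wide["maize"]
        + wide["millet_sorghum_share"] * wide["other_cereals"]
        + wide["sugarcane_share"] * wide["others"]
    )
    out = pd.DataFrame(
        {
            "country": wide["country"],
            "year": wide["year"],
            "q_concentrates": total,
            "q_c4_concentrates": q_c4,
            "q_c3_concentrates": total - q_c4,
        }
    )
    return out
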