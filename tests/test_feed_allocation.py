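import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rumisotope import feed_allocation as fa


class TestFCR:
    @pytest.mark.parametrize(
        "species, year, status, expected",
        [
            ("poultry", 2005, "developed", 1.95),
            ("pig", 1995, "developed", 3.28),
            ("poultry", 2005, "developing", 2.34),  # 1.95 * 1.2
            ("poultry", 2006, "developed", 1.94),
            ("pig", 2012, "developed", 3.28 - 0.015 * 17),
        ],
    )
    def test_schedule_values(self, species, year, status, expected):
        assert fa.fcr_at(species, year, status) == pytest.approx(expected)

    def test_unknown_species_rejected(self):
        with pytest.raises(fa.AllocationError):
            fa.fcr_at("camel", 2000)

    def test_floor_prevents_nonpositive_extrapolation(self):
        # far beyond the anchor the linear trend would go negative
        far = fa.FCRSchedule(base=1.0, anchor_year=2000, rate=-0.1)
        assert far.at(2050) == pytest.approx(0.5)


class TestFarmingIntensity:
    def test_developed_constant_at_anchor(self):
        for year in (1961, 1985, 2012):
            assert fa.farming_intensity_at(0.8, year, "developed") == 0.8

    def test_developing_hits_anchor_in_2000(self):
        assert fa.farming_intensity_at(0.6, 2000, "developing") == pytest.approx(0.6)

    def test_developing_start_ratio(self):
        f = fa.farming_intensity_at(0.6, 1961, "developing")
        assert f == pytest.approx(0.4 * 0.6)

    def test_monotone_and_capped(self):
        curve = fa.FarmingIntensity(0.7, "developing")
        values = [curve.at(y) for y in range(1961, 2101)]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] <= 0.95

    def test_bad_anchor_rejected(self):
        with pytest.raises(fa.AllocationError):
            fa.FarmingIntensity(1.2, "developed")


class TestLiveWeights:
    def make(self, rows):
        return pd.DataFrame(
            rows, columns=["country", "year", "species", "n_head", "yield_kg_per_head"]
        )

    def test_poultry_dressing(self):
        prod = self.make([("A", 2000, "chickens", 1000, 1.4)])
        w = fa.live_weight_totals(prod)
        assert w.loc[0, "weight_poultry"] == pytest.approx(2000.0)  # 1400 / 0.70

    def test_pig_dressing(self):
        prod = self.make([("A", 2000, "pig", 100, 60.0)])
        w = fa.live_weight_totals(prod)
        assert w.loc[0, "weight_pig"] == pytest.approx(10_000.0)  # 6000 / 0.60

    def test_eggs_no_dressing_and_zero_head(self):
        prod = self.make(
            [("A", 2000, "laying_hens", 500, 10.0), ("A", 2000, "pig", 0, 60.0)]
        )
        w = fa.live_weight_totals(prod)
        assert w.loc[0, "weight_egg"] == pytest.approx(5000.0)
        assert w.loc[0, "weight_pig"] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(fa.AllocationError):
            fa.live_weight_totals(self.make([("A", 2000, "pig", -1, 60.0)]))


class TestFeedRequirement:
    def test_direct_substitution(self):
        assert fa.feed_requirement(100.0, 2.0, 0.5) == pytest.approx(100.0)

    def test_backyard_consumes_nothing(self):
        assert fa.feed_requirement(1e6, 3.0, 0.0) == 0.0

    @given(w=st.floats(0, 1e9), f=st.floats(0.1, 5), i=st.floats(0, 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linearity_in_weight(self, w, f, i):
        assert fa.feed_requirement(2 * w, f, i) == pytest.approx(
            2 * fa.feed_requirement(w, f, i)
        )


def _simple_supply(**groups):
    base = {g: 0.0 for g in fa.FEED_GROUPS}
    base.update(groups)
    base.update(country="A", year=2000, millet_sorghum_share=0.0, sugarcane_share=0.0)
    return pd.DataFrame([base])


def _requirements(q_poultry=0.0, q_eggs=0.0, q_pig=0.0):
    return pd.DataFrame(
        [{"country": "A", "year": 2000, "q_poultry": q_poultry, "q_eggs": q_eggs, "q_pig": q_pig}]
    )


class TestAllocation:
    def test_no_monogastrics_means_all_to_ruminants(self):
        supply = _simple_supply(maize=100.0, brans=50.0)
        res = fa.allocate_concentrates(supply, _requirements())
        assert res.ruminant_totals()["q_concentrates"].iloc[0] == pytest.approx(150.0)
        assert res.shortfalls.empty

    def test_demand_equals_supply_leaves_zero_residual(self):
        req = _requirements(q_poultry=100.0)
        shares = fa.DEFAULT_COMPOSITION_SHARES["poultry"]
        supply = _simple_supply(**{g: 100.0 * s for g, s in shares.items()})
        res = fa.allocate_concentrates(supply, req)
        assert res.ruminant_totals()["q_concentrates"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_conservation_per_group(self, small_world):
        res = fa.allocate_concentrates(small_world.supply, small_world.truth.requirements)
        a = res.allocations
        total = a[["poultry", "eggs", "pig", "ruminant", "unused"]].sum(axis=1)
        np.testing.assert_allclose(total, a["supply"], rtol=1e-12)

    def test_shortfall_is_prorata_never_negative(self):
        req = _requirements(q_poultry=100.0, q_eggs=100.0)
        # maize supply covers only half of the tier-1 maize demand
        shares = fa.DEFAULT_COMPOSITION_SHARES["poultry"]
        supply = _simple_supply(maize=0.5 * 200.0 * shares["maize"])
        res = fa.allocate_concentrates(supply, req)
        row = res.allocations.set_index("group").loc["maize"]
        assert row["poultry"] == pytest.approx(row["eggs"])  # pro-rata within the tier
        assert row["ruminant"] == 0.0
        assert not res.shortfalls.empty

    def test_poultry_priority_over_pigs(self):
        req = _requirements(q_poultry=100.0, q_pig=100.0)
        p_share = fa.DEFAULT_COMPOSITION_SHARES["poultry"]["maize"]
        supply = _simple_supply(maize=100.0 * p_share)  # just enough for poultry
        res = fa.allocate_concentrates(supply, req)
        row = res.allocations.set_index("group").loc["maize"]
        assert row["poultry"] == pytest.approx(100.0 * p_share)
        assert row["pig"] == 0.0

    @given(extra=st.floats(0, 1e6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_more_poultry_never_raises_residual(self, extra):
        supply = _simple_supply(maize=1e6, other_cereals=1e6, cakes=1e6, brans=1e6, pulses=1e6)
        base = fa.allocate_concentrates(supply, _requirements(q_poultry=1e5))
        more = fa.allocate_concentrates(supply, _requirements(q_poultry=1e5 + extra))
        assert (
            more.ruminant_totals()["q_concentrates"].iloc[0]
            <= base.ruminant_totals()["q_concentrates"].iloc[0] + 1e-6
        )


class TestC3C4Split:
    def test_all_maize_is_c4(self):
        supply = _simple_supply(maize=100.0)
        res = fa.allocate_concentrates(supply, _requirements())
        split = fa.split_ruminant_concentrates_c3c4(res, supply)
        assert split["q_c4_concentrates"].iloc[0] == pytest.approx(100.0)
        assert split["q_c3_concentrates"].iloc[0] == pytest.approx(0.0)

    def test_subshare_arithmetic(self):
        supply = _simple_supply(maize=50.0, other_cereals=100.0)
        supply["millet_sorghum_share"] = 0.3
        res = fa.allocate_concentrates(supply, _requirements())
        split = fa.split_ruminant_concentrates_c3c4(res, supply)
        assert split["q_c4_concentrates"].iloc[0] == pytest.approx(80.0)  # 50 + 0.3*100

    def test_no_c4_crops(self):
        supply = _simple_supply(brans=70.0, cakes=30.0)
        res = fa.allocate_concentrates(supply, _requirements())
        split = fa.split_ruminant_concentrates_c3c4(res, supply)
        assert split["q_c4_concentrates"].iloc[0] == 0.0
        assert split["q_c3_concentrates"].iloc[0] == pytest.approx(100.0)

    def test_bad_subshare_rejected(self):
        supply = _simple_supply(maize=1.0)
        supply["sugarcane_share"] = 1.5
        res = fa.allocate_concentrates(supply, _requirements())
        with pytest.raises(fa.AllocationError):
            fa.split_ruminant_concentrates_c3c4(res, supply)


class TestGroundTruthRecovery:
    def test_zero_noise_allocation_recovery(self, small_world):
        res = fa.allocate_concentrates(small_world.supply, small_world.truth.requirements)
        split = fa.split_ruminant_concentrates_c3c4(res, small_world.supply)
        merged = split.merge(
            small_world.truth.concentrates, on=["country", "year"], suffixes=("", "_true")
        )
        np.testing.assert_allclose(
            merged["q_concentrates"], merged["q_concentrates_true"], rtol=1e-9
        )
        np.testing.assert_allclose(
            merged["q_c4_concentrates"], merged["q_c4_concentrates_true"], rtol=1e-9
        )
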