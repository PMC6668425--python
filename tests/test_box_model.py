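import numpy as np
import pandas as pd
import pytest

from rumisotope import box_model as bm
from rumisotope import synthetic_data as sd


class TestStep:
    def test_steady_state_fixed_point(self):
        c = 550.0 / (1 / 9.0)
        assert bm.step(c, 550.0, 1 / 9.0) == pytest.approx(c)

    def test_pure_decay(self):
        assert bm.step(100.0, 0.0, 0.2) == pytest.approx(100.0 * np.exp(-0.2))

    def test_small_lambda_limit_matches_taylor(self):
        # C + S*dt + O(lambda): compare against the expansion at lambda=1e-8
        out = bm.step(1000.0, 50.0, 1e-8)
        assert out == pytest.approx(1000.0 + 50.0, rel=1e-6)

    def test_nonpositive_sink_rejected(self):
        with pytest.raises(bm.BoxModelError):
            bm.step(100.0, 10.0, 0.0)


class TestIsotopologueSplit:
    def test_zero_delta_gives_standard_ratio(self):
        s12, s13 = bm.isotopologue_split(100.0, 0.0)
        assert s13 / s12 == pytest.approx(bm.R_VPDB, rel=1e-14)
        assert s12 + s13 == pytest.approx(100.0, rel=1e-14)

    def test_roundtrip_weighted_delta(self):
        rng = np.random.default_rng(1)
        flux = rng.uniform(1, 100, 14)
        delta = rng.uniform(-70, -10, 14)
        s12, s13 = bm.isotopologue_split(flux, delta)
        mix = bm.delta_of_ratio(s13.sum(), s12.sum())
        expected12, expected13 = bm.isotopologue_split(flux.sum(), mix)
        assert abs(s13.sum() - expected13) / expected13 < 1e-12

    def test_lower_delta_lowers_s13(self):
        _, s13_heavy = bm.isotopologue_split(100.0, -20.0)
        _, s13_light = bm.isotopologue_split(100.0, -60.0)
        assert s13_light < s13_heavy


class TestSinkDeduction:
    def test_constant_lambda_recovered(self, atmosphere):
        record, inventory = atmosphere
        lam = bm.deduce_sink(record, inventory.total())
        np.testing.assert_allclose(lam, 1.0 / 9.1, rtol=1e-10)

    def test_steady_record(self):
        years = pd.Index(range(1700, 1720), name="year")
        s = pd.Series(500.0, index=years)
        c = 500.0 / 0.1 / bm.TG_PER_PPB
        record = pd.Series(c, index=years)
        lam = bm.deduce_sink(record, s)
        np.testing.assert_allclose(lam, 0.1, rtol=1e-10)

    def test_impossible_record_names_year(self):
        years = pd.Index([1700, 1701], name="year")
        s = pd.Series(10.0, index=years)
        record = pd.Series([500.0, 5000.0], index=years)
        with pytest.raises(bm.BoxModelError, match="1700"):
            bm.deduce_sink(record, s)

    def test_roundtrip_rising_record(self, atmosphere):
        """Deduce-then-forward reproduces the record to <=1e-6 ppb over 312 years."""
        record, inventory = atmosphere
        s12, s13 = inventory.isotopologue_totals()
        burden = record * bm.TG_PER_PPB
        frac = bm.FractionationSpec()
        c12, c13, _ = bm.steady_state_split(
            float(s12.iloc[0]), float(s13.iloc[0]), float(burden.iloc[0]), frac.alpha
        )
        traj = bm.run_forward_closed(s12.iloc[:-1], s13.iloc[:-1], burden, c12, c13, frac=frac)
        assert np.abs(traj["concentration_ppb"] - record).max() <= 1e-6


class TestForward:
    def test_constant_forcing_steady(self):
        years = pd.Index(range(1700, 1800), name="year")
        sig = {"enteric": -62.0}
        fluxes = pd.DataFrame({"enteric": 550.0}, index=years)
        inv = bm.SourceInventory.from_constant_signatures(fluxes, sig)
        s12, s13 = inv.isotopologue_totals()
        lam = 1.0 / 9.0
        frac = bm.FractionationSpec()
        c_tot = 550.0 / lam
        c12, c13, lam12 = bm.steady_state_split(
            float(s12.iloc[0]), float(s13.iloc[0]), c_tot, frac.alpha
        )
        lam12_s = pd.Series(lam12, index=years[:-1])
        traj = bm.run_forward(
            s12.iloc[:-1], s13.iloc[:-1], lam12_s, frac.alpha * lam12_s, c12, c13
        )
        np.testing.assert_allclose(traj["burden_tg"], c_tot, rtol=1e-12)
        assert traj["delta13c_atm"].std() < 1e-10

    def test_steady_concentration_value(self):
        # S = 550 Tg/yr at lambda = 1/9 gives 550*9/2.767 ~ 1789 ppb
        c_ppb = 550.0 * 9.0 / bm.TG_PER_PPB
        assert c_ppb == pytest.approx(1789, abs=1)

    def test_no_fractionation_equilibrium_matches_source_delta(self):
        # single source delta and alpha = 1: equilibrium delta_atm = delta_source
        years = pd.Index(range(0, 400), name="year")
        fluxes = pd.DataFrame({"enteric": 500.0}, index=years)
        inv = bm.SourceInventory.from_constant_signatures(fluxes, {"enteric": -55.0})
        s12, s13 = inv.isotopologue_totals()
        lam = pd.Series(0.1, index=years[:-1])
        traj = bm.run_forward(s12.iloc[:-1], s13.iloc[:-1], lam, lam, 100.0, 0.001)
        assert traj["delta13c_atm"].iloc[-1] == pytest.approx(-55.0, abs=1e-9)

    def test_fractionated_equilibrium_matches_closed_form(self):
        # steady state per isotopologue: R_atm = R_src / alpha
        years = pd.Index(range(0, 600), name="year")
        fluxes = pd.DataFrame({"enteric": 500.0}, index=years)
        inv = bm.SourceInventory.from_constant_signatures(fluxes, {"enteric": -55.0})
        s12, s13 = inv.isotopologue_totals()
        frac = bm.FractionationSpec()
        lam12 = pd.Series(0.1, index=years[:-1])
        traj = bm.run_forward(
            s12.iloc[:-1], s13.iloc[:-1], lam12, frac.alpha * lam12, 5000.0, 50.0
        )
        r_src = bm.R_VPDB * (1 - 55.0 / 1000.0)
        expected = (r_src / frac.alpha / bm.R_VPDB - 1.0) * 1000.0
        assert traj["delta13c_atm"].iloc[-1] == pytest.approx(expected, abs=1e-9)

    def test_mass_conservation_per_step(self, atmosphere):
        record, inventory = atmosphere
        s12, s13 = inventory.isotopologue_totals()
        lam = pd.Series(0.12, index=record.index[:-1])
        c0 = float(record.iloc[0]) * bm.TG_PER_PPB
        frac = bm.FractionationSpec()
        c12, c13, _ = bm.steady_state_split(
            float(s12.iloc[0]), float(s13.iloc[0]), c0, frac.alpha
        )
        traj = bm.run_forward(s12.iloc[:-1], s13.iloc[:-1], lam, lam, c12, c13)
        total = traj["burden12_tg"] + traj["burden13_tg"]
        np.testing.assert_allclose(total, traj["burden_tg"], rtol=1e-12)


class TestInventoryConstruction:
    def test_linear_interpolation_midpoint(self):
        anchors = {c: 10.0 for c in bm.NATURAL_COMPONENTS}
        anchors.update({c: 10.0 for c in bm.ANTHROPOGENIC_COMPONENTS})
        decadal = pd.DataFrame(
            {c: [20.0, 20.0] for c in bm.ANTHROPOGENIC_COMPONENTS},
            index=pd.Index([1850, 1970], name="year"),
        )
        recent = pd.DataFrame(
            {c: [20.0] * 43 for c in bm.ANTHROPOGENIC_COMPONENTS},
            index=pd.Index(range(1970, 2013), name="year"),
        )
        inv = bm.build_source_inventory(anchors, decadal, recent)
        assert inv.fluxes.loc[1775, "fossil_fuel"] == pytest.approx(15.0)
        # natural components constant throughout
        assert inv.fluxes["wetlands"].nunique() == 1

    def test_agricultural_split_fractions(self):
        anchors = {c: 10.0 for c in bm.NATURAL_COMPONENTS}
        anchors.update(
            {c: 1.0 for c in bm.ANTHROPOGENIC_COMPONENTS if c not in bm.AGRICULTURAL_COMPONENTS}
        )
        anchors["agriculture"] = 100.0
        decadal = pd.DataFrame(
            {"agriculture": [100.0, 100.0]}, index=pd.Index([1850, 1970], name="year")
        )
        for c in bm.ANTHROPOGENIC_COMPONENTS:
            if c not in bm.AGRICULTURAL_COMPONENTS:
                decadal[c] = 1.0
        recent = pd.DataFrame(
            {c: [1.0] * 43 for c in bm.ANTHROPOGENIC_COMPONENTS},
            index=pd.Index(range(1970, 2013), name="year"),
        )
        recent[["rice", "enteric", "manure"]] = (
            np.outer(np.ones(43), [30.0, 60.0, 10.0])
        )
        split = {"rice": 0.3, "enteric": 0.6, "manure": 0.1}
        inv = bm.build_source_inventory(anchors, decadal, recent, ag_split_fractions=split)
        assert inv.fluxes.loc[1900, "rice"] == pytest.approx(30.0)
        assert inv.fluxes.loc[1900, "enteric"] == pytest.approx(60.0)
        assert inv.fluxes.loc[1900, "manure"] == pytest.approx(10.0)

    def test_missing_anchor_rejected(self):
        with pytest.raises(bm.BoxModelError):
            bm.build_source_inventory({}, pd.DataFrame(), pd.DataFrame())

    def test_component_sum_equals_total(self, atmosphere):
        _, inventory = atmosphere
        np.testing.assert_allclose(
            inventory.fluxes.sum(axis=1), inventory.total(), rtol=1e-12
        )


@pytest.fixture(scope="module")
def setup():
    record, inventory = sd.generate_atmosphere_inputs()
    rev_years = pd.Index(range(1961, 2013), name="year")
    frac = (rev_years.to_numpy() - 1961) / 51.0
    revised_flux = inventory.fluxes.loc[rev_years, "enteric"] * (0.85 + 0.12 * frac)
    revised_delta = pd.Series(-64.49 - 0.44 * frac, index=rev_years)
    return record, inventory, revised_flux, revised_delta


@pytest.fixture(scope="module")
def experiments(setup):
    record, inventory, revised_flux, revised_delta = setup
    return bm.run_experiments(inventory, record, revised_flux, revised_delta)


class TestExperiments:

    def test_null_perturbation_gives_zero_deltas(self, setup):
        record, inventory, _, _ = setup
        rev_years = pd.Index(range(1961, 2013), name="year")
        same_flux = inventory.fluxes.loc[rev_years, "enteric"]
        same_delta = pd.Series(-62.0, index=rev_years)
        ex = bm.run_experiments(inventory, record, same_flux, same_delta)
        np.testing.assert_allclose(ex["R1"]["d_concentration_ppb"], 0.0, atol=1e-9)
        np.testing.assert_allclose(ex["R1"]["d_delta13c_atm"], 0.0, atol=1e-9)

    def test_baseline_reproduces_record(self, setup, experiments):
        record, *_ = setup
        assert np.abs(experiments["baseline"]["concentration_ppb"] - record).max() < 1e-6

    def test_source_signature_shift_identity(self, setup, experiments):
        """Changing only the enteric delta by D shifts delta_source by (F_ent/F_tot)*D."""
        record, inventory, revised_flux, revised_delta = setup
        r2, r3 = experiments["R2"], experiments["R3"]
        years = revised_delta.index
        f_ent = revised_flux.loc[years]
        inv_r1 = inventory.with_enteric(flux=revised_flux)
        f_tot = inv_r1.total().loc[years]
        d_shift = revised_delta - (-64.49)
        expected = (f_ent / f_tot) * d_shift
        observed = (r2["delta13c_source"] - r3["delta13c_source"]).loc[years]
        np.testing.assert_allclose(observed, expected, atol=1e-12)

    def test_lighter_signature_lowers_delta_atm_after_1990(self, experiments):
        ex = experiments
        diff = (ex["R2"]["delta13c_atm"] - ex["R1"]["delta13c_atm"]).loc[1990:]
        assert (diff < 0).all()

    def test_concentration_same_across_isotope_scenarios(self, experiments):
        ex = experiments
        # R1 steps the isotopologue pair with the baseline lambda12/lambda13
        # while R2 closes on the total-sink path; the two total burdens agree
        # up to a second-order (alpha - 1) * composition-shift term
        assert (
            np.abs(ex["R2"]["concentration_ppb"] - ex["R1"]["concentration_ppb"]).max()
            < 1e-3
        )
        np.testing.assert_allclose(
            ex["R3"]["concentration_ppb"], ex["R2"]["concentration_ppb"], rtol=1e-12
        )

    def test_override_outside_span_rejected(self, setup):
        record, inventory, _, _ = setup
        bad_years = pd.Index(range(2010, 2020), name="year")
        bad_flux = pd.Series(100.0, index=bad_years)
        with pytest.raises(bm.BoxModelError):
            inventory.with_enteric(flux=bad_flux)
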