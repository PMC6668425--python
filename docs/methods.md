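# Methods

`rumisotope` reconstructs national enteric methane emissions of domestic
ruminants (cattle, buffaloes, goats, sheep) and the carbon-isotope
signature of those emissions from livestock statistics, and quantifies the
atmospheric consequences with a one-box two-isotopologue CH4 model.  This
note documents the models, the parameters that matter, the numerical
choices, and what the synthetic test worlds do and do not demonstrate.

## The feed model

Concentrate feed commodities (seven groups: maize, other cereals,
oilseeds, cakes of oilseeds, brans, pulses, others; all in kg dry matter)
are allocated in priority to poultry-meat and egg production, then to
pigs; ruminants receive the residual of every group except pulses.  The
monogastric requirement per country and year is

    Q = Weight × FCR × f_intensity

where `Weight` is total live weight of slaughtered animals (carcass mass
divided by a dressing fraction of 0.70 for poultry and 0.60 for pigs; egg
mass carries no dressing conversion), `FCR` is the feed conversion ratio,
and `f_intensity` is the fraction of production raised on commodity feed
(backyard production is assumed to consume none).

FCR schedules are linear in time: 1.95 kg DM per kg product in 2005 for
poultry meat and eggs, improving by 0.01 per year; 3.28 kg DM per kg
live-weight gain in 1995 for pigs, improving by 0.015 per year; developing
countries carry a 1.2 multiplier.  Extrapolated FCRs are floored at 50 %
of the anchor value so they can never become non-positive.

Farming intensity is constant at the year-2000 anchor for developed
countries.  For developing countries it follows a logistic curve with
asymptote 0.95 that passes exactly through the 2000 anchor; the curve's
rate is fixed (in closed form) by requiring the 1961 intensity to be 40 %
of the 2000 anchor.  Both the asymptote and the 1961 ratio are
configuration keys: the shape, anchor and cap are constrained by the
underlying intensification narrative, the rate is not, so it is exposed
rather than hard-coded.

The commodity groups each monogastric product draws from are a fixed
proportion table.  The default table in
`feed_allocation.DEFAULT_COMPOSITION_SHARES` is a synthetic stand-in for a
compound-feed recipe (cereal/cake/bran dominated); the allocation engine is
exact for any table supplied.  When a tier's demand for a group exceeds
what is left, the tier is served pro-rata within the group and a shortfall
record is emitted — the residual can never go negative, and nothing is
silently clipped.

C4 concentrates for ruminants are maize plus the millet+sorghum part of
"other cereals" plus the sugarcane part of "others"; the sub-shares are
held at their pre-allocation values.

## The ruminant energy balance

The national metabolizable-energy requirement ME (MJ/yr) is met by
concentrates, grazed grass, and stover+occasional ("other") feeds.  With a
gross-energy density of feed E_GE = 18.45 MJ per kg DM, class
digestibilities f_DE, and the maintenance fraction REM of the IPCC (2006)
inventory guidelines,

    REM = 1.123 − 4.092e−3·DE + 1.126e−5·DE² − 25.4/DE,  DE = 100·f_DE,

the other-feeds quantity is the closed-form solution of the linear balance

    ME = Σ_class Q_class · E_GE · f_DE,class · REM(f_DE,class).

Central digestibilities: 0.80 for concentrates (95 % CI 0.75–0.85), 0.55
for grass and for other feeds (95 % CI 0.45–0.65).  REM is recomputed from
f_DE whenever f_DE changes, including inside every Monte Carlo draw.  The
REM polynomial is only evaluated inside the envelope f_DE ∈ [0.3, 0.9];
values outside raise.  Negative solutions for the other-feeds quantity are
clamped to zero and flagged — they indicate inconsistent inputs (an ME
below what concentrates and grass already supply), not a physical diet.

Country C4 grass fractions are grass-use-weighted means of gridded C4
fractions over the country's cells; a country with zero grass use gets a
flagged neutral zero.  The six-pool diet basket splits grass by this
fraction and applies the same C3:C4 ratio to other feeds, which are
produced and consumed locally.

## Diet and methane isotopes

δ13C_diet is the dry-matter-weighted mean of four feed-category
signatures, all referenced to 2012: −25.10 ± 2.27 ‰ (C3 concentrates),
−28.25 ± 1.68 ‰ (C3 grass/other), −12.24 ± 0.34 ‰ (C4 concentrates),
−13.3 ± 1.1 ‰ (C4 grass/other), plus the atmospheric-CO2 adjustment

    Δ(year) = δ13C_CO2(year) − δ13C_CO2(2012),

with no time lag between plant growth and the atmosphere.  The ± values
are treated as one standard deviation for sampling; all temporal variation
of the category signatures flows through Δ only.

Diet maps to the methane signature through an empirical line fitted to 43
paired observations, δ13C_CH4 = 0.91·δ13C_diet − 43.49 ‰ (R² 0.58, slope
SE 0.12, intercept SE ≈ 2.8 ‰).  The estimator is a Monte Carlo
errors-in-variables scheme: both coordinates of every point are perturbed
by their stated uncertainties, an ordinary least-squares line is fitted per
replicate, and the ensemble mean/sd give coefficients and standard errors
(R² always refers to the central fit).  Plain OLS is available as
`method="ols"`; the printed standard errors of the source compilation
cannot disambiguate the estimator, so both are offered and the method tag
is recorded in the output.  The packaged 43-record table is a synthetic
stand-in (see its docstring): it reproduces the sample size, diet span,
direct/composition provenance split and fitted-line statistics of the
literature compilation, so the fit path is exercised end to end, but the
individual records are not the literature values.

The slope being near 1 makes the line compatible with a single kinetic
fractionation δ_CH4 ≈ δ_diet − ε with ε ≈ 43.5 ‰ discrimination.
`epsilon_forms` provides the exact first-order-kinetics form
δ_CH4 = (δ_diet/1000 − ε)/(1 + ε)·1000 alongside the linearization; ε is
stored as a positive dimensionless fraction (normal discrimination), and
the two forms differ by ε(ε − δ_diet/1000)/(1+ε) — second order in the
small quantities, which for ε ≈ 0.043 and δ_diet ≈ −23 ‰ is still ≈ 2.8 ‰,
so the package applies the fitted line, not the linearized ε form, in the
pipeline.

Tier-2 emissions: F = GE · Y_m / (E_CH4 · 1e9) Tg CH4, with
GE = total DM · 18.45 MJ/kg, Y_m = 6.5 % (95 % CI ± 1.0 %) for
wide-spread ruminant diets (a single global Y_m: high-concentrate feedlot
diets are globally negligible), and E_CH4 = 55.65 MJ per kg CH4.  National
signatures are flux-weighted into the global δ13C of ruminant methane.

## Monte Carlo uncertainty

Ensembles (default n = 1000) draw jointly: the three digestibilities
(Gaussian, sd = CI width / 3.92, truncated to (0.3, 0.9)), Y_m (sd =
half-width / 1.96, truncated positive), the four category signatures, and
the regression coefficients from the fitted parameter covariance.  One
draw is held fixed across all countries and years of a member — the
parameter uncertainties are systematic, which is what produces smooth
confidence bands rather than noise that averages out across countries.
Draws are shared across pipeline stages within a member rather than
re-drawn per stage.  95 % intervals are empirical 2.5/97.5 percentiles.
Members producing non-finite output are excluded and counted (more than
5 % aborts); clamped energy-balance rows are kept and flagged.  The
ensemble core is vectorized over (member × country-year), so a 1000-member
ensemble over the default world runs in well under a second.

## The one-box two-isotopologue model

The tropospheric burden C (Tg) obeys dC/dt = S(t) − λ(t)·C with annual
steps integrated in closed form (sources and sink constant within a year;
seasonality is ignored).  Burden converts to mixing ratio at 2.767 Tg per
ppb.  The inventory has 14 components — 5 natural (wetlands, termites,
oceans, wild animals, geologic; constant in time) and 9 anthropogenic
(fossil fuel, waste/landfill, rice, enteric, manure, and four burning
classes) — each with a δ13C signature splitting its flux into ¹²CH4 and
¹³CH4 by S13/S12 = R_std(1 + δ/1000), R_std = 0.0112372 (the absolute
standard ratio cancels in δ round-trips).  The sink discriminates with
λ13 = α·λ12, α = 1 + ε_sink, ε_sink = −6.9 ‰.

Given a concentration record, the mass-balancing total sink λ(t) is the
per-year scalar root of the step equation (Brent's method at machine
tolerance; a year in which the burden grows by more than the source allows
has no positive root and raises, naming the year).  The isotopologue split
of the sink is then re-deduced per year: λ12 is the root of the condition
that stepping both isotopologues (with λ13 = α·λ12) reproduces the
prescribed total burden.  This is an exact-closure reconstruction — cheap
at annual resolution — chosen over the approximation λ12 ≈ λ.  Integration
starts from an imposed steady state in the first record year: the total
burden is the record anchor, and the isotopologue partition is the steady
solution with λ12 = (S12 + S13/α)/C.

Experiments: the **baseline** closes the sink on the record with the
default inventory (enteric signature −62 ‰).  **R1** replaces the enteric
flux with the revised series from 1961 and runs forward with the baseline
isotopologue sinks — concentration departs from the record.  **R2** also
applies the revised time-varying enteric signature (its 1961 value is used
for the whole 1700–1960 spin-up) and re-deduces λ12/λ13 against the
perturbed total-burden path, which equals R1's total path up to a
second-order (α−1) × composition-shift term (≈ 1e−5 ppb in practice).
**R3** is R2 with the signature frozen at its 1961 value, isolating the
effect of the signature's temporal variation.

## The synthetic worlds

The generator emits the pipeline's input tables at trivial scale with
known ground truth, by inverting the models it feeds: commodity supply is
the monogastric requirement (computed with the feed model's own FCR and
intensity rules) plus a chosen positive ruminant residual; the ME series
is built from a chosen positive other-feeds quantity through the energy
balance.  Under zero noise (the default) every downstream stage therefore
recovers the latent truth exactly, which is the acceptance surface for the
engine.  Defaults mirror the study conditions at desk scale: 10 countries
(5 developed / 5 developing), 1961–2012, country C4 grass fractions in
[0.05, 0.6], other-feeds quantities 0.3–0.8 of grass biomass (other feeds
are the most uncertain diet term in practice), poultry/pig/egg production
growing faster in developing countries.  Growth rates and starting levels
are drawn once per country from ranges chosen to give order-of-magnitude
realistic national herds.  Noise, when enabled, is multiplicative
lognormal (unit mean) on positive tables and leaves the frozen ground
truth untouched.

The synthetic atmosphere combines 1700 anchors, decadal 1850–1970 values
(with an aggregated agriculture flux split by its 1970 fractions and a
grass-burning flux split into C3/C4 classes) and annual values to 2012,
and generates the concentration record by forward integration with a
constant true sink of 1/9.1 yr⁻¹ from an imposed 1700 steady state — so
sink deduction has an exact known answer.  Component δ13C signatures are
representative literature-style defaults (microbial sources near −60 ‰,
fossil near −44 ‰, pyrogenic heavy, C4 savanna burning heaviest); they are
configuration, not measurements.

What passing tests on these worlds shows: that the allocation, energy,
isotope, emission, regression, uncertainty and box-model machinery are
internally consistent, exactly conservative, and correctly calibrated
(interval coverage, parameter recovery).  What they do not show: agreement
with real FAOSTAT/EDGAR/NOAA data, realistic inter-country heterogeneity,
trade, herd demography, or any real-data validation of the default
composition-share and signature tables.

## Numerical choices and problem sizes

- Root-finds use `scipy.optimize.brentq` at near-machine tolerance
  (xtol 1e−15); the 313-year deduce-and-forward round trip closes to
  ≈ 2e−13 ppb.
- Energy-balance closure is algebraically exact; the round-trip test
  demands ≤ 1e−9 relative on 1000 random valid inputs.
- The regression calibration studies use 200 replicate fits (300 draws
  each) and the interval-calibration study 100 replicate two-country
  worlds with 400-member ensembles; both are vectorized and complete in
  seconds.
- Ties and degenerate inputs: zero-demand groups allocate zero (no 0/0);
  zero-grass-use countries get flagged neutral C4 fractions; empty diet
  baskets raise rather than return NaN.

## Known limitations

- The composition-share table and the feed-category/component signature
  defaults are stand-ins; conclusions about real geographies require the
  corresponding real tables.
- The pipeline carries no uncertainty on activity data (herd sizes,
  yields, commodity balances) — only on the stated model parameters.
- The box model is zero-dimensional: no interhemispheric gradient, no OH
  chemistry, no seasonal cycle; and the sink is never re-tuned after
  perturbation, so perturbed concentrations deliberately depart from any
  record.
- The resume mode of the pipeline orchestrator re-derives stages in memory
  and only re-writes missing outputs; it is a convenience, not a cache.
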