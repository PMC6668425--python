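# rumisotope

Domestic ruminants (cattle, buffaloes, goats, sheep) are the largest
anthropogenic methane source, and the ¹³C/¹²C signature of their enteric
emissions (δ13C_CH4-ruminant) is a key constraint when atmospheric
inversions separate microbial, fossil and pyrogenic methane.  That
signature depends on the C3 vs C4 composition of what the animals eat —
C4 plants are isotopically heavier — which in turn depends on how crop
concentrate feeds are divided between ruminants, pigs and poultry, and on
the C3/C4 makeup of grazed grass.  `rumisotope` is a tested, reusable
implementation of that reconstruction for 1961–2012, aimed at
methane-budget and isotope-inversion researchers:

- a **simple feed model**: monogastric feed requirements from production
  statistics (Q = Weight × FCR × f_intensity, with dressing fractions
  0.70/0.60 and time-dependent feed conversion ratios), priority
  allocation of the seven commodity groups, ruminant residual, C3/C4
  split;
- a **ruminant energy balance** closing the metabolizable-energy budget
  ME = Σ Q·E_GE·f_DE·REM(f_DE) for the stover+occasional feed quantity,
  with REM from the IPCC (2006) relation;
- **diet isotope mixing** over four feed-category signatures plus the
  declining δ13C of atmospheric CO2;
- **IPCC Tier-2 enteric emissions** F = GE·Y_m/(E_CH4·10⁹) with
  Y_m = 6.5 %;
- the **diet→methane regression** δ13C_CH4 = 0.91·δ13C_diet − 43.49 ‰
  (R² = 0.58), fitted to 43 paired observations by a Monte Carlo
  errors-in-variables scheme, and flux-weighted national→global
  signatures;
- **Monte Carlo uncertainty propagation** (n = 1000, systematic parameter
  draws, empirical 95 % intervals);
- a **one-box two-isotopologue atmospheric model** (1700–2012): burden
  step C_end = S/λ + (C_beg − S/λ)e^(−λ), 2.767 Tg/ppb, sink
  fractionation λ13 = αλ12 with ε_sink = −6.9 ‰, mass-balancing sink
  deduction from a concentration record, and the baseline/R1/R2/R3
  revision experiments;
- a **synthetic-data generator** that emits every input table with known
  ground truth, so the whole pipeline is testable without downloads.

## Worked example

```python
import rumisotope as ri

# a ten-country synthetic world, 1961-2012, with known ground truth
world = ri.synthetic_data.generate_livestock_world(
    ri.synthetic_data.SyntheticWorldConfig(seed=1)
)

# feed model: allocate commodities, hand the residual to ruminants
alloc = ri.feed_allocation.allocate_concentrates(
    world.supply, world.truth.requirements
)
conc = ri.feed_allocation.split_ruminant_concentrates_c3c4(alloc, world.supply)

# fit the diet -> methane signature line on the packaged 43-record table
obs = ri.datasets.load_diet_ch4_observations()
model = ri.diet_signature.fit_diet_ch4_regression(obs, n_draws=2000, seed=1)
print(f"slope {model.slope:.3f} +/- {model.se_slope:.3f}")
print(f"intercept {model.intercept:.2f} +/- {model.se_intercept:.2f} permil")
print(f"R^2 {model.r_squared:.3f}")
```

prints

```
slope 0.898 +/- 0.112
intercept -43.75 +/- 2.62 permil
R^2 0.582
```

i.e. the errors-in-variables fit recovers the empirical line (slope ≈ 0.91,
intercept ≈ −43.5 ‰) with a mild attenuation from the diet-side
measurement uncertainty; R² refers to the central fit.  Applying
`model.predict(-23.0)` gives −64.4 ‰, the methane signature of a typical
mixed C3/C4 diet.

The full pipeline — synthetic world, allocation, energy closure, isotope
mixing, emissions, signatures, Monte Carlo, box model — runs end to end
with

```sh
rumisotope run --out runs/demo --seed 1
```

and writes per-stage CSVs plus a manifest with checksums (identical seeds
give identical files).

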