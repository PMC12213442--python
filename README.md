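# laywise

Within-clutch egg-investment analysis for birds that lay one egg per day.

Many passerines adjust egg size along the laying sequence — a maternal
allocation strategy ("brood survival": later eggs larger; "brood reduction":
later eggs smaller; or a hump-shaped compromise). The classical way to
summarize this is the single number *D*, the deviation of the **last** egg's
volume from the clutch mean. `laywise` implements the full-sequence
alternative: a hierarchical penalized-smooth Gaussian model (a GAMM) of egg
volume over laying order, with random intercepts for clutch and year and
within-clutch AR(1) residuals — and shows quantitatively why *D* can miss a
hump-shaped strategy entirely.

## The model

Egg volume is estimated from calliper length *L* and breadth *B* (mm) as
v = 0.4673·L·B² + 0.042 (great-tit-specific constants), standard-scored over
the dataset, and modelled as

    v̄ᵢ = β₀ + f₁(zᵢ) + f₂(csᵢ) + f₃(Tᵢ) + f₄(zᵢ, csᵢ) + f₅(Tᵢ, csᵢ)
          + b_year(i) + b_clutch(i) + εᵢ

where *z* is the within-clutch standard score of laying position, *cs* the
dataset-scaled clutch size, *T* the dataset-scaled mean daily-minimum
temperature over the 3 days before laying (the egg-formation window);
f₁–f₃ are cubic regression splines, f₄–f₅ isotropic thin-plate interaction
surfaces, b's are ridge-penalized (i.i.d. Gaussian) random intercepts, and ε
follows an AR(1) process within each clutch (independent across clutches).
Smoothing parameters are selected by a restricted-likelihood (REML-type)
criterion; ρ is estimated by the two-pass procedure: fit without AR, pool all
within-clutch consecutive residual pairs, refit with the pooled lag-1
correlation fixed. Residual dependence beyond the modelled trend is profiled
per clutch by ACF/PACF against the white-noise band ±2/√n̄ (n̄ = mean clutch
size).

A fully parameterized synthetic-data generator mirrors this structure (5
years, ~145 clutches of 4–10 eggs, grand mean 1506.24 mm³, between-clutch CV
7.69%, a quadratic order effect spanning −2.5%…+2% of mean volume, AR(1)
residuals with ρ = 0.19) so every stage is testable without field data.

## Worked example

```python
import laywise as lw

eggs, temps, truth = lw.generate_dataset(lw.SyntheticConfig(seed=1))
frame = lw.build_model_frame(eggs, temps)
two = lw.two_pass_ar_fit(lw.default_design(), frame)
fit = two["pass2"]
print(f"rho (pass 1)        = {two['rho']:.3f}")
print(f"deviance explained  = {100 * fit.deviance_explained_:.1f}%")
print(f"order-smooth edf    = {fit.edf_['s(position_z)']:.2f}")
curve = lw.predict_order_effect(fit, frame)
print(f"order-effect curve  = {curve['deviation_pct'].min():.2f}% "
      f"to {curve['deviation_pct'].max():.2f}% of mean volume")
d = lw.clutch_summaries(eggs)["d_statistic"]
print(f"last-egg deviation D: mean {d.mean():.2f}%, mean |D| {d.abs().mean():.2f}%")
```

prints

```
rho (pass 1)        = 0.030
deviance explained  = 95.1%
order-smooth edf    = 3.70
order-effect curve  = -3.35% to 1.46% of mean volume
last-egg deviation D: mean -0.54%, mean |D| 1.63%
```

The fitted partial-effect curve recovers the injected hump: first eggs ~2.5%
below the mean, a peak of ~+2% past mid-sequence, last eggs back near the
mean (the printed curve is shifted slightly down because its additive
constant is absorbed by the model intercept). With measurement noise switched
off, every clutch's |D| stays below 1% even though the true order effect
spans 4.5 percentage points — the blindness of the last-egg statistic.

The same analysis runs from the shell:

```bash
laywise fit --seed 1 --out run1        # simulate + full analysis
laywise report --run run1
laywise fit --eggs eggs.csv --temps temps.csv --out run2   # your own data
```

Each run writes `terms.csv` (edf, statistic, p per smooth), `partition.csv`
(drop-one deviance shares), `concurvity.csv`, `basis_check.csv`, `lags.csv` /
`lag_summary.csv` (per-clutch ACF/PACF vs the white-noise band), a per-clutch
table with *D* (`clutches.csv`), the order-effect curve on both axes
(`order_effect_curve.csv`), and `run.json` with the seed, ρ and deviance
accounting.

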