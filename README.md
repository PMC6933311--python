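# sealflux

Bioenergetics and movement analysis for central-place foraging pinnipeds,
built around the doubly-labelled-water (DLW) study of lactating northern fur
seals (*Callorhinus ursinus*) from the Pribilof Islands. The package turns
raw isotope, body-mass, dive, satellite-track and milk fatty-acid inputs into
at-sea field metabolic rates (FMR), water influx (a prey-consumption proxy),
trip-level foraging metrics, diet clusters, and AICc model-averaged covariate
effects — and ships the study's 48-measurement trip table so the published
regression results can be recomputed on a laptop.

It is written for ecophysiologists and quantitative ecologists who need a
tested, scriptable implementation of the standard DLW/telemetry analysis
chain, with a synthetic-data generator whose estimators and simulators are
exact inverses, so every stage can be validated without field data.

## The science in brief

**DLW energetics.** An animal dosed with H₂¹⁸O and ³H₂O loses the oxygen
label as both water and CO₂ but the hydrogen label only as water. From the
fractional turnover rates `k_o` and `k_d` (day⁻¹, from log-linear washout of
the background-corrected blood concentrations) and the body water pool `N`
(mol, by ¹⁸O dilution with a 1.007 dilution-space factor), CO₂ production is

    rCO2 (mol/day) = (N / 2.078) (k_o − k_d) − 0.0062 k_d N

converted to energy at 23.9 kJ per litre CO₂. The measurement integrates the
whole release-to-recapture interval; subtracting an assumed onshore metabolic
rate times time ashore and dividing by time at sea yields the at-sea FMR
(W kg⁻¹). Water influx follows from `k_d` and the (linearly changing) pool:
`influx = k_d · N̄ + ΔN/Δt`.

**Behaviour.** Depth traces are zero-offset corrected (rolling lower-
percentile surface baseline), dives are maximal runs of samples strictly
deeper than 3 m, and ARGOS tracks are cleaned by quality class (drop B/Z)
and a 3 m s⁻¹ maximum-transit-rate filter before hourly interpolation.

**Diet.** Milk fatty-acid signatures are closed to 100%, centred-log-ratio
transformed, Ward-clustered on squared Euclidean distances and cut with an
adaptive (dynamic) tree cut; a linear discriminant analysis ranks the FAs
separating the clusters.

**Inference.** Every main-effect subset of the candidate predictors is fit
by maximum likelihood (random intercept per seal where it does not collapse
to zero variance), ranked by AICc, and coefficients are conditionally
averaged over the 95% cumulative-weight confidence set with Burnham–Anderson
unconditional standard errors.

## Worked example

```sh
python examples/06_model_averaging.py
```

prints (abridged):

```
candidate models : 64 (n = 47 complete cases)
95% confidence set: 41 models

model-averaged coefficients (conditional, 95% confidence set):
                estimate     se  ci_low  ci_high  sum_weight
Intercept          7.472  0.709   6.083    8.861       1.000
season[fall]       0.532  0.248   0.046    1.019       0.736
trip_duration     -0.155  0.077  -0.306   -0.004       0.738
...

fall effect    : +7.1% of the averaged intercept
trip-day effect: -2.1% per additional day at sea
```

The intercept is the at-sea FMR (W kg⁻¹) of a reference seal (summer,
covariates at zero); the `season[fall]` and `trip_duration` CIs exclude zero,
so season and trip length — not diving behaviour, diet cluster or instrument
drag — explain the variation in at-sea FMR: seals run about 7% hotter in
fall and about 2% cooler for each extra day at sea. The other examples cover
the DLW chain (`02`), dive metrics (`03`), track filtering (`04`), FA
clustering (`05`) and the full reproduction report (`01`).

A thin CLI mirrors the library (`sealflux data validate table1`,
`sealflux simulate --out-dir d`, `sealflux reproduce --source table1`, ...).

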