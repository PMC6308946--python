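# firegrade

Forest fire weather grading from environmental-station time series.

Operational fire-danger rating in China scores four daily meteorological
quantities on step intervals — daily maximum air temperature *A*, daily
minimum relative humidity *B*, daily precipitation *C* and daily maximum
wind speed *D* — and sums the scores into a composite index that is binned
into fire-weather grades I–V. Step scoring jumps discontinuously at
interval boundaries; `firegrade` replaces each step table with a fitted
logistic curve

```
Y'_i = K_i / (1 + exp(alpha_i + beta_i * X_i)),        K = {20, 20, 10, 40}
```

and corrects the composite with the moisture state of the litter layer:
a phenology term *Y'_E1* (0 off-season, 15 in the fire season, 20 in the
core fire season) and a soil-moisture term *Y'_E2* driven by the volumetric
water content of the humus layer (0 below 5 %, `4 − 80·VWC` between 5 % and
30 %, −20 at and above 30 %). The graded composite is

```
Y = Y'_A + Y'_B + Y'_C + Y'_D + Y'_E1 + Y'_E2
Grade:  I ≤25   II 26–50   III 51–72   IV 73–90   V ≥91
```

The package is aimed at anyone turning raw station telemetry (10-minute
multi-sensor records) into daily fire-weather grades: it covers logistic
curve fitting to the step-interval sample sets, daily aggregation with gap
handling and dry/wet-run counters, the index equations and grade table, a
synthetic station-weather generator for testing without field data, 72-byte
telemetry-frame packing with a lossy delivery channel, and statement
reporting — as a library and a `firegrade` CLI.

## Worked example

Fit the temperature index's scoring curve to its step-interval sample set:

```python
>>> import firegrade as fg
>>> res = fg.fit_logistic(fg.builtin_sample_sets()["A"])
>>> print(res.summary())
Step-interval logistic fit
==============================================
Index:            A
Method:           irls
No. observations: 6
K (fixed):        20
R-squared:        0.9771
----------------------------------------------
              coef     std err
alpha       3.6421      0.6232
beta       -0.2428      0.0384
----------------------------------------------
Midpoint (K/2 crossing): 15.0000 degC
```

The curve scores a daily maximum of 15 °C at exactly half the saturation
score (10 of 20 points) and approaches 0 and 20 in the cold and hot tails.
Score a hot, dry, windy day in the core fire season — six rain-free days,
dry litter:

```python
>>> eqs = fg.IndexEquations.published()
>>> a = eqs.assess("2017-04-10", t_max=24.0, rh_min=0.28, precip_mm=0.0,
...                wind_max=8.5, humus_vwc=0.09, dry_run=6, wet_run=0)
>>> [round(v, 2) for v in (a.y_a, a.y_b, a.y_c, a.y_d, a.y_e1, a.y_e2)]
[17.98, 18.71, 39.28, 17.53, 20.0, -3.2]
>>> round(a.total, 1), a.grade
(110.3, 5)
```

Heat, dry air and the accumulated dry spell dominate (the dry-run bonus
lifts *Y'_C* to 39.3); the litter is dry enough that the soil correction
subtracts only 3.2 points, and the day grades V — the highest danger class.

The same pipeline from the shell:

```bash
firegrade simulate --days 92 --seed 1 --out sensors.csv
firegrade aggregate --input sensors.csv --out daily.csv
firegrade assess    --input daily.csv  --out assessments.csv
firegrade report    --summaries daily.csv --assessments assessments.csv \
                    --period monthly --out monthly.csv
firegrade refit     --out fitted_params.json
```

## Layout

| module | contents |
| --- | --- |
| `firegrade.samples` | step-interval sample sets, config load/dump |
| `firegrade.model` | `StepLogisticModel` / `StepLogisticResults` (IRLS and NLS fitting, R², summary) |
| `firegrade.indices` | component indices *Y'_A*…*Y'_E2*, phenology calendar, composite and grade table |
| `firegrade.aggregate` | daily aggregation, gap policy, dry/wet-run counters, CSV interchange |
| `firegrade.synthetic` | seeded stochastic station-weather generator, parameter recovery |
| `firegrade.telemetry` | 72-byte frame encode/decode, Bernoulli delivery channel |
| `firegrade.report` | daily/monthly/annual statements |
| `firegrade.cli` | `simulate`, `aggregate`, `assess`, `refit`, `report` subcommands |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
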