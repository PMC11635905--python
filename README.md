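# habitdecay

Idiographic and multilevel trajectory analysis of **habit decay** from
daily diary data.

When people try to break an everyday habit — snacking in front of the
TV, smoking with the morning coffee — how fast does the felt
automaticity of the behavior fade, and does it settle at a stable lower
level? Intensive-longitudinal designs answer this with daily
self-reports of habit strength (the 4-item Self-Report Behavioral
Automaticity Index, SRBAI, scored 0–4), giving one noisy, gappy time
series per person over an 84-day decay phase. `habitdecay` provides the
full analysis chain for such data, aimed at health-psychology and
behavioral-medicine researchers working with e-diary studies:

1. **Preprocessing** — after-midnight responses reassigned to the
   previous day, same-day duplicates averaged, items averaged into the
   SRBAI score, isolated missing days imputed by the neighbor mean
   (longer gaps retained), and participants filtered by retention rules
   (≥ 6 observed measurements, engagement through the decay-phase
   midpoint).
2. **Person-specific models** — six trajectory families fitted per
   participant: constant, linear, quadratic, cubic,
   asymptotic `f(t) = A + (R0 − A) e^{−e^λ t}`, and 4-parameter
   logistic `f(t) = L + (U − L) / (1 + e^{(t−m)/s})`. Polynomials are
   solved by exact OLS; the curves by bounded nonlinear least squares
   from a deterministic multi-start grid. The best family minimizes the
   Gaussian BIC `n ln(SSE/n) + k ln n` (error variance counted in `k`).
3. **Validity gate** — four checks decide whether fitted values validly
   describe a decay trajectory: (1) decreasing fitted values, (2) BIC
   selection stable under leave-one-out deletion of every single
   observation, (3) RMSE ≤ 0.33, (4) no missing gap longer than 21
   days. Constant best fits go through a separate "stably strong habit"
   verdict using checks 2–4.
4. **Stabilization** — time for decay to stabilize, strictly within the
   observed window: the day 95 % of the drop to the lower asymptote is
   completed (closed forms for both curve families), the first day the
   7-day change in fitted values falls below a threshold (0.1 default,
   0.01 alternative), and the first day fitted values cross the scale
   midpoint 2.0.
5. **Multilevel models** — variance decomposition (ICC of the
   random-intercept model), cubic linear mixed models in rescaled time
   (0 → 1.72) with an iterative random-effects ladder and
   behavioral-group contrasts, and a two-stage estimator of the
   nonlinear asymptotic mixed model. All ML, compared by BIC.
6. **Synthetic cohorts** — a seeded generator emulating the structure
   of a four-group, 194-participant diary study (≈ 29 % missing values,
   late-series gap clustering, duplicates, after-midnight responses)
   with known ground-truth families, parameters and stabilization days,
   so every stage is testable end to end.

## Worked example

```python
import math
import numpy as np
from habitdecay import (DiarySeries, fit_all_families, select_best,
                        classify, time_to_95_asymptote, evaluate)

rng = np.random.default_rng(7)
t = np.arange(84.0)
latent = evaluate("asymptotic", [0.8, 3.4, math.log(0.09)], t)
y = np.clip(np.round((latent + rng.normal(0, 0.3, 84)) * 4) / 4, 0, 4)
series = DiarySeries("P0001", "SB", y)

fits = fit_all_families(series)
best, margin = select_best(fits)
print(f"best family: {best} (BIC margin {margin:.1f})")
print("theta:", np.round(fits[best].theta, 3), f"RMSE {fits[best].rmse:.3f}")
verdict = classify(series, fits)
print("validity:", verdict.overall_valid,
      [verdict.step1_decreasing, verdict.step2_loo_stable,
       verdict.step3_rmse_ok, verdict.step4_gap_ok])
est = time_to_95_asymptote(fits[best], series)
print(f"decay stabilizes (95% of drop) by day {est.day}")
```

Output:

```
best family: asymptotic (BIC margin 2.3)
theta: [ 0.814  3.534 -2.187] RMSE 0.251
validity: True [True, True, True, True]
decay stabilizes (95% of drop) by day 27
```

The participant's series is best described by an asymptotic decay from
an initial strength of ≈ 3.5 toward a floor of ≈ 0.8 at rate
e^(−2.187) ≈ 0.11/day; all four validity checks pass, and 95 % of the
total drop is completed by day 27. The true generating curve (rate
0.09/day) stabilizes at day ⌈ln 20 / 0.09⌉ = 34; a 7-day error is at
the upper end of what this noise level produces (the median absolute
error across replicates is ≈ 3 days — see `scripts/acceptance.py`).

## Command line

The same pipeline runs from the shell; each subcommand executes the
stages up to and including its own:

```bash
habitdecay all --seed 3 --out results/          # simulate + full analysis
habitdecay select --input diary.csv --out results/ --no-loo
habitdecay stabilize --config run.yaml --threshold-window 0.01
```

Outputs are tidy CSVs per stage (fits, verdicts, stabilization
estimates, mixed-model ladder, plot data) plus `summary.json` and
`run_metadata.json`; a run is bit-reproducible from config + seed.

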