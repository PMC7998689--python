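# surftens

Surface tension of liquid organic acids from a feed-forward neural network,
benchmarked against classical corresponding-states correlations.

## The problem

The vapour–liquid surface tension σ of a pure liquid decreases with
temperature and vanishes exactly at the critical point. For organic acids —
additives in foods, fuels, detergents and pharmaceuticals — experimental σ
data are sparse, multi-source, and often disagree at the same temperature,
and no single analytical correlation reproduces the whole family with
acceptable accuracy: the classical corresponding-states (CSP) estimates give
overall average deviations above 20 % on a pooled acid corpus.

`surftens` implements the alternative: a single-hidden-layer perceptron

σ = f(T_r, T_b, ω),  T_r = T/T_c,

with min–max normalized inputs and output, a logistic hidden layer and a
linear output neuron. The selected architecture is (3, 41, 1) — 206
trainable coefficients. Training minimizes the RMSE of the normalized
residuals by Levenberg–Marquardt (damped Gauss–Newton with the exact
analytic Jacobian), restarted from 30 random initializations; the pooled
data are split 75 / 15 / 10 into training / test / prediction subsets, the
test subset drives early stopping and restart selection, and the prediction
subset is never consulted before the final evaluation.

Model quality is reported with the field's standard statistics, per subset
and per fluid:

- PD_i = 100 (σ_calc(T_i) − σ_i) / σ_i — signed percent deviation;
- AAD = mean |PD_i| and PDm = max |PD_i| (percent);
- RMSE (N/m) and R² about the data mean.

The package also provides: the four CSP baselines (Brock–Bird, Sastri–Rao
with the acid parameter set, Pitzer, and a power-law form in T_c, ω, M_w)
with a benchmark runner; effect-factor input ranking; a hidden-size sweep
(2–50 neurons) for architecture selection; a synthetic-corpus generator
that emulates the statistical structure of a multi-source acid compilation
(98 fluids, 4–165 points each, σ(T) vanishing at T_c, duplicated
temperatures with independent scatter); and a CLI wiring it all together.

## Worked example

```python
from surftens import (GeneratorConfig, generate_dataset, SurfaceTensionANN,
                      TrainingConfig, run_csp_benchmark)
from surftens.csp import summary_table

ds, _ = generate_dataset(GeneratorConfig(n_fluids=30, seed=42))
res = SurfaceTensionANN(ds, n_hidden=12, seed=42).fit(
    restarts=4, config=TrainingConfig(max_iterations=200, seed=42))
print(res.summary())
print(summary_table(run_csp_benchmark(ds)))
```

prints

```
Surface-tension feed-forward network
====================================================
architecture      (3, 12, 1)   [61 coefficients]
inputs            Tr, Tb, omega
activation        logistic (hidden), linear (output)
data              N = 666 over 30 fluids
split             training/test/prediction = 500/100/66
restarts          4 completed (winner #0)

    subset   N  AAD_pct  PDm_pct  RMSE_N_per_m       R2
  training 500     0.89     6.56      0.000223 0.999570
      test 100     0.98     6.63      0.000243 0.999515
prediction  66     0.88     2.57      0.000256 0.999472
  complete 666     0.90     6.63      0.000230 0.999551

                brock_bird  sastri_rao  pitzer  gharagheizi
N10                    3.0         9.0     2.0         15.0
maxAAD_pct           171.3        91.7   388.3         60.8
minAAD_pct             2.9         3.0     4.1          1.0
overallAAD_pct        45.1        21.7    67.0         11.9
```

The network reproduces the pooled corpus with a complete-set AAD of 0.90 %
and a worst point at 6.6 %, while the best corresponding-states baseline
stays above 11 % overall — the prediction-subset row shows the accuracy on
data the fit never saw. `res.predict(fluid, T)` then returns σ in N/m for
any fluid record and temperature below its T_c (inputs outside the training
range are flagged as extrapolation, not rejected).

The same pipeline runs from the shell:

```sh
surftens simulate --n-fluids 98 --seed 1 --out run/
surftens fit      --data run/dataset.csv --hidden 41 --restarts 30 --out run/fit/
surftens csp      --data run/dataset.csv --out run/csp/
surftens predict  --model run/fit/model.json --fluids consts.csv -T 300,350 --out run/pred/
```

Measured corpora are read from CSV (columns
`fluid,family,Tc_K,Tb_K,omega,Pc_bar,Mw_g_mol,T_K,sigma,source`, σ in N/m
or mN/m via `--units`), so the full workflow applies unchanged to real
acid data.

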