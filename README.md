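# cateforest

Random-forest estimation of **conditional average treatment effects
(CATE) for a continuous treatment and a continuous response**, with a
reproducible confounder/collider simulation benchmark.

Many applied questions in epidemiology and biostatistics are of the
form "how much does one more unit of exposure change the outcome, for
a patient like this one?" — a dose–response slope that varies with
covariates. `cateforest` targets the varying-coefficient model

    E[Y | X = x, G = g] = mu(x) + tau(x) * g

where `Y` is the response, `G` the continuous treatment (dose),
`X = (X1, ..., Xp)` the covariates, `mu(x)` a nuisance prognostic
surface and `tau(x)` the CATE to be estimated.

## Method

The estimator is a bootstrap ensemble of CART-style trees used as a
*weight-generating machine* rather than an averaging device:

1. **Tree growth** under one of two bespoke split rules, both built on
   the within-node linear model `Y = mu + tau*G`:
   * **HET** maximizes treatment-effect heterogeneity,
     `N_L * N_R * |tau_L - tau_R|`;
   * **CMB** minimizes the pooled residual sum of squares of the two
     child models (a CART-flavoured version of model-based recursive
     partitioning).
2. **Prediction via the BOP** ("bag of observations for prediction"):
   for a query point `x`, collect — as a multiset, with bootstrap
   multiplicities — all in-bag training observations that share `x`'s
   terminal node in each tree, then fit `Y = mu + tau*G` by weighted
   OLS on that multiset. The fitted slope is `tau_hat(x)`.
3. **Local centering** (orthogonalization): before growing the causal
   forest, the response and/or treatment can be replaced by residuals
   against out-of-bag regression-forest estimates of `m(x) = E[Y|X]`
   and the propensity `pi(x) = E[G|X]`. The four variants are `NoC`
   (none), `Cy` (response), `Cg` (treatment) and `Cyg` (both); `Cyg`
   is the robust default under confounding.

The benchmark harness simulates datasets with five covariates, a
piecewise-constant prognostic baseline, three treatment-effect shapes
(step, linear, quadratic in `X4`), an optional confounder (`X1` drives
both dose and outcome) and an optional collider (`X5` is generated
from the outcome signal), for 27 scenarios in total, and scores
methods by `MSE_CATE` on independent test sets with rank tables and
paired t-tests.

## Worked example

```python
import numpy as np
from cateforest import (ScenarioConfig, make_dataset, ForestConfig,
                        pipeline_fit, predict_tau, mse_cate)

train = make_dataset(ScenarioConfig("linear", "none", "none", n=1000, seed=7))
test = make_dataset(ScenarioConfig("linear", "none", "none", n=500, seed=8))

fitted = pipeline_fit(train, "Cyg", ForestConfig(rule="CMB", n_trees=100, seed=1))
tau_hat = predict_tau(fitted, test.X)
print(f"test MSE_CATE: {mse_cate(tau_hat, test.tau_true):.3f}")

grid = np.full((5, 5), 5.0)
grid[:, 3] = [1, 3, 5, 7, 9]
for x4, t in zip(grid[:, 3], predict_tau(fitted, grid)):
    print(f"X4 = {x4:.0f}   true tau = {x4 / 2:.2f}   estimated tau = {t:.2f}")
```

Output:

```
test MSE_CATE: 0.059
X4 = 1   true tau = 0.50   estimated tau = 0.43
X4 = 3   true tau = 1.50   estimated tau = 1.54
X4 = 5   true tau = 2.50   estimated tau = 2.84
X4 = 7   true tau = 3.50   estimated tau = 3.29
X4 = 9   true tau = 4.50   estimated tau = 4.56
```

The linear effect `tau(X4) = X4/2` is recovered across the covariate
range; the mean squared error of 0.06 compares with an effect variance
of about 2.1, i.e. ~97% of the CATE variation is explained.

The same pipeline is available from the shell:

```bash
cateforest simulate --effect linear --confounding strong --n 1000 --seed 7 --out train.csv
cateforest fit --data train.csv --rule CMB --variant Cyg --trees 100 --out model.jsonl
cateforest predict --model model.jsonl --data test.csv --out preds.csv
cateforest study --effects linear --reps 10 --trees 50 --out results/
```

Every command writes a JSON manifest (parameters, seeds, version) next
to its outputs, and reruns with identical configuration produce
byte-identical files.

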