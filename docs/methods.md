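# Methods

## Model and estimand

The package estimates the conditional average treatment effect of a
continuous treatment under the varying-coefficient model

    E[Y | X = x, G = g] = mu(x) + tau(x) * g.

`tau(x)` is the local dose–response slope. Identification requires the
usual unconfoundedness condition — given `X`, the treatment is as good
as random — plus the linearity in `g` assumed above. Nothing in the
implementation restricts `G`'s support, but the simulation design uses
`G` in [0, 1].

## Forests as weight generators

Each forest consists of `n_trees` CART-style trees grown on
n-out-of-n bootstrap samples (63.2% subsampling without replacement is
available as `samptype="swor"` but is not the default). Trees have
unlimited depth; growth stops only when no valid split exists. A split
is valid when both children contain at least `min_node` bootstrap rows
*counted with multiplicity* and, under the causal rules, when neither
child has essentially constant treatment.

Prediction does not average tree outputs. For a query `x` the *bag of
observations for prediction* (BOP) is the multiset union, across
trees, of in-bag training rows sharing `x`'s terminal node, each row
carried with its bootstrap multiplicity. `tau_hat(x)` is the slope of
the multiplicity-weighted OLS fit of the working response on the
working treatment over the BOP. `predict_batch` computes the same
quantity from per-leaf cached sufficient sums (sum w, wG, wG², wY,
wGY), which agrees with the explicit BOP regression to floating-point
precision and makes prediction O(trees × depth) per query.

## Split rules

At a candidate split with children `(t_L, t_R)` of sizes `(N_L, N_R)`,
with `tau_hat_L`, `tau_hat_R` the child OLS slopes:

* **HET** (maximize): `w(N_L, N_R) * |tau_hat_L - tau_hat_R|`. The
  size weight is the product `N_L * N_R` by default; a
  `sqrt(N_L * N_R)` alternative is available via
  `ForestConfig(het_weight="sqrt")` because the two readings are hard
  to distinguish typographically and behave almost identically in the
  benchmark (the sqrt variant measured marginally worse under strong
  confounding).
* **CMB** (minimize): pooled within-child residual sum of squares of
  `Y = mu + tau*G`.
* **VAR** (minimize): pooled within-child squared deviation from child
  means — the classic regression-tree rule, used only by the auxiliary
  nuisance forests.

Candidate generation follows randomized splitting: `mtry` covariates
drawn without replacement; for each, `nsplit` thresholds drawn
uniformly between the node's min and max of that covariate
(`nsplit=None` enumerates all midpoints, used by the exhaustive-search
tests). Ties go to the first-drawn candidate, so the search is a pure
function of the node RNG stream.

All split evaluation runs on prefix sums of (Y, G) moments after
centering at the node mean, giving O(1) work per candidate and
agreement with direct per-side OLS fits to ~1e-10.

## Local centering

`m(x) = E[Y|X]` and `pi(x) = E[G|X]` are estimated by VAR-rule
forests on the same hyperparameters as the causal forest (uniformity
chosen for comparability; the design specifies no separate tuning),
using out-of-bag predictions so no row's estimate uses its own
response. The four variants NoC/Cy/Cg/Cyg subtract neither, `m_hat`,
`pi_hat`, or both. Centering is a one-shot preprocessing step: the
centered variables feed both tree growth and the BOP regressions.
Within a benchmark repetition the nuisance estimates are computed once
and shared across all variants and split rules, removing spurious
between-method variance. Rows that are never out-of-bag (probability
~0.632^n_trees) fall back to the in-bag ensemble prediction and are
counted.

## Degeneracy and fallbacks

A node, or a BOP, with `Var(G) < 1e-12 * range(G_train)^2` (or with
fewer than two effective observations) is *degenerate*: its slope is
undefined. Degenerate children invalidate a candidate split under
HET/CMB; a degenerate BOP triggers a flagged fallback to the
full-training-sample OLS slope. With continuous treatments and
`min_node=30` this is unreachable in practice, but the prediction
contract is total. When the training treatment is globally constant
the tolerance becomes infinite and everything is flagged.

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| `n_trees` | 100 | trees per forest |
| `mtry` | 5 | candidate covariates per node (all five, in the benchmark DGP) |
| `min_node` | 30 | minimum bootstrap rows (with multiplicity) per child |
| `nsplit` | 10 | random candidate thresholds per covariate |
| `bootstrap` | true | n-out-of-n sampling with replacement |
| `het_weight` | product | HET size weight (`product` or `sqrt`) |

These defaults are the benchmark's study conditions, not tuned values.

## Simulation design

Five covariates: `X1..X4 ~ U(0,10)` i.i.d.; the baseline
`mu in {1,2,3,4}` is piecewise constant on `(X1, X2, X3)` half-planes
split at 5. Treatment-effect shapes in `X4`: step (1 below 5, else 5),
linear (`X4/2`), quadratic (`(X4-5)^2/5`). Response noise is
`N(0, 0.5^2)`.

* **Confounding:** `G = clip(0.6 - X1/50 + eps_G, 0, 1)` with
  `sd(eps_G) = 0.17` (weak) or `0.07` (strong); otherwise
  `G ~ U(0,1)`. Mean sample correlations cor(X1, G) ~ -0.33 / -0.64.
* **Collider:** `X5 = h + eps_X` with `h` the realized noiseless
  response mean (computed from the truncated `G`, the same `h` that
  generates `Y`) and `sd(eps_X) = 4` (weak) or `1.5` (strong);
  otherwise `X5 ~ U(0,10)`. Mean cor(X5, Y) ~ 0.34–0.41 (weak) and
  0.67–0.75 (strong), depending on the effect shape. Note the analytic
  value for the step shape without confounding is 0.40, slightly above
  the informally quoted 0.28–0.39 span for weak colliders.

The full grid is 3 shapes × 3 confounding × 3 collider = 27 scenarios;
study conditions are 100 repetitions, n_train = 1000, n_test = 500,
scored by `MSE_CATE = mean((tau_hat - tau)^2)` on the test set, with
MAE and a Kendall-based concordance as companions. Boundary
conventions (`<= 5` for baseline regions, `< 5` for the step effect)
are measure-zero events.

What the generator does **not** emulate: nonlinear dose–response,
heteroscedastic or heavy-tailed noise, discrete or high-dimensional
covariates, and treatment effects driven by more than one covariate.
Passing benchmarks here therefore demonstrate correctness of the
machinery and its behavior under confounding/collider distortions, not
performance on arbitrary real data.

## Seeds and determinism

Every dataset expands a single integer seed into independent
substreams (covariates, treatment noise, response noise, collider
noise); forests spawn one substream per tree; the study harness
derives per-(scenario, repetition) sub-seeds for train data, test
data, nuisance forests and causal forests from a master seed. Within a
repetition all methods share the train/test draw, the nuisance
realizations and the causal-forest seed, so method comparisons are
fully paired. The whole pipeline is a pure function of its
configuration; the CLI writes manifests and 17-significant-digit CSV
for lossless round trips.

## Benchmark comparisons

Methods are ranked per scenario by median MSE (ties averaged). Paired
comparisons use two-sided paired t-tests on per-repetition MSE at the
5% level; the percent difference in mean MSE uses the **larger** mean
as denominator — a symmetric convention bounded by 100%, which is
*conservative* relative to the common smaller-mean denominator (it
reports smaller percentages), worth keeping in mind when comparing
against a 20% threshold. External gradient-forest and
conditional-inference implementations are out of scope; the harness
compares the HET and CMB rules across the four centering variants.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run scaled-down versions of
the study: calibration correlations use 100 replicates of n = 1000;
the HET/CMB closeness check uses 6 scenarios (each effect shape in the
strong-confounder and strong-collider corners) × 10 paired
repetitions, 50 trees, n_train = 500, n_test = 250; centering-ordering
checks use n_train = 800 with 60 trees and 10 repetitions, a size
chosen because the collider's differential effect on the
partially-centered variants is smaller than Monte-Carlo noise at
n ≤ 400; parameter-recovery checks use the full n = 1000 with 100
trees over 5 seeds.

## Known limitations

* Under a strong confounder the treatment has small conditional
  variance (~0.09 before centering), so child-slope estimates at
  `min_node=30` are noisy and the HET statistic — a maximum over many
  noisy candidates — chases noise. At n = 1000 the HET–CMB mean-MSE
  difference stays near 20%; at n = 500 it can reach 40–50% in
  strong-confounder scenarios. The scaled-down closeness check
  inherits this inflation; the full-scale behavior is the meaningful
  one.
* No honesty/sample-splitting for the causal forest and no
  cross-fitting for the nuisances; confidence intervals are out of
  scope.
* Quadratic-in-dose within-node models and variable-importance
  machinery are not implemented.
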