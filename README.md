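# cellallometry

Why isn't each cell its own cell type? Across the tree of life the
number of cell types *K* grows far more slowly than the number of cells
*N* — and, unusually for an allometric relationship, log *K* vs log *N*
is not a straight line. `cellallometry` is a Bayesian analysis toolkit
for this relationship, aimed at quantitative biologists comparing two
explanations:

* a **double power law**: two scaling regimes with a breakpoint
  *n*<sub>bp</sub>, i.e. a piecewise linear relation between
  *n* = log₁₀ *N* and *k* = log₁₀ *K*;
* a **diminishing returns** model: new cell types arise by discrete
  segregation events whose fitness change is

  Δf = a N^γ b^(−K) − c N^δ,  b > 1,

  so each existing type cuts the next event's benefit by a factor *b*.
  Requiring Δf ≥ 0 yields a closed-form capacity
  K = A + B·log₁₀ N with A = log₁₀(a/c)/log₁₀ b and
  B = (γ−δ)/log₁₀ b, hence the concave regression curve
  k = log₁₀(A + B·n).

Both mean models are fit in double log-space with normally distributed
residuals whose standard deviation is either constant (Σ) or increases
linearly with *n* (Σ₀ + s<sub>Σ</sub>·n) — four models in total
(`dpl_const`, `dpl_var`, `dr_const`, `dr_var`). Posteriors are sampled
by ensemble MCMC with convergence diagnostics, summarized as means and
95% highest-density intervals with posterior-predictive bands, and
ranked by leave-one-out expected log predictive density (PSIS-LOO),
with an exact refitting oracle for validation. A synthetic-data
generator reproduces the statistical structure of published cell-type
surveys so the full pipeline runs and is tested offline.

## Worked example

Simulate a 60-organism survey from the diminishing-returns truth
(A = −0.29, B = 1.29, Σ = 0.33) and refit it:

```sh
$ cellallometry simulate --size 60 --seed 12 --out demo
demo/dataset.csv
$ cellallometry fit demo/dataset.csv --model dr_const --seed 1 --out demo_fit
            mean  hdi_lower  hdi_upper   rhat       ess
parameter
A         1.0290    -0.3034     2.4903 1.0002 9805.1634
B         1.1025     0.7516     1.4638 1.0000 9887.5135
Sigma     0.3288     0.2709     0.3921 1.0004 9777.3736
```

The noise level Σ is recovered tightly (0.33 generated, 0.329 ± HDI
[0.27, 0.39] fitted). The capacity slope B's HDI covers the generating
1.29; the intercept A is weakly identified — 60 points over fourteen
decades leave it a wide HDI that here brushes the generating −0.29 at
its lower edge (see `docs/methods.md` on why the K ≥ 1 constraint
biases A upward). R-hat ≈ 1.000 and effective sample sizes near 10⁴
indicate a clean fit; non-convergence would exit with code 3 instead.

`cellallometry compare demo/dataset.csv --out cmp` fits all four
models, writes the elpd ranking (`comparison.csv`) and a four-panel
figure with posterior-mean curves, 95% HDI bands and
posterior-predictive bands. `cellallometry theory --a 1 --b 10 --c 1
--gamma 1 --delta 0` tabulates the closed-form capacity against the
discrete event-by-event simulation (for these parameters,
K = log₁₀ N exactly).

To analyze an observed survey instead, point `fit`/`compare` at any
CSV with cell-count and cell-type-count columns (auto-detected, or set
`--cells-col`/`--types-col`).

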