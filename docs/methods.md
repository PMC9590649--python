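# Methods

## The scientific question

Surveys of cell-type counts across organisms (mostly morphology-based)
show that the number of cell types K grows far more slowly than the
number of cells N — and, unusually for allometry, the relation in
double log-space is not a single straight line. Two explanations are
compared here:

* **Double power law** — two power-law regimes with a breakpoint,
  i.e. a piecewise linear relation between n = log10 N and
  k = log10 K.
* **Diminishing returns** — a mechanistic model in which new cell
  types arise by discrete segregation events whose fitness benefit
  shrinks geometrically with the number of existing types.

## The fitness model

A segregation event converting one cell type into two carries a cost
and a benefit, both scaling as power laws in organism size:

    delta_f(N, K) = a N^gamma b^(-K) - c N^delta,   b > 1

with K the number of existing types. New types accumulate while
`delta_f >= 0`; solving `delta_f = 0` for K gives the capacity

    K = A + B log10 N,   A = log10(a/c)/log10 b,   B = (gamma-delta)/log10 b

so that k = log10(A + B n): concave in log-log space, not a power law.
If the benefit declined only as a power of K, a single power law for K
in N would follow; the geometric decline is what produces the observed
curvature. Boundary events (`delta_f = 0` exactly) are accepted,
because the closed form solves the equality case. The forward
simulator starts from K = 1 (an organism has at least one cell type;
the +1 event convention is assumed) and must land within one event of
the capacity — this is enforced as a cross-check in the tests, not
assumed.

`capacity` may return values below 1 for tiny N. Display code floors
at 1; values entering likelihoods are never silently modified.

## The regression models

All four models assume k ~ Normal(f(n), sigma(n)) in double log-space:

| model | f(n) | sigma(n) |
|---|---|---|
| dpl_const | k0 + piecewise slopes s_small / s_large around n_bp | Sigma |
| dpl_var | same | Sigma0 + s_Sigma n |
| dr_const | log10(A + B n) | Sigma |
| dr_var | same | Sigma0 + s_Sigma n |

Priors: k0 ~ Uniform(-0.5, 0.5); s_small, s_large, A, B ~ Normal(0, 20);
n_bp ~ Normal(5, 2); Sigma ~ HalfCauchy(scale 10); Sigma0, s_Sigma ~
HalfNormal(sd 1). The HalfCauchy scale is the half-width at half
maximum of a Cauchy at 0 truncated to positive values; the half
distributions carry the factor-of-two normalization on the positive
half-line. One published block prints the k0 prior as
"Uniform(0.5, 0.5)"; this is read as a typo for Uniform(-0.5, 0.5),
matching the constant-sd block.

Regression variables are base-10 logarithms; all densities are natural
log, so elpd values are in conventional nats. Domain violations
(A + B n <= 0 at a data point; sigma(n) <= 0) yield log-probability
-inf rather than exceptions — equivalent to truncating the prior to the
valid region, and exactly what a sampler needs in order to reject.

## Sampling

`sample_posterior` runs affine-invariant ensemble MCMC (emcee) with a
move mixture of 50% KDE, 30% differential evolution and 20% DE-snooker.
Defaults: 2 independent ensembles ("chains"), 2000 burn-in steps,
10,000 kept draws per chain, 32 walkers (or 6 per dimension if larger),
thinning 3. Walkers start from an overdispersed cloud around a
Nelder-Mead polish of a data-derived heuristic (overdispersion matters
twice: DE moves derive their proposal scale from the ensemble spread,
and R-hat is only meaningful when chains start dispersed). With no data
the walkers are initialized by prior draws and the run samples the
prior — used to validate the sampler against closed-form moments.

The contract is diagnostic, not algorithmic: split-R-hat < 1.01 and
bulk ESS >= 400, else the fit is flagged (and the CLI exits 3). R-hat
is computed across the independent ensembles with split halves over
time — walkers inside an ensemble interact, so they are not the
independent chains R-hat assumes, and treating them as such produced
spuriously high values even when pooled estimates were stable. ESS is
computed on per-walker trajectories, which carry the true
autocorrelation structure. Ensemble moves have no divergence concept,
so the divergence count is always zero; `target_accept` is recorded in
configs and manifests for provenance (it governs step-size-adapting
samplers) but does not alter this algorithm.

All randomness derives from the config seed through
`numpy.random.SeedSequence`; identical configurations reproduce
summaries bit-identically on one machine.

## Posterior summaries

The HDI of a sample is the narrowest contiguous window of
ceil(prob * S) sorted draws, ties broken toward the lower bound.
Regression curves are evaluated on 200 evenly spaced n values spanning
the data range padded by 2%. Per grid point: the posterior mean and
95% HDI of f(n) over all draws, and a posterior-predictive band from
one simulated k ~ Normal(f(n), sigma(n)) per posterior draw (one draw
keeps the band estimator unbiased). Draws where f(n) is undefined at a
grid point are excluded and counted — not clamped, which would bias the
bands; more than 1% exclusions triggers a warning.

## Model comparison

elpd is estimated by PSIS-LOO: per observation, importance ratios
1/p(k_i | theta_s) are tail-stabilized by fitting a generalized Pareto
distribution to the largest ratios and replacing them with expected
order statistics, truncated at the raw maximum (the standard
Vehtari–Gelman–Gabry recipe; the Pareto fit is delegated to arviz's
`psislw`). elpd_i is a weighted log-mean of the pointwise likelihood,
assembled via log-sum-exp throughout; se = sqrt(n Var(elpd_i)), and
pairwise model differences are computed pointwise with their own se.
A difference within its se is labeled indistinguishable. Observations
with Pareto shape > 0.7 are flagged. An exact leave-one-out refitting
oracle (one full fit per held-out observation, guarded to <= 100
points) provides the independent check; PSIS and exact refitting must
agree within one standard error, and the tests enforce this on
synthetic datasets.

## Synthetic data

The generator runs a chosen model forwards: n uniform over a range
(default 0.3–14, bacteria to blue whale, matching the span of published
surveys), k ~ Normal(f(n), sigma(n)), then N = 10^n, K = 10^k.
Records violating 1 <= K <= N are redrawn whole (clipping would distort
the noise model the fitters assume); this conditions the design on the
constraint, which mildly depletes the smallest organisms. One measurable
consequence: where the capacity curve sits below k = 0 (the smallest
organisms), surviving records lie only above the curve, so the fitted —
untruncated — likelihood sees data biased upward exactly where the
intercept A is identified. In repeated-simulation checks the 95% HDI
for A covers its generating value in about 16 of 20 replicates (B and
Sigma: 19–20 of 20), and a control run without the constraint restores
nominal coverage for all three parameters. This is a property of
fitting an unbounded noise model to logically bounded counts, not of
the sampler. The
`fisher_like_profile` defaults — 60 organisms, diminishing-returns
truth A = -0.29, B = 1.29, constant Sigma = 0.33 — emulate the
published survey's structure; the survey's actual record count is not
stated in the text, and 60 points over 14 decades yields interval
widths comparable to the published ones. What the generator does not
emulate: phylogenetic correlation between related organisms, uneven
sampling of the size axis, and measurement error in N itself. Passing
recovery tests therefore demonstrate correctness of the machinery under
the assumed sampling model, not robustness to those real-data features.

## Problem sizes and numerical choices

Tests run the sampler at reduced budgets (tune 500–1000, draws
2000–4000) chosen so the full suite completes quickly while every
convergence contract still holds; parameter recovery uses 20 replicate
datasets of 60 points, and the PSIS-vs-exact study uses 5 replicates of
30 points (31 fits each). The acceptance script fits all four models at
2 chains x 8000 draws after 2000 burn-in steps. Optimizer polish is
Nelder-Mead (2000 iterations, xatol 1e-6); prior normalization is
verified by quadrature to 1e-6; closed-form zero-crossing identity to
1e-9 relative to the cost scale.

## Known limitations

* The ensemble sampler needs visibly more draws than a gradient
  sampler would for the breakpoint model's curved ridge; the defaults
  accommodate this.
* Exact-refit LOO is O(n) full fits and intentionally guarded.
* The double power law's breakpoint is weakly identified on data
  generated from the diminishing-returns truth (wide, occasionally
  multimodal posterior); diagnostics flag rather than hide this.
* With an observed dataset whose noise is far from the study
  conditions, the data-derived walker initialization may need a larger
  `tune`.
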