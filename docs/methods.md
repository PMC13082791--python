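# Methods

This note documents the models, numerical choices and simulation designs
implemented in `endoprec`, and what the package's tests do and do not
establish.

## Observer model

**Encoding.**  A number `x` produces a representation
`r | x ~ N(mu(x), nu^2 w^(2 alpha))` with `mu(x) = x` (linear) or
`mu(x) = log x` (logarithmic).  `nu > 0` is the baseline imprecision of the
observer, `alpha >= 0` the exponent with which the representation noise
scales with the width `w` of the uniform prior in force.  The Fisher
information is `I(x) = (mu'(x) / (nu w^alpha))^2`.  `nu = 0` is accepted
only to express the explicit motor-noise-only model variant.

**Decoding and response.**  Estimates are the posterior mean
`x*(r) = E[x | r]` under a *discrete* uniform prior over the integers of
the range — matching how stimuli are actually sampled.  (The continuous
and discrete priors give near-identical predictions at these ranges; the
efficient-coding layer uses continuous densities, where the calculus is
cleaner.)  The motor stage draws from `N(x*(r), sigma0^2)` truncated to the
prior range and rounds to the nearest integer; the boundary rounding cells
are `[x_min, x_min + 1/2]` and `[x_max - 1/2, x_max]`, so every draw maps
to an in-range integer, as a bounded slider enforces.

**Likelihood.**  `P(response | x)` integrates the motor-cell masses over
the representation with a fixed quadrature: 201 nodes spanning
`mu(x) ± 6 nu w^alpha`, Gaussian weights normalized to sum to one.  A fixed
deterministic rule (rather than adaptive integration) keeps likelihoods
smooth for the optimizer.  Posterior weights are computed with a max-shift
before exponentiation; pmf rows sum to 1 to 1e-12.  `sigma0 = 0` degrades
gracefully to a point-mass motor stage at the rounded Bayesian estimate.

**Choice rule.**  Two independently encoded averages compared through
their Bayesian estimates give
`P('red') = (1 - eta) Phi((mu(x_R) - mu(x_B) - bias) / (sqrt(2) nu w^alpha)) + eta/2`.
The bias term is zero in the symmetric discrimination task and free in the
risky-choice variant, where the decision variable is
`p X - C - bias`.  With `nu = 0` the rule degenerates to a step function
with ties at 1/2.

**Range-normalization baseline.**  The non-Bayesian baseline maps `x` to
the unit range, reads it out with noise `N(0, nu~^2)` and maps back, so
pre-truncation response variance is `sigma0^2 + nu~^2 w^2` — affine in the
*squared* width.  This is the signature the variance diagnostics are built
to discriminate against the `w^1` scaling of the efficient-coding account.

## Efficient coding

The allocation problem is: choose the per-signal Fisher information
`I_1(.)` and continuous signal count `n` to minimize
`L_a[n I_1] + lambda n`, `L_a[I] = int pi^a / I dx`, subject to
`int sqrt(I_1) dx <= sqrt(K)`.  Closed forms: on a uniform prior
`I_1 = K / w^2` (independent of the task exponent `a`),
`n = w^((3-a)/2) / sqrt(lambda K)`, and in general
`I = pi^(2a/3) / sqrt(theta int pi^(a/3))` with `theta = lambda / K`; hence
imprecision `1/sqrt(I)` scales as `w^(1/2)` (`a = 1`) and `w^(3/4)`
(`a = 2`).  `n` is treated as continuous throughout.

**Numerical solver.**  `brute_force_allocation` optimizes
`s(x) = sqrt(I_1(x)) >= 0` on a grid (the budget is then linear in the
decision variable) jointly with `log n`, using SLSQP with analytic
gradients, from a neutral feasible start (flat `s` at half budget,
`n = 1`).  It never consults the closed forms except as a post-hoc
convergence certificate, so it serves as an independent oracle; on uniform
and triangular priors it reproduces the closed form to ~1e-6 relative and
saturates the budget to 1e-4.  Grids: 512 points for closed-form profiles,
96 for the solver runs in tests and the acceptance script (agreement is
already at the 1e-6 level there; larger grids only cost time).

**Log-constrained variant.**  Constraining the signal to the logarithmic
shape `I_1 ∝ 1/x^2` (as a log encoding or multiplicative noise would
produce) and re-solving for `n` yields the exact total Fisher information
with the same width scaling and a `(x_mid / x)^2` profile; the exact form
exceeds its leading-order expansion by a relative deficit `(h/x_mid)^2 / 6`
to second order, which the package verifies numerically.

## Synthetic data

The generators reproduce the experimental designs: estimation with priors
[50,70], [40,80], [30,90] (widths 20/40/60), 120 scored trials per
condition and 36 subjects; discrimination with priors [35,65] (31
subjects) and [10,90] (32 subjects), 200 scored trials of five red plus
five blue integers; risky choice between a certain amount and a `p = 1/2`
lottery.  Responses come from the observer model itself.

Choices the designs leave open, fixed here once:

- **Population heterogeneity.**  Per-subject `nu_s` and `sigma0_s` are
  log-normal around configurable medians with log-sd 0.3 by default
  (noise parameters are positive and right-skewed); the exponent `alpha`
  is shared by all subjects, since it reflects the task, not the person.
- **Default observer parameters.**  Estimation: `nu = 1.0`,
  `sigma0 = 2.0`, `alpha = 0.5`, linear encoding — these produce central
  response sds of roughly 4/6.5/8 across the three widths, the scale of
  imprecision a human estimator shows in this numerosity range.
  Discrimination: `nu = 0.22`, `alpha = 0.75`, `eta = 0.05`, giving
  psychometric slopes that reach ~60% at average differences of about 1
  (narrow) and 2 (wide).
- **Risky amounts.**  Lottery amounts are uniform over the condition's
  prior ([8,16] narrow, [2,22] wide); the certain amount is uniform over
  the prior scaled by `p`, so the two options are balanced and the choice
  set is informative about the noise scale.
- **Ties** in the noiseless discrimination limit go to 'red'
  (configurable only by symmetry of the labels); **half labels** follow
  trial index (first half vs second), mirroring the stability analysis.
- Rewards (`0.10 - (xhat - x)^2 / 600` per estimation trial) are computed
  for completeness but never used by fitting.

What the generators do *not* emulate: dot-array rendering, display timing,
learning/feedback phases, sequential within-trial evidence accumulation,
and any drift of parameters over a session.  Passing tests therefore
establish the internal consistency and statistical power of the pipeline
under the model's own assumptions — not that real observers satisfy them.

## Model fitting

Bounded maximum likelihood (L-BFGS-B) with a documented deterministic
10-point multi-start grid by default; tests and the acceptance script pass
explicit 2–3 point start lists, which suffice because the likelihood
surfaces here are smooth with a single relevant basin.  Bounds:
`alpha ∈ [0, 1.5]`, noise scales in `(1e-6, 50)`, lapse `eta ∈ [0, 0.5]`
(a lapse above one half is unidentifiable against a sign flip).  Mixed
shared/individual structures are fit as one joint bounded problem rather
than by block coordinate descent; fully shared structures dominate the
test surface.  Single-condition discrimination data identify only
`nu~ = nu w^alpha`; the per-subject API exposes `nu~` directly and the
pooled fit refuses a free `(nu, alpha)` pair on one condition.

BIC is `k ln N - 2 logL`.  Random-effects Bayesian model selection uses
the standard variational Dirichlet update from a uniform Dirichlet(1,...,1)
prior, iterated to 1e-6, with per-subject log evidence approximated by
`-BIC/2`.  The magnitude-split probit compares a two-scale model (both
averages below vs above the prior's middle) against a one-scale
restriction by a likelihood-ratio test against chi-square(1), with no
boundary correction (the scales are interior parameters).

**Parameter-recovery conventions.**  Recovery of pooled (shared)
parameters is checked on data generated with homogeneous subjects: a
shared parameter is only well-defined as a recovery target when the
generating process actually shares it.  Population heterogeneity (log-sd
0.3) is switched on for the analyses that need it — the KS matching of
per-subject `nu~` across conditions, where inter-subject spread is the
object of study.  The psychometric-collapse diagnostic likewise uses
homogeneous populations and long sessions (1000 trials) so that the
binwise gap reflects the width-scaling misfit rather than sampling noise
or condition-level differences in subject draws.

## Hierarchical variability model

Per condition `c` and presented number `x`:
`xhat ~ N(m_sc(x), sigma_sc(x)^2)`, `m_sc(x) ~ N(m_0c(x), tau^2)`,
`ln sigma_sc(x) ~ N(ln sigma_0c(x), nu^2)`, with hyperpriors
`m_0c(x) ~ N(x, 20^2)`, `sigma_0c(x) ~ N+(7, 7^2)`, `tau ~ N+(5, 10^2)`,
`nu ~ N+(5, 10^2)` (truncated at zero and renormalized).  Parameters are
indexed per cell actually present in the data; subject-level parameters
exist only for cells the subject saw.

Sampling is Metropolis-within-Gibbs: conjugate Gaussian updates for all
means, elementwise log-scale random-walk MH for the scales and hyper-sds,
plus *joint translation moves* that shift a cell's fixed effect together
with all its subject-level effects.  The translation moves matter: when
`tau` or `nu` collapse toward zero (e.g. with homogeneous subjects) the
conditional updates alone get stuck in the funnel, and the translations
restore mixing (max split-R-hat drops from ~2.9 to ~1.04 on such data).
Step sizes adapt during warmup only, so the post-warmup chain exactly
targets the posterior.  Desk-scale default: 4 chains of 500 draws after
500 warmup sweeps; analyses in the tests use 1000/1000 where the extra
precision is cheap.  Convergence is reported as max split-chain R-hat with
a 1.05 flag; non-convergence warns but still returns summaries.

Calibration is checked by simulating from the model itself — cell-level
truth drawn from the hyperpriors, `tau = 3`, `nu = 0.3` fixed at plausible
values (drawing them from their own very wide hyperpriors would produce
pathological data scales without changing the calibration logic) — and
verifying that 90% posterior intervals for `sigma_0c(x)` cover the truth
at the nominal rate.

## Descriptive battery

Excursion variances subtract the per-number mean response before pooling a
bin, isolating trial-to-trial variability from stimulus heterogeneity;
the five-bin schemes per condition are fixed (middle bin centered on the
prior midpoint, neighbors of equal size, remainder at the edges:
50–52/53–57/58–62/63–67/68–70; 40–46/47–55/56–64/65–73/74–80;
30–40/41–53/54–66/67–79/80–90).  The variance estimator uses `ddof = 1`
for data analysis by default (`ddof = 0` available; hand-check examples in
the tests use the population convention where stated).  Levene's test is
mean-centered classically, with the median-centered Brown–Forsythe
variant a flag away; Levene on excursions is anticonservative when
per-number cell counts are tiny (the mean subtraction correlates the
residuals), so stability analyses should pool enough trials per number —
the tests use ≥ 20.  Binomial CIs use the normal approximation with a
small-sample guard, or exact Clopper–Pearson by flag.  Psychometric bin
edges are equal-count quantiles of the pooled normalized differences.
Holm adjustment is the standard step-down with monotonicity enforcement.

## Problem sizes

Test and acceptance runs use: estimation recovery at full design scale
(36 × 3 × 120 = 12,960 trials); discrimination recovery at full scale
(63 × 200 = 12,600 trials); solver grids of 96 points; 50 (tests) or 20
(script) KS replicates; hierarchical calibration on 2 × 24 cells with 8
subjects and 6 trials per cell.  These sizes give Monte-Carlo error well
below every tolerance asserted.

## Known limitations

- The brute-force solver assumes the optimum has `I_1 > 0` on the prior's
  support (true for the priors considered); priors with atoms or
  disconnected support are untested.
- Mixed shared/individual fits with many subjects optimize a large joint
  vector and are slow; they are exact but not the tool for exploratory
  sweeps.
- The hierarchical model treats responses as continuous Gaussians,
  ignoring the integer rounding the observer model applies; at these
  response scales (sd >> 1) the discreteness is immaterial.
- No real-data ingestion logic beyond plain CSV; data-cleaning choices
  (e.g. response-time filters) are the caller's responsibility.
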