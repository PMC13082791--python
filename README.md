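# endoprec — endogenous precision of the number sense

Behavioral variability in numerosity tasks is not a fixed property of the
observer: when numbers are drawn from a wider uniform prior, responses
become noisier, but *sublinearly* in the prior width `w`, and the scaling
depends on the task.  `endoprec` implements, end to end, a resource-rational
account of this phenomenon and the analysis pipeline used to test it:

- **Observer model.**  A presented number `x` elicits a Gaussian internal
  representation `r | x ~ N(mu(x), nu^2 w^(2 alpha))`, with `mu` the identity
  (linear encoding) or the natural log (logarithmic encoding).  Estimates are
  the posterior mean `x*(r) = E[x | r]` under the discrete uniform prior,
  corrupted by motor noise (sd `sigma0`, truncated to the slider range,
  rounded to integers).  Binary choices between two averages follow the
  probit rule `P('red') = (1-eta) Phi((mu(x_R) - mu(x_B)) / (sqrt(2) nu w^alpha)) + eta/2`
  with lapse rate `eta`.
- **Efficient coding.**  The observer accumulates `n` i.i.d. signals, each
  with Fisher information `I_1(x)` under the budget
  `int sqrt(I_1) dx <= sqrt(K)` and unit cost `lambda`, and minimizes
  `L_a[n I_1] + lambda n` with `L_a[I] = int pi^a / I`, where `a = 1` for an
  estimation (squared-error) objective and `a = 2` for discrimination.
  The solution makes the imprecision `1/sqrt(I)` scale as `w^(1/2)` in
  estimation and `w^(3/4)` in discrimination — the package's central
  quantitative prediction, available in closed form and from an independent
  numerical solver.
- **Inference.**  Maximum-likelihood fits of every model structure
  (exponent fixed/free/per-subject, noise parameters shared or individual,
  either encoding, lapses), BIC comparison, a magnitude-split probit with
  likelihood-ratio test, Kolmogorov–Smirnov matching of rescaled
  per-subject imprecision across conditions, and random-effects Bayesian
  model selection.
- **Descriptives and hierarchy.**  Binned excursion variances, CV curves,
  relative errors, affine variance extrapolation across widths,
  psychometric collapse diagnostics, half-split stability checks, and a
  Bayesian hierarchical mixed-effects model of response variability sampled
  by Metropolis-within-Gibbs.
- **Synthetic data.**  Trial-table generators that emulate the experimental
  designs (estimation: priors [50,70], [40,80], [30,90], 120 trials per
  condition, 36 subjects; discrimination: priors [35,65] and [10,90], 200
  trials, five red and five blue numbers per trial; risky choice: certain
  amount vs a p=1/2 lottery) with responses produced by the observer model
  itself, so the whole pipeline is testable without any external data.

## Worked example

```python
from endoprec import behavioral_stats as bs, efficient_coding as ec
from endoprec import model_fitting as mf, synthetic_data as sd
from endoprec.specs import SubjectPopulation

# the two task-specific scaling exponents predicted by the allocation problem
print(ec.scaling_exponent([20, 40, 60], a=1))   # 0.5
print(ec.scaling_exponent([30, 80], a=2))       # 0.75

# variance extrapolation: measured sds 4.2 (w=20) and 6.8 (w=40); what
# should the w=60 variance be if variance is affine in w^2, or in w?
print(bs.affine_extrapolate([(20, 4.2**2), (40, 6.8**2)], "width_squared", 60))
print(bs.affine_extrapolate([(20, 4.2**2), (40, 6.8**2)], "width", 60))

# generate estimation data at alpha = 1/2 and refit the exponent
pop = SubjectPopulation(n_subjects=36, nu_log_sd=0.0, sigma0_log_sd=0.0,
                        shared_alpha=0.5, seed=7)
table = sd.gen_estimation(pop)
fit = mf.fit_estimation(
    table, mf.FitStructure(alpha_mode="shared_free", alpha_value=None),
    starts=[(1.0, 2.0, 0.5)])
print({k: round(v, 3) for k, v in fit.params.items()}, round(fit.bic, 1))
```

Output:

```
0.5000000000000011
0.749999999999999
93.90666666666665
74.83999999999999
{'nu': 1.005, 'alpha': 0.495, 'sigma0': 2.074} 75744.2
```

The first two numbers are the exponents `1/2` and `3/4`.  The extrapolation
contrasts the two variance hypotheses: affine-in-`w^2` (a range-normalization
signature) predicts variance 93.91 at `w = 60`, affine-in-`w` predicts 74.84;
data generated (or observed) under the `w^(1/2)` scaling fall near the
latter.  The refit recovers the generating parameters
(`nu = 1`, `alpha = 0.5`, `sigma0 = 2`).

A thin CLI mirrors the library: `endoprec simulate`, `endoprec solve`,
`endoprec fit`, `endoprec analyze` (see `endoprec --help`).

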