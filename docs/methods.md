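# Methods

## Models and assumptions

### Conjugate backbone

Every count-based analysis in the package assumes the observed cells arise
from a multinomial (or product of binomials) sample of a well-defined
population, and places a Dirichlet (or Beta) prior on the cell
probabilities — uniform by default, i.e. all hyperparameters equal to one.
The posterior is then Dirichlet/Beta in closed form and is sampled i.i.d.;
there is no Markov-chain error for these analyses, only ordinary Monte Carlo
error.  Two consequences are used heavily in testing:

- **Beta aggregation.** For `θ ~ Dir(α)` and index sets `A ⊆ B`,
  `Σ_A θ / Σ_B θ ~ Beta(Σ_A α, Σ_{B∖A} α)`.  TPF, FPF, PPV, NPV and the
  marginal TPF/FPF of paired tables are all sub-sum ratios, so their exact
  posterior means are available and every Monte Carlo mean is checked
  against them.
- **Bilinear expectation.** The ordinal AUC
  `Σ_{i>j} θ_i φ_j + ½ Σ_i θ_i φ_i` is bilinear in the independent `θ` and
  `φ`, so its exact posterior mean is the same form evaluated at the
  posterior means.

The diagnostic likelihood ratios and the verification-corrected fractions
are *not* linear in the cell probabilities; their posterior means are
defined as means of per-draw transforms (not transforms of means), which is
what a Monte Carlo treatment of the full posterior gives.  The same applies
to the paired-comparison ratios TPF₁/TPF₂ and FPF₁/FPF₂.

### Binormal ROC for continuous scores

Scores in each disease class are modelled as normal with class-specific
mean and variance, parameterised as a heteroscedastic regression on the
disease indicator: `y_i ~ N(β₁ + β₂ d_i, 1/τ_{d_i})`, with priors
`β_j ~ N(0, precision 10⁻⁶)` and `τ_g ~ Gamma(0.001, 0.001)`.  Both full
conditionals are conjugate (bivariate normal via weighted least squares;
Gamma with shape `0.001 + n_g/2` and rate `0.001 + RSS_g/2`), so the Gibbs
sampler is effectively i.i.d. after a short burn-in.  Per iteration the ROC
functionals are

    la1 = β₂ √τ₀ ,   la2 = τ₀/τ₁ ,   auc = Φ(la1 / √(1 + la2)).

The default standardizes the separation by the *non-diseased* sd (this is
the convention of the worked diabetes analysis); a `convention="diseased"`
flag reports the textbook `(a, b)` pair instead.  The choice affects only
the reported `(la1, la2)`: the AUC is algebraically invariant, reducing to
`Φ((μ₁−μ₀)/√(σ₀²+σ₁²))` either way.  Scores can optionally be
log-transformed before fitting; the default is no transformation.

### Verification bias (MAR)

The correction assumes verification depends on the observed test result
only — `P(V=1 | D, Y) = P(V=1 | Y)` — so the likelihood factors into
verified-subject binomials for `φ_i = P(D=1 | Y=i)` and a full-sample
multinomial for the result margins `θ_i`.  Corrected fractions follow by
Bayes' theorem per joint draw, and for ordinal tests the corrected ROC area
is the usual strict-plus-half-ties form in the corrected `α_i, β_i`.  In the
result tables the tie term is reported *halved* (so the area equals the sum
of the two displayed components); the full tie probability is also present
in the machine-readable output as `a2_full`.  Extreme verification designs
in which one result category is never verified are out of scope: the
correction needs verified subjects in every category that carries
information.

Known direction of the naive bias: when positives are verified more often
than negatives, verified-only estimates of both TPF and FPF are too large;
the synthetic-data coverage test checks both the direction of that bias and
that the corrected 95% intervals cover the generating truth.

### Latent class without a gold standard

Two binary tests applied to the same subjects, conditionally independent
given the unobserved disease state.  The Gibbs sampler augments the data
with per-cell latent diseased counts (binomial conditionals with
assignment probabilities such as `p s₁ s₂ / [p s₁ s₂ + (1−p)(1−c₁)(1−c₂)]`
for the both-positive cell) and updates `p, s₁, s₂, c₁, c₂` from conjugate
Beta conditionals; informative Beta priors simply replace the uniform
hyperparameters.  With only two tests the model has more parameters (5)
than degrees of freedom in the data (3), and the likelihood is invariant
under the relabeling `(p, s, c) → (1−p, 1−c, 1−s)`; with uniform priors the
posterior is therefore bimodal and the chain wanders across both modes
(this is surfaced by `log_likelihood` and tested directly).  Substantive
conclusions require informative priors, as in the bundled Strongyloides
analysis.

### Combined tests

BP/BN fractions are plain sums of the joint cell probabilities (the
"truncated" column-normalized probabilities are exposed but deliberately
unused — only the plain cells reproduce the published combined-test
posterior).  The likelihood-ratio ROC ranks discrete cells by decreasing
`LR = θ_cell/φ_cell` with ties grouped into single steps and `φ = 0 < θ`
cells ranked first; by the Neyman–Pearson lemma this frontier dominates
every decision rule on the same cells, which the suite verifies by
exhaustive enumeration on small grids.  The risk score `P(D=1 | Y)` is a
monotone increasing transform of LR, hence shares its ROC exactly; it is
estimated by Bayesian logistic regression with `N(0, precision 10⁻⁴)`
priors, sampled by random-walk Metropolis whose proposal is shaped by the
posterior-mode inverse Hessian (an in-package Newton/BFGS mode finder) and
whose scalar step adapts during burn-in to a 0.3–0.45 acceptance rate,
after which it is frozen so the chain remains a valid Metropolis sampler.
The ROC area of the fitted risk scores is reported either by refitting the
binormal model to the posterior-mean risk scores by class (mirroring the
published pipeline) or by the empirical Mann–Whitney statistic; risk scores
are bounded and skewed, so the Mann–Whitney route is the distribution-free
cross-check.

## Defaults that matter

| parameter | default | rationale |
| --- | --- | --- |
| conjugate draws | 55,000 | published run size for the worked conjugate analyses; MC error ≈ 1e-4 on fraction scales |
| BP/BN draws | 25,000 | published run size for the combined-test analysis |
| binormal chain | 75,000 iterations, 5,000 burn-in | published run size; conditionals conjugate, burn-in generous |
| latent-class chain | 125,000 iterations, 10,000 burn-in | published run size for the no-gold analyses |
| logistic chain | 45,000 iterations, 5,000 burn-in | published run size for the risk-score analyses |
| coefficient prior precision | 1e-6 (normal regression), 1e-4 (logistic) | vague priors of the published analyses |
| precision prior | Gamma(0.001, 0.001) | vague conjugate prior of the published analyses |
| MC error estimator | batch means, 50 batches | estimator not stated in the source analyses; 50 batches is a common default |
| quantiles | empirical, linear interpolation | matches standard MCMC summary tables |

All stochastic entry points take a single integer seed; the same seed gives
bit-identical draws, chains, and machine-readable reports.

## Synthetic data: what it does and does not show

The generators sample exactly the structure each model assumes:
multinomial cells, MAR verification that never looks at disease status,
conditional independence given the latent class, normal scores per class, a
logistic risk model.  Recovery and coverage tests on these data therefore
validate the *implementation* (correct posteriors under the assumed model),
not the *assumptions*: real studies can violate MAR, conditional
independence, or binormality, and nothing here measures robustness to such
violations.  Correlated-tests-given-disease scenarios beyond an explicit
joint cell-probability matrix are not generated.

## Numerical choices and degenerate inputs

- Ratio measures guard denominators with a floor of 1e-300; under Dirichlet
  posteriors a zero denominator has probability zero, so the floor only
  prevents spurious division warnings.
- `beta_margin` with numerator equal to denominator returns the degenerate
  point mass at 1 (`Beta(a, 0)` by convention).
- Counts must be integers; fractional "counts" are rejected because the
  conjugate updates assume multinomial data.
- Latent-class parameters are clipped to `(1e-6, 1 − 1e-6)` inside the
  chain to keep the binomial assignment probabilities defined when a Beta
  draw underflows to 0 or 1.
- The empirical ROC appends the always-positive `(1,1)` and never-positive
  `(0,0)` rules so trapezoidal areas are well defined.
- Logistic regression under complete separation remains proper because of
  the normal prior; the acceptance rate is reported so a poorly mixing
  chain is visible.

## Fixture notes

- The blood-glucose fixture holds the 78 printed values with the first 59
  labelled diseased; that split reproduces the non-diseased sample mean
  (107.5) and group difference (16.1) that the published regression
  reports.
- The coronary-stenosis *non-diseased* table is not fully printed in the
  study report; its cells (168, 0, 30, 38) are reconstructed by exhaustive
  search over non-negative integer tables summing to 236 that reproduce the
  published posterior means and the printed specificities (71% CT, 84%
  MRI).  The search has a unique solution and is re-run as a test oracle.
  The fixture is marked DERIVED and its provenance string says so.
- The analogous non-diseased *ordinal* joint table for the paired
  five-category lung study is not reconstructible from printed information;
  that pipeline is exercised on synthetic joints instead.

## Known limitations

- No MCMC diagnostics beyond batch-means MC error (the conjugate analyses
  are i.i.d.; the Gibbs chains here mix in a handful of iterations, but no
  R-hat or ESS is computed).
- Two tests only in the latent-class model; no relaxation of conditional
  independence.
- No covariate-adjusted ROC regression, no partial AUC, no smooth ordinal
  ROC, no multi-reader agreement, and no plotting — summaries only.
- The published verification-bias example table is internally inconsistent
  with its published posterior summary (see the corrected-sensitivity test
  tolerances); this package follows the printed counts and the stated
  estimator.
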