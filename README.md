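# bayesdta — Bayesian medical test accuracy

`bayesdta` estimates the accuracy of medical diagnostic tests by Bayesian
posterior inference, for biostatisticians and clinical researchers analysing
small count tables and subject-level score data.  It covers:

- **Basic measures of a binary test** — TPF (sensitivity), FPF
  (1 − specificity), PPV, NPV, and the diagnostic likelihood ratios
  PDLR = TPF/FPF and NDLR = FNF/TNF, from the conjugate Dirichlet posterior
  `θ | data ~ Dir(n₀₀+1, n₀₁+1, n₁₀+1, n₁₁+1)` of the test-by-disease cell
  probabilities, plus paired comparison of two modalities via per-draw
  TPF/FPF ratios.
- **ROC curves and AUC** — empirical ROC points and the posterior of
  `AUC = P(Y > X) + ½ P(Y = X)` for ordinal scores (independent Dirichlet
  posteriors per disease class), and the binormal area
  `AUC = Φ(a / √(1 + b²))` for continuous scores, fit by a conjugate Gibbs
  sampler for the two-group heteroscedastic normal regression
  `y_i ~ N(β₁ + β₂ d_i, 1/τ_{d_i})`.
- **Verification-bias correction** — when only some subjects reach the gold
  standard and verification depends only on the test result (MAR), Bayes'
  theorem converts the posteriors of `φ_i = P(D=1 | Y=i)` and
  `θ_i = P(Y=i)` into corrected result-given-disease fractions
  `α_i = φ_i θ_i / ΣφΘ`, yielding corrected TPF/FPF (binary) or a corrected
  ROC area (ordinal).
- **No gold standard** — a latent-class Gibbs sampler for two conditionally
  independent binary tests, estimating prevalence and both tests'
  sensitivity/specificity with uniform or informative Beta priors.
- **Combined tests** — believe-the-positive / believe-the-negative rules for
  paired binary tests, optimal likelihood-ratio ROC curves (Neyman–Pearson),
  and logistic-regression risk scores `logit P(D=1|Y) = γ + λ'Y` whose ROC
  area measures the combined accuracy.

All worked datasets (exercise stress testing for coronary artery disease,
mammography ratings, blood glucose for diabetes, paired CT/MRI reads,
hepatic scintigraphy and mammography verification studies, the
Strongyloides stool/serology study, coronary stenosis segments) are bundled
as plain-text fixtures with provenance strings, and a synthetic-data module
generates datasets with each model's exact structure for recovery tests.

## Worked example

```python
from bayesdta import load_fixture
from bayesdta.binary_accuracy import basic_measures

table, provenance = load_fixture("est_cad")   # 2x2 stress-test study, n=1468
result = basic_measures(table, n_draws=55_000, seed=1)
for name in ("tpf", "fpf", "ppv", "npv", "pdlr", "ndlr"):
    s = result[name]
    print(f"{name:5s} mean {s.mean:.4f}  sd {s.sd:.4f}  "
          f"95% ({s.q025:.4f}, {s.q975:.4f})")
```

prints

```
tpf   mean 0.7967  sd 0.0125  95% (0.7720, 0.8207)
fpf   mean 0.2613  sd 0.0208  95% (0.2215, 0.3035)
ppv   mean 0.8759  sd 0.0107  95% (0.8542, 0.8962)
npv   mean 0.6109  sd 0.0211  95% (0.5695, 0.6518)
pdlr  mean 3.0686  sd 0.2512  95% (2.6196, 3.6032)
ndlr  mean 0.2754  sd 0.0186  95% (0.2401, 0.3129)
```

The stress test detects about 80% of diseased subjects (TPF), but roughly a
quarter of healthy subjects also test positive (FPF); a positive result
raises the probability of disease to 0.876 (PPV), while a negative result
leaves a 39% residual disease probability (1 − NPV) in this high-prevalence
cohort.  The same interface drives the other analyses, e.g.

```sh
bayesdta roc-ordinal  --fixture mammography --seed 1
bayesdta roc-binormal --fixture diabetes    --seed 1
bayesdta latent-class --fixture strongyloides --priors priors.yaml --seed 1
```

## Layout

- `src/bayesdta/tables_io.py` — typed count-table containers, delimited IO,
  bundled fixtures
- `src/bayesdta/posterior_engine.py` — conjugate posteriors, sampling,
  summaries, the exact Beta-aggregation oracle
- `src/bayesdta/binary_accuracy.py`, `ordinal_roc.py`, `binormal_roc.py`,
  `verification_bias.py`, `latent_class.py`, `combined_tests.py` — the
  models
- `src/bayesdta/synthetic.py` — structure-faithful data generators
- `src/bayesdta/cli.py` — the `bayesdta` command
- `docs/methods.md` — modelling assumptions, defaults, and numerical choices
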