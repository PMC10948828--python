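# imputemean

Estimation of a finite-population mean under item nonresponse, for survey
statisticians and methodologists comparing imputation strategies.

In many surveys the study variable `y` is missing for part of the sample
(item nonresponse) while an auxiliary variable `x` — correlated with `y` and
with known population mean `X̄` — is observed for every sampled unit.  Under
simple random sampling without replacement (SRSWOR) and a missing-completely-
at-random (MCAR) response mechanism, a long line of imputation rules
substitutes model-based values for the missing `y` so that the completed-
sample mean improves on the plain respondent mean.  This package implements
twelve classical rules of that family (labelled `t0, tr, t1, …, t10`) plus a
Searls-type two-constant exponential estimator (`tp`)

    tp = { κ₁ ȳᵣ + κ₂ ȳᵣ x̄ᵣ/X̄ } · exp( (X̄ − x̄ᵣ) / (X̄ + x̄ᵣ) ),

whose constants (κ₁, κ₂) solve a 2×2 normal-equation system built from the
first-order moment scalars A…F, trading a small bias for lower MSE.

Three layers are provided, mirroring how such estimators are studied:

* **theory** — first-order bias and minimum MSE of every estimator, optimal
  tuning constants, percentage relative efficiency (PRE), efficiency
  conditions of `tp` against each competitor, and benchmark report tables;
* **sample engine** — the per-unit imputation rules themselves, each
  satisfying the completion identity *mean(completed sample) = closed-form
  estimator* to floating-point accuracy;
* **Monte Carlo** — a seeded engine that generates a finite bivariate-normal
  population, repeatedly draws SRSWOR samples with MCAR response, and reports
  empirical MSE/PRE next to the theoretical values.

Several of the source formulas for these estimators are mutually
inconsistent (they can yield negative "MSEs").  Both the literal
(`as_printed`) and the repaired (`table_consistent`, default) computations
are implemented and selectable; see `docs/methods.md` for the full audit.

## Worked example

```python
import imputemean as im

sample = im.SampleData(y_resp=[2.0, 4.0], x_resp=[1.0, 3.0],
                       x_nonresp=[2.0, 2.0], Xbar=2.0)
completed = im.impute("tr", sample)
print(im.beta_hat(sample))          # 1.5
print(completed.y_completed)        # [2. 4. 3. 3.]
print(completed.point_estimate)     # 3.0
```

The ratio rule fills each missing `y` with `β̂·xᵢ`, where `β̂ = Σy/Σx = 1.5`
over respondents; the mean of the completed sample, 3.0, equals the
closed-form ratio estimator `(ȳᵣ/x̄ᵣ)·x̄ₙ = (3/2)·2` — the completion
identity that every rule in the package obeys.

At the parameter level, the shipped benchmark fixtures reproduce the
reference MSE/PRE grid:

```python
pops = im.load_table1_populations()
table = im.build_table([pops[k] for k in ("POP1", "POP2", "POP3")],
                       labels=["POP1", "POP2", "POP3"])
print(im.round_table(table))
```

```
                POP1           POP2            POP3
                 mse     pre    mse     pre     mse     pre
t0         126223.30  100.00  16.44  100.00   97.40  100.00
tr         203174.22   62.13  11.77  139.66   74.60  130.57
t1          98104.25  128.66  11.76  139.78   69.22  140.71
t3         927898.32   13.60  15.15  108.53  193.13   50.43
...
tp         125960.99  100.21  16.40  100.24   93.93  103.70
```

Row `t0` is the respondent-mean variance (e.g. 97.40 for POP3); `t1` and its
first-order equivalents cut that to 69.22 (PRE 140.71, i.e. 40% more
efficient); the regression-type `t3`–`t5` can be far *less* efficient than
doing nothing.  The `tp` row is the Searls stationary value — see
`docs/methods.md` for why its published reference column is not reproducible.

The `examples/` scripts walk through each capability: `theory_report.py`,
`impute_small_sample.py`, `searls_solve.py`, `monte_carlo_study.py`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main outputs end to end: the three-population
theory grid, the Searls solve under both B-sign conventions with its
normal-equation residuals, and a seeded desk-scale Monte Carlo study
(N=1000, n=100, r=80, m=5000) including the calibration of the empirical
t0 MSE against the exact SRSWOR/MCAR variance `(1/r − 1/N)·S_y²`, then
writes the results JSON to `--out`.
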