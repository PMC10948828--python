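# Methods

## Setting and notation

A finite population of `N` identifiable units carries the study variable `y`
with mean `Ȳ` (the estimand) and an auxiliary variable `x` with known mean
`X̄`.  An SRSWOR sample `s` of size `n` is drawn; `r` units respond with
`(y, x)` pairs, the remaining `n − r` supply only `x`.  Response is MCAR:
independent of both variables.  Moment parameters are the coefficients of
variation `C_y = S_y/Ȳ`, `C_x = S_x/X̄`, the correlation `ρ`, and
`C_yx = ρ C_y C_x`; all `S`-quantities use the `N−1` divisor.  The
finite-population variance fractions are `θ_{a,b} = 1/a − 1/b` for the
nestings (r, N), (r, n), (n, N); they satisfy `θ_{r,N} = θ_{r,n} + θ_{n,N}`
exactly.

All bias/MSE expressions are first-order Taylor approximations in the
relative errors `ȳ_r = Ȳ(1+e₀)`, `x̄_r = X̄(1+e₁)` with
`E(e₀²) = θ_{r,N}C_y²`, `E(e₁²) = θ_{r,N}C_x²`, `E(e₀e₁) = θ_{r,N}C_yx`.

## Estimators

Each estimator is defined twice, consistently: as a per-unit imputation rule
`y_.i` (observed `y` kept — or, for t1/t7, linearly transformed — on the
respondent set R; a model-based value on the nonrespondent set R^c) and as
the closed form its completed-sample mean equals:

| id  | closed form | tuning constant |
|-----|-------------|-----------------|
| t0  | `ȳ_r` | — |
| tr  | `(ȳ_r/x̄_r)·x̄_n` | — |
| t1  | `ȳ_r(λ + (1−λ)x̄_n/x̄_r)` | λ |
| t2  | `ȳ_r(x̄_n/x̄_r)^β` | β (exponent) |
| t3  | `[ȳ_r + β̂(X̄−x̄_r)]·X̄/x̄_r` | — |
| t4  | `[ȳ_r + β̂(X̄−x̄_n)]·X̄/x̄_n` | — |
| t5  | `[ȳ_r + β̂(X̄−x̄_n)]·x̄_n/x̄_r` | — |
| t6  | `ȳ_r·x̄_n/(αx̄_r + (1−α)x̄_n)` | α |
| t7  | `αȳ_r + (1−α)ȳ_r·g` | α |
| t8  | `ȳ_r(δ−x̄_r)/(δ−x̄_n)` | δ |
| t9  | `ȳ_r[mx̄_r+(1−m)x̄_n]/[mx̄_n+(1−m)x̄_r]` | m |
| t10 | `[αȳ_r + (1−α)ȳ_r·x̄_r/X̄]·g` | α |
| tp  | `[κ₁ȳ_r + κ₂ȳ_r·x̄_r/X̄]·g` | κ₁, κ₂ |

with `g = exp((X̄−x̄_r)/(X̄+x̄_r))`, `β̂ = Σ_R y / Σ_R x` and `x̄_n` the mean
of all `n` auxiliary values.  `tp` reduces to `t10` exactly when
`κ₁ + κ₂ = 1`; freeing that sum is what buys the Searls shrinkage.

The **completion identity** — mean of the completed `n` values equals the
closed form — is the defining contract of `impute()` and is tested over
randomized samples at 1e-10 relative for every method with a rule.  The
t2/t6/t8/t9 rules spread the bracketed total `n·t − r·ȳ_r` over R^c
proportionally to `x_i`; t10/tp spread it equally.  t3–t5 are defined in the
literature only as point estimators; `impute()` returns an estimator-only
result flagged `no_imputation_rule` for them.

Source-text repairs required for the identity to hold (each verified
numerically): the t6 rule's denominator must be `αx̄_r + (1−α)x̄_n` (its
printed form has the weights swapped and a stray sign); the first term of
the t9 rule's numerator must carry `x̄_r`, not `x̄_n`; `x̄_n` must average
over `n` units, not `r`; and the ratio rule imputes `β̂·x_i`, not `β̂·ỹ_i`.

## Theory modes

Evaluated literally, several published minimum-MSE expressions are not
usable as MSEs — e.g. the t2/t6/t7 closed form goes to ≈ −6966 on the POP1
benchmark — and contradict the published numerical table, which those same
sources use for their efficiency claims.  Two modes are therefore exposed:

* `as_printed` — the literal expressions; any negative result carries a
  `negative_mse` flag plus a runtime warning and is never fed into a PRE.
* `table_consistent` (default) — the repaired dictionary under which the
  published benchmark cells reproduce to two decimals:
  * `MSE(tr) = Ȳ²[θ_{r,N}C_y² + θ_{r,n}(C_x² − 2C_yx)]` (θ_{r,N} on the
    `C_y²` term);
  * `MSE_min(t1) = Ȳ²C_y²[θ_{r,N} − θ_{r,n}ρ²]`, identical for t8 and t9
    by algebra, and adopted for t2, t6, t7 and t10 (their tables equal
    t1's column);
  * `t3/t4/t5 = V(t0) + ⟨term⟩` with the respective θ-weights, replacing the
    printed `MSE_min(t1) − ⟨term⟩` base that goes negative.

Every tunable estimator's pre-optimization MSE profile is also exposed
(`mse_profile`), and an independent numeric minimization over the constant
recovers the published optimal constants (`λ_opt = 1 − C_yx/C_x²`,
`β_opt = α_opt(t6) = ρC_y/C_x`, `α_opt(t7) = 1 − 2C_yx/C_x²`,
`δ_opt = X̄(C_x/(ρC_y) − 1)`, `m_opt = ½(1 − ρC_y/C_x)`,
`α_opt(t10) = ½ + ρC_y/C_x`) and their closed-form minima.  Note the
t7/t10 profiles place `θ_{r,N}` on every term, so their true minima equal
`θ_{r,N}Ȳ²C_y²(1−ρ²)`, not `MSE_min(t1)` — one more internal inconsistency
of the printed t7 closed form.

## The Searls estimator

The first-order MSE of `tp` is the quadratic
`Ȳ²[1 + κ₁²A + κ₂²B + 2κ₁κ₂C − 2κ₁D − 2κ₂F]` with

    A = 1 + θ_{r,N}(C_y² + C_x² − 2C_yx)      C = 1 + θ_{r,N}C_y²
    D = 1 − ½θ_{r,N}C_yx + ⅜θ_{r,N}C_x²       F = 1 − ½θ_{r,N}C_yx − ⅛θ_{r,N}C_x²

and `B` published as `1 + θ_{r,N}(C_y² − 2C_yx)` although the expansion it
is derived from implies `+2C_yx`.  Both are implemented behind `b_sign`
(default `printed_minus`, the literal definition).  The solved constants
`κ₁ = (BD−CF)/M`, `κ₂ = (AF−DC)/M`, `M = AB−C²`, satisfy the normal
equations to 1e-10 by construction.

Two facts matter for interpreting results:

1. **Saddle vs minimum.** With `printed_minus`, `M < 0` on all three
   benchmark populations: the coefficient matrix `[[A,C],[C,B]]` is
   indefinite and the stationary point is a saddle of that quadratic.  With
   `expansion_plus` the matrix is positive definite and the stationary point
   is the true minimum — which the perturbation-dominance property test
   exercises.  (That true minimum can itself be negative, e.g. POP2/POP3:
   the first-order quadratic is an approximation, not a variance.)
2. **Minimum-MSE formula.** The published closed form `Ȳ²[1 − L/M²]`
   algebraically equals `Ȳ²[1 − t(2−M)]` with `t = (Du+Fv)/M`, while the
   quadratic's exact stationary value is `Ȳ²[1 − t]`; they coincide only at
   `M = 1`.  The default path (`formula="stationary"`) is the exact
   stationary value, validated against direct evaluation of the quadratic at
   the optimum to 1e-9 relative; the literal form is retained for audit.

Consequently the published `tp` benchmark column (90,056.57 / 10.04 / 61.49)
is **not reproducible** from any combination of the printed definitions: the
closest recomputation (POP3, printed sign, stationary value) gives 93.93.
The package reports the computed values and makes no attempt to match those
cells; `tp`'s correctness surface is property-based (normal equations,
quadratic consistency, perturbation dominance under positive definiteness,
reduction to t10 at `κ₁+κ₂=1`).

Efficiency conditions of `tp` against each competitor are evaluated as
direct differences of MSE values in squared y units (the printed condition
displays mix `Ȳ²`-scaled and unscaled quantities; comparing actual MSEs is
the scale-consistent reading).

## Monte Carlo engine

Protocol: one finite population of `N` paired draws from the configured
bivariate normal; exact moments computed from the *realized* values (these
parameterize the plug-in constants and define the target `Ȳ`); then `m`
replicates of SRSWOR sampling and MCAR response; empirical
`MSE = (1/m)Σ(t_ij − Ȳ)²` and `PRE = 100·MSE(t0)/MSE(t_i)`.  A single
seeded numpy `Generator` drives population, sampling and response in that
order, making every sub-result reproducible from (config, seed).

Design choices:

* **Plug-in constants** are resolved once from the realized population's
  exact moments (the natural reading of a study that "computes the
  parameters for the simulated population"); per-replicate respondent-based
  estimation is an explicit opt-in (`constants_source="respondent"`) and is
  outside the closed-form theory.
* **Degenerate replicates** (vanishing denominators, e.g. `δ = x̄_n` for t8)
  are redrawn by default, with the count reported; a drop-and-count policy
  is selectable.  A cap of 1000 redraws guards against misconfigured runs.
* **Negative auxiliary values.** The shipped superpopulation has
  `C_x ≈ 2.4`, so about a third of generated `x` values are negative — the
  `x > 0` assumption of the closed-form theory is violated by the stated
  simulation world itself.  The engine therefore relaxes the positivity
  check (`require_positive_x=False`) and relies on the per-method
  denominator guards; user-constructed samples keep strict checking.
* The shipped configs are `SIM-PAPER` (N=5000, n=200, r=160, m=50000, the
  full-scale published design) and `SIM-DESK` (N=1000, n=100, r=80, m=5000),
  the desk-scale default used by tests so the suite stays fast.

Calibration: the empirical MSE of `t0` is checked against the exact
SRSWOR/MCAR variance `(1/r − 1/N)S_y²` of the realized population within 3
Monte Carlo standard errors (a ~0.997-probability event; the test retries
once at an independent seed).  The published simulation PRE table (uniform
149.81 for t1–t10, 172.68 for tp) is **not** reproduced: it is inconsistent
with the theoretical PREs its own design implies (≈ 123.6 at
θ_{r,N}=0.00605, θ_{r,n}=0.00125, ρ=0.961) and with this engine's empirical
output, which shows the first-order equivalence class splitting (t7/t10/tp
empirically far below their first-order MSEs at this design — the
exponential-shrinkage estimators' higher-order terms dominate; t3/t8
heavy-tailed).  The engine reports empirical and theoretical columns side by
side so the discrepancy is visible rather than hidden.

## What the synthetic world does and does not establish

The generator emulates a single homogeneous bivariate-normal population with
the benchmark moments and an MCAR response mechanism with fixed `r`.  Real
survey data differ in ways deliberately out of scope: skewed/heavy-tailed
variables, response mechanisms correlated with `y` or `x` (MAR/MNAR),
stratified or multi-stage designs, and random (binomial) respondent counts.
A green Monte Carlo test therefore establishes internal consistency of the
estimators and engine under the stated world, not robustness beyond it.

## Numerical conventions

Display tables round half away from zero to 2 decimals; all comparisons use
unrounded values.  Population variances use the `N−1` divisor throughout.
Benchmark-cell tests use 0.05% relative tolerance (the printed input
parameters are themselves 3–4 significant figures).  Degenerate inputs —
census designs (`θ_{r,N}=0`, singular Searls system), `ρ=0` (undefined
`δ_opt`), `δ = x̄_n` poles, zero denominators — raise typed errors rather
than returning NaN.
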