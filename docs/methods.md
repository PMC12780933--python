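# Methods

## Model

Each muscle's measurement table is modelled as a fully crossed Gaussian
random-effects design. For participant p, repetition r, occasion o and
observer ob,

y = μ + Σ_c u_c + ε,   u_c ~ N(0, σ²_c),   ε ~ N(0, σ²_res),

where c ranges over nonempty subsets of the facets (p, r, o, ob) and each u_c
is drawn once per distinct level combination of its facets. The participant
facet is the object of measurement: σ²_p is true-score variance, everything
else is error from some scenario's point of view. Gaussian effects are
assumed because the variance-component model constrains only second moments,
and Gaussianity makes REML the maximum-likelihood estimator of the same
family the generator draws from. With one record per design cell the full
four-facet interaction is aliased with the residual; it is excluded from the
default model and flagged by the identifiability check if requested.

Facet labels are unordered categories; designs are fully crossed only. Each
muscle is always fitted separately — correlations between muscles measured on
a shared image are not modelled.

## Estimation

**Balanced ANOVA (EMS).** For every facet subset S the mean square MS_S is
built from marginal means by inclusion–exclusion, and the linear system
E[MS_S] = σ²_res + Σ_{T ⊇ S} (N/n_T)·σ²_T is solved by least squares over all
strata. Negative solutions are clipped to 0 and flagged (`clipped`), matching
the REML boundary behaviour. Balanced designs only.

**REML.** On balanced data the observation covariance is diagonalised exactly
by the ANOVA strata, so the restricted log-likelihood reduces to
−½ Σ_S df_S (log λ_S + MS_S/λ_S) with λ_S the stratum expectation above. This
is maximised with L-BFGS-B under σ² ≥ 0 with analytic gradients, starting
from the clipped ANOVA solution (which is already the stationary point when
interior — hence the exact ANOVA/REML agreement on balanced data). The
asymptotic covariance of the estimates is the inverse expected information
½ Cᵀ diag(df/λ²) C. Estimates below 1e-10 are reported as exactly 0.
Unbalanced tables use a dense-matrix implementation of the standard
restricted likelihood (verified against lme4), capped at 4000 records; the
stratified path has no size limit. λ values are floored at 1e-12 so
degenerate (constant) tables converge to the all-zero boundary instead of
diverging.

**Backward simplification.** Components are removed deterministically, ties
broken lexicographically: first components on single-level facets
(structurally absent variance), then aliased components (non-protected,
highest interaction order first), then iteratively the smallest non-protected
estimate below `drop_tol` (default 1e-6 cm², i.e. only numerically-zero
boundary estimates). The optional likelihood-ratio rule (`criterion="lrt"`,
cutoff 3.84 = 5% χ²₁) additionally removes the component whose removal
changes the restricted log-likelihood least; this is the rule that reproduces
the analyst decision of excluding whole blocks of negligible interactions
(e.g. everything involving repetition), because truth-zero components land on
the boundary only about half the time — the other half they take small
positive values of order 1/√n that no fixed threshold separates cleanly from
genuinely tiny components. Protected components (participant, residual, and
the repetition main effect whenever repetitions exist) are never dropped, so
all repetition-level variance remains accounted for even when its estimate is
at the boundary.

**Model-eligibility check.** On balanced data the total error variance is
invariant to how it is partitioned across nested models, so SEM estimates
from a one-/two-/three-way model ladder must agree; `model_consistency_check`
flags relative SEM disagreements above 5% (configurable) as evidence of
mis-specification, reporting (not raising) per-rung failures.

## Reliability metrics

The intra-observer G-coefficient uses the error sum
σ²_r + σ²_o + σ²_pr + σ²_po + σ²_ro + σ²_res; the inter-observer version adds
σ²_ob, σ²_pob, σ²_rob, σ²_oob, σ²_pro, σ²_prob, σ²_poob, σ²_proob. The
formulas are applied exactly as published, including the asymmetry that the
p×r×o term enters only the inter-observer denominator. Components absent from
a simplified model contribute exactly 0. SEM is the square root of the same
error sum, SDC = 1.96·√2·SEM, %SDC = 100·SDC/mean; identities G = σ²_p/(σ²_p
+ SEM²) and SDC/SEM = 1.96√2 hold to machine precision and are enforced by
property tests. Band boundaries: poor is closed at 0.50 (the bound is stated
inclusively); moderate/good/excellent are half-open at 0.75 and 0.90.

**Confidence intervals.** The exact published CI formula is not specified
beyond "enhanced Wald"; the default here propagates the REML covariance
through the G ratio by the delta method, builds the interval on the logit
scale (variance-stabilising for a bounded ratio, skewness-correcting near the
boundary), back-transforms and clamps to [0,1]; upper limits beyond 1 are
reported as exactly 1.00. Monte-Carlo calibration on the single-observer arm
(G ≈ 0.98, 30 participants) gives 95% ± 1% empirical coverage. A parametric
bootstrap (simulate from the fitted components, refit, percentile limits) is
available as a cross-check. Whether to report the CI from the full or the
simplified model is not externally fixed; the package reports the
simplified-model CI and records the model used.

## Agreement diagnostics

Bland–Altman differences are taken against BLUP predictions from a
participant + observer crossed random-effects model (Henderson equations at
the REML variance estimates), so every repetition contributes one point
without averaging; occasion is deliberately not in the prediction model. Raw
cell means are available via `predictor="cell_means"` for sensitivity
analysis. Bias and 1.96·SD limits of agreement summarise the differences.
The funnel-shape check regresses |difference| on the prediction; because
repetitions of one participant share the unshrunk remainder of that
participant's effect, the slope's p-value uses a CR1 cluster-robust sandwich
variance (clustered by participant) with t(G−1) reference, which holds the
test at its nominal 5% size (naive OLS p-values over-reject at ~8–9%).

## Synthetic data and presets

The generator draws exactly from the model above; same seed gives an
identical table, values are never truncated at zero (truncation would bias
the components; a warning is emitted instead), and components touching
single-level facets contribute no draw because their variance is confounded
with the grand mean. Presets encode the two emulated study arms:

| preset | design (p×ob×o×r) | μ (cm) | components (cm²) |
|---|---|---|---|
| ab_gmax | 30×3×2×3 | 3.85 | p .4396, o .005, po .02, ob .01, pob .02, res .12 |
| ab_gmed | 30×3×2×3 | 2.31 | p .1378, o .003, po .015, ob .005, pob .0865, res .055 |
| ab_gmin | 30×3×2×3 | 1.19 | p .0313, o .0005, po .001, ob .0005, pob .0015, poob .0082, res .009 |
| sci_default | 30×1×1×3 | 1.83 | p .30, r 0, res .005 |

The participant-level variances (and Gmed's p×ob, Gmin's p×o×ob) are the
reported per-muscle values; the remaining components are package defaults
chosen once so that the implied SEM and G magnitudes match the corresponding
published table rows (e.g. ab_gmax implies intra G ≈ 0.75, inter SEM ≈ 0.42,
%SDC ≈ 30; sci_default implies G ≈ 0.984 with SEM ≈ 0.07). Repetition-related
variances default to zero, mirroring the finding that repetitions within an
occasion showed no systematic variance. The AB presets use 30 participants
(the gluteal analysis set after one exclusion); `n_participants` overrides.

What the generator does **not** emulate: observer bias (fixed effects),
heteroscedastic residuals, non-Gaussian tails, learning effects over the
study, or between-muscle correlation from shared images. Passing tests
therefore demonstrate correctness of the estimation machinery under the
stated model, not robustness of ultrasound measurement itself.

## Monte-Carlo problem sizes and numerical conventions

Stochastic tests use fixed seeds. Parameter recovery runs 200 replicates at
500 participants (ANOVA estimator; mean of every component with truth >
0.01 cm² within 10%); CI coverage uses 500 replicates of the single-observer
arm; the agreement type-I/power checks use 500 simulations each (50 and 100
participants), with the type-I acceptance band fixed a priori at
[0.025, 0.085] around the nominal 5%; ANOVA/REML equivalence is checked to
1e-6 cm² on 50 random balanced designs with 2–5 levels per facet, comparing
only fits whose ANOVA solution is interior (boundary cases differ by
construction). Quartiles use linear interpolation; SDs use the n−1
denominator; presentation rounding (2 dp for G/SEM/SDC/thickness, integer
%SDC) is applied only at the formatting step, never to stored values.

## Known limitations

- Unbalanced-design ANOVA (Henderson III) is not implemented; unbalanced
  tables go through REML only.
- The dense REML path holds an N×N covariance per component mask and is
  limited to 4000 records.
- The Wald CI relies on asymptotic normality of the REML estimates; for very
  small designs (few participants) the parametric bootstrap is preferable.
- Fixed observer effects (systematic bias between observers) are outside the
  random-effects formulation; the Bland–Altman bias statistic is the only
  bias-sensitive output.
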