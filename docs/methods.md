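# Methods

This note documents the statistical model behind each stage, the
defaults and why they were chosen, the synthetic data the tests run on,
and the numerical conventions.

## Direct age standardization (`ecorisk.rates`)

The standardized rate for one county-stratum is the weighted mean of
age-band crude rates, `1e5 * sum_a w_a cases_a / pop_a`, with the
weights of a fixed standard population. The built-in default is the
2000 U.S. standard million in 18 five-year bands; any `age_band,weight`
CSV can replace it. Weights are renormalized over the bands present, so
partial windows (25–49, 50–69, 70–84) are handled without a separate
weight file per window; the exact sub-band weighting inside each window
is therefore configuration, not code. Rates are invariant to uniform
rescaling of raw weights. Within-county rate variances/CIs are not
computed; the pipeline reports dispersion across counties.

Strata enter the association analysis only when the number of counties
with cumulative cases strictly above 5 strictly exceeds 60% of the
county universe (the exposure table defines that universe). Both
inequalities are strict, which for 62 counties makes the threshold 38:
the smallest integer exceeding 37.2. The filter is monotone: relaxing
either threshold never removes a retained stratum.

## Segmented trends (`ecorisk.trends`)

The trend model is `ln r(t) = a + b t + sum_j g_j (t - c_j)_+`:
continuous piecewise-linear in calendar year, the convention of
joinpoint software (disconnected per-segment regressions would allow
jumps at the breaks). Segment slopes are linear contrasts of the
coefficients; APC, AAPC and their CIs transform from the log-slope
scale by `100(e^x - 1)`, with t-based intervals (df = n − #params) and
the delta method for the length-weighted AAPC contrast. The AAPC CI
method of the reference software is not uniquely defined in the
literature we target; the delta method was chosen and is documented
here.

Break placements are searched exhaustively over observed interior
years, so for series up to ~19 years the grid search *is* the global
optimum (tested against independent enumeration). Model size
(0–2 joinpoints by default) is chosen by a sequential permutation test:
k vs k+1 with statistic `(RSS_k − RSS_{k+1})/RSS_{k+1}`, null
distribution from permuting the k-model residuals, 499 permutations,
each test at level 0.05/max_joinpoints (Bonferroni over the sequence).
BIC selection (`n ln(RSS/n) + p ln n`) is offered as a fast
alternative. `min_seg_obs = 3` observations per segment, counting both
endpoints (a break year belongs to the segments on both sides); this is
configurable.

Degenerate zero-residual fits report the documented limits rather than
failing: p = 0 for a nonzero slope, p = 1 for a zero slope, point CIs.
A series long enough only for the 0-joinpoint model returns that model
with a warning in the selection trace.

Classification: increasing/decreasing when the AAPC p-value is below
0.05 (two-sided t), else stable.

## Screening (`ecorisk.screening`)

All variables are z-scored with the sample SD (n−1), so bivariable
slopes equal Pearson correlations (asserted to 1e−10) and coefficients
are comparable across factors. Each factor is fitted twice — unadjusted
and adjusted for the forced race & SES columns — and pooled when either
two-sided p < 0.1 (0.2/0.3 as sensitivity settings; pooling is monotone
in the threshold). Missing values are handled by per-model listwise
deletion with the n used recorded per record; no imputation. No
multiple-testing adjustment is applied at this stage by design.

"Highly correlated with percent-white" is operationalized as
|r| > conflict threshold (default 0.6, the same threshold the
multivariable stage uses); the adjustment set for that factor then
drops percent-white, and the decision is logged per factor. Strictness
at the boundary (r exactly at threshold keeps race) matches the
strict-inequality convention used throughout.

Per-factor failures (constant columns, rank deficiency) are recorded in
the screening output and exclude the factor; they are not fatal.

## Best-subset selection (`ecorisk.selection`)

Candidate pairs with pairwise-complete |Pearson r| strictly above the
threshold form the edges of a conflict graph. Compatible combinations
are its **maximal** independent sets (enumerated as cliques of the
complement graph); since the subset search scores every subset of every
combination, restricting to maximal sets is lossless — every
independent set is contained in some maximal one, which the tests
verify exhaustively on random graphs. An enumeration ceiling (40 nodes)
guards against graphs whose MIS count explodes.

Within a combination, all subsets (including the empty one) are scored
by the Gaussian profile BIC, `n ln(RSS/n) + k ln n`, with additive
constants dropped (they cancel in within-pool comparisons; BICs are
comparable only within one outcome/forced-set pool). `k` counts the
intercept, the forced covariates and the selected variables — forced
coefficients are estimated parameters. RSS is floored at 1e−300 so an
exact fit yields a finite BIC. Ties break toward fewer variables, then
lexicographic names. Weak hierarchy: the squared latitude term is
admitted only alongside latitude. Rank-deficient subsets are skipped.

Pooling/pruning: drop adjusted R^2 < 0.3; deduplicate identical
subsets; collapse nested groups — connected components of the
proper-subset relation, keeping each component's lowest-BIC member
("group of nested models" is not formally defined in the tradition this
follows, so the connected-component reading is used and oracle-tested);
rank by BIC; flag survivors within strictly less than 2 BIC units of
the best as comparable. An empty pool after filtering is an explicit
"no model explains ≥ 30% of variation" result, not an error.

Sensitivity modes: screening P ∈ {0.1, 0.2, 0.3}; conflict r ∈
{0.6, 0.5}; and race-as-candidate, where percent-white leaves the
forced set and competes in the pool (then subject to conflict edges
like any candidate).

OLS estimation and t-based inference are computed in closed form
(`ecorisk._ols`) because the Monte-Carlo suites run tens of thousands
of 62-row fits; equivalence with statsmodels OLS (params, SEs,
p-values, CIs) is asserted in the tests to 1e−9.

## Synthetic data (`ecorisk.datagen`)

The generator emulates the structure the analysis assumes, with known
ground truth:

* **Exposures**: jointly Gaussian blocks with equicorrelation within
  blocks (PSD checked; a block of size m needs rho ≥ −1/(m−1)).
  Real exposures are mixed-scale, but everything is z-scored before
  modelling, so the correlation structure is the only feature
  downstream stages see.
* **Outcomes**: `y = sum beta_i x_i + eps`, homoscedastic Gaussian
  noise (the linear-model assumption of the analysis); the realized
  population R^2, `Var(signal)/(Var(signal)+sigma^2)` with signal
  variance from the sample covariance, is reported alongside, and
  `noise_sd_for_r2` inverts the formula. An optional heteroscedastic
  extension was considered and deliberately not made the default,
  since the fitted models assume homoscedasticity.
* **Counts**: Poisson with mean `rate x population / 1e5` per age band.
* **Trend series**: piecewise log-linear with slope `ln(1 + APC/100)`
  per segment, continuous at 0–2 break years, Gaussian noise on the
  log scale.

One global seed expands into fixed per-generator sub-streams (numpy
`SeedSequence` spawn keys), so adding a generator never perturbs
existing draws and all outputs are bit-reproducible per seed.

What the generator does **not** emulate: the marginal distributions of
real exposure variables, spatial autocorrelation between counties, and
population-size-dependent noise in county rates. Passing tests
therefore demonstrate correctness of the machinery and recoverability
under the stated conditions, not performance on real surveillance data.

### Default study conditions

The benchmark conditions used by the tests and the acceptance script:
62 counties; 20 candidate exposures including one correlated pair at
rho = 0.8 (above the 0.6 conflict threshold); two planted factors at
standardized beta = 0.5 with noise calibrated to population R^2 = 0.5;
three forced covariates with rho = 0.3 among themselves and no true
effect; trend series of 19 years with log-scale noise SD 0.02. These
mirror the scale of the county-level setting the package targets
(~62 counties, ~31 exposures, 2000–2018 annual series); simulation
replicate counts (100 study replicates, 200 trend replicates) keep the
whole suite in the minutes range while leaving comfortable
Monte-Carlo margins around the asserted rates.

## Determinism and report stability

All randomness flows from explicit seeds; permutation tests draw from a
dedicated sub-stream. Report files are written with fixed float
formats, sorted orderings and no timestamps, so a rerun with identical
inputs and seed is byte-identical (the output directory itself is not
part of the manifest for the same reason).

## Known limitations

* Post-selection inference: coefficients and CIs of the selected model
  are not corrected for the search; they mirror the presentation
  conventions of the analysis tradition this implements and should be
  read descriptively.
* Ecological associations only; nothing here supports individual-level
  or causal interpretation.
* No spatial error structure, regularized selection (deliberately
  excluded), or joinpoint models beyond 2 breaks (ceiling is
  configurable but untested beyond 2).
* BIC values are comparable only within a pool sharing outcome, n and
  forced set; cross-pool or cross-implementation comparisons differ by
  constants.
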