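# Methods

This note documents the statistical procedures implemented in
`trialmark`, the assumptions behind them, the defaults and why, what
the synthetic-trial generator does and does not emulate, and the
numerical and design choices made where more than one defensible
option existed.

## Data model

One two-arm randomised trial: a clinical table (treatment indicator
T ∈ {0,1} with t = 1 the experimental arm by convention; overall and
progression-free survival as months plus 0/1 event flags; a binary
response; covariates; one categorical label per subtype scheme) joined
on patient id with a strictly binary patients × features alteration
matrix.  Missing alteration values are rejected by default
(`missing_as: zero` imputes wild type); patients missing a subtype
label stay in the unstratified analyses but drop out of that scheme's
strata; patients missing the response drop out of response models
only.  Categorical covariates are expanded to reference-coded
indicators with the most frequent level as reference.

## Stage 1 — molecular landscape

Enrichment and depletion of each feature in each subtype level are
upper- and lower-tail hypergeometric probabilities
(`scipy.stats.hypergeom`), computed only for features altered in at
least `n_min` labelled patients.  Benjamini–Hochberg correction is
applied within one family per (scheme, direction); the two directions
are logically distinct hypotheses and pooling them would make each
feature compete with its own mirror image.  Records with q < FDR_mol
(default 0.05) are flagged.

Mutual exclusivity is found by a greedy, network-free search.  A
member's exclusivity p is the one-sided Fisher exact probability of
seeing at most the observed co-occurrence between that member and the
union of the other members; the module score is the worst member p.
Each eligible feature seeds a module that grows by the candidate
minimising the score while the score stays below `mutex_alpha`
(default 0.05); ties prefer larger union coverage, then lexicographic
name, making output deterministic.  Duplicate member sets are merged.
Published exclusivity tools lean on curated signalling networks to
focus the search; this implementation deliberately does not — any
externally derived grouping can be injected as a custom module in the
config, and custom unions (e.g. RAS = {KRAS, NRAS}) are first-class.
Note the statistical honesty of the Fisher test cuts both ways: two
rare features with disjoint support are *not* a module unless their
expected overlap is large enough for zero overlap to be surprising.

Module and custom unions become additional binary columns (1 iff any
member altered) appended to the feature matrix; original columns are
kept.

## Stages 2–4 — screening, interaction, subgroup selection

All models are expressed by their linear predictor:

* arm-specific screen (per endpoint, arm, stratum):
  f(x) = α₀ⱼ + α₁ⱼ xⱼ + Σₗ Cₗ
* interaction model (per endpoint, stratum, both arms):
  f(x,t) = β₀ⱼ + β₁ⱼ xⱼ + β₂ⱼ xⱼ t + Σₗ Cₗ
* subgroup CATE (within the mutant or wild-type population):
  f(t) = γ₀ + γ₁ t + Σₗ Cₗ

Survival endpoints use the Cox partial likelihood with the Efron tie
correction; the intercept is absorbed by the baseline hazard, so α₀/β₀/γ₀
exist only in the logistic (response) models.  The interaction model
is used exactly as written above — without a treatment main effect.
That asymmetry is intentional and kept (the staged design expects the
arm-specific screen to carry main effects); `include_treatment_main:
true` adds β_t·t for sensitivity analyses.  All p-values are two-sided
Wald tests; 95% CIs are exp(coef ± 1.96·SE).

Eligibility: a (feature, stratum, arm) combination needs at least
`n_min` mutants and `n_min` wild-types (for interaction tests, in each
arm separately); a module union is tested only where it redistributes
at least `n_min` patients over every single member, evaluated on the
stratum (both arms, endpoint-observed patients).  Degenerate outcomes
(no events; a single response class) and non-converged fits (monotone
likelihood / separation, detected as coefficient runaway beyond e¹⁵)
are excluded before BH correction and recorded in the audit table, so
family sizes shrink accordingly and every enumerated combination is
accounted for.

BH families: (endpoint, arm, scheme) for the screen at FDR_α (default
0.1), (endpoint, scheme) for interactions at FDR_β (default 0.2).  The
unstratified analyses form their own families (scheme "none") rather
than joining each scheme's family; the alternative (one family per
scheme including the unstratified tests) would count the cohort-wide
test q+1 times.  A biomarker is putatively predictive when q(β₂) <
FDR_β *and* the screen flagged the same (endpoint, feature, level) in
at least one arm.

For each predictive biomarker, γ₁ is estimated in both the mutant and
wild-type population of the stratum and the population with larger
|γ₁| is selected; exact ties go to the mutant population (fixed,
documented, arbitrary).  If one population is degenerate the other is
selected with a warning.  The non-selected population's γ₁ is retained
as companion metadata.

## Stage 5 — resampling

**Permutation adjustment.**  Treatment labels are permuted uniformly
across the whole cohort (preserving marginal arm sizes; alterations,
subtypes and outcomes untouched, so all treatment-independent
quantities are computed once).  For each of U permutations the entire
treatment-dependent search — screen, interaction, selection, with
identical thresholds — runs on the null data; p⁽ᵘ⁾ is the smallest
subgroup p-value found, or 1 when the null search selects nothing
(conservative and keeps the estimator defined).  The adjusted p of a
found subgroup is (1/U)·Σ 1{p⁽ᵘ⁾ ≤ p_γ}; `add_one_permutation: true`
reports (1+Σ)/(1+U) instead, which never returns exactly zero.
Default U = 1000.

**Bootstrap bias correction.**  B patient-level resamples with
replacement (default B = 500).  For each originally found (feature,
level) the mutant-vs-wild-type selection is replayed on the resample,
giving A⁽ᵇ⁾; the per-replicate corrected value is
γ₁(A) + γ₁(A⁽ᵇ⁾) − γ₁⁽ᵇ⁾(A⁽ᵇ⁾), where γ₁(·) is fitted on the original
data and γ₁⁽ᵇ⁾(·) on the resample.  The corrected estimate is the mean
and the interval the 2.5/97.5 percentiles of these per-replicate
values (the alternative — recentring an interval on the corrected
estimate — is noted but not used).  All arithmetic stays on the log
scale; effects are exponentiated only at reporting.  Replicates with a
degenerate candidate population are skipped with the denominator
reduced; a subgroup with more than 20% skipped replicates is flagged
unstable.

In the `force_best` calibration mode (used by the type-I-error,
winner's-curse and null-uniformity studies, where a best subgroup must
always exist) the significance gates are bypassed and the selection
operator is "the best subgroup across all eligible candidates".  Its
bootstrap replays that entire selection on each resample, and the
optimism term is computed on the selection-aligned |effect| scale
before being mapped back to the original subgroup's direction: the
selection is two-sided, so resamples whose winners happen to have
opposite signs would otherwise cancel each other's optimism and leave
the curse uncorrected (measured on null trials: signed replay removes
~24% of the selected |effect|, aligned replay ~69%, per-pair replay
~4%).  The thresholded pipeline search keeps the per-pair replay and
the signed formula.

Randomness: one master seed; the permutation and bootstrap streams are
spawned as independent child sequences, so p_adj and the corrected
estimates are reproducible bit for bit.

## Reporting

Ratios are reported under the reciprocal convention by default: any
HR/OR above 1 is flipped to its reciprocal and tagged with the
direction it favours (`benefit-in-experimental-arm` /
`benefit-in-control-arm`; for prognostic effects, index vs reference
group), so a reported ratio is always ≤ 1 and "smaller is the flagged
direction's benefit".  Stored coefficients are always raw.
Kaplan–Meier coordinates per reported subgroup and arm are exported
with lifelines' product-limit estimator and its (exponential)
Greenwood 95% bands.  All outputs are TSV plus one JSON summary; a
MANIFEST lists completed stages so partial runs are inspectable.

## Cross-validation stability

`stability_cv` runs repeats × folds arm-stratified training splits
(default 5 × 5), executes screening + interaction on each training set
with the interaction threshold relaxed to `cv_fdr_beta` (default 0.3,
compensating the smaller training sample), and tallies how often each
(feature, scheme, level, endpoint) ranks in the top k (default 10) by
interaction p-value.  Resampling correction is skipped inside CV: the
tally measures identification stability, not effect sizes.  The
ranking statistic is the interaction p-value; counts are bounded by
repeats × folds.

## Synthetic trials

The generator draws, per patient: subtype labels (independent
categoricals per scheme); binary features with configurable marginal
frequencies, optionally enriched in chosen levels via odds
multipliers, and with *hard* mutual exclusivity inside declared groups
(one categorical draw per group, so co-occurrence is exactly zero;
infeasible frequency sums are rejected); a Bernoulli treatment arm;
exponential event times with log-hazard = log(baseline) + prognostic
terms + t·(arm effect + subgroup-specific predictive terms),
independently exponentially censored (observed time = min, event flag
accordingly) for OS and PFS separately; and a logistic binary
response.  Constant hazards make proportional hazards exact, so every
planted log-HR is literally the estimand of the corresponding model —
which is the property the generative-truth tests rely on.  A Weibull
shape or soft exclusivity would be straightforward extensions but are
not defaults.

What the generator does *not* emulate: correlated co-mutation
structure beyond exclusivity groups, non-proportional hazards,
informative censoring, covariate–feature dependence, and measurement
error in the alteration calls.  Tests passing on this generator
therefore demonstrate correctness of the machinery and calibration
under the model's own assumptions, not robustness to their violation.

The packaged `mcrc_trial_design` (n = 400, 1:1 arms, 30 features with
frequencies geometrically spaced 0.50→0.03, one 3-member exclusivity
group, a 65/35 sidedness scheme and a 4-level molecular-subtype
scheme, two feature–subtype enrichments, two prognostic effects, one
predictive effect of HR 0.5 for mutants of G01 in left-sided tumours,
OS baseline hazard 0.028/month ≈ 25-month median with censoring
0.008/month ≈ 22% censored, PFS baseline 0.069/month, and two mildly
prognostic covariates) is the default cohort for examples and tests.

## Problem sizes in the test and acceptance runs

Simulation studies are scaled to keep a full run fast while leaving
the statistical bands intact; sizes were fixed from fitter throughput
measurements, once:

* family-wise type-I error: 60 null trials (n = 300, 12 features, two
  2-level schemes), U = 100; the bound is 0.05 + 3 binomial SD at the
  number of trials run.
* planted recovery: 50 replicates of the n = 600 design above.
* winner's curse: 60–80 null trials, B = 100.
* permutation-null uniformity: 60–80 outer replicates, U = 80–100,
  KS test against uniform at p > 0.01.
* CI coverage: 500 fits at n = 300; coefficient recovery at n = 5000.

## Known limitations

* Power of the full gated search at the planted-effect sizes used in
  the recovery study is ≈ 0.68 with ~22% censoring (≈ 0.94 with a
  fully observed endpoint): with realistic censoring, an HR-0.4
  interaction in a 12%-of-cohort subgroup at n = 600 is near the edge
  of detectability at the default thresholds.  The corresponding test
  asserts the stricter 0.80 recovery bound and is expected to fail
  until the design or thresholds change; it is kept as an honest
  statement of that gap.
* The permutation adjustment re-runs the full search per permutation;
  at U = 1000 on a 400-patient, 40-feature, 7-stratum trial this is
  minutes of compute, not seconds.
* No proportional-hazards diagnostics, penalised fits, time-varying
  effects, or multi-feature subgroup rules (single feature × single
  level only).
* Non-converged fits are dropped from BH families rather than
  replaced by penalised estimates; with very sparse strata this can
  shrink families noticeably (the audit table shows where).
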