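# Methods

## Scope and model

senosurv evaluates a gene signature as a prognostic marker in a
right-censored time-to-event cohort. The statistical chain is:

1. per-gene univariate Cox proportional-hazards regression of the
   endpoint on the gene's standardized log2 expression;
2. signed weights from the hazard ratios (risk genes negative, protective
   genes positive), combined into a per-sample weighted-average score;
3. dichotomization of the score at the minimum-log-rank-p cutoff inside
   the interquartile range, with Kaplan–Meier curves and a Cox
   high-vs-low hazard ratio for the selected split;
4. Benjamini–Hochberg FDR control across the family of
   signature × endpoint × stratum tests;
5. two-variable Cox models (signature term + one covariate at a time) to
   probe independence from clinical factors.

Underlying assumptions: proportional hazards for every Cox fit,
non-informative right-censoring, and expression measured on a positive
linear intensity scale comparable across samples after mean scaling.
No proportional-hazards diagnostics, competing risks or time-varying
effects are modelled.

## Harmonization

Arrays are multiplied by `target / mean(sample)` so every sample's mean
intensity over the current feature set equals the target (default 1000,
the conventional secondary-scaling level for MAS5-type intensities).
Scaling is idempotent and order-preserving and only makes sense on the
linear scale, so all log transforms are deferred to scoring.

Duplicate samples are detected by exact equality of the full expression
vector after rounding to 4 decimals — the rounding makes the rule robust
to float round-off introduced by scaling, while anything short of a true
technical replicate will differ in many probes.

The QC rule keeps a sample iff every metric lies within the central 95%
interval of that metric across the cohort. The interval is implemented as
the 2.5th–97.5th percentile span (robust to the heavy-tailed metrics the
rule is meant to catch); a parametric mean ± 1.96·SD alternative is
available via `method="normal"`. Intervals are computed once on the
pooled cohort and applied once — no iteration, no per-batch intervals
(per-batch filtering would re-introduce exactly the batch dependence the
harmonization removes). Note a consequence the user should expect: with
five continuous metrics, roughly 20% of a clean cohort falls outside at
least one 95% interval, so the filter is deliberately optional in the
pipeline — it runs only when a QC table is supplied.

Probe→gene collapse keeps, per gene, the probe with the largest IQR
across samples (ties: lexicographically smallest probe id). This is a
deterministic, annotation-free stand-in for annotation-database probe
pickers; users with curated probe choices can express them directly in
the supplied probe→gene map.

## Scoring

Weights default to w_g = −ln HR_g. The sign convention (HR > 1 ⇒ w < 0)
makes a high score protective by construction. The log-HR magnitude is
the natural effect-size weighting consistent with deriving weights "from
the hazard ratios"; a `sign_only` mode (w ∈ {−1, 0, +1}) is retained for
sensitivity analysis. Zero-variance genes keep weight 0 (flagged) rather
than being dropped, so weight vectors always align with the matched gene
list.

The score is S_i = Σ w_g e_ig / Σ|w_g|. In the default `zscore` mode,
e_ig is the per-gene z-score of log2 intensity, computed without a
pseudocount so the score is *exactly* invariant to positive rescaling of
the raw matrix; matrices containing zeros need an explicit pseudocount,
which trades away that exact invariance. A `raw` mode (weighted mean of
intensities) reproduces the literal weighted average of normalized
signals.

Weights are derived and applied on the same cohort by default (the
single-database convention). This in-sample derivation biases downstream
p-values optimistically; it is documented here rather than silently
"fixed" because the package's purpose includes reproducing that
platform behaviour. The two-variable models and the permutation-adjusted
scan p are the provided counterweights.

## Survival estimators

Kaplan–Meier, the 1-df log-rank test and Cox regression are implemented
in `survival.py` with vectorized internals, because the cutoff scan needs
the log-rank statistic for hundreds of candidate dichotomies (and
thousands more under permutation) per test. The Cox partial likelihood
uses Efron tie handling by default — dichotomized follow-up months
produce heavy ties, where Efron is markedly more accurate; Breslow is
available via `ties="breslow"`. Newton–Raphson iterates with step-halving
until the gradient norm is below 1e-8 (max 100 iterations); Wald 95%
intervals use the fixed quantile 1.959964. A constant covariate raises an
error naming it; monotone likelihood (perfect separation) is detected at
|β| > 12 and returns a *flagged* result rather than failing or reporting
silently absurd estimates. The test-suite cross-checks all three
estimators against an independent implementation (lifelines) and against
hand-computed and grid-search oracles.

## Cutoff scan and multiplicity

Candidates are all distinct score values within the [25th, 75th]
percentile of the score with at least `min_group` (default 5) samples on
each side; "high" means score strictly greater than the cutoff; the
selected cutoff minimizes the log-rank p, ties breaking to the smallest
cutoff for determinism. The reported p for the selected split is that
unadjusted minimum — the convention of cutoff-optimizing platforms —
and the result object carries the candidate count, the full p-vs-cutoff
profile, a multiplicity note, and (optionally) a permutation-based
selection-adjusted p (score permuted against fixed outcomes, min-p
recomputed; `(1 + #{perm ≤ obs}) / (B + 1)`). Under a null score the
minimum-p rejects far above the nominal 5% (about 25% in the acceptance
study at n=100); the permutation p restores approximately nominal
calibration. BH correction across signatures/strata/endpoints is applied
to the selected p-values at FDR 10% by default.

## Synthetic cohorts

`generate_cohort` emulates the statistical structure the analysis
assumes, with ground truth recorded for recovery tests:

- per-gene log2 intensities ~ Normal(μ_g, 1) with μ_g ~ U(6, 10),
  exponentiated to a positive MAS5-like intensity scale;
- sample hazard h_i = λ0 · exp(Σ_g β_g z_ig + Σ_c γ_c), driven by the
  *latent* z-scores, so batch shifts are pure nuisance and harmonization's
  job is isolated in tests;
- event times exponential with rate h_i; censoring = min(exponential,
  administrative horizon) — the simplest mechanism satisfying the
  non-informative censoring assumed by KM/Cox;
- per-batch multiplicative intensity factors exp(N(0, σ_batch));
- categorical covariates drawn from configurable frequencies (defaults
  mirror a large mixed NSCLC cohort: ~48% adenocarcinoma, ~37% squamous,
  male predominance, ~10% never-smokers with substantial missingness);
- injected exact-duplicate columns and QC-outlier samples appended last
  and flagged in the truth object.

Reference study conditions (the generator defaults): 800 samples, 4
batches (σ_batch = 0.3 on the natural-log scale), 500 genes with a
40-gene signature at |β| = 0.5 per latent SD, baseline hazard 0.02
events/month, exponential censoring 0.005/month with a 240-month horizon
(≈30% censoring). Recovery studies use n=600 (group effect ln HR = −1,
100 seeds) and n=800 (weight signs, 50 seeds); the null-calibration and
selection-inflation studies use n=60–100 per replicate with 500–1000
replicates — sizes chosen so each study's Monte-Carlo error is small
relative to the property being asserted.

What passing tests do **not** show about real data: the generator draws
independent genes (no co-expression modules), exact proportional hazards,
exponential baselines, and batch effects that are pure global intensity
shifts. Real cohorts violate all four; results on real data depend on
those violations being mild, and the package makes no claim about them.

Randomness uses separate named substreams (expression, survival, batch,
covariates, injection) spawned from one seed, so perturbing one component
leaves the others byte-reproducible.

## Numerical and design choices

- Score > cutoff defines "high"; stated once, used everywhere.
- Quantile computations use linear-interpolation percentiles throughout.
- Percentages in cohort summaries round half-up to one decimal, making
  count-derived percentages exactly reproducible; the full-cohort
  denominator is the default, with an annotated-only switch.
- Strata with fewer than 30 samples are analysed but flagged
  `underpowered`, matching the common ≥30-sample inclusion floor for
  cohort integration.
- The event-convention antisymmetry of the scoring chain is exact at the
  weight level (inverting every HR negates every weight and score); it is
  *not* an exact property of refitting Cox models with a flipped event
  indicator under censoring, and is tested in its exact form.
- The `run_analysis` bundle is byte-deterministic given config + seed:
  fixed float formats, sorted JSON keys, and timestamp-free logs.

## Known limitations

- In-sample weight derivation (see above); a held-out or k-fold scheme is
  a straightforward extension but is not the default behaviour evaluated
  here.
- The max-IQR probe picker is a heuristic; with curated annotation the
  supplied map should carry the curated choice.
- Wald intervals can be poor near monotone likelihood; flagged fits
  should not be interpreted beyond direction.
- The permutation-adjusted p treats the candidate set as fixed by the
  score multiset, which is correct for the implemented scan but not for
  scans whose candidate grid depends on outcomes.
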