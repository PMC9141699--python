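# Methods

`gsprog` screens gene sets for prognostic value in right-censored survival
cohorts and, optionally, corroborates hits with differential-coexpression
evidence from paired tumor/normal panels. This note records the statistical
model, the numerical choices, and what the synthetic benchmarks do and do not
establish.

## Gene-level screen

Each gene is tested with a univariate Cox proportional-hazards model on its
standardized log expression, `z-score of log2(FPKM + 1)` per gene row.
The statistic is the signed score test: `z = U(0) / sqrt(I(0))`, the partial
likelihood score and information at `beta = 0`, with the **Efron** correction
for tied event times (the stronger of the two standard tie approximations, and
the one used throughout). The two-sided p-value comes from `chi2(1)` on `z^2`;
the hazard ratio is `exp(beta_hat)` from a Newton–Raphson fit of the same
partial likelihood (coefficient capped at ±20 to keep the ratio finite under
monotone separation). No multiple-testing correction is applied at this stage:
the p-values are used as a ranking, and the downstream permutation test is the
confirmatory filter.

Standardization uses the population standard deviation (divisor *n*); the
convention is fixed by a regression test because every downstream weight and
score depends on it. Constant expression rows standardize to zero, are flagged,
and are excluded from model fitting.

## Enrichment screen

Genes are ranked by `-log10(p)` descending (capped at 320 so p-value underflow
stays finite), putting survival-significant genes at the top. A gene set is
scored with the classic weighted Kolmogorov–Smirnov running sum (hit increments
proportional to `|metric|^w`, `w = 1` by default; miss decrements `1/(N - k)`),
but only the **positive** maximum is reported: only the significant end of the
ranking is of interest, so the scan is one-tailed. The null distribution draws
random same-size gene sets from the ranked universe (gene-tag permutation) —
the ranking is a single fixed vector, so phenotype permutation is unavailable
at this stage. The screen's p-value uses the plus-one convention
`(hits + 1)/(n_perm + 1)`; a zero here would only break log-scale reporting,
and this stage makes no final claims. Default set-size window: 3–500 genes
after intersection with the measured universe.

## Composite gene expression score (CGES)

For a k-gene set the per-patient surrogate expression value is

    CGES = 1 / (1 + exp(-(sum_i beta_i * x_i - m)))

with `x_i` the standardized log expression, `beta_i` the gene's signed Cox
score z from the screen, and `m` the median of the linear combination across
the training patients. The logistic transform maps the supervised linear risk
score into (0, 1), centered at 0.5 for the median patient; it is strictly
monotone in the linear term and invariant to constant shifts absorbed by `m`.

Because the weights are supervised, raw scores overfit. Patients are therefore
scored by **leave-one-out cross-validation**: weights and `m` are refit on the
other n−1 patients before scoring each patient. Folds with fewer than two
events impute 0.5 (logged). Patients are split at the median CGES — the only
symmetric, parameter-free dichotomization, and the one consistent with the
median-centering role of `m` — and the two groups are compared with the
two-group log-rank statistic in `(O-E)^2 / V` form.

Significance comes from an outcome-permutation null with `n_perm = 1000` by
default: (time, event) pairs are permuted jointly across patients, the weights
are **refit on each permuted outcome**, all patients are scored, the median
split and log-rank statistic are recomputed. Refitting under the null is what
preserves the supervision effect (validity); the LOOCV is not nested inside
permutations by default because that multiplies cost ~n-fold while the
observed statistic remains the stricter cross-validated one — the default
test is therefore mildly conservative (measured type-I rate ≈ 0.025 at
nominal 0.05 on null 5-gene sets, n = 80; see the acceptance script). A
`strict_null` flag enables the fully nested variant.

The permutation p-value is the plain exceedance fraction
`#(chi2_perm >= chi2_obs) / n_perm` — **zero is attainable by design**. Sets
tied at `p = 0` are ranked by the z-score of the observed statistic against
the permutation null, `(chi2_obs - mean) / sd`; ordering is p ascending, then
z descending, then set name. The reported hazard ratio is a univariate Cox fit
of survival on the high-vs-low group indicator.

All permutation machinery is vectorized: at `beta = 0` the score and
information reduce to risk-set suffix sums, so weights for a thousand permuted
outcomes are computed in a handful of array passes (memory-bounded chunks for
large sets).

## Differential-coexpression corroboration

**Rewiring statistic.** Per dataset and gene set, each condition's absolute
Pearson correlation matrix (unit diagonal zeroed) yields a non-negative,
L1-normalized dominant-eigenvector gene weight vector; the statistic is the L1
distance between the tumor and normal weight vectors. Significance by
permuting condition labels over the pooled samples (100 permutations, plus-one
convention). The statistic responds to *heterogeneous* rewiring — genes whose
connectivity changes relative to the rest of the set (e.g. a hub decoupling,
where measured power is ~96% at 30+30 samples) — and is largely blind to
*uniform* correlation changes that leave the weight pattern uniform in both
conditions: an exchangeable 0.7 → 0.0 collapse moves per-dataset p-values only
slightly below uniform. This is a known limitation, inherent to
eigenvector-weight statistics, and it bounds what the panel-recovery benchmark
below can show.

**Meta pooling.** Per-dataset permutation exceedance counts are treated as
binomial proportions, continuity-corrected by 0.5, pooled on the logit scale
with a random-effects model whose between-dataset variance is estimated by
REML (bounded scalar optimization; the tau² = 0 limit reproduces the
closed-form inverse-variance combination exactly, which is tested).
Uncertainty is nonparametric: datasets are resampled with replacement
(100 bootstrap replicates) for a percentile confidence interval. `boot_p` is a
one-sided bootstrap test of collective differential coexpression: the fraction
of bootstrap pooled proportions at or above 0.5, the chance level of a
permutation exceedance proportion (plus-one convention). A set whose rewiring
statistic consistently beats its permutation null across the panel drives
`boot_p` toward its floor; the significance claim is `boot_p < 0.05`. What the
underlying reference workflow's generalized linear mixed model computes
exactly is not recoverable from its published description; the binomial-logit
reading here is this package's documented interpretation. Pooling is intended
for sets prognostic in several datasets (`min_cancers`, default 5).

**Link classification.** For every canonical gene pair, Pearson correlations
in each condition give `M = max(|r_n|, |r_t|)` and `L = log(|r_t| / |r_n|)`
with a 1e-3 floor on both magnitudes. The boundary curve is the rolling
`1 - q_outlier` empirical quantile of `|L|` over `M` bins of width 0.1
(defaults `q_outlier = 0.01`); bins with fewer than 10 pairs widen
symmetrically until populated, since a near-empty bin cannot support a
quantile. Pairs above the boundary are differentially coexpressed:
strengthened when `|r_t| > |r_n|`, else weakened. Links touching a constant
gene are skipped. On identical conditions every `L` is 0 and nothing is
flagged.

## Crosstalk networks

Two constructions, never mixed in one network:

* **Cross-link enrichment** (from merged links of a single class): for each
  set pair, the observed count of links crossing between the sets' *exclusive*
  members is tested against a hypergeometric null — drawing the observed
  number of links from all possible unordered pairs over the union gene
  universe. Genes shared by both sets are excluded from the cross-count, so
  set redundancy cannot masquerade as crosstalk. Edges kept at p < alpha
  (nominal by default; a Benjamini–Hochberg option exists on the CLI surface
  via alpha pre-adjustment).
* **Profile similarity**: Pearson correlation of `-log10 p`
  differential-coexpression profiles across the dataset panel, one-tailed
  (positive similarity) significance by permuting dataset labels (1000
  shuffles). Constant profiles are skipped.

Exports: edge-list TSV (full float precision) and GraphML, edge width
`-log10(p)` capped at 320.

## Synthetic data

`simulate_cohort` draws background genes as i.i.d. standard normals and each
planted set as noisy readouts of a latent factor with **loading 0.8**
(within-set gene–gene correlation 0.64 — a realistic coherent functional
module; the value is a fixed generator constant, not a tuning knob). Survival
is exponential with log-hazard `effect × latent factor`, so proportional
hazards hold exactly and Cox-based recovery is a fair test; censoring is
independent uniform with the horizon calibrated by bisection to the target
censored fraction (default 0.3). Expression is emitted on a raw FPKM-like
scale `2^(z+5) - 1` so the standardization transform is exercised end to end.

`simulate_paired_panel` draws tumor/normal dataset pairs with an exchangeable
within-set correlation that changes from `rho_normal` to `rho_tumor` in the
planted set and stays at `rho_normal` in a matched null set; background genes
are independent. Matrices are emitted row-standardized (Pearson correlation is
invariant to that, so planted correlations are preserved exactly).
Positive-definiteness of the exchangeable target is checked before sampling.

Both generators are pure functions of their spec, seed included.

**What the benchmarks show.** The synthetic cohorts satisfy the Cox model
exactly, have independent censoring, no batch structure, and Gaussian
marginals; passing the calibration and power benchmarks therefore establishes
the *statistical machinery* (validity of the permutation null, recovery of a
genuinely coherent prognostic module), not robustness to real-data pathologies
(non-proportional hazards, informative censoring, expression outliers,
correlated background). The paired-panel benchmark, because of the uniform-
rewiring limitation above, demonstrates calibration of the rewiring test and
its meta pooling but only weak recovery of exchangeable decorrelation; hub-
style rewiring is where the statistic earns its keep, and that regime is
tested directly.

## Problem sizes in the shipped benchmarks

Type-I calibration: 200 null 5-gene sets, 80 patients, 1000 permutations.
Power: 50 replicate cohorts, 150 patients, planted 5-gene set with log-hazard
0.7 per factor SD, 30% censoring, matched 5-gene background set as the
specificity control. Rewiring: 10 panels of 5 datasets, 30+30 samples.
Exhaustive oracles: all event/censor patterns up to n = 10 for the Cox score;
all set placements for universes up to N = 8 for enrichment; universes up to
15 genes for cross-link enrichment. These sizes were chosen so the full
benchmark battery completes in a few minutes on one core while keeping every
rate estimate's Monte-Carlo error well below the decision margins.
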