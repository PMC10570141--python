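# Methods

This note records the statistical models, the defaults and why they are
set where they are, what the synthetic data do and do not emulate, and the
design choices made where more than one reasonable construction existed.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Count model and differential expression

Counts are modelled as NB2: for gene *g*, sample *s* with size factor
*s_s* (column total / 10⁶, i.e. CPM scaling) and group mean *q_gk*,

    y_gs ~ NB(mu = q_gk * s_s,  Var = mu + alpha_g * mu^2).

Equality of group means is tested by likelihood ratio with dispersion held
fixed; the group-mean MLE under fixed dispersion solves the score equation
exactly via the fixed point `q = Σ y/(1+αμ) / Σ s/(1+αμ)`.

**Dispersion.** Pooled within-group variances of normalized counts behave,
at adequate counts, like `(mu + alpha*mu^2) * chi2_df / df`. The estimator:

1. fit a mean–variance trend as binned medians of log variance over
   20 equal-size bins of log mean, linearly interpolated, and **debias**
   the median by `median(chi2_df)/df` (a raw median of chi-square-scattered
   variances underestimates the mean — left uncorrected this alone makes
   the test anticonservative);
2. estimate the **prior df** carried by the trend from the excess of the
   observed log-variance scatter (robust MAD estimate, so a minority of
   truly differential genes does not inflate it) over the chi-square
   sampling scatter `trigamma(df/2)`;
3. squeeze each gene's variance toward the trend with weights
   `df : prior_df` and convert back to a dispersion.

**Reference distribution.** The LRT statistic is referred to
`F(df1, resid_df + prior_df)` (chi-square in the large-prior limit). With
known dispersion the chi-square reference is correct even at 3 vs 3; all
small-sample anticonservatism comes from dispersion noise, which is exactly
what the prior-df denominator absorbs. When gene-to-gene dispersion scatter
is pure sampling noise the prior df grows and the test recovers full
power; with genuinely heterogeneous dispersions it stays conservative.
A fixed shrinkage weight was rejected because no single value keeps the
two-group null calibrated and the multigroup test powerful at the same
time.

**Normalization.** Total-count scaling, deliberately, not TMM/median-of-
ratios: the series analysed here are dominated by non-differential genes,
where total-count scaling is adequate. When a large fraction of the
library trends with age, composition bias shrinks apparent fold changes
(visible in the generators when trend genes are made a majority); users
with such data should interpret symmetric up/down calls cautiously.

**Gates.** Two-group DEG: raw *P* < 0.05 and |log₂FC| > log₂ 1.5
(fold-change pseudocount 0.5 on normalized counts). Three or more groups:
BH-adjusted *P* < 0.05 and at least one pairwise |log₂FC| > log₂ 1.5.
Batch correction is out of scope; series are assumed batch-homogeneous.

## ADEM calling

A neighbor scan runs the pairwise NB test between each adjacent pair of
ages, with one dispersion fit and one set of size factors shared across
all comparisons, plus the one-way test across all ages.

A gene is **P-ADEM** when some window of at least `min_run = 5`
consecutive timepoints (i.e. ≥ 4 steps) satisfies, on log₂ group means:

- no step falls by more than the step tolerance, and
- the window's net change is positive,

with **N-ADEM** symmetric. The longest qualifying window is reported
(earliest on ties; on an up/down tie the larger net change wins, so a gene
never carries both directions).

**Step tolerance.** Default is adaptive: a step may move against the trend
by at most `z = 1` standard error of the between-timepoint difference of
log₂ means, with the SE computed from the NB model
(`Var(y/s) = q/s + alpha*q^2`, moderated dispersion) rather than from raw
2-df replicate SEMs. Strict monotonicity (`epsilon = 0`) is available but
detects under half of genuinely monotone genes at realistic noise
(dispersion 0.1, 3 replicates) — persistence up to noise, not sample-path
monotonicity, is the operative notion. A fixed `epsilon` in log₂ units is
also accepted.

**DEG prerequisite.** Default `require_deg="multigroup"`: the gene must be
a DEG in the one-way test across all ages. Rationale: a gradual gene's
*per-step* change (0.3 log₂) can never clear the per-step fold-change gate
(log₂ 1.5 ≈ 0.585), so requiring a significant adjacent step
(`"any_step_in_run"`, also provided) silently redefines ADEM genes as
step-change genes; the multigroup gate instead asks whether the gene
changes anywhere over the series, which is what the run rule then
localizes in time. `"none"` disables the gate (used by the permutation
null, where it would otherwise mask the ordering dependence being tested).

Per-gene age association is ordinary least squares of log₂(CPM+1) on age
across individual samples, reporting Pearson r, two-sided p, slope and a
95 % CI; zero-variance genes return r = 0 flagged degenerate rather than
NaN.

## Staging and trajectory shape

Samples are embedded by PCA of log₂(CPM+1) (components sign-fixed so the
largest-magnitude loading is positive), replicate-averaged per timepoint,
and segmented by exhaustive search over contiguous partitions — feasible
exactly for the ≤ 10 timepoints this design has. The number of stages
minimizes

    SSE_z(S) + penalty * S * dim * log(T),    penalty = 0.5,

where SSE_z is computed on per-dimension variance-standardized summaries.
Standardization makes the criterion scale-free (a raw-SSE criterion would
change its verdict if expression units changed); the optimality guarantee
therefore also lives on the standardized scale. Ties prefer fewer stages,
then earlier boundaries. Penalty 0.5 was fixed by analysis of worked
examples (a penalty ≥ ~0.9 forces two stages even on cleanly three-stage
toy data); it is exposed as a parameter.

Trajectory shape is a Gaussian-BIC contest between a constant model
(k = 1), a linear-in-age model (k = 2) and a single persistent step placed
before each interior timepoint in turn (k = 3, counting the changepoint).
Ties prefer the simpler model. The changepoint age reported is the first
post-step timepoint. There is no field-standard quantitative boundary
between "gradual" and "precipitous" population aging; this contest is an
explicit operationalization and ΔBIC (linear − step) is reported so users
can apply their own cutoff.

## Signature scoring and set comparison

The module score of a gene set in a cell is the mean log-normalized
expression of the set minus the mean over control genes: genes are ranked
by dataset-average expression and cut into `n_bins = 25` equal-frequency
bins (capped so every bin holds at least two genes); each set gene draws
`n_ctrl = 100` controls from its own bin — without replacement when the
bin allows, with replacement otherwise, never itself. Scores are exactly
invariant to adding a constant to the whole matrix. The bin/control
defaults follow the common settings of this scoring family and are
configurable; all sampling derives from a single integer seed.

Set overlaps report exact counts plus a one-sided hypergeometric
enrichment p. The universe is an explicit argument (defaulting in the
pipeline to the genes surviving the expression filter) because overlap
p-values are meaningless without it. Fold-change concordance is OLS +
Pearson over the shared genes of two log₂FC maps, requiring ≥ 3 shared
genes.

## Turnover and senescence suite

- **Cumulative divisions**: Σᵢ log₂(recoveredᵢ/residualᵢ) over
  depletion–repopulation rounds; exact arithmetic, additive over rounds.
- **Telomere length**: `ref_length * 2^((Cq_t,tel − Cq_r,tel) − (Cq_t,scr −
  Cq_r,scr))`, applied verbatim as the assay protocol prints it. Note the
  exponent sign is opposite the conventional `2^(−ΔΔCq)` (in which more
  template means lower Cq); a `convention="standard"` switch negates the
  exponent. The two agree whenever the double difference is zero, and
  their product is always `ref²`.
- **Sholl AUC**: trapezoidal integral of intersection counts over radius,
  from the first ring outward (no extrapolation to radius 0); the default
  grid starts at 5 μm and steps by 5 μm.
- **Senescence index**: density / Sholl AUC; larger = denser and less
  ramified, the aged-like morphology.
- **Y-maze alternation**: overlapping windows of three consecutive arm
  entries visiting three distinct arms, divided by (total entries − 2),
  × 100 — consistent with that denominator, windows overlap.

## Synthetic data

All generators are pure functions of their parameters and one integer
seed (`numpy.random.default_rng`; no global state).

**Bulk series.** Defaults mirror the female study design: ages
3, 6, 9, 12, 14, 16, 24 months, 3 replicates per age (the study used 2–6),
NB counts with shared dispersion α = 0.1, per-sample library factors
log-uniform in [0.7, 1.3], baseline log₂ means uniform in [4, 10], and
gene lengths log-uniform in [0.5, 5] kb. Gradual trend genes move
±0.3 log₂ per adjacent timepoint; switch genes jump once (±1 log₂ by
default) and stay — a step function matching a precipitous, persistent
transition. Dispersion and effect sizes are not reported by any study for
these data; the defaults are chosen to be realistic for sorted-cell bulk
RNA-seq and testable, not fitted to the deposited series. Effects are
per-step rather than per-month: the design's age spacing is irregular and
the trend rule operates on adjacent groups.

**Cells.** Two groups with NB counts (dispersion 0.5, per-cell depth
factors), signature-gene means scaled by `2^shift_log2` in the shifted
group. **Sholl**: Poisson counts around a Gaussian-in-radius unimodal
template with per-cell peak-height jitter, truncated at zero. **qPCR**: a
plate whose noiseless read-through reproduces the requested length ratio
exactly. **Turnover**: rounds at a fixed residual fraction with optional
log-normal jitter; the returned truth is computed from the emitted pairs,
so it is exact by construction.

**Timepoint summaries** (for staging/shape testing): Gaussian per-sample
noise around a true per-timepoint profile, averaged over `n_replicates`
(default 3) — the noise level is stated per *sample*, and the
replicate-averaging mirrors how the pipeline actually forms summaries.

**What the generators do not emulate**: batch effects, sex mixtures in one
series, read-level artifacts, doublets/ambient RNA, mean–variance
relationships beyond NB2, or genuinely heterogeneous per-gene dispersions.
Passing tests therefore demonstrate correctness of the algorithms under a
clean NB world, not robustness to those real-data pathologies.

## Problem sizes and numerical choices

Recovery and calibration checks run at 2,000 genes (trend recovery,
10 seeds), 5,000 genes (null calibration), 50 seeds (staging, scoring) and
100 simulations per shape — sizes at which the Monte-Carlo error of each
rate is comfortably below the margin being asserted, while the whole suite
and the acceptance script each finish in about a minute on one core.
Fold-change pseudocount 0.5; dispersions clipped to [1e-8, 100]; prior df
capped at 1e6 (beyond which the chi-square reference is used directly);
BIC residual floors at 1e-12 of the data scale to keep exact fits finite;
p-values clipped below at 1e-300. Degenerate inputs (zero-variance genes,
all-identical timepoints) return defined, flagged results rather than NaN
wherever a sensible value exists, and typed validation errors otherwise.

## Known limitations

- Total-count normalization: composition bias when trending genes carry a
  large read share (see above).
- The ADEM run rule reports the longest window only; a gene rising twice
  with a dip between reports the longer limb, not both.
- The stage search is exhaustive and intended for timepoint counts ≤ ~15;
  it is not a general changepoint engine.
- The multigroup fold-change summary (max pairwise contrast of group
  means) is descriptive, not a shrunk estimator.
- Telomere lengths inherit the assay formula's printed sign convention by
  default; compare against `convention="standard"` before interpreting
  directionality.
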