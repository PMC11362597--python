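# Methods

`apmstools` implements a complete statistical workflow for bait–prey
interactome discovery from affinity-purification mass spectrometry (AP-MS)
label-free quantification (LFQ) data: a GST-tagged bait pulled down against
a GST-only control, candidate partners validated by co-immunoprecipitation
(co-IP) against an IgG control, and nucleotide-state dependence of GTPase
partners probed by paired pulldowns from GTPγS- vs GDPβS-loaded lysates.
This note records the models, the parameter conventions, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## Data model

The central object is a protein-by-sample matrix of MaxLFQ intensities with
an explicit boolean missingness mask. In LFQ data a zero or blank cell means
*not detected*, never a measured zero; the reader converts such cells to
masked entries at parse time, and every detection-based computation
(filtering, detection rates, overlap partitions, detected-count QC) runs on
the pre-imputation mask. A separate design table maps samples to conditions
with replicate numbers and, for the loading experiment, pair identifiers
tying together the two pulldowns derived from one lysate portion.

## Preprocessing

Processing order is **log2 → detection filter → MNAR imputation →
normalization**. (Whether imputation should precede or follow normalization
is genuinely open; we impute first so that the imputation moments are
estimated on the unnormalized per-sample distributions, and the
normalization then calibrates complete matrices. Each stage is exposed
separately, so the alternative order is a two-line change for users who
want it.)

**Detection filter.** A protein is kept iff its non-missing fraction over
all samples is ≥ `min_frac_global` (default 0) **and** its non-missing
fraction within at least one condition is ≥ `min_frac_one_condition`
(default 0.60). Comparisons are inclusive — a protein detected in exactly
60 % of one condition's samples survives — because the thresholds are
minima. The filter is idempotent.

**MNAR imputation.** Intensity-dependent dropout left-censors LFQ data, so
missing values are drawn from a left-shifted Gaussian in the Perseus
tradition: for sample *j* with observed log2 mean μ<sub>j</sub> and sample
standard deviation σ<sub>j</sub> (ddof = 1), each missing cell is an
independent draw from

    Normal(μ_j − shift·σ_j, (width·σ_j)²),   shift = 1.8, width = 0.3.

Moments are per sample by default (a pooled-statistics mode is available via
`per_sample=False`). Draws are generated per sample in sample order from a
single seeded generator, so a run is bit-reproducible given the seed, and
observed cells are never altered. A sample with fewer than two observed
values cannot supply moments and is an error.

**Normalization.** Three methods: `none`, `median_center` (subtract each
sample's median), and the default `vsn_like`. The `vsn_like` method is a
variance-stabilizing calibration: each sample is affinely mapped onto the
pooled quantile reference (the mean of the per-sample order statistics),
then an inverse-hyperbolic-sine (glog) transform of the linear intensity,
expressed in log2-like units, is applied. The affine fit is deliberately
robust: the shift comes from the sample median and the scale from the
10th–50th-percentile spread. Using a tail-sensitive scale (SD or IQR) would
let the minority of strongly bait-enriched proteins inflate a bait sample's
scale estimate and shrink exactly the fold changes under test; the lower
half of the distribution is dominated by non-differential background in
both conditions and gives a calibration that is invariant to upper-tail
enrichment. The calibration is strictly monotone within each sample, so
ranks are preserved, and two samples differing by a constant offset become
identical. The method used is recorded in the run manifest.

**Row standardisation** (for heatmaps) divides by the population SD
(ddof = 0), matching common heatmap tooling; `ddof` is an argument.

## Differential enrichment

Per protein, a two-group comparison of the imputed log2 matrix gives
log2FC = mean(bait) − mean(control) and the pooled within-group variance s²
on d = n₁ + n₂ − 2 degrees of freedom. Variances are then shrunk across
proteins with the standard empirical-Bayes scaled-F model: s² | σ² ~
σ²·χ²_d/d with a scaled inverse-chi-square prior (d₀, s₀²) on σ². The
hyperparameters are estimated by moment matching on log s² using
digamma/trigamma inversion (Newton iteration for the trigamma inverse);
when the empirical spread of log s² does not exceed the trigamma floor, d₀
is infinite and s₀² is the mean observed variance. The moderated statistic
is

    t = log2FC / sqrt( s̃² (1/n₁ + 1/n₂) ),   s̃² = (d₀ s₀² + d s²)/(d₀ + d),

referred to a t distribution on d + d₀ degrees of freedom (standard normal
when d₀ is infinite). This reduces continuously to the ordinary two-sample
t as d₀ → 0. The unit tests verify exact agreement (≤ 1e-6 on p-values,
and in practice machine precision) with R limma's `lmFit`/`eBayes` on a
frozen ten-protein fixture.

P-values are adjusted by the Benjamini–Hochberg step-up procedure
(implemented directly; cross-checked in the tests against both a
brute-force oracle and statsmodels). Candidate selection uses adjusted
p < α (default 0.01) and a log2FC cut of 2, one-directional by default
(bait-enriched only, matching how such candidate lists are reported); the
symmetric mode exists for volcano plots.

## Co-IP credibility scoring

Each pulldown candidate is re-examined in the co-IP data and given:

* a **confidence** label from its detection rate across the co-IP bait
  samples — `high` above 80 %, `moderate` from 60 % to 80 % inclusive
  (both boundaries read as part of the middle bin), `unlikely` below 60 %;
* an **enrichment** label from its bait-vs-control fold change relative to
  the median fold change over the evaluable (non-`unlikely`) candidates —
  strictly above the median is `high`, at or below is `low` (ties go to
  `low`).

The labels combine into four tiers: `unlikely` (excluded), `low_credibility`
(moderate + low), `satisfactory` (high + low or moderate + high) and
`high_credibility` (high + high). Fold changes are computed from observed
(non-imputed) log2 group means; a candidate whose control values are all
missing is floored at the control samples' observed minima so it receives a
large finite fold change rather than an infinity. The threshold scale is
configurable (`linear`, i.e. 2^log2FC, by default, or `log2`) and the
median is always recomputed from the data rather than hard-coded, since a
published threshold value is only meaningful for the cohort it was computed
on. The bait protein itself is excluded from the reported tier tally.

## Paired nucleotide-loading comparison

For each protein the per-pair difference of observed log2 intensities
(GTPγS member minus GDPβS member) is averaged into log2ΔFC and tested
against zero with a two-sided paired (one-sample) t-test. Pairs with a
missing member for that protein are dropped; with fewer than two usable
pairs no p-value is emitted and the row is flagged. Differences use
observed values only — at n = 3 pairs, imputation noise would dominate the
signal. If all pair differences are identical the t statistic is
degenerate; we report p = 1 when the common difference is zero and p = 0
otherwise. A protein is called state-dependent when |log2ΔFC| ≥ 0.2 and
p < 0.05; the magnitude enters, so either direction of preference counts.
Swapping the state labels negates every log2ΔFC and leaves p unchanged.

## QC battery

* **PCA** of samples on the centered (optionally unit-scaled) imputed log2
  matrix, full SVD for determinism; variance fractions are returned in
  descending order.
* **Pearson correlation matrix** over all sample pairs; constant samples
  are an error.
* **Detected counts**: per-sample non-missing counts from the
  pre-imputation mask, compared between conditions with an unpaired
  two-sided t-test (p = 1 short-circuit for exactly identical groups).
* **Overlap partition**: a protein is "detected in a condition" when
  non-missing in ≥ 1 sample of it; the union splits into a-only / b-only /
  shared. Percentages are rounded to 2 decimals by the largest-remainder
  method so the three displayed values always sum to exactly 100.00 —
  plain rounding can lose or gain 0.01.
* **Normality summary**: skewness, excess kurtosis and the
  D'Agostino–Pearson omnibus p per condition's pooled observed log2 values.
* **Hierarchical clustering**: Euclidean distance, average linkage (scipy),
  rows and/or columns, standard dendrogram leaf ordering, optional flat cut
  at k clusters. Pass the Z-scored matrix to emulate a clustered heatmap.

## Synthetic data generator

`generate_pulldown` draws per-protein log2 baselines ~ Normal(25, 2²) —
typical MaxLFQ magnitudes — adds uniform [2.5, 6] log2 effects to a
minority (default fraction 90/775 ≈ 11.6 %) of true interactors in bait
samples, adds replicate noise (SD 0.5), and applies logistic dropout
P(missing | x) = expit(slope·(mid − x)) with mid = 22, slope = 1, yielding
roughly 15 % missingness concentrated at low intensities — left-censored,
exactly the regime MNAR imputation assumes, and monotone by construction.
Default design sizes are 6 + 6 pulldown, 5 + 5 co-IP and 3 loading pairs.
`generate_coip` reuses the pulldown truth with attenuated effects (factor
0.8) and independently forces a fraction (default 0.15) of true interactors
to low detection to exercise the exclusion tier. `generate_loading` gives
both pair members a shared per-lysate random effect (SD 0.5), so pairing
genuinely cancels variance, and adds the state effect (default 0.785 log2
units, a realistic GTPase nucleotide-preference shift) to the GTPγS member
of state-dependent interactors (default 10 % of true interactors). Seeds
for the co-IP and loading tables are derived from the global seed by fixed
offsets.

What the generator does **not** emulate: peptide-level effects and
roll-up, correlated background binding (contaminants co-varying across
samples), batch effects, intensity-dependent variance beyond the dropout
mechanism, and heavy-tailed replicate noise. Passing benchmarks therefore
demonstrate correctness and calibration of the statistical machinery under
the stated model, not performance guarantees on any particular real
dataset.

## Standing benchmarks

`apmstools.benchmarks` (used by both the test suite and
`scripts/acceptance.py`) recomputes:

* **Imputation distribution** — 10⁵ draws for a sample constructed to have
  observed mean 25 and SD 2 must average 21.4 (= 25 − 1.8·2) with SD 0.6
  (= 0.3·2).
* **Null calibration** — 500 no-effect datasets at the default design:
  the fraction with ≥ 1 selected candidate at α = 0.01 and log2FC ≥ 2
  stays ≤ 2 %.
* **Spike recovery** — 200 datasets with all effects pinned at 4 log2
  units, σ = 0.5, 6 vs 6: sensitivity ≥ 0.95 and observed FDR ≤ 0.05.
* **Loading-shift recovery** — 1000 replicates of a 0.785 log2 shift at
  n = 3 pairs, per-sample residual SD 0.1, dropout disabled (the shift
  recovery is the point; its targets sit far above the censoring region):
  the replicate-averaged estimate lands within 0.01 of truth. Simulated at
  40 proteins per replicate — the estimator is per-protein, so the panel
  size only sets the averaging budget.
* **End-to-end tier recovery** — 25 replicates of pulldown + co-IP with
  effects ≥ 3, complete detection and no attenuation: ≥ 90 % of true
  interactors end in the satisfactory-or-better tiers. (25 replicates of
  300 proteins give a standard error of ~1 % on the mean rate, ample for a
  90 % bound.)

## Known limitations

* Only two-group contrasts; no batch covariates or multi-factor designs.
* The empirical-Bayes prior assumes exchangeable variances; the
  imputation step violates this mildly for high-missingness proteins
  (imputed cells have width 0.3·σ, not the replicate SD), which in
  practice makes their moderated variances conservative.
* The `vsn_like` normalization is a calibration on the log scale, not a
  full arsinh-model maximum-likelihood fit on raw intensities; for data
  already delayed-normalized upstream (MaxLFQ) this is the appropriate
  light touch, and `median_center` is the documented fallback.
* The co-IP fold-change floor for all-missing controls is a pragmatic
  censoring convention, not an estimate; affected candidates are rare and
  always sit far above any sensible enrichment threshold.
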