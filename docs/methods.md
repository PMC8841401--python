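# Methods

This note documents the statistical model behind `ptermark`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions used throughout.

## Count model and normalization

Counts are modeled as negative binomial, `K_gj ~ NB(mean = s_j q_gj,
dispersion = α_g)` with `Var = μ + α μ²`.  Size factors use
median-of-ratios: the per-gene reference is the geometric mean across
samples over genes with positive counts in every sample, and each sample's
factor is the median of its count/reference ratios.  When no gene is
positive everywhere (very sparse data), a `--pseudo-reference` fallback
adds 0.5 to all counts for reference construction only.  Factors are not
re-centred, so two identical samples get factors of exactly 1.

Median-of-ratios is a consistent estimator of relative library size only
when most genes are not differentially expressed; its per-sample median has
sampling noise of order `1.25 σ_logratio / √G`.  At a realistic
expressed-transcriptome scale (~16,000 genes) the estimator recovers known
factors spanning 0.5–2.0 to within ~1% even with 5% planted DE genes; on
the small 2,000-gene simulation used as the marker testbed the median's
noise alone is ~±3%, which is a property of any median-based estimator at
that gene count, not of this implementation.  The acceptance script
therefore measures size-factor recovery at the 16,000-gene scale.

**TPM** is computed per sample as `rate_g = count_g / length_g`,
`tpm_g = 10⁶ rate_g / Σ rate`, and is used only for signature-score style
analyses; the DE and marker stages work on normalized counts.  The zero-row
expression filter is applied before any normalization.  **Row z-scores**
use the sample standard deviation (n−1); zero-variance rows become all-zero
and are flagged rather than NaN.

## Differential expression

The two-group test is a deliberately compact NB Wald test:

- Dispersion: method-of-moments on normalized counts pooled within groups
  (`(s² − ξ m)/m²` with `ξ = mean(1/s_j)`), multiplied by
  `exp(log(ν/2) − ψ(ν/2))` (ν = pooled within-group df) — the standard
  correction for the downward log-scale bias of sample-variance-based
  estimates — floored at 1e-8, then shrunk halfway in log space toward a
  trend `a₀ + a₁/mean` fitted by Huber robust regression over genes with
  base mean > 5 (moment estimates are unstable below that).
- GLM: `log μ = offset + β₀ + β₁ x` with `x` the group indicator, fitted by
  IRLS vectorized across genes; `β₁` is clamped at ±25 on the natural-log
  scale to keep degenerate fits finite.
- Inference: Wald statistic `β₁/SE(β₁)` from the expected information,
  two-sided standard normal tail, BH adjustment over all genes with a
  non-NA p (no independent filtering).
- Degenerate genes: all-zero in both groups → NA row; all-zero in one group
  → fold change from the fitted group means with a half-count offset,
  flagged in `zero_group`.

This omits Cox-Reid dispersion adjustment, Cook's-distance outlier
refitting, independent filtering and LFC shrinkage on purpose: the package's
contribution is the downstream marker procedure, and the DE stage needs to
be a *calibrated* NB Wald test rather than a bit-level clone of any
particular tool.  On simulated null data (two identical NB groups, n=8 vs
8) the raw p-values are near-uniform (fraction below 0.05 ≈ 0.053–0.060,
KS distance < 0.02) and per-gene estimates agree with an independent NB GLM
fit and with pyDESeq2 (fold-change correlation > 0.999 on a mixed
signal/null simulation).

DEG thresholds: two-group contrasts use `|log2FC| > 2` and adjusted
`p < 0.05`; the marker gate uses the stricter upregulation-only
`log2FC > 2`, adjusted `p < 0.001`.  All comparisons are strict, so values
exactly at a threshold never pass.

## The marker procedure

Stage order and conventions:

1. Gene axes of training and validation counts are joined (intersection by
   default; union available), genes with zero reads in all pooled samples
   are dropped.
2. **DEG gate**: NB Wald tests of target vs each control class on the
   training cohort; a gene must be upregulated past the thresholds against
   every class.  The conjunction is what rejects confounders that are
   elevated in only some classes.
3. **Diagnosis correlation**: Pearson r of `log2(normalized counts + 1)`
   (training-only normalization) against the 0/1 diagnosis indicator;
   p from the t-transform on n−2 df.  Candidates require `p < 0.001` and
   are sorted by r.
4. **Joint normalization**: one median-of-ratios model over both cohorts.
   The factor scale is anchored so training factors have geometric mean 1;
   this makes training-side percentiles invariant to a global library-size
   change in the validation cohort (tripling every validation library
   leaves all normalized values exactly unchanged).
5. **Percentile specificity**: the shared percentile primitive is the
   linear-interpolation quantile (`h = (n−1)q` between order statistics).
   Training specificity compares the target class's 10th percentile with
   the 75th percentile of each other class separately, combined by
   maximum — the strict, class-balanced reading; a `pool_others` option
   pools all non-target samples instead.  The validation gap subtracts the
   same (training-side) other-class maximum from the validation cohort's
   10th percentile, because other tissues exist only in training.
6. **Ranking**: markers specific in both cohorts are ranked by the pooled
   (training + validation target samples) 10th percentile minus the
   other-class maximum, descending, ties broken lexicographically by gene
   id.

Expression scales: correlation uses log2 (variance-stabilized, appropriate
for a linear correlation); percentile criteria use linear normalized counts
so gaps are differences of normalized reads.  Both are recorded in
`MarkerConfig`.

## Enrichment and signature scores

Over-representation uses the upper-tail hypergeometric p-value
`P(X ≥ k)` for overlap k between the (deduplicated) query and each gene set
within the universe, with the gene ratio `k/n`.  The default universe is
the expressed transcriptome after filtering; no set-size filters are
applied by default (flags exist), a documented divergence from common ORA
tools.  The Mann-Whitney U test is exact by full enumeration of the
`C(n1+n2, n1)` labelings (via a rank-walk DP) when the pooled size is ≤ 14
and there are no ties — enumeration at that size is instant, and beyond it
the normal approximation with tie and continuity corrections is accurate —
and two-sided p is the probability of a statistic at least as far from
`n1 n2 / 2` as observed.  Panel scores are the mean row z-score over panel
genes present in the matrix, with missing genes reported.

## Synthetic data

The generator emulates the structure the analysis assumes: log-normal
baseline gene means (natural-log mean 4.0, sd 1.5 — a realistic bulk
dynamic range), a single NB dispersion α = 0.1 (typical for bulk tissue
replicates), log-normal library-size variation (sd 0.3), five tissue
classes sized 8/8/12/7/7 with the first as target, 50 markers whose target
mean is multiplied 8-fold in both cohorts, 50 confounders multiplied
8-fold in one random non-target class, and six validation samples of the
target tissue only whose per-gene baselines carry a log-normal batch shift
(sd 0.5) emulating the cultured-cell context shift.  Feature lengths are
uniform 500–5000 bases.  Explicit per-sample library factors can be
supplied for estimator-recovery experiments.

What it does *not* emulate: 3'-bias or positional coverage, per-gene
dispersion heterogeneity (a global α is the default), correlated genes or
modules, compositional effects beyond library scaling, and annotation
ambiguity.  Passing recovery tests therefore demonstrates that the
procedure is correct and well-calibrated under its own model assumptions,
not that it is robust to every artifact of real FFPE-derived data.

## Problem sizes and determinism

The test suite and the acceptance script use 2,000-gene simulations for
pipeline recovery (20 seeds), 5,000 genes × 5 seeds for null calibration,
and 16,000 genes for size-factor recovery; these sizes were chosen so each
check is statistically meaningful while the whole suite runs in seconds.
All randomness flows through `numpy.random.default_rng` seeded from the
configuration, and identical inputs produce byte-identical output tables
(stable sorts with explicit tie-breaks everywhere).

## Known limitations

- The DE stage is a simplified NB Wald test (see above); exact DESeq2
  outputs (e.g. published DEG counts) are not reproduced.
- The Pearson correlation uses one target-vs-rest indicator; per-class
  contrast coding is not implemented.
- Covariates (age, sex) are carried in the sample sheet but not adjusted
  for in the GLM.
- With fewer than ~4 target samples the 10th percentile is dominated by the
  minimum, making the specificity criterion fragile; the generator's n=8
  design reflects the intended regime.
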