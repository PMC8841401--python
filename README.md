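# ptermark

Tissue-specific marker-gene discovery for bulk RNA-seq count data.

`ptermark` implements a screening pipeline for finding genes that are
specific to one tissue class (the *target*, e.g. pterygium) among several
control classes (e.g. healthy conjunctiva and ocular-surface tumors), with
confirmation in an independent external cohort of target-tissue samples
(e.g. cultured cells).  It operates on gene-level count tables in
featureCounts layout and is aimed at analysts working with multi-class bulk
transcriptome compendia who need markers that discriminate a disease from
*all* of its differential diagnoses, not just from healthy tissue.

## The method

Counts `K_gj` for gene g in sample j are modeled as negative binomial with
mean `s_j q_gj` and dispersion `α_g` (`Var = μ + α μ²`), where size factors
`s_j` come from median-of-ratios normalization: the reference for gene g is
its geometric mean across samples (restricted to genes observed in every
sample) and `s_j = median_g(K_gj / ref_g)`.

The marker screen then proceeds in five stages:

1. **DEG gate.** A two-group NB Wald test (log-link GLM fitted by IRLS;
   moment dispersion estimates shrunk halfway in log space toward an
   `a₁/μ + a₀` trend) contrasts the target class with *each* control class
   in the training cohort.  A gene passes only if `log2FC > 2` and
   BH-adjusted `p < 0.001` against **every** control class.
2. **Correlation filter.** The Pearson correlation between each gene's
   `log2(normalized counts + 1)` and the diagnosis indicator (1 = target)
   must reach `p < 0.001`; candidates are arranged by `r`.
3. **Joint normalization.** Training and validation cohorts are normalized
   together in a single median-of-ratios model so expression values are
   comparable across cohorts (the factor scale is anchored on the training
   cohort).
4. **Percentile specificity.** A candidate is *training-specific* when its
   10th percentile of normalized expression in target training samples
   strictly exceeds the 75th percentile of every other tissue class.  Its
   *validation gap* — the 10th percentile over validation samples minus the
   maximal other-class 75th percentile — must be strictly positive.
5. **Ranking.** Surviving markers are ranked by the gap between the 10th
   percentile over pooled training + validation target samples and the
   maximal other-class 75th percentile.

Supporting tools: TPM, row z-scores, BH adjustment, hypergeometric
over-representation analysis with gene ratios (`k/n`), marker-panel
signature scores compared by (exact, for small samples) Mann-Whitney U, and
a negative-binomial simulator that plants target-specific markers and
confounder genes to measure recovery.

## Worked example

Simulate the default five-class study design (target n=8, controls
n=8/12/7/7, 6 validation samples, 2000 genes, 50 planted markers at
8-fold, 50 confounders), run the marker screen, and score recovery:

```sh
$ cat sim.yaml
n_genes: 2000
n_markers: 50
n_background_de: 50
seed: 1
$ ptermark simulate --config sim.yaml --out-prefix sim1
simulated 2000 genes, 42 training and 6 validation samples (seed 1)
$ ptermark markers --train-counts sim1.train.tsv --val-counts sim1.val.tsv \
    --samples sim1.samples.tsv --target pterygium --out-prefix run1
50 candidate genes, 49 specific markers
$ ptermark evaluate --truth sim1.truth.tsv --called run1.specific.tsv
{
  "sensitivity": 0.98,
  "fdr": 0.0,
  "tp": 49,
  "fp": 0,
  "fn": 1,
  "n_called": 49,
  "n_markers": 50,
  "confounders_called": 0
}
```

49 of the 50 planted markers survive all five stages with no false
positives; none of the 50 confounders (genes upregulated in a non-target
class) leaks through, because the DEG gate requires upregulation against
every control class simultaneously.  The ranked marker table reports, per
gene, the correlation with diagnosis, the training/validation percentile
gaps and the pooled top score:

```
gene_id  pearson_r       q75_other_max  val_gap        top_score      rank
G00371   0.911357966697  1426.17739041  14128.5372117  4305.58533577  1
G01356   0.933750993397  793.692868804  3562.32644894  3564.48017911  2
G00338   0.925302331347  699.695804788  3243.00979353  2722.68216308  3
```

Other subcommands: `ptermark normalize` (TPM / median-of-ratios / log2 /
z-score tables), `ptermark de` (two-group NB Wald test), `ptermark ora`
(over-representation against GMT gene sets), `ptermark score`
(panel signature scores + Mann-Whitney comparison).

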