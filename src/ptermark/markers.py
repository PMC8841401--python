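"""Tissue-specific marker-gene discovery.

The procedure identifies genes specific to one target tissue class among
several control classes:

1. **DEG gate** — the gene must be upregulated (log2FC > 2, adjusted
   p < 0.001 by default) versus *every* control class in pairwise NB Wald
   tests on the training cohort.
2. **Correlation filter** — the Pearson correlation between the gene's
   log2 expression and the diagnosis indicator (1 = target class) must be
   significant (p < 0.001), and candidates are arranged by the correlation
   coefficient.
3. **Percentile specificity (training)** — after a single joint
   normalization of training and validation cohorts, the 10th percentile of
   normalized expression in target-class training samples must exceed the
   75th percentile in every other tissue class.
4. **Validation gap** — the 10th percentile in the external validation
   cohort (target-tissue samples only) minus the maximal other-class 75th
   percentile must be positive.
5. **Ranking** — surviving markers are ranked by the gap between the 10th
   percentile over pooled training + validation target samples and the
   maximal other-class 75th percentile.

All threshold comparisons are strict, so ties at a boundary fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    CountMatrix,
    SampleSheet,
    COHORT_TRAINING,
    COHORT_VALIDATION,
)
from .normalization import (
    ExpressionMatrix,
    log_transform,
    normalized_counts,
    size_factors_median_of_ratios,
)
from .diffexp import nb_wald_test

__all__ = [
    "MarkerConfig",
    "MarkerPipelineResult",
    "percentile",
    "deg_gate",
    "diagnosis_correlation",
    "joint_normalize",
    "training_specificity",
    "validation_specificity",
    "rank_top_markers",
    "run_marker_pipeline",
]


@dataclass
class MarkerConfig:
    """Thresholds and conventions of the marker procedure.

    Defaults follow the screening design this pipeline implements: an
    upregulation-only DEG gate at log2FC > 2 and adjusted p < 0.001 versus
    every control class, a Pearson p < 0.001 correlation filter, and the
    10th-vs-75th percentile specificity rule.
    """

    lfc: float = 2.0
    deg_alpha: float = 0.001
    corr_alpha: float = 0.001
    q_low: float = 0.10
    q_high: float = 0.75
    pool_others: bool = False     # pool all non-target samples instead of per-class max
    gene_join: str = "intersection"  # or "union"
    pseudo_reference: bool = False
    log_pseudocount: float = 1.0

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        return cls(**d)


def percentile(values, q: float) -> float:
    """Linear-interpolation quantile shared by every percentile criterion.

    For sorted values ``v_0 <= ... <= v_{n-1}`` the index ``h = (n-1) q`` is
    formed and the result interpolates linearly between the order statistics
    at floor(h) and ceil(h).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("percentile of empty vector")
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must lie in [0, 1]")
    return float(np.quantile(v, q, method="linear"))


def deg_gate(
    counts: CountMatrix,
    sheet: SampleSheet,
    target: str | None = None,
    lfc: float = 2.0,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Pairwise target-vs-control DEG gate over the training cohort.

    Runs an NB Wald test of the target class against each control class and
    requires upregulation (log2fc > lfc, strict) with padj < alpha in EVERY
    comparison.  Returns one row per gene with a ``pass_<class>`` flag,
    per-class log2fc/padj columns and the conjunction ``de_pass``.
    """
    target = target or sheet.target_class
    controls = [c for c in sheet.training_classes() if c != target]
    if not controls:
        raise ValueError("no control classes in the training cohort")
    out = pd.DataFrame({"gene_id": list(counts.gene_ids)})
    de_pass = np.ones(counts.n_genes, dtype=bool)
    for ctrl in controls:
        res = nb_wald_test(counts, sheet, target, ctrl, cohort=COHORT_TRAINING)
        l2 = res["log2fc"].to_numpy()
        padj = res["padj"].to_numpy()
        with np.errstate(invalid="ignore"):
            ok = (l2 > lfc) & (padj < alpha)
        ok &= ~np.isnan(l2) & ~np.isnan(padj)
        out[f"log2fc_vs_{ctrl}"] = l2
        out[f"padj_vs_{ctrl}"] = padj
        out[f"pass_{ctrl}"] = ok
        de_pass &= ok
    out["de_pass"] = de_pass
    return out


def diagnosis_correlation(
    expr: ExpressionMatrix, sheet: SampleSheet, target: str | None = None
) -> pd.DataFrame:
    """Pearson correlation of each gene with the diagnosis indicator.

    Training cohort only; the indicator is 1 for target-class samples and 0
    otherwise.  p-values come from ``t = r sqrt((n-2)/(1-r^2))`` on n-2
    degrees of freedom, two-sided.  Zero-variance genes get NA.
    """
    target = target or sheet.target_class
    ids = sheet.ids(cohort=COHORT_TRAINING)
    if len(ids) < 3:
        raise ValueError("correlation requires >=3 training samples")
    indicator = np.array(
        [1.0 if sheet.frame.loc[s, "tissue_class"] == target else 0.0 for s in ids]
    )
    if indicator.min() == indicator.max():
        raise ValueError("all training samples are in one class")
    x = expr.columns(ids)
    n = len(ids)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = indicator - indicator.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    r = np.where(denom == 0, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.abs(r) >= 1.0, 0.0, p))
    return pd.DataFrame({"gene_id": list(expr.gene_ids), "pearson_r": r, "pearson_p": p})


def _join_genes(train: CountMatrix, validation: CountMatrix, policy: str):
    """Align two count matrices on a shared gene axis (intersection or union)."""
    if policy == "intersection":
        val_set = set(validation.gene_ids)
        genes = [g for g in train.gene_ids if g in val_set]
        if not genes:
            raise ValueError("empty gene intersection between cohorts")
    elif policy == "union":
        genes = list(dict.fromkeys(list(train.gene_ids) + list(validation.gene_ids)))
    else:
        raise ValueError(f"unknown gene_join policy {policy!r}")

    def reindex(cm: CountMatrix) -> CountMatrix:
        idx = cm.gene_index()
        counts = np.zeros((len(genes), cm.n_samples), dtype=np.int64)
        lengths = None
        if cm.feature_lengths is not None:
            lengths = np.ones(len(genes), dtype=np.int64)
        for i, g in enumerate(genes):
            j = idx.get(g)
            if j is not None:
                counts[i] = cm.counts[j]
                if lengths is not None:
                    lengths[i] = cm.feature_lengths[j]
        return CountMatrix(genes, list(cm.sample_ids), counts, lengths)

    return reindex(train), reindex(validation)


def joint_normalize(
    train: CountMatrix,
    validation: CountMatrix,
    gene_join: str = "intersection",
    pseudo_reference: bool = False,
) -> ExpressionMatrix:
    """Single median-of-ratios normalization across both cohorts.

    Training and validation samples are pooled into one matrix (after the
    gene join) and one set of size factors is computed, so normalized values
    are directly comparable across cohorts.  The factor scale is anchored on
    the training cohort (training factors have geometric mean 1), so a
    global library-size change in the validation cohort cannot shift the
    training values it is compared against.
    """
    t, v = _join_genes(train, validation, gene_join)
    pooled = t.hstack(v)
    sf = size_factors_median_of_ratios(pooled, pseudo_reference=pseudo_reference)
    sf = sf / np.exp(np.mean(np.log(sf[: t.n_samples])))
    return normalized_counts(pooled, sf)


def _other_class_q75(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    target: str,
    q_high: float,
    pool_others: bool,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Max (or pooled) high percentile over non-target training classes."""
    controls = [c for c in sheet.training_classes() if c != target]
    if not controls:
        raise ValueError("no non-target classes in training cohort")
    per_class: dict[str, np.ndarray] = {}
    if pool_others:
        ids = [s for c in controls for s in sheet.ids(COHORT_TRAINING, c)]
        pooled = np.quantile(expr.columns(ids), q_high, axis=1, method="linear")
        return pooled, {"pooled_others": pooled}
    for c in controls:
        ids = sheet.ids(COHORT_TRAINING, c)
        if not ids:
            raise ValueError(f"training class {c!r} has no samples")
        per_class[c] = np.quantile(expr.columns(ids), q_high, axis=1, method="linear")
    q75_max = np.max(np.vstack(list(per_class.values())), axis=0)
    return q75_max, per_class


def training_specificity(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    genes: list[str] | None = None,
    target: str | None = None,
    q_low: float = 0.10,
    q_high: float = 0.75,
    pool_others: bool = False,
) -> pd.DataFrame:
    """Percentile-gap specificity in the training cohort.

    ``train_specific`` is True iff the gene's ``q_low`` percentile over
    target-class training samples strictly exceeds the ``q_high`` percentile
    of every other training class (combined by maximum, or over a pooled
    non-target sample set with ``pool_others``).
    """
    target = target or sheet.target_class
    tgt_ids = sheet.ids(COHORT_TRAINING, target)
    if not tgt_ids:
        raise ValueError("no target-class training samples")
    q10 = np.quantile(expr.columns(tgt_ids), q_low, axis=1, method="linear")
    q75_max, _ = _other_class_q75(expr, sheet, target, q_high, pool_others)
    df = pd.DataFrame({
        "gene_id": list(expr.gene_ids),
        "q10_target_train": q10,
        "q75_other_max": q75_max,
        "train_specific": q10 > q75_max,
    })
    if genes is not None:
        df = df[df["gene_id"].isin(set(genes))].reset_index(drop=True)
    return df


def validation_specificity(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    genes: list[str] | None = None,
    target: str | None = None,
    q_low: float = 0.10,
    q_high: float = 0.75,
    pool_others: bool = False,
) -> pd.DataFrame:
    """Percentile gap in the validation cohort.

    ``val_gap`` is the ``q_low`` percentile over validation target samples
    minus the maximal other-class ``q_high`` percentile; the other-class
    percentiles come from the training cohort, the only place other tissues
    exist.  ``val_specific`` requires a strictly positive gap.
    """
    target = target or sheet.target_class
    val_ids = sheet.ids(COHORT_VALIDATION, target)
    if not val_ids:
        raise ValueError("no validation samples")
    q10v = np.quantile(expr.columns(val_ids), q_low, axis=1, method="linear")
    q75_max, _ = _other_class_q75(expr, sheet, target, q_high, pool_others)
    gap = q10v - q75_max
    df = pd.DataFrame({
        "gene_id": list(expr.gene_ids),
        "q10_target_val": q10v,
        "val_gap": gap,
        "val_specific": gap > 0,
    })
    if genes is not None:
        df = df[df["gene_id"].isin(set(genes))].reset_index(drop=True)
    return df


def rank_top_markers(records: pd.DataFrame) -> pd.DataFrame:
    """Rank markers passing both cohorts by the pooled percentile gap.

    ``top_score`` (computed upstream) is the ``q_low`` percentile over pooled
    training + validation target samples minus the maximal other-class
    ``q_high`` percentile.  Sorting is by descending score with lexicographic
    gene_id tie-break; ranks run 1..k.
    """
    keep = records[records["train_specific"] & records["val_specific"]].copy()
    keep = keep.sort_values(
        ["top_score", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    keep["rank"] = np.arange(1, len(keep) + 1)
    return keep


@dataclass
class MarkerPipelineResult:
    """Outputs of the full marker pipeline.

    ``candidates`` — genes surviving the DEG gate and correlation filter,
    arranged by correlation coefficient.  ``specific`` — ranked markers
    specific in both cohorts.  ``dossier`` — one row per expressed gene with
    every stage's statistics and pass flags.
    """

    candidates: pd.DataFrame
    specific: pd.DataFrame
    dossier: pd.DataFrame
    normalized: ExpressionMatrix = field(repr=False, default=None)


def run_marker_pipeline(
    train: CountMatrix,
    validation: CountMatrix,
    sheet: SampleSheet,
    config: MarkerConfig | None = None,
) -> MarkerPipelineResult:
    """Run the full marker-gene discovery procedure.

    Stage order: expression filter -> pairwise DEG gate -> diagnosis
    correlation filter (arranged by r) -> joint normalization -> training
    percentile specificity -> validation gap -> pooled-gap ranking.
    """
    cfg = config or MarkerConfig()
    target = sheet.target_class

    train_j, val_j = _join_genes(train, validation, cfg.gene_join)
    pooled = train_j.hstack(val_j)
    expressed = (pooled.counts.sum(axis=1) > 0)
    train_f = train_j.subset_genes(expressed)
    val_f = val_j.subset_genes(expressed)

    if not sheet.ids(cohort=COHORT_VALIDATION):
        raise ValueError("validation cohort is empty; cannot validate markers")

    gate = deg_gate(train_f, sheet, target, lfc=cfg.lfc, alpha=cfg.deg_alpha)

    train_norm = normalized_counts(
        train_f.subset_samples(sheet.ids(cohort=COHORT_TRAINING)),
        pseudo_reference=cfg.pseudo_reference,
    )
    corr = diagnosis_correlation(
        log_transform(train_norm, cfg.log_pseudocount), sheet, target
    )

    dossier = gate.merge(corr, on="gene_id")
    with np.errstate(invalid="ignore"):
        corr_pass = dossier["pearson_p"].to_numpy() < cfg.corr_alpha
    corr_pass &= ~np.isnan(dossier["pearson_p"].to_numpy())
    dossier["corr_pass"] = corr_pass
    dossier["candidate"] = dossier["de_pass"] & dossier["corr_pass"]

    candidates = (
        dossier.loc[dossier["candidate"],
                    ["gene_id", "pearson_r", "pearson_p"] +
                    [c for c in dossier.columns if c.startswith(("log2fc_vs_", "padj_vs_"))]]
        .sort_values(["pearson_r", "gene_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )

    joint = joint_normalize(train_f, val_f, cfg.gene_join, cfg.pseudo_reference)
    tspec = training_specificity(
        joint, sheet, None, target, cfg.q_low, cfg.q_high, cfg.pool_others
    )
    vspec = validation_specificity(
        joint, sheet, None, target, cfg.q_low, cfg.q_high, cfg.pool_others
    )
    dossier = dossier.merge(tspec, on="gene_id").merge(vspec, on="gene_id")

    tgt_ids = sheet.ids(COHORT_TRAINING, target) + sheet.ids(COHORT_VALIDATION, target)
    pooled_q10 = np.quantile(joint.columns(tgt_ids), cfg.q_low, axis=1, method="linear")
    pooled_map = dict(zip(joint.gene_ids, pooled_q10))
    dossier["top_score"] = [
        pooled_map[g] - q75
        for g, q75 in zip(dossier["gene_id"], dossier["q75_other_max"])
    ]
    dossier["marker"] = (
        dossier["candidate"] & dossier["train_specific"] & dossier["val_specific"]
    )

    spec_records = dossier[dossier["candidate"]][
        ["gene_id", "pearson_r", "q10_target_train", "q75_other_max",
         "train_specific", "q10_target_val", "val_gap", "val_specific", "top_score"]
    ]
    specific = rank_top_markers(spec_records)
    return MarkerPipelineResult(candidates, specific, dossier, joint)
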