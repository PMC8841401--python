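"""Expression filtering, TPM, median-of-ratios size factors, log and z-score transforms.

The normalization used throughout the pipeline is the median-of-ratios scheme
standard for negative-binomial count models: a per-gene geometric-mean
reference is built over genes observed in every sample, and each sample's
size factor is the median of its count/reference ratios.  TPM is computed
from assigned reads and feature length for signature-score style analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountMatrix

__all__ = [
    "ExpressionMatrix",
    "filter_expressed",
    "compute_tpm",
    "size_factors_median_of_ratios",
    "normalized_counts",
    "log_transform",
    "row_zscore",
]

VALID_KINDS = ("tpm", "normalized_counts", "log2", "zscore")


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample expression matrix tagged with its scale.

    ``kind`` is one of ``tpm`` (columns sum to 1e6), ``normalized_counts``
    (counts divided by size factors), ``log2`` or ``zscore`` (row-centred and
    scaled).  ``zero_variance_genes`` flags rows that were constant before
    z-scoring and were set to all-zero.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    kind: str
    zero_variance_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene_ids x sample_ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def columns(self, sample_ids: list[str]) -> np.ndarray:
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        return self.values[:, [pos[s] for s in sample_ids]]


def filter_expressed(counts: CountMatrix) -> CountMatrix:
    """Remove genes with zero reads in all samples; order preserving and idempotent."""
    keep = counts.counts.sum(axis=1) > 0
    return counts.subset_genes(keep)


def compute_tpm(counts: CountMatrix) -> ExpressionMatrix:
    """Transcripts per million from assigned reads and feature length.

    Per sample: ``rate_g = count_g / length_g``; ``tpm_g = 1e6 * rate_g / sum(rate)``.
    A sample with zero total counts yields an all-zero column and a warning.
    """
    if counts.feature_lengths is None:
        raise ValueError("TPM requires feature lengths (Length column missing)")
    rate = counts.counts / counts.feature_lengths[:, None]
    denom = rate.sum(axis=0)
    tpm = np.zeros_like(rate)
    nonzero = denom > 0
    tpm[:, nonzero] = rate[:, nonzero] / denom[nonzero] * 1e6
    if (~nonzero).any():
        dead = [counts.sample_ids[j] for j in np.flatnonzero(~nonzero)]
        warnings.warn(f"samples with zero total counts yield all-zero TPM: {dead}")
    return ExpressionMatrix(list(counts.gene_ids), list(counts.sample_ids), tpm, "tpm")


def size_factors_median_of_ratios(
    counts: CountMatrix | np.ndarray, pseudo_reference: bool = False
) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    The reference is the per-gene geometric mean across samples, restricted to
    genes with a positive count in every sample; each sample's factor is the
    median ratio of its counts to that reference.  With ``pseudo_reference``
    set, 0.5 is added to all counts for reference construction only, which
    rescues sparse matrices that have no gene observed in every sample.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    mat = mat.astype(float)
    if pseudo_reference:
        ref_mat = mat + 0.5
        use = np.ones(mat.shape[0], dtype=bool)
    else:
        ref_mat = mat
        use = (mat > 0).all(axis=1)
        if not use.any():
            raise ValueError(
                "no gene has positive counts in every sample; re-run with the "
                "pseudo-reference fallback (--pseudo-reference)"
            )
    log_ref = np.log(ref_mat[use]).mean(axis=1)
    ratios = np.log(ref_mat[use]) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise ValueError("degenerate size factors; check input counts")
    return factors


def normalized_counts(
    counts: CountMatrix, size_factors: np.ndarray | None = None,
    pseudo_reference: bool = False,
) -> ExpressionMatrix:
    """Counts divided by median-of-ratios size factors."""
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(counts, pseudo_reference)
    size_factors = np.asarray(size_factors, dtype=float)
    if size_factors.shape != (counts.n_samples,):
        raise ValueError("one size factor per sample required")
    vals = counts.counts / size_factors[None, :]
    return ExpressionMatrix(
        list(counts.gene_ids), list(counts.sample_ids), vals, "normalized_counts"
    )


def log_transform(x: ExpressionMatrix | np.ndarray, pseudocount: float = 1.0):
    """log2(value + pseudocount); input values must be non-negative."""
    vals = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    if (vals < 0).any():
        raise ValueError("log transform requires non-negative values")
    out = np.log2(vals + pseudocount)
    if isinstance(x, ExpressionMatrix):
        return ExpressionMatrix(list(x.gene_ids), list(x.sample_ids), out, "log2")
    return out


def row_zscore(x: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score: subtract the row mean, divide by the sample (n-1) SD.

    Expresses each value in standard-deviation units relative to the gene's
    mean across samples.  Zero-variance rows become all-zero and are listed
    in ``zero_variance_genes``.
    """
    if len(x.sample_ids) < 2:
        raise ValueError("z-score requires at least 2 samples")
    mean = x.values.mean(axis=1, keepdims=True)
    sd = x.values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (x.values - mean) / safe_sd
    z[flat] = 0.0
    return ExpressionMatrix(
        list(x.gene_ids), list(x.sample_ids), z, "zscore",
        zero_variance_genes=[g for g, f in zip(x.gene_ids, flat) if f],
    )
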