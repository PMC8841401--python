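"""Negative-binomial Wald differential expression between two sample groups.

A deliberately compact NB test in the style of the standard count-based DE
tools: median-of-ratios size factors, per-gene method-of-moments dispersion
shrunk in log space halfway toward a fitted a1/mean + a0 trend, a two-group
NB GLM with log link fitted by iteratively reweighted least squares, and a
Wald test on the group coefficient with Benjamini-Hochberg adjustment.

It omits Cox-Reid dispersion adjustment, outlier refitting, independent
filtering and LFC shrinkage: the goal is a correct, calibrated NB Wald test
driving the downstream marker procedure, not a bit-level clone of any
particular tool.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import digamma

from .core_io import CountMatrix, SampleSheet, COHORT_TRAINING
from .normalization import size_factors_median_of_ratios

__all__ = ["nb_wald_test", "bh_adjust", "call_deg", "estimate_dispersions"]

_LN2 = np.log(2.0)
_MIN_DISP = 1e-8
_MAX_DISP = 100.0
_MAX_ABS_BETA = 25.0  # natural-log scale; |log2FC| cap ~ 36


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, NA-aware.

    NaN entries are excluded from the family size m and returned as NaN;
    adjusted values are ``min_{j>=i} p_(j) * m / j`` capped at 1, in the
    original order.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return out
    idx = np.flatnonzero(ok)
    order = idx[np.argsort(p[idx], kind="stable")]
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out[order] = np.minimum(adj, 1.0)
    return out


def _dispersion_trend(base_mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Robust fit of disp ~ a0 + a1/mean over well-expressed genes.

    Uses Huber-weighted robust regression; coefficients are clamped to be
    non-negative.  Falls back to the median dispersion when too few genes
    qualify (base_mean > 5) for a stable fit.
    """
    use = (base_mean > 5.0) & np.isfinite(disp) & (disp > _MIN_DISP)
    fallback = float(np.median(disp[np.isfinite(disp)])) if np.isfinite(disp).any() else 0.1
    fallback = min(max(fallback, _MIN_DISP), _MAX_DISP)
    if use.sum() < 10:
        return np.full(base_mean.shape, fallback)
    X = sm.add_constant(1.0 / base_mean[use])
    try:
        fit = sm.RLM(disp[use], X, M=sm.robust.norms.HuberT()).fit()
        a0, a1 = float(fit.params[0]), float(fit.params[1])
    except Exception:
        return np.full(base_mean.shape, fallback)
    a0, a1 = max(a0, _MIN_DISP), max(a1, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        trend = a0 + a1 / base_mean
    trend[~np.isfinite(trend)] = fallback
    return np.clip(trend, _MIN_DISP, _MAX_DISP)


def estimate_dispersions(
    norm: np.ndarray, group_a: np.ndarray, group_b: np.ndarray,
    inv_sf: np.ndarray,
) -> np.ndarray:
    """Per-gene NB dispersion alpha (var = mu + alpha mu^2).

    Method-of-moments on normalized counts pooled within groups — the
    within-group variance of normalized counts has expectation
    ``mu * mean(1/s) + alpha * mu^2``.  The pooled estimate is multiplied by
    ``exp(log(nu/2) - digamma(nu/2))`` (nu = pooled within-group df), the
    standard correction for the downward log-scale bias of sample variances,
    then floored at 1e-8 and shrunk halfway in log space toward the robust
    a1/mean + a0 trend.
    """
    est_num = np.zeros(norm.shape[0])
    est_den = 0.0
    for sel in (group_a, group_b):
        n = int(sel.sum())
        if n < 2:
            continue
        sub = norm[:, sel]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        xi = float(inv_sf[sel].mean())
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - xi * m) / m**2
        a[~np.isfinite(a)] = 0.0
        est_num += (n - 1) * a
        est_den += n - 1
    nu = max(est_den, 1.0)
    bias_corr = float(np.exp(np.log(nu / 2.0) - digamma(nu / 2.0)))
    mom = np.clip(est_num / nu * bias_corr, _MIN_DISP, _MAX_DISP)
    base_mean = norm.mean(axis=1)
    trend = _dispersion_trend(base_mean, mom)
    return np.exp(0.5 * (np.log(mom) + np.log(trend)))


def _irls_two_group(
    y: np.ndarray, x: np.ndarray, offsets: np.ndarray, alpha: np.ndarray,
    b0: np.ndarray, b1: np.ndarray, max_iter: int = 60, tol: float = 1e-10,
):
    """Vectorized IRLS for the two-group NB GLM with log link, per gene.

    Model: mu_gj = s_j * exp(b0_g + b1_g * x_j).  Returns the coefficients
    and the Wald standard error of b1 from the expected information.
    """
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x[None, :]
        mu = np.exp(np.clip(offsets[None, :] + eta, -50.0, 50.0))
        mu = np.maximum(mu, 1e-10)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swxx = (w * x * x).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x * z).sum(axis=1)
        det = sw * swxx - swx**2
        det = np.where(det <= 0, np.nan, det)
        nb0 = (swxx * swz - swx * swxz) / det
        nb1 = (sw * swxz - swx * swz) / det
        nb0 = np.clip(np.nan_to_num(nb0, nan=0.0), -_MAX_ABS_BETA, _MAX_ABS_BETA)
        nb1 = np.clip(np.nan_to_num(nb1, nan=0.0), -_MAX_ABS_BETA, _MAX_ABS_BETA)
        delta = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        b0, b1 = nb0, nb1
        if float(delta.max(initial=0.0)) < tol:
            break
    # expected information at the final estimate
    eta = b0[:, None] + b1[:, None] * x[None, :]
    mu = np.maximum(np.exp(np.clip(offsets[None, :] + eta, -50.0, 50.0)), 1e-10)
    w = mu / (1.0 + alpha[:, None] * mu)
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    swxx = (w * x * x).sum(axis=1)
    det = sw * swxx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se_b1 = np.sqrt(sw / det)
    return b0, b1, se_b1


def nb_wald_test(
    counts: CountMatrix,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    cohort: str | None = COHORT_TRAINING,
    size_factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test.

    ``log2fc`` is the log2 fold change of ``group_a`` over ``group_b``
    (positive = higher in A).  Genes with zero counts in both groups get an
    NA row; genes with all-zero counts in one group are flagged in
    ``zero_group`` and their fold change is computed from the fitted group
    means with a half-count offset to avoid infinite estimates.

    Parameters
    ----------
    cohort
        Restrict the contrast to one cohort (default training); ``None``
        uses samples of the two classes from both cohorts.
    size_factors
        Optional externally supplied per-sample factors (aligned with the
        selected samples); by default median-of-ratios factors are computed
        over the two groups.
    """
    ids_a = sheet.ids(cohort=cohort, tissue_class=group_a)
    ids_b = sheet.ids(cohort=cohort, tissue_class=group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(
            f"each group needs >=2 samples (got {group_a}: {len(ids_a)}, "
            f"{group_b}: {len(ids_b)})"
        )
    sub = counts.subset_samples(ids_a + ids_b)
    y = sub.counts.astype(float)
    x = np.array([1.0] * len(ids_a) + [0.0] * len(ids_b))

    if size_factors is None:
        try:
            sf = size_factors_median_of_ratios(sub)
        except ValueError:
            sf = size_factors_median_of_ratios(sub, pseudo_reference=True)
    else:
        sf = np.asarray(size_factors, dtype=float)
        if sf.shape != (y.shape[1],):
            raise ValueError("size_factors must align with the selected samples")
    offsets = np.log(sf)
    norm = y / sf[None, :]
    base_mean = norm.mean(axis=1)

    in_a = x == 1.0
    in_b = ~in_a
    zero_a = (y[:, in_a] == 0).all(axis=1)
    zero_b = (y[:, in_b] == 0).all(axis=1)
    all_zero = zero_a & zero_b
    zero_group = (zero_a | zero_b) & ~all_zero

    alpha = estimate_dispersions(norm, in_a, in_b, 1.0 / sf)

    m_a = norm[:, in_a].mean(axis=1)
    m_b = norm[:, in_b].mean(axis=1)
    b1 = np.log((m_a + 0.5) / (m_b + 0.5))
    b0 = np.log(m_b + 0.5)
    b0, b1, se_b1 = _irls_two_group(y, x, offsets, alpha, b0, b1)

    log2fc = b1 / _LN2
    se = se_b1 / _LN2

    if zero_group.any():
        # half-count offset on the fitted group means; SE from the
        # information evaluated at those adjusted means
        mu_a = np.exp(np.clip(b0 + b1, -50, 50))[zero_group] + 0.5
        mu_b = np.exp(np.clip(b0, -50, 50))[zero_group] + 0.5
        log2fc[zero_group] = np.log2(mu_a / mu_b)
        a_z = alpha[zero_group]
        mu_mat = np.where(in_a[None, :], mu_a[:, None], mu_b[:, None]) * sf[None, :]
        w = mu_mat / (1.0 + a_z[:, None] * mu_mat)
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swxx = (w * x * x).sum(axis=1)
        det = sw * swxx - swx**2
        se[zero_group] = np.sqrt(sw / det) / _LN2

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))

    bad = all_zero | ~np.isfinite(se) | (se <= 0)
    log2fc = np.where(all_zero, np.nan, log2fc)
    se = np.where(bad, np.nan, se)
    wald = np.where(bad, np.nan, wald)
    pvalue = np.where(bad, np.nan, pvalue)
    padj = bh_adjust(pvalue)

    return pd.DataFrame({
        "gene_id": sub.gene_ids,
        "base_mean": base_mean,
        "log2fc": log2fc,
        "se": se,
        "wald": wald,
        "pvalue": pvalue,
        "padj": padj,
        "dispersion": np.where(all_zero, np.nan, alpha),
        "zero_group": zero_group,
    })


def call_deg(
    results: pd.DataFrame, lfc_threshold: float = 2.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Differentially expressed genes: |log2fc| > threshold AND padj < alpha.

    Both inequalities are strict; NA padj never passes.  Returns gene_id,
    log2fc, padj and direction (+1 up in group A, -1 down).
    """
    lfc = results["log2fc"].to_numpy()
    padj = results["padj"].to_numpy()
    with np.errstate(invalid="ignore"):
        hit = (np.abs(lfc) > lfc_threshold) & (padj < alpha)
    hit &= ~np.isnan(lfc) & ~np.isnan(padj)
    out = results.loc[hit, ["gene_id", "log2fc", "padj"]].copy()
    out["direction"] = np.sign(out["log2fc"]).astype(int)
    return out.reset_index(drop=True)
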