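"""Hypergeometric over-representation analysis and rank-based group comparison.

Over-representation of a query gene list in curated gene sets is tested with
the one-sided (upper-tail) hypergeometric distribution within a background
universe, reporting the gene ratio (overlap / query size) alongside BH-
adjusted p-values.  Marker-panel signature scores (mean row z-score over a
panel) are compared between sample groups with the Mann-Whitney U test,
exact by enumeration for small samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneSetCollection
from .diffexp import bh_adjust
from .normalization import ExpressionMatrix

__all__ = ["ORARow", "UTestResult", "hypergeom_ora", "mann_whitney_u", "panel_score"]

EXACT_U_MAX_N = 14  # total sample size up to which the exact null is enumerated


def hypergeom_ora(
    query,
    sets: GeneSetCollection,
    universe,
    min_set: int | None = None,
    max_set: int | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation analysis.

    For each term with set size K (within the universe of size N), query
    size n and overlap k, the p-value is P(X >= k) for X hypergeometric.
    Query genes outside the universe are dropped with a warning; the query
    is deduplicated.  Rows are sorted by (pvalue, term_id) and BH-adjusted
    across all tested terms.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty universe")
    uni_set = set(uni)
    q = list(dict.fromkeys(query))
    if not q:
        raise ValueError("empty query")
    dropped = [g for g in q if g not in uni_set]
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) outside the universe were dropped"
        )
    q_in = [g for g in q if g in uni_set]
    if not q_in:
        raise ValueError("no query genes inside the universe")
    q_set = set(q_in)
    N, n = len(uni_set), len(q_set)

    rows = []
    for term, (name, genes) in sets:
        members = [g for g in genes if g in uni_set]
        K = len(members)
        if min_set is not None and K < min_set:
            continue
        if max_set is not None and K > max_set:
            continue
        overlap = sorted(g for g in members if g in q_set)
        k = len(overlap)
        # upper tail P(X >= k); survival function at k-1, log-space internals
        pvalue = float(stats.hypergeom.sf(k - 1, N, K, n))
        pvalue = min(max(pvalue, 0.0), 1.0)
        rows.append({
            "term_id": term,
            "term_name": name,
            "k": k,
            "set_size": K,
            "query_size": n,
            "universe_size": N,
            "pvalue": pvalue,
            "gene_ratio": k / n,
            "overlap_genes": ",".join(overlap),
        })
    df = pd.DataFrame(rows, columns=[
        "term_id", "term_name", "k", "set_size", "query_size", "universe_size",
        "pvalue", "gene_ratio", "overlap_genes",
    ])
    if len(df):
        df["padj"] = bh_adjust(df["pvalue"].to_numpy())
        df = df.sort_values(["pvalue", "term_id"], kind="stable").reset_index(drop=True)
    else:
        df["padj"] = []
    return df


@dataclass
class UTestResult:
    U: float          # statistic for the first sample
    pvalue: float     # two-sided
    method: str       # "exact" | "normal_approx"


def _u_distribution(n1: int, n2: int) -> list[int]:
    """Null counts of the Mann-Whitney U statistic for untied samples.

    Walks the pooled order statistics from smallest to largest, tracking how
    many first-sample elements have been placed; assigning a position to the
    first sample adds one U unit per second-sample element already placed
    (each is smaller).  Entry u of the result is the number of labelings
    with statistic u; the entries sum to C(n1+n2, n1).
    """
    max_u = n1 * n2
    table = [[0] * (max_u + 1) for _ in range(n1 + 1)]
    table[0][0] = 1
    for pos in range(1, n1 + n2 + 1):
        new = [[0] * (max_u + 1) for _ in range(n1 + 1)]
        for j in range(min(pos, n1) + 1):
            n2_used = (pos - 1) - j
            for u, c in enumerate(table[j]):
                if not c:
                    continue
                if n2_used + 1 <= n2:          # position goes to sample 2
                    new[j][u] += c
                if j + 1 <= n1:                # position goes to sample 1
                    new[j + 1][u + n2_used] += c
        table = new
    return table[n1]


def mann_whitney_u(x, y) -> UTestResult:
    """Two-sided Mann-Whitney U test.

    U is computed for the first sample from midrank sums.  When the pooled
    size is at most 14 and there are no ties, the exact two-sided p-value is
    obtained from the full enumeration distribution as the probability of a
    statistic at least as far from n1*n2/2 as observed; otherwise a normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()

    if n1 + n2 <= EXACT_U_MAX_N and not has_ties:
        dist = _u_distribution(n1, n2)
        center = n1 * n2 / 2.0
        d = abs(u - center)
        total = comb(n1 + n2, n1)
        count = sum(int(c) for uu, c in enumerate(dist) if abs(uu - center) >= d - 1e-12)
        return UTestResult(U=float(u), pvalue=min(count / total, 1.0), method="exact")

    N = n1 + n2
    mean = n1 * n2 / 2.0
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return UTestResult(U=float(u), pvalue=1.0, method="normal_approx")
    z = (abs(u - mean) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = min(2.0 * stats.norm.sf(z), 1.0)
    return UTestResult(U=float(u), pvalue=float(p), method="normal_approx")


def panel_score(expr: ExpressionMatrix, panel) -> tuple[pd.Series, list[str]]:
    """Per-sample signature score: mean row z-score over the panel genes present.

    Returns the score series (indexed by sample) and the list of panel genes
    missing from the matrix.  Raises if no panel gene is present.
    """
    if expr.kind != "zscore":
        raise ValueError("panel_score expects a z-scored expression matrix")
    panel = list(dict.fromkeys(panel))
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    present = [g for g in panel if g in idx]
    missing = [g for g in panel if g not in idx]
    if not present:
        raise ValueError("no panel gene present in the expression matrix")
    rows = expr.values[[idx[g] for g in present]]
    score = pd.Series(rows.mean(axis=0), index=expr.sample_ids, name="panel_score")
    return score, missing
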