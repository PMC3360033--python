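"""Paired per-bucket condition tests with FDR control, and Ward clustering.

For each pair of storage conditions, every chemical-shift bucket is
tested with a paired Wilcoxon signed-rank test across subjects (the
within-woman design pairs the samples), and Benjamini-Hochberg false
discovery rates are computed across buckets within each condition pair.
The exact signed-rank null distribution is computed by dynamic
programming over rank sums, which is equivalent to enumerating all 2^n
sign assignments but feasible for any n up to the exact-mode cutoff;
above the cutoff a normal approximation with tie and continuity
corrections is used.
"""

from __future__ import annotations

from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from statsmodels.stats.multitest import multipletests

from .types import BucketTestResult

EXACT_WILCOXON_LIMIT = 25


class WilcoxonResult(NamedTuple):
    statistic: float
    p_value: float
    degenerate: bool = False


def _exact_signed_rank_p(doubled_ranks: np.ndarray, w2: int) -> float:
    """Two-sided exact p for the signed-rank sum via subset-sum counting.

    ``doubled_ranks`` are 2x the (possibly midpoint) ranks, so all
    integers; the null assigns each rank a positive sign independently
    with probability 1/2.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original treatment); the
    statistic is the sum of ranks of positive differences. If every
    difference is zero the statistic is undefined and p = 1 is returned
    with ``degenerate=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be equal-length non-empty 1-D sequences")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, degenerate=True)
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_LIMIT:
        doubled = np.rint(2 * ranks).astype(int)
        p = _exact_signed_rank_p(doubled, int(round(2 * w)))
        return WilcoxonResult(w, p)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts ** 3 - tie_counts).sum()) / 48.0
    cc = 0.5 * np.sign(w - mean)
    z = (w - mean - cc) / np.sqrt(var)
    return WilcoxonResult(w, float(min(1.0, 2.0 * stats.norm.sf(abs(z)))))


def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bucket_condition_report(bucket_table: pd.DataFrame,
                            metadata: pd.DataFrame) -> list[BucketTestResult]:
    """Per-bucket paired Wilcoxon tests for every condition pair.

    ``bucket_table`` is a samples x buckets normalized integral table
    (interval columns); ``metadata`` is indexed by sample_id with
    ``subject_id`` and ``condition`` columns. FDR is controlled across
    buckets within each condition pair.
    """
    meta = metadata.loc[bucket_table.index]
    conditions = sorted(meta["condition"].unique())
    results: list[BucketTestResult] = []
    for cond_a, cond_b in combinations(conditions, 2):
        by_subj_a = {meta.loc[i, "subject_id"]: i
                     for i in meta.index[meta["condition"] == cond_a]}
        by_subj_b = {meta.loc[i, "subject_id"]: i
                     for i in meta.index[meta["condition"] == cond_b]}
        shared = sorted(set(by_subj_a) & set(by_subj_b))
        if len(shared) < 2:
            continue
        rows_a = bucket_table.loc[[by_subj_a[s] for s in shared]]
        rows_b = bucket_table.loc[[by_subj_b[s] for s in shared]]
        pair_results = []
        for col in bucket_table.columns:
            res = wilcoxon_signed_rank(rows_a[col].to_numpy(), rows_b[col].to_numpy())
            pair_results.append(
                BucketTestResult(
                    bucket=(float(col.left), float(col.right)),
                    condition_pair=(cond_a, cond_b),
                    statistic=res.statistic, p_value=res.p_value,
                    degenerate=res.degenerate,
                )
            )
        qs = fdr_bh([r.p_value for r in pair_results])
        for r, q in zip(pair_results, qs):
            r.q_value = float(q)
        results.extend(pair_results)
    if not results:
        raise ValueError("no condition pair has >= 2 paired subjects")
    return results


def hierarchical_cluster(X, method: str = "ward") -> np.ndarray:
    """Agglomerative clustering of a samples x features matrix.

    Returns the scipy linkage matrix (merge list with heights). Ward
    linkage on Euclidean distances by default; ties are broken by
    scipy's deterministic nearest-pair scan order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with >= 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    return linkage(X, method=method)


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(Z)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    inner = f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)})"
    return inner + ";"
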