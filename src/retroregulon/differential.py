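"""Rank-based differential expression and cluster-marker detection.

Two-group contrasts use the two-sided Wilcoxon rank-sum (Mann-Whitney)
test: exact null enumeration when the combined sample size is at most 12
and there are no ties, otherwise the normal approximation with tie and
continuity correction. One-vs-rest cluster markers use the
Kruskal-Wallis test (which on two groups is the squared standardized
rank-sum statistic) with Benjamini-Hochberg adjustment within each
cluster. Fold changes are mean-based with a pseudocount so that zero
means never produce infinities.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import AbundanceMatrix, DifferentialResult

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12


def _values(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, AbundanceMatrix) else matrix


def _adjust(p: np.ndarray, correction: str) -> np.ndarray:
    if correction == "bonferroni":
        return np.minimum(1.0, p * len(p))
    if correction in {"bh", "BH", "fdr_bh"}:
        return multipletests(p, method="fdr_bh")[1]
    if correction in {"none", None}:
        return p.copy()
    raise ValueError(f"unknown correction {correction!r}")


def _mwu_row(a: np.ndarray, b: np.ndarray) -> tuple:
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 0.0, 1.0
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_de(
    matrix,
    labels: pd.Series,
    group_a: str,
    group_b: str,
    correction: str = "bonferroni",
    pseudocount: float = 1.0,
) -> DifferentialResult:
    """Two-sided Wilcoxon rank-sum differential test, ``group_a`` vs ``group_b``.

    ``labels`` maps sample -> group; fold change is
    ``log2((mean_a + pc) / (mean_b + pc))`` so positive values mean
    higher in ``group_a``. ``padj`` applies ``correction`` over all
    features tested.
    """
    vals = _values(matrix)
    labels = labels.reindex(vals.columns)
    sa = vals.columns[labels == group_a]
    sb = vals.columns[labels == group_b]
    for g, s in ((group_a, sa), (group_b, sb)):
        if len(s) == 0:
            raise ValueError(f"group {g!r} absent from labels")
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    A, B = vals[sa].to_numpy(), vals[sb].to_numpy()
    stat = np.empty(len(vals))
    p = np.empty(len(vals))
    for i in range(len(vals)):
        stat[i], p[i] = _mwu_row(A[i], B[i])
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        # undefined (NaN) when a pseudocounted mean is non-positive, e.g. z-scored input
        lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    direction = np.sign(np.nan_to_num(mean_a - mean_b)).astype(int)
    table = pd.DataFrame(
        {
            "lfc": lfc,
            "stat": stat,
            "p": p,
            "padj": _adjust(p, correction),
            "direction": direction,
            "mean_a": mean_a,
            "mean_b": mean_b,
        },
        index=vals.index,
    )
    return DifferentialResult(table=table, group_a=group_a, group_b=group_b,
                              correction=correction)


def cluster_markers(
    matrix,
    cluster_labels: pd.Series,
    correction: str = "bh",
    fdr: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One-vs-rest Kruskal-Wallis markers per cluster.

    For every cluster c and feature, tests cluster-c samples against all
    remaining samples; p-values are BH-adjusted within each cluster's
    feature list. A feature is flagged ``marker`` when adjusted p < fdr
    and the fold change versus the rest is positive.

    Returns a long DataFrame indexed by (cluster, feature).
    """
    vals = _values(matrix)
    cluster_labels = cluster_labels.reindex(vals.columns)
    clusters = sorted(cluster_labels.dropna().unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    out = []
    for c in clusters:
        inc = vals.columns[cluster_labels == c]
        exc = vals.columns[cluster_labels != c]
        if len(inc) < 2:
            raise ValueError(f"cluster {c!r} has fewer than 2 samples")
        A, B = vals[inc].to_numpy(), vals[exc].to_numpy()
        stat = np.empty(len(vals))
        p = np.empty(len(vals))
        for i in range(len(vals)):
            x, y = A[i], B[i]
            if np.all(np.concatenate([x, y]) == x[0]):
                stat[i], p[i] = 0.0, 1.0
                continue
            res = stats.kruskal(x, y)
            stat[i], p[i] = float(res.statistic), float(res.pvalue)
        padj = _adjust(p, correction)
        mean_in, mean_out = A.mean(axis=1), B.mean(axis=1)
        lfc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
        out.append(pd.DataFrame({
            "cluster": c, "feature": vals.index, "lfc": lfc, "stat": stat,
            "p": p, "padj": padj, "marker": (padj < fdr) & (lfc > 0),
        }))
    return pd.concat(out, ignore_index=True).set_index(["cluster", "feature"])


def select_variable(matrix, n_features: int) -> list:
    """Top ``n_features`` by variance across samples (log-scale input expected).

    Deterministic: ties broken by feature ID. ``n_features`` larger than
    the matrix returns everything with a logged warning.
    """
    vals = _values(matrix)
    if n_features > len(vals):
        logger.warning("requested %d variable features but only %d available",
                       n_features, len(vals))
        n_features = len(vals)
    var = vals.var(axis=1, ddof=0)
    order = sorted(vals.index, key=lambda f: (-var[f], f))
    return order[:n_features]
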