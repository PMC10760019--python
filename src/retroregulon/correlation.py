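"""KRAB zinc-finger / TE-family anticorrelation screen.

A KZNF that represses a TE family should show reduced family expression
in the samples where it is high: across individuals this appears as a
negative rank correlation between the KZNF transcript and the mean
expression of the family's loci. The screen computes Spearman's rho for
every (family, KZNF) pair, adjusts across the full pair grid by
Benjamini-Hochberg, and reports pairs below a negative rho cutoff.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def spearman_matrix(family_expr: pd.DataFrame, kznf_expr: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho for every (TE family, KZNF) pair across shared samples.

    Mid-rank ties; two-sided p from the t approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))``; BH adjustment (column ``q``)
    across all testable pairs. Constant vectors give NaN rho (count
    logged).
    """
    samples = family_expr.columns.intersection(kznf_expr.columns)
    n = len(samples)
    if n < 4:
        raise ValueError(f"need at least 4 shared samples, got {n}")
    F = family_expr[samples].to_numpy(dtype=float)
    K = kznf_expr[samples].to_numpy(dtype=float)

    def rank_rows(M):
        return np.apply_along_axis(stats.rankdata, 1, M)

    RF, RK = rank_rows(F), rank_rows(K)
    RF = RF - RF.mean(axis=1, keepdims=True)
    RK = RK - RK.mean(axis=1, keepdims=True)
    sf = np.sqrt((RF ** 2).sum(axis=1))
    sk = np.sqrt((RK ** 2).sum(axis=1))
    const_f, const_k = sf == 0, sk == 0
    n_const = int(const_f.sum() + const_k.sum())
    if n_const:
        logger.warning("%d constant vector(s); their correlations reported as NaN", n_const)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (RF @ RK.T) / np.outer(np.where(const_f, np.nan, sf), np.where(const_k, np.nan, sk))
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)

    out = pd.DataFrame({
        "te_family": np.repeat(family_expr.index.to_numpy(), len(kznf_expr)),
        "kznf": np.tile(kznf_expr.index.to_numpy(), len(family_expr)),
        "rho": rho.ravel(),
        "p": p.ravel(),
        "n": n,
    })
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def anticorrelation_screen(
    results: pd.DataFrame,
    rho_max: float = -0.3,
    q_max: float = 0.05,
    known_pairs: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Filter the correlation table to significant anticorrelated pairs.

    Keeps pairs with ``rho <= rho_max`` and ``q <= q_max``, sorted by
    rho ascending. When ``known_pairs`` (columns te_family, kznf) is
    supplied — e.g. repressor-target pairs confirmed by binding data —
    a recovery report flags which of them the screen found.
    """
    hits = results[(results["rho"] <= rho_max) & (results["q"] <= q_max)]
    hits = hits.sort_values("rho", kind="mergesort").reset_index(drop=True)
    report = None
    if known_pairs is not None:
        found = set(zip(hits["te_family"], hits["kznf"]))
        report = known_pairs.copy()
        report["recovered"] = [
            (f, k) in found for f, k in zip(known_pairs["te_family"], known_pairs["kznf"])
        ]
    return hits, report
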