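"""Population-specific cis-regulatory TE-gene pair calling.

A TE-derived peak is linked to a gene when the peak lies within
``max_dist`` of the gene's TSS; the (peak, gene) pair becomes a putative
cis-regulatory pair when the peak is differentially accessible between
the two populations, the gene is differentially expressed in the same
contrast, and (by default) the two effects point the same way.

With small per-group sample sizes an exact rank test has a bounded
minimum p-value (2/70 at 4 vs 4), so multiplicity-corrected thresholds
over genome-scale feature lists are unattainable in principle; the
default thresholds are therefore nominal p-values in each layer, and the
false-positive control comes from demanding joint, concordant support in
two independent data layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import wilcoxon_de
from .types import DifferentialResult, PeakSet


def diff_accessibility(
    peak_matrix: pd.DataFrame,
    labels: pd.Series,
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
) -> DifferentialResult:
    """Wilcoxon rank-sum on per-peak normalized signal, ``group_a`` vs ``group_b``.

    Reports the nominal p alongside a BH-adjusted column; fold change is
    of group means with a pseudocount.
    """
    return wilcoxon_de(peak_matrix, labels, group_a, group_b,
                       correction="bh", pseudocount=pseudocount)


def link_peaks_to_tss(
    te_peaks: PeakSet,
    genes: pd.DataFrame,
    max_dist: int = 10_000,
) -> pd.DataFrame:
    """Candidate (peak, gene) pairs with TSS within ``max_dist`` of the peak.

    Distance is interval-to-point: 0 when the TSS falls inside the peak,
    otherwise the gap to the nearer peak boundary; the cutoff is
    inclusive. The signed summit-to-TSS distance (positive when the TSS
    is at a larger coordinate than the summit) is reported for ranking.
    All qualifying genes are retained for each peak.
    """
    rows = []
    for chrom, gsub in genes.groupby("chrom", sort=False):
        psub = te_peaks.df[te_peaks.df["chrom"] == chrom]
        if not len(psub):
            continue
        tss = gsub["tss"].to_numpy()
        gids = gsub["gene_id"].to_numpy()
        order = np.argsort(tss)
        tss, gids = tss[order], gids[order]
        for r in psub.itertuples(index=False):
            lo = np.searchsorted(tss, r.start - max_dist, side="left")
            hi = np.searchsorted(tss, r.end + max_dist, side="right")
            summit = r.start + r.summit_offset
            for t, g in zip(tss[lo:hi], gids[lo:hi]):
                dist = max(r.start - t, t - r.end, 0)
                if dist <= max_dist:
                    rows.append((r.peak_id, g, int(dist), int(t - summit)))
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance", "summit_to_tss"])


@dataclass
class CisRegThresholds:
    """Cutoffs applied to the two statistical layers."""

    access_p: float = 0.05
    access_lfc: float = 0.5      # |accessibility lfc| must exceed this
    expr_p: float = 0.05
    require_concordance: bool = True
    use_adjusted_expr: bool = False   # threshold the adjusted expression p instead


def call_cisreg_pairs(
    candidates: pd.DataFrame,
    access_stats: pd.DataFrame,
    expr_stats: pd.DataFrame,
    thresholds: CisRegThresholds | None = None,
) -> pd.DataFrame:
    """Emit putative cis-regulatory TE-gene pairs.

    ``candidates`` come from :func:`link_peaks_to_tss` (optionally
    carrying a ``locus_id`` column from the peak-TE overlap table);
    ``access_stats`` is indexed by peak_id with columns lfc, p;
    ``expr_stats`` by gene_id with columns lfc, p, padj. A pair is
    emitted iff the peak passes the accessibility thresholds, the gene
    passes the expression threshold, and (if required) the directions
    agree. Output is sorted by gene then distance.
    """
    th = thresholds or CisRegThresholds()
    missing_p = set(candidates["peak_id"]) - set(access_stats.index)
    if missing_p:
        raise ValueError(f"candidates reference peaks without accessibility stats: {sorted(missing_p)[:5]}")
    missing_g = set(candidates["gene_id"]) - set(expr_stats.index)
    if missing_g:
        raise ValueError(f"candidates reference genes without expression stats: {sorted(missing_g)[:5]}")

    out = candidates.copy()
    out["access_lfc"] = access_stats.loc[out["peak_id"], "lfc"].to_numpy()
    out["access_p"] = access_stats.loc[out["peak_id"], "p"].to_numpy()
    out["expr_lfc"] = expr_stats.loc[out["gene_id"], "lfc"].to_numpy()
    ecol = "padj" if th.use_adjusted_expr else "p"
    out["expr_padj"] = expr_stats.loc[out["gene_id"], ecol].to_numpy()
    keep = (
        (out["access_p"] < th.access_p)
        & (out["access_lfc"].abs() >= th.access_lfc)
        & (out["expr_padj"] < th.expr_p)
    )
    out["concordant"] = np.sign(out["access_lfc"]) == np.sign(out["expr_lfc"])
    if th.require_concordance:
        keep &= out["concordant"]
    out = out[keep].sort_values(["gene_id", "distance"], kind="mergesort").reset_index(drop=True)
    return out
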