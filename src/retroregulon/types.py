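"""Core data containers shared across the pipeline.

All genomic intervals are 0-based half-open; external formats (GTF,
RepeatMasker ``.out``) are converted at the I/O boundary. The TSS of a
'-'-strand gene is ``end - 1`` (the last base): a TSS is a base, not a
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

TE_LOCI_COLUMNS = ["locus_id", "chrom", "start", "end", "strand", "subfamily", "family"]
GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "gene_class"]
PEAK_COLUMNS = ["peak_id", "chrom", "start", "end", "summit_offset", "score", "sample_or_group"]


def _check_intervals(df: pd.DataFrame, chrom_sizes: Optional[Mapping[str, int]], what: str) -> None:
    if len(df) == 0:
        return
    bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        raise ValueError(f"invalid {what} interval(s), e.g. {bad.iloc[0].to_dict()}")
    if chrom_sizes is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                raise ValueError(f"unknown chromosome {chrom!r} in {what}")
            if (sub["end"] > chrom_sizes[chrom]).any():
                raise ValueError(f"{what} interval beyond end of {chrom}")


@dataclass
class GenomeAnnotation:
    """Coordinate universe: chromosome sizes, TE loci, and gene TSSs.

    ``te_loci`` columns: locus_id, chrom, start, end, strand, subfamily,
    family. ``genes`` columns: gene_id, chrom, tss, strand, gene_class
    (``gene`` or ``kznf``).
    """

    chrom_sizes: dict
    te_loci: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.te_loci = self.te_loci.reset_index(drop=True)
        self.genes = self.genes.reset_index(drop=True)
        _check_intervals(self.te_loci, self.chrom_sizes, "TE locus")
        if self.te_loci["locus_id"].duplicated().any():
            raise ValueError("duplicate locus_id in te_loci")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in genes")
        fam = self.te_loci.groupby("subfamily")["family"].nunique()
        if (fam > 1).any():
            bad = fam[fam > 1].index[0]
            raise ValueError(f"subfamily {bad!r} maps to more than one family")

    @property
    def te_lengths(self) -> pd.Series:
        s = (self.te_loci["end"] - self.te_loci["start"]).astype(int)
        s.index = self.te_loci["locus_id"]
        return s

    def total_te_bp(self) -> int:
        return int((self.te_loci["end"] - self.te_loci["start"]).sum())


@dataclass
class PeakSet:
    """Called accessibility peaks with summit offsets (bp from peak start)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _check_intervals(self.df, None, "peak")
        if len(self.df):
            width = self.df["end"] - self.df["start"]
            bad = (self.df["summit_offset"] < 0) | (self.df["summit_offset"] >= width)
            if bad.any():
                raise ValueError(
                    f"summit offset outside peak for {self.df.loc[bad, 'peak_id'].tolist()[:5]}"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def summit_positions(self) -> pd.Series:
        s = self.df["start"] + self.df["summit_offset"]
        s.index = self.df["peak_id"]
        return s


@dataclass
class SignalTrack:
    """Per-chromosome binned coverage.

    ``data`` maps chromosome -> per-bin vector of length
    ``ceil(chrom_len / bin_size)``; ``normalization`` is one of raw,
    RPKM, RPM, zscore.
    """

    bin_size: int
    data: dict
    normalization: str = "raw"
    total_reads: Optional[float] = None

    def __post_init__(self) -> None:
        if self.normalization not in {"raw", "RPKM", "RPM", "zscore"}:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}
        if self.normalization in {"RPKM", "RPM"}:
            for c, v in self.data.items():
                if (v < 0).any():
                    raise ValueError(f"negative {self.normalization} values on {c}")

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def values_over(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bp values over [start, end); out-of-range positions are NaN."""
        n = len(self.data[chrom]) * self.bin_size
        out = np.full(end - start, np.nan)
        lo, hi = max(start, 0), min(end, n)
        if lo < hi:
            idx = np.arange(lo, hi) // self.bin_size
            out[lo - start : hi - start] = self.data[chrom][idx]
        return out


@dataclass
class AbundanceMatrix:
    """Features x samples matrix with a unit tag and per-feature metadata.

    ``feature_meta`` (indexed like ``values``) carries ``kind``
    (gene / te_locus / te_family), ``length`` (bp) and ``family``.
    """

    values: pd.DataFrame
    unit: str = "counts"
    feature_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.unit not in {"counts", "TPM", "log2TPM1p", "zscore"}:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.feature_meta is not None:
            self.feature_meta = self.feature_meta.reindex(self.values.index)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset(self, features) -> "AbundanceMatrix":
        meta = None if self.feature_meta is None else self.feature_meta.loc[features]
        return AbundanceMatrix(self.values.loc[features], self.unit, meta)


@dataclass
class TruthTable:
    """Planted ground truth echoed by the simulators, for recovery tests."""

    de: Optional[pd.DataFrame] = None              # feature, lfc, group/cluster
    cluster_labels: Optional[pd.Series] = None     # sample -> cluster id
    kznf_pairs: Optional[pd.DataFrame] = None      # kznf, family, target_rho
    accessible_te: Optional[pd.DataFrame] = None   # locus_id, lfc, gene_id, peak_id
    group_means: Optional[pd.DataFrame] = None     # realized per-group feature means


@dataclass
class DifferentialResult:
    """Per-feature rank-test output for one contrast."""

    table: pd.DataFrame        # lfc, stat, p, padj, direction
    group_a: str
    group_b: str
    correction: str

    def significant(self, alpha: float = 0.05, adjusted: bool = True) -> pd.DataFrame:
        col = "padj" if adjusted else "p"
        return self.table[self.table[col] < alpha]


@dataclass
class PCAResult:
    scores: pd.DataFrame       # samples x PCs
    loadings: pd.DataFrame     # features x PCs
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


@dataclass
class ClusterAssignment:
    """Sample -> cluster labels, contiguous from 1, sorted by size (desc)."""

    labels: pd.Series
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        uniq = sorted(self.labels.unique())
        if uniq != list(range(1, len(uniq) + 1)):
            raise ValueError("cluster labels must be contiguous from 1")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())
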