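"""Readers and writers for the standard genomic and tabular formats.

Coordinate conventions at the boundary:

* BED / narrowPeak / bedGraph: already 0-based half-open, taken as-is.
* RepeatMasker ``.out``: 1-based inclusive; start is decremented.
* GTF: 1-based inclusive; the TSS of a '+' gene at ``start..end`` is
  ``start - 1`` and of a '-' gene is ``end - 1`` (0-based base position).
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import AbundanceMatrix, PeakSet, SignalTrack, TE_LOCI_COLUMNS

logger = logging.getLogger(__name__)

METADATA_REQUIRED = ["sample_id", "group", "subtype", "cohort"]


def _validate_chroms(df: pd.DataFrame, chrom_sizes: Optional[Mapping[str, int]], what: str) -> None:
    if chrom_sizes is None:
        return
    unknown = set(df["chrom"]) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"unknown chromosome(s) {sorted(unknown)} in {what}")


def read_te_annotation(
    path,
    format: str = "bed",
    family_map: Optional[Mapping[str, str]] = None,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Read TE loci from BED6 or RepeatMasker ``.out`` into the internal table.

    BED name column is the subfamily; family comes from ``family_map``
    (defaulting to the subfamily itself). RepeatMasker rows supply the
    class/family column directly and are converted from 1-based inclusive
    to 0-based half-open.
    """
    rows = []
    if format == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}: line {lineno}: expected >=6 BED columns")
                try:
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
                sub, strand = parts[3], parts[5]
                fam = family_map.get(sub, sub) if family_map else sub
                rows.append((f"te_{lineno}", chrom, start, end, strand, sub, fam))
    elif format == "repeatmasker_out":
        with open(path) as fh:
            lines = fh.read().splitlines()
        for lineno, line in enumerate(lines[3:], 4):  # 3 header lines
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 11:
                raise ValueError(f"{path}: line {lineno}: expected >=11 RepeatMasker columns")
            try:
                chrom = parts[4]
                start = int(parts[5]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            strand = "-" if parts[8] == "C" else parts[8]
            sub, fam = parts[9], parts[10]
            rows.append((f"te_{lineno}", chrom, start, end, strand, sub, fam))
    else:
        raise ValueError(f"unknown TE annotation format {format!r}")
    df = pd.DataFrame(rows, columns=TE_LOCI_COLUMNS)
    if len(df):
        bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
        if len(bad):
            raise ValueError(f"invalid interval at locus {bad.iloc[0]['locus_id']}")
    _validate_chroms(df, chrom_sizes, "TE annotation") if len(df) else None
    return df


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gene_annotation(
    path,
    kznf_ids: Optional[Iterable[str]] = None,
    feature_type: str = "gene",
) -> pd.DataFrame:
    """Read gene records from a GTF into the internal gene/TSS table.

    ``kznf_ids`` marks the supplied gene IDs with gene_class ``kznf``
    (the KRAB zinc-finger catalogue is caller-provided, not inferred).
    """
    kznf = set(kznf_ids) if kznf_ids is not None else set()
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GTF columns")
            if parts[2] != feature_type:
                continue
            chrom, start, end, strand, attrs = parts[0], int(parts[3]), int(parts[4]), parts[6], parts[8]
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}: line {lineno}: gene without strand")
            m = dict(_GTF_ATTR.findall(attrs))
            gid = m.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}: line {lineno}: missing gene_id attribute")
            tss = start - 1 if strand == "+" else end - 1
            rows.append((gid, chrom, tss, strand, "kznf" if gid in kznf else "gene"))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand", "gene_class"])
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate gene_id {df.loc[dup, 'gene_id'].iloc[0]!r}")
    return df


def read_peaks(path, sample_or_group: str = "", chrom_sizes=None) -> PeakSet:
    """Read narrowPeak (10 columns) or BED peaks.

    A narrowPeak summit of -1 ("not determined") is replaced by the peak
    midpoint; a summit outside the peak is an error.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] not in {"", "."} else f"peak_{lineno}"
            score = float(parts[4]) if len(parts) > 4 else 0.0
            width = end - start
            if len(parts) >= 10:  # narrowPeak: col 10 is summit offset
                summit = int(parts[9])
                if summit == -1:
                    summit = width // 2
                elif not (0 <= summit < width):
                    raise ValueError(f"{path}: line {lineno}: summit {summit} outside peak of width {width}")
            else:
                summit = width // 2
            rows.append((name, chrom, start, end, summit, score, sample_or_group))
    df = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end", "summit_offset", "score", "sample_or_group"])
    _validate_chroms(df, chrom_sizes, "peaks") if len(df) else None
    return PeakSet(df)


def write_peaks(peaks: PeakSet, path) -> None:
    """Write a PeakSet as narrowPeak (signalValue/p/q filled with placeholders)."""
    with open(path, "w") as fh:
        for r in peaks.df.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.peak_id}\t{r.score:g}\t.\t0\t-1\t-1\t{r.summit_offset}\n"
            )


def read_counts(path, require_integer: bool = True) -> AbundanceMatrix:
    """Read a features-x-samples TSV count matrix (first column feature_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicated feature_id {df.index[df.index.duplicated()][0]!r}")
    for j, col in enumerate(df.columns):
        num = pd.to_numeric(df[col], errors="coerce")
        if num.isna().any():
            i = int(np.where(num.isna())[0][0])
            raise ValueError(f"non-numeric value at row {df.index[i]!r}, column {col!r}")
        df[col] = num
    if (df.values < 0).any():
        raise ValueError("negative count in matrix")
    if require_integer and not np.allclose(df.values, np.round(df.values)):
        raise ValueError("non-integer values in raw count matrix")
    return AbundanceMatrix(df.astype(float), unit="counts")


def write_table(obj, path) -> None:
    """Write an AbundanceMatrix or DataFrame as TSV (round-trip safe)."""
    df = obj.values if isinstance(obj, AbundanceMatrix) else obj
    df.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_REQUIRED if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required column(s) {missing}")
    return meta.set_index("sample_id")


def read_bedgraph(path, chrom_sizes: Mapping[str, int], bin_size: int,
                  normalization: str = "raw") -> SignalTrack:
    """Import a bedGraph onto a fixed-bin SignalTrack (intervals must align to bins)."""
    data = {c: np.zeros(int(np.ceil(L / bin_size))) for c, L in chrom_sizes.items()}
    bg = pd.read_csv(path, sep="\t", header=None, comment="t",
                     names=["chrom", "start", "end", "value"])
    for r in bg.itertuples(index=False):
        if r.chrom not in data:
            raise ValueError(f"unknown chromosome {r.chrom!r} in bedGraph")
        if r.start % bin_size or (r.end % bin_size and r.end != chrom_sizes[r.chrom]):
            raise ValueError(f"bedGraph interval {r.start}-{r.end} not aligned to {bin_size} bp bins")
        data[r.chrom][r.start // bin_size : int(np.ceil(r.end / bin_size))] = r.value
    return SignalTrack(bin_size=bin_size, data=data, normalization=normalization)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, vals in track.data.items():
            for i, v in enumerate(vals):
                if v != 0:
                    fh.write(f"{chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v:g}\n")


def write_te_bed(te_loci: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in te_loci.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.subfamily}\t0\t{r.strand}\n")
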