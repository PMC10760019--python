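"""Chromatin-accessibility analysis around transposable elements.

Covers track normalization (RPKM / RPM / z-score), peak-TE overlap with
the 50%-of-peak + summit-inside-TE rule, TE-family enrichment against a
width-matched random null, family metaprofiles anchored at element left
boundaries, and per-cluster family accessibility summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import GenomeAnnotation, PeakSet, SignalTrack

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- tracks

def rpkm_bins(track: SignalTrack, total_reads: Optional[float] = None) -> SignalTrack:
    """Reads per kilobase of bin per million sequenced: c_b / (kb * M)."""
    if track.normalization != "raw":
        raise ValueError("RPKM expects a raw count track")
    total = float(total_reads if total_reads is not None else track.total())
    if total <= 0:
        raise ValueError("total reads must be positive")
    scale = (track.bin_size / 1000.0) * (total / 1e6)
    data = {c: v / scale for c, v in track.data.items()}
    return SignalTrack(track.bin_size, data, "RPKM", total_reads=total)


def rpm_bins(track: SignalTrack, total_reads: Optional[float] = None) -> SignalTrack:
    """Reads per million per bin: c_b / M."""
    if track.normalization != "raw":
        raise ValueError("RPM expects a raw count track")
    total = float(total_reads if total_reads is not None else track.total())
    if total <= 0:
        raise ValueError("total reads must be positive")
    data = {c: v / (total / 1e6) for c, v in track.data.items()}
    return SignalTrack(track.bin_size, data, "RPM", total_reads=total)


def zscore_track(track: SignalTrack) -> SignalTrack:
    """Z-score across all bins of the track (constant track -> all zero)."""
    allv = np.concatenate([v for v in track.data.values()])
    mu, sd = allv.mean(), allv.std(ddof=0)
    if sd == 0:
        data = {c: np.zeros_like(v) for c, v in track.data.items()}
    else:
        data = {c: (v - mu) / sd for c, v in track.data.items()}
    return SignalTrack(track.bin_size, data, "zscore", total_reads=track.total_reads)


def bin_reads(read_positions: Mapping[str, Sequence[int]], chrom_sizes: Mapping[str, int],
              bin_size: int = 100, extend: int = 100) -> SignalTrack:
    """Build a raw count track from read start positions.

    Each read is extended by ``extend`` bp and contributes to every bin
    its extended footprint touches (fractional bins count fully).
    """
    data = {c: np.zeros(int(np.ceil(L / bin_size))) for c, L in chrom_sizes.items()}
    total = 0
    for chrom, pos in read_positions.items():
        vec = data[chrom]
        L = chrom_sizes[chrom]
        for p in pos:
            total += 1
            lo = max(0, p) // bin_size
            hi = min(L - 1, p + extend) // bin_size
            vec[lo : hi + 1] += 1
    return SignalTrack(bin_size, data, "raw", total_reads=total)


# ---------------------------------------------------------------- overlap

def _te_trees(te_loci: pd.DataFrame) -> dict:
    trees: dict = {}
    for chrom, sub in te_loci.groupby("chrom", sort=False):
        t = IntervalTree()
        for r in sub.itertuples(index=False):
            t.addi(r.start, r.end, r.locus_id)
        trees[chrom] = t
    return trees


def peak_te_overlap(
    peaks: PeakSet,
    te_loci: pd.DataFrame,
    min_frac: float = 0.5,
    require_summit: bool = True,
) -> pd.DataFrame:
    """Peak-TE pairs passing the overlap rule.

    A pair is retained when the TE covers at least ``min_frac`` of the
    peak (boundary inclusive) and, if ``require_summit``, the peak
    summit lies inside the TE interval. A peak may pair with several
    loci; every qualifying pair is kept.

    Returns columns peak_id, locus_id, overlap_bp, overlap_frac_of_peak,
    summit_in_te.
    """
    trees = _te_trees(te_loci)
    rows = []
    for r in peaks.df.itertuples(index=False):
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        width = r.end - r.start
        summit = r.start + r.summit_offset
        for iv in tree.overlap(r.start, r.end):
            ov = min(r.end, iv.end) - max(r.start, iv.begin)
            frac = ov / width
            s_in = iv.begin <= summit < iv.end
            if frac >= min_frac and (s_in or not require_summit):
                rows.append((r.peak_id, iv.data, ov, frac, s_in))
    return pd.DataFrame(
        rows, columns=["peak_id", "locus_id", "overlap_bp", "overlap_frac_of_peak", "summit_in_te"]
    )


# ------------------------------------------------------------ enrichment

@dataclass
class EnrichmentResult:
    """Per-family observed vs width-matched-random expected peak counts."""

    table: pd.DataFrame  # family, observed, expected, expected_sd, log2_ratio, p_enrich, p_deplete
    n_draws: int


def _count_per_family(overlaps: pd.DataFrame, te_loci: pd.DataFrame) -> pd.Series:
    families = te_loci["family"].unique()
    if len(overlaps) == 0:
        return pd.Series(0, index=families, dtype=float)
    fam_of = te_loci.set_index("locus_id")["family"]
    ov = overlaps.assign(family=overlaps["locus_id"].map(fam_of))
    counts = ov.groupby("family")["peak_id"].nunique()
    return counts.reindex(families, fill_value=0).astype(float)


def family_enrichment(
    peaks: PeakSet,
    annotation: GenomeAnnotation,
    n_draws: int = 100,
    seed: int = 0,
    min_frac: float = 0.5,
    require_summit: bool = True,
    exclude: Optional[pd.DataFrame] = None,
    pseudocount: float = 0.5,
) -> EnrichmentResult:
    """TE-family enrichment of peaks against a size-matched random null.

    Each draw replaces every peak with a uniformly placed interval of
    the same width (summit offset preserved), genome-wide outside the
    optional ``exclude`` regions, and applies the identical overlap
    rule. ``log2_ratio = log2((obs + pc) / (mean_expected + pc))``;
    ``p_enrich = (1 + #draws >= obs) / (n_draws + 1)``.
    """
    chroms = list(annotation.chrom_sizes)
    sizes = np.array([annotation.chrom_sizes[c] for c in chroms], dtype=float)
    widths = (peaks.df["end"] - peaks.df["start"]).to_numpy()
    max_size = sizes.max()
    if (widths > max_size).any():
        raise ValueError("peak wider than every chromosome; cannot place random intervals")

    excl_trees: dict = {}
    if exclude is not None and len(exclude):
        for chrom, sub in exclude.groupby("chrom", sort=False):
            t = IntervalTree()
            for r in sub.itertuples(index=False):
                t.addi(r.start, r.end)
            excl_trees[chrom] = t

    observed = _count_per_family(
        peak_te_overlap(peaks, annotation.te_loci, min_frac, require_summit),
        annotation.te_loci,
    )

    rng = np.random.default_rng(seed)
    draws = np.zeros((n_draws, len(observed)))
    summits = peaks.df["summit_offset"].to_numpy()
    for d in range(n_draws):
        rows = []
        for i, w in enumerate(widths):
            for _ in range(200):
                ok = sizes >= w
                probs = np.where(ok, sizes - w + 1, 0.0)
                ci = rng.choice(len(chroms), p=probs / probs.sum())
                start = int(rng.integers(0, int(sizes[ci]) - w + 1))
                chrom = chroms[ci]
                t = excl_trees.get(chrom)
                if t is not None and t.overlaps(start, start + w):
                    continue
                rows.append((f"rand_{i}", chrom, start, start + int(w), int(summits[i]), 0.0, ""))
                break
            else:
                raise ValueError("could not place random interval outside excluded regions")
        rand = PeakSet(pd.DataFrame(
            rows, columns=["peak_id", "chrom", "start", "end", "summit_offset", "score", "sample_or_group"]
        ))
        draws[d] = _count_per_family(
            peak_te_overlap(rand, annotation.te_loci, min_frac, require_summit),
            annotation.te_loci,
        ).to_numpy()

    expected = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=0)
    obs = observed.to_numpy()
    log2_ratio = np.log2((obs + pseudocount) / (expected + pseudocount))
    p_enrich = (1 + (draws >= obs[None, :]).sum(axis=0)) / (n_draws + 1)
    p_deplete = (1 + (draws <= obs[None, :]).sum(axis=0)) / (n_draws + 1)
    table = pd.DataFrame({
        "family": observed.index, "observed": obs, "expected": expected,
        "expected_sd": sd, "log2_ratio": log2_ratio,
        "p_enrich": p_enrich, "p_deplete": p_deplete,
    }).set_index("family")
    return EnrichmentResult(table=table, n_draws=n_draws)


# ------------------------------------------------------------ profiles

def metaprofile(
    tracks: Mapping[str, SignalTrack],
    family_loci: pd.DataFrame,
    window: int = 5000,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Mean signal per bin in a +/-window around locus left boundaries.

    ``tracks`` maps group/cluster -> track; raw tracks are scaled to
    reads-per-million first, normalized tracks are used as-is. The
    anchor is the locus start (lower coordinate) regardless of strand.
    Positions beyond chromosome ends are excluded from the means.

    Returns groups x bins (columns are bp offsets of bin starts,
    -window .. +window inclusive: 2*window/bin_size + 1 bins).
    """
    if window % bin_size:
        raise ValueError("window must be divisible by bin size")
    if len(family_loci) == 0:
        raise ValueError("family has no loci")
    nb = window // bin_size
    offsets = np.arange(-nb, nb + 1) * bin_size
    out = {}
    for group, track in tracks.items():
        if track.normalization == "raw":
            track = rpm_bins(track)
        sums = np.zeros(len(offsets))
        counts = np.zeros(len(offsets))
        for r in family_loci.itertuples(index=False):
            if r.chrom not in track.data:
                continue
            vals = track.values_over(r.chrom, r.start - window, r.start + window + bin_size)
            per_bin = vals.reshape(len(offsets), bin_size)
            m = np.nanmean(per_bin, axis=1)
            good = ~np.isnan(m)
            sums[good] += m[good]
            counts[good] += 1
        with np.errstate(invalid="ignore"):
            out[group] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(out, index=offsets).T


def family_accessibility_by_cluster(
    tracks: Mapping[str, SignalTrack],
    family_loci: pd.DataFrame,
    cluster_labels: pd.Series,
) -> pd.DataFrame:
    """Mean normalized signal over family loci, per sample then per cluster.

    ``tracks`` maps sample -> normalized track. A cluster with no ATAC
    samples is reported as NaN. Returns clusters x (mean, sd, n).
    """
    per_sample = {}
    for sample, track in tracks.items():
        acc = []
        for r in family_loci.itertuples(index=False):
            if r.chrom not in track.data:
                continue
            lo = r.start // track.bin_size
            hi = (r.end - 1) // track.bin_size + 1
            acc.append(track.data[r.chrom][lo:hi])
        per_sample[sample] = float(np.concatenate(acc).mean()) if acc else np.nan
    s = pd.Series(per_sample)
    rows = {}
    for c in sorted(cluster_labels.unique()):
        members = cluster_labels.index[cluster_labels == c].intersection(s.index)
        v = s.loc[members].dropna()
        rows[c] = {
            "mean": v.mean() if len(v) else np.nan,
            "sd": v.std(ddof=0) if len(v) else np.nan,
            "n": len(v),
        }
    return pd.DataFrame(rows).T


def peak_signal_matrix(tracks: Mapping[str, SignalTrack], peaks: PeakSet) -> pd.DataFrame:
    """Peaks x samples matrix of mean per-bin signal inside each peak."""
    cols = {}
    for sample, track in tracks.items():
        vals = []
        for r in peaks.df.itertuples(index=False):
            lo = r.start // track.bin_size
            hi = (r.end - 1) // track.bin_size + 1
            vals.append(float(track.data[r.chrom][lo:hi].mean()))
        cols[sample] = vals
    return pd.DataFrame(cols, index=peaks.df["peak_id"])
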