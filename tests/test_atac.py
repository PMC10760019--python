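"""Track normalization, peak-TE overlap, enrichment null, metaprofiles."""

import numpy as np
import pandas as pd
import pytest

import retroregulon as rr
from retroregulon.atac import (
    bin_reads,
    family_accessibility_by_cluster,
    family_enrichment,
    metaprofile,
    peak_te_overlap,
    rpkm_bins,
    rpm_bins,
    zscore_track,
)


def _peaks(rows):
    return rr.PeakSet(pd.DataFrame(
        rows,
        columns=["peak_id", "chrom", "start", "end", "summit_offset", "score", "sample_or_group"],
    ))


def _te(rows):
    return pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end",
                                       "strand", "subfamily", "family"])


def test_rpkm_hand_arithmetic():
    track = rr.SignalTrack(100, {"chr1": np.array([10.0, 0.0])}, "raw")
    out = rpkm_bins(track, total_reads=1_000_000)
    assert out.data["chr1"][0] == pytest.approx(100.0)  # 10 / (0.1 kb * 1 M)


def test_rpkm_depth_invariance():
    t1 = rr.SignalTrack(100, {"chr1": np.array([5.0, 10.0, 15.0])}, "raw")
    t2 = rr.SignalTrack(100, {"chr1": np.array([10.0, 20.0, 30.0])}, "raw")
    np.testing.assert_allclose(rpkm_bins(t1).data["chr1"], rpkm_bins(t2).data["chr1"])
    np.testing.assert_allclose(rpm_bins(t1).data["chr1"], rpm_bins(t2).data["chr1"])


def test_zscore_uniform_track_is_zero():
    t = rr.SignalTrack(100, {"chr1": np.full(50, 3.0)}, "raw")
    assert (zscore_track(t).data["chr1"] == 0).all()


def test_zscore_standardizes():
    t = rr.SignalTrack(100, {"chr1": np.arange(10, dtype=float), "chr2": np.ones(5)}, "raw")
    z = zscore_track(t)
    allv = np.concatenate(list(z.data.values()))
    assert allv.mean() == pytest.approx(0, abs=1e-12)
    assert allv.std() == pytest.approx(1, abs=1e-12)


def test_bin_reads_conserves_and_extends():
    track = bin_reads({"chr1": [0, 250]}, {"chr1": 1000}, bin_size=100, extend=100)
    # read at 0 covers bins 0-1; read at 250 covers bins 2-3
    np.testing.assert_array_equal(track.data["chr1"][:4], [1, 1, 1, 1])
    assert track.total_reads == 2


@pytest.mark.parametrize(
    "te_start, te_end, kept",
    [(0, 350, True),      # overlap 250 of width 500 = exactly 50% (boundary inclusive)
     (550, 1000, False)], # overlap 50 of width 500 = 10%
)
def test_overlap_threshold_boundary(te_start, te_end, kept):
    peaks = _peaks([("p1", "chr1", 100, 600, 100, 0.0, "")])  # summit at 200
    te = _te([("L1", "chr1", te_start, te_end, "+", "S", "F")])
    ov = peak_te_overlap(peaks, te, min_frac=0.5, require_summit=True)
    assert (len(ov) == 1) == kept
    if kept:
        assert ov.iloc[0]["overlap_bp"] == 250
        assert ov.iloc[0]["overlap_frac_of_peak"] == pytest.approx(0.5)


def test_overlap_summit_requirement():
    peaks = _peaks([("p1", "chr1", 100, 600, 450, 0.0, "")])  # summit at 550
    te = _te([("L1", "chr1", 0, 350, "+", "S", "F")])         # frac 0.5 but no summit
    assert len(peak_te_overlap(peaks, te, require_summit=True)) == 0
    assert len(peak_te_overlap(peaks, te, require_summit=False)) == 1


def brute_force_overlaps(peaks_df, te_df, min_frac, require_summit):
    rows = []
    for p in peaks_df.itertuples(index=False):
        for t in te_df.itertuples(index=False):
            if p.chrom != t.chrom:
                continue
            ov = min(p.end, t.end) - max(p.start, t.start)
            if ov <= 0:
                continue
            frac = ov / (p.end - p.start)
            summit = p.start + p.summit_offset
            s_in = t.start <= summit < t.end
            if frac >= min_frac and (s_in or not require_summit):
                rows.append((p.peak_id, t.locus_id, ov))
    return sorted(rows)


def test_overlap_matches_brute_force_on_random_intervals(rng):
    n = 300
    peaks_rows = []
    for i in range(n):
        s = int(rng.integers(0, 50_000))
        w = int(rng.integers(50, 800))
        peaks_rows.append((f"p{i}", f"chr{rng.integers(1, 3)}", s, s + w,
                           int(rng.integers(0, w)), 0.0, ""))
    te_rows = []
    for i in range(n):
        s = int(rng.integers(0, 50_000))
        w = int(rng.integers(50, 800))
        te_rows.append((f"L{i}", f"chr{rng.integers(1, 3)}", s, s + w, "+", "S", "F"))
    peaks, te = _peaks(peaks_rows), _te(te_rows)
    for min_frac, summit in [(0.5, True), (0.5, False), (0.25, False)]:
        got = sorted(map(tuple, peak_te_overlap(peaks, te, min_frac, summit)
                         [["peak_id", "locus_id", "overlap_bp"]].to_numpy()))
        assert got == brute_force_overlaps(peaks.df, te.copy(), min_frac, summit)


def test_overlap_translation_invariance(rng):
    peaks = _peaks([("p1", "chr1", 100, 600, 250, 0.0, "")])
    te = _te([("L1", "chr1", 50, 450, "+", "S", "F")])
    base = peak_te_overlap(peaks, te)
    shifted_p = _peaks([("p1", "chrX", 10_100, 10_600, 250, 0.0, "")])
    shifted_t = _te([("L1", "chrX", 10_050, 10_450, "+", "S", "F")])
    shifted = peak_te_overlap(shifted_p, shifted_t)
    assert base["overlap_bp"].tolist() == shifted["overlap_bp"].tolist()


def test_enrichment_null_calibrated(uniform_enrichment_setup):
    """Uniformly placed peaks show no family enrichment (expected >= 200)."""
    enr = uniform_enrichment_setup
    row = enr.table.iloc[0]
    assert row["expected"] >= 200
    assert abs(row["log2_ratio"]) <= 0.2


@pytest.fixture(scope="module")
def uniform_enrichment_setup():
    spec = rr.GenomeSpec(n_chroms=1, chrom_len=1_000_000, n_genes=5, n_kznf=1,
                         families={"LTR12": (1, 600, 500)})
    ann = rr.make_genome(spec, seed=2)
    rng = np.random.default_rng(8)
    rows = []
    for i in range(1000):
        s = int(rng.integers(0, 1_000_000 - 200))
        rows.append((f"p{i}", "chr1", s, s + 200, 100, 0.0, ""))
    peaks = _peaks(rows)
    return family_enrichment(peaks, ann, n_draws=100, seed=3)


def test_enrichment_detects_planted_concentration(small_genome):
    """Peaks planted on one family's loci give a large positive log2 ratio."""
    fam_loci = small_genome.te_loci[small_genome.te_loci["family"] == "LTR12"].head(40)
    rows = [(f"pk{i}", r.chrom, r.start, r.end, (r.end - r.start) // 2, 0.0, "")
            for i, r in enumerate(fam_loci.itertuples(index=False))]
    enr = family_enrichment(_peaks(rows), small_genome, n_draws=99, seed=4)
    row = enr.table.loc["LTR12"]
    assert row["log2_ratio"] >= 1.5
    assert row["p_enrich"] == pytest.approx(1 / 100)


def test_enrichment_peak_too_wide_errors(small_genome):
    peaks = _peaks([("p1", "chr1", 0, 900_000, 100, 0.0, "")])
    pk = rr.PeakSet(peaks.df.assign(end=2_000_000))
    with pytest.raises(ValueError, match="wider"):
        family_enrichment(pk, small_genome, n_draws=1, seed=0)


def test_metaprofile_flat_track_and_spike():
    sizes = {"chr1": 100_000}
    loci = _te([("L1", "chr1", 20_000, 20_500, "+", "S", "F"),
                ("L2", "chr1", 60_000, 60_500, "-", "S", "F")])
    flat = rr.SignalTrack(100, {"chr1": np.ones(1000)}, "RPM")
    prof = metaprofile({"g": flat}, loci, window=5000, bin_size=100)
    assert prof.shape == (1, 101)
    np.testing.assert_allclose(prof.loc["g"], 1.0)

    spike = np.zeros(1000)
    spike[200] = spike[600] = 50.0  # bins containing each locus start
    tr = rr.SignalTrack(100, {"chr1": spike}, "RPM")
    prof2 = metaprofile({"g": tr}, loci, window=5000, bin_size=100)
    assert prof2.columns[prof2.loc["g"].argmax()] == 0  # anchor bin


def test_metaprofile_matches_brute_force(rng):
    sizes = {"chr1": 50_000}
    vals = rng.random(500)
    track = rr.SignalTrack(100, {"chr1": vals}, "RPM")
    starts = [7_130, 21_055, 43_990]   # not bin-aligned; last one truncated at 5 kb
    loci = _te([(f"L{i}", "chr1", s, s + 400, "+", "S", "F")
                for i, s in enumerate(starts)])
    window, bin_size = 5000, 100
    prof = metaprofile({"g": track}, loci, window=window, bin_size=bin_size)

    offs = np.arange(-window, window + bin_size, bin_size)
    expected = []
    for off in offs:
        acc = []
        for s in starts:
            lo = s + off
            bps = np.arange(lo, lo + bin_size)
            ok = (bps >= 0) & (bps < 50_000)
            if ok.any():
                v = np.where(ok, vals[np.clip(bps, 0, 49_999) // 100], np.nan)
                acc.append(np.nanmean(v))
        expected.append(np.nanmean(acc))
    np.testing.assert_allclose(prof.loc["g"].to_numpy(), expected, rtol=1e-10)


def test_metaprofile_empty_family_errors():
    track = rr.SignalTrack(100, {"chr1": np.ones(10)}, "RPM")
    with pytest.raises(ValueError, match="loci"):
        metaprofile({"g": track}, _te([]), window=500, bin_size=100)


def test_family_accessibility_by_cluster():
    loci = _te([("L1", "chr1", 100, 300, "+", "S", "F")])
    mk = lambda level: rr.SignalTrack(100, {"chr1": np.full(10, level)}, "RPM")
    tracks = {"s1": mk(1.0), "s2": mk(3.0), "s3": mk(5.0)}
    labels = pd.Series({"s1": 1, "s2": 1, "s3": 2, "s4": 3})
    out = family_accessibility_by_cluster(tracks, loci, labels)
    assert out.loc[1, "mean"] == pytest.approx(2.0)
    assert out.loc[2, "mean"] == pytest.approx(5.0)
    assert np.isnan(out.loc[3, "mean"])     # cluster without ATAC samples
    assert out.loc[2, "n"] == 1             # single-sample cluster mean = sample mean
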