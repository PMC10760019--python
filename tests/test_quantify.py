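"""EM abundance estimation, TPM, family aggregation, log/z scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import retroregulon as rr
from retroregulon.quantify import em_quantify, tpm_normalize, aggregate_families, log_zscale


def grid_mle_two_features(classes, lengths, n_grid=200_001):
    """Brute-force maximizer of the class multinomial likelihood for 2 features.

    Scans the read-generation probability of feature A on a dense grid;
    returns expected counts at the optimum (independent of the EM path).
    """
    feats = sorted(lengths)
    a, b = feats
    p = np.linspace(0.0, 1.0, n_grid)
    ll = np.zeros_like(p)
    for fs, n in classes:
        fs = set(fs)
        if fs == {a}:
            q = p
        elif fs == {b}:
            q = 1 - p
        else:
            q = np.ones_like(p)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll += n * np.log(q)
    ll[np.isnan(ll)] = -np.inf
    p_hat = p[np.argmax(ll)]
    total = sum(n for _, n in classes)
    exp = {a: 0.0, b: 0.0}
    for fs, n in classes:
        fs = set(fs)
        if fs == {a}:
            exp[a] += n
        elif fs == {b}:
            exp[b] += n
        else:
            denom = p_hat + (1 - p_hat)
            exp[a] += n * p_hat / denom
            exp[b] += n * (1 - p_hat) / denom
    return exp, total


@pytest.mark.parametrize(
    "classes, expected",
    [
        ([({"A"}, 50), ({"B"}, 0), ({"A", "B"}, 50)], {"A": 100.0, "B": 0.0}),
        ([({"A"}, 30), ({"B"}, 30), ({"A", "B"}, 40)], {"A": 50.0, "B": 50.0}),
    ],
)
def test_em_matches_brute_force_grid_mle(classes, expected):
    lengths = {"A": 1000, "B": 1000}
    res = em_quantify(classes, lengths, tol=1e-12, max_iter=10_000)
    oracle, _ = grid_mle_two_features(classes, lengths)
    for f in ("A", "B"):
        assert res.counts[f] == pytest.approx(expected[f], abs=1e-5)
        assert res.counts[f] == pytest.approx(oracle[f], abs=1e-3)


def test_em_no_ambiguity_equals_proportional_estimate():
    res = em_quantify([({"A"}, 90), ({"B"}, 10)], {"A": 1000, "B": 1000})
    assert res.tpm["A"] == pytest.approx(900_000, rel=1e-9)
    assert res.tpm["B"] == pytest.approx(100_000, rel=1e-9)
    assert res.n_iter <= 2


def test_em_likelihood_non_decreasing_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n_feat = int(rng.integers(2, 8))
        feats = [f"F{i}" for i in range(n_feat)]
        lengths = {f: float(rng.integers(200, 3000)) for f in feats}
        classes = []
        for _ in range(int(rng.integers(2, 10))):
            size = int(rng.integers(1, n_feat + 1))
            members = rng.choice(feats, size=size, replace=False)
            classes.append((set(members.tolist()), int(rng.integers(0, 500))))
        res = em_quantify(classes, lengths)
        diffs = np.diff(res.log_likelihood)
        assert (diffs >= -1e-8 * np.maximum(1, np.abs(res.log_likelihood[:-1]))).all()
        total = sum(n for _, n in classes)
        assert res.counts.sum() == pytest.approx(total, rel=1e-9, abs=1e-9)


def test_em_errors():
    with pytest.raises(ValueError, match="empty"):
        em_quantify([(set(), 10)], {"A": 100})
    with pytest.raises(ValueError, match="length"):
        em_quantify([({"A"}, 10)], {"A": 0})


def test_tpm_hand_arithmetic_and_single_feature():
    counts = pd.DataFrame({"s": [10.0, 10.0]}, index=["a", "b"])
    tpm = tpm_normalize(counts, {"a": 100, "b": 200})
    assert tpm.values.loc["a", "s"] == pytest.approx(666_666.6667, rel=1e-6)
    assert tpm.values.loc["b", "s"] == pytest.approx(333_333.3333, rel=1e-6)
    one = tpm_normalize(pd.DataFrame({"s": [7.0]}, index=["a"]), {"a": 500})
    assert one.values.loc["a", "s"] == pytest.approx(1e6)


def test_tpm_columns_sum_to_million_random(rng):
    counts = pd.DataFrame(rng.integers(0, 1000, size=(30, 5)).astype(float),
                          index=[f"f{i}" for i in range(30)])
    counts.iloc[:, 0] += 1  # ensure non-zero first column
    lengths = pd.Series(rng.integers(200, 5000, size=30), index=counts.index)
    tpm = tpm_normalize(counts, lengths)
    nonzero = tpm.values.sum(axis=0) > 0
    np.testing.assert_allclose(tpm.values.sum(axis=0)[nonzero], 1e6, rtol=1e-9)


def test_tpm_zero_column_warns_not_errors(caplog):
    counts = pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.0, 0.0]}, index=["a", "b"])
    tpm = tpm_normalize(counts, {"a": 100, "b": 100})
    assert (tpm.values["s2"] == 0).all()


def test_aggregate_families_mean_and_bounds(rng):
    vals = pd.DataFrame(rng.random(size=(6, 4)) * 100,
                        index=[f"L{i}" for i in range(6)])
    meta = pd.DataFrame({
        "kind": "te_locus", "length": 500,
        "family": ["FAM1"] * 3 + ["FAM2"] * 2 + ["FAM3"],
    }, index=vals.index)
    mat = rr.AbundanceMatrix(vals, unit="TPM", feature_meta=meta)
    fam = aggregate_families(mat)
    np.testing.assert_allclose(fam.values.loc["FAM1"], vals.iloc[:3].mean(axis=0))
    # one-locus family equals the locus row
    np.testing.assert_allclose(fam.values.loc["FAM3"], vals.iloc[5])
    # mean bounded by member loci
    for f, members in (("FAM1", vals.iloc[:3]), ("FAM2", vals.iloc[3:5])):
        assert (fam.values.loc[f] >= members.min(axis=0) - 1e-12).all()
        assert (fam.values.loc[f] <= members.max(axis=0) + 1e-12).all()


def test_aggregate_example_values():
    vals = pd.DataFrame({"s": [2.0, 4.0, 6.0]}, index=["a", "b", "c"])
    meta = pd.DataFrame({"kind": "te_locus", "length": 1, "family": "F"}, index=vals.index)
    fam = aggregate_families(rr.AbundanceMatrix(vals, unit="TPM", feature_meta=meta))
    assert fam.values.loc["F", "s"] == pytest.approx(4.0)


def test_aggregate_missing_family_errors():
    vals = pd.DataFrame({"s": [1.0]}, index=["a"])
    meta = pd.DataFrame({"kind": "te_locus", "length": 1, "family": [None]}, index=vals.index)
    with pytest.raises(ValueError, match="family"):
        aggregate_families(rr.AbundanceMatrix(vals, unit="TPM", feature_meta=meta))


def test_log_zscale_rows_standardized(toy_matrix):
    mat = rr.AbundanceMatrix(toy_matrix, unit="TPM")
    z = log_zscale(mat)
    np.testing.assert_allclose(z.values.mean(axis=1), 0, atol=1e-12)
    np.testing.assert_allclose(z.values.std(axis=1, ddof=0), 1, atol=1e-12)


def test_log_zscale_constant_row_and_pseudocount():
    vals = pd.DataFrame({"s1": [0.0, 5.0], "s2": [0.0, 9.0]}, index=["zero", "var"])
    z = log_zscale(rr.AbundanceMatrix(vals, unit="TPM"))
    assert (z.values.loc["zero"] == 0).all()  # log2(0+1)=0 everywhere -> z 0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 10_000), min_size=2, max_size=8))
def test_tpm_scale_invariance(counts):
    """Multiplying a column by a constant leaves its TPM unchanged."""
    if sum(counts) == 0:
        counts[0] = 1
    idx = [f"f{i}" for i in range(len(counts))]
    lengths = {f: 100 * (i + 1) for i, f in enumerate(idx)}
    c1 = pd.DataFrame({"s": np.array(counts, dtype=float)}, index=idx)
    c2 = c1 * 7.0
    t1 = tpm_normalize(c1, lengths).values
    t2 = tpm_normalize(c2, lengths).values
    np.testing.assert_allclose(t1, t2, rtol=1e-9)
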