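"""Abundance estimation and normalization.

Multi-mapping reads are summarized as equivalence classes: each class is
the set of features (gene transcripts or TE loci) a read is equally
compatible with, together with the number of reads in the class. The EM
estimator maximizes the class multinomial likelihood

    L(theta) = prod_c ( sum_{f in c} theta_f * l_f / Z )^{n_c},
    Z = sum_g theta_g * l_g,

where theta_f is the molar (transcript-fraction) abundance of feature f
and l_f its length: the probability that a read originates from f is
proportional to theta_f * l_f. TPM is theta scaled to sum to 1e6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import AbundanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class EMResult:
    """Per-feature output of :func:`em_quantify`."""

    counts: pd.Series        # expected read counts, sums to total reads
    tpm: pd.Series           # 1e6 * theta
    theta: pd.Series         # molar abundance fractions (sum 1)
    n_iter: int
    log_likelihood: np.ndarray  # per-iteration class multinomial log-likelihood


def em_quantify(
    classes: Sequence[Tuple],
    lengths: Mapping[str, float],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> EMResult:
    """Resolve ambiguous equivalence-class counts by expectation-maximization.

    Parameters
    ----------
    classes
        Sequence of ``(feature_set, count)``; ``feature_set`` is any
        iterable of feature IDs, ``count`` a non-negative read count.
    lengths
        Feature -> effective length in bp (annotated length; no
        fragment-length correction).
    tol
        Convergence threshold on ``max |delta theta|``.

    Returns
    -------
    EMResult with expected counts (summing to the total input reads),
    TPM, the molar abundances theta, and the log-likelihood trace (which
    is non-decreasing up to floating-point round-off).
    """
    feats = sorted(lengths)
    if not feats:
        raise ValueError("no features supplied")
    ell = np.array([float(lengths[f]) for f in feats])
    if (ell <= 0).any():
        raise ValueError("feature with non-positive length")
    fidx = {f: i for i, f in enumerate(feats)}

    memb, counts = [], []
    for fs, n in classes:
        members = [fidx[f] for f in fs]
        if not members:
            raise ValueError("empty equivalence class")
        if n < 0:
            raise ValueError("negative class count")
        memb.append(np.array(members, dtype=int))
        counts.append(float(n))
    counts = np.array(counts)
    total = counts.sum()

    nF = len(feats)
    theta = np.full(nF, 1.0 / nF)
    ll_trace = []
    n_iter = 0
    expected = np.zeros(nF)
    for n_iter in range(1, max_iter + 1):
        w = theta * ell                       # read-generation weights
        w = w / w.sum()
        expected[:] = 0.0
        ll = 0.0
        for members, n in zip(memb, counts):
            pc = w[members].sum()
            if pc > 0:
                expected[members] += n * w[members] / pc
                if n > 0:
                    ll += n * np.log(pc)
            elif n > 0:
                ll = -np.inf
        ll_trace.append(ll)
        with np.errstate(invalid="ignore"):
            new_theta = np.where(ell > 0, expected / ell, 0.0)
        s = new_theta.sum()
        new_theta = new_theta / s if s > 0 else np.full(nF, 1.0 / nF)
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        if delta < tol:
            break

    tpm = pd.Series(theta * 1e6, index=feats)
    cts = pd.Series(expected, index=feats)
    if total > 0:  # conservation up to round-off
        cts *= total / cts.sum()
    return EMResult(counts=cts, tpm=tpm, theta=pd.Series(theta, index=feats),
                    n_iter=n_iter, log_likelihood=np.array(ll_trace))


def tpm_normalize(counts, lengths) -> AbundanceMatrix:
    """Transcripts-per-million: ``(c/l) / sum_g(c_g/l_g) * 1e6`` per sample.

    ``counts`` is a features x samples DataFrame or counts-unit
    AbundanceMatrix; all-zero columns stay zero with a logged warning.
    """
    meta = None
    if isinstance(counts, AbundanceMatrix):
        meta = counts.feature_meta
        counts = counts.values
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any():
        raise ValueError(f"missing length for {lengths.index[lengths.isna()][0]!r}")
    if (lengths <= 0).any():
        raise ValueError("non-positive feature length")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        logger.warning("all-zero column(s) in TPM normalization: %s", list(counts.columns[zero]))
        denom = denom.replace(0, 1.0)
    tpm = rate.div(denom, axis=1) * 1e6
    return AbundanceMatrix(tpm, unit="TPM", feature_meta=meta)


def aggregate_families(matrix: AbundanceMatrix, method: str = "mean") -> AbundanceMatrix:
    """Aggregate TE locus rows to family level.

    ``method='mean'`` averages member-locus values on the input scale
    (expression-scale mean); ``method='log_mean'`` averages
    log2(x + 1) and transforms back, for callers preferring a
    geometric-flavoured summary.
    """
    if matrix.feature_meta is None or "family" not in matrix.feature_meta.columns:
        raise ValueError("feature_meta with a 'family' column is required")
    fam = matrix.feature_meta["family"]
    if fam.isna().any():
        raise ValueError(f"locus without family: {fam.index[fam.isna()][0]!r}")
    if method == "mean":
        agg = matrix.values.groupby(fam).mean()
    elif method == "log_mean":
        agg = np.exp2(np.log2(matrix.values + 1).groupby(fam).mean()) - 1
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    agg.index.name = None
    meta = pd.DataFrame(
        {"kind": "te_family", "length": np.nan, "family": agg.index}, index=agg.index
    )
    return AbundanceMatrix(agg, unit=matrix.unit, feature_meta=meta)


def log_zscale(matrix: AbundanceMatrix, pseudocount: float = 1.0) -> AbundanceMatrix:
    """log2(x + pseudocount), then per-feature z-score across samples.

    Constant features get z = 0 everywhere.
    """
    if (matrix.values.values < 0).any():
        raise ValueError("negative values cannot be log-scaled")
    lg = np.log2(matrix.values + pseudocount)
    mu = lg.mean(axis=1)
    sd = lg.std(axis=1, ddof=0)
    z = lg.sub(mu, axis=0).div(sd.replace(0, 1.0), axis=0)
    return AbundanceMatrix(z, unit="zscore", feature_meta=matrix.feature_meta)
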