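"""Synthetic genomes, counts, read classes, peaks and signal with ground truth.

The simulators emulate the statistical structure the downstream analysis
assumes — negative-binomial counts with group/cluster structure and
planted differential features, a shared latent factor coupling each
planted KZNF positively and its target TE family's loci negatively
(yielding a monotone negative association suitable for rank
correlation), equivalence-class read ambiguity among loci, and binned
Poisson accessibility signal with planted accessible TE loci near
planted upregulated genes. Every simulator is a pure function of its
inputs and seed and returns the planted truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import AbundanceMatrix, GenomeAnnotation, PeakSet, SignalTrack, TruthTable

SUBTYPES = ["naive", "CM", "EM", "TM", "total"]


# ------------------------------------------------------------ design

@dataclass
class PlantedEffect:
    """A differential feature: lfc applied in one group or one cluster."""

    feature: str
    lfc: float
    group: Optional[str] = None
    cluster: Optional[int] = None


@dataclass
class KznfPlant:
    """A planted repressor-target pair with a target rank correlation."""

    kznf: str
    family: str
    rho: float = -0.7


@dataclass
class AccessiblePlant:
    """A TE locus made more accessible (log2 fold) in one group, near a gene."""

    locus_id: str
    lfc: float
    gene_id: str
    group: str = "EC"


@dataclass
class DesignSpec:
    """Study design for the simulators: groups, noise, and planted structure."""

    n_samples: dict = field(default_factory=lambda: {"EC": 4, "HC": 5})
    nb_dispersion: float = 0.1
    library_sizes: Optional[Mapping[str, float]] = None
    base_log_mean: float = float(np.log(100.0))
    base_log_sigma: float = 1.0
    planted_de: Sequence[PlantedEffect] = field(default_factory=list)
    planted_cluster_labels: Optional[Mapping[str, int]] = None
    planted_kznf_pairs: Sequence[KznfPlant] = field(default_factory=list)
    planted_accessible_te: Sequence[AccessiblePlant] = field(default_factory=list)
    # accessibility-signal parameters
    atac_bin: int = 100
    atac_baseline_rate: float = 2.0        # reads per 100-bp bin
    atac_peak_rate_factor: float = 4.0     # elevation inside non-differential peaks
    atac_depth: Optional[Mapping[str, float]] = None
    n_background_peaks: int = 50
    peak_width_median: float = 400.0
    peak_width_sigma: float = 0.4
    cohorts: Sequence[str] = ("cohortA", "cohortB")

    def samples(self) -> pd.Series:
        """Sample -> group labels, samples named ``<group><index>``."""
        labels = {}
        for g, n in self.n_samples.items():
            for i in range(n):
                labels[f"{g}{i + 1:03d}"] = g
        return pd.Series(labels, name="group")

    def metadata(self, seed: int = 0) -> pd.DataFrame:
        """Sample metadata (group, subtype, cohort); subtype and cohort are
        assigned at random, orthogonally to any planted clusters."""
        rng = np.random.default_rng(seed)
        labels = self.samples()
        return pd.DataFrame({
            "group": labels,
            "subtype": rng.choice(SUBTYPES, size=len(labels)),
            "cohort": rng.choice(list(self.cohorts), size=len(labels)),
        }, index=labels.index).rename_axis("sample_id")


def clustered_design(
    group: str = "EC",
    n_samples: int = 128,
    n_clusters: int = 4,
    markers_per_cluster: int = 25,
    lfc: float = 2.0,
    nb_dispersion: float = 0.1,
    marker_prefix: str = "GENE",
) -> DesignSpec:
    """Design with planted sample clusters and per-cluster marker genes.

    Samples are split round-robin into ``n_clusters`` clusters; markers
    are named ``<marker_prefix><i>`` and must exist in the annotation
    passed to :func:`simulate_counts`.
    """
    design = DesignSpec(n_samples={group: n_samples}, nb_dispersion=nb_dispersion)
    labels = {s: (i % n_clusters) + 1 for i, s in enumerate(design.samples().index)}
    design.planted_cluster_labels = labels
    planted = []
    f = 1
    for c in range(1, n_clusters + 1):
        for _ in range(markers_per_cluster):
            planted.append(PlantedEffect(f"{marker_prefix}{f:04d}", lfc, cluster=c))
            f += 1
    design.planted_de = planted
    return design


# ------------------------------------------------------------ genome

@dataclass
class GenomeSpec:
    """Shape of the synthetic genome and its TE / gene complement."""

    n_chroms: int = 1
    chrom_len: int = 1_000_000
    families: Mapping[str, tuple] = field(
        default_factory=lambda: {"LTR12": (2, 100, 500), "MER41": (2, 100, 500)}
    )  # family -> (n_subfamilies, n_loci, locus_len)
    n_genes: int = 100
    n_kznf: int = 10


def make_genome(spec: GenomeSpec, seed: int = 0) -> GenomeAnnotation:
    """Place TE loci (non-overlapping within a family) and gene TSSs uniformly."""
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": spec.chrom_len for i in range(spec.n_chroms)}
    genome_bp = spec.n_chroms * spec.chrom_len
    placed_bp = sum(n * L for _, n, L in spec.families.values())
    if placed_bp >= 0.5 * genome_bp:
        raise ValueError(
            f"requested {placed_bp} TE bp on a {genome_bp} bp genome; "
            "use a larger genome or fewer/shorter loci"
        )
    chroms = list(chrom_sizes)
    rows = []
    lid = 0
    for fam, (n_sub, n_loci, locus_len) in spec.families.items():
        trees = {c: IntervalTree() for c in chroms}
        placed = 0
        attempts = 0
        max_attempts = 200 * max(n_loci, 1)
        while placed < n_loci:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"could not place {n_loci} non-overlapping {fam} loci; "
                    "use a larger genome"
                )
            c = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, chrom_sizes[c] - locus_len))
            if trees[c].overlaps(start, start + locus_len):
                continue
            trees[c].addi(start, start + locus_len)
            lid += 1
            sub = f"{fam}_{(placed % n_sub) + 1}" if n_sub > 1 else fam
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"{fam}_L{lid:05d}", c, start, start + locus_len, strand, sub, fam))
            placed += 1
    te = pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end", "strand", "subfamily", "family"])

    grows = []
    for i in range(spec.n_genes + spec.n_kznf):
        c = chroms[int(rng.integers(len(chroms)))]
        tss = int(rng.integers(0, chrom_sizes[c]))
        strand = "+" if rng.random() < 0.5 else "-"
        if i < spec.n_genes:
            gid, klass = f"GENE{i + 1:04d}", "gene"
        else:
            gid, klass = f"ZNF{i - spec.n_genes + 1:03d}", "kznf"
        grows.append((gid, c, tss, strand, klass))
    genes = pd.DataFrame(grows, columns=["gene_id", "chrom", "tss", "strand", "gene_class"])
    return GenomeAnnotation(chrom_sizes=chrom_sizes, te_loci=te, genes=genes)


def add_linked_genes(
    annotation: GenomeAnnotation,
    n_links: int,
    seed: int = 0,
    max_offset: int = 5_000,
) -> tuple:
    """Relocate ``n_links`` gene TSSs to within ``max_offset`` of distinct TE loci.

    Used to plant cis-regulatory TE-gene geometry: each chosen gene's
    TSS is moved next to a distinct TE locus so the 10 kb linking window
    is satisfiable by construction. Returns ``(annotation, links)``
    where links has columns locus_id, gene_id.
    """
    rng = np.random.default_rng(seed)
    te = annotation.te_loci
    genes = annotation.genes.copy()
    ordinary = genes.index[genes["gene_class"] == "gene"]
    if n_links > min(len(te), len(ordinary)):
        raise ValueError("not enough TE loci or genes to plant the requested links")
    loci = te.iloc[rng.choice(len(te), size=n_links, replace=False)]
    gene_rows = rng.choice(ordinary.to_numpy(), size=n_links, replace=False)
    links = []
    for (_, locus), gi in zip(loci.iterrows(), gene_rows):
        offset = int(rng.integers(50, max_offset))
        tss = min(locus["end"] + offset, annotation.chrom_sizes[locus["chrom"]] - 1)
        genes.loc[gi, ["chrom", "tss"]] = [locus["chrom"], tss]
        links.append((locus["locus_id"], genes.loc[gi, "gene_id"]))
    ann = GenomeAnnotation(annotation.chrom_sizes, annotation.te_loci, genes)
    return ann, pd.DataFrame(links, columns=["locus_id", "gene_id"])


# ------------------------------------------------------------ counts

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(float)


def simulate_counts(
    annotation: GenomeAnnotation,
    design: DesignSpec,
    seed: int = 0,
) -> tuple:
    """Negative-binomial gene + TE-locus counts with planted structure.

    ``counts_fs ~ NB(mean = base_f * lib_s * 2^{lfc if s affected} *
    latent adjustments, dispersion)``. Each planted KZNF-TE pair shares
    a per-sample standard-normal latent factor entering the KZNF mean as
    ``exp(+beta z)`` and every locus of the target family as
    ``exp(-beta z)``; beta is chosen from the target correlation
    magnitude ``|r|`` as ``beta = |r| * sqrt(v / (1 - r^2))`` with v the
    approximate log-scale noise variance of the KZNF.

    Returns ``(AbundanceMatrix(counts), TruthTable)``.
    """
    rng = np.random.default_rng(seed)
    labels = design.samples()
    samples = list(labels.index)
    te = annotation.te_loci
    feats = list(annotation.genes["gene_id"]) + list(te["locus_id"])
    kinds = ["gene"] * len(annotation.genes) + ["te_locus"] * len(te)
    lengths = [1000.0] * len(annotation.genes) + list((te["end"] - te["start"]).astype(float))
    fam = [None] * len(annotation.genes) + list(te["family"])
    meta = pd.DataFrame({"kind": kinds, "length": lengths, "family": fam}, index=feats)

    base = rng.lognormal(design.base_log_mean, design.base_log_sigma, size=len(feats))
    lib = np.array([
        (design.library_sizes or {}).get(s, 1.0) for s in samples
    ])
    log2mu = np.log2(base)[:, None] + np.log2(lib)[None, :]

    fidx = {f: i for i, f in enumerate(feats)}
    clusters = design.planted_cluster_labels or {}
    de_rows = []
    for eff in design.planted_de:
        if eff.feature not in fidx:
            raise ValueError(f"planted feature {eff.feature!r} not in annotation")
        if eff.group is not None:
            mask = np.array([labels[s] == eff.group for s in samples])
            target = eff.group
        else:
            mask = np.array([clusters.get(s) == eff.cluster for s in samples])
            target = f"cluster:{eff.cluster}"
        log2mu[fidx[eff.feature], mask] += eff.lfc
        de_rows.append((eff.feature, eff.lfc, target))

    kz_rows = []
    fam_arr = np.array([f if f is not None else "" for f in fam])
    for plant in design.planted_kznf_pairs:
        if plant.kznf not in fidx:
            raise ValueError(f"planted KZNF {plant.kznf!r} not in annotation")
        members = np.where(fam_arr == plant.family)[0]
        if len(members) == 0:
            raise ValueError(f"planted family {plant.family!r} has no loci")
        r = abs(plant.rho)
        ki = fidx[plant.kznf]
        v = design.nb_dispersion + 1.0 / base[ki]
        beta = r * np.sqrt(v / max(1e-9, 1.0 - r ** 2))
        z = rng.standard_normal(len(samples))
        log2mu[ki] += beta * z / np.log(2)
        log2mu[members] -= beta * z[None, :] / np.log(2)
        kz_rows.append((plant.kznf, plant.family, plant.rho, beta))

    mu = np.exp2(log2mu)
    counts = _nb_draw(rng, mu, design.nb_dispersion)
    mat = AbundanceMatrix(
        pd.DataFrame(counts, index=feats, columns=samples), unit="counts", feature_meta=meta
    )
    group_means = pd.DataFrame({
        g: counts[:, [i for i, s in enumerate(samples) if labels[s] == g]].mean(axis=1)
        for g in design.n_samples
    }, index=feats)
    truth = TruthTable(
        de=pd.DataFrame(de_rows, columns=["feature", "lfc", "target"]),
        cluster_labels=pd.Series(clusters) if clusters else None,
        kznf_pairs=pd.DataFrame(kz_rows, columns=["kznf", "family", "target_rho", "beta"]),
        group_means=group_means,
    )
    return mat, truth


# ------------------------------------------------------------ read classes

def simulate_read_classes(
    true_props: Mapping[str, float],
    ambiguity: Mapping[str, Sequence[str]],
    n_reads: int,
    seed: int = 0,
    class_weights: Optional[Mapping[str, float]] = None,
) -> list:
    """Draw reads from per-feature proportions and report equivalence classes.

    Each read's source feature is drawn from ``true_props``; the read is
    assigned to one of the classes containing its source (uniformly, or
    proportionally to ``class_weights`` when given). Emitted class
    counts always sum to ``n_reads``.

    Returns ``[(frozenset(features), count), ...]`` in class order.
    """
    feats = list(true_props)
    props = np.array([true_props[f] for f in feats], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("true proportions must sum to 1")
    class_ids = list(ambiguity)
    members = {c: frozenset(ambiguity[c]) for c in class_ids}
    containing = {f: [c for c in class_ids if f in members[c]] for f in feats}
    for f, cs in containing.items():
        if not cs:
            raise ValueError(f"feature {f!r} absent from every class")

    rng = np.random.default_rng(seed)
    source = rng.multinomial(n_reads, props)
    counts = {c: 0 for c in class_ids}
    for f, n_f in zip(feats, source):
        if n_f == 0:
            continue
        cs = containing[f]
        if len(cs) == 1:
            counts[cs[0]] += int(n_f)
            continue
        w = np.array([(class_weights or {}).get(c, 1.0) for c in cs], dtype=float)
        split = rng.multinomial(int(n_f), w / w.sum())
        for c, k in zip(cs, split):
            counts[c] += int(k)
    return [(members[c], counts[c]) for c in class_ids]


# ------------------------------------------------------------ ATAC

def _peak_frame(rows) -> PeakSet:
    return PeakSet(pd.DataFrame(
        rows, columns=["peak_id", "chrom", "start", "end", "summit_offset", "score", "sample_or_group"]
    ))


def simulate_atac(
    annotation: GenomeAnnotation,
    design: DesignSpec,
    seed: int = 0,
) -> tuple:
    """Peaks per group and per-sample binned Poisson signal with planted loci.

    Background peaks are placed uniformly (log-normal widths, median
    ``peak_width_median``) and carry elevated signal in every sample;
    each planted accessible TE locus becomes a peak spanning the locus
    (summit at its center) in the planted group's peak set, with signal
    elevated by ``2^lfc`` in that group only. Per-sample depth scales
    every Poisson rate; depth 0 gives an all-zero track.

    Returns ``(peaks_by_group, tracks_by_sample, TruthTable)``.
    """
    rng = np.random.default_rng(seed)
    labels = design.samples()
    B = design.atac_bin
    chrom_sizes = annotation.chrom_sizes
    te_by_id = annotation.te_loci.set_index("locus_id")
    tss_by_id = annotation.genes.set_index("gene_id")["tss"]

    planted_rows = []
    for plant in design.planted_accessible_te:
        if plant.locus_id not in te_by_id.index:
            raise ValueError(f"planted locus {plant.locus_id!r} not in annotation")
        if plant.gene_id not in tss_by_id.index:
            raise ValueError(f"planted gene {plant.gene_id!r} not in annotation")
        loc = te_by_id.loc[plant.locus_id]
        t = tss_by_id[plant.gene_id]
        if max(loc["start"] - t, t - loc["end"], 0) > 10_000:
            raise ValueError(
                f"planted link {plant.locus_id}-{plant.gene_id}: TSS farther than 10 kb"
            )
        width = int(loc["end"] - loc["start"])
        planted_rows.append((
            f"peak_{plant.locus_id}", loc["chrom"], int(loc["start"]), int(loc["end"]),
            width // 2, 10.0, plant.group,
        ))

    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    peaks_by_group = {}
    bg_union = []
    for g in design.n_samples:
        rows = []
        for i in range(design.n_background_peaks):
            w = int(np.clip(rng.lognormal(np.log(design.peak_width_median),
                                          design.peak_width_sigma), 150, 2000))
            probs = np.maximum(sizes - w + 1, 0)
            ci = int(rng.choice(len(chroms), p=probs / probs.sum()))
            start = int(rng.integers(0, int(sizes[ci]) - w + 1))
            rows.append((f"{g}_bg{i + 1:04d}", chroms[ci], start, start + w, w // 2, 1.0, g))
        bg_union.extend(rows)
        rows_g = rows + [r for r in planted_rows if r[6] == g]
        peaks_by_group[g] = _peak_frame(rows_g)

    # per-bin Poisson rates: baseline, elevated in background peaks everywhere,
    # elevated by 2^lfc in planted peaks for the planted group only
    base_rate = {c: np.full(int(np.ceil(L / B)), design.atac_baseline_rate)
                 for c, L in chrom_sizes.items()}
    for _, chrom, start, end, *_ in bg_union:
        base_rate[chrom][start // B:(end - 1) // B + 1] = (
            design.atac_baseline_rate * design.atac_peak_rate_factor
        )

    tracks = {}
    truth_rows = []
    for s in labels.index:
        depth = (design.atac_depth or {}).get(s, 1.0)
        rate = {c: v * depth for c, v in base_rate.items()}
        for plant, row in zip(design.planted_accessible_te, planted_rows):
            _, chrom, start, end, *_ = row
            lo, hi = start // B, (end - 1) // B + 1
            factor = 2.0 ** plant.lfc if labels[s] == plant.group else 1.0
            rate[chrom][lo:hi] = design.atac_baseline_rate * design.atac_peak_rate_factor * depth * factor
        data = {c: rng.poisson(v).astype(float) for c, v in rate.items()}
        tr = SignalTrack(B, data, "raw")
        tr.total_reads = tr.total()
        tracks[s] = tr

    for plant, row in zip(design.planted_accessible_te, planted_rows):
        truth_rows.append((plant.locus_id, plant.lfc, plant.gene_id, row[0], plant.group))
    truth = TruthTable(accessible_te=pd.DataFrame(
        truth_rows, columns=["locus_id", "lfc", "gene_id", "peak_id", "group"]
    ))
    return peaks_by_group, tracks, truth
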