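# Methods

This note documents the models, defaults and design choices behind
`retroregulon`, and what the synthetic-data tests do and do not
establish about real data.

## Combined gene + TE quantification

Genes and TE loci form one feature universe. Sequencing ambiguity is
represented at the equivalence-class level: a class is the set of
features a read is equally compatible with, with a count. The EM
estimator maximizes the class multinomial likelihood in the molar
abundance parameters θ (transcript fractions): the probability a read
originates from feature f is proportional to θ_f·ℓ_f, so the E-step
splits each class count across its members by θ_f·ℓ_f and the M-step
sets θ_f ∝ n̂_f/ℓ_f. This parameterization is the one under which the
class likelihood is guaranteed non-decreasing per iteration (asserted in
tests on random instances); with equal lengths it reduces to splitting
by current estimated counts. Settings: uniform initialization, tolerance
1e-8 on max |Δθ|, max 1000 iterations. Effective length equals annotated
length — no fragment-length correction; this is adequate for the
locus-level TE model but a known simplification for short features.

TPM is computed per sample as (c/ℓ)/Σ(c/ℓ)·10⁶. Family-level expression
defaults to the arithmetic mean of member-locus values in the input unit
(expression-scale mean); a log-space mean is selectable
(`method="log_mean"`) since either reading of "average family
expression" is defensible. Scaling for clustering is log₂(x+1) followed
by per-feature z-scoring; constant features get z = 0.

## Rank-based differential testing

Two-group contrasts use the two-sided Mann–Whitney test: exact null
enumeration when n_A+n_B ≤ 12 and the data are tie-free, otherwise the
normal approximation with tie and continuity correction. Fold changes
are log₂ of pseudocounted (default 1 TPM) group means, avoiding
infinities at zero expression. Cluster markers use one-vs-rest
Kruskal–Wallis (equivalent on two groups to the squared standardized
rank-sum deviate) with BH adjustment within each cluster's feature list;
the marker rule is FDR < 0.05 with positive fold change versus the rest.
Bonferroni is min(1, m·p); BH follows the step-up definition (validated
against a brute-force implementation).

## Clustering

Samples are clustered on the first 5 principal components of the scaled
matrix (SVD-based PCA, sign fixed by making each component's
largest-magnitude loading positive), a k = 20 nearest-neighbor graph on
Euclidean distance in PC space with shared-neighbor Jaccard edge
weights, and Louvain modularity communities at resolution 1.0 with a
fixed seed. k, resolution, and the PC count are exposed; the number of
clusters is an outcome. These defaults follow the dominant convention
for KNN-graph expression clustering. No explicit batch integration is
performed beyond per-feature scaling of the concatenated matrix; instead
the cohort-vs-cluster chi-square composition test serves as a confound
diagnostic (on synthetic data with cohorts assigned orthogonally to
planted clusters it is non-significant in the large majority of seeds).

## Accessibility analysis

Tracks are per-100-bp-bin counts. RPKM_b = c_b/(bin_kb·M), RPM_b =
c_b/M, with z-scoring across all bins of a track. When read positions
are supplied, each read is extended by 100 bp before binning.

Peak–TE overlap uses the strictest reading consistent with using both
summit files and a 50% threshold: the TE must cover at least 50% of the
peak (boundary inclusive) *and* contain the peak summit (the summit
requirement is toggleable). Family enrichment replaces each peak, per
draw, with a uniformly placed width-matched interval genome-wide
(optionally outside an exclusion BED, e.g. low-mappability regions), and
applies the identical overlap rule; expected counts are means over 100
draws (count configurable), log₂ ratios use an ε = 0.5 pseudocount, and
significance is the permutation p (1 + #{draws ≥ obs})/(n_draws + 1),
which is super-uniform under the null by construction. A dedicated
gene-set-style enrichment significance is deliberately not emulated; the
permutation p is the supported significance.

Metaprofiles anchor at the locus left boundary (lower coordinate,
strand-ignored), average per-bp signal into 100-bp bins over ±5 kb (101
bins), exclude out-of-chromosome positions from means, and scale raw
tracks to reads-per-million per group before averaging.

## Cis-regulatory pair calling

Candidates are TE-associated peaks whose interval lies within 10 kb of a
TSS (interval-to-point distance, inclusive; distance measured to the
half-open end coordinate so a peak ending at 1000 is exactly 10,000 bp
from a TSS at 11,000). The TSS of a '−' gene is its last base (end−1).
Differential accessibility is Wilcoxon on normalized per-peak signal.
Default thresholds: accessibility nominal p < 0.05 and |lfc| ≥ 0.5,
expression nominal p < 0.05, concordant directions required. With n = 4
vs 4 the exact rank test's smallest two-sided p is 2/70 ≈ 0.029, so any
multiplicity-corrected cutoff over thousands of features is unattainable
in principle; false positives are instead controlled by requiring joint,
directionally concordant support in two independent data layers (the
per-candidate null rate is ≈ 0.029² / 2 ≈ 4×10⁻⁴). Callers preferring
adjusted expression p can switch via `CisRegThresholds`. Family-level
enrichment is reported alongside but does not gate pair calling.

## KZNF–TE correlation screen

Spearman's ρ (mid-rank ties) for every (family, KZNF) pair on
log₂(TPM+1) family-mean expression, two-sided p from the t
approximation, BH across the full grid. The screen keeps ρ ≤ −0.3,
q ≤ 0.05 by default. Pooled and per-cluster screens are both possible by
subsetting the sample columns before calling. Kendall's τ would be an
equally defensible ranked statistic; ρ is the default because it is the
conventional quantity reported for this analysis.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
at desk scale:

- **Genome**: uniform non-overlapping placement of TE loci within each
  family (rejection sampling, bounded retries), uniform gene TSSs;
  defaults 1 Mb, 2 families × 100 loci of 500 bp, 110 genes of which 10
  KZNFs.
- **Counts**: negative binomial with per-feature log-normal base means
  (log-mean log 100, log-sd 1), gene-wise dispersion 0.1, per-sample
  library-size factors, and planted log₂ fold changes per group or per
  planted cluster. Group sizes default to the study-like 4 EC vs 5 HC;
  the clustering design uses 128 single-group samples in 4 planted
  clusters with 25 markers each at lfc = 2.
- **KZNF–TE coupling**: a shared standard-normal latent factor per
  planted pair enters the KZNF mean as exp(+βz) and every target-family
  locus mean as exp(−βz); β is derived from the target correlation
  magnitude as β = |r|·√(v/(1−r²)) with v the approximate log-scale
  noise variance of the KZNF. This yields a monotone negative
  association valid for rank correlation; realized Spearman ρ runs
  slightly below the Pearson target (median ≈ −0.62 for a −0.7 target),
  which the screen's −0.3 cutoff absorbs comfortably.
- **Accessibility**: per-bin Poisson counts; background peaks uniform
  with log-normal widths (median 400 bp, a realistic ATAC peak scale)
  and elevated rate in all samples; planted accessible TE loci become
  peaks spanning the locus with 2^lfc-fold elevated rate in the planted
  group only; per-sample depth scales all rates (depth 0 gives an empty
  track).

What the generator does **not** model: read-level sequence content and
mappability, fragment-length effects, GC bias, cell-type composition
shifts, batch effects with expression consequences, and correlated
gene–gene structure beyond the planted factors. Passing recovery tests
therefore demonstrates the correctness and calibration of the
algorithms under their assumed noise model, not robustness to every
artefact of real sequencing data.

## Problem sizes and numerical choices

Recovery experiments use: 128 samples / 4 clusters for clustering; 2000
genes, 50 planted links, 4 vs 4 samples for cis-regulatory recovery; 10
TE families, 25 KZNFs, 128 samples for the anticorrelation screen; 100k
reads / 10 features for EM recovery; 1000 features for test-calibration
checks. These sizes mirror the study-scale designs the pipeline targets
while keeping the full suite quick to run. Ties in rank tests fall back
to the corrected normal approximation; empirical p-values use the
add-one rule so they are never zero; Louvain label order is fixed by
community size then smallest member, making labels deterministic for a
fixed seed; all simulators are pure functions of (inputs, seed).

## Known limitations

Annotated-length TPM (no effective-length modelling); no covariate
adjustment or paired designs in the rank tests; no batch integration
beyond scaling; enrichment null is uniform-genome (supply an exclusion
BED to approximate mappability); the cis-regulatory caller links by
proximity and concordance only — it does not model enhancer–promoter
contact or TF occupancy.
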