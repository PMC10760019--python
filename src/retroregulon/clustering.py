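"""Sample clustering: PCA, shared-neighbor KNN graph, Louvain communities.

The pipeline mirrors the convention dominant in expression analysis:
z-scaled features are reduced to a handful of principal components
(default 5), samples become nodes of a k-nearest-neighbor graph built on
Euclidean distance in PC space with shared-neighbor (Jaccard) edge
weights, and communities are found by modularity (Louvain) optimization.
The number of clusters is an outcome, not an input.
"""

from __future__ import annotations

import logging
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .types import AbundanceMatrix, ClusterAssignment, PCAResult

logger = logging.getLogger(__name__)


def pca(matrix, n_pc: int = 5) -> PCAResult:
    """Principal components of a z-scaled features x samples matrix.

    Samples are observations. Deterministic up to sign; signs are fixed
    by making each component's largest-magnitude loading positive.
    """
    vals = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    X = vals.to_numpy().T  # samples x features
    if n_pc > min(X.shape):
        raise ValueError(f"n_pc={n_pc} exceeds min(n_samples, n_features)={min(X.shape)}")
    model = PCA(n_components=n_pc, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # features x PCs
    for j in range(n_pc):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(n_pc)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=vals.columns, columns=cols),
        loadings=pd.DataFrame(loadings, index=vals.index, columns=cols),
        explained_variance=model.explained_variance_,
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def knn_graph(scores: pd.DataFrame, k: int = 20, metric: str = "euclidean") -> nx.Graph:
    """Undirected KNN graph over samples in PC space.

    Each sample is joined to its k nearest neighbors (self excluded);
    the union of directed edges is kept once and weighted by the Jaccard
    overlap of the two endpoints' neighborhoods (each including the node
    itself), the shared-nearest-neighbor weighting.
    """
    n = len(scores)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")
    X = scores.to_numpy()
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric).fit(X)
    _, idx = nn.kneighbors(X)
    names = list(scores.index)
    hoods = []
    for i in range(n):
        ordered = [j for j in idx[i].tolist() if j != i][:k]  # distance order, self out
        hoods.append(set(ordered) | {i})
    G = nx.Graph()
    G.add_nodes_from(names)
    for i in range(n):
        for j in hoods[i]:
            if j == i or G.has_edge(names[i], names[j]):
                continue
            inter = len(hoods[i] & hoods[j])
            union = len(hoods[i] | hoods[j])
            G.add_edge(names[i], names[j], weight=inter / union)
    return G


def community_clusters(graph: nx.Graph, resolution: float = 1.0, seed: int = 0) -> ClusterAssignment:
    """Louvain modularity communities on the weighted graph.

    Labels are 1..K, ordered by community size (largest first, ties by
    smallest member node); deterministic for a fixed seed.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: (-len(c), sorted(map(str, c))[0]))
    labels = {}
    for lab, comm in enumerate(comms, start=1):
        for node in comm:
            labels[node] = lab
    s = pd.Series(labels).reindex(list(graph.nodes))
    return ClusterAssignment(labels=s, params={"resolution": resolution, "seed": seed})


def cluster_composition(
    assignment: ClusterAssignment,
    metadata: pd.DataFrame,
    field: str,
    n_sim: int = 2000,
    seed: int = 0,
):
    """Cluster x category contingency table with a chi-square independence test.

    Samples without metadata are excluded (count logged). When any
    expected cell is below 5 the p-value is computed by Monte-Carlo
    sampling of tables with the observed margins instead of the
    asymptotic chi-square distribution. A single-category table has no
    defined test; p is NaN.

    Returns ``(counts, proportions, p)``.
    """
    if field not in metadata.columns:
        raise ValueError(f"field {field!r} not in metadata")
    labels = assignment.labels
    common = labels.index.intersection(metadata.index)
    dropped = len(labels) - len(common)
    if dropped:
        logger.warning("%d sample(s) missing metadata excluded from composition", dropped)
    tab = pd.crosstab(labels.loc[common], metadata.loc[common, field])
    tab.index.name = "cluster"
    props = tab.div(tab.sum(axis=1), axis=0)
    if tab.shape[1] < 2 or tab.shape[0] < 2:
        return tab, props, float("nan")
    chi2, p, _, expected = stats.chi2_contingency(tab)
    if (expected < 5).any():
        rng = np.random.default_rng(seed)
        sampler = stats.random_table(tab.sum(axis=1).to_numpy(), tab.sum(axis=0).to_numpy())
        sims = sampler.rvs(n_sim, random_state=rng)
        exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.to_numpy().sum()
        chi2_sim = (((sims - exp) ** 2) / exp).sum(axis=(1, 2))
        p = float((1 + np.sum(chi2_sim >= chi2 - 1e-12)) / (n_sim + 1))
    return tab, props, float(p)
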