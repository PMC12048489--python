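"""Cosine similarity of axons by shared synaptic connectivity, and its
hierarchical clustering.

Each seed axon is represented by a weight vector of raw synapse counts onto
its (thresholded) partners. The cosine similarity of two axons is the dot
product of their unit-normalized weight vectors: 1 when they synapse with the
same relative weights onto the same partners, 0 when their partner support is
disjoint. Agglomerative clustering runs on the distance 1 - S.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .core import EdgeList, ValidationError
from .partners import extract_partners

logger = logging.getLogger(__name__)


@dataclass
class WeightVectorSet:
    """Seed x partner matrix of raw synapse counts (one direction)."""

    matrix: pd.DataFrame
    direction: str
    threshold: int

    @property
    def seeds(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def partners(self) -> list[str]:
        return list(self.matrix.columns)


def weight_vectors(
    edges: EdgeList,
    seeds: Iterable[str],
    direction: str = "downstream",
    threshold: int = 4,
    *,
    partners: Sequence[str] | None = None,
) -> WeightVectorSet:
    """Build the seed x partner count matrix.

    Partner columns default to the thresholded partner set of the seed
    population (per-seed inclusion rule), sorted for determinism; once a
    partner qualifies, all seed counts onto it enter the matrix.
    """
    seeds = list(seeds)
    if partners is None:
        partners = list(
            extract_partners(edges, seeds, direction, threshold).members.index
        )
    matrix = pd.DataFrame(0, index=seeds, columns=list(partners), dtype=int)
    for seed in seeds:
        counts = (
            edges.out_counts(seed)
            if direction == "downstream"
            else edges.in_counts(seed)
        )
        for partner, count in counts.items():
            if partner in matrix.columns:
                matrix.loc[seed, partner] = count
    matrix.index.name = "seed_id"
    return WeightVectorSet(matrix, direction, threshold)


def cosine_similarity_matrix(W: WeightVectorSet | pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine similarity of seed weight vectors.

    Seeds whose vector is all-zero get undefined (NaN) entries; an all-zero
    matrix is an error. The result is exactly symmetric with a unit diagonal
    for nonzero seeds.
    """
    matrix = W.matrix if isinstance(W, WeightVectorSet) else W
    values = matrix.to_numpy(dtype=float)
    nonzero = values.any(axis=1)
    if not nonzero.any():
        raise ValidationError("all seed weight vectors are zero")
    if not nonzero.all():
        logger.warning(
            "%d seed(s) have zero weight vectors; similarity undefined",
            int((~nonzero).sum()),
        )
    S = np.full((len(matrix), len(matrix)), np.nan)
    sub = _sk_cosine(values[nonzero])
    sub = np.clip((sub + sub.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(sub, 1.0)
    S[np.ix_(nonzero, nonzero)] = sub
    out = pd.DataFrame(S, index=matrix.index, columns=matrix.index)
    return out


def _cluster_from_similarity(
    S: np.ndarray,
    method: str,
    n_clusters: int | None,
    distance_threshold: float | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Agglomerative clustering on distance 1 - S.

    Returns (labels, leaf_order, linkage matrix); labels are contiguous
    integers starting at 0, numbered by first appearance along the dendrogram
    leaf order so results are deterministic.
    """
    n = S.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 seeds to cluster")
    D = np.clip(1.0 - S, 0.0, None)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = scipy_linkage(squareform(D, checks=False), method=method)
    leaf_order = leaves_list(Z)
    if n_clusters is not None:
        raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        if distance_threshold is None:
            raise ValidationError("need n_clusters or distance_threshold")
        raw = fcluster(Z, t=distance_threshold, criterion="distance")
    relabel: dict[int, int] = {}
    for leaf in leaf_order:
        relabel.setdefault(raw[leaf], len(relabel))
    labels = np.array([relabel[r] for r in raw], dtype=int)
    return labels, leaf_order, Z


class ConnectivityClustering(BaseEstimator, ClusterMixin):
    """Agglomerative clustering of axons by connectivity similarity.

    Fit on a seed x partner weight matrix (array or DataFrame). Cosine
    similarity is computed internally and clustered with the given linkage on
    distance 1 - S; cut either at ``n_clusters`` or at ``distance_threshold``.
    Seeds with all-zero weight vectors are excluded and labelled -1.

    Attributes
    ----------
    similarity_matrix_ : ndarray, pairwise cosine similarity (NaN for
        zero-vector seeds).
    labels_ : ndarray of cluster labels (contiguous ints, -1 for excluded).
    leaf_order_ : indices of the fitted seeds in dendrogram leaf order.
    linkage_ : scipy linkage matrix of the fitted seeds.
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        distance_threshold: float | None = 0.5,
        linkage: str = "average",
    ):
        self.n_clusters = n_clusters
        self.distance_threshold = distance_threshold
        self.linkage = linkage

    def fit(self, X, y=None):
        matrix = X.matrix if isinstance(X, WeightVectorSet) else X
        index = (
            matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(len(matrix))
        )
        values = np.asarray(matrix, dtype=float)
        if values.ndim != 2:
            raise ValidationError("weight matrix must be 2-dimensional")
        nonzero = values.any(axis=1)
        S_full = cosine_similarity_matrix(
            pd.DataFrame(values, index=index)
        ).to_numpy()
        sub_labels, leaf_order, Z = _cluster_from_similarity(
            S_full[np.ix_(nonzero, nonzero)],
            self.linkage,
            self.n_clusters,
            self.distance_threshold,
        )
        labels = np.full(len(values), -1, dtype=int)
        labels[nonzero] = sub_labels
        kept = np.flatnonzero(nonzero)
        self.similarity_matrix_ = S_full
        self.labels_ = labels
        self.leaf_order_ = kept[leaf_order]
        self.linkage_ = Z
        self.index_ = index
        self.n_clusters_ = int(sub_labels.max()) + 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class SimilarityResult:
    """Similarity matrix with cluster labels and dendrogram leaf order."""

    matrix: pd.DataFrame
    labels: pd.Series
    leaf_order: list[str]


def cluster_similarity(
    S: pd.DataFrame,
    n_clusters: int | None = None,
    distance_threshold: float | None = None,
    linkage: str = "average",
) -> SimilarityResult:
    """Cluster a precomputed similarity matrix (labels + leaf order)."""
    values = S.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError("similarity matrix contains undefined entries")
    labels, leaf_order, _ = _cluster_from_similarity(
        values, linkage, n_clusters, distance_threshold
    )
    index = S.index
    return SimilarityResult(
        S,
        pd.Series(labels, index=index, name="cluster"),
        [index[i] for i in leaf_order],
    )


@dataclass
class CrossPopulationResult:
    """Joint clustering of two seed populations over unified partner columns."""

    matrix: pd.DataFrame
    labels: pd.Series
    leaf_order: list[str]
    origin: pd.Series
    cluster_composition: pd.DataFrame  # cluster x origin counts


def cross_population_similarity(
    W_a: WeightVectorSet,
    W_b: WeightVectorSet,
    *,
    names: tuple[str, str] = ("a", "b"),
    n_clusters: int | None = None,
    distance_threshold: float | None = 0.5,
    linkage: str = "average",
) -> CrossPopulationResult:
    """Similarity clustering of the union of two populations.

    Partner columns are aligned to their union (missing counts are zero).
    With no shared partner columns, cross-population similarity is all zero
    (a warning is logged) and the populations cannot co-cluster.
    """
    shared = set(W_a.matrix.columns) & set(W_b.matrix.columns)
    if not shared:
        logger.warning("populations share no partner columns; cross-similarity is 0")
    columns = sorted(set(W_a.matrix.columns) | set(W_b.matrix.columns))
    combined = pd.concat(
        [
            W_a.matrix.reindex(columns=columns, fill_value=0),
            W_b.matrix.reindex(columns=columns, fill_value=0),
        ]
    )
    origin = pd.Series(
        [names[0]] * len(W_a.matrix) + [names[1]] * len(W_b.matrix),
        index=combined.index,
        name="origin",
    )
    model = ConnectivityClustering(
        n_clusters=n_clusters, distance_threshold=distance_threshold, linkage=linkage
    ).fit(combined)
    labels = pd.Series(model.labels_, index=combined.index, name="cluster")
    composition = (
        pd.crosstab(labels[labels >= 0], origin[labels >= 0])
        .reindex(columns=list(names), fill_value=0)
    )
    S = pd.DataFrame(
        model.similarity_matrix_, index=combined.index, columns=combined.index
    )
    return CrossPopulationResult(
        S,
        labels,
        [combined.index[i] for i in model.leaf_order_],
        origin,
        composition,
    )
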