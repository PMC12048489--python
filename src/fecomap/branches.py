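"""Spatial K-means partition of a subtype's output synapses into branches,
and per-partner branch preference scores.

Output synapses of one sensory subtype are clustered by Euclidean distance in
raw nm (no per-axis scaling) into k branches (default 3, the number of major
axon branches). Branch labels are canonicalized by ascending centroid
coordinate along the dorsal-ventral axis (z by default) so the partition is
deterministic and anatomically ordered. A partner's branch preference is the
fraction of the synapses it receives that come from each branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .core import ValidationError

logger = logging.getLogger(__name__)

_AXES = {"x": 0, "y": 1, "z": 2}


class SynapseBranchKMeans(BaseEstimator, ClusterMixin):
    """K-means over synapse coordinates with canonical branch ordering.

    k-means++ initialization with ``n_init`` restarts (best inertia kept);
    deterministic given ``random_state``. After fitting, labels are relabelled
    so that branch 0 has the smallest centroid coordinate along
    ``order_axis``.
    """

    def __init__(
        self,
        n_branches: int = 3,
        random_state: int | None = 0,
        n_init: int = 10,
        order_axis: str = "z",
    ):
        self.n_branches = n_branches
        self.random_state = random_state
        self.n_init = n_init
        self.order_axis = order_axis

    def fit(self, X, y=None):
        coords = np.asarray(X, dtype=float)
        if coords.ndim != 2:
            raise ValidationError("coordinates must be an (n, d) array")
        if len(coords) < self.n_branches:
            raise ValidationError(
                f"need at least {self.n_branches} synapses, got {len(coords)}"
            )
        axis = _AXES.get(self.order_axis)
        if axis is None or axis >= coords.shape[1]:
            raise ValidationError(f"invalid order_axis {self.order_axis!r}")
        km = KMeans(
            n_clusters=self.n_branches,
            init="k-means++",
            n_init=self.n_init,
            random_state=self.random_state,
        ).fit(coords)
        order = np.argsort(km.cluster_centers_[:, axis], kind="stable")
        relabel = np.empty(self.n_branches, dtype=int)
        relabel[order] = np.arange(self.n_branches)
        self.labels_ = relabel[km.labels_]
        self.cluster_centers_ = km.cluster_centers_[order]
        self.inertia_ = km.inertia_
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class BranchAssignment:
    """Branch label (1..k) per synapse row plus branch centroids in nm."""

    labels: pd.Series  # indexed like the synapse table rows
    centroids: pd.DataFrame  # branch -> (x, y, z)

    @property
    def k(self) -> int:
        return len(self.centroids)


def cluster_synapse_locations(
    synapses: pd.DataFrame,
    k: int = 3,
    rng_seed: int = 0,
    order_axis: str = "z",
) -> BranchAssignment:
    """Partition the output synapses of one subtype into ``k`` spatial branches."""
    model = SynapseBranchKMeans(
        n_branches=k, random_state=rng_seed, order_axis=order_axis
    ).fit(synapses[["x", "y", "z"]].to_numpy())
    labels = pd.Series(model.labels_ + 1, index=synapses.index, name="branch")
    centroids = pd.DataFrame(
        model.cluster_centers_,
        index=pd.RangeIndex(1, k + 1, name="branch"),
        columns=["x", "y", "z"],
    )
    return BranchAssignment(labels, centroids)


def branch_preference(
    assignment: BranchAssignment, synapses: pd.DataFrame
) -> pd.DataFrame:
    """Per-partner fraction of synapses received from each branch.

    ``synapses`` must be the same rows the assignment was fitted on (with a
    ``post_id`` column). Returns one row per postsynaptic neuron with k
    fraction columns summing to 1 and the total synapse count.
    """
    df = pd.DataFrame(
        {"post_id": synapses["post_id"], "branch": assignment.labels}
    )
    counts = (
        df.groupby(["post_id", "branch"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=range(1, assignment.k + 1), fill_value=0)
    totals = counts.sum(axis=1)
    fractions = counts.div(totals, axis=0)
    fractions.columns = [f"branch_{b}" for b in fractions.columns]
    fractions["n_synapses"] = totals.astype(int)
    fractions = fractions.sort_index()
    return fractions


def subsample_preference(
    assignment: BranchAssignment,
    synapses: pd.DataFrame,
    fraction: float,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Strongest branch preference per partner after uniform synapse subsampling.

    Synapses are subsampled without replacement while the fitted branch labels
    are held fixed. Partners whose synapses are all dropped are excluded (a
    count is logged). Returns per partner the preferred branch, its
    preference, and the number of retained synapses.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    n_keep = int(round(fraction * len(synapses)))
    keep = np.sort(rng.choice(len(synapses), size=n_keep, replace=False))
    sub = synapses.iloc[keep]
    sub_assignment = BranchAssignment(assignment.labels.iloc[keep], assignment.centroids)
    prefs = branch_preference(sub_assignment, sub)
    n_dropped = synapses["post_id"].nunique() - len(prefs)
    if n_dropped:
        logger.warning("subsampling dropped %d partner(s) entirely", n_dropped)
    branch_cols = [c for c in prefs.columns if c.startswith("branch_")]
    values = prefs[branch_cols].to_numpy()
    best = values.argmax(axis=1)
    return pd.DataFrame(
        {
            "preferred_branch": best + 1,
            "max_preference": values[np.arange(len(best)), best],
            "n_synapses": prefs["n_synapses"],
        },
        index=prefs.index,
    )
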