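"""Threshold-based partner extraction and composition/overlap summaries.

A neuron counts as a *partner* of a seed population when some single seed
neuron connects to it with at least ``threshold`` synapses in the stated
direction (>=4 received from a seed axon for downstream partners, >=3 made
onto a seed axon for upstream ones). Pooled-count inclusion (the sum over
seeds reaching threshold) is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import EdgeList, ValidationError, neuron_index

logger = logging.getLogger(__name__)


@dataclass
class PartnerSet:
    """Partners of a seed population in one direction, with summed counts."""

    seeds: tuple[str, ...]
    direction: str
    threshold: int
    members: pd.Series  # partner_id -> total synapses from/to the seeds

    def ids(self) -> set[str]:
        return set(self.members.index)

    def __len__(self) -> int:
        return len(self.members)


def _seed_counts(edges: EdgeList, seed: str, direction: str) -> dict[str, int]:
    if direction == "downstream":
        return edges.out_counts(seed)
    if direction == "upstream":
        return edges.in_counts(seed)
    raise ValidationError(f"direction must be downstream or upstream, got {direction!r}")


def extract_partners(
    edges: EdgeList,
    seeds: Iterable[str],
    direction: str = "downstream",
    threshold: int = 4,
    *,
    pooled: bool = False,
) -> PartnerSet:
    """Partners of ``seeds`` meeting the inclusion threshold.

    Inclusion is per seed neuron by default: a partner qualifies when *any*
    single seed reaches ``threshold`` synapses with it. After inclusion, the
    per-partner count sums the synapses over all seeds (including
    sub-threshold contributions).
    """
    seeds = tuple(seeds)
    if not seeds:
        raise ValidationError("seed set is empty")
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    totals: dict[str, int] = {}
    qualified: set[str] = set()
    for seed in seeds:
        for partner, count in _seed_counts(edges, seed, direction).items():
            totals[partner] = totals.get(partner, 0) + count
            if count >= threshold:
                qualified.add(partner)
    if pooled:
        qualified = {p for p, total in totals.items() if total >= threshold}
    members = pd.Series(
        {p: totals[p] for p in sorted(qualified)}, dtype=int, name="count"
    )
    members.index.name = "partner_id"
    return PartnerSet(seeds, direction, threshold, members)


def class_composition(
    edges: EdgeList,
    seeds: Iterable[str],
    neurons: pd.DataFrame,
    *,
    by: str = "neuron_class",
    labeled_only: bool = False,
) -> pd.DataFrame:
    """Per-seed fraction of output synapses onto each target category.

    ``by`` selects the annotation column used to bin targets (morphological
    class by default, or e.g. ``hemilineage``). Fractions are synapse-weighted
    and sum to 1 per seed; targets with an unknown label appear as an explicit
    ``unknown`` column (and fragments as the ``fragment`` class) unless
    ``labeled_only`` drops them from the denominator. Seeds without output
    synapses are excluded with a warning.
    """
    info = neuron_index(neurons)
    labels = info[by]
    rows: dict[str, dict[str, float]] = {}
    for seed in seeds:
        out = edges.out_counts(seed)
        if not out:
            logger.warning("seed %s has no output synapses; excluded", seed)
            continue
        binned: dict[str, float] = {}
        for post, count in out.items():
            label = labels.get(post, "unknown")
            if pd.isna(label):
                label = "unknown"
            binned[label] = binned.get(label, 0.0) + count
        if labeled_only:
            binned.pop("unknown", None)
            binned.pop("fragment", None)
        total = sum(binned.values())
        if total == 0:
            logger.warning("seed %s has no labeled targets; excluded", seed)
            continue
        rows[seed] = {k: v / total for k, v in binned.items()}
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    table = table[sorted(table.columns)]
    table.index.name = "seed_id"
    return table


def composition_by_group(
    edges: EdgeList,
    seed_groups: Mapping[str, Sequence[str]],
    neurons: pd.DataFrame,
    *,
    by: str = "neuron_class",
    labeled_only: bool = False,
) -> pd.DataFrame:
    """Synapse-weighted aggregate composition per seed group (e.g. subtype)."""
    info = neuron_index(neurons)
    labels = info[by]
    rows: dict[str, dict[str, float]] = {}
    for group, seeds in seed_groups.items():
        binned: dict[str, float] = {}
        for seed in seeds:
            for post, count in edges.out_counts(seed).items():
                label = labels.get(post, "unknown")
                if pd.isna(label):
                    label = "unknown"
                binned[label] = binned.get(label, 0.0) + count
        if labeled_only:
            binned.pop("unknown", None)
            binned.pop("fragment", None)
        total = sum(binned.values())
        if total:
            rows[group] = {k: v / total for k, v in binned.items()}
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    table = table[sorted(table.columns)]
    table.index.name = "group"
    return table


def shared_partner_matrix(
    edges: EdgeList,
    seed_groups: Mapping[str, Sequence[str]],
    reference_groups: Mapping[str, Sequence[str]],
    threshold: int = 4,
) -> pd.DataFrame:
    """Percent of each seed group's postsynaptic partners shared with each
    reference group.

    Entry (i, j) is ``100 * |P_i intersect R_j| / |P_i|`` where ``P_i`` is
    the postsynaptic partner set of seed group i and ``R_j`` the set of
    neurons receiving >= ``threshold`` synapses from some neuron of reference
    group j. An empty postsynaptic set yields NaN (missing), not 0.
    """
    post_sets = {
        name: extract_partners(edges, seeds, "downstream", threshold).ids()
        for name, seeds in seed_groups.items()
    }
    ref_sets = {
        name: extract_partners(edges, seeds, "downstream", threshold).ids()
        for name, seeds in reference_groups.items()
    }
    out = pd.DataFrame(
        index=list(seed_groups), columns=list(reference_groups), dtype=float
    )
    for i, pi in post_sets.items():
        for j, rj in ref_sets.items():
            out.loc[i, j] = 100.0 * len(pi & rj) / len(pi) if pi else np.nan
    out.index.name = "seed_group"
    return out


def recurrence_fractions(
    edges: EdgeList, class_partition: pd.Series
) -> pd.DataFrame:
    """Class-to-class output fractions.

    Entry (i, j) = synapses from class-i neurons onto class-j neurons divided
    by the *total* output synapses of class i (so rows sum to <= 1, the
    remainder going to targets outside the partition). A class with zero
    output gets a NaN row.
    """
    classes = sorted(class_partition.unique())
    counts = pd.DataFrame(0.0, index=classes, columns=classes)
    totals = pd.Series(0.0, index=classes)
    membership = class_partition.to_dict()
    for pre, post, count in edges.edges.itertuples(index=False):
        ci = membership.get(pre)
        if ci is None:
            continue
        totals[ci] += count
        cj = membership.get(post)
        if cj is not None:
            counts.loc[ci, cj] += count
    out = counts.div(totals, axis=0)
    out[totals == 0] = np.nan
    out.index.name = "from_class"
    return out


def overlap_counts(a: PartnerSet, b: PartnerSet) -> tuple[int, int, int]:
    """(|A only|, |A intersect B|, |B only|) for two partner sets."""
    if a.direction != b.direction or a.threshold != b.threshold:
        raise ValidationError(
            "partner sets must be built with the same direction and threshold"
        )
    sa, sb = a.ids(), b.ids()
    return len(sa - sb), len(sa & sb), len(sb - sa)
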