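"""Signed mono-, di- and tri-synaptic motor impact scores, and motor-module /
sensory-subtype preference scores for premotor neurons.

The monosynaptic impact of neuron A onto neuron B is the number of synapses
A makes onto B divided by B's *total* input synapse count, signed by A's
putative transmitter (excitatory positive, inhibitory negative). The motor
impact of a sensory seed onto a motor module sums, over all motor neurons
(MNs) of the module:

* hop 1 - the seed's direct impact onto each MN, forced positive (sensory
  afferents are assumed cholinergic);
* hop 2 - for every interneuron I postsynaptic to the seed and presynaptic
  to a module MN, |impact(seed, I)| * |impact(I, MN)| signed by I;
* hop 3 - for every ordered pair (P, Q) of distinct interneurons with an
  identified hemilineage, |impact(seed, P)| * |impact(P, Q)| * |impact(Q,
  MN)|, positive when P and Q share a sign and negative otherwise.

Intermediates exclude motor neurons and the seed itself; an intermediate
with an undefined sign (hop 2) or unidentified hemilineage (hop 3) is
excluded and tallied in a coverage report. Only edges whose synapse count
passed the reconstruction threshold participate; raw counts (never
thresholded ones) enter the ratios, so the score is invariant to a global
rescaling of all synapse counts on a fixed partner graph.

This summary captures trends in multi-layer motor connectivity but is not a
predictor of activity: it ignores circuit dynamics and intrinsic membrane
properties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import DEFAULT_SIGNS, EdgeList, SignMap, ValidationError, neuron_index, sign_of

logger = logging.getLogger(__name__)


def edge_impact(
    pre: str,
    post: str,
    edges: EdgeList,
    neurons: pd.DataFrame,
    signs: SignMap = DEFAULT_SIGNS,
) -> float | None:
    """Signed single-edge impact of ``pre`` onto ``post``.

    Magnitude count(pre, post) / input_total[post]; sign from the presynaptic
    neuron's transmitter. Returns ``None`` (undefined, not an error) when the
    sign is undefined, 0.0 when there is no edge; a zero input total is an
    error naming the postsynaptic neuron.
    """
    count = edges.count(pre, post)
    if count == 0:
        return 0.0
    total = int(edges.input_total.get(post, 0))
    if total <= 0:
        raise ValidationError(f"neuron {post} has zero recorded input synapses")
    info = neuron_index(neurons)
    s = sign_of(info.loc[pre], signs)
    if s is None:
        return None
    return s * count / total


@dataclass
class ImpactResult:
    """Signed impact of one seed onto one motor module, split by hop count."""

    seed_id: str
    module: int
    impact_1: float
    impact_2: float
    impact_3: float
    coverage: dict = field(default_factory=dict)

    @property
    def impact_total(self) -> float:
        return self.impact_1 + self.impact_2 + self.impact_3


class MotorImpactScorer(BaseEstimator):
    """Computes motor impact scores over a fitted connectome.

    Parameters
    ----------
    threshold : minimum synapse count for an edge to participate (the
        reconstruction threshold; partner-graph selection, default 4).
    sign_map : transmitter -> polarity convention.
    exclude_shared_intermediate : drop P == Q terms from the trisynaptic sum
        (a neuron that is both post-seed and pre-MN is already covered by the
        disynaptic term).

    ``fit(edge_list, neurons)`` precomputes dense ratio matrices; ``score``
    evaluates one (seed, module) pair and ``transform`` returns a long-format
    table over many.
    """

    def __init__(
        self,
        threshold: int = 4,
        sign_map: SignMap = DEFAULT_SIGNS,
        exclude_shared_intermediate: bool = True,
    ):
        self.threshold = threshold
        self.sign_map = sign_map
        self.exclude_shared_intermediate = exclude_shared_intermediate

    def fit(self, edge_list: EdgeList, neurons: pd.DataFrame):
        info = neuron_index(neurons)
        ids = list(info.index)
        pos = {nid: i for i, nid in enumerate(ids)}
        n = len(ids)
        totals = np.zeros(n)
        for nid, total in edge_list.input_total.items():
            if nid in pos:
                totals[pos[nid]] = total
        R = np.zeros((n, n))
        for pre, post, count in edge_list.edges.itertuples(index=False):
            if count < self.threshold:
                continue
            i, j = pos.get(pre), pos.get(post)
            if i is None or j is None:
                continue
            if totals[j] <= 0:
                raise ValidationError(
                    f"neuron {post} receives edges but has zero input total"
                )
            R[i, j] = count / totals[j]
        sign = np.array(
            [
                np.nan if (s := sign_of(info.loc[nid], self.sign_map)) is None else s
                for nid in ids
            ]
        )
        hemi = info["hemilineage"].to_numpy()
        self.ids_ = ids
        self.pos_ = pos
        self.ratio_ = R
        self.sign_ = sign
        self.is_motor_ = (info["neuron_class"] == "motor").to_numpy()
        self.hemi_known_ = np.array(
            [isinstance(h, str) and h not in ("", "unknown") for h in hemi]
        )
        self.modules_ = {
            int(m): np.array([pos[nid] for nid in info.index[info["motor_module"] == m]])
            for m in info["motor_module"].dropna().unique()
        }
        return self

    def score(self, seed_id: str, module: int) -> ImpactResult:
        """Impact of one sensory seed onto one motor module."""
        mn = self.modules_.get(int(module))
        if mn is None or len(mn) == 0:
            raise ValidationError(f"motor module {module} contains no motor neurons")
        s = self.pos_[seed_id]
        R, sign = self.ratio_, self.sign_

        # hop 1: direct seed -> MN, forced excitatory
        impact_1 = float(np.abs(R[s, mn]).sum())

        candidate = (R[s] > 0) & ~self.is_motor_
        candidate[s] = False
        defined = ~np.isnan(sign)
        coverage = {
            "undefined_sign_intermediates": int((candidate & ~defined).sum()),
            "unidentified_hemilineage_intermediates": int(
                (candidate & ~self.hemi_known_).sum()
            ),
        }

        # hop 2: seed -> I -> MN, I with a defined transmitter sign
        di = candidate & defined
        to_module = R[:, mn].sum(axis=1)
        impact_2 = float(((R[s, di] * sign[di]) * to_module[di]).sum())

        # hop 3: seed -> P -> Q -> MN over hemilineage-identified interneurons
        tri = ~self.is_motor_ & defined & self.hemi_known_
        tri[s] = False
        H = np.flatnonzero(tri)
        if len(H):
            a = R[s, H] * sign[H]
            M = R[np.ix_(H, H)] * sign[H][None, :]
            if self.exclude_shared_intermediate:
                np.fill_diagonal(M, 0.0)
            impact_3 = float(a @ M @ to_module[H])
        else:
            impact_3 = 0.0
        return ImpactResult(seed_id, int(module), impact_1, impact_2, impact_3, coverage)

    def transform(
        self,
        seed_ids: Iterable[str],
        modules: Iterable[int] | None = None,
    ) -> pd.DataFrame:
        """Long-format impact table over seeds x modules."""
        modules = sorted(self.modules_) if modules is None else list(modules)
        rows = []
        for seed in seed_ids:
            for module in modules:
                r = self.score(seed, module)
                rows.append(
                    (seed, module, r.impact_1, r.impact_2, r.impact_3, r.impact_total)
                )
        return pd.DataFrame(
            rows,
            columns=["seed_id", "module", "impact_1", "impact_2", "impact_3", "impact_total"],
        )


def motor_impact(
    seed_id: str,
    module: int,
    edges: EdgeList,
    neurons: pd.DataFrame,
    signs: SignMap = DEFAULT_SIGNS,
    threshold: int = 4,
) -> ImpactResult:
    """One-shot motor impact of a sensory seed onto a motor module."""
    scorer = MotorImpactScorer(threshold=threshold, sign_map=signs).fit(edges, neurons)
    return scorer.score(seed_id, module)


def module_preference(
    edges: EdgeList,
    neurons: pd.DataFrame,
    premotor_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Motor-module preference vector per premotor neuron.

    For each neuron making >= 1 synapse onto a motor neuron: synapses onto
    each module's MNs divided by synapses onto all MNs (rows sum to 1).
    Neurons with no MN output are excluded with a warning when explicitly
    requested.
    """
    info = neuron_index(neurons)
    module_of = info.loc[info["neuron_class"] == "motor", "motor_module"].astype(int)
    modules = sorted(module_of.unique())
    mn_ids = set(module_of.index)
    rows: dict[str, dict[int, float]] = {}
    candidates = (
        premotor_ids
        if premotor_ids is not None
        else sorted(edges.edges["pre_id"].unique())
    )
    for nid in candidates:
        out = edges.out_counts(nid)
        onto_mn = {post: c for post, c in out.items() if post in mn_ids}
        total = sum(onto_mn.values())
        if total == 0:
            if premotor_ids is not None:
                logger.warning("neuron %s makes no motor-neuron synapses; excluded", nid)
            continue
        binned = {m: 0.0 for m in modules}
        for post, c in onto_mn.items():
            binned[int(module_of[post])] += c / total
        rows[nid] = binned
    out_df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    out_df = out_df[modules]
    out_df.index.name = "neuron_id"
    out_df.columns = [f"module_{m}" for m in modules]
    return out_df


def subtype_preference(
    edges: EdgeList,
    neurons: pd.DataFrame,
    neuron_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sensory-subtype preference vector per FeCO-recipient neuron.

    For each neuron receiving >= 1 synapse from a FeCO axon: synapses
    received from each subtype divided by total FeCO synapses received (rows
    sum to 1).
    """
    from .core import FECO_SUBTYPES

    info = neuron_index(neurons)
    feco = info[(info["neuron_class"] == "sensory") & info["subtype"].isin(FECO_SUBTYPES)]
    subtype_of = feco["subtype"]
    rows: dict[str, dict[str, float]] = {}
    candidates = (
        neuron_ids
        if neuron_ids is not None
        else sorted(edges.edges["post_id"].unique())
    )
    for nid in candidates:
        incoming = edges.in_counts(nid)
        from_feco = {pre: c for pre, c in incoming.items() if pre in subtype_of.index}
        total = sum(from_feco.values())
        if total == 0:
            if neuron_ids is not None:
                logger.warning("neuron %s receives no FeCO synapses; excluded", nid)
            continue
        binned = {s: 0.0 for s in FECO_SUBTYPES}
        for pre, c in from_feco.items():
            binned[subtype_of[pre]] += c / total
        rows[nid] = binned
    out_df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    out_df = out_df[list(FECO_SUBTYPES)]
    out_df.index.name = "neuron_id"
    return out_df
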