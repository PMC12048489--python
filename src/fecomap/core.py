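"""Shared data model for annotated connectome tables.

A connectome here is two flat tables: a neuron annotation table (one row per
neuron: morphological class, sensory subtype, hemilineage, fast-acting
transmitter, segment, motor-module id) and a synapse table (one row per
synaptic contact: presynaptic id, postsynaptic id, x/y/z position in nm).
Everything downstream works on the :class:`EdgeList` aggregated from them.

Synapse polarity is inferred from the transmitter released by the presynaptic
neuron: acetylcholine is excitatory, GABA inhibitory, and glutamate --
excitatory at the neuromuscular junction but acting through the
glutamate-gated chloride channel GluCl in the VNC -- defaults to inhibitory.
Sensory afferents are assumed cholinergic and therefore always excitatory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

NEURON_CLASSES = (
    "sensory",
    "motor",
    "local",
    "intersegmental",
    "ascending",
    "descending",
    "fragment",
)

#: The five sensory subtypes of the femoral chordotonal organ. Claw neurons
#: encode tibia position, hook neurons directional tibia movement, and club
#: neurons bidirectional movement and high-frequency vibration.
FECO_SUBTYPES = ("claw_ext", "claw_flex", "hook_ext", "hook_flex", "club")

SUBTYPES = FECO_SUBTYPES + ("none",)

TRANSMITTERS = ("ACh", "GABA", "Glu", "unknown")


class ValidationError(ValueError):
    """Raised when an input table violates the schema or an invariant."""


@dataclass(frozen=True)
class SignMap:
    """Transmitter -> polarity convention.

    ``sign`` returns +1, -1 or ``None``; an unknown transmitter maps to
    ``None`` (undefined), never silently to a sign. The defaults follow the
    central-nervous-system convention (Glu inhibitory via GluCl); override
    ``signs`` for e.g. neuromuscular contexts where Glu is excitatory.
    """

    signs: Mapping[str, int] = field(
        default_factory=lambda: {"ACh": +1, "GABA": -1, "Glu": -1}
    )

    def sign(self, transmitter: str) -> int | None:
        return self.signs.get(transmitter)


DEFAULT_SIGNS = SignMap()


def sign_of(neuron: Mapping, signs: SignMap = DEFAULT_SIGNS) -> int | None:
    """Polarity of a neuron's output synapses.

    Sensory neurons are assumed cholinergic and always return +1; every other
    neuron returns the :class:`SignMap` value for its transmitter, which may
    be ``None`` (undefined).
    """
    if neuron["neuron_class"] == "sensory":
        return +1
    return signs.sign(neuron.get("transmitter", "unknown"))


@dataclass
class EdgeList:
    """Aggregated directed connectivity: (pre, post, synapse count) edges.

    ``input_total`` maps every postsynaptic id to its total number of input
    synapses from *all* sources (including autapses, fragments and edges
    below any analysis threshold); it is the denominator of every impact
    ratio. ``edges`` is sorted by (pre_id, post_id) so that identical inputs
    produce an identical object regardless of synapse-row order.
    """

    edges: pd.DataFrame
    input_total: pd.Series
    n_autapses: int = 0

    def __post_init__(self) -> None:
        self.edges = (
            self.edges.sort_values(["pre_id", "post_id"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.input_total = self.input_total.sort_index()
        self.input_total.index.name = "post_id"
        self.input_total.name = "input_total"
        bad = self.edges[self.edges["count"] < 1]
        if len(bad):
            raise ValidationError("edge counts must be >= 1")
        self._out: dict[str, dict[str, int]] = {}
        self._in: dict[str, dict[str, int]] = {}
        for pre, post, count in self.edges.itertuples(index=False):
            self._out.setdefault(pre, {})[post] = int(count)
            self._in.setdefault(post, {})[pre] = int(count)

    # -- lookups -------------------------------------------------------
    def count(self, pre: str, post: str) -> int:
        return self._out.get(pre, {}).get(post, 0)

    def out_counts(self, pre: str) -> dict[str, int]:
        """post_id -> synapse count for one presynaptic neuron."""
        return dict(self._out.get(pre, {}))

    def in_counts(self, post: str) -> dict[str, int]:
        """pre_id -> synapse count for one postsynaptic neuron."""
        return dict(self._in.get(post, {}))

    def total_synapses(self) -> int:
        return int(self.edges["count"].sum())

    def scaled(self, factor: int) -> "EdgeList":
        """Multiply every synapse count (and input total) by ``factor``."""
        if factor < 1:
            raise ValueError("factor must be a positive integer")
        edges = self.edges.copy()
        edges["count"] = edges["count"] * factor
        return EdgeList(edges, self.input_total * factor, self.n_autapses * factor)

    def __eq__(self, other: object) -> bool:  # order-insensitive equality
        if not isinstance(other, EdgeList):
            return NotImplemented
        return (
            self.edges.equals(other.edges)
            and self.input_total.equals(other.input_total)
            and self.n_autapses == other.n_autapses
        )


def build_edge_list(
    synapses: pd.DataFrame,
    neurons: pd.DataFrame | None = None,
    *,
    include_autapses: bool = False,
) -> EdgeList:
    """Aggregate a synapse table into an :class:`EdgeList`.

    Counts equal the number of synapse rows per ordered (pre, post) pair.
    Autapse rows (pre == post) are excluded from the edges by default but are
    always counted in ``input_total``, which records the full predicted input
    of each neuron. When ``neurons`` is given, every id in the synapse table
    must appear in it (fragments included as class ``fragment``); unknown ids
    raise :class:`ValidationError` listing the offenders.
    """
    if neurons is not None:
        known = set(neurons["neuron_id"])
        ids = pd.unique(
            pd.concat([synapses["pre_id"], synapses["post_id"]], ignore_index=True)
        )
        unknown = sorted(set(ids) - known)
        if unknown:
            raise ValidationError(
                f"synapse table references {len(unknown)} unknown neuron id(s): "
                + ", ".join(map(str, unknown[:20]))
            )
    if len(synapses) == 0:
        edges = pd.DataFrame({"pre_id": [], "post_id": [], "count": []}).astype(
            {"pre_id": str, "post_id": str, "count": int}
        )
        return EdgeList(edges, pd.Series(dtype=int), 0)

    input_total = synapses.groupby("post_id").size().astype(int)
    is_autapse = synapses["pre_id"] == synapses["post_id"]
    n_autapses = int(is_autapse.sum())
    rows = synapses if include_autapses else synapses[~is_autapse]
    edges = (
        rows.groupby(["pre_id", "post_id"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    return EdgeList(edges, input_total, 0 if include_autapses else n_autapses)


@dataclass
class AnalysisConfig:
    """Tunable parameters shared by the whole pipeline.

    ``out_threshold``/``in_threshold`` are the reconstruction-completeness
    thresholds for calling something a partner (>=4 synapses received from a
    seed axon; >=3 synapses made onto a seed axon); they mitigate false
    positives from automatic synapse detection.
    """

    out_threshold: int = 4
    in_threshold: int = 3
    n_branches: int = 3
    n_resamples: int = 50
    rng_seed: int = 0
    linkage: str = "average"
    n_clusters: int | None = None
    distance_threshold: float | None = 0.5
    pooled_inclusion: bool = False
    include_fragment_inputs: bool = True
    saturation_target_n: int = 152
    log_fit_form: str = "shifted"

    def __post_init__(self) -> None:
        if self.out_threshold < 1 or self.in_threshold < 1:
            raise ValidationError("thresholds must be >= 1")
        if self.n_resamples < 1:
            raise ValidationError("n_resamples must be >= 1")
        if self.n_branches < 1:
            raise ValidationError("n_branches must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def feco_seeds(neurons: pd.DataFrame, segment: str | None = None) -> pd.DataFrame:
    """Rows of the neuron table that are FeCO sensory axons.

    Optionally restrict to one segment (e.g. ``"T1L"``, the front left leg
    neuromere).
    """
    mask = (neurons["neuron_class"] == "sensory") & neurons["subtype"].isin(
        FECO_SUBTYPES
    )
    if segment is not None:
        mask &= neurons["segment"] == segment
    return neurons[mask]


def neuron_index(neurons: pd.DataFrame) -> pd.DataFrame:
    """The neuron table indexed by ``neuron_id`` (id order preserved)."""
    return neurons.set_index("neuron_id", drop=False)
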