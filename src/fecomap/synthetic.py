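"""Synthetic annotated connectomes with planted, recoverable structure.

The generator emulates the statistical structure of a proofread leg
sensorimotor connectome: ~150 FeCO sensory neurons in five subtypes (claw
extension/flexion, hook extension/flexion, club), interneurons in labelled
hemilineages with known transmitters, motor neurons grouped into modules
named after the 18 front-leg muscles, club terminals stratified along the
dorsal-ventral axis into three frequency groups, and premotor interneurons
dedicated to one sensory subtype and one motor module.

Planted structure, all recorded in :class:`GroundTruth`:

* each proprioceptive subtype wires (directly and through dedicated
  excitatory premotor neurons) to its "excited" tibia module and through
  dedicated inhibitory premotor neurons to the antagonist module, so
  flexion- and extension-tuned seeds have opposite-signed motor impacts;
* club seeds make no motor-neuron contacts and reach motor circuits only
  through a faint indirect long-tendon-muscle pathway, so their motor impact
  is more than an order of magnitude weaker;
* clubs from different "legs" that share a frequency group share downstream
  partner pools, so cross-leg clustering groups by frequency, not leg;
* interneuron classes downstream of clubs (hemilineages 10B, 8B, 0A/0B, 9A)
  are recurrently wired with fixed block probabilities;
* proprioceptive output synapses are drawn from three separated spatial
  branch clouds, with each partner preferring one branch.

Synapse counts per connected pair are negative binomial (overdispersed, as
connectome edge weights are), truncated at 1; optional multiplicative count
jitter and a cross-block edge rate provide the documented noise conditions.
Roughly half of every interneuron's input synapses come from unproofread
``fragment`` objects, emulating incomplete reconstruction, so impact
denominators reflect full predicted input. Fidelity to any real dataset is
qualitative, not quantitative: no attempt is made to clone real degree
distributions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AnalysisConfig, FECO_SUBTYPES, ValidationError

PROPRIO_SUBTYPES = ("claw_ext", "claw_flex", "hook_ext", "hook_flex")

#: Front-leg muscle labels used as default motor-module names (module id ->
#: label); ids 8/9 are the antagonist tibia extensor/flexor pair and 13 the
#: long tendon muscle that controls substrate grip.
MODULE_LABELS = {
    1: "coxa_promotor",
    2: "coxa_remotor",
    3: "coxa_abductor",
    4: "coxa_adductor",
    5: "trochanter_extensor",
    6: "trochanter_flexor",
    7: "femur_reductor",
    8: "tibia_extensor",
    9: "tibia_flexor",
    10: "tibia_accessory_flexor",
    11: "tarsus_depressor",
    12: "tarsus_levator",
    13: "long_tendon_muscle",
    14: "tergotrochanter",
    15: "sternotrochanter",
    16: "pleural_remotor",
    17: "trochanter_reductor",
    18: "tarsus_retro_depressor",
}

#: Hemilineage -> primary fast transmitter (neurons of one hemilineage share
#: a transmitter, which is how signs are inferred for real data).
HEMILINEAGE_TRANSMITTER = {
    "10B": "ACh",
    "8B": "ACh",
    "0A/0B": "GABA",
    "9A": "GABA",
    "13B": "GABA",
    "20A/22A": "ACh",
    "15B": "Glu",
    "1B": "GABA",
    "23B": "ACh",
}

_CLASS_CENTERS = {
    "local": (20000.0, 20000.0, 25000.0),
    "intersegmental": (25000.0, 15000.0, 30000.0),
    "ascending": (30000.0, 10000.0, 35000.0),
    "motor": (15000.0, 25000.0, 20000.0),
    "sensory": (20000.0, 20000.0, 30000.0),
    "fragment": (22000.0, 18000.0, 28000.0),
}

_PROPRIO_BASE = {
    "claw_ext": (10000.0, 12000.0, 20000.0),
    "claw_flex": (12000.0, 14000.0, 24000.0),
    "hook_ext": (14000.0, 16000.0, 28000.0),
    "hook_flex": (16000.0, 18000.0, 32000.0),
}

#: Planted sign scheme: flexion-tuned seeds excite the tibia extensor module
#: and inhibit the flexor module; extension-tuned seeds do the opposite.
ANTAGONISTS = {
    "claw_flex": (8, 9),
    "hook_flex": (8, 9),
    "claw_ext": (9, 8),
    "hook_ext": (9, 8),
}

_DEFAULT_MODULE_MNS = {
    m: n
    for m, n in zip(
        MODULE_LABELS,
        [3, 2, 3, 2, 2, 3, 2, 4, 4, 2, 2, 2, 3, 2, 2, 2, 2, 2],
    )
}


@dataclass
class SyntheticSpec:
    """Study conditions for the generator; defaults are the reconstruction-
    scale conditions (subtype counts 8/13/9/13/37, a 14-club second leg,
    three frequency groups, club interneuron pools 10B=38/8B=15/0A-0B=18/
    9A=19, half of interneuron input unproofread)."""

    subtype_counts: dict = field(
        default_factory=lambda: {
            "claw_ext": 8,
            "claw_flex": 13,
            "hook_ext": 9,
            "hook_flex": 13,
            "club": 37,
        }
    )
    second_leg_club_count: int = 14
    n_frequency_groups: int = 3
    module_mns: dict = field(default_factory=lambda: dict(_DEFAULT_MODULE_MNS))
    n_premotor_per_block: int = 3
    premotor_dedication_prob: float = 0.9
    club_interneurons: dict = field(
        default_factory=lambda: {"10B": 38, "8B": 15, "0A/0B": 18, "9A": 19}
    )
    n_proprio_locals_per_subtype: int = 5
    n_gate_neurons: int = 4
    other_sensory: dict = field(
        default_factory=lambda: {
            "hair_plate": 5,
            "campaniform": 5,
            "wing": 4,
            "neck_chordotonal": 3,
        }
    )
    n_fragments: int = 300
    background_input_fraction: float = 0.5
    p_within: float = 0.8
    cross_block_rate: float = 0.10
    count_mean: float = 6.0
    count_dispersion: float = 2.0
    strong_count_mean: float = 10.0
    count_jitter: bool = True
    z_strata: tuple = (15000.0, 30000.0, 45000.0)
    stratum_sd: float = 3000.0
    branch_offsets: tuple = (-7000.0, 0.0, 7000.0)
    branch_sd: float = 2000.0
    branch_fidelity: float = 0.8
    leg_x_offset: float = 60000.0

    def validate(self) -> None:
        for name, p in (
            ("premotor_dedication_prob", self.premotor_dedication_prob),
            ("cross_block_rate", self.cross_block_rate),
            ("p_within", self.p_within),
            ("background_input_fraction", self.background_input_fraction),
            ("branch_fidelity", self.branch_fidelity),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        unknown = set(self.subtype_counts) - set(FECO_SUBTYPES)
        if unknown:
            raise ValidationError(f"unknown subtypes in spec: {sorted(unknown)}")
        for m in (8, 9, 13):
            if m not in self.module_mns:
                raise ValidationError(
                    "module_mns must include the tibia extensor (8), tibia "
                    "flexor (9) and long tendon muscle (13) modules"
                )
        if self.n_frequency_groups < 1:
            raise ValidationError("need at least one frequency group")
        if self.background_input_fraction >= 1.0:
            raise ValidationError("background_input_fraction must be < 1")

    # -- size presets ---------------------------------------------------
    @classmethod
    def paper_scale(cls) -> "SyntheticSpec":
        return cls()

    @classmethod
    def small(cls) -> "SyntheticSpec":
        return cls(
            subtype_counts={
                "claw_ext": 4,
                "claw_flex": 6,
                "hook_ext": 5,
                "hook_flex": 6,
                "club": 16,
            },
            second_leg_club_count=6,
            module_mns={1: 2, 5: 2, 8: 3, 9: 3, 13: 2, 14: 2},
            n_premotor_per_block=2,
            club_interneurons={"10B": 12, "8B": 6, "0A/0B": 6, "9A": 6},
            n_proprio_locals_per_subtype=4,
            n_gate_neurons=3,
            other_sensory={
                "hair_plate": 3,
                "campaniform": 3,
                "wing": 2,
                "neck_chordotonal": 2,
            },
            n_fragments=40,
        )

    @classmethod
    def tiny(cls) -> "SyntheticSpec":
        return cls(
            subtype_counts={"claw_flex": 1, "hook_flex": 1, "club": 2},
            second_leg_club_count=0,
            n_frequency_groups=2,
            module_mns={8: 1, 9: 1, 13: 1},
            n_premotor_per_block=1,
            club_interneurons={"10B": 2, "8B": 1, "0A/0B": 1, "9A": 1},
            n_proprio_locals_per_subtype=1,
            n_gate_neurons=1,
            other_sensory={},
            n_fragments=2,
            count_mean=8.0,
            strong_count_mean=12.0,
            cross_block_rate=0.0,
            count_jitter=False,
        )


@dataclass
class GroundTruth:
    """Planted labels emitted alongside the tables, for recovery tests."""

    neurons: pd.DataFrame  # organ, freq_group, dedication, leg per neuron
    edges: pd.DataFrame  # pre_id, post_id, block-of-origin label
    synapse_branch: pd.Series  # planted branch per synapse row (-1 if n/a)
    antagonists: dict
    frequency_groups: pd.Series  # club seed -> frequency group


def _split_groups(ids: list, n_groups: int) -> dict[str, int]:
    """Round-robin split of an ordered id list into n near-equal groups."""
    return {nid: i % n_groups for i, nid in enumerate(ids)}


class _Builder:
    def __init__(self, spec: SyntheticSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.neuron_rows: list[dict] = []
        self.edges: dict[tuple[str, str], int] = {}
        self.edge_block: dict[tuple[str, str], str] = {}
        self.pools: dict[str, list[str]] = {}
        self.gt_rows: list[dict] = []

    # -- neurons -------------------------------------------------------
    def add_neuron(
        self,
        nid: str,
        neuron_class: str,
        *,
        subtype: str = "none",
        hemilineage: str = "unknown",
        transmitter: str = "unknown",
        segment: str = "T1L",
        motor_module=None,
        organ: str = "none",
        freq_group: int = -1,
        dedicated_subtype: str = "none",
        dedicated_module: int = -1,
        dedicated: bool = False,
    ) -> str:
        self.neuron_rows.append(
            dict(
                neuron_id=nid,
                neuron_class=neuron_class,
                subtype=subtype,
                hemilineage=hemilineage,
                transmitter=transmitter,
                segment=segment,
                motor_module=motor_module,
            )
        )
        self.gt_rows.append(
            dict(
                neuron_id=nid,
                organ=organ,
                freq_group=freq_group,
                dedicated_subtype=dedicated_subtype,
                dedicated_module=dedicated_module,
                dedicated=dedicated,
            )
        )
        return nid

    # -- counts --------------------------------------------------------
    def draw_count(self, mean: float) -> int:
        spec, rng = self.spec, self.rng
        r = spec.count_dispersion
        p = r / (r + mean)
        count = 0
        while count < 1:  # zero-truncated negative binomial
            count = int(rng.negative_binomial(r, p))
        if spec.count_jitter:
            count = max(1, int(round(count * rng.lognormal(0.0, 0.2))))
        return count

    def add_edge(self, pre: str, post: str, mean: float, block: str) -> None:
        if pre == post:
            return
        key = (pre, post)
        count = self.draw_count(mean)
        if key in self.edges:
            self.edges[key] += count
        else:
            self.edges[key] = count
            self.edge_block[key] = block
    def block(
        self, pres: list, posts: list, p: float, mean: float, name: str
    ) -> None:
        for pre in pres:
            for post in posts:
                if self.rng.random() < p:
                    self.add_edge(pre, post, mean, name)


def generate_connectome(
    spec: SyntheticSpec, rng_seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (neuron table, synapse table, ground truth). Deterministic
    given ``rng_seed``."""
    spec.validate()
    rng = np.random.default_rng(rng_seed)
    b = _Builder(spec, rng)

    # ---- sensory seeds ----
    seeds_by_subtype: dict[str, list[str]] = {}
    for subtype in FECO_SUBTYPES:
        n = spec.subtype_counts.get(subtype, 0)
        ids = [
            b.add_neuron(
                f"t1l_{subtype}_{i:02d}",
                "sensory",
                subtype=subtype,
                transmitter="ACh",
                segment="T1L",
                organ="feco",
            )
            for i in range(n)
        ]
        seeds_by_subtype[subtype] = ids
    t2r_clubs = [
        b.add_neuron(
            f"t2r_club_{i:02d}",
            "sensory",
            subtype="club",
            transmitter="ACh",
            segment="T2R",
            organ="feco",
        )
        for i in range(spec.second_leg_club_count)
    ]
    club_groups = _split_groups(seeds_by_subtype["club"], spec.n_frequency_groups)
    club_groups.update(_split_groups(t2r_clubs, spec.n_frequency_groups))
    for row in b.gt_rows:
        if row["neuron_id"] in club_groups:
            row["freq_group"] = club_groups[row["neuron_id"]]

    # ---- motor neurons per module ----
    mns_by_module: dict[int, list[str]] = {}
    for module, n_mn in sorted(spec.module_mns.items()):
        mns_by_module[module] = [
            b.add_neuron(
                f"mn_m{module:02d}_{i:02d}",
                "motor",
                transmitter="Glu",
                motor_module=module,
            )
            for i in range(n_mn)
        ]

    # ---- dedicated premotor blocks (proprio subtype x antagonist module) ----
    inhib_cycle = [("13B", "GABA"), ("15B", "Glu"), ("13B", "GABA")]
    premotors: list[str] = []
    pm_info: dict[str, tuple[str, int]] = {}  # pm -> (subtype, module)
    pm_dedicated: dict[str, bool] = {}
    active_proprio = [s for s in PROPRIO_SUBTYPES if seeds_by_subtype.get(s)]
    for subtype in active_proprio:
        excited, inhibited = ANTAGONISTS[subtype]
        for module in (excited, inhibited):
            excitatory = module == excited
            for i in range(spec.n_premotor_per_block):
                hemi, tx = (
                    ("20A/22A", "ACh")
                    if excitatory
                    else inhib_cycle[i % len(inhib_cycle)]
                )
                dedicated = rng.random() < spec.premotor_dedication_prob
                nid = b.add_neuron(
                    f"pm_{subtype}_m{module:02d}_{i:02d}",
                    "local",
                    hemilineage=hemi,
                    transmitter=tx,
                    dedicated_subtype=subtype,
                    dedicated_module=module,
                    dedicated=dedicated,
                )
                premotors.append(nid)
                pm_info[nid] = (subtype, module)
                pm_dedicated[nid] = dedicated
        b.pools[f"pm_{subtype}"] = [
            pm for pm in premotors if pm_info[pm][0] == subtype
        ]
    ltm_premotor = b.add_neuron(
        "pm_ltm_00",
        "local",
        hemilineage="20A/22A",
        transmitter="ACh",
        dedicated_subtype="none",
        dedicated_module=13,
        dedicated=True,
    )

    # ---- club interneuron pools ----
    def slug(hemi: str) -> str:
        return hemi.replace("/", "").replace("A", "a").replace("B", "b")

    club_pools: dict[str, list[str]] = {}
    group_pools: dict[int, list[str]] = {g: [] for g in range(spec.n_frequency_groups)}
    for hemi in ("10B", "8B", "0A/0B", "9A"):
        n = spec.club_interneurons.get(hemi, 0)
        tx = HEMILINEAGE_TRANSMITTER[hemi]
        ids = []
        for i in range(n):
            if hemi in ("10B", "8B"):
                cls = "ascending" if i % 5 < 2 else "intersegmental"
            elif hemi == "0A/0B":
                cls = "intersegmental"
            else:
                cls = "local"
            ids.append(
                b.add_neuron(
                    f"in_{slug(hemi)}_{i:02d}",
                    cls,
                    hemilineage=hemi,
                    transmitter=tx,
                )
            )
        club_pools[hemi] = ids
        if hemi in ("10B", "8B"):
            for nid, g in _split_groups(ids, spec.n_frequency_groups).items():
                group_pools[g].append(nid)

    # ---- subtype-specific local interneuron pools ----
    locals_by_subtype: dict[str, list[str]] = {}
    local_cycle = [("1B", "GABA"), ("23B", "ACh")]
    for subtype in active_proprio:
        ids = []
        for i in range(spec.n_proprio_locals_per_subtype):
            hemi, tx = local_cycle[i % 2]
            ids.append(
                b.add_neuron(
                    f"in_loc_{subtype}_{i:02d}",
                    "local",
                    hemilineage=hemi,
                    transmitter=tx,
                )
            )
        locals_by_subtype[subtype] = ids

    # ---- 9A gate neurons (inhibit hook axons and premotor neurons) ----
    gates = [
        b.add_neuron(
            f"in_9a_gate_{i:02d}", "local", hemilineage="9A", transmitter="GABA"
        )
        for i in range(spec.n_gate_neurons)
    ]

    # ---- non-FeCO sensory populations ----
    other_sensory: dict[str, list[str]] = {}
    for organ, n in sorted(spec.other_sensory.items()):
        other_sensory[organ] = [
            b.add_neuron(
                f"sn_{organ}_{i:02d}", "sensory", transmitter="ACh", organ=organ
            )
            for i in range(n)
        ]

    fragments = [
        b.add_neuron(f"frag_{i:03d}", "fragment") for i in range(spec.n_fragments)
    ]

    # ---- edges ----
    mean, strong = spec.count_mean, spec.strong_count_mean
    for subtype in active_proprio:
        seeds = seeds_by_subtype[subtype]
        excited, _ = ANTAGONISTS[subtype]
        b.block(seeds, b.pools[f"pm_{subtype}"], spec.p_within, strong * 0.8,
                f"seed_{subtype}->premotor")
        b.block(seeds, mns_by_module[excited], 0.5, mean * 0.7,
                f"seed_{subtype}->mn_direct")
        b.block(seeds, locals_by_subtype[subtype], 0.7, mean,
                f"seed_{subtype}->local")
    for subtype in ("hook_ext", "hook_flex"):
        if seeds_by_subtype.get(subtype):
            b.block(seeds_by_subtype[subtype], gates, 0.5, mean * 0.7,
                    f"seed_{subtype}->gate")

    all_clubs = seeds_by_subtype["club"] + t2r_clubs
    for club in all_clubs:
        g = club_groups[club]
        for partner in group_pools[g]:
            if rng.random() < 0.9:
                b.add_edge(club, partner, strong, f"club_g{g}->group_pool")
        for partner in club_pools["0A/0B"]:
            if rng.random() < 0.7:
                b.add_edge(club, partner, mean, "club->0a0b_shared")
        for partner in club_pools["9A"]:
            if rng.random() < 0.5:
                b.add_edge(club, partner, mean * 0.8, "club->9a_shared")

    for pm in premotors:
        subtype, module = pm_info[pm]
        b.block([pm], mns_by_module[module], 1.0, strong, "premotor->mn")
        if not pm_dedicated[pm]:
            other_modules = [m for m in mns_by_module if m != module]
            second = other_modules[int(rng.integers(len(other_modules)))]
            b.block([pm], mns_by_module[second], 0.8, mean * 0.7,
                    "premotor->mn_secondary")
            other_subtypes = [s for s in active_proprio if s != subtype]
            if other_subtypes:
                s2 = other_subtypes[int(rng.integers(len(other_subtypes)))]
                extra_seeds = list(
                    rng.choice(
                        seeds_by_subtype[s2],
                        size=min(2, len(seeds_by_subtype[s2])),
                        replace=False,
                    )
                )
                b.block(extra_seeds, [pm], 1.0, mean * 0.7,
                        "seed_secondary->premotor")
    b.block(gates, premotors, 0.5, mean * 0.8, "gate->premotor")
    for subtype in ("hook_ext", "hook_flex"):
        if seeds_by_subtype.get(subtype):
            b.block(gates, seeds_by_subtype[subtype], 0.5, mean * 0.8, "gate->hook")

    # faint indirect club -> motor pathway through the long tendon muscle
    b.block([ltm_premotor], mns_by_module[13], 1.0, mean, "ltm_premotor->mn")
    b.block(club_pools["8B"][:3], [ltm_premotor], 0.5, 4.0, "8b->ltm_premotor")

    for organ in ("hair_plate", "campaniform"):
        for sn in other_sensory.get(organ, []):
            for subtype in active_proprio:
                b.block([sn], locals_by_subtype[subtype], 0.3, mean * 0.8,
                        f"{organ}->proprio_local")
            b.block([sn], premotors, 0.15, mean * 0.7, f"{organ}->premotor")
    for organ in ("wing", "neck_chordotonal"):
        for sn in other_sensory.get(organ, []):
            b.block([sn], club_pools["10B"] + club_pools["8B"], 0.25, mean * 0.8,
                    f"{organ}->club_pool")
            b.block([sn], club_pools["0A/0B"], 0.3, mean * 0.8, f"{organ}->0a0b")

    recurrence = {
        ("10B", "8B"): 0.30,
        ("10B", "0A/0B"): 0.20,
        ("8B", "0A/0B"): 0.25,
        ("8B", "10B"): 0.20,
        ("0A/0B", "10B"): 0.25,
        ("0A/0B", "8B"): 0.20,
        ("0A/0B", "9A"): 0.20,
        ("9A", "10B"): 0.30,
        ("9A", "8B"): 0.20,
    }
    for (src, dst), p in recurrence.items():
        b.block(club_pools[src], club_pools[dst], p, mean * 0.8,
                f"recur_{slug(src)}->{slug(dst)}")

    # cross-block noise: weak edges from seeds onto foreign pools
    if spec.cross_block_rate > 0:
        foreign_pool_of: dict[str, list[str]] = {}
        all_proprio_targets = sorted(
            {t for s in active_proprio
             for t in b.pools[f"pm_{s}"] + locals_by_subtype[s]}
        )
        club_targets = sorted(
            set(club_pools["10B"] + club_pools["8B"] + club_pools["0A/0B"]
                + club_pools["9A"])
        )
        for subtype in active_proprio:
            own = set(b.pools[f"pm_{subtype}"] + locals_by_subtype[subtype])
            foreign_pool_of[subtype] = [
                t for t in all_proprio_targets + club_targets if t not in own
            ]
        for club in all_clubs:
            g = club_groups[club]
            own = set(group_pools[g])
            foreign_pool_of[club] = [
                t for t in all_proprio_targets + club_targets if t not in own
            ]
        for subtype in active_proprio:
            for seed in seeds_by_subtype[subtype]:
                n_own = sum(1 for (p_, _q) in b.edges if p_ == seed)
                n_cross = rng.binomial(n_own, spec.cross_block_rate)
                pool = foreign_pool_of[subtype]
                for t in rng.choice(pool, size=min(n_cross, len(pool)), replace=False):
                    b.add_edge(seed, t, 3.0, "cross_block")
        for club in all_clubs:
            n_own = sum(1 for (p_, _q) in b.edges if p_ == club)
            n_cross = rng.binomial(n_own, spec.cross_block_rate)
            pool = foreign_pool_of[club]
            for t in rng.choice(pool, size=min(n_cross, len(pool)), replace=False):
                b.add_edge(club, t, 3.0, "cross_block")

    # a sprinkling of seed output onto unproofread fragments
    if fragments:
        for subtype in FECO_SUBTYPES:
            for seed in seeds_by_subtype.get(subtype, []):
                if rng.random() < 0.5:
                    frag = fragments[int(rng.integers(len(fragments)))]
                    b.add_edge(seed, frag, 3.0, "seed->fragment")

    # ---- synapse placement ----
    neurons = pd.DataFrame(b.neuron_rows)
    neurons["motor_module"] = pd.array(neurons["motor_module"], dtype="Int64")
    info = neurons.set_index("neuron_id")
    seg_of = info["segment"].to_dict()
    class_of = info["neuron_class"].to_dict()
    subtype_of = info["subtype"].to_dict()

    preferred_branch: dict[tuple[str, str], int] = {}
    rows_pre, rows_post, xs, ys, zs, branches = [], [], [], [], [], []
    for (pre, post), count in b.edges.items():
        cls = class_of[pre]
        offset_x = spec.leg_x_offset if seg_of[pre] == "T2R" else 0.0
        if cls == "sensory" and subtype_of[pre] in PROPRIO_SUBTYPES:
            base = _PROPRIO_BASE[subtype_of[pre]]
            key = (subtype_of[pre], post)
            if key not in preferred_branch:
                preferred_branch[key] = int(rng.integers(3))
            pref = preferred_branch[key]
            branch_idx = np.where(
                rng.random(count) < spec.branch_fidelity,
                pref,
                rng.integers(0, 3, size=count),
            )
            cz = base[2] + np.asarray(spec.branch_offsets)[branch_idx]
            xs.append(rng.normal(base[0] + offset_x, spec.branch_sd, count))
            ys.append(rng.normal(base[1], spec.branch_sd, count))
            zs.append(rng.normal(cz, spec.branch_sd))
            branches.append(branch_idx + 1)
        elif cls == "sensory" and subtype_of[pre] == "club":
            g = club_groups[pre]
            xs.append(rng.normal(20000.0 + offset_x, 4000.0, count))
            ys.append(rng.normal(20000.0, 4000.0, count))
            zs.append(rng.normal(spec.z_strata[g % len(spec.z_strata)],
                                 spec.stratum_sd, count))
            branches.append(np.full(count, -1))
        else:
            cx, cy, cz = _CLASS_CENTERS.get(cls, _CLASS_CENTERS["sensory"])
            xs.append(rng.normal(cx + offset_x, 8000.0, count))
            ys.append(rng.normal(cy, 8000.0, count))
            zs.append(rng.normal(cz, 8000.0, count))
            branches.append(np.full(count, -1))
        rows_pre.extend([pre] * count)
        rows_post.extend([post] * count)

    # ---- background input from fragments (unproofread upstream partners) ----
    bg_frac = spec.background_input_fraction
    if fragments and bg_frac > 0:
        in_graph: dict[str, int] = {}
        for (pre, post), count in b.edges.items():
            in_graph[post] = in_graph.get(post, 0) + count
        for post in sorted(in_graph):
            if class_of[post] in ("fragment", "sensory"):
                continue
            total = in_graph[post]
            deficit = int(round(total / (1.0 - bg_frac))) - total
            cx, cy, cz = _CLASS_CENTERS.get(class_of[post], _CLASS_CENTERS["sensory"])
            while deficit > 0:
                count = min(b.draw_count(spec.count_mean), deficit)
                frag = fragments[int(rng.integers(len(fragments)))]
                b.edges[(frag, post)] = b.edges.get((frag, post), 0) + count
                b.edge_block.setdefault((frag, post), "background")
                rows_pre.extend([frag] * count)
                rows_post.extend([post] * count)
                xs.append(rng.normal(cx, 8000.0, count))
                ys.append(rng.normal(cy, 8000.0, count))
                zs.append(rng.normal(cz, 8000.0, count))
                branches.append(np.full(count, -1))
                deficit -= count

    synapses = pd.DataFrame(
        {
            "pre_id": rows_pre,
            "post_id": rows_post,
            "x": np.concatenate(xs) if xs else np.array([]),
            "y": np.concatenate(ys) if ys else np.array([]),
            "z": np.concatenate(zs) if zs else np.array([]),
        }
    )
    gt_edges = pd.DataFrame(
        [
            {"pre_id": pre, "post_id": post, "block": b.edge_block[(pre, post)]}
            for (pre, post) in b.edges
        ]
    )
    gt = GroundTruth(
        neurons=pd.DataFrame(b.gt_rows),
        edges=gt_edges,
        synapse_branch=pd.Series(
            np.concatenate(branches) if branches else np.array([], dtype=int),
            name="branch",
        ).astype(int),
        antagonists={s: ANTAGONISTS[s] for s in active_proprio},
        frequency_groups=pd.Series(club_groups, name="freq_group"),
    )
    return neurons, synapses, gt


SIZES = ("tiny", "small", "paper_scale")


def make_fixture(size: str, rng_seed: int, out_dir) -> dict[str, Path]:
    """Generate a connectome of a named size and write its CSVs + ground
    truth to ``out_dir``. Returns the paths written."""
    from . import io as io_tables

    if size not in SIZES:
        raise ValidationError(f"size must be one of {SIZES}")
    spec = getattr(SyntheticSpec, size)()
    neurons, synapses, gt = generate_connectome(spec, rng_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "neurons": out / "neurons.csv",
        "synapses": out / "synapses.csv",
        "gt_neurons": out / "ground_truth_neurons.csv",
        "gt_edges": out / "ground_truth_edges.csv",
        "config": out / "config.yaml",
    }
    io_tables.write_neuron_table(neurons, paths["neurons"])
    io_tables.write_synapse_table(synapses, paths["synapses"])
    io_tables.write_frame(gt.neurons, paths["gt_neurons"])
    io_tables.write_frame(gt.edges, paths["gt_edges"])
    AnalysisConfig(rng_seed=rng_seed).to_yaml(paths["config"])
    return paths
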