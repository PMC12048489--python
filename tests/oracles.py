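"""Independent brute-force oracles and random-graph builders used by tests.

Everything here is deliberately written as plain dict/loop enumeration,
independent of the package's matrix-based implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fecomap.core import EdgeList

TRANSMITTER_SIGN = {"ACh": 1, "GABA": -1, "Glu": -1}


def random_annotated_graph(rng: np.random.Generator, n_max: int = 60):
    """A random annotated connectome: neuron table + EdgeList.

    Classes, transmitters, hemilineages and modules are drawn independently;
    input totals exceed the in-graph sums by a random amount, emulating
    unproofread input.
    """
    n = int(rng.integers(10, n_max + 1))
    classes = list(
        rng.choice(
            ["sensory", "motor", "local", "intersegmental", "ascending", "fragment"],
            size=n,
            p=[0.2, 0.2, 0.3, 0.15, 0.1, 0.05],
        )
    )
    classes[0] = "sensory"  # at least one seed
    classes[1] = classes[2] = "motor"  # at least one populated module
    ids = [f"n{i:03d}" for i in range(n)]
    subtypes, hemis, txs, modules = [], [], [], []
    for cls in classes:
        subtypes.append(
            str(rng.choice(["claw_ext", "claw_flex", "hook_ext", "hook_flex", "club"]))
            if cls == "sensory"
            else "none"
        )
        hemis.append(str(rng.choice(["10B", "9A", "13B", "20A/22A", "unknown"])))
        txs.append(str(rng.choice(["ACh", "GABA", "Glu", "unknown"])))
        modules.append(int(rng.integers(1, 3)) if cls == "motor" else None)
    neurons = pd.DataFrame(
        {
            "neuron_id": ids,
            "neuron_class": classes,
            "subtype": subtypes,
            "hemilineage": hemis,
            "transmitter": txs,
            "segment": "T1L",
            "motor_module": pd.array(modules, dtype="Int64"),
        }
    )
    rows = []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < 0.15:
                rows.append((ids[i], ids[j], int(rng.integers(1, 13))))
    edges = pd.DataFrame(rows, columns=["pre_id", "post_id", "count"])
    in_sum = edges.groupby("post_id")["count"].sum() if len(edges) else pd.Series(dtype=int)
    totals = pd.Series(
        {nid: int(in_sum.get(nid, 0)) + int(rng.integers(0, 11)) for nid in ids}
    )
    totals[totals == 0] = 1
    return neurons, EdgeList(edges, totals)


def enumerate_motor_impact(
    seed: str,
    module: int,
    edges: EdgeList,
    neurons: pd.DataFrame,
    threshold: int = 4,
    exclude_pq: bool = True,
):
    """Exhaustive signed path enumeration (lengths 1-3) of the motor impact.

    Mirrors the scoring rules -- eligibility by synapse-count threshold,
    intermediates exclude motor neurons and the seed, disynaptic
    intermediates need a defined sign, trisynaptic intermediates an
    identified hemilineage -- via explicit loops over all paths.
    """
    info = neurons.set_index("neuron_id")
    elig: dict[str, dict[str, int]] = {}
    for pre, post, count in edges.edges.itertuples(index=False):
        if count >= threshold:
            elig.setdefault(pre, {})[post] = count
    totals = edges.input_total

    def ratio(a: str, b: str) -> float:
        return elig[a][b] / totals[b]

    def sign(nid: str):
        row = info.loc[nid]
        if row["neuron_class"] == "sensory":
            return 1
        return TRANSMITTER_SIGN.get(row["transmitter"])

    def hemi_ok(nid: str) -> bool:
        h = info.loc[nid, "hemilineage"]
        return isinstance(h, str) and h not in ("", "unknown")

    mns = [
        nid
        for nid in info.index
        if info.loc[nid, "neuron_class"] == "motor"
        and info.loc[nid, "motor_module"] == module
    ]
    interm = [
        nid
        for nid in info.index
        if info.loc[nid, "neuron_class"] != "motor" and nid != seed
    ]

    i1 = sum(ratio(seed, mn) for mn in mns if mn in elig.get(seed, {}))

    i2 = 0.0
    for I in interm:
        if I not in elig.get(seed, {}):
            continue
        s = sign(I)
        if s is None:
            continue
        for mn in mns:
            if mn in elig.get(I, {}):
                i2 += ratio(seed, I) * ratio(I, mn) * s

    i3 = 0.0
    for P in interm:
        if P not in elig.get(seed, {}) or not hemi_ok(P):
            continue
        sP = sign(P)
        if sP is None:
            continue
        for Q in interm:
            if exclude_pq and Q == P:
                continue
            if Q not in elig.get(P, {}) or not hemi_ok(Q):
                continue
            sQ = sign(Q)
            if sQ is None:
                continue
            for mn in mns:
                if mn in elig.get(Q, {}):
                    i3 += ratio(seed, P) * ratio(P, Q) * ratio(Q, mn) * sP * sQ

    return i1, i2, i3


def brute_force_cosine(W: np.ndarray) -> np.ndarray:
    """Double-loop cosine similarity of matrix rows (NaN for zero rows)."""
    n = len(W)
    S = np.full((n, n), np.nan)
    norms = [np.sqrt(sum(x * x for x in row)) for row in W]
    for i in range(n):
        for j in range(n):
            if norms[i] > 0 and norms[j] > 0:
                dot = sum(a * b for a, b in zip(W[i], W[j]))
                S[i, j] = dot / (norms[i] * norms[j])
    return S
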