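"""Partner extraction thresholds, compositions, overlaps, recurrence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fecomap as fm
from fecomap.core import EdgeList


def _edge_list(rows, extra_totals=None):
    edges = pd.DataFrame(rows, columns=["pre_id", "post_id", "count"])
    totals = edges.groupby("post_id")["count"].sum()
    if extra_totals:
        totals = totals.add(pd.Series(extra_totals), fill_value=0).astype(int)
    return EdgeList(edges, totals)


def _neurons(spec):
    """spec: list of (id, class, subtype) or (id, class)."""
    rows = []
    for item in spec:
        nid, cls = item[0], item[1]
        subtype = item[2] if len(item) > 2 else "none"
        rows.append(
            dict(
                neuron_id=nid,
                neuron_class=cls,
                subtype=subtype,
                hemilineage="unknown",
                transmitter="unknown",
                segment="T1L",
                motor_module=1 if cls == "motor" else None,
            )
        )
    df = pd.DataFrame(rows)
    df["motor_module"] = pd.array(df["motor_module"], dtype="Int64")
    return df


class TestExtractPartners:
    def test_per_seed_threshold(self):
        edges = _edge_list([("S", "B", 4), ("S", "C", 3)])
        pset = fm.extract_partners(edges, ["S"], "downstream", 4)
        assert dict(pset.members) == {"B": 4}

    def test_threshold_one_keeps_everything(self):
        edges = _edge_list([("S", "B", 4), ("S", "C", 3), ("S", "D", 1)])
        pset = fm.extract_partners(edges, ["S"], "downstream", 1)
        assert pset.ids() == {"B", "C", "D"}

    def test_counts_summed_after_inclusion(self):
        # C qualifies through S2 only, but S1's sub-threshold synapses count
        edges = _edge_list([("S1", "C", 2), ("S2", "C", 5)])
        pset = fm.extract_partners(edges, ["S1", "S2"], "downstream", 4)
        assert dict(pset.members) == {"C": 7}

    def test_pooled_inclusion_option(self):
        edges = _edge_list([("S1", "C", 2), ("S2", "C", 2)])
        assert len(fm.extract_partners(edges, ["S1", "S2"], threshold=4)) == 0
        pooled = fm.extract_partners(edges, ["S1", "S2"], threshold=4, pooled=True)
        assert dict(pooled.members) == {"C": 4}

    def test_upstream_direction(self):
        edges = _edge_list([("A", "S", 5), ("B", "S", 2)])
        pset = fm.extract_partners(edges, ["S"], "upstream", 3)
        assert pset.ids() == {"A"}

    def test_empty_seed_set_rejected(self):
        with pytest.raises(fm.ValidationError):
            fm.extract_partners(_edge_list([("a", "b", 1)]), [])

    def test_matches_brute_force_scan_on_random_graph(self):
        rng = np.random.default_rng(11)
        rows = [
            (f"s{rng.integers(10)}", f"p{rng.integers(25)}", int(rng.integers(1, 9)))
            for _ in range(200)
        ]
        agg: dict[tuple, int] = {}
        for p, q, c in rows:
            agg[(p, q)] = agg.get((p, q), 0) + c
        edges = _edge_list([(p, q, c) for (p, q), c in agg.items()])
        seeds = [f"s{i}" for i in range(10)]
        for threshold in (1, 3, 5):
            pset = fm.extract_partners(edges, seeds, "downstream", threshold)
            expected: dict[str, int] = {}
            qualified = set()
            for (p, q), c in agg.items():
                if p in seeds:
                    expected[q] = expected.get(q, 0) + c
                    if c >= threshold:
                        qualified.add(q)
            assert pset.ids() == qualified
            for q in qualified:
                assert pset.members[q] == expected[q]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        rows = [
            (f"s{rng.integers(4)}", f"p{rng.integers(12)}", int(rng.integers(1, 10)))
            for _ in range(40)
        ]
        agg: dict[tuple, int] = {}
        for p, q, c in rows:
            agg[(p, q)] = agg.get((p, q), 0) + c
        edges = _edge_list([(p, q, c) for (p, q), c in agg.items()])
        seeds = [f"s{i}" for i in range(4)]
        previous = None
        for threshold in range(1, 9):
            ids = fm.extract_partners(edges, seeds, "downstream", threshold).ids()
            if previous is not None:
                assert ids <= previous
            previous = ids

    def test_row_order_invariance(self):
        rows = [("S", "B", 4), ("S", "C", 6), ("T", "B", 2)]
        a = fm.extract_partners(_edge_list(rows), ["S", "T"], threshold=2)
        b = fm.extract_partners(_edge_list(rows[::-1]), ["S", "T"], threshold=2)
        assert dict(a.members) == dict(b.members)


class TestClassComposition:
    def test_hand_fractions(self):
        neurons = _neurons([("S", "sensory", "club"), ("M", "motor"), ("L", "local")])
        edges = _edge_list([("S", "M", 6), ("S", "L", 4)])
        comp = fm.class_composition(edges, ["S"], neurons)
        assert comp.loc["S", "motor"] == pytest.approx(0.6)
        assert comp.loc["S", "local"] == pytest.approx(0.4)

    def test_single_class_gets_one(self):
        neurons = _neurons([("S", "sensory", "club"), ("M", "motor")])
        comp = fm.class_composition(_edge_list([("S", "M", 3)]), ["S"], neurons)
        assert comp.loc["S", "motor"] == 1.0

    def test_rows_sum_to_one_including_fragments(self, small_world):
        neurons, _, _, edges = small_world
        seeds = list(fm.feco_seeds(neurons)["neuron_id"])
        comp = fm.class_composition(edges, seeds, neurons)
        assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-12)

    def test_club_targets_intersegmental_proprio_targets_local_motor(self, paper_world):
        neurons, _, _, edges = paper_world
        info = neurons.set_index("neuron_id")
        seeds = fm.feco_seeds(neurons, "T1L")["neuron_id"]
        groups = {
            s: [n for n in seeds if info.loc[n, "subtype"] == s]
            for s in fm.FECO_SUBTYPES
        }
        comp = fm.composition_by_group(edges, groups, neurons)
        club = comp.loc["club"]
        assert club.get("intersegmental", 0) + club.get("ascending", 0) > 0.5
        for subtype in ("claw_ext", "claw_flex", "hook_ext", "hook_flex"):
            row = comp.loc[subtype]
            assert row.get("local", 0) + row.get("motor", 0) > 0.5


class TestSharedPartnerMatrix:
    def _toy(self):
        # group A -> {p1, p2}; group B -> {p2, p3}; group C -> {p4}
        edges = _edge_list(
            [
                ("a1", "p1", 5), ("a1", "p2", 5),
                ("b1", "p2", 5), ("b1", "p3", 5),
                ("c1", "p4", 5),
            ]
        )
        groups = {"A": ["a1"], "B": ["b1"], "C": ["c1"]}
        return edges, groups

    def test_self_overlap_is_100(self):
        edges, groups = self._toy()
        m = fm.shared_partner_matrix(edges, groups, groups, threshold=4)
        assert all(m.loc[g, g] == 100.0 for g in groups)

    def test_disjoint_sets_are_0(self):
        edges, groups = self._toy()
        m = fm.shared_partner_matrix(edges, groups, groups, threshold=4)
        assert m.loc["A", "C"] == 0.0 and m.loc["C", "A"] == 0.0

    def test_hand_enumerated_intersections(self):
        edges, groups = self._toy()
        m = fm.shared_partner_matrix(edges, groups, groups, threshold=4)
        # A's partners {p1,p2}; B reaches {p2,p3}: overlap p2 -> 50%
        assert m.loc["A", "B"] == pytest.approx(50.0)
        assert m.loc["B", "A"] == pytest.approx(50.0)

    def test_empty_postsynaptic_set_is_missing(self):
        edges, groups = self._toy()
        groups = dict(groups, D=["ghost"])
        m = fm.shared_partner_matrix(edges, groups, groups, threshold=4)
        assert np.isnan(m.loc["D", "A"])


class TestRecurrenceFractions:
    def test_single_class_all_internal(self):
        edges = _edge_list([("a", "b", 3), ("b", "a", 2)])
        part = pd.Series({"a": "X", "b": "X"})
        m = fm.recurrence_fractions(edges, part)
        assert m.loc["X", "X"] == 1.0

    def test_rows_sum_below_one_with_external_targets(self):
        edges = _edge_list([("a", "b", 3), ("a", "ext", 1)])
        part = pd.Series({"a": "X", "b": "Y"})
        m = fm.recurrence_fractions(edges, part)
        assert m.loc["X", "Y"] == pytest.approx(0.75)
        assert m.sum(axis=1)["X"] == pytest.approx(0.75)

    def test_four_class_toy_matches_tally(self):
        rng = np.random.default_rng(5)
        ids = [f"n{i}" for i in range(20)]
        part = pd.Series({nid: "ABCD"[i % 4] for i, nid in enumerate(ids)})
        rows = {}
        for _ in range(120):
            p, q = rng.choice(ids, 2, replace=False)
            rows[(p, q)] = rows.get((p, q), 0) + int(rng.integers(1, 6))
        edges = _edge_list([(p, q, c) for (p, q), c in rows.items()])
        m = fm.recurrence_fractions(edges, part)
        # brute-force tally
        num: dict[tuple, float] = {}
        den: dict[str, float] = {}
        for (p, q), c in rows.items():
            den[part[p]] = den.get(part[p], 0) + c
            num[(part[p], part[q])] = num.get((part[p], part[q]), 0) + c
        for (ci, cj), c in num.items():
            assert m.loc[ci, cj] == pytest.approx(c / den[ci], abs=1e-12)


class TestOverlapCounts:
    def _pset(self, ids):
        members = pd.Series({i: 5 for i in ids}, dtype=int)
        return fm.PartnerSet(("s",), "downstream", 4, members)

    def test_identical_and_disjoint(self):
        a = self._pset(["x", "y"])
        assert fm.overlap_counts(a, self._pset(["x", "y"])) == (0, 2, 0)
        assert fm.overlap_counts(a, self._pset(["z"])) == (2, 0, 1)

    def test_random_sets_match_set_algebra(self):
        rng = np.random.default_rng(9)
        universe = [f"p{i}" for i in range(40)]
        sa = set(rng.choice(universe, 15, replace=False))
        sb = set(rng.choice(universe, 20, replace=False))
        got = fm.overlap_counts(self._pset(sorted(sa)), self._pset(sorted(sb)))
        assert got == (len(sa - sb), len(sa & sb), len(sb - sa))
        assert got[0] + got[1] == len(sa)

    def test_mismatched_construction_rejected(self):
        a = self._pset(["x"])
        b = fm.PartnerSet(("s",), "upstream", 4, a.members)
        with pytest.raises(fm.ValidationError):
            fm.overlap_counts(a, b)
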