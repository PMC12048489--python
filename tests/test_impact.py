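"""Signed multi-hop motor impact scores and preference vectors."""

import numpy as np
import pandas as pd
import pytest

import fecomap as fm
from fecomap.core import EdgeList
from oracles import enumerate_motor_impact, random_annotated_graph


def _neurons(rows):
    df = pd.DataFrame(
        rows,
        columns=[
            "neuron_id",
            "neuron_class",
            "subtype",
            "hemilineage",
            "transmitter",
            "motor_module",
        ],
    )
    df["segment"] = "T1L"
    df["motor_module"] = pd.array(df["motor_module"], dtype="Int64")
    return df


def _edges(rows, totals):
    return EdgeList(
        pd.DataFrame(rows, columns=["pre_id", "post_id", "count"]),
        pd.Series(totals),
    )


class TestEdgeImpact:
    def setup_method(self):
        self.neurons = _neurons(
            [
                ("S", "sensory", "club", "unknown", "ACh", None),
                ("G", "local", "none", "9A", "GABA", None),
                ("U", "local", "none", "unknown", "unknown", None),
                ("M", "motor", "none", "unknown", "Glu", 1),
            ]
        )

    def test_cholinergic_fraction(self):
        edges = _edges([("S", "M", 5)], {"M": 10})
        assert fm.edge_impact("S", "M", edges, self.neurons) == pytest.approx(0.5)

    def test_gabaergic_fraction(self):
        edges = _edges([("G", "M", 2)], {"M": 8})
        assert fm.edge_impact("G", "M", edges, self.neurons) == pytest.approx(-0.25)

    def test_no_edge_is_zero(self):
        edges = _edges([("S", "M", 5)], {"M": 10})
        assert fm.edge_impact("G", "M", edges, self.neurons) == 0.0

    def test_undefined_sign_is_none(self):
        edges = _edges([("U", "M", 4)], {"M": 10})
        assert fm.edge_impact("U", "M", edges, self.neurons) is None

    def test_zero_denominator_names_post(self):
        edges = _edges([("S", "M", 5)], {"M": 10, "G": 0})
        edges.input_total["M"] = 0
        with pytest.raises(fm.ValidationError, match="M"):
            fm.edge_impact("S", "M", edges, self.neurons)


class TestMotorImpact:
    def _simple(self):
        return _neurons(
            [
                ("S", "sensory", "claw_flex", "unknown", "ACh", None),
                ("I", "local", "none", "20A/22A", "ACh", None),
                ("J", "local", "none", "9A", "GABA", None),
                ("M1", "motor", "none", "unknown", "Glu", 1),
                ("M2", "motor", "none", "unknown", "Glu", 1),
            ]
        )

    def test_direct_only(self):
        edges = _edges([("S", "M1", 4)], {"M1": 20, "M2": 10})
        r = fm.motor_impact("S", 1, edges, self._simple(), threshold=4)
        assert (r.impact_1, r.impact_2, r.impact_3) == (pytest.approx(0.2), 0.0, 0.0)

    def test_disynaptic_excitatory_and_inhibitory(self):
        edges = _edges(
            [("S", "I", 6), ("I", "M1", 10)], {"I": 12, "M1": 20, "M2": 5}
        )
        r = fm.motor_impact("S", 1, edges, self._simple(), threshold=4)
        assert r.impact_2 == pytest.approx(+0.25)
        edges = _edges(
            [("S", "J", 6), ("J", "M1", 10)], {"J": 12, "M1": 20, "M2": 5}
        )
        r = fm.motor_impact("S", 1, edges, self._simple(), threshold=4)
        assert r.impact_2 == pytest.approx(-0.25)
        assert r.impact_1 == 0.0

    def test_trisynaptic_sign_rule(self):
        # S -> J(GABA) -> I(ACh) -> M1: inhibitory x excitatory = negative
        edges = _edges(
            [("S", "J", 6), ("J", "I", 6), ("I", "M1", 10)],
            {"J": 12, "I": 12, "M1": 20, "M2": 5},
        )
        r = fm.motor_impact("S", 1, edges, self._simple(), threshold=4)
        expected = -(6 / 12) * (6 / 12) * (10 / 20)
        assert r.impact_3 == pytest.approx(expected, abs=1e-12)

    def test_undefined_intermediates_excluded_and_counted(self):
        neurons = _neurons(
            [
                ("S", "sensory", "club", "unknown", "ACh", None),
                ("U", "local", "none", "unknown", "unknown", None),
                ("M1", "motor", "none", "unknown", "Glu", 1),
            ]
        )
        edges = _edges(
            [("S", "U", 6), ("U", "M1", 10)], {"U": 12, "M1": 20}
        )
        r = fm.motor_impact("S", 1, edges, neurons, threshold=4)
        assert r.impact_2 == 0.0
        assert r.coverage["undefined_sign_intermediates"] == 1

    def test_empty_module_rejected(self):
        edges = _edges([("S", "M1", 4)], {"M1": 20})
        with pytest.raises(fm.ValidationError):
            fm.motor_impact("S", 99, edges, self._simple(), threshold=4)

    @pytest.mark.parametrize("graph_seed", range(25))
    def test_matches_exhaustive_path_enumeration(self, graph_seed):
        rng = np.random.default_rng(graph_seed)
        neurons, edges = random_annotated_graph(rng, n_max=60)
        threshold = int(rng.choice([1, 2, 4]))
        scorer = fm.MotorImpactScorer(threshold=threshold).fit(edges, neurons)
        seeds = neurons.loc[neurons["neuron_class"] == "sensory", "neuron_id"]
        for seed in list(seeds)[:3]:
            for module in (1, 2):
                if module not in scorer.modules_:
                    continue
                got = scorer.score(seed, module)
                i1, i2, i3 = enumerate_motor_impact(
                    seed, module, edges, neurons, threshold
                )
                assert got.impact_1 == pytest.approx(i1, abs=1e-12)
                assert got.impact_2 == pytest.approx(i2, abs=1e-12)
                assert got.impact_3 == pytest.approx(i3, abs=1e-12)

    @pytest.mark.parametrize("factor", [2, 3, 7])
    def test_ratio_invariance_under_count_scaling(self, factor):
        rng = np.random.default_rng(100 + factor)
        neurons, edges = random_annotated_graph(rng, n_max=40)
        scorer = fm.MotorImpactScorer(threshold=1).fit(edges, neurons)
        scaled = fm.MotorImpactScorer(threshold=1).fit(edges.scaled(factor), neurons)
        seed = neurons.loc[neurons["neuron_class"] == "sensory", "neuron_id"].iloc[0]
        for module in scorer.modules_:
            a, b = scorer.score(seed, module), scaled.score(seed, module)
            assert a.impact_total == pytest.approx(b.impact_total, abs=1e-12)

    def test_all_excitatory_network_is_non_negative(self):
        rng = np.random.default_rng(55)
        neurons, edges = random_annotated_graph(rng, n_max=40)
        neurons = neurons.assign(transmitter="ACh")
        scorer = fm.MotorImpactScorer(threshold=1).fit(edges, neurons)
        for seed in neurons.loc[neurons["neuron_class"] == "sensory", "neuron_id"][:5]:
            for module in scorer.modules_:
                assert scorer.score(seed, module).impact_total >= 0

    def test_planted_antagonist_sign_structure(self, paper_world):
        neurons, _, gt, edges = paper_world
        info = neurons.set_index("neuron_id")
        scorer = fm.MotorImpactScorer(threshold=4).fit(edges, neurons)
        seeds = fm.feco_seeds(neurons)["neuron_id"]
        totals: dict[tuple, list] = {}
        for seed in seeds:
            subtype = info.loc[seed, "subtype"]
            for module in (8, 9):
                totals.setdefault((subtype, module), []).append(
                    scorer.score(seed, module).impact_total
                )
        for subtype, (excited, inhibited) in gt.antagonists.items():
            assert np.mean(totals[(subtype, excited)]) > 0
            assert np.mean(totals[(subtype, inhibited)]) < 0
        club = np.abs(totals[("club", 8)] + totals[("club", 9)]).mean()
        proprio = np.abs(
            [v for (s, _), vals in totals.items() if s != "club" for v in vals]
        ).mean()
        assert club < 0.1 * proprio


class TestPreferenceScores:
    def _world(self):
        neurons = _neurons(
            [
                ("S1", "sensory", "club", "unknown", "ACh", None),
                ("S2", "sensory", "hook_flex", "unknown", "ACh", None),
                ("P", "local", "none", "20A/22A", "ACh", None),
                ("A1", "motor", "none", "unknown", "Glu", 1),
                ("A2", "motor", "none", "unknown", "Glu", 1),
                ("B1", "motor", "none", "unknown", "Glu", 2),
            ]
        )
        edges = _edges(
            [
                ("P", "A1", 5), ("P", "A2", 3), ("P", "B1", 2),
                ("S1", "P", 6), ("S2", "P", 2),
            ],
            {"A1": 5, "A2": 3, "B1": 2, "P": 8},
        )
        return neurons, edges

    def test_module_preference_hand_fraction(self):
        neurons, edges = self._world()
        prefs = fm.module_preference(edges, neurons)
        assert prefs.loc["P", "module_1"] == pytest.approx(0.8)
        assert prefs.loc["P", "module_2"] == pytest.approx(0.2)

    def test_single_module_premotor_prefers_fully(self):
        neurons, edges = self._world()
        edges2 = _edges([("P", "A1", 7)], {"A1": 7})
        prefs = fm.module_preference(edges2, neurons)
        assert prefs.loc["P", "module_1"] == 1.0

    def test_subtype_preference_hand_fraction(self):
        neurons, edges = self._world()
        prefs = fm.subtype_preference(edges, neurons)
        assert prefs.loc["P", "club"] == pytest.approx(0.75)
        assert prefs.loc["P", "hook_flex"] == pytest.approx(0.25)

    def test_vectors_sum_to_one_on_fixture(self, small_world):
        neurons, _, _, edges = small_world
        mod = fm.module_preference(edges, neurons)
        sub = fm.subtype_preference(edges, neurons)
        assert np.allclose(mod.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(sub.sum(axis=1), 1.0, atol=1e-12)

    def test_dedicated_premotors_prefer_their_planted_module(self, paper_world):
        neurons, _, gt, edges = paper_world
        prefs = fm.module_preference(edges, neurons)
        dedicated = gt.neurons.query("dedicated and dedicated_module > 0")
        hits = 0
        for _, row in dedicated.iterrows():
            if row["neuron_id"] not in prefs.index:
                continue
            best = prefs.loc[row["neuron_id"]].idxmax()
            hits += best == f"module_{row['dedicated_module']}"
        assert hits / len(dedicated) > 0.9
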