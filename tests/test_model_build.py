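"""Topology and validation of the folding state graph."""

import numpy as np
import pytest

from switchsim import (
    KineticModel,
    ModelValidationError,
    PauseSite,
    RateTable,
    SimulationConfig,
    StateSpec,
    TransitionSpec,
    build_default_model,
)
from switchsim.model import load_packaged_model


def edge_map(model):
    return {(t.source, t.target): (t.rate, t.kind) for t in model.transitions}


class TestStateAndTransitionInvariants:
    def test_pa_at_mutually_exclusive(self):
        with pytest.raises(ModelValidationError):
            StateSpec(id="bad", position=10, helices=frozenset({"PA", "AT"}))

    @pytest.mark.parametrize("rate", [0.0, -1.0, np.inf, np.nan])
    def test_rates_positive_finite(self, rate):
        with pytest.raises(ModelValidationError):
            TransitionSpec(source="a", target="b", rate=rate)

    def test_no_self_transitions(self):
        with pytest.raises(ModelValidationError):
            TransitionSpec(source="a", target="a", rate=1.0)

    def test_absorbing_states_have_no_exits(self):
        states = [
            StateSpec(id="a", position=1),
            StateSpec(id="end", position=2, role="terminated"),
        ]
        trs = [
            TransitionSpec("a", "end", 1.0, "termination_commit"),
            TransitionSpec("end", "a", 1.0, "folding"),
        ]
        with pytest.raises(ModelValidationError, match="absorbing"):
            KineticModel(states, trs)

    def test_synthesis_must_increase_position(self):
        states = [StateSpec(id="a", position=5), StateSpec(id="b", position=5)]
        with pytest.raises(ModelValidationError, match="increase position"):
            KineticModel(states, [TransitionSpec("a", "b", 1.0, "synthesis")])

    def test_duplicate_transitions_rejected(self):
        states = [StateSpec(id="a", position=1), StateSpec(id="b", position=2)]
        trs = [
            TransitionSpec("a", "b", 1.0, "synthesis"),
            TransitionSpec("a", "b", 2.0, "synthesis"),
        ]
        with pytest.raises(ModelValidationError, match="duplicate"):
            KineticModel(states, trs)


class TestDefaultTopology:
    def test_apo_model_has_no_ligand_states_or_edges(self):
        m = build_default_model(SimulationConfig(ligand_present=False))
        assert not any(s.ligand_bound for s in m.states)
        assert not any(t.kind == "ligand_binding" for t in m.transitions)

    def test_pause_interval_steps_run_at_v_over_factor(self):
        cfg = SimulationConfig(ligand_present=True)
        m = build_default_model(cfg)
        slowed = expected = 0
        for t in m.transitions:
            if t.kind != "synthesis":
                continue
            pos = m.state(t.source).position
            if t.source.startswith(("PA@", "ligPA@", "ligPA*@")) and 107 <= pos <= 112:
                assert t.rate == pytest.approx(20.0 / 70.0)
                slowed += 1
            elif m.state(t.target).position <= 164:
                assert t.rate == pytest.approx(20.0)
        # 6 slowed steps in each of the three aptamer-class chains
        assert slowed == 18

    def test_factor_one_is_edge_for_edge_identical_to_no_pause(self):
        cfg_nopause = SimulationConfig(pause_sites=())
        cfg_f1 = SimulationConfig(pause_sites=(PauseSite(107, 112, 1.0),))
        m0 = build_default_model(cfg_nopause)
        m1 = build_default_model(cfg_f1)
        assert edge_map(m0) == edge_map(m1)
        assert [s.id for s in m0.states] == [s.id for s in m1.states]

    def test_apo_succession_is_linear_and_holo_branched(self):
        apo = build_default_model(SimulationConfig(ligand_present=False))
        holo = build_default_model(SimulationConfig(ligand_present=True))
        # apo: every state has at most one non-side-branch continuation
        apo_confs = {s.id.split("@")[0] for s in apo.states}
        assert apo_confs == {"P", "PA", "[PA]T", "P[AT]", "[PA][TH]", "terminated", "readthrough"}
        assert {s.id.split("@")[0] for s in holo.states} >= apo_confs | {
            "ligPA",
            "lig[PA]T",
            "lig[PA][TH]",
        }

    def test_rate_table_constants_appear_on_their_edges(self):
        rates = RateTable()
        m = build_default_model(SimulationConfig(ligand_present=True))
        em = edge_map(m)
        assert em[("[PA]T@134", "P[AT]@134")] == (rates.k_AT_anneal, "folding")
        assert em[("P[AT]@164", "[PA][TH]@164")] == (rates.k_AT_dissoc_apo, "folding")
        assert em[("lig[PA]T@164", "lig[PA][TH]@164")] == (rates.k_TH_anneal, "folding")
        assert em[("PA@100", "ligPA@100")] == (rates.k_lig_bind, "ligand_binding")
        assert em[("ligPA@100", "ligPA*@100")] == (rates.k_tert, "folding")
        assert em[("P[AT]@150", "lig[PA]T@150")] == (rates.k_AT_dissoc_lig, "ligand_binding")
        assert em[("P[AT]@164", "ligP[AT]@164")] == (rates.k_refold_holo, "ligand_binding")
        assert em[("ligP[AT]@164", "lig[PA][TH]@164")] == (
            rates.k_AT_dissoc_combined,
            "folding",
        )

    def test_pause_interval_outside_transcript_rejected(self):
        with pytest.raises(ModelValidationError, match="outside the transcript"):
            SimulationConfig(pause_sites=(PauseSite(300, 306, 70.0),))

    def test_rate_table_rejects_nonpositive_entries(self):
        from switchsim.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            RateTable(k_lig_bind=-0.1)


class TestSerialization:
    def test_yaml_round_trip(self, tmp_path):
        m = build_default_model(SimulationConfig(ligand_present=True, granularity="segment"))
        path = tmp_path / "model.yaml"
        m.to_yaml(path)
        m2 = KineticModel.from_yaml(path)
        assert edge_map(m) == edge_map(m2)
        assert [(s.id, s.position, s.helices, s.ligand_bound, s.role) for s in m.states] == [
            (s.id, s.position, s.helices, s.ligand_bound, s.role) for s in m2.states
        ]

    def test_packaged_model_matches_builder(self):
        packaged = load_packaged_model()
        built = build_default_model(
            SimulationConfig(ligand_present=True, granularity="segment")
        )
        assert edge_map(packaged) == edge_map(built)


class TestSegmentMode:
    def test_segment_rates_match_mean_transit_times(self):
        cfg = SimulationConfig(ligand_present=False, granularity="segment")
        m = build_default_model(cfg)
        em = edge_map(m)
        assert em[("P@75", "PA@89")][0] == pytest.approx(20.0 / 14.0)
        # aptamer block: 39 fast steps + 6 slowed 70-fold
        assert em[("PA@89", "[PA]T@134")][0] == pytest.approx(20.0 / (39 + 6 * 70))
        assert em[("P[AT]@134", "P[AT]@164")][0] == pytest.approx(20.0 / 30.0)
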