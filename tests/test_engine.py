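"""Markov cohort engine: conservation, toy traces, orderings and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pvmarkov as pv
from pvmarkov.engine import PROGRESSION_STATES, State
from _oracles import path_enumeration_trace


def _config(life_table, risk_set, horizon=5.0, start_age=57.0, **kw):
    kw.setdefault("fixed_group", "ALL_HIGH")
    return pv.ModelConfig(
        start_age=start_age,
        horizon_years=horizon,
        risk_set=risk_set,
        life_table=life_table,
        **kw,
    )


class TestStepAndRun:
    def test_no_risks_no_mortality_leaves_cohort_unchanged(
        self, immortal_table, zero_risks
    ):
        cfg = _config(immortal_table, zero_risks, horizon=5.0)
        trace = pv.run(cfg)
        assert np.allclose(trace.occupancy, trace.occupancy[0])
        assert np.all(trace.new_events == 0)

    def test_single_risk_two_cycle_hand_computation(self, immortal_table, zero_risks):
        risk = pv.RiskSet(**{**_riskset_dict(zero_risks), "p_mf_high": 0.1})
        cfg = _config(immortal_table, risk, horizon=0.5)
        trace = pv.run(cfg)
        free = trace.occupancy[2, State.LOW_JAK2] + trace.occupancy[2, State.HIGH_JAK2]
        assert free == pytest.approx(0.81, rel=1e-12)
        assert trace.occupancy[2, State.MF] == pytest.approx(0.19, rel=1e-12)
        assert pv.cumulative_incidence(trace, State.MF) == pytest.approx(0.19, rel=1e-12)

    def test_zero_horizon_gives_initial_row_only(self, immortal_table, zero_risks):
        trace = pv.run(_config(immortal_table, zero_risks, horizon=0.0))
        assert trace.occupancy.shape == (1, 6)

    def test_zero_risk_run_reduces_to_life_table(self, life_table, zero_risks):
        cfg = _config(life_table, zero_risks, horizon=20.0, fixed_group="ALL_LOW")
        trace = pv.run(cfg)
        os = pv.restricted_auc(pv.os_curve(trace), 0, 20)
        assert os == pytest.approx(
            pv.general_population_rmst(life_table, 57, 20), abs=1e-12
        )

    def test_excess_exit_probability_names_state_and_cycle(self, life_table, zero_risks):
        risk = pv.RiskSet(
            **{**_riskset_dict(zero_risks), "p_al": 0.5, "p_mf_high": 0.4, "p_thrombosis_high": 0.2}
        )
        cfg = _config(life_table, risk, horizon=1.0)
        with pytest.raises(pv.ConfigurationError, match="HIGH_JAK2.*cycle 0"):
            pv.run(cfg)

    def test_run_is_deterministic(self, base_config):
        a, b = pv.run(base_config), pv.run(base_config)
        assert np.array_equal(a.occupancy, b.occupancy)
        assert np.array_equal(a.new_events, b.new_events)

    def test_trace_frame_layout(self, base_config):
        df = pv.run(base_config).to_frame()
        assert list(df.columns) == [
            "cycle", "age", "low", "high", "al", "mf",
            "thrombosis", "dead", "new_al", "new_mf", "new_thrombosis",
        ]
        assert len(df) == base_config.n_cycles + 1
        assert df["age"].iloc[0] == 57.0

    def test_config_validation(self, life_table, zero_risks):
        with pytest.raises(ValueError, match="whole number"):
            _config(life_table, zero_risks, horizon=1.1)
        with pytest.raises(ValueError, match="exactly one"):
            pv.ModelConfig(
                start_age=57, horizon_years=1.0, risk_set=zero_risks,
                life_table=life_table,
            )
        with pytest.raises(ValueError, match="not covered"):
            _config(life_table, zero_risks, start_age=108.0, horizon=10.0)


def _riskset_dict(rs):
    return {
        k: getattr(rs, k)
        for k in (
            "p_thrombosis_low", "p_thrombosis_high", "p_al", "p_mf_low",
            "p_mf_high", "m_thrombosis", "m_al", "m_mf",
        )
    }


risk_probs = st.floats(min_value=0.0, max_value=0.05)
mort_probs = st.floats(min_value=0.0, max_value=0.6)


@st.composite
def risk_sets(draw):
    return pv.RiskSet(
        p_thrombosis_low=draw(risk_probs),
        p_thrombosis_high=draw(risk_probs),
        p_al=draw(risk_probs),
        p_mf_low=draw(risk_probs),
        p_mf_high=draw(risk_probs),
        m_thrombosis=draw(mort_probs),
        m_al=draw(mort_probs),
        m_mf=draw(mort_probs),
    )


class TestInvariants:
    @settings(max_examples=40, deadline=None)
    @given(
        risk=risk_sets(),
        props=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=3, max_size=8),
        same_cycle=st.booleans(),
    )
    def test_conservation_and_absorption(self, risk, props, same_cycle):
        lt = pv.synthesize_life_table()
        traj = pv.Jak2Trajectory(proportion_high=np.array(props))
        cfg = pv.ModelConfig(
            start_age=60.0, horizon_years=5.0, risk_set=risk, life_table=lt,
            trajectory=traj, fixed_group=None,
            same_cycle_progression_death=same_cycle,
        )
        trace = pv.run(cfg)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(trace.occupancy >= -1e-15)
        assert np.all(np.diff(trace.occupancy[:, State.DEAD]) >= -1e-15)
        assert np.all(trace.new_events >= 0.0)

    def test_high_burden_dominance_every_cycle(self, base_config):
        low = pv.run(base_config.with_(trajectory=None, fixed_group="ALL_LOW"))
        high = pv.run(base_config.with_(trajectory=None, fixed_group="ALL_HIGH"))
        cum = lambda tr, k: np.cumsum(tr.new_events[:, k])
        assert np.all(cum(high, 1) >= cum(low, 1))   # myelofibrosis
        assert np.all(cum(high, 2) >= cum(low, 2))   # thrombosis
        assert np.all(
            high.occupancy[:, State.DEAD] >= low.occupancy[:, State.DEAD] - 1e-15
        )

    def test_competing_risks_suppress_leukemia_in_high_burden_group(self, base_config):
        """Equal AL risk per cycle, yet the high-burden subgroup accrues less
        leukemia because myelofibrosis and thrombosis remove it from risk."""
        low = pv.run(base_config.with_(trajectory=None, fixed_group="ALL_LOW"))
        high = pv.run(base_config.with_(trajectory=None, fixed_group="ALL_HIGH"))
        al_low = pv.cumulative_incidence(low, State.AL)
        al_high = pv.cumulative_incidence(high, State.AL)
        assert al_high < al_low


class TestPathEnumerationOracle:
    @pytest.mark.parametrize("horizon", [0.25, 0.5, 0.75])
    @pytest.mark.parametrize(
        "risk_kwargs",
        [
            {"p_mf_high": 0.1, "m_mf": 0.3},
            {"p_thrombosis_high": 0.2, "p_al": 0.05, "m_thrombosis": 0.4, "m_al": 0.5},
            {"p_mf_low": 0.07, "p_mf_high": 0.2, "m_mf": 0.25},
        ],
    )
    def test_trace_matches_exhaustive_enumeration(
        self, life_table, zero_risks, horizon, risk_kwargs
    ):
        risk = pv.RiskSet(**{**_riskset_dict(zero_risks), **risk_kwargs})
        traj = pv.Jak2Trajectory(proportion_high=np.array([0.6, 0.5, 0.45, 0.45]))
        cfg = pv.ModelConfig(
            start_age=62.0, horizon_years=horizon, risk_set=risk,
            life_table=life_table, trajectory=traj,
        )
        trace = pv.run(cfg)
        occ, new = path_enumeration_trace(cfg)
        assert np.allclose(trace.occupancy, occ, atol=1e-12)
        assert np.allclose(trace.new_events, new, atol=1e-12)


class TestConventions:
    def test_same_cycle_death_exposes_new_entrants(self, immortal_table, zero_risks):
        risk = pv.RiskSet(**{**_riskset_dict(zero_risks), "p_mf_high": 0.1, "m_mf": 0.5})
        base = _config(immortal_table, risk, horizon=0.25)
        deferred = pv.run(base)
        same = pv.run(base.with_(same_cycle_progression_death=True))
        assert deferred.occupancy[1, State.MF] == pytest.approx(0.1)
        assert same.occupancy[1, State.MF] == pytest.approx(0.05)
        assert same.occupancy[1, State.DEAD] == pytest.approx(0.05)

    def test_background_floor_adds_mortality_in_progression(self, life_table, zero_risks):
        risk = pv.RiskSet(**{**_riskset_dict(zero_risks), "p_mf_high": 0.1, "m_mf": 0.02})
        cfg = _config(life_table, risk, horizon=10.0, start_age=80.0)
        plain = pv.run(cfg)
        floored = pv.run(cfg.with_(phase2_background_floor=True))
        assert (
            floored.occupancy[-1, State.DEAD] > plain.occupancy[-1, State.DEAD]
        )

    def test_reallocation_tracks_trajectory(self, immortal_table, zero_risks):
        traj = pv.Jak2Trajectory(proportion_high=np.array([0.2, 0.8, 0.5]))
        cfg = pv.ModelConfig(
            start_age=57, horizon_years=0.5, risk_set=zero_risks,
            life_table=immortal_table, trajectory=traj,
        )
        trace = pv.run(cfg)
        assert trace.occupancy[0, State.HIGH_JAK2] == pytest.approx(0.2)
        assert trace.occupancy[1, State.HIGH_JAK2] == pytest.approx(0.8)
        assert trace.occupancy[2, State.HIGH_JAK2] == pytest.approx(0.5)
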