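import numpy as np
import pandas as pd
import pytest

from growthzones import (
    GrowthLaw,
    NoiseModel,
    NondimParams,
    Trajectory,
    classify_growth_pattern,
    divide,
    model,
    neto_length,
    simulate_cycle,
    simulate_lineage,
)
from growthzones.cycle import DaughterInit


class TestGrowthLaw:
    def test_quasi_static_floor(self):
        with pytest.raises(ValueError):
            GrowthLaw("linear_l", 1.0, rho=5)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            GrowthLaw("exponential", 1.0, 100)


class TestSimulateCycle:
    def test_zero_growth_relaxes_to_equilibrium(self, wt_scenario):
        tr = simulate_cycle(wt_scenario.params, 1.2, [0.6, 0.1], growth_law=None)
        res = np.max(np.abs(model.rhs(wt_scenario.params, tr.end_l, tr.end_state)))
        assert res < 1e-8
        assert tr.end_l == pytest.approx(1.2)

    def test_wild_type_cycle_has_one_neto(self, wt_scenario):
        tr = simulate_cycle(
            wt_scenario.params, wt_scenario.l_birth, [0.7, 0.0],
            GrowthLaw("linear_l", 1.0, 100),
        )
        assert len(tr.events_of("NETO")) == 1
        assert len(tr.events_of("division")) == 1
        pat = classify_growth_pattern(tr)
        assert pat.label == "monopolar_then_NETO"
        assert 0 < pat.neto_cycle_fraction < 1

    def test_bipolar_regime_has_no_activation_events(self):
        """With strong basal activation both zones stay above threshold and
        nothing happens until division."""
        p = NondimParams(0.5, 20.0, (0.5, 0.5))
        tr = simulate_cycle(p, 1.0, [0.6, 0.6], GrowthLaw("linear_l", 1.0, 50))
        kinds = {k for _, k, _ in tr.events}
        assert kinds <= {"division"}

    def test_l_monotone_between_divisions(self, wt_scenario):
        tr = simulate_cycle(
            wt_scenario.params, wt_scenario.l_birth, [0.7, 0.0],
            GrowthLaw("linear_l", 1.0, 50),
        )
        assert np.all(np.diff(tr.l) >= -1e-12)

    def test_trajectory_respects_box_and_substrate(self, wt_scenario):
        tr = simulate_cycle(
            wt_scenario.params, wt_scenario.l_birth, [0.7, 0.0],
            GrowthLaw("activity_proportional", 1.0, 50),
        )
        assert np.all(tr.x >= -1e-9) and np.all(tr.x <= 1 + 1e-9)
        s = tr.l - tr.x @ wt_scenario.params.a_array
        assert np.all(s >= -1e-9)

    def test_event_times_stable_under_tolerance_halving(self, wt_scenario):
        t1 = simulate_cycle(wt_scenario.params, wt_scenario.l_birth, [0.7, 0.0],
                            GrowthLaw("linear_l", 1.0, 100), rtol=1e-8, atol=1e-10)
        t2 = simulate_cycle(wt_scenario.params, wt_scenario.l_birth, [0.7, 0.0],
                            GrowthLaw("linear_l", 1.0, 100), rtol=5e-9, atol=5e-11)
        e1 = t1.events_of("NETO")[0][0]
        e2 = t2.events_of("NETO")[0][0]
        assert abs(e1 - e2) < 0.01 * t1.duration

    def test_invalid_initial_state_rejected(self, wt_scenario):
        with pytest.raises(ValueError):
            simulate_cycle(wt_scenario.params, 1.0, [1.5, 0.0])

    def test_hysteresis_between_growing_and_shrinking(self, wt_scenario, wt_diagram):
        """Inside the monopolar/bipolar overlap a growing cell stays
        monopolar while a shrinking cell stays bipolar."""
        fold = neto_length(wt_diagram, "monopolar_1")
        bip = [b for b in wt_diagram.branches if b.label == "bipolar"][0]
        onset = float(bip.l[bip.stable_mask()].min())
        assert onset < fold  # positive-width overlap
        l_mid = 0.5 * (onset + fold)
        p = wt_scenario.params
        up = simulate_cycle(p, onset + 0.01, [0.7, 0.0],
                            GrowthLaw("linear_l", 1.0, 100), l_div=l_mid)
        down = simulate_cycle(p, fold - 0.01, [0.65, 0.65],
                              GrowthLaw("linear_l", 1.0, 100), l_div=l_mid)
        assert up.end_state[0] > 0.3 and up.end_state[1] < 0.3    # monopolar
        assert np.all(down.end_state > 0.3)                        # bipolar


class TestDivide:
    def test_substrate_conservation(self, wt_scenario):
        d1, d2 = divide(wt_scenario.params, [0.8, 0.1], end_l=1.6, split=0.5)
        assert d1.l_birth + d2.l_birth == pytest.approx(1.6)
        assert d1.l_birth == pytest.approx(0.8)

    def test_old_end_keeps_activity_new_end_resets(self, wt_scenario):
        d1, d2 = divide(wt_scenario.params, [0.8, 0.1], end_l=1.6, x_new=0.02)
        assert d1.init_state == (0.8, 0.02)
        assert d2.init_state == (0.1, 0.02)

    def test_invalid_split_rejected(self, wt_scenario):
        for s in (0.0, 1.0, -0.1, 1.2):
            with pytest.raises(ValueError):
                divide(wt_scenario.params, [0.5, 0.5], 1.0, split=s)

    def test_inheritance_rule_reassigns_weights(self, wt_scenario):
        rule = lambda p, i: (0.6, 0.4) if i == 0 else (0.5, 0.5)
        d1, d2 = divide(wt_scenario.params, [0.8, 0.1], 1.6, inheritance_rule=rule)
        assert d1.params.a == (0.6, 0.4)
        assert d2.params.a == (0.5, 0.5)

    def test_monopolar_daughter_lands_in_connected_basin(self, wt_scenario):
        """The daughter inheriting the active tip relaxes onto the monopolar
        state (basin membership by forward integration)."""
        p = wt_scenario.params
        d1, _ = divide(p, [0.72, 0.08], end_l=2.1)
        tr = simulate_cycle(p, d1.l_birth, list(d1.init_state), growth_law=None)
        assert tr.end_state[0] > 0.3 and tr.end_state[1] < 0.3


def _synthetic_traj(params, sets_and_times, duration=100.0):
    """Manufacture a trajectory realising a prescribed active-set history."""
    ts = np.linspace(0, duration, 500)
    x = np.full((len(ts), 2), 0.05)
    for t0, s in sets_and_times:
        mask = ts >= t0
        for z in (0, 1):
            x[mask, z] = 0.7 if z in s else 0.05
    events = []
    prev = sets_and_times[0][1]
    for t0, s in sets_and_times[1:]:
        for z in set(s) - set(prev):
            events.append((t0, "activation", z))
        for z in set(prev) - set(s):
            events.append((t0, "deactivation", z))
        if len(prev) == 1 and len(s) == 2 and prev[0] in s:
            events.append((t0, "NETO", [z for z in s if z != prev[0]][0]))
        if len(prev) == 1 and len(s) == 1 and prev != s:
            events.append((t0, "tip_switch", s[0]))
        prev = s
    return Trajectory(t=ts, l=np.linspace(1, 2, len(ts)), x=x, events=events,
                      params=params, growth_law=None, l_birth=1.0, l_div=2.0)


class TestClassifyGrowthPattern:
    @pytest.mark.parametrize("history,expected", [
        ([(0.0, (0,)), (40.0, (0, 1))], "monopolar_then_NETO"),
        ([(0.0, (1,)), (30.0, (0,)), (70.0, (0, 1))], "tip_switch_then_NETO"),
        ([(0.0, (0, 1))], "bipolar_from_birth"),
        ([(0.0, (0,))], "monopolar_no_NETO"),
        ([(0.0, ())], "orb"),
    ])
    def test_rule_table(self, wt_scenario, history, expected):
        traj = _synthetic_traj(wt_scenario.params, history)
        assert classify_growth_pattern(traj).label == expected


class TestLineage:
    def test_zero_noise_single_pattern(self, wt_scenario):
        records, summary = simulate_lineage(
            wt_scenario.params, 2, wt_scenario.l_birth,
            GrowthLaw("linear_l", 1.0, 20),
        )
        labels = {r["pattern"].label for r in records}
        assert labels == {"monopolar_then_NETO"}

    def test_seeded_noise_is_bit_reproducible(self, wt_scenario):
        kw = dict(
            generations=2, l_birth=wt_scenario.l_birth,
            growth_law=GrowthLaw("linear_l", 1.0, 20),
            noise_model=NoiseModel(cv_eps=0.05, cv_beta=0.05), seed=11,
        )
        _, s1 = simulate_lineage(wt_scenario.params, **kw)
        _, s2 = simulate_lineage(wt_scenario.params, **kw)
        pd.testing.assert_frame_equal(s1, s2)

    def test_noise_without_seed_rejected(self, wt_scenario):
        with pytest.raises(ValueError, match="seed"):
            simulate_lineage(
                wt_scenario.params, 1, 1.05,
                noise_model=NoiseModel(cv_eps=0.1),
            )
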