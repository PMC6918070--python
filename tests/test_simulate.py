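"""Simulator unit and property tests: threshold primitive, steady state,
shifts, conservation laws, and the qPCR/turbidostat generators."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

import mmphys as m
from mmphys.simulate import InitiatorState, accumulate_and_fire

LN2 = math.log(2.0)


class TestAccumulateAndFire:
    def test_threshold_crossing_with_carryover(self):
        st_ = InitiatorState(accum=0.9, delta=1.0, n_ori=4)
        st_, fired = accumulate_and_fire(st_, added_volume=0.2 * 4)
        assert fired
        assert st_.n_ori == 8
        assert st_.accum == pytest.approx(0.1)

    def test_no_growth_never_fires(self):
        st_ = InitiatorState(accum=0.5, delta=1.0, n_ori=2)
        for _ in range(100):
            st_, fired = accumulate_and_fire(st_, 0.0)
            assert not fired
        assert st_.accum == pytest.approx(0.5)

    def test_negative_added_volume_rejected(self):
        with pytest.raises(ValueError):
            accumulate_and_fire(InitiatorState(0.0, 1.0, 2), -0.1)

    def test_fixed_point_is_twice_delta(self):
        # iterate the noiseless inter-initiation map v <- v/2 + delta
        delta = 0.6
        v = 5.0
        for _ in range(30):
            v = v / 2.0 + delta
        assert v == pytest.approx(2 * delta, rel=1e-8)

    def test_discrete_stepping_matches_event_driven(self, noiseless_slow):
        """Brute-force discrete-time integration of the threshold primitive
        reproduces the event-driven simulator's initiation size per ori."""
        cond = m.GrowthCondition(name="slow", tau_mean=60.0, C_mean=35.0,
                                 D_mean=15.0, width_mean=0.9,
                                 si_mean=1.2).noiseless()
        lam = cond.growth_rate
        st_ = InitiatorState(accum=0.0, delta=cond.si_mean / 2, n_ori=1)
        V, dt = 1.0, 0.001
        s_i_obs = []
        t, next_div = 0.0, None
        for _ in range(800_000):
            dV = V * (math.exp(lam * dt) - 1.0)
            V += dV
            n_before = st_.n_ori
            st_, fired = accumulate_and_fire(st_, dV)
            t += dt
            if fired:
                s_i_obs.append(V / n_before)
                next_div = t + cond.C_mean + cond.D_mean
            if next_div is not None and t >= next_div:
                V /= 2.0
                st_.n_ori = max(1, st_.n_ori // 2)
                next_div = None
        truth = noiseless_slow.initiations.query("t_init_min > 300")
        assert np.mean(s_i_obs[-5:]) == pytest.approx(
            truth["s_i_um3"].iloc[-1], rel=1e-3)

    @given(add=st.floats(min_value=0.0, max_value=0.99))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_subthreshold_accumulation_is_additive(self, add):
        st_ = InitiatorState(accum=0.0, delta=1.0, n_ori=2)
        st_, fired = accumulate_and_fire(st_, add * 2)
        assert not fired
        assert st_.accum == pytest.approx(add)


class TestSteadyState:
    def test_noiseless_tau_equals_c_plus_d(self):
        """tau = 60, C = 40, D = 20: every generation doubles exactly, with
        one initiation per generation at a constant size per ori."""
        cond = m.GrowthCondition(name="nl", tau_mean=60.0, C_mean=40.0,
                                 D_mean=20.0, width_mean=0.9,
                                 si_mean=1.2).noiseless()
        res = m.simulate_steady_state(cond, None, n_generations=25, seed=2)
        cells = res.cells[res.cells["t_birth_min"] > 300]
        inits = res.initiations[res.initiations["t_init_min"] > 300]
        np.testing.assert_allclose(
            cells["V_div_um3"] / cells["V_birth_um3"], 2.0, rtol=1e-9)
        np.testing.assert_allclose(
            cells["t_div_min"] - cells["t_birth_min"], 60.0, rtol=1e-9)
        assert inits.groupby("cell_id").size().eq(1).all()
        np.testing.assert_allclose(inits["s_i_um3"], 1.2, rtol=1e-9)

    def test_volume_conserved_and_length_identity_at_division(self, steady_run):
        """The tracked daughter's birth volume is exactly the septum
        fraction of the mother's division volume, and with equal widths the
        two daughter lengths sum to the mother length plus W/3 (the two new
        hemispherical poles)."""
        for _, grp in steady_run.cells.groupby("lineage"):
            grp = grp.sort_values("t_birth_min")
            vb = grp["V_birth_um3"].to_numpy()[1:]
            vd = grp["V_div_um3"].to_numpy()[:-1]
            f = grp["septum_fraction"].to_numpy()[:-1]
            np.testing.assert_allclose(vb, f * vd, rtol=1e-9)
        row = steady_run.cells.iloc[10]
        V, W, f = row["V_div_um3"], row["width_um"], row["septum_fraction"]
        lsum = (m.length_from_volume(f * V, W)
                + m.length_from_volume((1 - f) * V, W))
        assert lsum == pytest.approx(m.length_from_volume(V, W) + W / 3,
                                     rel=1e-12)

    def test_origins_fire_in_powers_of_two(self, steady_run):
        assert set(steady_run.initiations["n_ori"]) <= {1, 2, 4, 8}

    def test_mean_initiation_size_recovers_configured(self):
        res = m.simulate_steady_state(m.DEFAULT_CONDITION, None,
                                      n_generations=60, n_lineages=8, seed=21)
        s = res.initiations.query("t_init_min > 180")["s_i_um3"]
        sem = s.std() / np.sqrt(len(s))
        assert len(s) >= 400
        assert abs(s.mean() - 1.2) < 2 * sem

    def test_initiation_adder_slope_zero(self, steady_run):
        """Per-ori volume added between consecutive initiations is
        uncorrelated with the per-ori volume at initiation (adder)."""
        added, at_init = [], []
        for _, grp in steady_run.initiations.groupby("lineage"):
            s = grp.sort_values("t_init_min")["s_i_um3"].to_numpy()
            added.extend(s[1:] - s[:-1] / 2.0)
            at_init.extend(s[:-1])
        assert len(added) >= 500
        fit = sm.OLS(added, sm.add_constant(np.asarray(at_init))).fit()
        lo, hi = fit.conf_int()[1]
        assert lo <= 0.0 <= hi

    def test_same_seed_bit_identical(self):
        a = m.simulate_steady_state(m.DEFAULT_CONDITION, m.SamplingConfig(),
                                    15, 2, seed=9)
        b = m.simulate_steady_state(m.DEFAULT_CONDITION, m.SamplingConfig(),
                                    15, 2, seed=9)
        assert a.frames.equals(b.frames)
        assert a.cells.equals(b.cells)
        assert a.initiations.equals(b.initiations)

    def test_frame_invariants(self, steady_run):
        fr = steady_run.frames
        fl = fr[fr["pair_count"].notna()]
        n_pos = fl["focus_positions"].str.count(";") + 1
        n_pos[fl["focus_positions"] == ""] = 0
        assert (n_pos == fl["pair_count"]).all()
        # times non-decreasing within a lineage
        for _, grp in fr.groupby("lineage"):
            assert grp["time_min"].is_monotonic_increasing

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            m.simulate_steady_state(m.DEFAULT_CONDITION, None, n_generations=0)
        with pytest.raises(ValueError):
            m.GrowthCondition(name="bad", tau_mean=-5.0)
        with pytest.raises(ValueError):
            m.GrowthCondition(name="bad", tau_mean=40.0, septum_mean=1.5)


class TestShift:
    def test_no_initiation_during_pause(self, shift_run):
        res = shift_run["result"]
        for lin, pauses in enumerate(res.pauses):
            ev = res.initiations[res.initiations["lineage"] == lin]
            for p0, p1 in pauses:
                inside = (ev["t_init_min"] > p0) & (ev["t_init_min"] < p1)
                assert not inside.any()

    def test_upshift_division_size_closed_form(self):
        """Noiseless tau 65 -> 30 upshift: the post-shift steady division
        size follows from anchoring both steady states at the invariant
        initiation size: ratio = exp(lam_new (C+D)_new) / exp(lam_old (C+D)_old)."""
        minimal = m.CONDITIONS["succinate_minimal"].noiseless()
        rich = m.CONDITIONS["succinate_rich"].noiseless()
        sched = m.ShiftSchedule(segments=((0.0, minimal), (600.0, rich)),
                                pause_after_downshift=(0.0, 0.0))
        res = m.simulate_shift(sched, None, total_duration=1200.0,
                               n_lineages=1, seed=3)
        cells = res.cells
        pre = cells.query("400 < t_div_min < 600")["V_div_um3"].iloc[-1]
        post = cells.query("t_birth_min > 900")["V_div_um3"].iloc[-1]
        lam_old, lam_new = LN2 / 65.0, LN2 / 30.0
        predicted = math.exp(lam_new * 60.0) / math.exp(lam_old * 74.0)
        assert post / pre == pytest.approx(predicted, rel=1e-9)

    def test_schedule_validation(self):
        cond = m.DEFAULT_CONDITION
        with pytest.raises(ValueError):
            m.ShiftSchedule(segments=((0.0, cond),))
        with pytest.raises(ValueError):
            m.ShiftSchedule(segments=((0.0, cond), (0.0, cond)))
        with pytest.raises(ValueError):
            m.ShiftSchedule(segments=((10.0, cond), (20.0, cond)))


class TestQpcr:
    def test_noiseless_limits(self):
        d0 = m.simulate_qpcr(0.0, 40.0, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(d0.frequencies, 1.0)
        d1 = m.simulate_qpcr(40.0, 40.0, [0.0, 1.0])
        assert d1.frequencies[0] / d1.frequencies[1] == pytest.approx(2.0)

    def test_table_loci_formula(self):
        pos = list(m.TABLE_LOCI.values())
        d = m.simulate_qpcr(40.0, 28.0, pos)
        np.testing.assert_allclose(
            d.frequencies, 2.0 ** ((40.0 / 28.0) * (1.0 - np.abs(pos))),
            rtol=1e-12)

    def test_positions_validated(self):
        with pytest.raises(ValueError):
            m.simulate_qpcr(40.0, 28.0, [0.0, 1.5])

    def test_noise_is_mean_one(self):
        d = m.simulate_qpcr(0.0, 40.0, np.ones(4000), noise_cv=0.10, seed=4)
        assert d.frequencies.mean() == pytest.approx(1.0, abs=0.01)


class TestTurbidostat:
    def test_noiseless_round_trip(self):
        trace = m.simulate_turbidostat(40.0, n_cycles=5)
        assert trace.od[0] == pytest.approx(0.05)
        fits = m.fit_growth_intervals(trace)
        np.testing.assert_allclose(fits["tau_min"], 40.0, rtol=1e-9)
        np.testing.assert_allclose(fits["doublings"], 2.0, rtol=1e-9)

    def test_dilution_interval_length(self):
        trace = m.simulate_turbidostat(40.0, n_cycles=4)
        np.testing.assert_allclose(np.diff(trace.dilution_times), 80.0,
                                   rtol=1e-12)

    def test_noisy_recovery(self):
        trace = m.simulate_turbidostat(40.0, n_cycles=10, noise_cv=0.02,
                                       seed=8)
        fits = m.fit_growth_intervals(trace)
        assert fits["tau_min"].mean() == pytest.approx(40.0, rel=0.03)

    def test_invalid_setpoints(self):
        with pytest.raises(ValueError):
            m.simulate_turbidostat(40.0, od_low=0.3, od_high=0.2)
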