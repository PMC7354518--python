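import math

import numpy as np
import pytest

from kcvkit.channel import (
    FAST_FLICKER_RATE,
    SLOW_GATING_RATE,
    GatingModel,
    IdealizedTrace,
    Segment,
    SimConfig,
    Trace,
    flicker_artifact_check,
    flicker_model,
    idealize,
    iv_and_conductance,
    open_probability,
    read_trace,
    simulate_trace,
    write_trace,
)


def slow_model(gamma=87.0):
    return GatingModel(k_co0=SLOW_GATING_RATE, k_oc0=SLOW_GATING_RATE, gamma_pS=gamma)


class TestGatingModel:
    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            GatingModel(k_co0=0, k_oc0=10)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            GatingModel(k_co0=1, k_oc0=1, gamma_pS=-5)

    def test_open_level_unit_arithmetic(self):
        m = GatingModel(k_co0=1, k_oc0=1, gamma_pS=100.0)
        assert m.open_level_pA(100.0) == pytest.approx(10.0)

    def test_voltage_dependent_rates(self):
        m = GatingModel(k_co0=10, k_oc0=10, s_oc=-0.02)
        assert m.k_oc(-100) == pytest.approx(10 * math.exp(2.0))
        assert m.k_co(-100) == pytest.approx(10.0)


class TestSimulateTrace:
    def test_never_closing_channel_sits_at_open_level(self):
        # k_oc tiny: open dwell ~1e6 s >> trace
        m = GatingModel(k_co0=1000.0, k_oc0=1e-6, gamma_pS=100.0)
        t = simulate_trace(m, 100.0, SimConfig(seed=2, duration=1.0, noise_sd=0.5))
        assert np.mean(t.current_pA) == pytest.approx(10.0, abs=0.2)

    def test_trace_length(self):
        t = simulate_trace(slow_model(), 80.0, SimConfig(seed=1, duration=2.0))
        assert len(t) == 10000

    def test_seed_reproducibility(self):
        cfg = SimConfig(seed=11, duration=2.0)
        t1 = simulate_trace(slow_model(), 80.0, cfg)
        t2 = simulate_trace(slow_model(), 80.0, cfg)
        assert np.array_equal(t1.current_pA, t2.current_pA)

    def test_mean_open_dwell_matches_rate(self):
        # exponential-dwell oracle on the hidden state sequence
        m = GatingModel(k_co0=50.0, k_oc0=40.0, gamma_pS=87.0)
        cfg = SimConfig(seed=4, duration=20.0, noise_sd=0.0, filter_corner=None)
        t = simulate_trace(m, 100.0, cfg)
        s = t.states
        # run lengths of open state, excluding censored ends
        bounds = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [len(s)]))
        dwells = [
            (e - st) / cfg.fs
            for st, e in zip(starts[1:-1], ends[1:-1])
            if s[st] == 1
        ]
        mean = np.mean(dwells)
        se = mean / math.sqrt(len(dwells))
        assert abs(mean - 1 / 40.0) < 3 * se

    def test_filter_needs_headroom(self):
        with pytest.raises(ValueError):
            SimConfig(fs=1500.0, filter_corner=1000.0)


class TestIdealize:
    def test_square_wave_exact_boundaries(self):
        cur = np.array(([0.0] * 50 + [8.0] * 50) * 10)
        t = Trace(voltage_mV=80.0, fs=5000.0, current_pA=cur)
        ideal = idealize(t, min_event_samples=3)
        assert [seg.n_samples for seg in ideal.segments] == [50] * 20
        assert ideal.segments[0].state == "closed"
        assert ideal.open_level_pA == pytest.approx(8.0)
        assert ideal.closed_level_pA == pytest.approx(0.0)

    def test_always_open_single_segment(self):
        t = Trace(voltage_mV=80.0, fs=5000.0, current_pA=np.full(2000, 8.0))
        ideal = idealize(t, single_level="open")
        assert len(ideal.segments) == 1
        assert ideal.segments[0].state == "open"
        assert ideal.open_level_pA == pytest.approx(8.0)

    def test_all_constant_errors(self):
        t = Trace(voltage_mV=80.0, fs=5000.0, current_pA=np.zeros(2000))
        with pytest.raises(ValueError, match="constant"):
            idealize(t)

    def test_segments_sum_to_length(self):
        t = simulate_trace(slow_model(), 80.0, SimConfig(seed=6, duration=2.0))
        ideal = idealize(t)
        assert sum(s.n_samples for s in ideal.segments) == len(t)

    def test_states_alternate(self):
        t = simulate_trace(slow_model(), 80.0, SimConfig(seed=7, duration=2.0))
        segs = idealize(t).segments
        assert all(a.state != b.state for a, b in zip(segs, segs[1:]))

    def test_misassignment_below_one_percent(self):
        # oracle: the simulator's hidden state sequence
        m = slow_model(gamma=100.0)  # open level 8 pA at 80 mV
        cfg = SimConfig(seed=8, duration=5.0, noise_sd=1.6, filter_corner=None)
        t = simulate_trace(m, 80.0, cfg)
        ideal = idealize(t)
        assigned = np.concatenate(
            [np.full(s.n_samples, 1 if s.state == "open" else 0) for s in ideal.segments]
        )
        mis = np.mean(assigned != t.states)
        assert mis < 0.01

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            IdealizedTrace(
                segments=(Segment("open", 5), Segment("open", 5)),
                closed_level_pA=0.0,
                open_level_pA=5.0,
                n_samples=10,
            )


class TestOpenProbability:
    def test_all_open(self):
        ideal = IdealizedTrace((Segment("open", 100),), 0.0, 5.0, 100)
        assert open_probability(ideal) == 1.0

    def test_all_closed(self):
        ideal = IdealizedTrace((Segment("closed", 100),), 0.0, 5.0, 100)
        assert open_probability(ideal) == 0.0

    def test_stationary_recovery(self):
        # Po within 3 s.e. of k_co/(k_co+k_oc) over a seeded batch
        m = GatingModel(k_co0=30.0, k_oc0=10.0, gamma_pS=87.0)
        expected = 30.0 / 40.0
        pos = []
        for seed in range(10):
            t = simulate_trace(m, 100.0, SimConfig(seed=seed, duration=5.0))
            pos.append(open_probability(idealize(t)))
        mean = np.mean(pos)
        se = np.std(pos, ddof=1) / math.sqrt(len(pos))
        assert abs(mean - expected) < 3 * se + 1e-3


class TestIVAndConductance:
    def test_exact_points(self):
        # synthetic noiseless square traces: i = 0.1 pA/mV -> 100 pS
        traces = []
        for v in (40.0, 80.0, 120.0):
            level = 0.1 * v
            cur = np.array(([0.0] * 100 + [level] * 100) * 10)
            traces.append(Trace(voltage_mV=v, fs=5000.0, current_pA=cur))
        est = iv_and_conductance(traces, fit_voltages=(40.0, 80.0, 120.0))
        assert est.gamma_pS == pytest.approx(100.0)
        assert est.gamma_se_pS == pytest.approx(0.0, abs=1e-9)

    def test_single_voltage_fit_errors(self):
        cur = np.array(([0.0] * 100 + [4.0] * 100) * 10)
        t = Trace(voltage_mV=40.0, fs=5000.0, current_pA=cur)
        with pytest.raises(ValueError):
            iv_and_conductance([t], fit_voltages=(40.0,))

    def test_missing_fit_voltage_errors(self):
        cur = np.array(([0.0] * 100 + [4.0] * 100) * 10)
        t = Trace(voltage_mV=40.0, fs=5000.0, current_pA=cur)
        with pytest.raises(ValueError):
            iv_and_conductance([t], fit_voltages=(40.0, 80.0))

    @pytest.mark.parametrize("gamma", [45.0, 87.0, 110.0])
    def test_recovery_within_five_percent(self, gamma):
        traces = []
        for k, v in enumerate((-120.0, -80.0, -40.0, 40.0, 80.0, 120.0)):
            traces.append(
                simulate_trace(slow_model(gamma), v, SimConfig(seed=100 + k, duration=10.0))
            )
        est = iv_and_conductance(traces)
        assert abs(est.gamma_pS - gamma) / gamma < 0.05


class TestFlickerArtifact:
    def test_artifact_with_filter(self):
        rep = flicker_artifact_check(
            flicker_model(87.0), slow_model(87.0), SimConfig(seed=21, duration=2.0)
        )
        assert rep.neg_over_pos_ratio_fast < 0.9
        assert rep.neg_over_pos_ratio_slow > 0.9
        assert rep.artifact_present

    def test_slow_model_symmetric(self):
        rep = flicker_artifact_check(
            slow_model(87.0), slow_model(87.0), SimConfig(seed=22, duration=2.0)
        )
        assert rep.neg_over_pos_ratio_fast > 0.9

    def test_ratio_recovers_without_filter(self):
        cfg = SimConfig(seed=23, duration=2.0, fs=100000.0, filter_corner=None, noise_sd=0.3)
        rep = flicker_artifact_check(flicker_model(87.0), slow_model(87.0), cfg)
        assert rep.neg_over_pos_ratio_fast > 0.9


class TestTraceIO:
    def test_roundtrip(self, tmp_path):
        t = simulate_trace(slow_model(), 80.0, SimConfig(seed=30, duration=0.5, fs=2000.0, filter_corner=500.0))
        p = tmp_path / "trace.tsv"
        write_trace(t, p)
        back = read_trace(p)
        assert back.voltage_mV == 80.0
        assert back.fs == 2000.0
        assert np.allclose(back.current_pA, t.current_pA, atol=1e-6)
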