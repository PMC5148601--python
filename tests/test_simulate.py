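"""Synthetic-unit generator: rates, failures, conductance, trace rendering."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from endbulb.simulate import (
    UnitConfig, InhibitionConfig, Silence, simulate_anf,
    simulate_inhibitory_conductance, apply_sbc_mechanism, simulate_unit,
    render_trace,
)
from endbulb.stimuli import ToneProtocol, synthesize_modulated
from endbulb.events import detect_events, fit_threshold_epsp


def single_tone_protocol(cf, level, duration=1.0, reps=20):
    return ToneProtocol(
        frequencies=np.array([cf]), levels=np.array([level]),
        tone_duration=duration, ramp_duration=0.005,
        inter_stimulus_interval=0.3, repetitions=reps,
        presentation_order=np.array([[0, 0, r] for r in range(reps)]))


class TestAnfRates:
    def test_spontaneous_count(self, default_unit):
        ev = simulate_anf(default_unit, Silence(10.0), seed=1)
        expected = default_unit.spont_rate * 10.0
        assert abs(len(ev) - expected) < 3 * np.sqrt(expected)

    def test_driven_plateau_rate(self, default_unit):
        proto = single_tone_protocol(default_unit.cf, 50.0)
        ev = simulate_anf(default_unit, proto, seed=2)
        resp = ev[(ev.time_s >= 0.05) & (ev.time_s < 1.0)]
        rate = len(resp) / (0.95 * 20)
        assert rate == pytest.approx(default_unit.max_rate, rel=0.05)

    def test_zero_duration_stimulus_empty(self, default_unit):
        ev = simulate_anf(default_unit, Silence(0.0), seed=1)
        assert len(ev) == 0

    def test_refractoriness_and_ordering(self, spont_events):
        ev, _ = spont_events
        for _, g in ev.groupby("trial"):
            d = np.diff(g.time_s.to_numpy())
            assert np.all(d >= 0.0007 - 1e-12)

    def test_seeded_determinism(self, default_unit):
        a = simulate_anf(default_unit, Silence(2.0), seed=5)
        b = simulate_anf(default_unit, Silence(2.0), seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestConductance:
    def test_disabled_is_zero(self, default_unit):
        inh = replace(default_unit.inhibition_resolved(), enabled=False)
        t = np.arange(0, 0.5, 0.0002)
        proto = single_tone_protocol(default_unit.cf, 60.0, duration=0.1)
        g = simulate_inhibitory_conductance(inh, proto, t,
                                            protocol_cell=(2000.0, 60.0),
                                            unit=default_unit)
        assert np.all(g == 0)

    def test_delay_and_decay(self, default_unit):
        inh = default_unit.inhibition_resolved()
        t = np.arange(0, 0.5, 0.0002)
        proto = single_tone_protocol(default_unit.cf, 60.0, duration=0.1)
        g = simulate_inhibitory_conductance(inh, proto, t,
                                            protocol_cell=(2000.0, 60.0),
                                            unit=default_unit)
        # onset no earlier than the synaptic delay
        assert g[t < inh.delay].max() < 1e-6
        # post-offset decay follows the exponential time constant
        i0 = np.searchsorted(t, 0.110)
        i1 = np.searchsorted(t, 0.120)
        ratio = g[i1] / g[i0]
        assert ratio == pytest.approx(np.exp(-0.010 / inh.decay_tau), rel=0.15)

    def test_peak_monotone_in_level(self, default_unit):
        inh = default_unit.inhibition_resolved()
        t = np.arange(0, 0.3, 0.0002)
        proto = single_tone_protocol(default_unit.cf, 60.0, duration=0.1)
        peaks = []
        for level in (20.0, 30.0, 40.0, 50.0):
            g = simulate_inhibitory_conductance(
                inh, proto, t, protocol_cell=(2000.0, level),
                unit=default_unit)
            peaks.append(g.max())
        assert np.all(np.diff(peaks) > 0)


class TestSbcMechanism:
    def test_suprathreshold_limit(self, default_unit):
        ev = simulate_anf(default_unit, Silence(5.0), seed=3)
        ev["rising_slope_Vps"] = 100.0  # far above threshold
        cfg = replace(default_unit, forced_fail_window=0.0,
                      relative_refractory_end=1e-9)
        out, _ = apply_sbc_mechanism(ev, None, cfg, seed=4)
        assert (1 - out.is_ap.mean()) < 0.01

    def test_spontaneous_failure_fraction(self, spont_events):
        ev, _ = spont_events
        assert 1 - ev.is_ap.mean() == pytest.approx(0.28, abs=0.04)

    def test_driven_failure_fraction(self, default_unit):
        proto = single_tone_protocol(default_unit.cf, 50.0, reps=30)
        ev, _ = simulate_unit(default_unit, proto, seed=8)
        resp = ev[(ev.time_s >= 0.1) & (ev.time_s < 1.0)]
        assert 1 - resp.is_ap.mean() == pytest.approx(0.49, abs=0.05)

    def test_ground_truth_threshold_identity(self, rgs_unit):
        ev, rgs, truth = rgs_unit
        inh = truth.config.inhibition_resolved()
        expected = (truth.config.base_threshold_epsp
                    + inh.subtractive_gain * truth.conductance)
        assert np.allclose(truth.effective_threshold, expected)

    def test_failure_fraction_matches_generative_probability(self, spont_events):
        ev, truth = spont_events
        observed = 1 - ev.is_ap.mean()
        expected = 1 - truth.p_ap.mean()
        n = len(ev)
        assert abs(observed - expected) < 4 * np.sqrt(0.25 / n)

    def test_end_to_end_determinism(self, default_unit):
        a, _ = simulate_unit(default_unit, Silence(2.0), seed=9)
        b, _ = simulate_unit(default_unit, Silence(2.0), seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestInhibitionOnThreshold:
    """Fitted threshold-EPSP behaviour under the generative inhibition."""

    def test_stimulated_threshold_rises_spontaneous_unchanged(self, default_unit):
        cfg = default_unit
        sp, _ = simulate_unit(cfg, Silence(40.0), seed=31)
        proto = single_tone_protocol(cfg.cf, 50.0, reps=25)
        st, truth = simulate_unit(cfg, proto, seed=32)
        resp = st[(st.time_s >= 0.1) & (st.time_s < 1.0)]
        d_sp = fit_threshold_epsp(sp).d
        d_st = fit_threshold_epsp(resp).d
        assert d_sp == pytest.approx(cfg.base_threshold_epsp, abs=0.3)
        assert d_st > d_sp + 1.0

    def test_inhibition_disabled_thresholds_match(self, default_unit):
        cfg = replace(default_unit,
                      inhibition=replace(default_unit.inhibition, enabled=False))
        sp, _ = simulate_unit(cfg, Silence(40.0), seed=41)
        proto = single_tone_protocol(cfg.cf, 50.0, reps=25)
        st, _ = simulate_unit(cfg, proto, seed=42)
        resp = st[(st.time_s >= 0.1) & (st.time_s < 1.0)]
        f_sp = fit_threshold_epsp(sp)
        f_st = fit_threshold_epsp(resp)
        # same inflection point within combined fit uncertainty
        tol = 3 * np.hypot(f_sp.d_se, f_st.d_se) + 0.15
        assert abs(f_st.d - f_sp.d) < tol

    def test_pure_subtraction_raises_d_not_a(self, default_unit):
        inh = replace(default_unit.inhibition, divisive_gain=0.0)
        cfg = replace(default_unit, inhibition=inh,
                      forced_fail_window=0.0, relative_refractory_end=1e-9,
                      absolute_refractory=0.0002)
        sp, _ = simulate_unit(cfg, Silence(60.0), seed=51)
        proto = single_tone_protocol(cfg.cf, 50.0, reps=40)
        st, _ = simulate_unit(cfg, proto, seed=52)
        resp = st[(st.time_s >= 0.1) & (st.time_s < 1.0)]
        f_sp = fit_threshold_epsp(sp)
        f_st = fit_threshold_epsp(resp)
        assert f_st.d > f_sp.d + 1.0
        assert abs(f_st.a - f_sp.a) < 3 * np.hypot(f_sp.a_se, f_st.a_se) + 0.1


class TestRenderTrace:
    def test_noise_free_peak_amplitude(self):
        ev = pd.DataFrame({
            "condition": "x", "trial": 0, "time_s": [0.05],
            "rising_slope_Vps": [7.0], "falling_slope_Vps": [21.0],
            "amplitude_mV": [6.0], "is_ap": [True], "freq_hz": np.nan,
            "level_db": np.nan, "rep": 0})
        t, v = render_trace(ev, noise_sd=0.0, duration=0.1,
                            prepotential_fraction=0.0)
        assert v.max() == pytest.approx(6.0, rel=0.02)

    def test_empty_stream_pure_noise(self):
        ev = pd.DataFrame(columns=["condition", "trial", "time_s",
                                   "rising_slope_Vps", "falling_slope_Vps",
                                   "amplitude_mV", "is_ap", "freq_hz",
                                   "level_db", "rep"])
        t, v = render_trace(ev, noise_sd=0.1, seed=3, duration=0.2)
        assert np.std(v) == pytest.approx(0.1, rel=0.1)
        assert abs(np.mean(v)) < 0.01

    def test_detection_round_trip(self, default_unit):
        """Rendered events are recovered by slope-threshold detection."""
        ev, _ = simulate_unit(default_unit, Silence(3.0), seed=5)
        ev = ev.sort_values("time_s")
        keep = np.concatenate([[True], np.diff(ev.time_s) > 0.0025])
        ev = ev[keep].head(100)
        noise_sd = ev.amplitude_mV.min() / 40.0
        t, v = render_trace(ev, sample_rate=50_000, noise_sd=noise_sd,
                            seed=1, duration=3.0, prepotential_fraction=0.05)
        det = detect_events((t, v), rising_slope_threshold=3.5)
        t_true = ev.time_s.to_numpy()
        t_det = det.time_s.to_numpy()
        hits = sum(np.min(np.abs(t_det - tt)) < 0.0002 for tt in t_true)
        assert hits >= 99
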