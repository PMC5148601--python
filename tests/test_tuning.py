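"""Frequency-response areas, CF/threshold recovery, Q values, asymmetry, RLG."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from endbulb.simulate import UnitConfig, simulate_unit
from endbulb.stimuli import generate_fra_protocol
from endbulb.tuning import (
    FRA, TuningSummary, build_fra, significant_cells, estimate_cf_threshold,
    q_values, asymmetry_index, rate_level,
)


def synthetic_fra(values, freqs=None, levels=None, base=0.0, sd=1.0):
    values = np.asarray(values, float)
    n_f, n_l = values.shape
    if freqs is None:
        freqs = np.geomspace(500, 8000, n_f)
    if levels is None:
        levels = np.linspace(0, 90, n_l)
    return FRA(frequencies=np.asarray(freqs, float),
               levels=np.asarray(levels, float), metric="input_rate",
               values=values, n_presentations=np.full((n_f, n_l), 5),
               baseline_mean=base, baseline_sd=sd)


class TestBuildFra:
    def test_rate_monotone_with_level_at_cf(self, fra_events, default_unit):
        ev, proto = fra_events
        fra = build_fra(ev, proto, "input_rate")
        fi = int(np.argmin(np.abs(fra.frequencies - default_unit.cf)))
        col = fra.values[fi]
        assert col[-1] > col[0] + 100  # driven at top level, spont at bottom

    def test_input_rate_dominates_output_rate(self, fra_events):
        ev, proto = fra_events
        fra_in = build_fra(ev, proto, "input_rate")
        fra_out = build_fra(ev, proto, "output_rate")
        ok = np.isfinite(fra_in.values)
        assert np.all(fra_in.values[ok] >= fra_out.values[ok] - 1e-9)

    def test_failure_and_threshold_maps_correlate(self, fra_events):
        ev, proto = fra_events
        ff = build_fra(ev, proto, "failure_fraction")
        th = build_fra(ev, proto, "threshold_epsp")
        both = np.isfinite(ff.values) & np.isfinite(th.values)
        r = spearmanr(ff.values[both], th.values[both]).statistic
        assert r >= 0.5

    def test_protocol_mismatch_raises(self, fra_events):
        ev, proto = fra_events
        bad = ev.copy()
        bad.loc[bad.index[:5], "freq_hz"] = 12345.0
        with pytest.raises(ValueError, match="absent from the protocol"):
            build_fra(bad, proto, "input_rate")


class TestCfThreshold:
    def test_recovery_across_seeded_units(self, default_unit):
        cf_err, thr_err = [], []
        for seed in range(20):
            proto = generate_fra_protocol(default_unit.cf / 4,
                                          default_unit.cf * 4, 0.0, 90.0,
                                          repetitions=5, seed=900 + seed)
            ev, _ = simulate_unit(default_unit, proto, seed=950 + seed)
            fra = build_fra(ev, proto, "input_rate")
            s = estimate_cf_threshold(fra)
            step_oct = np.log2(proto.frequencies[1] / proto.frequencies[0])
            cf_err.append(abs(np.log2(s.cf / default_unit.cf)) / step_oct)
            level_step = proto.levels[1] - proto.levels[0]
            thr_err.append(abs(s.threshold - default_unit.threshold_level)
                           / level_step)
        assert np.median(cf_err) <= 1.0
        assert np.median(thr_err) <= 1.0

    def test_all_baseline_fra_undefined(self):
        fra = synthetic_fra(np.zeros((5, 4)), base=0.0, sd=1.0)
        with pytest.raises(ValueError, match="CF undefined"):
            estimate_cf_threshold(fra)

    def test_inhibitory_threshold_above_excitatory(self, default_unit):
        # the paper-scale contrast is a population mean with large spread,
        # so average over several seeded units
        deltas = []
        for seed in range(5):
            proto = generate_fra_protocol(default_unit.cf / 4,
                                          default_unit.cf * 4, 0.0, 90.0,
                                          repetitions=5, seed=860 + seed)
            ev, _ = simulate_unit(default_unit, proto, seed=880 + seed)
            exc = estimate_cf_threshold(build_fra(ev, proto, "input_rate"))
            inh = estimate_cf_threshold(build_fra(ev, proto,
                                                  "threshold_epsp"))
            deltas.append(inh.threshold - exc.threshold)
        assert np.mean(deltas) >= 5.0
        assert min(deltas) >= 0.0


class TestQValues:
    def test_q_formula_on_constructed_fra(self):
        # rectangular response, criterion halfway between band and floor:
        # the interpolated borders sit half a grid step outside the band
        freqs = np.geomspace(500, 8000, 41)   # 0.1-octave steps
        vals = np.zeros((41, 10))
        band = (freqs >= 1599) & (freqs <= 2501)
        vals[band, :] = 100.0
        fra = synthetic_fra(vals, freqs=freqs, base=0.0, sd=25.0)
        s = TuningSummary(cf=2000.0, threshold=0.0)
        out = q_values(fra, s)
        step_oct = np.log2(freqs[1] / freqs[0])
        f_in = freqs[band]
        f_l_exp = f_in[0] * 2.0 ** (-step_oct / 2)
        f_u_exp = f_in[-1] * 2.0 ** (step_oct / 2)
        assert out.q10 == pytest.approx(2000.0 / (f_u_exp - f_l_exp),
                                        rel=0.02)
        assert out.f_lower == pytest.approx(f_l_exp, rel=0.01)
        assert out.f_upper == pytest.approx(f_u_exp, rel=0.01)

    def test_q40_missing_when_levels_insufficient(self):
        fra = synthetic_fra(np.full((10, 3), 100.0),
                            levels=np.array([0.0, 10.0, 20.0]))
        out = q_values(fra, TuningSummary(cf=2000.0, threshold=0.0))
        assert math.isnan(out.q40) and not math.isnan(out.q10)

    def test_inhibitory_map_broader_than_excitatory(self, fra_events):
        ev, proto = fra_events
        fra_exc = build_fra(ev, proto, "input_rate")
        fra_inh = build_fra(ev, proto, "threshold_epsp")
        s_exc = q_values(fra_exc, estimate_cf_threshold(fra_exc))
        s_inh = q_values(fra_inh, estimate_cf_threshold(fra_inh))
        assert s_inh.q10 < s_exc.q10


class TestAsymmetryIndex:
    def test_symmetric_borders_zero(self):
        s = TuningSummary(cf=2000, threshold=0, f_lower=1000, f_upper=4000)
        assert asymmetry_index(s) == pytest.approx(0.0)

    def test_formula_value(self):
        s = TuningSummary(cf=2000, threshold=0, f_lower=1000, f_upper=8000)
        assert asymmetry_index(s) == pytest.approx(math.log(2))

    def test_antisymmetry_under_log_mirror(self):
        s = TuningSummary(cf=2000, threshold=0, f_lower=800, f_upper=3200)
        mirrored = TuningSummary(cf=2000, threshold=0,
                                 f_lower=2000 * 2000 / 3200.0,
                                 f_upper=2000 * 2000 / 800.0)
        assert asymmetry_index(mirrored) == pytest.approx(
            -asymmetry_index(s), abs=1e-12)

    def test_border_at_cf_undefined(self):
        s = TuningSummary(cf=2000, threshold=0, f_lower=2000, f_upper=4000)
        with pytest.raises(ValueError):
            asymmetry_index(s)

    def test_excitatory_fra_has_low_frequency_tail(self, fra_events):
        ev, proto = fra_events
        fra = build_fra(ev, proto, "input_rate")
        s = q_values(fra, estimate_cf_threshold(fra))
        assert s.asymmetry_index < 0


class TestRateLevel:
    def test_rlg_formula(self, fra_events, default_unit):
        ev, proto = fra_events
        rl = rate_level(ev, proto, default_unit.cf)
        expected = math.log10((rl.fr_max - rl.fr_min) / rl.fr_spont)
        assert rl.rlg == pytest.approx(expected)
        assert rl.fr_max >= rl.fr_min

    def test_output_gain_below_input_gain(self, fra_events, default_unit):
        ev, proto = fra_events
        rl_in = rate_level(ev, proto, default_unit.cf)
        rl_out = rate_level(ev, proto, default_unit.cf, output=True)
        assert rl_out.rlg < rl_in.rlg
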