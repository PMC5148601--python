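"""Synthetic paired ANF-input / SBC-output event streams.

Generates event streams with the statistical structure the analysis stages
assume: inhomogeneous-Poisson auditory-nerve firing with dead time, driven by
an asymmetric-triangular frequency tuning and a saturating level function;
near-threshold Gaussian EPSP rising slopes with bounded short-term
facilitation; and a spike-generation stage in which a co-tuned inhibitory
conductance acts subtractively on the threshold EPSP and divisively on the
effective slope.  Ground truth (per-event conductance, effective threshold,
success probability) is retained for parameter-recovery tests.

The inhibition toggle (``InhibitionConfig.enabled``) emulates glycine-receptor
blockade: disabled means the conductance is identically zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._util import rng_from, child_seeds, db_to_power
from .stimuli import (
    ToneProtocol, ModulatedStimulus, RGSStimulus, Spectrogram,
    tone_envelope,
)

EVENT_COLUMNS = [
    "condition", "trial", "time_s", "rising_slope_Vps", "falling_slope_Vps",
    "amplitude_mV", "is_ap", "freq_hz", "level_db", "rep",
]


@dataclass(frozen=True)
class Silence:
    """A stimulus-free epoch of given duration (spontaneous activity)."""
    duration: float


@dataclass(frozen=True)
class InhibitionConfig:
    """Co-tuned inhibitory conductance acting on the SBC spike mechanism.

    The conductance is the stimulus drive in a Gaussian log-frequency window
    (``tuning_width`` octaves SD around ``tuning_center``), thresholded at
    ``activation_threshold_level``, convolved with a delayed single-
    exponential kernel.  It is dimensionless, normalized so a sustained
    supra-threshold on-CF tone drives it to ~1.  ``enabled=False`` is the
    strychnine toggle: conductance identically zero.
    """

    enabled: bool = True
    delay: float = 0.001                 # s, onset delay of evoked inhibition
    decay_tau: float = 0.010             # s, exponential decay
    subtractive_gain: float = 3.9        # V/s threshold elevation per unit g
    divisive_gain: float = 0.05          # fractional slope division per unit g
    tuning_center: Optional[float] = None        # Hz; None -> unit CF
    tuning_width: float = 1.2            # octaves (Gaussian SD) - broadband
    activation_threshold_level: Optional[float] = None  # dB; None -> unit thr + 15
    activation_slope_db: float = 3.0     # dB width of the activation sigmoid


@dataclass(frozen=True)
class UnitConfig:
    """Generative parameters of one synthetic ANF->SBC unit.

    Rate model: rate(t) = spont + (max - spont) * sigmoid((L_eff(t) -
    threshold - dynamic_midpoint_db) / dynamic_slope_db), where L_eff is the
    stimulus level seen through the asymmetric triangular tuning filter
    (low-frequency tail shallower than the high-frequency flank).  EPSP
    rising slopes are Gaussian around a facilitation-modulated mean; falling
    slopes are drawn from well-separated AP/failure distributions after the
    spike decision.
    """

    cf: float = 2000.0                   # Hz
    threshold_level: float = 10.0        # dB SPL
    q10: float = 2.5
    flank_asymmetry: float = 2.6         # w_lo / w_hi octave ratio (tail broader)
    spont_rate: float = 85.0             # Hz
    max_rate: float = 282.0              # Hz, driven plateau at CF
    dynamic_midpoint_db: float = 10.0    # dB above threshold at half drive
    dynamic_slope_db: float = 5.0
    absolute_refractory: float = 0.0007  # s
    epsp_slope_mean: float = 6.15        # V/s
    epsp_slope_sd: float = 0.8           # V/s
    falling_slope_ap_mean: float = 21.1  # V/s
    falling_slope_ap_sd: float = 4.9
    falling_slope_fail_mean: float = 4.4
    falling_slope_fail_sd: float = 1.2
    amplitude_ap_mean: float = 6.0       # mV
    amplitude_ap_sd: float = 1.0
    amplitude_fail_mean: float = 2.0
    amplitude_fail_sd: float = 0.5
    base_threshold_epsp: float = 6.1     # V/s, Boltzmann inflection d
    boltzmann_slope_a: float = 0.4       # V/s
    facilitation_gain: float = 1.7       # fractional slope boost at saturation
    facilitation_tau: float = 0.004      # s, generative preceding-activity kernel
    facilitation_scale: float = 3.0      # PreAct units at tanh half-saturation
    forced_fail_window: float = 0.001    # s after an AP: EPSPs always fail
    relative_refractory_end: float = 0.002  # s; threshold ramps back to base
    refractory_threshold_boost: float = 3.0  # V/s at end of hard window
    inhibition: InhibitionConfig = field(default_factory=InhibitionConfig)
    seed: int = 0

    def __post_init__(self):
        if self.spont_rate < 0 or self.max_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.epsp_slope_sd <= 0:
            raise ValueError("slope SDs must be > 0")
        if self.falling_slope_ap_mean <= self.falling_slope_fail_mean:
            raise ValueError("AP falling-slope mean must exceed failure mean")

    # -- tuning geometry -----------------------------------------------------
    def flank_halfwidths(self) -> tuple:
        """(w_hi, w_lo): octave half-widths of the tuning V at +10 dB.

        Solved from Q10 = CF / BW10 with BW10 = CF (2^w_hi - 2^-w_lo) and the
        configured low/high asymmetry ratio.
        """
        rho = self.flank_asymmetry
        bw_oct_target = 1.0 / self.q10  # BW10 / CF

        def f(w_hi):
            return (2.0 ** w_hi - 2.0 ** (-rho * w_hi)) - bw_oct_target

        w_hi = brentq(f, 1e-6, 6.0)
        return w_hi, rho * w_hi

    def flank_attenuation_db(self, freq_hz: np.ndarray) -> np.ndarray:
        """Threshold elevation (dB) at ``freq_hz`` re the CF minimum."""
        w_hi, w_lo = self.flank_halfwidths()
        d_oct = np.log2(np.asarray(freq_hz, dtype=float) / self.cf)
        s_hi = 10.0 / w_hi   # dB per octave, steep high-frequency flank
        s_lo = 10.0 / w_lo   # shallow low-frequency tail
        return np.where(d_oct >= 0, s_hi * d_oct, s_lo * (-d_oct))

    def rate_from_level(self, level_db: np.ndarray) -> np.ndarray:
        """Firing rate (Hz) from the effective (tuning-filtered) level."""
        x = (np.asarray(level_db, dtype=float) - self.threshold_level
             - self.dynamic_midpoint_db) / self.dynamic_slope_db
        return self.spont_rate + (self.max_rate - self.spont_rate) / (1.0 + np.exp(-x))

    def inhibition_resolved(self) -> InhibitionConfig:
        """Inhibition config with unit-dependent defaults filled in."""
        inh = self.inhibition
        center = inh.tuning_center if inh.tuning_center is not None else self.cf
        act = (inh.activation_threshold_level
               if inh.activation_threshold_level is not None
               else self.threshold_level + 15.0)
        return replace(inh, tuning_center=center, activation_threshold_level=act)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "UnitConfig":
        d = json.loads(text)
        d["inhibition"] = InhibitionConfig(**d["inhibition"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Generative bookkeeping kept alongside a simulated stream."""

    config: UnitConfig
    conductance: np.ndarray          # per-event inhibitory conductance g
    effective_threshold: np.ndarray  # per-event theta = d + sub_gain * g (V/s)
    p_ap: np.ndarray                 # per-event generative success probability


# ---------------------------------------------------------------------------
# Stimulus -> component power traces
# ---------------------------------------------------------------------------

def _weighted_level(stimulus, config: UnitConfig, t: np.ndarray,
                    weight_db_fn, level_db: float) -> np.ndarray:
    """Effective stimulus level (dB) seen through a frequency weighting.

    ``weight_db_fn(f)`` returns the attenuation in dB applied to a spectral
    component at frequency ``f``.  Component powers (linear, peak-normalized
    per tone) are attenuated, summed, and converted back to dB; silence maps
    to -inf handled by the caller's sigmoid.
    """
    power = np.zeros_like(t, dtype=float)
    if isinstance(stimulus, Silence) or stimulus is None:
        pass
    elif isinstance(stimulus, ModulatedStimulus):
        if stimulus.kind == "AM":
            env = np.interp(t, stimulus.times, stimulus.envelope,
                            left=0.0, right=0.0)
            w = db_to_power(-weight_db_fn(stimulus.carrier_frequency))
            power += w * db_to_power(level_db) * env ** 2
        else:  # FM: instantaneous frequency trace
            f_inst = np.interp(t, stimulus.times, stimulus.envelope,
                               left=np.nan, right=np.nan)
            valid = np.isfinite(f_inst)
            w = np.zeros_like(t)
            w[valid] = db_to_power(-weight_db_fn(f_inst[valid]))
            power += w * db_to_power(level_db)
    elif isinstance(stimulus, RGSStimulus):
        dt = t[1] - t[0] if len(t) > 1 else 1e-4
        for tone in stimulus.tones:
            w = db_to_power(-float(weight_db_fn(tone.center_frequency)))
            if w < 1e-8:
                continue
            n, b = tone.envelope_order, tone.bandwidth
            t_peak = tone.envelope_peak_lag
            t_end = t_peak + 6.0 * n / (2 * np.pi * b)
            i0 = max(0, int(math.floor((tone.onset - t[0]) / dt)))
            i1 = min(len(t), int(math.ceil((tone.onset + t_end - t[0]) / dt)) + 1)
            if i1 <= i0:
                continue
            tt = np.maximum(t[i0:i1] - tone.onset, 0.0)
            env = (tt ** (n - 1)) * np.exp(-2 * np.pi * b * tt)
            pk = ((n - 1) / (2 * np.pi * b)) ** (n - 1) * np.exp(-(n - 1))
            power[i0:i1] += w * db_to_power(tone.level) * (env / pk) ** 2
    else:
        raise TypeError(f"unsupported stimulus type {type(stimulus).__name__}")
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(power, where=power > 0,
                               out=np.full_like(power, -200.0))


def _tone_level_trace(protocol: ToneProtocol, config: UnitConfig,
                      freq: float, level: float, t: np.ndarray,
                      weight_db_fn) -> np.ndarray:
    env = tone_envelope(protocol, t)
    power = db_to_power(level - float(weight_db_fn(freq))) * env ** 2
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(power, where=power > 0,
                               out=np.full_like(power, -200.0))


def _inhibition_weight_fn(inh: InhibitionConfig):
    def w_db(f):
        d_oct = np.log2(np.asarray(f, dtype=float) / inh.tuning_center)
        # Gaussian spectral window expressed as an attenuation in dB
        return -10.0 * np.log10(np.exp(-0.5 * (d_oct / inh.tuning_width) ** 2))
    return w_db


def simulate_inhibitory_conductance(
    inh: InhibitionConfig,
    stimulus,
    t: np.ndarray,
    *,
    level_db: float = 60.0,
    protocol_cell: Optional[tuple] = None,
    unit: Optional[UnitConfig] = None,
) -> np.ndarray:
    """Inhibitory conductance time series g(t) on a uniform time axis.

    The drive is the stimulus level inside the inhibitory Gaussian frequency
    window, passed through an activation sigmoid at
    ``activation_threshold_level``, then convolved with a delayed
    single-exponential kernel (unit integral, so a sustained saturating
    drive yields g -> 1).  Disabled inhibition returns zeros.

    ``protocol_cell=(freq, level)`` selects one tone presentation when the
    stimulus is a ToneProtocol.
    """
    if not inh.enabled:
        return np.zeros_like(t, dtype=float)
    if inh.tuning_center is None or inh.activation_threshold_level is None:
        if unit is None:
            raise ValueError("unresolved inhibition config requires `unit`")
        inh = unit.inhibition_resolved()
    w_db = _inhibition_weight_fn(inh)
    if isinstance(stimulus, ToneProtocol):
        if protocol_cell is None:
            raise ValueError("ToneProtocol conductance needs protocol_cell=(freq, level)")
        freq, level = protocol_cell
        lvl = _tone_level_trace(stimulus, unit, freq, level, t, w_db)
    else:
        lvl = _weighted_level(stimulus, unit, t, w_db, level_db)
    drive = 1.0 / (1.0 + np.exp(-(lvl - inh.activation_threshold_level)
                                / inh.activation_slope_db))
    dt = t[1] - t[0] if len(t) > 1 else 1e-4
    k_t = np.arange(0.0, inh.delay + 8.0 * inh.decay_tau, dt)
    kernel = np.where(k_t >= inh.delay,
                      np.exp(-(k_t - inh.delay) / inh.decay_tau), 0.0)
    kernel *= dt / inh.decay_tau  # unit integral
    g = np.convolve(drive, kernel)[: len(t)]
    return g


# ---------------------------------------------------------------------------
# ANF event generation
# ---------------------------------------------------------------------------

def _poisson_dead_time(rate: np.ndarray, t: np.ndarray, t_ref: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson event times with absolute dead time.

    The driving intensity is dead-time compensated, lambda = r / (1 - r*t_ref),
    so the delivered event rate matches the nominal rate profile.
    """
    denom = np.maximum(1.0 - rate * t_ref, 0.2)
    lam = rate / denom
    lam_max = float(np.max(lam))
    if lam_max <= 0 or len(t) < 2:
        return np.empty(0)
    duration = t[-1] + (t[1] - t[0])
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    accept = rng.uniform(0.0, lam_max, size=n_cand) < np.interp(cand, t, lam)
    cand = cand[accept]
    if len(cand) == 0:
        return cand
    keep = np.empty(len(cand), dtype=bool)
    last = -np.inf
    for i, ct in enumerate(cand):
        ok = (ct - last) >= t_ref
        keep[i] = ok
        if ok:
            last = ct
    return cand[keep]


def _draw_slopes(times: np.ndarray, config: UnitConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """EPSP rising slopes with tanh-bounded facilitation.

    The generative preceding-activity trace uses the (short) facilitation
    kernel; it is normalized by the mean slope so the tanh argument is a
    dimensionless activity measure.
    """
    n = len(times)
    slopes = np.empty(n)
    acc = 0.0          # sum of S_i exp((t_i - t)/tau) over preceding events
    t_prev = -np.inf
    tau = config.facilitation_tau
    mu0, sd = config.epsp_slope_mean, config.epsp_slope_sd
    gain, scale = config.facilitation_gain, config.facilitation_scale
    noise = rng.normal(0.0, sd, size=n)
    for i in range(n):
        if np.isfinite(t_prev):
            acc *= math.exp(-(times[i] - t_prev) / tau)
        pre = acc / mu0
        mu = mu0 * (1.0 + gain * math.tanh(pre / scale))
        slopes[i] = mu + noise[i]
        acc += slopes[i]
        t_prev = times[i]
    return np.maximum(slopes, 0.1)


def _trial_plan(stimulus, n_trials: int, level_db: float):
    """List of (trial_index, duration, cache_key, tags) per trial."""
    plan = []
    if isinstance(stimulus, ToneProtocol):
        period = stimulus.presentation_period
        for k, (fi, li, rep) in enumerate(stimulus.presentation_order):
            tags = {"freq_hz": float(stimulus.frequencies[fi]),
                    "level_db": float(stimulus.levels[li]), "rep": int(rep)}
            plan.append((k, period, (int(fi), int(li)), tags))
    else:
        if isinstance(stimulus, Silence) or stimulus is None:
            dur = stimulus.duration if stimulus is not None else 0.0
        else:
            dur = stimulus.duration
        for k in range(n_trials):
            plan.append((k, dur, "shared",
                         {"freq_hz": np.nan, "level_db": float(level_db),
                          "rep": int(k)}))
    return plan


def simulate_anf(
    config: UnitConfig,
    stimulus,
    n_trials: int = 1,
    seed: int = 0,
    *,
    level_db: float = 60.0,
    dt: float = 0.0002,
    condition: str = "default",
) -> pd.DataFrame:
    """Simulate the ANF input event stream (spike decision undecided).

    Returns an event table with per-event time, trial, rising slope, and
    stimulus tags; falling slopes/amplitudes/is_ap are filled in by
    :func:`apply_sbc_mechanism`.  For a ToneProtocol each presentation is one
    trial tagged with its (frequency, level, repetition).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    plan = _trial_plan(stimulus, n_trials, level_db)
    w_exc = config.flank_attenuation_db
    rate_cache: dict = {}
    rows = []
    seeds = child_seeds(seed, max(len(plan), 1))
    for trial, duration, key, tags in plan:
        if duration <= 0:
            continue
        t = np.arange(0.0, duration, dt)
        if key not in rate_cache:
            if isinstance(stimulus, ToneProtocol):
                lvl = _tone_level_trace(stimulus, config, tags["freq_hz"],
                                        tags["level_db"], t, w_exc)
            elif isinstance(stimulus, Silence) or stimulus is None:
                lvl = np.full_like(t, -200.0)
            else:
                lvl = _weighted_level(stimulus, config, t, w_exc, level_db)
            rate_cache[key] = config.rate_from_level(lvl)
        rate = rate_cache[key]
        rng = rng_from(int(seeds[trial]))
        times = _poisson_dead_time(rate, t, config.absolute_refractory, rng)
        if len(times) == 0:
            continue
        slopes = _draw_slopes(times, config, rng)
        for tm, sl in zip(times, slopes):
            rows.append((condition, trial, tm, sl, np.nan, np.nan, False,
                         tags["freq_hz"], tags["level_db"], tags["rep"]))
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df["trial"] = df["trial"].astype(int) if len(df) else df["trial"]
    return df


# ---------------------------------------------------------------------------
# SBC spike mechanism
# ---------------------------------------------------------------------------

def apply_sbc_mechanism(
    events: pd.DataFrame,
    conductance,
    config: UnitConfig,
    seed: int = 0,
) -> tuple:
    """Decide AP success per event and draw waveform statistics.

    ``conductance`` is either a single ``(t, g)`` pair shared by all trials
    or a mapping ``trial -> (t, g)``.  The effective slope is
    s* = rising_slope / (1 + divisive_gain * g); the success probability is
    the Boltzmann law P(AP) = 1 / (1 + exp((theta - s*) / a)) with
    theta = base_threshold_epsp + subtractive_gain * g.  Events within the
    hard forced-failure window after an AP always fail; between the hard
    window and ``relative_refractory_end`` the threshold is boosted on a
    linearly recovering ramp.  Falling slopes and amplitudes are then drawn
    from the AP or failure distribution.

    Returns ``(events_with_is_ap, GroundTruth)``.
    """
    events = events.sort_values(["trial", "time_s"], kind="stable").reset_index(drop=True)
    inh = config.inhibition_resolved()
    n = len(events)
    g_event = np.zeros(n)
    if n and inh.enabled and conductance is not None:
        if isinstance(conductance, dict):
            for trial, (tg, gg) in conductance.items():
                m = events["trial"].to_numpy() == trial
                g_event[m] = np.interp(events.loc[m, "time_s"].to_numpy(), tg, gg)
        else:
            tg, gg = conductance
            g_event = np.interp(events["time_s"].to_numpy(), tg, gg)

    theta = config.base_threshold_epsp + inh.subtractive_gain * g_event
    s_eff = events["rising_slope_Vps"].to_numpy() / (1.0 + inh.divisive_gain * g_event)

    rng = rng_from(seed)
    u = rng.uniform(size=n)
    is_ap = np.zeros(n, dtype=bool)
    p_ap = np.zeros(n)
    times = events["time_s"].to_numpy()
    trials = events["trial"].to_numpy()
    a = config.boltzmann_slope_a
    hard, ramp_end = config.forced_fail_window, config.relative_refractory_end
    boost = config.refractory_threshold_boost
    last_ap = -np.inf
    last_trial = None
    for i in range(n):
        if trials[i] != last_trial:
            last_ap, last_trial = -np.inf, trials[i]
        dt_ap = times[i] - last_ap
        if dt_ap < hard:
            p = 0.0
        else:
            th = theta[i]
            if dt_ap < ramp_end:
                th = th + boost * (ramp_end - dt_ap) / (ramp_end - hard)
            p = 1.0 / (1.0 + math.exp(min((th - s_eff[i]) / a, 60.0)))
        p_ap[i] = p
        if u[i] < p:
            is_ap[i] = True
            last_ap = times[i]

    out = events.copy()
    out["is_ap"] = is_ap
    n_ap = int(is_ap.sum())
    fall = np.empty(n)
    amp = np.empty(n)
    fall[is_ap] = rng.normal(config.falling_slope_ap_mean,
                             config.falling_slope_ap_sd, n_ap)
    fall[~is_ap] = rng.normal(config.falling_slope_fail_mean,
                              config.falling_slope_fail_sd, n - n_ap)
    amp[is_ap] = rng.normal(config.amplitude_ap_mean, config.amplitude_ap_sd, n_ap)
    amp[~is_ap] = rng.normal(config.amplitude_fail_mean,
                             config.amplitude_fail_sd, n - n_ap)
    out["falling_slope_Vps"] = np.maximum(fall, 0.2)
    out["amplitude_mV"] = np.maximum(amp, 0.1)
    truth = GroundTruth(config=config, conductance=g_event,
                        effective_threshold=theta, p_ap=p_ap)
    return out, truth


def simulate_unit(
    config: UnitConfig,
    stimulus,
    n_trials: int = 1,
    seed: int = 0,
    *,
    level_db: float = 60.0,
    dt: float = 0.0002,
    condition: str = "default",
) -> tuple:
    """End-to-end simulation: ANF events -> conductance -> SBC mechanism.

    Returns ``(events, GroundTruth)`` with is_ap decided.
    """
    s_anf, s_mech = (int(s) for s in child_seeds(seed, 2))
    events = simulate_anf(config, stimulus, n_trials, s_anf,
                          level_db=level_db, dt=dt, condition=condition)
    inh = config.inhibition_resolved()
    conductance = None
    if inh.enabled:
        if isinstance(stimulus, ToneProtocol):
            t = np.arange(0.0, stimulus.presentation_period, dt)
            conductance = {}
            cache = {}
            for trial, (fi, li, rep) in enumerate(stimulus.presentation_order):
                key = (int(fi), int(li))
                if key not in cache:
                    cell = (float(stimulus.frequencies[fi]),
                            float(stimulus.levels[li]))
                    cache[key] = simulate_inhibitory_conductance(
                        inh, stimulus, t, protocol_cell=cell, unit=config)
                conductance[trial] = (t, cache[key])
        elif isinstance(stimulus, Silence) or stimulus is None:
            conductance = None
        else:
            t = np.arange(0.0, stimulus.duration, dt)
            g = simulate_inhibitory_conductance(inh, stimulus, t,
                                                level_db=level_db, unit=config)
            conductance = (t, g)
    return apply_sbc_mechanism(events, conductance, config, s_mech)


# ---------------------------------------------------------------------------
# Voltage-trace rendering (for event-detection round trips)
# ---------------------------------------------------------------------------

def render_trace(
    events: pd.DataFrame,
    sample_rate: float = 50_000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration: Optional[float] = None,
    trial: int = 0,
    prepotential_fraction: float = 0.15,
) -> tuple:
    """Render one trial's events as a continuous voltage trace (mV).

    Each event is a stereotyped prepotential-EPSP(-AP) template: a small
    Gaussian prepotential bump followed by a half-cosine rise and fall whose
    maximum slopes equal the event's recorded rising and falling slopes and
    whose height equals its amplitude.  The event timestamp sits at the
    maximum-rising-slope point (the rise midpoint).  Overlapping templates
    superpose linearly.  Returns ``(t, v)``.
    """
    if sample_rate < 20_000:
        raise ValueError("sample_rate must be >= 20 kHz")
    ev = events[events["trial"] == trial]
    if duration is None:
        duration = (float(ev["time_s"].max()) + 0.01) if len(ev) else 0.1
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    v = np.zeros(n)
    for _, row in ev.iterrows():
        amp = float(row["amplitude_mV"])
        s_r = float(row["rising_slope_Vps"]) * 1000.0   # mV/s
        s_f = float(row["falling_slope_Vps"]) * 1000.0
        t_rise = amp * np.pi / (2.0 * s_r)
        t_fall = amp * np.pi / (2.0 * s_f)
        t0 = float(row["time_s"]) - t_rise / 2.0        # rise start
        i0 = max(0, int(np.floor((t0 - 0.002) * sample_rate)))
        i1 = min(n, int(np.ceil((t0 + t_rise + t_fall) * sample_rate)) + 1)
        if i1 <= i0:
            continue
        tt = t[i0:i1] - t0
        seg = np.zeros_like(tt)
        rise = (tt >= 0) & (tt < t_rise)
        seg[rise] = 0.5 * amp * (1 - np.cos(np.pi * tt[rise] / t_rise))
        fall = (tt >= t_rise) & (tt < t_rise + t_fall)
        seg[fall] = 0.5 * amp * (1 + np.cos(np.pi * (tt[fall] - t_rise) / t_fall))
        # prepotential: small bump ahead of the EPSP foot
        pp_amp = prepotential_fraction * amp
        seg += pp_amp * np.exp(-0.5 * ((tt + 0.0007) / 0.00015) ** 2)
        v[i0:i1] += seg
    if noise_sd > 0:
        v = v + rng_from(seed).normal(0.0, noise_sd, size=n)
    return t, v


# ---------------------------------------------------------------------------
# Linear-Poisson reference unit (STRF recovery fixtures)
# ---------------------------------------------------------------------------

def simulate_linear_poisson_events(
    spectrogram: Spectrogram,
    kernel: np.ndarray,
    n_trials: int,
    seed: int,
    *,
    base_rate: float = 30.0,
    gain: float = 1.0,
) -> list:
    """Events from a linear-Poisson model with a known spectrotemporal kernel.

    rate(t) = max(0, base_rate + gain * (kernel (*) spectrogram)(t)), with the
    kernel given on the spectrogram's frequency axis over its leading lag
    bins.  Returns a list of per-trial spike-time arrays; used to validate
    STRF estimation by parameter recovery.
    """
    S = spectrogram.values
    n_f, n_t = S.shape
    n_lag = kernel.shape[1]
    if kernel.shape[0] != n_f:
        raise ValueError("kernel frequency axis must match the spectrogram")
    drive = np.zeros(n_t)
    for f in range(n_f):
        drive += np.convolve(S[f], kernel[f])[:n_t]
    rate = np.maximum(base_rate + gain * drive, 0.0)
    dt = spectrogram.time_bin
    lam_max = float(rate.max())
    duration = n_t * dt
    out = []
    for s in child_seeds(seed, n_trials):
        rng = rng_from(int(s))
        n_cand = rng.poisson(lam_max * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        idx = np.minimum((cand / dt).astype(int), n_t - 1)
        acc = rng.uniform(0.0, lam_max, size=n_cand) < rate[idx]
        out.append(cand[acc])
    return out
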