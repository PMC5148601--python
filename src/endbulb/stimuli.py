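"""Acoustic stimulus synthesis for endbulb input-output experiments.

Four stimulus classes are generated as parameter structures (with optional
sampled audio): the pseudorandom tone matrix used to map frequency response
areas (FRA), sinusoidally amplitude- and frequency-modulated tones (SAM/SFM),
and the randomized gamma-tone sequence (RGS) — a sparse dynamic broadband
stimulus used for spectrotemporal receptive-field estimation.  A spectrogram
renderer turns an RGS tone list into the time-frequency matrix on which
reverse correlation operates.

Conventions: times are seconds from stimulus onset on half-open intervals
[onset, onset + duration); frequencies in Hz; levels in dB SPL.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np

from ._util import rng_from, check_positive, db_to_power

DEFAULT_SAMPLE_RATE = 97_656.0  # Hz, close to typical 97.7 kHz acquisition clocks


def erb_bandwidth(frequency_hz: np.ndarray | float) -> np.ndarray | float:
    """Equivalent-rectangular-bandwidth law BW(f) = 24.7 + 0.108 f (Hz).

    Default gamma-tone bandwidth model; any callable f -> BW may be
    substituted where a ``bandwidth_model`` argument is accepted.
    """
    return 24.7 + 0.108 * np.asarray(frequency_hz, dtype=float)


# ---------------------------------------------------------------------------
# FRA tone protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToneProtocol:
    """Pseudorandom pure-tone matrix for frequency-response-area mapping.

    ``presentation_order`` lists (frequency index, level index, repetition)
    triples covering every frequency x level pair exactly ``repetitions``
    times in a seeded pseudorandom order.
    """

    frequencies: np.ndarray          # Hz, log-spaced, strictly increasing
    levels: np.ndarray               # dB SPL, linear-spaced, strictly increasing
    tone_duration: float = 0.100     # s
    ramp_duration: float = 0.005     # s, cos^2 on/off ramps
    inter_stimulus_interval: float = 0.300  # s
    repetitions: int = 5
    presentation_order: np.ndarray = field(default=None, repr=False)

    @property
    def n_presentations(self) -> int:
        return len(self.presentation_order)

    @property
    def presentation_period(self) -> float:
        """Tone plus following silence, the per-presentation time slot."""
        return self.tone_duration + self.inter_stimulus_interval

    def to_json(self) -> str:
        d = asdict(self)
        d["frequencies"] = self.frequencies.tolist()
        d["levels"] = self.levels.tolist()
        d["presentation_order"] = self.presentation_order.tolist()
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ToneProtocol":
        d = json.loads(text)
        return cls(
            frequencies=np.asarray(d["frequencies"], dtype=float),
            levels=np.asarray(d["levels"], dtype=float),
            tone_duration=d["tone_duration"],
            ramp_duration=d["ramp_duration"],
            inter_stimulus_interval=d["inter_stimulus_interval"],
            repetitions=d["repetitions"],
            presentation_order=np.asarray(d["presentation_order"], dtype=int),
        )


def generate_fra_protocol(
    freq_lo: float,
    freq_hi: float,
    level_lo: float,
    level_hi: float,
    repetitions: int = 5,
    seed: int = 0,
    n_frequencies: int = 20,
    n_levels: int = 10,
    tone_duration: float = 0.100,
    ramp_duration: float = 0.005,
    inter_stimulus_interval: float = 0.300,
) -> ToneProtocol:
    """Build the pseudorandom FRA tone matrix.

    Frequencies are equally spaced on a log scale between ``freq_lo`` and
    ``freq_hi``; levels equally spaced on a linear dB scale.  Default grid is
    20 frequencies x 10 levels, 100 ms tones with 5 ms ramps and a 300 ms
    inter-stimulus interval.
    """
    if freq_lo <= 0 or freq_hi <= 0:
        raise ValueError("tone frequencies must be positive")
    if not (freq_lo < freq_hi and level_lo < level_hi):
        raise ValueError("require freq_lo < freq_hi and level_lo < level_hi")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    freqs = np.geomspace(freq_lo, freq_hi, n_frequencies)
    levels = np.linspace(level_lo, level_hi, n_levels)
    fi, li, ri = np.meshgrid(
        np.arange(n_frequencies), np.arange(n_levels), np.arange(repetitions),
        indexing="ij",
    )
    order = np.column_stack([fi.ravel(), li.ravel(), ri.ravel()])
    rng = rng_from(seed)
    order = order[rng.permutation(len(order))]
    return ToneProtocol(
        frequencies=freqs,
        levels=levels,
        tone_duration=tone_duration,
        ramp_duration=ramp_duration,
        inter_stimulus_interval=inter_stimulus_interval,
        repetitions=repetitions,
        presentation_order=order,
    )


def tone_envelope(protocol: ToneProtocol, t: np.ndarray) -> np.ndarray:
    """Amplitude envelope of one tone presentation on local time ``t``.

    cos^2 on/off ramps of ``ramp_duration``; 1 in the plateau; 0 outside
    [0, tone_duration).
    """
    env = np.zeros_like(t, dtype=float)
    dur, ramp = protocol.tone_duration, protocol.ramp_duration
    inside = (t >= 0) & (t < dur)
    env[inside] = 1.0
    rise = inside & (t < ramp)
    env[rise] = np.sin(0.5 * np.pi * t[rise] / ramp) ** 2
    fall = inside & (t >= dur - ramp)
    env[fall] = np.sin(0.5 * np.pi * (dur - t[fall]) / ramp) ** 2
    return env


# ---------------------------------------------------------------------------
# SAM / SFM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModulatedStimulus:
    """A sinusoidally amplitude- (AM) or frequency- (FM) modulated tone.

    For AM, ``envelope`` holds the amplitude envelope 1 + depth*sin(...);
    for FM it holds the instantaneous-frequency trace in Hz.  ``waveform`` is
    optional sampled audio normalized to unit peak.
    """

    kind: str                       # "AM" | "FM"
    carrier_frequency: float        # Hz
    modulation_frequency: float     # Hz
    duration: float                 # s
    start_phase: float              # degrees
    modulation_depth: float = 1.0   # AM only, fraction in [0, 1]
    fm_range: tuple = (-1.0, 2.0)   # FM only, octaves re carrier
    sample_rate: float = DEFAULT_SAMPLE_RATE
    envelope: np.ndarray = field(default=None, repr=False)
    waveform: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.envelope)) / self.sample_rate


def synthesize_modulated(
    kind: str,
    carrier: float,
    mod_freq: float,
    duration: float,
    depth_or_range=1.0,
    start_phase: float = -90.0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    render_waveform: bool = False,
) -> ModulatedStimulus:
    """Synthesize a SAM or SFM tone.

    AM: envelope e(t) = 1 + depth*sin(2 pi f_m t + phi0); with depth = 1 and
    phi0 = -90 deg the envelope starts at its zero minimum.  FM: the
    instantaneous frequency traverses ``depth_or_range`` octaves re the
    carrier sinusoidally (default one octave below to two above).
    """
    kind = kind.upper()
    if kind not in ("AM", "FM"):
        raise ValueError(f"kind must be 'AM' or 'FM', got {kind!r}")
    if not mod_freq < carrier:
        raise ValueError("modulation frequency must be below the carrier")
    check_positive("duration", duration)
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    phi0 = np.deg2rad(start_phase)
    if kind == "AM":
        depth = float(depth_or_range)
        if not 0.0 <= depth <= 1.0:
            raise ValueError("AM modulation depth must lie in [0, 1]")
        env = 1.0 + depth * np.sin(2 * np.pi * mod_freq * t + phi0)
        wave = None
        if render_waveform:
            wave = env * np.sin(2 * np.pi * carrier * t)
            wave = wave / np.max(np.abs(wave))
        return ModulatedStimulus(
            kind="AM", carrier_frequency=carrier, modulation_frequency=mod_freq,
            duration=duration, start_phase=start_phase, modulation_depth=depth,
            sample_rate=sample_rate, envelope=env, waveform=wave,
        )
    lo, hi = (float(depth_or_range[0]), float(depth_or_range[1])) \
        if np.iterable(depth_or_range) else (-1.0, 2.0)
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    octaves = mid + half * np.sin(2 * np.pi * mod_freq * t + phi0)
    inst_freq = carrier * 2.0 ** octaves
    wave = None
    if render_waveform:
        phase = 2 * np.pi * np.cumsum(inst_freq) / sample_rate
        wave = np.sin(phase)
        wave = wave / np.max(np.abs(wave))
    return ModulatedStimulus(
        kind="FM", carrier_frequency=carrier, modulation_frequency=mod_freq,
        duration=duration, start_phase=start_phase, fm_range=(lo, hi),
        sample_rate=sample_rate, envelope=inst_freq, waveform=wave,
    )


# ---------------------------------------------------------------------------
# Randomized gamma-tone sequence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaToneSpec:
    """One gamma-tone: onset (s), center frequency (Hz), bandwidth (Hz),
    level (dB SPL), envelope order (dimensionless count)."""

    onset: float
    center_frequency: float
    bandwidth: float
    level: float
    envelope_order: int = 4

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError("gamma-tone onset must be >= 0")
        if self.bandwidth <= 0:
            raise ValueError("gamma-tone bandwidth must be > 0")

    @property
    def envelope_peak_lag(self) -> float:
        """Time from onset to the gamma-envelope maximum, (n-1)/(2 pi b)."""
        return (self.envelope_order - 1) / (2 * np.pi * self.bandwidth)


@dataclass(frozen=True)
class RGSStimulus:
    """Randomized gamma-tone sequence: equal-level gamma-tones placed
    uniformly on the log2-frequency axis over [-1, +2] octaves re the cell's
    CF, with exponentially distributed inter-onset intervals."""

    tones: tuple                    # of GammaToneSpec
    duration: float                 # s
    cf_reference: float             # Hz
    iei_time_constant: float        # s
    seed: int

    @property
    def onsets(self) -> np.ndarray:
        return np.asarray([tn.onset for tn in self.tones])

    @property
    def center_frequencies(self) -> np.ndarray:
        return np.asarray([tn.center_frequency for tn in self.tones])

    @property
    def levels(self) -> np.ndarray:
        return np.asarray([tn.level for tn in self.tones])

    def to_json(self) -> str:
        return json.dumps({
            "duration": self.duration,
            "cf_reference": self.cf_reference,
            "iei_time_constant": self.iei_time_constant,
            "seed": self.seed,
            "tones": [asdict(tn) for tn in self.tones],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RGSStimulus":
        d = json.loads(text)
        tones = tuple(GammaToneSpec(**tn) for tn in d["tones"])
        return cls(tones=tones, duration=d["duration"],
                   cf_reference=d["cf_reference"],
                   iei_time_constant=d["iei_time_constant"], seed=d["seed"])


def generate_rgs(
    cf: float,
    duration: float = 30.0,
    iei_tau: float = 0.010,
    seed: int = 0,
    level: float = 60.0,
    octave_range: tuple = (-1.0, 2.0),
    envelope_order: int = 4,
    bandwidth_model: Callable = erb_bandwidth,
) -> RGSStimulus:
    """Generate a randomized gamma-tone sequence.

    Tone center frequencies are i.i.d. uniform on the log2 axis over
    ``octave_range`` re ``cf``; inter-onset intervals are i.i.d.
    exponential with mean ``iei_tau`` (5 or 10 ms typical); all tones share
    one level; bandwidths come from ``bandwidth_model`` evaluated at each
    center frequency.  Fully reproducible from ``seed``.
    """
    check_positive("cf", cf)
    check_positive("duration", duration)
    check_positive("iei_tau", iei_tau)
    if duration < iei_tau:
        warnings.warn(
            "stimulus duration is shorter than one expected inter-onset "
            "interval; the tone list may be empty", stacklevel=2)
    rng = rng_from(seed)
    # draw enough intervals to exceed the duration with near certainty
    n_guess = max(16, int(duration / iei_tau * 1.5) + 50)
    onsets = np.cumsum(rng.exponential(iei_tau, size=n_guess))
    while onsets[-1] < duration:
        onsets = np.concatenate(
            [onsets, onsets[-1] + np.cumsum(rng.exponential(iei_tau, size=n_guess))])
    # consume exactly len(onsets) uniforms so the draw count is deterministic
    octs = rng.uniform(octave_range[0], octave_range[1], size=len(onsets))
    keep = onsets < duration
    onsets, octs = onsets[keep], octs[keep]
    freqs = cf * 2.0 ** octs
    tones = tuple(
        GammaToneSpec(onset=float(o), center_frequency=float(f),
                      bandwidth=float(bandwidth_model(f)), level=float(level),
                      envelope_order=envelope_order)
        for o, f in zip(onsets, freqs)
    )
    return RGSStimulus(tones=tones, duration=float(duration), cf_reference=float(cf),
                       iei_time_constant=float(iei_tau), seed=int(seed))


# ---------------------------------------------------------------------------
# Spectrogram rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrogram:
    """Time-frequency stimulus-energy matrix on a log2-spaced frequency axis.

    ``values`` holds linear power per (frequency, time) bin; each gamma-tone
    contributes a patch of total energy proportional to its linear power
    10^(level/10), so summed energy scales with tone count.
    """

    frequencies: np.ndarray          # Hz, log-spaced bin centers
    times: np.ndarray                # s, bin centers
    values: np.ndarray               # (n_freq, n_time), linear power
    freq_bin_octaves: float
    time_bin: float                  # s
    scale: str = "linear"

    def to_db(self, floor_db: float = -100.0) -> np.ndarray:
        with np.errstate(divide="ignore"):
            out = 10.0 * np.log10(self.values)
        return np.maximum(out, floor_db)


def render_spectrogram(
    stimulus: RGSStimulus,
    bins_per_octave: int = 12,
    time_bin: float = 0.0005,
    octave_range: tuple = (-1.0, 2.0),
) -> Spectrogram:
    """Render an RGS tone list into a stimulus spectrogram.

    Each gamma-tone contributes a separable patch: the squared gamma envelope
    t^(n-1) e^(-2 pi b t) in time (peak at onset + (n-1)/(2 pi b)) and a
    Gaussian profile on the log2-frequency axis whose FWHM corresponds to the
    tone bandwidth.  Patches are normalized to unit total mass, scaled by the
    tone's linear power, and added; an empty tone list yields an all-zero
    (valid) spectrogram.
    """
    check_positive("bins_per_octave", bins_per_octave)
    check_positive("time_bin", time_bin)
    lo, hi = octave_range
    n_freq = int(round((hi - lo) * bins_per_octave)) + 1
    oct_axis = np.linspace(lo, hi, n_freq)
    freqs = stimulus.cf_reference * 2.0 ** oct_axis
    n_time = int(np.ceil(stimulus.duration / time_bin))
    times = (np.arange(n_time) + 0.5) * time_bin
    values = np.zeros((n_freq, n_time))
    d_oct = (hi - lo) / (n_freq - 1)

    for tone in stimulus.tones:
        n = tone.envelope_order
        b = tone.bandwidth
        # squared gamma envelope, sampled until it has decayed to ~1e-4 peak
        t_peak = tone.envelope_peak_lag
        t_end = t_peak + 6.0 * n / (2 * np.pi * b)
        i0 = int(np.floor(tone.onset / time_bin))
        i1 = min(n_time, int(np.ceil((tone.onset + t_end) / time_bin)) + 1)
        if i1 <= i0:
            continue
        tt = times[i0:i1] - tone.onset
        tt = np.maximum(tt, 0.0)
        env = (tt ** (n - 1)) * np.exp(-2 * np.pi * b * tt)
        env2 = env ** 2
        s = env2.sum()
        if s <= 0:
            continue
        env2 /= s
        # Gaussian spectral profile: FWHM in octaves from the Hz bandwidth
        bw_oct = b / (tone.center_frequency * np.log(2))
        sigma_oct = max(bw_oct / (2 * np.sqrt(2 * np.log(2))), d_oct / 2)
        c_oct = np.log2(tone.center_frequency / stimulus.cf_reference)
        prof = np.exp(-0.5 * ((oct_axis - c_oct) / sigma_oct) ** 2)
        ps = prof.sum()
        if ps <= 0:
            continue
        prof /= ps
        values[:, i0:i1] += db_to_power(tone.level) * np.outer(prof, env2)

    return Spectrogram(frequencies=freqs, times=times, values=values,
                       freq_bin_octaves=d_oct, time_bin=time_bin)
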