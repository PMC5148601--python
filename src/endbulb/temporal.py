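"""Temporal-coding metrics: vector strength, Corr_Norm, shuffled
autocorrelograms, reproducibility, modulation depth, dispersion, sparsity.

All metrics operate on spike (event) times grouped by trial, or on binned
PSTHs.  Conventions follow standard auditory practice: vector strength over
complete modulation periods with the first 20 ms of every repetition
excluded; the shuffled autocorrelogram (SAC) counts all-order cross-trial
coincidences (same-trial pairs always excluded) normalized so independent
stationary Poisson trains sit at 1; sparsity indices are computed on PSTHs
sampled at 100 Hz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PSTH:
    """Peri-stimulus time histogram: rate per bin (Hz) averaged over trials."""

    edges: np.ndarray        # s, len n_bins + 1
    rate: np.ndarray         # Hz
    n_trials: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def duration(self) -> float:
        return float(self.edges[-1] - self.edges[0])

    @property
    def total_spikes(self) -> float:
        return float(np.sum(self.rate) * self.bin_width * self.n_trials)


def build_psth(trains: Sequence[np.ndarray], duration: float,
               bin_width: float = 0.010, t0: float = 0.0) -> PSTH:
    """PSTH from per-trial spike-time arrays; rate in Hz."""
    edges = np.arange(t0, t0 + duration + bin_width / 2, bin_width)
    counts = np.zeros(len(edges) - 1)
    for tr in trains:
        counts += np.histogram(tr, bins=edges)[0]
    rate = counts / (len(trains) * bin_width)
    return PSTH(edges=edges, rate=rate, n_trials=len(trains))


def trains_from_events(events: pd.DataFrame, ap_only: bool = False) -> list:
    """Per-trial spike-time arrays from an event table (trial-sorted)."""
    ev = events if not ap_only else events[events["is_ap"].astype(bool)]
    return [g["time_s"].to_numpy() for _, g in ev.groupby("trial", sort=True)]


# ---------------------------------------------------------------------------
# Vector strength
# ---------------------------------------------------------------------------

def vector_strength(spike_times, mod_freq: float,
                    onset_exclusion: float = 0.020,
                    duration: Optional[float] = None):
    """Vector strength with Rayleigh significance.

    Spikes within ``onset_exclusion`` of trial onset are discarded and the
    analysis is constrained to complete modulation periods.  VS =
    |sum exp(i 2 pi f t)| / n; the p-value uses the Rayleigh approximation
    (statistic 2 n VS^2, p = exp(-n VS^2)).  ``spike_times`` may be one
    array or a sequence of per-trial arrays.  Returns ``(VS, p, n)``;
    fewer than 2 usable spikes -> (nan, nan, n).
    """
    if len(spike_times) and np.isscalar(spike_times[0]):
        trains = [np.asarray(spike_times, float)]
    else:
        trains = [np.asarray(tr, float) for tr in spike_times]
    phases = []
    period = 1.0 / mod_freq
    for tr in trains:
        if duration is not None:
            n_per = math.floor((duration - onset_exclusion) / period)
            t_hi = onset_exclusion + n_per * period
        else:
            t_hi = np.inf
        sel = tr[(tr >= onset_exclusion) & (tr < t_hi)]
        phases.append((sel - onset_exclusion) * mod_freq)
    ph = np.concatenate(phases) if phases else np.empty(0)
    n = len(ph)
    if n < 2:
        return math.nan, math.nan, n
    z = np.exp(2j * np.pi * ph)
    vs = float(abs(z.sum()) / n)
    p = float(math.exp(-n * vs * vs)) if n * vs * vs < 700 else 0.0
    return vs, p, n


# ---------------------------------------------------------------------------
# Corr_Norm
# ---------------------------------------------------------------------------

def corr_norm(psth: PSTH, envelope: np.ndarray, max_lag: float = 0.010) -> float:
    """Latency-adjusted non-centered correlation of PSTH and stimulus envelope.

    CN = max over lags in [0, max_lag] of <r e> / sqrt(<r^2><e^2>), with the
    envelope circularly shifted (the PSTH must cover an integer number of
    modulation periods, making the circular shift exact).  For nonnegative
    signals CN lies in [0, 1]; a temporally flat response against a
    100%-depth raised-sine envelope yields 1/sqrt(1.5) ~= 0.82, and values
    above 0.9 require the response to follow the envelope shape.
    """
    r = np.asarray(psth.rate, float)
    e = np.asarray(envelope, float)
    if len(e) != len(r):
        raise ValueError("envelope must be sampled on the PSTH bins")
    if np.min(e) < 0:
        raise ValueError("envelope must be nonnegative")
    denom = math.sqrt(float(np.mean(r ** 2)) * float(np.mean(e ** 2)))
    if denom == 0:
        return math.nan
    n_shift = int(round(max_lag / psth.bin_width))
    best = -np.inf
    for k in range(n_shift + 1):
        best = max(best, float(np.mean(r * np.roll(e, k))))
    return best / denom


def raised_sine_envelope(mod_freq: float, depth: float, n_bins: int,
                         bin_width: float, start_phase_deg: float = -90.0
                         ) -> np.ndarray:
    """Stimulus modulation envelope (1 + depth*sin)/2 sampled at bin centers."""
    t = (np.arange(n_bins) + 0.5) * bin_width
    return 0.5 * (1.0 + depth * np.sin(2 * np.pi * mod_freq * t
                                       + np.deg2rad(start_phase_deg)))


# ---------------------------------------------------------------------------
# Shuffled autocorrelogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Correlogram:
    """Normalized all-order cross-trial coincidence counts by lag.

    Value 1 is the chance level for independent stationary Poisson trains
    under the Joris-style normalization N(N-1) r^2 w D (N trials, mean
    per-trial rate r, coincidence window w, duration D).
    """

    lags: np.ndarray       # s, symmetric about 0
    values: np.ndarray
    n_trials: int
    mean_rate: float       # Hz
    coincidence_window: float
    duration: float

    @property
    def center_value(self) -> float:
        return float(self.values[len(self.values) // 2])


def _pair_differences(pooled: np.ndarray, trial_id: np.ndarray,
                      max_lag: float) -> np.ndarray:
    """All nonnegative cross-trial spike-time differences <= max_lag, sorted."""
    order = np.argsort(pooled, kind="stable")
    t = pooled[order]
    tid = trial_id[order]
    hi = np.searchsorted(t, t + max_lag, side="right")
    counts = hi - np.arange(len(t)) - 1
    total = int(counts.sum())
    diffs = np.empty(total)
    same = np.empty(total, dtype=bool)
    pos = 0
    for i in range(len(t)):
        c = counts[i]
        if c <= 0:
            continue
        seg = slice(pos, pos + c)
        diffs[seg] = t[i + 1: i + 1 + c] - t[i]
        same[seg] = tid[i + 1: i + 1 + c] == tid[i]
        pos += c
    return np.sort(diffs[~same])


def shuffled_autocorrelogram(
    trains: Sequence[np.ndarray],
    duration: float,
    coincidence_window: float = 0.0002,
    max_lag: float = 0.015,
    lag_step: float = 0.00005,
) -> Correlogram:
    """All-order cross-trial correlogram (SAC), same-trial pairs excluded.

    Coincidences are counted in a sliding window of ``coincidence_window``
    centered on each lag of a grid with step ``lag_step``, and normalized by
    N(N-1) r^2 w D so that independent homogeneous Poisson trains give 1 at
    every lag.  Identical trains across trials produce a delta-like central
    peak of height ~ 1/(r w).
    """
    trains = [np.asarray(tr, float) for tr in trains]
    n_trials = len(trains)
    if n_trials < 2:
        raise ValueError("the shuffled autocorrelogram needs >= 2 trials")
    m_total = sum(len(tr) for tr in trains)
    if m_total < 2:
        raise ValueError("need at least 2 spikes in total")
    r = m_total / n_trials / duration
    if r == 0:
        raise ValueError("zero firing rate")
    pooled = np.concatenate(trains)
    tid = np.concatenate([np.full(len(tr), i) for i, tr in enumerate(trains)])
    half_w = coincidence_window / 2
    diffs = _pair_differences(pooled, tid, max_lag + half_w)
    n_zero = int(np.searchsorted(diffs, 0.0, side="right"))
    n_lags = int(round(max_lag / lag_step))
    taus = np.arange(n_lags + 1) * lag_step
    lo, hi = taus - half_w, taus + half_w
    # ordered-pair coincidence count per lag window [lo, hi), built from the
    # nonnegative unordered differences: the negative part of a window that
    # straddles 0 maps to mirrored positive differences, and exact-zero
    # pairs count once per ordering
    counts = (np.searchsorted(diffs, hi, side="left").astype(float)
              - np.searchsorted(diffs, np.maximum(lo, 0.0), side="left"))
    straddle = lo < 0
    counts[straddle] += (np.searchsorted(diffs, -lo[straddle], side="right")
                         - n_zero)
    counts[straddle] += n_zero
    values = np.concatenate([counts[:0:-1], counts])
    lags = np.arange(-n_lags, n_lags + 1) * lag_step
    norm = n_trials * (n_trials - 1) * r * r * coincidence_window * duration
    return Correlogram(lags=lags, values=values / norm, n_trials=n_trials,
                       mean_rate=r, coincidence_window=coincidence_window,
                       duration=duration)


def reproducibility(corr: Correlogram) -> float:
    """Height of the SAC central peak (value at lag 0); chance = 1."""
    return corr.center_value


def modulation_depth(corr: Correlogram, mod_period: float,
                     centered: bool = True) -> float:
    """SD of the correlogram over one modulation period at the center.

    ``centered=True`` (default) takes the cycle centered on lag 0;
    otherwise the cycle starting at lag 0.
    """
    lags = corr.lags
    if centered:
        sel = np.abs(lags) <= mod_period / 2
    else:
        sel = (lags >= 0) & (lags <= mod_period)
    vals = corr.values[sel]
    if len(vals) < 2:
        return math.nan
    return float(np.std(vals))


def temporal_dispersion(corr: Correlogram) -> float:
    """Full width (s) of the central peak at half its height above asymptote.

    The asymptote is the mean value over the outer third of lags.  A flat
    correlogram (peak not above the asymptote) returns NaN; a peak displaced
    from 0 by more than one coincidence window triggers a warning.
    """
    lags, vals = corr.lags, corr.values
    outer = np.abs(lags) >= (2.0 / 3.0) * np.abs(lags).max()
    asym = float(vals[outer].mean())
    i_pk = int(np.argmax(vals))
    peak = float(vals[i_pk])
    if abs(lags[i_pk]) > corr.coincidence_window:
        warnings.warn(f"correlogram peak at {lags[i_pk] * 1e3:.2f} ms, "
                      "not at zero lag", stacklevel=2)
    if peak <= asym or not np.isfinite(peak):
        return math.nan
    half = asym + 0.5 * (peak - asym)
    # walk outwards from the peak to the half crossings, interpolating
    left = right = None
    for j in range(i_pk, -1, -1):
        if vals[j] < half:
            f = (half - vals[j]) / (vals[j + 1] - vals[j])
            left = lags[j] + f * (lags[j + 1] - lags[j])
            break
    for j in range(i_pk, len(vals)):
        if vals[j] < half:
            f = (half - vals[j - 1]) / (vals[j] - vals[j - 1])
            right = lags[j - 1] + f * (lags[j] - lags[j - 1])
            break
    if left is None or right is None:
        return math.nan
    return float(right - left)


# ---------------------------------------------------------------------------
# Sparsity
# ---------------------------------------------------------------------------

def sparsity(psth: PSTH, method: str = "variance",
             csi_threshold: float = 15.0) -> float:
    """Temporal sparsity of a firing-rate time series.

    - ``variance``: S = 1 - <r>^2 / <r^2>, in [0, 1]; 0 for any constant
      nonzero rate, 1 - 1/N for a single active bin out of N.
    - ``kurtosis``: raw fourth standardized moment of the rate distribution
      (3 for Gaussian rates); historical measure.
    - ``csi``: Close-to-Silence Index, the fraction of PSTH bins with rate
      below ``csi_threshold`` (Hz, default 15).

    An all-zero PSTH has undefined variance sparsity and kurtosis (NaN) and
    CSI = 1.
    """
    r = np.asarray(psth.rate if isinstance(psth, PSTH) else psth, float)
    if len(r) == 0:
        raise ValueError("empty PSTH")
    if method == "variance":
        m2 = float(np.mean(r ** 2))
        if m2 == 0:
            return math.nan
        return 1.0 - float(np.mean(r)) ** 2 / m2
    if method == "kurtosis":
        sd = float(np.std(r))
        if sd == 0:
            return math.nan
        return float(np.mean(((r - r.mean()) / sd) ** 4))
    if method == "csi":
        return float(np.mean(r < csi_threshold))
    raise ValueError(f"unknown sparsity method {method!r}")


def sparsity_debiased(psth: PSTH) -> float:
    """Variance sparsity with the Poisson shot-noise bias removed.

    A PSTH estimated from finitely many trials inflates <r^2> by the
    counting term <r>/(n_trials * bin); subtracting it makes the index
    invariant under binomial thinning of the spike trains in expectation,
    which is what a pure PSTH scaling should be.
    """
    r = psth.rate
    m2 = float(np.mean(r ** 2))
    m1 = float(np.mean(r))
    shot = m1 / (psth.n_trials * psth.bin_width)
    m2_corr = m2 - shot
    if m2_corr <= 0:
        return math.nan
    return 1.0 - m1 ** 2 / m2_corr
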