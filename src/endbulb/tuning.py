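"""Frequency-response areas and tuning metrics.

An FRA is a frequency x level matrix of any per-event response metric
(input rate, output rate, failure fraction, or threshold EPSP).  From an
excitatory (rate) FRA the characteristic frequency, threshold, Q10/Q40
sharpness, border frequencies, and asymmetry index are derived; from a
threshold-EPSP FRA the same machinery maps the inhibitory response area.
A rate-level function at one frequency yields the rate-level gain
RLG = log10((FRmax - FRmin) / FRspont).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .stimuli import ToneProtocol
from .events import fit_threshold_epsp

RATE_METRICS = ("input_rate", "output_rate")
METRICS = RATE_METRICS + ("failure_fraction", "threshold_epsp")


@dataclass
class FRA:
    """Frequency x level map of one response metric.

    ``values`` has shape (n_frequencies, n_levels); NaN marks cells where
    the metric is undefined (e.g. an unfittable threshold EPSP).  The
    spontaneous baseline (mean, SD across presentations) of the same metric
    is taken from the tail of the inter-stimulus intervals.
    """

    frequencies: np.ndarray
    levels: np.ndarray
    metric: str
    values: np.ndarray
    n_presentations: np.ndarray
    baseline_mean: float
    baseline_sd: float
    values_se: Optional[np.ndarray] = None   # per-cell standard errors (fits)

    def __post_init__(self):
        if self.values.shape != (len(self.frequencies), len(self.levels)):
            raise ValueError("FRA matrix shape must be |freqs| x |levels|")


@dataclass
class TuningSummary:
    """CF, threshold, and sharpness summary of one FRA."""

    cf: float                 # Hz
    threshold: float          # dB SPL
    q10: float = math.nan
    q40: float = math.nan
    f_lower: float = math.nan  # Hz, lower border 40 dB above threshold
    f_upper: float = math.nan
    asymmetry_index: float = math.nan


@dataclass
class RateLevelFunction:
    """Firing rate vs level at one frequency, with the rate-level gain."""

    levels: np.ndarray
    rates: np.ndarray
    fr_max: float
    fr_min: float
    fr_spont: float
    rlg: float               # log10((FRmax - FRmin)/FRspont); NaN if undefined


def _response_window(protocol: ToneProtocol, offset_tail: float = 0.010):
    """Tone-response window: tone duration plus a 10 ms offset tail."""
    return 0.0, protocol.tone_duration + offset_tail


def _baseline_window(protocol: ToneProtocol, length: float = 0.100):
    """Spontaneous window: the final ``length`` of each inter-stimulus gap."""
    period = protocol.presentation_period
    return period - length, period


def build_fra(events: pd.DataFrame, protocol: ToneProtocol,
              metric: str = "input_rate",
              bin_width_Vps: float = 0.5) -> FRA:
    """Assemble an FRA of the requested metric from tagged events.

    Events must carry (freq_hz, level_db, rep) tags and per-presentation
    times on [0, presentation period).  Rate metrics are computed over the
    tone window (tone duration + 10 ms tail); ``threshold_epsp`` is fitted
    per cell from events of both classes and left NaN where unfittable.
    The spontaneous baseline of the same metric comes from the final 100 ms
    of the inter-stimulus interval, pooled across all presentations.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    freqs, levels = protocol.frequencies, protocol.levels
    t0, t1 = _response_window(protocol)
    b0, b1 = _baseline_window(protocol)
    n_f, n_l = len(freqs), len(levels)

    covered = {(float(f), float(l)) for f, l in
               zip(events["freq_hz"], events["level_db"])}
    expected = {(float(freqs[fi]), float(levels[li]))
                for fi, li, _ in protocol.presentation_order}
    # cells can legitimately produce no events only if rates are ~0; the
    # contract check is on tag consistency, not on emptiness
    stray = covered - expected - {(f, l) for f, l in covered
                                  if not (np.isfinite(f) and np.isfinite(l))}
    if stray:
        raise ValueError(f"events tagged with cells absent from the protocol: "
                         f"{sorted(stray)[:5]} ...")

    tt = events["time_s"].to_numpy()
    in_resp = (tt >= t0) & (tt < t1)
    in_base = (tt >= b0) & (tt < b1)
    values = np.full((n_f, n_l), np.nan)
    values_se = np.full((n_f, n_l), np.nan)
    n_pres = np.zeros((n_f, n_l), dtype=int)

    def cell_metric(sub: pd.DataFrame, window: float, reps: int) -> tuple:
        if metric == "input_rate":
            return len(sub) / (window * reps), math.nan
        if metric == "output_rate":
            return int(sub["is_ap"].astype(bool).sum()) / (window * reps), math.nan
        if metric == "failure_fraction":
            if len(sub) == 0:
                return math.nan, math.nan
            return float((~sub["is_ap"].astype(bool)).mean()), math.nan
        # threshold_epsp
        y = sub["is_ap"].to_numpy().astype(bool)
        if len(sub) < 10 or y.all() or (~y).all():
            return math.nan, math.nan
        try:
            fit = fit_threshold_epsp(sub, bin_width=bin_width_Vps)
            return fit.d, fit.d_se
        except ValueError:
            return math.nan, math.nan

    ev_resp = events[in_resp]
    grouped = dict(tuple(ev_resp.groupby(["freq_hz", "level_db"])))
    for fi in range(n_f):
        for li in range(n_l):
            reps = int(np.sum((protocol.presentation_order[:, 0] == fi)
                              & (protocol.presentation_order[:, 1] == li)))
            n_pres[fi, li] = reps
            if reps == 0:
                continue
            sub = grouped.get((float(freqs[fi]), float(levels[li])))
            if sub is None:
                sub = ev_resp.iloc[0:0]
            values[fi, li], values_se[fi, li] = cell_metric(sub, t1 - t0, reps)

    # baseline: per-presentation metric over the spontaneous window
    ev_base = events[in_base]
    total_pres = protocol.n_presentations
    per_pres = ev_base.groupby("trial").size().reindex(
        range(total_pres), fill_value=0).to_numpy()
    if metric in RATE_METRICS:
        if metric == "output_rate":
            per_pres = ev_base[ev_base["is_ap"].astype(bool)].groupby(
                "trial").size().reindex(range(total_pres), fill_value=0).to_numpy()
        base_vals = per_pres / (b1 - b0)
        baseline_mean, baseline_sd = float(base_vals.mean()), float(base_vals.std())
    elif metric == "failure_fraction":
        baseline_mean = float((~ev_base["is_ap"].astype(bool)).mean()) \
            if len(ev_base) else math.nan
        # SD across presentations of the per-presentation failure fraction
        by = ev_base.groupby("trial")["is_ap"].apply(
            lambda s: float((~s.astype(bool)).mean()))
        baseline_sd = float(by.std(ddof=0)) if len(by) > 1 else math.nan
    else:  # threshold_epsp: pooled spontaneous fit; SD via fit SE
        try:
            fit = fit_threshold_epsp(ev_base, bin_width=bin_width_Vps)
            baseline_mean, baseline_sd = fit.d, fit.d_se
        except ValueError:
            baseline_mean, baseline_sd = math.nan, math.nan

    return FRA(frequencies=freqs, levels=levels, metric=metric, values=values,
               n_presentations=n_pres, baseline_mean=baseline_mean,
               baseline_sd=baseline_sd,
               values_se=values_se if metric == "threshold_epsp" else None)


def significant_cells(fra: FRA, k: float = 2.0,
                      min_elevation: float = 1.0) -> np.ndarray:
    """Boolean mask of cells where the metric is significantly elevated.

    Rate-like metrics: value > baseline mean + k * baseline SD.  Fitted
    metrics carrying per-cell standard errors (threshold EPSP): the
    elevation is scored against the combined cell + baseline fit
    uncertainty, (value - baseline) / sqrt(se_cell^2 + se_base^2) > k, and
    must additionally exceed ``min_elevation`` (V/s, two fit bins by
    default) — fit standard errors on sparse cells are optimistic, and the
    absolute floor guards the 200-cell scan against them.
    """
    if not np.isfinite(fra.baseline_mean):
        raise ValueError("no spontaneous baseline available")
    if fra.values_se is not None:
        base_se = fra.baseline_sd if np.isfinite(fra.baseline_sd) else 0.0
        with np.errstate(invalid="ignore"):
            z = ((fra.values - fra.baseline_mean)
                 / np.sqrt(fra.values_se ** 2 + base_se ** 2))
            return (z > k) & (fra.values > fra.baseline_mean + min_elevation)
    crit = fra.baseline_mean + k * (fra.baseline_sd
                                    if np.isfinite(fra.baseline_sd) else 0.0)
    with np.errstate(invalid="ignore"):
        return fra.values > crit


def estimate_cf_threshold(fra: FRA, k: float = 2.0) -> TuningSummary:
    """CF and threshold from the lowest level with a significant cell.

    A cell is significant when its metric exceeds the spontaneous baseline
    mean + k SD (default k = 2).  The CF is the frequency of the significant
    cell at the lowest such level; ties break toward the larger metric, then
    the lower frequency.  No significant cell -> ValueError.
    """
    sig = significant_cells(fra, k)
    for li in range(len(fra.levels)):
        col = np.flatnonzero(sig[:, li])
        if len(col) == 0:
            continue
        vals = fra.values[col, li]
        best = col[np.lexsort((fra.frequencies[col], -vals))][0]
        return TuningSummary(cf=float(fra.frequencies[best]),
                             threshold=float(fra.levels[li]))
    raise ValueError("no FRA cell is significantly above the baseline; "
                     "CF undefined")


def _border_frequencies(fra: FRA, sig: np.ndarray, li: int, crit: float):
    """Outermost significance borders at one level, interpolated on log2(f).

    The border sits where the metric crosses the significance criterion
    between the outermost significant cell and its non-significant
    neighbor; edge cells extend to the FRA edge.
    """
    col = np.flatnonzero(sig[:, li])
    if len(col) == 0:
        return math.nan, math.nan
    lo_i, hi_i = int(col[0]), int(col[-1])
    logf = np.log2(fra.frequencies)

    def interp(inner: int, outer: int) -> float:
        v_in, v_out = fra.values[inner, li], fra.values[outer, li]
        if not (np.isfinite(v_in) and np.isfinite(v_out)) or v_in == v_out:
            return float(fra.frequencies[inner])
        f = (v_in - crit) / (v_in - v_out)
        f = min(max(f, 0.0), 1.0)
        return float(2.0 ** (logf[inner] + f * (logf[outer] - logf[inner])))

    f_l = float(fra.frequencies[0]) if lo_i == 0 else interp(lo_i, lo_i - 1)
    f_u = float(fra.frequencies[-1]) if hi_i == len(logf) - 1 \
        else interp(hi_i, hi_i + 1)
    return f_l, f_u


def q_values(fra: FRA, summary: TuningSummary, k: float = 2.0) -> TuningSummary:
    """Q10/Q40 sharpness and 40-dB border frequencies.

    Bandwidths are taken between the outermost significant cells at
    threshold + 10 dB (and + 40 dB), linearly interpolated on the log2
    frequency axis; Q = CF / bandwidth.  Missing level coverage leaves Q40
    (and the borders) NaN.
    """
    sig = significant_cells(fra, k)
    crit = fra.baseline_mean + k * (fra.baseline_sd
                                    if np.isfinite(fra.baseline_sd) else 0.0)
    out = TuningSummary(cf=summary.cf, threshold=summary.threshold)
    for d_db, attr in ((10.0, "q10"), (40.0, "q40")):
        target = summary.threshold + d_db
        li = int(np.argmin(np.abs(fra.levels - target)))
        if abs(fra.levels[li] - target) > (fra.levels[1] - fra.levels[0]) / 2 \
                + 1e-9 or fra.levels[li] < target - 1e-9:
            continue
        f_l, f_u = _border_frequencies(fra, sig, li, crit)
        if not (np.isfinite(f_l) and np.isfinite(f_u)) or f_u <= f_l:
            continue
        setattr(out, attr, summary.cf / (f_u - f_l))
        if d_db == 40.0:
            out.f_lower, out.f_upper = f_l, f_u
    if np.isfinite(out.f_lower) and np.isfinite(out.f_upper):
        try:
            out.asymmetry_index = asymmetry_index(out)
        except ValueError:
            pass
    return out


def asymmetry_index(summary: TuningSummary) -> float:
    """AI = ln[ log2(F_U/CF) / log2(CF/F_L) ].

    0 for log-symmetric borders; negative values mark FRAs extending to
    lower frequencies (low-frequency tails), positive to higher ones.
    Requires F_L < CF < F_U; a border equal to CF is undefined.
    """
    f_l, f_u, cf = summary.f_lower, summary.f_upper, summary.cf
    if not (f_l < cf < f_u):
        raise ValueError("asymmetry index requires F_L < CF < F_U")
    up = math.log2(f_u / cf)
    down = math.log2(cf / f_l)
    if up <= 0 or down <= 0:
        raise ValueError("border frequency coincides with CF; AI undefined")
    return math.log(up / down)


def rate_level(events: pd.DataFrame, protocol: ToneProtocol,
               at_frequency: float, output: bool = False,
               spont_floor: Optional[float] = None) -> RateLevelFunction:
    """Rate-level function at one protocol frequency, with RLG.

    RLG = log10((FRmax - FRmin)/FRspont); the spontaneous rate comes from
    the inter-stimulus baseline windows.  FRspont = 0 leaves RLG NaN unless
    a ``spont_floor`` (Hz) is supplied.
    """
    fi = int(np.argmin(np.abs(protocol.frequencies - at_frequency)))
    freq = protocol.frequencies[fi]
    t0, t1 = _response_window(protocol)
    b0, b1 = _baseline_window(protocol)
    sel = events["freq_hz"] == float(freq)
    if output:
        events = events[events["is_ap"].astype(bool)]
        sel = events["freq_hz"] == float(freq)
    rates = np.full(len(protocol.levels), np.nan)
    for li, level in enumerate(protocol.levels):
        reps = int(np.sum((protocol.presentation_order[:, 0] == fi)
                          & (protocol.presentation_order[:, 1] == li)))
        if reps == 0:
            continue
        sub = events[sel & (events["level_db"] == float(level))]
        tt = sub["time_s"].to_numpy()
        rates[li] = np.sum((tt >= t0) & (tt < t1)) / ((t1 - t0) * reps)
    tt = events["time_s"].to_numpy()
    n_base = int(np.sum((tt >= b0) & (tt < b1)))
    fr_spont = n_base / ((b1 - b0) * len(protocol.presentation_order))
    fr_max, fr_min = float(np.nanmax(rates)), float(np.nanmin(rates))
    denom = fr_spont if fr_spont > 0 else (spont_floor or 0.0)
    if denom > 0 and fr_max > fr_min:
        rlg = math.log10((fr_max - fr_min) / denom)
    else:
        rlg = math.nan
    return RateLevelFunction(levels=protocol.levels, rates=rates,
                             fr_max=fr_max, fr_min=fr_min,
                             fr_spont=fr_spont, rlg=rlg)
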