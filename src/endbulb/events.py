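"""Event detection, classification, and threshold-EPSP estimation.

Events are detected on continuous voltage traces with a slope threshold on
the rising flank of the EPSP and time-stamped at the maximum rising slope.
Classification into successful (AP-triggering) and failed EPSPs uses the
maximum falling slope after the detection point: APs fall much faster than
bare EPSPs, making the two falling-slope distributions well separated.

The threshold EPSP — the rising slope at which AP probability crosses 50% —
is the inflection point d of a Boltzmann function
``phi(x) = 1 / (1 + exp((d - x)/a))`` fitted to per-bin success fractions
(weighted by bin counts).  ``ThresholdEpspModel`` exposes this fit in a
model/results style; a logistic-regression fit on raw events is provided as
a cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import norm

SUCC, FAIL = "EPSP_succ", "EPSP_fail"


def boltzmann(x, d, a):
    """phi(x) = 1 / (1 + exp((d - x)/a)); monotone increasing for a > 0."""
    return 1.0 / (1.0 + np.exp(np.clip((d - x) / a, -60.0, 60.0)))


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_events(
    trace,
    rising_slope_threshold: float,
    sample_rate: Optional[float] = None,
    dead_time: float = 0.0005,
    smooth: float = 0.0002,
    fall_window: float = 0.002,
    max_event_rate: float = 1000.0,
) -> pd.DataFrame:
    """Detect EPSP events on a voltage trace via a rising-slope threshold.

    ``trace`` is ``(t, v)`` in (s, mV), or ``v`` with ``sample_rate`` given.
    One event is produced per suprathreshold rising flank (with dead time),
    time-stamped at the maximum rising slope; the subsequent maximum falling
    slope and the peak amplitude are extracted per event.  The threshold is
    in V/s; it must sit above the noise slope floor — if detections exceed
    ``max_event_rate`` a too-many-events warning is raised with the count.
    """
    if isinstance(trace, tuple):
        t, v = np.asarray(trace[0], float), np.asarray(trace[1], float)
        fs = 1.0 / (t[1] - t[0])
    else:
        if sample_rate is None:
            raise ValueError("sample_rate required when trace is a bare array")
        v = np.asarray(trace, float)
        fs = float(sample_rate)
        t = np.arange(len(v)) / fs
    if len(v) < 3:
        return _empty_event_frame()
    w = max(1, int(round(smooth * fs)))
    if w > 1:
        v_s = np.convolve(v, np.ones(w) / w, mode="same")
    else:
        v_s = v
    slope = np.gradient(v_s) * fs / 1000.0  # mV/sample * samples/s -> V/s
    above = slope > rising_slope_threshold
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.insert(starts, 0, 0)
    if above[-1]:
        ends = np.append(ends, len(v))
    rows = []
    last = -np.inf
    n_fall = int(round(fall_window * fs))
    for s0, s1 in zip(starts, ends):
        i_pk = s0 + int(np.argmax(slope[s0:s1]))
        if t[i_pk] - last < dead_time:
            continue
        last = t[i_pk]
        j1 = min(len(v), i_pk + n_fall)
        fall = -float(np.min(slope[i_pk:j1])) if j1 > i_pk else np.nan
        base = float(np.min(v_s[max(0, s0 - int(0.001 * fs)): s0 + 1]))
        amp = float(np.max(v_s[i_pk:j1])) - base if j1 > i_pk else np.nan
        rows.append(("trace", 0, float(t[i_pk]), float(slope[i_pk]), fall,
                     amp, False, np.nan, np.nan, 0))
    duration = t[-1] - t[0]
    if duration > 0 and len(rows) / duration > max_event_rate:
        warnings.warn(
            f"detected {len(rows)} events in {duration:.3f} s "
            "(threshold may be below the noise slope floor)", stacklevel=2)
    from .simulate import EVENT_COLUMNS
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _empty_event_frame() -> pd.DataFrame:
    from .simulate import EVENT_COLUMNS
    return pd.DataFrame(columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def auto_falling_slope_criterion(falling_slopes: np.ndarray) -> float:
    """Separation criterion from a two-Gaussian mixture of falling slopes.

    Fits a two-component Gaussian mixture (EM) and places the criterion at
    the mixture-density minimum between the component means; refuses
    (ValueError) when the fitted components are not separated (unimodal
    distribution).
    """
    x = np.asarray(falling_slopes, float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError("too few falling slopes for an automatic criterion")
    # light-weight EM for a 1-D two-Gaussian mixture
    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    sd = np.full(2, x.std() / 2 + 1e-9)
    pi = np.array([0.5, 0.5])
    for _ in range(200):
        r = np.stack([p * norm.pdf(x, m, s) for p, m, s in zip(pi, mu, sd)])
        r_sum = r.sum(axis=0)
        r_sum[r_sum == 0] = 1e-300
        r /= r_sum
        nk = r.sum(axis=1)
        mu_new = (r @ x) / nk
        sd_new = np.sqrt((r * (x - mu_new[:, None]) ** 2).sum(axis=1) / nk) + 1e-6
        pi_new = nk / len(x)
        if np.max(np.abs(mu_new - mu)) < 1e-8:
            mu, sd, pi = mu_new, sd_new, pi_new
            break
        mu, sd, pi = mu_new, sd_new, pi_new
    lo, hi = np.argsort(mu)
    separation = (mu[hi] - mu[lo]) / math.sqrt(sd[lo] * sd[hi] + 1e-12)
    if separation < 2.0 or min(pi) < 0.02:
        raise ValueError(
            "falling-slope distribution appears unimodal; "
            f"mixture separation {separation:.2f} is insufficient for 'auto'")
    # criterion at the mixture-density minimum between the component means
    # (robust to unequal component SDs, unlike the midpoint of the means)
    grid = np.linspace(mu[lo], mu[hi], 2001)
    dens = (pi[lo] * norm.pdf(grid, mu[lo], sd[lo])
            + pi[hi] * norm.pdf(grid, mu[hi], sd[hi]))
    return float(grid[int(np.argmin(dens))])


def classify_events(events: pd.DataFrame, criterion="auto") -> pd.DataFrame:
    """Label events as EPSP_succ / EPSP_fail by their maximum falling slope.

    ``criterion`` is a falling-slope threshold in V/s, or ``"auto"`` to place
    it at the density minimum of a two-component mixture fit.  Adds
    ``label`` and (re)sets ``is_ap`` consistently.
    """
    if "falling_slope_Vps" not in events or events["falling_slope_Vps"].isna().all():
        raise ValueError("falling slopes are required for classification")
    if isinstance(criterion, str):
        if criterion != "auto":
            raise ValueError(f"unknown criterion {criterion!r}")
        criterion = auto_falling_slope_criterion(
            events["falling_slope_Vps"].to_numpy())
    out = events.copy()
    is_ap = out["falling_slope_Vps"].to_numpy() > float(criterion)
    out["is_ap"] = is_ap
    out["label"] = np.where(is_ap, SUCC, FAIL)
    out.attrs["falling_slope_criterion_Vps"] = float(criterion)
    return out


def failure_fraction(events: pd.DataFrame, window: Optional[tuple] = None,
                     ci: float = 0.95):
    """EPSP_fail / (EPSP_succ + EPSP_fail), with a binomial (Wilson) CI.

    ``window`` restricts to events with time in [t0, t1).  Returns
    ``(fraction, (lo, hi), n)``; an empty selection yields NaN, not zero.
    """
    ev = events
    if window is not None:
        t = ev["time_s"].to_numpy()
        ev = ev[(t >= window[0]) & (t < window[1])]
    n = len(ev)
    if n == 0:
        return math.nan, (math.nan, math.nan), 0
    k = int((~ev["is_ap"].astype(bool)).sum())
    frac = k / n
    z = norm.ppf(0.5 + ci / 2)
    denom = 1 + z * z / n
    center = (frac + z * z / (2 * n)) / denom
    half = z * math.sqrt(frac * (1 - frac) / n + z * z / (4 * n * n)) / denom
    return frac, (max(0.0, center - half), min(1.0, center + half)), n


# ---------------------------------------------------------------------------
# Threshold-EPSP (Boltzmann) fit
# ---------------------------------------------------------------------------

@dataclass
class BoltzmannFit:
    """Result of a threshold-EPSP fit.

    ``d`` (V/s) is the threshold EPSP — the rising slope giving 50% AP
    probability; ``a`` (V/s) the slope parameter.  Standard errors come from
    the weighted-least-squares covariance.
    """

    d: float
    a: float
    d_se: float
    a_se: float
    bin_centers: np.ndarray
    bin_fractions: np.ndarray
    bin_counts: np.ndarray
    n_events: int
    method: str
    rss: float

    def predict(self, x):
        return boltzmann(np.asarray(x, float), self.d, self.a)

    def summary(self) -> str:
        lines = [
            "Threshold-EPSP Boltzmann fit",
            "=" * 38,
            f"method            {self.method}",
            f"events            {self.n_events}",
            f"occupied bins     {len(self.bin_centers)}",
            f"threshold d (V/s) {self.d: .3f}  (se {self.d_se:.3f})",
            f"slope a (V/s)     {self.a: .3f}  (se {self.a_se:.3f})",
            f"weighted RSS      {self.rss: .4f}",
        ]
        return "\n".join(lines)


class ThresholdEpspModel:
    """Boltzmann model of AP success probability vs EPSP rising slope.

    Parameters
    ----------
    rising_slopes : array of per-event maximum rising slopes (V/s)
    success : boolean array, True where the event triggered an AP

    ``fit(method="binned")`` reproduces the binned weighted-least-squares
    procedure (bin width 0.5 V/s, each bin weighted by its event count);
    ``method="logistic"`` fits the same law by logistic regression on the
    raw events and is used as a cross-check.
    """

    def __init__(self, rising_slopes, success):
        x = np.asarray(rising_slopes, float)
        y = np.asarray(success, bool)
        ok = np.isfinite(x)
        self.x, self.y = x[ok], y[ok]
        if len(self.x) == 0:
            raise ValueError("no events supplied")

    @classmethod
    def from_events(cls, events: pd.DataFrame) -> "ThresholdEpspModel":
        return cls(events["rising_slope_Vps"].to_numpy(),
                   events["is_ap"].to_numpy().astype(bool))

    def fit(self, bin_width: float = 0.5, method: str = "binned",
            min_occupied_bins: int = 3) -> BoltzmannFit:
        x, y = self.x, self.y
        if y.all() or (~y).all():
            raise ValueError(
                "threshold fit undefined: events of both classes are required")
        lo = math.floor(x.min() / bin_width) * bin_width
        hi = math.ceil(x.max() / bin_width) * bin_width + bin_width / 2
        edges = np.arange(lo, hi, bin_width)
        idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        succ = np.bincount(idx, weights=y.astype(float), minlength=len(edges) - 1)
        occ = counts > 0
        if occ.sum() < min_occupied_bins:
            raise ValueError(
                f"only {occ.sum()} occupied bins; need >= {min_occupied_bins}")
        centers = (edges[:-1] + bin_width / 2)[occ]
        frac = succ[occ] / counts[occ]
        w = counts[occ].astype(float)

        if method == "logistic":
            d, a, d_se, a_se = self._fit_logistic()
            resid = frac - boltzmann(centers, d, a)
            rss = float(np.sum(w * resid ** 2) / w.sum())
        elif method == "binned":
            p0 = (float(np.median(x)), 1.0)
            try:
                popt, pcov = curve_fit(
                    boltzmann, centers, frac, p0=p0,
                    sigma=1.0 / np.sqrt(w), absolute_sigma=False, maxfev=20_000)
            except RuntimeError as err:
                raise ValueError(f"Boltzmann fit did not converge: {err}") from err
            d, a = (float(p) for p in popt)
            d_se, a_se = (float(s) for s in np.sqrt(np.diag(pcov)))
            resid = frac - boltzmann(centers, d, a)
            rss = float(np.sum(w * resid ** 2) / w.sum())
        else:
            raise ValueError(f"unknown method {method!r}")
        return BoltzmannFit(d=d, a=a, d_se=d_se, a_se=a_se, bin_centers=centers,
                            bin_fractions=frac, bin_counts=counts[occ],
                            n_events=len(x), method=method, rss=rss)

    def _fit_logistic(self):
        # Newton-Raphson logistic regression: logit p = (x - d)/a
        x, y = self.x, self.y.astype(float)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.zeros(2)
        beta[1] = 1.0 / max(x.std(), 1e-6)
        beta[0] = -beta[1] * x.mean()
        for _ in range(100):
            eta = np.clip(X @ beta, -30, 30)
            p = 1.0 / (1.0 + np.exp(-eta))
            wdiag = np.maximum(p * (1 - p), 1e-10)
            grad = X.T @ (y - p)
            hess = (X * wdiag[:, None]).T @ X
            step = np.linalg.solve(hess, grad)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-10:
                break
        cov = np.linalg.inv(hess)
        b0, b1 = beta
        if b1 <= 0:
            raise ValueError("logistic fit produced a non-increasing curve")
        d, a = -b0 / b1, 1.0 / b1
        # delta method for the (d, a) standard errors
        J = np.array([[-1.0 / b1, b0 / b1 ** 2], [0.0, -1.0 / b1 ** 2]])
        cov_da = J @ cov @ J.T
        return float(d), float(a), float(math.sqrt(cov_da[0, 0])), \
            float(math.sqrt(cov_da[1, 1]))


def fit_threshold_epsp(events: pd.DataFrame, bin_width: float = 0.5,
                       method: str = "binned") -> BoltzmannFit:
    """Convenience wrapper: Boltzmann threshold-EPSP fit on an event table."""
    return ThresholdEpspModel.from_events(events).fit(bin_width=bin_width,
                                                      method=method)


# ---------------------------------------------------------------------------
# Preceding activity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreActConfig:
    """Exponential preceding-activity kernel configuration.

    ``tau`` defaults to 60 ms (10 and 100 ms are the standard alternates);
    ``scope='ap'`` restricts the preceding events entering the sum to
    successful APs.
    """

    tau: float = 0.060
    scope: str = "all"   # "all" | "ap"

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.scope not in ("all", "ap"):
            raise ValueError("scope must be 'all' or 'ap'")


def preceding_activity(events: pd.DataFrame,
                       config: PreActConfig = PreActConfig()) -> np.ndarray:
    """Exponentially weighted preceding-event activity per event.

    PreAct(t0) = (1/median(S)) * sum_i S_i exp((t_i - t0)/tau) over all
    preceding events of the same trial (trials are independent
    presentations, so the sum never crosses a trial boundary); S_i are the
    preceding EPSP rising slopes and the normalizer is the median slope of
    the trial's events in scope.  The first event of each trial gets 0.
    """
    order = events.reset_index(drop=True).sort_values(
        ["trial", "time_s"], kind="stable")
    pos = order.index.to_numpy()  # positional indices into the input order
    times = order["time_s"].to_numpy()
    slopes = order["rising_slope_Vps"].to_numpy()
    trials = order["trial"].to_numpy()
    in_scope = np.ones(len(order), dtype=bool) if config.scope == "all" \
        else order["is_ap"].to_numpy().astype(bool)
    tau = config.tau
    vals = np.zeros(len(order))
    start = 0
    for i in range(1, len(order) + 1):
        if i == len(order) or trials[i] != trials[start]:
            seg = slice(start, i)
            med = np.median(slopes[seg][in_scope[seg]]) \
                if in_scope[seg].any() else np.nan
            acc, t_prev = 0.0, None
            for k in range(start, i):
                if t_prev is not None:
                    acc *= math.exp(-(times[k] - t_prev) / tau)
                vals[k] = acc / med if (med and not math.isnan(med)) else 0.0
                if in_scope[k]:
                    acc += slopes[k]
                t_prev = times[k]
            start = i
    # map back to the original row order
    out = np.zeros(len(events))
    out[pos] = vals
    return out


def iei_dependence(events: pd.DataFrame,
                   iei_edges: Optional[np.ndarray] = None,
                   min_count: int = 50,
                   bin_width_Vps: float = 0.5) -> pd.DataFrame:
    """Per-IEI-bin profile of normalized slope, threshold EPSP, failure fraction.

    IEIs are computed within trials (the first event of each trial has no
    IEI and is excluded).  Slopes are normalized by the unit's median rising
    slope.  The threshold EPSP is fitted per bin only where both classes
    occur and the bin holds at least ``min_count`` events; other cells are
    NaN-flagged.
    """
    if iei_edges is None:
        iei_edges = np.geomspace(0.0005, 0.100, 13)
    ev = events.sort_values(["trial", "time_s"], kind="stable").copy()
    iei = ev.groupby("trial")["time_s"].diff().to_numpy()
    slopes = ev["rising_slope_Vps"].to_numpy()
    med = np.median(slopes)
    ok = np.isfinite(iei)
    idx = np.digitize(iei[ok], iei_edges) - 1
    rows = []
    for b in range(len(iei_edges) - 1):
        sel = np.flatnonzero(ok)[idx == b]
        n = len(sel)
        if n == 0:
            rows.append((iei_edges[b], iei_edges[b + 1], 0,
                         math.nan, math.nan, math.nan))
            continue
        sub = ev.iloc[sel]
        mean_norm_slope = float(sub["rising_slope_Vps"].mean() / med)
        ff = float((~sub["is_ap"].astype(bool)).mean())
        thr = math.nan
        y = sub["is_ap"].to_numpy().astype(bool)
        if n >= min_count and y.any() and (~y).any():
            try:
                thr = fit_threshold_epsp(sub, bin_width=bin_width_Vps).d
            except ValueError:
                pass
        rows.append((iei_edges[b], iei_edges[b + 1], n,
                     mean_norm_slope, thr, ff))
    return pd.DataFrame(rows, columns=[
        "iei_lo_s", "iei_hi_s", "n_events", "mean_norm_slope",
        "threshold_epsp_Vps", "failure_fraction"])
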