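"""Spectrotemporal receptive-field estimation and input-output comparison.

STRFs are estimated by generalized (whitened) reverse correlation: the
event-triggered average of the stimulus spectrogram over lags, decorrelated
by the stimulus autocovariance with ridge regularization.  Input STRFs use
all EPSP events, output STRFs only the successful ones; both event classes
are time-stamped at maximum EPSP slope, so their STRFs share congruent
reference points and can be subtracted after SD normalization.  The
resulting difference-STRF localizes, in time and frequency, where output
sensitivity falls below the input — the signature of inhibition (together
with refractory/adaptation effects) during ongoing broadband stimulation.

Population significance uses per-bin one-sample t-tests with
Benjamini-Hochberg FDR control; single-STRF significance uses a
circular-shift permutation null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import ttest_1samp, norm, t as t_dist

from .stimuli import Spectrogram
from .stats import benjamini_hochberg


@dataclass
class STRF:
    """A spectrotemporal receptive field on (frequency, lag) axes.

    Positive lag means stimulus time preceding the event; the lag axis
    starts at 0.  ``normalized()`` returns the unit-SD variant used for
    input-output subtraction; ``sd`` records the normalizer.
    """

    frequencies: np.ndarray      # Hz
    lags: np.ndarray             # s, starting at 0
    weights: np.ndarray          # (n_freq, n_lag)
    event_class: str = "input"   # "input" (all EPSPs) | "output" (EPSP_succ)
    n_events: int = 0
    ridge: float = 0.0
    null_sd: Optional[float] = None        # permutation SD about the null mean
    null_mean: Optional[np.ndarray] = None  # per-bin permutation mean
    null_df: int = 0                       # permutations - 1 (t reference)

    @property
    def sd(self) -> float:
        return float(self.weights.std())

    def normalized(self, mode: str = "sd") -> np.ndarray:
        if mode == "sd":
            return self.weights / self.sd
        if mode == "peak":
            return self.weights / np.max(np.abs(self.weights))
        raise ValueError(f"unknown normalization {mode!r}")

    def z_scores(self) -> np.ndarray:
        """Per-bin z-scores against the circular-shift permutation null."""
        if self.null_sd is None or self.null_sd == 0:
            raise ValueError("no permutation null attached; fit with n_null > 0")
        return (self.weights - self.null_mean) / self.null_sd

    def p_values(self) -> np.ndarray:
        # the null SD comes from finitely many permutations, so the
        # reference distribution is Student-t, not normal
        z = self.z_scores()
        df = max(self.null_df, 2)
        return 2.0 * t_dist.sf(np.abs(z), df)


@dataclass
class DifferenceSTRF:
    """SD-normalized output STRF minus SD-normalized input STRF."""

    frequencies: np.ndarray
    lags: np.ndarray
    values: np.ndarray
    sd_input: float
    sd_output: float
    null_sd: Optional[float] = None
    null_mean: Optional[np.ndarray] = None
    null_df: int = 0

    def p_values(self) -> np.ndarray:
        if self.null_sd is None or self.null_sd == 0:
            raise ValueError("no permutation null available")
        centered = self.values if self.null_mean is None \
            else self.values - self.null_mean
        df = max(self.null_df, 2)
        return 2.0 * t_dist.sf(np.abs(centered) / self.null_sd, df)


@dataclass
class SignificanceMask:
    """Per-bin p-values and the BH-FDR rejection mask at level q."""

    p_values: np.ndarray
    mask: np.ndarray
    q: float
    mean_difference: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Core estimator
# ---------------------------------------------------------------------------

class _WhitenedDesign:
    """Cached stimulus statistics for repeated STRF solves on one stimulus.

    The normal-equation matrix X'X of the lagged-spectrogram design is
    block-Toeplitz; its blocks are the circular cross-correlations of the
    spectrogram channels, computed once by FFT.  Ridge solves for many
    response vectors (real events, permutation shifts, output vs input, and
    ridge grids) reuse the cached X'X and per-ridge Cholesky factors.
    """

    def __init__(self, spectrogram: Spectrogram, n_lag: int):
        S = spectrogram.values
        self.S = S
        self.n_f, self.n_t = S.shape
        self.n_lag = n_lag
        self.dt = spectrogram.time_bin
        F = np.fft.rfft(S, axis=1)
        # cc[f, g, k] = sum_u S[f, u] S[g, u - k] (circular); keep only the
        # lags the block-Toeplitz normal matrix needs, one row at a time to
        # bound memory
        cc = np.empty((self.n_f, self.n_f, 2 * n_lag - 1))
        for f1 in range(self.n_f):
            row = np.fft.irfft(F[f1][None, :] * np.conj(F), n=self.n_t, axis=1)
            cc[f1, :, n_lag - 1:] = row[:, :n_lag]                 # m = 0..n_lag-1
            cc[f1, :, : n_lag - 1] = row[:, self.n_t - n_lag + 1:]  # m < 0
        n = self.n_f * n_lag
        XtX = np.empty((n, n))
        for l1 in range(n_lag):
            for l2 in range(n_lag):
                # X'X[(f1,l1),(f2,l2)] = sum_u S[f1,u] S[f2, u-(l2-l1)]
                XtX[l1::n_lag, l2::n_lag] = cc[:, :, n_lag - 1 + (l2 - l1)]
        self.XtX = XtX
        self.diag_mean = float(np.trace(XtX) / n)
        self._F = F
        self._cho = {}

    def _factor(self, ridge: float):
        if ridge not in self._cho:
            n = self.XtX.shape[0]
            self._cho[ridge] = cho_factor(
                self.XtX + ridge * self.diag_mean * np.eye(n))
        return self._cho[ridge]

    def xty(self, y: np.ndarray) -> np.ndarray:
        Fy = np.fft.rfft(y)
        # lag-l stimulus-response correlation: sum_v S[f, v] y[v + l],
        # i.e. the stimulus l bins BEFORE each event
        cc = np.fft.irfft(np.conj(self._F) * Fy[None, :], n=self.n_t, axis=1)
        return cc[:, : self.n_lag].reshape(-1)

    def solve(self, y: np.ndarray, ridge: float) -> np.ndarray:
        w = cho_solve(self._factor(ridge), self.xty(y))
        return w.reshape(self.n_f, self.n_lag)


def _event_counts(spectrogram: Spectrogram, event_times, n_trials: int
                  ) -> np.ndarray:
    if len(event_times) and not np.isscalar(event_times[0]):
        pooled = np.concatenate([np.asarray(tr, float) for tr in event_times])
    else:
        pooled = np.asarray(event_times, float)
    dt = spectrogram.time_bin
    edges = np.arange(len(spectrogram.times) + 1) * dt
    return np.histogram(pooled, bins=edges)[0].astype(float)


def estimate_strf(
    spectrogram: Spectrogram,
    event_times,
    max_lag: float = 0.025,
    regularization="auto",
    *,
    n_trials: int = 1,
    event_class: str = "input",
    n_null: int = 0,
    null_seed: int = 0,
    design: Optional[_WhitenedDesign] = None,
) -> STRF:
    """Estimate an STRF by ridge-regularized whitened reverse correlation.

    ``event_times`` is one pooled array or a per-trial sequence of event
    timestamps (s, on the stimulus clock; trials are identical stimulus
    repetitions).  ``regularization`` is the ridge coefficient relative to
    the mean design diagonal, or "auto" to select it by held-out predictive
    correlation over contiguous stimulus segments.  ``n_null > 0`` attaches
    a circular-shift permutation null SD for per-bin significance.

    Fewer than 100 events triggers a noisy-estimate warning; zero events is
    an error.
    """
    y = _event_counts(spectrogram, event_times, n_trials)
    n_events = int(y.sum())
    if n_events == 0:
        raise ValueError("cannot estimate an STRF from zero events")
    if n_events < 100:
        warnings.warn(f"only {n_events} events; the STRF estimate will be "
                      "noisy", stacklevel=2)
    dt = spectrogram.time_bin
    n_lag = int(round(max_lag / dt)) + 1
    lags = np.arange(n_lag) * dt

    if design is None or design.n_lag != n_lag:
        design = _WhitenedDesign(spectrogram, n_lag)
    if regularization == "auto":
        regularization = _select_ridge(spectrogram, y, n_lag, design=design)
    lam = float(regularization)
    w = design.solve(y, lam)
    null_sd = null_mean = None
    if n_null > 0:
        rng = np.random.default_rng(null_seed)
        n_t = len(y)
        lo = max(2 * n_lag, int(0.05 * n_t))
        null_w = np.empty((n_null, design.n_f, n_lag))
        for i in range(n_null):
            shift = int(rng.integers(lo, n_t - lo))
            null_w[i] = design.solve(np.roll(y, shift), lam)
        null_mean = null_w.mean(axis=0)
        null_sd = float((null_w - null_mean).std())
    return STRF(frequencies=spectrogram.frequencies, lags=lags, weights=w,
                event_class=event_class, n_events=n_events, ridge=lam,
                null_sd=null_sd, null_mean=null_mean,
                null_df=max(n_null - 1, 0))


def _select_ridge(spectrogram: Spectrogram, y: np.ndarray, n_lag: int,
                  grid=(0.01, 0.1, 1.0, 10.0), n_folds: int = 4,
                  design: Optional[_WhitenedDesign] = None) -> float:
    """Ridge selection by held-out predictive correlation across segments."""
    if design is None:
        design = _WhitenedDesign(spectrogram, n_lag)
    n_t = len(y)
    seg = n_t // n_folds
    best_lam, best_r = grid[0], -np.inf
    for lam in grid:
        rs = []
        for k in range(n_folds):
            test = slice(k * seg, (k + 1) * seg)
            y_tr = y.copy()
            y_tr[test] = y.mean()     # neutralize the held-out segment
            w = design.solve(y_tr, lam)
            pred = _predict(spectrogram, w)
            r = np.corrcoef(pred[test], y[test])[0, 1]
            if np.isfinite(r):
                rs.append(r)
        score = float(np.mean(rs)) if rs else -np.inf
        if score > best_r:
            best_r, best_lam = score, lam
    return best_lam


def _predict(spectrogram: Spectrogram, w: np.ndarray) -> np.ndarray:
    S = spectrogram.values
    n_t = S.shape[1]
    out = np.zeros(n_t)
    for f in range(S.shape[0]):
        out += np.convolve(S[f], w[f])[:n_t]
    return out


def event_triggered_average(spectrogram: Spectrogram, event_times,
                            max_lag: float = 0.025) -> STRF:
    """Plain (unwhitened) event-triggered average, the classical fallback."""
    y = _event_counts(spectrogram, event_times, 1)
    if y.sum() == 0:
        raise ValueError("cannot average over zero events")
    dt = spectrogram.time_bin
    n_lag = int(round(max_lag / dt)) + 1
    S = spectrogram.values
    F = np.fft.rfft(S, axis=1)
    Fy = np.fft.rfft(y)
    # stimulus preceding each event: sum_v S[f, v] y[v + l]
    cc = np.fft.irfft(np.conj(F) * Fy[None, :], n=S.shape[1], axis=1)
    w = cc[:, :n_lag] / y.sum()
    return STRF(frequencies=spectrogram.frequencies,
                lags=np.arange(n_lag) * dt, weights=w,
                event_class="input", n_events=int(y.sum()))


def estimate_paired_strfs(
    spectrogram: Spectrogram,
    trains_input,
    trains_output,
    max_lag: float = 0.025,
    regularization=1.0,
    *,
    n_trials: int = 1,
    n_null: int = 20,
    null_seed: int = 0,
    design: Optional[_WhitenedDesign] = None,
):
    """Input and output STRFs with a paired permutation null for their
    difference.

    Output events are a subset of the input events, so the two STRFs share
    estimation noise; a valid null for the normalized difference must
    circularly shift both response vectors by the SAME offset.  Returns
    ``(strf_in, strf_out, DifferenceSTRF)`` where the difference carries the
    paired null (per-bin mean, pooled SD, t degrees of freedom).
    """
    y_in = _event_counts(spectrogram, trains_input, n_trials)
    y_out = _event_counts(spectrogram, trains_output, n_trials)
    if y_in.sum() == 0 or y_out.sum() == 0:
        raise ValueError("both event streams must be nonempty")
    dt = spectrogram.time_bin
    n_lag = int(round(max_lag / dt)) + 1
    if design is None or design.n_lag != n_lag:
        design = _WhitenedDesign(spectrogram, n_lag)
    lam = float(regularization) if regularization != "auto" else \
        _select_ridge(spectrogram, y_in, n_lag, design=design)
    w_in = design.solve(y_in, lam)
    w_out = design.solve(y_out, lam)
    null_mean = null_sd = None
    if n_null > 0:
        rng = np.random.default_rng(null_seed)
        n_t = len(y_in)
        lo = max(2 * n_lag, int(0.05 * n_t))
        null_d = np.empty((n_null, design.n_f, n_lag))
        for i in range(n_null):
            shift = int(rng.integers(lo, n_t - lo))
            wi = design.solve(np.roll(y_in, shift), lam)
            wo = design.solve(np.roll(y_out, shift), lam)
            null_d[i] = wo / wo.std() - wi / wi.std()
        null_mean = null_d.mean(axis=0)
        null_sd = float((null_d - null_mean).std())
    lags = np.arange(n_lag) * dt
    s_in = STRF(frequencies=spectrogram.frequencies, lags=lags, weights=w_in,
                event_class="input", n_events=int(y_in.sum()), ridge=lam)
    s_out = STRF(frequencies=spectrogram.frequencies, lags=lags, weights=w_out,
                 event_class="output", n_events=int(y_out.sum()), ridge=lam)
    diff = DifferenceSTRF(frequencies=spectrogram.frequencies, lags=lags,
                          values=s_out.normalized() - s_in.normalized(),
                          sd_input=s_in.sd, sd_output=s_out.sd,
                          null_sd=null_sd, null_mean=null_mean,
                          null_df=max(n_null - 1, 2))
    return s_in, s_out, diff


# ---------------------------------------------------------------------------
# Difference STRFs and significance
# ---------------------------------------------------------------------------

def difference_strf(strf_in: STRF, strf_out: STRF) -> DifferenceSTRF:
    """Normalized output minus input STRF.

    Both STRFs must share axes and be aligned to maximum-EPSP-slope event
    timestamps; each is normalized to unit SD before subtraction, removing
    the overall firing-rate gain so the difference reflects tuning shape.
    Identical event sets give a zero matrix.
    """
    if (len(strf_in.frequencies) != len(strf_out.frequencies)
            or len(strf_in.lags) != len(strf_out.lags)
            or not np.allclose(strf_in.frequencies, strf_out.frequencies)
            or not np.allclose(strf_in.lags, strf_out.lags)):
        raise ValueError("input and output STRF axes do not match")
    diff = strf_out.normalized() - strf_in.normalized()
    null_sd = null_mean = None
    if strf_in.null_sd and strf_out.null_sd:
        null_sd = math.hypot(strf_in.null_sd / strf_in.sd,
                             strf_out.null_sd / strf_out.sd)
        null_mean = (strf_out.null_mean / strf_out.sd
                     - strf_in.null_mean / strf_in.sd)
    return DifferenceSTRF(frequencies=strf_in.frequencies, lags=strf_in.lags,
                          values=diff, sd_input=strf_in.sd,
                          sd_output=strf_out.sd, null_sd=null_sd,
                          null_mean=null_mean,
                          null_df=min(strf_in.null_df, strf_out.null_df))


def align_to_peak(diff: DifferenceSTRF, peak_index: tuple,
                  target_index: tuple) -> DifferenceSTRF:
    """Shift a difference-STRF so its input excitatory peak sits at a common
    origin (integer-bin shifts; sub-bin offsets are rounded)."""
    df = peak_index[0] - target_index[0]
    dl = peak_index[1] - target_index[1]
    vals = np.roll(np.roll(diff.values, -df, axis=0), -dl, axis=1)
    nm = None if diff.null_mean is None else \
        np.roll(np.roll(diff.null_mean, -df, axis=0), -dl, axis=1)
    return DifferenceSTRF(frequencies=diff.frequencies, lags=diff.lags,
                          values=vals, sd_input=diff.sd_input,
                          sd_output=diff.sd_output, null_sd=diff.null_sd,
                          null_mean=nm, null_df=diff.null_df)


def population_significance(differences: Sequence[DifferenceSTRF],
                            q: float = 0.01) -> SignificanceMask:
    """Point-wise one-sample t-tests across units with BH-FDR control.

    All difference-STRFs must be peak-aligned and share shapes.  Returns
    the boolean mask at FDR level ``q`` together with the across-unit mean
    difference matrix.
    """
    if len(differences) < 3:
        raise ValueError("population significance needs >= 3 units")
    stack = np.stack([d.values for d in differences])
    mean = stack.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = ttest_1samp(stack, 0.0, axis=0)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    fdr = benjamini_hochberg(p.ravel(), q)
    mask = fdr.rejected.reshape(p.shape)
    return SignificanceMask(p_values=p, mask=mask, q=q, mean_difference=mean)


def single_unit_significance(diff: DifferenceSTRF, q: float = 0.01
                             ) -> SignificanceMask:
    """BH-FDR mask of one difference-STRF against its permutation null."""
    p = diff.p_values()
    fdr = benjamini_hochberg(p.ravel(), q)
    return SignificanceMask(p_values=p, mask=fdr.rejected.reshape(p.shape),
                            q=q, mean_difference=diff.values)


# ---------------------------------------------------------------------------
# Shape metrics
# ---------------------------------------------------------------------------

def _fwhm(axis: np.ndarray, profile: np.ndarray, i_pk: int) -> float:
    peak = profile[i_pk]
    half = peak / 2.0
    left = axis[0] if profile[0] >= half else None
    for j in range(i_pk, 0, -1):
        if profile[j - 1] < half:
            f = (profile[j] - half) / (profile[j] - profile[j - 1])
            left = axis[j] + f * (axis[j - 1] - axis[j])
            break
    right = axis[-1] if profile[-1] >= half else None
    for j in range(i_pk, len(profile) - 1):
        if profile[j + 1] < half:
            f = (profile[j] - half) / (profile[j] - profile[j + 1])
            right = axis[j] + f * (axis[j + 1] - axis[j])
            break
    if left is None or right is None:
        return math.nan
    return float(right - left)


def strf_metrics(strf: STRF) -> dict:
    """Excitation/inhibition sums and half-widths of the excitatory peak.

    Sums run over all bins of each sign of the SD-normalized STRF (no noise
    threshold); half-widths are FWHM of the excitatory peak along the
    frequency (octaves) and lag (s) axes through the peak bin.  With no
    positive bin the half-widths are NaN.
    """
    w = strf.normalized() if isinstance(strf, STRF) else np.asarray(strf)
    freqs = strf.frequencies
    lags = strf.lags
    excitation = float(w[w > 0].sum())
    inhibition = float(-w[w < 0].sum())
    out = {"excitation_sum": excitation, "inhibition_sum": inhibition,
           "spectral_half_width_oct": math.nan,
           "temporal_half_width_s": math.nan}
    if excitation <= 0:
        return out
    i_f, i_l = np.unravel_index(int(np.argmax(w)), w.shape)
    oct_axis = np.log2(freqs / freqs[0])
    out["spectral_half_width_oct"] = _fwhm(oct_axis, w[:, i_l], i_f)
    out["temporal_half_width_s"] = _fwhm(lags, w[i_f, :], i_l)
    return out
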