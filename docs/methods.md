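# Methods

This note documents the models, estimators, and numerical choices behind
`endbulb`, and what its synthetic-data generator does and does not emulate.

## The synthetic ANF→SBC unit

The generator produces paired input/output event streams for one synapse:
every event is an ANF input (an EPSP); a subset triggers a postsynaptic AP
(the SBC output).

**Firing-rate model.** The ANF fires as an inhomogeneous Poisson process
with an absolute dead time of 0.7 ms.  The driving intensity is dead-time
compensated, λ = r/(1 − r·t_ref), so delivered event rates match the
nominal profile r(t) = r_spont + (r_max − r_spont)·σ((L_eff(t) − θ_L −
m)/s), with r_spont = 85 Hz, r_max = 282 Hz, audiometric threshold θ_L =
10 dB SPL, half-drive point m = 10 dB above threshold, and dynamic-range
slope s = 5 dB.  L_eff is the stimulus level seen through an asymmetric
triangular tuning filter on the log₂-frequency axis: the high-frequency
flank is steep and the low-frequency tail shallow (flank ratio 2.6,
giving asymmetry indices near −1), with the two 10-dB half-widths solved
from Q₁₀ = 2.5.  Spectral components of any stimulus (tone, SAM/FM
envelope, gamma-tone sequence) are attenuated by the filter in dB, summed
as power, and converted back to level.

**EPSP slopes and facilitation.** Rising slopes are Gaussian around a
facilitation-modulated mean: μ(t) = μ₀·(1 + g_f·tanh(PreAct/κ)), with μ₀ =
6.15 V/s, SD 0.8 V/s, g_f = 1.7, κ = 3, and a fast generative
preceding-activity kernel (exponential, τ = 4 ms) normalized by the mean
slope.  The *analysis-side* PreAct uses the standard τ = 60 ms kernel (10
and 100 ms as alternates) normalized by the median slope; the two are
deliberately distinct — the analysis must not assume the generative
kernel.

**Spike mechanism.** An event succeeds with the Boltzmann probability
P(AP) = 1/(1 + e^{(θ(t) − s*)/a}), a = 0.4 V/s, where the effective slope
is s* = s/(1 + g_div·g(t)) and the threshold θ(t) = d + g_sub·g(t), d =
6.1 V/s.  This makes the analysis-side Boltzmann fit the exact inverse of
the generative law.  Refractoriness of the SBC spike generator is a hard
forced-failure window of 1 ms after each AP plus a linearly recovering
threshold boost (3 V/s) out to 2 ms, reproducing the elevated failure
fraction at inter-event intervals below 2 ms.  Falling slopes and
amplitudes are then drawn from well-separated success/failure
distributions (21.1 ± 4.9 vs 4.4 ± 1.2 V/s; 6 ± 1 vs 2 ± 0.5 mV).

**Inhibitory conductance.** The dimensionless conductance g(t) is the
stimulus drive inside a broad Gaussian log-frequency window (SD 1.2
octaves, centered on CF), passed through an activation sigmoid 15 dB above
the unit's excitatory threshold (3 dB slope), and convolved with a delayed
exponential kernel (1 ms delay, 10 ms decay, unit integral, so a sustained
saturating drive yields g → 1).  `enabled=False` zeroes it — the analogue
of glycine-receptor blockade.  Defaults g_sub = 3.9 V/s and g_div = 0.05
per unit conductance.

**Calibration.** The free parameters above were fixed once, jointly,
against the study conditions the generator must reproduce: spontaneous
input rate 85 Hz and driven plateau 282 Hz (exact by construction);
spontaneous failure fraction ≈ 0.28 and CF-tone (50 dB) failure fraction ≈
0.49; spontaneous threshold-EPSP ≈ 6.1 V/s with a several-V/s elevation
under on-CF stimulation; an inhibitory response area detectable ~15 dB
above the excitatory threshold and broader than it; and output RGS
responses that are sparser and more reproducible than their inputs.  The
divisive/subtractive split of the conductance action is a calibration, not
a measurement — the data constrain their joint effect only.  One
consequence of the strong, fast facilitation this calibration requires is
that the Spearman correlation between PreAct (τ = 60 ms) and EPSP slope in
spontaneous activity comes out near 0.37 rather than the ~0.2 seen in
vivo, and the facilitation window is compressed to IEIs of roughly 1–7 ms.

## Estimators

**Threshold EPSP.** Success fraction per 0.5-V/s rising-slope bin, then
weighted nonlinear least squares (weights = bin counts, initialization at
the median slope and a = 1 V/s) of φ(x) = 1/(1+e^{(d−x)/a}).  A logistic
regression on raw events (Newton–Raphson, delta-method standard errors) is
the cross-check; the binned fit is primary.  Undefined when only one class
is present or fewer than three bins are occupied.

**Event detection.** Rising-slope threshold on a lightly smoothed trace
(0.2 ms boxcar), one event per suprathreshold flank with 0.5 ms dead time,
time-stamped at the maximum rising slope; maximum falling slope within the
next 2 ms and peak amplitude are extracted per event.  The numeric
threshold is a required, unit-specific parameter (it depends on the
recording's signal-to-noise ratio); detections above 1000 events/s raise a
too-many-events warning.  Round-trip testing renders known event streams
as prepotential–EPSP(–AP) templates whose piecewise half-cosine rise/fall
reproduce each event's recorded slopes exactly.

**Classification.** Falling slope above a per-unit criterion → success.
The automatic criterion fits a two-component Gaussian mixture by EM and
takes the mixture-density minimum between the component means (robust to
the very unequal component SDs); clearly unimodal distributions are
refused.

**FRA machinery.** Response window = tone duration + 10 ms; spontaneous
baseline = final 100 ms of each 300 ms inter-stimulus interval.  A cell is
significant when its metric exceeds baseline mean + 2 SD (SD across
presentations); for the fitted threshold-EPSP metric the criterion is a
z-score against combined cell + baseline fit uncertainty *plus* an
absolute elevation floor of 1 V/s, because least-squares standard errors
on sparse cells are optimistic and a 200-cell scan would otherwise pick up
spurious minima.  Tuning borders interpolate the criterion crossing
linearly on the log₂-frequency axis.

**Temporal metrics.** Vector strength over complete modulation periods
with the first 20 ms of each repetition excluded; Rayleigh p = e^{−nVS²}.
Corr_Norm is the non-mean-subtracted cosine similarity between PSTH and
stimulus envelope, maximized over lags in [0, 10 ms]; this normalization
is pinned by the flat-response value 1/√1.5 ≈ 0.82.  The shuffled
autocorrelogram counts all-order cross-trial coincidences (same-trial
pairs excluded) in a 0.2 ms window on a 0.05 ms lag grid, normalized by
N(N−1)·r²·w·D so independent stationary Poisson trains sit at 1; the
window count is exact (order statistics, not a binned convolution), and
exact-zero differences count once per ordering so identical trains give
the analytic 1/(r·w) peak.  Reproducibility is the lag-0 value; modulation
depth the SD over one modulation period centered on lag 0 (a flag selects
the cycle starting at 0 instead); dispersion the full width at half of
(peak − asymptote) with the asymptote taken as the mean over the outer
third of lags.  Sparsity indices operate on 100 Hz PSTHs; the variance
index S = 1 − ⟨r⟩²/⟨r²⟩, the raw kurtosis, and the close-to-silence index
(fraction of bins below 15 Hz) are all provided.

**Shot-noise debiasing.** A PSTH from finitely many trials inflates ⟨r²⟩
by the Poisson counting term ⟨r⟩/(n_trials·Δ).  The removal comparisons
(and the divisive-thinning acceptance quantity) use the debiased variance
index, which is exactly thinning-invariant in expectation — without the
correction, binomial thinning alone raises the plain index by ~0.01–0.04
purely through counting noise.  The plain index remains the default for
descriptive reporting.

**STRF estimation.** Generalized reverse correlation: the lagged
spectrogram design's normal equations are solved with ridge
regularization, exploiting the block-Toeplitz structure of X'X (channel
cross-correlations by FFT, one Cholesky factorization reused across
response vectors).  The lag grid is 0–25 ms at 0.5 ms; the frequency grid
12 bins/octave over −1..+2 octaves re CF; the default ridge is 1.0 times
the mean design diagonal, with "auto" selecting from a grid by held-out
predictive correlation over contiguous stimulus segments.  Circular
(FFT) boundary conditions are used throughout — negligible for 30 s
stimuli.  Gamma-tone spectrogram patches are separable (squared gamma
envelope in time, Gaussian in log-frequency with FWHM equal to the tone
bandwidth, ERB law by default) and normalized to unit mass times linear
tone power, so total spectrogram energy is proportional to tone count.

**STRF significance.** Per-bin nulls come from circular shifts of the
response vector (20 by default); because the null SD is estimated from
finitely many shifts, p-values use a Student-t reference with n_null − 1
degrees of freedom.  Input and output STRFs of one unit share estimation
noise (the output events are a subset of the input events), so the
difference-STRF null shifts *both* response vectors by the same offset.
Population significance across units is point-wise one-sample t-tests with
Benjamini–Hochberg control at q = 0.01, the procedure used for the
population difference-STRF.

**Removal models.** Divisive: binomial thinning at p = target/input rate.
Subtractive: per-bin removal probability min(1, c/r(t)) with c solved by
bisection so the expected global rate matches the target; the
instantaneous rate r(t) is estimated on 2 ms bins.  A coarser rate bin
(e.g. 10 ms) imprints its own width on the output correlogram and can
*widen* the central peak; 2 ms sits safely below the dispersion scale
while keeping per-bin counts meaningful.  Removal decisions are seeded
independently per mode; metric PSTHs stay at 10 ms.

## Problem sizes

Default verification sizes were chosen to keep every check comfortably
determined: 20-unit RGS populations (10 trials × 12 s) for the removal
contrasts, 30 s × 20 trials for STRF kernel recovery and the 16-unit
population difference-STRF, 5000 events for Boltzmann recovery, and 10⁴
samples for closed-form metric checks.  The acceptance script uses the
full 30 s × 20 trial × 20 unit configuration.

## What the generator does and does not show

Passing tests demonstrate that every estimator recovers the quantities the
generative model defines, at realistic rates, failure fractions, and
tuning shapes — they do not certify behaviour on real recordings, whose
EPSP waveforms, non-Poisson ANF statistics (e.g. refractory-driven
regularity, adaptation), electrode artifacts, and non-stationarities the
generator does not emulate.  Two known structural limitations:

- The generative output does **not** robustly improve vector strength over
  its input at every SAM modulation frequency.  Failures in the model
  concentrate at high instantaneous rate (the refractory window) and the
  facilitation and inhibitory conductance both trail the envelope, so
  output VS changes hover around zero.  The subtractive removal
  transformation — which removes spikes preferentially at low
  instantaneous rate — does improve VS, modulation depth, and
  reproducibility at every modulation frequency, and that is the contrast
  the property tests assert.  The same tension is informative: a purely
  threshold-plus-refractoriness mechanism is not by itself sufficient for
  the phase-locking improvement, which is precisely why the
  low-rate-targeting subtractive component matters.
- At long inter-event intervals, unfacilitated events sit close to
  threshold and fail more often than in vivo, where reliability is flat
  beyond the refractory window; the refractory failure profile is
  therefore verified with facilitation disabled.

## Design choices made where the design was open

- Gamma-tone bandwidths follow the ERB law BW(f) = 24.7 + 0.108 f Hz
  (configurable callable); envelope order 4; audio at 97 656 Hz when
  rendered (analysis operates on tone lists and spectrograms, so waveform
  rendering is optional).
- Cohen's U1 is computed distribution-free via the single-crossing
  identity U1 = 2D/(1+D), D the two-sample KS statistic (equal to the
  normal-theory U1 under a pure location shift; U1(d=1) ≈ 0.55).
- Trials are independent presentations: no kernel, IEI, or removal
  computation ever crosses a trial boundary; spike removal operates
  per trial so trial-resolved metrics remain defined.
- Times are seconds from stimulus onset on half-open intervals; all
  generators and removal operators are bit-reproducible from their seeds.
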