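# Methods

## Signal model and detection

Recordings are mono WAV files normalised to [−1, 1]; the package analyses
them at their native sample rate (no resampling — frequencies, not bin
indices, are the contract). The spectral representation is a Hann-windowed
magnitude STFT in dB re full-scale sine, with window `fft_size` = 256
samples and `fft_overlap` = 0.87, giving hop = round(256 × 0.13) = 33
samples (85.9 µs at 384 kHz) and 1.5 kHz bins — short enough to resolve
0.2 ms events, narrow enough to separate the seven 5 kHz scan bands. Only
frames lying fully inside the signal are produced; values are clamped at
`db_floor` = −120 dB. The window length is a package choice: it is not
constrained by the detector's published operating point, which fixes only
the overlap.

Band restriction is STFT-bin masking over the half-open interval
[f_lo, f_hi); the highest band closes at Nyquist. The seven default bands
tile 15–50 kHz contiguously (15–20 … 45–50 kHz), the only tiling of
5 kHz bands consistent with scanning that range with seven bands.

### Noise floor

Each band maintains per-bin background statistics from past frames: an
exponential moving average m of the dB power and an EMA second moment, both
with weight w = hop/NWS (NWS = 20 ms), initialised from the per-bin means
of the first NWS of frames. The floor handed to the trigger is

    floor = m + k·s,   s = sqrt(EMA[x²] − m²),   k = 2.5 by default.

The k·s margin makes the detector constant-false-alarm-rate (CFAR): the
dB power of a single STFT bin of stationary noise is the log of an
(approximately) exponential variate and fluctuates with σ ≈ 5.6 dB, so a
fixed few-dB margin over the *mean* would trigger on a large fraction of
noise frames regardless of noise level. With k = 2.5 the floor sits near
the upper envelope of the noise and the per-frame false-trigger
probability under exponential statistics, exp(−10^((k·5.57 + threshold −
2.51)/10)), is below 1e-9 — effectively zero events per minute — while any
signal standing `threshold` dB above that envelope still triggers. k was
fixed from this tail budget, not fitted. All SNR values in the package
(detector output, synthesis targets, reported ranges) are defined against
this floor; like any detector-relative SNR they are specific to the
analysis parameters.

While an event is open the floor is frozen; if an event persists beyond
`duration_thr` = 80 ms, background monitoring resumes frame by frame so a
stuck trigger cannot permanently freeze the estimate. The EMA recursions
are evaluated with `scipy.signal.lfilter` over noise stretches and
per-frame during events; the two paths apply identical arithmetic, so
detection output is bit-reproducible.

### Event extraction

A frame triggers when any in-band bin exceeds its floor by `threshold` =
5 dB. The event's frame track follows the in-band argmax bin (ties broken
toward the lower frequency). Forward extension continues while the in-band
peak stays more than `snr_thr` = 4 dB above the frozen floor and within
`end_thr` = 20 dB of the running event maximum; an additional termination
fires when the descent angle atan(ΔdB/frame) of the 3-frame-smoothed peak
amplitude exceeds `angle_thr` = 40° once the power has fallen `end_thr`
below the maximum. Backward extension applies the same SNR gate and the
`start_thr` = 20 dB dynamic-range gate using the pre-trigger floor values.
Event SNR is the maximum per-frame exceedance over the frozen floor.
The published operating point does not specify the termination mechanics;
the smoothing and angle conventions here are explicit, configurable
stand-ins. Detections closer than `min_tbe` = 2 ms (start-to-end gap)
merge with concatenated tracks and maximum SNR; merged events shorter than
`min_dur` = 0.2 ms are discarded. Bands are processed independently;
events are never deduplicated across bands.

Degenerate inputs: a recording shorter than one FFT window yields an empty
spectrogram and no detections, not an error; silence stays at the dB floor
and triggers nothing.

## Window features

Windows are four consecutive detections within one band (stride 1, n
detections → n − 3 windows); windows never span bands, because an
inter-pulse interval across two independent detectors is not physically
meaningful. IPIs are start-to-start in ms. Regressions of IPI (3 points)
and SNR (4 points) on the signal index 1..n use ordinary least squares;
SNRr is the adjusted R² 1 − (1 − R²)·3/2, set to 0 when the SNR values are
constant (the statistic is undefined there and 0 is the least-informative
imputation). Standard deviations and variances are sample statistics
(n − 1). IPIshannon is the Gaussian differential entropy ½·ln(2πe·σ²) with
σ in seconds, floored at 1 ns: on three intervals this is the standard
entropy measure that can reach the deeply negative values (< −10 nats at
σ < ~11 µs) used by the training outlier rule; a discrete
normalised-proportion entropy is bounded in [0, ln 3] and could not.
Smoothness is the RMS residual (kHz) of the linear time–frequency fit;
a mean-absolute-second-difference alternative is available. Tracks of
length ≤ 2 have smoothness 0 and single-point tracks slope 0.

## Classifier

Training applies, in order: removal of extreme outliers among non-buzz
windows (SNRvar > 3000 or IPIshannon < −10, read as a disjunction of two
flags — a conjunctive mode is available); z-scoring of all 21 predictors
(sample sd); PCA on the scaled features with per-class PC1 quantile
stratification at the 20/40/60/80 percentiles; seeded sampling of 150
windows per (class × stratum) giving exactly 1500 rows; a stratified 80/20
split for a threshold sweep of held-out accuracy over 0.5–1.0 in steps of
0.05; and a final 500-tree random forest rebuilt on the entire balanced
set. Forest size and bootstrap defaults are package choices recorded in
the bundle. The shipped predictors are IPIsd, duravg and SNRavg — the
low-correlation variables that dominate PC1 separation of buzz from
non-buzz — and `select_features` reproduces that choice by greedy |PC1
loading| ranking with an r > 0.6 correlation cutoff. Window probability is
the forest's positive vote fraction; the decision threshold (default 0.8)
is inclusive.

A recording is *buzz* when at least one window is positive; the optional
voting rule raises that bar (default 2 when enabled), and the optional
prescan skips files with no echolocation-like signal in a single broadband
15–50 kHz pass with min_dur relaxed to 1 ms. Multiple buzzes in one
recording are counted by grouping positive windows separated by more than
`buzz_gap_threshold` = 1 s (the gap value is a package default; it is
configurable). Per-file processing is independent, so parallel and
sequential classification agree exactly.

## Synthetic recordings

The generator's defaults define the study conditions for all end-to-end
checks. Feeding buzzes are trains of 30 downward linear-FM pulses
(raised-cosine envelope) whose IPI shrinks geometrically 15 → 4 ms — a
terminal rate of 250 pulses/s, in the > 100 pulses/s regime — and whose
durations shrink 2 → 0.5 ms; high-guild buzzes sweep 48 → 36 kHz, low-guild
34 → 24 kHz (terminal frequency below 30 kHz). Search-phase sequences use
3–8 ms pulses at 100 ms intervals with ≤ 5 % jitter whose sign alternates
between consecutive intervals, so interval spread never collapses to
buzz-like values; broadband clicks are 0.15 ms noise bursts at irregular
5–50 ms gaps (the documented false-positive hazard); noise recordings are
stationary white (optionally pink) noise. Corpus SNRs are drawn uniformly
from 8–25 dB, spanning faint-to-strong pulses around the detector's
4–5 dB gates; recordings are 2 s at 384 kHz with a white-noise bed of
σ = 0.005 (≈ −46 dBFS), comfortably above 16-bit quantisation.

Pulse amplitudes are calibrated so the pulse's peak STFT bin sits exactly
`snr_db` above the recording's own measured CFAR floor at that bin — the
same convention the detector reports — which makes cross-module SNR
calibration testable (detected SNR within ±3 dB of injected for isolated
in-band bursts). Broadband clicks are amplitude-capped at 0.5 full scale
to avoid clipping, so their effective SNR may fall short of the request.

What the generator does *not* emulate: species-specific call shapes and
harmonics, atmospheric attenuation, echoes and acoustic scattering,
recorder/microphone frequency responses, and overlapping bats. Passing
tests therefore demonstrate that the pipeline recovers the stated pulse
phenomenology under calibrated noise, not field-grade performance; on real
recordings the detector-level class overlap is larger (detection gaps
inflate buzz IPI statistics), which is why the classifier, not the
detector, carries the final decision.

## Problem sizes and numerical choices

End-to-end checks train on a 200-recording corpus (100 buzz / 100
non-buzz, non-buzz cycling search/clicks/noise) and evaluate on a disjoint
100-recording corpus — sizes chosen to exercise the full procedure,
including the exact 1500-row balancing, in minutes on one CPU. Detector
recall is measured on 200 injected constant-frequency bursts (0.5–2 ms,
SNR 15–30 dB) with ±1 ms onset tolerance; false alarms on 60 s of
stationary white noise. Spectrogram power is stored as float32 (µdB
rounding); all detector state arithmetic is float64. All randomness flows
from explicit integer seeds through `numpy.random.default_rng` /
`SeedSequence`, and manifests, audio, detections and classifications are
bit-reproducible under a fixed seed.

## Known limitations

* The detector's event-termination details (angle smoothing, gate
  conventions) are stand-ins for an incompletely specified upstream
  algorithm; downstream features are robust to these choices but exact
  per-event boundaries are convention-dependent.
* Cross-band duplicate suppression is deliberately absent; a pulse
  sweeping several bands yields one detection per band, and window
  features are band-local by construction.
* The CFAR floor adapts within NWS = 20 ms; impulsive but *dense*
  interference (duty cycle approaching 1 within a band) can elevate the
  floor and mask genuine pulses.
* Recording-level aggregation defaults to any-window, which on long noisy
  files trades specificity for sensitivity; enable voting or the prescan
  for noisy deployments.
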