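# batbuzz

Automated detection of **feeding buzzes** — the rapid terminal-phase
echolocation pulse trains (> 100 pulses/s, sub-millisecond durations) bats
emit while capturing prey — in full-spectrum ultrasonic WAV recordings.
Feeding buzzes index foraging activity and hence habitat quality, but their
short, faint, highly directional pulses are routinely missed by detectors
tuned for the louder search-phase calls that species classifiers target.
`batbuzz` is aimed at bat researchers and acoustic-survey practitioners who
want buzz counts out of the same recordings they already collect.

## Method

1. **Narrow-band adaptive-threshold detection.** A Hann-windowed STFT
   (256 samples, 87 % overlap at 384 kHz) is scanned one 5 kHz band at a
   time over seven bands tiling 15–50 kHz. Working in narrow bands lowers
   the local noise floor and exposes weak buzz pulses. Each band keeps a
   per-bin running noise estimate (EMA of the dB power plus a CFAR margin
   of *k*·σ, smoothing window NWS = 20 ms); a frame triggers an event when
   its in-band peak rises more than *threshold* = 5 dB above the floor, and
   the event extends over contiguous frames within the SNR (4 dB) and
   dynamic-range (20 dB) gates, with a 40° amplitude-descent termination
   rule. Events closer than min_TBE = 2 ms merge; events shorter than
   min_dur = 0.2 ms are dropped.
2. **Moving-window features.** Over every four consecutive detections in a
   band, 21 variables summarise the inter-pulse interval
   (IPIslope, IPIint, IPImin, IPImax, IPIavg, IPIsd, IPIvar, IPIshannon),
   the SNR (SNRr, SNRmin, SNRmax, SNRavg, SNRsd, SNRvar), the FM slope
   (slopeavg, slopemin, slopesd), duration (duravg, dursd) and the
   time–frequency smoothness (smoothavg, smoothvar).
3. **Balanced random-forest classification.** Extreme non-buzz outliers
   (SNRvar > 3000 or IPIshannon < −10) are removed, features are z-scored,
   PC1 scores of each class are split into five quantiles and 150 windows
   are drawn per stratum (1500 in total), and a 500-tree random forest is
   trained on the dominant low-correlation predictors IPIsd, duravg and
   SNRavg. A recording is labelled *buzz* when at least one window (or an
   optional vote count) reaches the 0.8 decision threshold; a 1 s gap rule
   groups positive windows into separate buzzes.
4. **Synthetic ground truth.** A seeded generator synthesizes feeding
   buzzes, search-phase sequences, broadband clicks and stationary noise
   with exact pulse times and calibrated SNR, so every stage is testable
   without field recordings.

## Worked example

```python
from batbuzz import scan_bands
from batbuzz.synth import BuzzSpec, synth_buzz_recording

rec, onsets = synth_buzz_recording(BuzzSpec(snr_db=20.0), seed=3)
for band, dets in scan_bands(rec).items():
    if dets:
        print(band.label, len(dets))
```

prints (`examples/01_synthesize_and_detect.py` shows the full table):

```
35-40kHz 30
40-45kHz 30
45-50kHz 30
```

— all 30 injected pulses recovered in each band the 48→36 kHz sweep
crosses, with median detected SNR 19.5 dB in the core band against the
injected 20 dB. The remaining examples walk through window features
(`02`), training (`03`, held-out window accuracy 0.99 at the 0.8
threshold on a 40-file corpus) and evaluation (`04`, balanced accuracy
0.95 on a 20-file corpus).

The same pipeline is scriptable from the shell:

```bash
batbuzz synth --n-buzz 20 --n-nonbuzz 20 --out corpus --seed 1
batbuzz featurize corpus --manifest corpus/manifest.csv --out windows.csv
batbuzz train windows.csv --out model.joblib
batbuzz classify corpus model.joblib --out preds.csv
batbuzz evaluate preds.csv corpus/manifest.csv --out metrics.json --roc roc.csv
```

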