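"""Per-signal descriptors and the 21 moving-window variables.

Feeding buzzes are characterised less by any single pulse than by how pulse
timing, strength and shape evolve over short runs of consecutive
detections.  A moving window of four consecutive detections (stride 1,
always within one frequency band) yields three inter-pulse intervals (IPI,
start-to-start) and four values of SNR, FM slope, duration and smoothness,
from which 21 summary variables are computed.

Conventions:

* sd/var are sample statistics (n-1 denominator);
* IPIshannon is the Gaussian differential entropy 0.5*ln(2*pi*e*sigma^2)
  with sigma in seconds (floored at 1e-9 s), the only standard "entropy of
  the IPI" on three values that can reach the < -10 range used as an
  extreme-outlier flag downstream;
* regressions on the IPI (3 points) and SNR (4 points) use ordinary least
  squares against the signal index 1..n;
* SNRr is the adjusted R-squared 1 - (1 - R^2) * 3/2, defined as 0 when the
  SNR values have zero variance;
* smoothness is the RMS residual of the linear time-frequency fit (kHz); a
  mean-absolute-second-difference alternative is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .audio import FrequencyBand
from .detector import Detection

__all__ = [
    "FEATURE_NAMES",
    "SignalDescriptors",
    "WindowFeatures",
    "interpulse_intervals",
    "track_slope_smoothness",
    "signal_descriptors",
    "window_features",
    "sliding_windows",
    "windows_to_frame",
]

FEATURE_NAMES: tuple[str, ...] = (
    "IPIslope", "IPIint", "IPImin", "IPImax", "IPIavg", "IPIsd", "IPIvar",
    "IPIshannon",
    "SNRr", "SNRmin", "SNRmax", "SNRavg", "SNRsd", "SNRvar",
    "slopeavg", "slopemin", "slopesd",
    "duravg", "dursd",
    "smoothavg", "smoothvar",
)

_SIGMA_FLOOR_S = 1e-9  # guards the log when all IPIs coincide


@dataclass(frozen=True)
class SignalDescriptors:
    """Scalar descriptors of one detection."""

    duration: float    # ms
    snr: float         # dB
    slope: float       # kHz/ms
    smoothness: float  # kHz
    start_time: float  # s


@dataclass(frozen=True)
class WindowFeatures:
    """The 21 variables of one four-detection moving window."""

    IPIslope: float
    IPIint: float
    IPImin: float
    IPImax: float
    IPIavg: float
    IPIsd: float
    IPIvar: float
    IPIshannon: float
    SNRr: float
    SNRmin: float
    SNRmax: float
    SNRavg: float
    SNRsd: float
    SNRvar: float
    slopeavg: float
    slopemin: float
    slopesd: float
    duravg: float
    dursd: float
    smoothavg: float
    smoothvar: float
    window_start_time: float
    band: FrequencyBand

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def interpulse_intervals(detections: Sequence[Detection]) -> np.ndarray:
    """Start-to-start intervals in ms between consecutive detections."""
    starts = np.array([d.start_time for d in detections], dtype=np.float64)
    if np.any(np.diff(starts) < 0):
        raise ValueError("detections must be sorted by start_time")
    if starts.size < 2:
        return np.empty(0)
    return np.diff(starts) * 1000.0


def track_slope_smoothness(
    freq_track: np.ndarray,
    frame_times: np.ndarray,
    smoothness_mode: str = "rms_residual",
) -> tuple[float, float]:
    """Least-squares slope (kHz/ms) and roughness (kHz) of a frequency track.

    Slope is 0 for single-point tracks; smoothness is 0 for tracks of
    length <= 2 (a line fits two points exactly).
    """
    f = np.asarray(freq_track, dtype=np.float64) / 1000.0           # kHz
    t = np.asarray(frame_times, dtype=np.float64)
    t = (t - t[0]) * 1000.0                                          # ms
    n = f.size
    if n < 2:
        return 0.0, 0.0
    coeffs = np.polyfit(t, f, 1)
    slope = float(coeffs[0])
    if n <= 2:
        return slope, 0.0
    if smoothness_mode == "rms_residual":
        resid = f - np.polyval(coeffs, t)
        smooth = float(np.sqrt(np.mean(resid ** 2)))
    elif smoothness_mode == "abs_second_diff":
        smooth = float(np.mean(np.abs(np.diff(f, 2))))
    else:
        raise ValueError(f"unknown smoothness mode: {smoothness_mode}")
    return slope, smooth


def signal_descriptors(detection: Detection) -> SignalDescriptors:
    slope, smooth = track_slope_smoothness(detection.freq_track, detection.frame_times)
    return SignalDescriptors(
        duration=detection.duration,
        snr=detection.snr,
        slope=slope,
        smoothness=smooth,
        start_time=detection.start_time,
    )


def _ols_index(y: np.ndarray) -> tuple[float, float, float]:
    """OLS of y on index 1..n: (slope, intercept, r_squared)."""
    n = y.size
    x = np.arange(1, n + 1, dtype=np.float64)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    syy = np.sum((y - ym) ** 2)
    r2 = 0.0 if syy == 0.0 else (sxy ** 2) / (sxx * syy)
    return float(slope), float(intercept), float(r2)


def window_features(window: Sequence[Detection]) -> WindowFeatures:
    """Compute the 21 variables over exactly four consecutive detections."""
    if len(window) != 4:
        raise ValueError(f"a moving window holds exactly 4 detections, got {len(window)}")
    desc = [signal_descriptors(d) for d in window]
    ipis = interpulse_intervals(window)                      # 3 values, ms
    snrs = np.array([d.snr for d in desc])
    slopes = np.array([d.slope for d in desc])
    durs = np.array([d.duration for d in desc])
    smooths = np.array([d.smoothness for d in desc])

    ipi_slope, ipi_int, _ = _ols_index(ipis)
    ipi_sd = float(np.std(ipis, ddof=1))
    sigma_s = max(ipi_sd * 1e-3, _SIGMA_FLOOR_S)
    ipi_shannon = 0.5 * math.log(2.0 * math.pi * math.e * sigma_s ** 2)

    snr_var = float(np.var(snrs, ddof=1))
    if snr_var == 0.0:
        snr_r = 0.0
    else:
        _, _, r2 = _ols_index(snrs)
        snr_r = 1.0 - (1.0 - r2) * 3.0 / 2.0
    snr_sd = float(np.std(snrs, ddof=1))

    return WindowFeatures(
        IPIslope=ipi_slope,
        IPIint=ipi_int,
        IPImin=float(ipis.min()),
        IPImax=float(ipis.max()),
        IPIavg=float(ipis.mean()),
        IPIsd=ipi_sd,
        IPIvar=ipi_sd ** 2,
        IPIshannon=ipi_shannon,
        SNRr=snr_r,
        SNRmin=float(snrs.min()),
        SNRmax=float(snrs.max()),
        SNRavg=float(snrs.mean()),
        SNRsd=snr_sd,
        SNRvar=snr_sd ** 2,
        slopeavg=float(slopes.mean()),
        slopemin=float(slopes.min()),
        slopesd=float(np.std(slopes, ddof=1)),
        duravg=float(durs.mean()),
        dursd=float(np.std(durs, ddof=1)),
        smoothavg=float(smooths.mean()),
        smoothvar=float(np.var(smooths, ddof=1)),
        window_start_time=window[0].start_time,
        band=window[0].band,
    )


def sliding_windows(detections: Sequence[Detection]) -> list[WindowFeatures]:
    """Stride-1 windows of four consecutive detections (band-local).

    n detections yield max(0, n - 3) windows.
    """
    dets = list(detections)
    return [window_features(dets[i:i + 4]) for i in range(max(0, len(dets) - 3))]


def windows_to_frame(
    per_band: dict[FrequencyBand, list[Detection]],
    source_id: str = "",
    label: str | None = None,
) -> pd.DataFrame:
    """Window-feature table for one recording: one row per moving window."""
    rows = []
    for band in sorted(per_band, key=lambda b: b.f_lo):
        for wf in sliding_windows(per_band[band]):
            row = wf.as_dict()
            row.update(
                source_id=source_id,
                band_lo=band.f_lo,
                band_hi=band.f_hi,
                window_start_s=wf.window_start_time,
            )
            if label is not None:
                row["label"] = label
            rows.append(row)
    cols = list(FEATURE_NAMES) + ["source_id", "band_lo", "band_hi", "window_start_s"]
    if label is not None:
        cols.append("label")
    return pd.DataFrame(rows, columns=cols)
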