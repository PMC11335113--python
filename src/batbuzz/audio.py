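"""WAV input/output and short-time spectral analysis for ultrasonic recordings.

The spectral representation used throughout the package is a Hann-windowed
magnitude STFT expressed in dB re full-scale sine: a sinusoid of amplitude
1.0 lying exactly on a bin centre reads 0 dB at that bin.  Frequency-band
restriction is performed by masking STFT bins, not by time-domain filtering;
the detector operates on the FFT spectrum, so the two are equivalent for
peak detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import rfft, rfftfreq
from scipy.io import wavfile
from scipy.signal import get_window

log = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "Spectrogram",
    "FrequencyBand",
    "BandError",
    "read_wav",
    "write_wav",
    "compute_spectrogram",
    "band_bins",
]


class BandError(ValueError):
    """A frequency band selects no spectrogram bins or lies above Nyquist."""


@dataclass(frozen=True)
class FrequencyBand:
    """Half-open frequency interval [f_lo, f_hi) in Hz."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(f"invalid band: [{self.f_lo}, {self.f_hi}) Hz")

    @property
    def label(self) -> str:
        return f"{self.f_lo / 1000:g}-{self.f_hi / 1000:g}kHz"

    def contains(self, freq_hz: float) -> bool:
        return self.f_lo <= freq_hz < self.f_hi


@dataclass
class Recording:
    """Mono waveform with amplitudes in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("Recording needs at least one sample in a 1-D array")
        if int(self.sample_rate) <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        self.sample_rate = int(self.sample_rate)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Recording contains non-finite amplitudes")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def nyquist(self) -> float:
        return self.sample_rate / 2.0


@dataclass
class Spectrogram:
    """Frame x frequency-bin power matrix in dB re full-scale sine.

    ``power_db`` is stored as float32: dB values well exceed the precision
    needed by the detector, and long recordings (minutes at 384 kHz with 87 %
    overlap) would otherwise not fit comfortably in memory.
    """

    power_db: np.ndarray
    frame_times: np.ndarray
    bin_freqs: np.ndarray
    fft_size: int
    overlap_fraction: float
    sample_rate: int
    hop: int = field(init=False)

    def __post_init__(self) -> None:
        self.hop = max(1, int(round(self.fft_size * (1.0 - self.overlap_fraction))))
        n_frames = self.power_db.shape[0]
        if n_frames != self.frame_times.size:
            raise ValueError("frame_times length does not match power matrix")
        if n_frames > 1:
            steps = np.diff(self.frame_times)
            expected = self.hop / self.sample_rate
            if not np.allclose(steps, expected, rtol=1e-9, atol=1e-12):
                raise ValueError("frame_times are not uniformly spaced at one hop")
        if not np.all(np.diff(self.bin_freqs) > 0):
            raise ValueError("bin_freqs must be strictly increasing")
        if n_frames and not np.all(np.isfinite(self.power_db)):
            raise ValueError("power_db contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.power_db.shape[0]

    @property
    def hop_s(self) -> float:
        return self.hop / self.sample_rate

    @property
    def nyquist(self) -> float:
        return self.sample_rate / 2.0


def read_wav(path) -> Recording:
    """Read a PCM or IEEE-float WAV file as a normalized mono Recording.

    Multichannel files keep only the first channel.  Integer formats are
    scaled by the full-scale magnitude of their type (an int16 value of
    32767 maps to 32767/32768).
    """
    rate, data = wavfile.read(path)
    if data.size == 0:
        raise ValueError(f"{path}: WAV file contains no samples")
    if data.ndim > 1:
        log.info("%s: %d channels, keeping the first", path, data.shape[1])
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return Recording(samples=samples, sample_rate=int(rate), source_id=str(path))


def write_wav(recording: Recording, path) -> None:
    """Write a Recording as 16-bit PCM.  Amplitudes beyond [-1, 1] are clipped."""
    x = recording.samples
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak > 1.0:
        log.warning("%s: amplitude overflow (peak %.3f), clipping", path, peak)
        x = np.clip(x, -1.0, 1.0)
    pcm = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, recording.sample_rate, pcm)


def compute_spectrogram(
    recording: Recording,
    fft_size: int = 256,
    overlap_fraction: float = 0.87,
    db_floor: float = -120.0,
) -> Spectrogram:
    """Hann-windowed magnitude STFT in dB, clamped below at ``db_floor``.

    hop = round(fft_size * (1 - overlap_fraction)); only frames lying fully
    inside the signal are produced, so a recording shorter than one window
    yields an empty (0-frame) spectrogram.
    """
    if fft_size < 32 or fft_size & (fft_size - 1):
        raise ValueError(f"fft_size must be a power of two >= 32, got {fft_size}")
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError(f"overlap_fraction must lie in [0, 1), got {overlap_fraction}")
    fs = recording.sample_rate
    hop = max(1, int(round(fft_size * (1.0 - overlap_fraction))))
    x = recording.samples
    n = x.size
    if n < fft_size:
        empty = np.empty((0, fft_size // 2 + 1), dtype=np.float32)
        return Spectrogram(empty, np.empty(0), rfftfreq(fft_size, 1.0 / fs),
                           fft_size, overlap_fraction, fs)

    starts = np.arange(0, n - fft_size + 1, hop)
    win = get_window("hann", fft_size, fftbins=True)
    # Amplitude calibration: a full-scale on-bin sine has |X| = sum(win)/2.
    scale = np.float32(2.0 / win.sum())
    mag_floor = np.float32(10.0 ** (db_floor / 20.0))

    # float32 throughout: ~1e-6 dB rounding, far below any detector margin
    views = sliding_window_view(x.astype(np.float32), fft_size)[::hop]
    win32 = win.astype(np.float32)
    out = np.empty((starts.size, fft_size // 2 + 1), dtype=np.float32)
    chunk = 8192  # frames per batch, bounds the transient windowed matrix
    for lo in range(0, starts.size, chunk):
        frames = views[lo:lo + chunk] * win32
        mag = np.abs(rfft(frames, axis=1)) * scale
        np.maximum(mag, mag_floor, out=mag)
        np.log10(mag, out=mag)
        mag *= 20.0
        np.maximum(mag, np.float32(db_floor), out=mag)  # exact floor after rounding
        out[lo:lo + chunk] = mag

    frame_times = (starts + fft_size / 2.0) / fs
    return Spectrogram(out, frame_times, rfftfreq(fft_size, 1.0 / fs),
                       fft_size, overlap_fraction, fs)


def band_bins(spectrogram: Spectrogram, band: FrequencyBand) -> np.ndarray:
    """Indices of spectrogram bins with f_lo <= freq < f_hi (half-open)."""
    if band.f_lo < 0 or band.f_hi > spectrogram.nyquist + 1e-9:
        raise BandError(
            f"band {band.label} outside [0, {spectrogram.nyquist:g}] Hz"
        )
    freqs = spectrogram.bin_freqs
    sel = (freqs >= band.f_lo) & (freqs < band.f_hi)
    if band.f_hi >= spectrogram.nyquist - 1e-9:
        sel |= freqs == spectrogram.nyquist  # close the interval at Nyquist
    idx = np.nonzero(sel)[0]
    if idx.size == 0:
        raise BandError(f"band {band.label} selects no spectrogram bins")
    return idx
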