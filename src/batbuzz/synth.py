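"""Seeded synthesis of labelled ultrasonic recordings with ground truth.

The generator emulates the acoustic content a full-spectrum bat recorder
captures in the 15-50 kHz band of interest:

* **feeding buzzes** — trains of downward linear-FM pulses whose inter-pulse
  interval shrinks geometrically into the > 100 pulses/s regime and whose
  duration shrinks toward the sub-millisecond terminal phase;
* **search-phase sequences** — longer (3-8 ms) FM pulses at regular 80-120 ms
  intervals with a small alternating-sign jitter;
* **broadband clicks** — very short wideband bursts at irregular intervals,
  the documented false-positive hazard for buzz detectors;
* **stationary noise** — white (optionally pink) noise only.

Every pulse is mixed at a target SNR defined exactly as the detector
measures it: peak STFT-bin power of the pulse relative to the per-bin CFAR
noise floor (EMA mean + k * EMA std of the dB power) of the recording's own
noise bed, at the default analysis parameters.  This makes cross-module SNR
calibration a testable contract rather than a hope.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .audio import Recording, compute_spectrogram, write_wav
from .detector import DetectorParams

__all__ = [
    "BuzzSpec",
    "CorpusManifest",
    "synth_pulse",
    "synth_buzz_recording",
    "synth_nonbuzz_recording",
    "synth_corpus",
    "synth_burst_recording",
    "file_sha256",
]

DEFAULT_SAMPLE_RATE = 384_000
DEFAULT_NOISE_SIGMA = 0.005
_NONBUZZ_SUBTYPES = ("search_phase", "clicks", "noise")


@dataclass(frozen=True)
class BuzzSpec:
    """Acoustic parameters of one synthetic feeding buzz."""

    n_pulses: int = 30
    ipi_start: float = 15.0       # ms, first inter-pulse interval
    ipi_end: float = 4.0          # ms, terminal interval (geometric interpolation)
    pulse_dur_start: float = 2.0  # ms
    pulse_dur_end: float = 0.5    # ms
    f_start: float = 48.0         # kHz, sweep onset frequency of each pulse
    f_end: float = 36.0           # kHz, sweep terminal frequency (downward FM)
    snr_db: float = 20.0          # per-pulse peak-bin SNR over the noise floor
    onset: float = 0.5            # s, time of the first pulse

    def __post_init__(self) -> None:
        if self.n_pulses < 2:
            raise ValueError("a buzz needs at least 2 pulses")
        if not (0 < self.ipi_end <= self.ipi_start):
            raise ValueError("require 0 < ipi_end <= ipi_start")
        if self.ipi_end < 3.0:
            raise ValueError("ipi_end below the 3 ms floor")
        if self.f_end >= self.f_start:
            raise ValueError("buzz pulses sweep downward: f_end < f_start")

    @property
    def terminal_rate(self) -> float:
        """Instantaneous pulse rate at the end of the buzz, pulses/s."""
        return 1000.0 / self.ipi_end

    def ipis_ms(self) -> np.ndarray:
        n = self.n_pulses - 1
        if n == 1:
            return np.array([self.ipi_end])
        frac = np.arange(n) / (n - 1)
        return self.ipi_start * (self.ipi_end / self.ipi_start) ** frac

    def durations_ms(self) -> np.ndarray:
        return np.linspace(self.pulse_dur_start, self.pulse_dur_end, self.n_pulses)

    @property
    def span_s(self) -> float:
        return (self.ipis_ms().sum() + self.durations_ms()[-1]) / 1000.0


def synth_pulse(f_start: float, f_end: float, dur: float,
                sample_rate: int = DEFAULT_SAMPLE_RATE) -> np.ndarray:
    """Linear-FM cosine sweep (kHz in, ms in) with a raised-cosine envelope.

    Peak amplitude is 1 before any mixing; the envelope ends at exactly zero.
    """
    if dur <= 0:
        raise ValueError("pulse duration must be positive")
    nyq_khz = sample_rate / 2000.0
    if max(f_start, f_end) >= nyq_khz:
        raise ValueError(f"pulse frequency {max(f_start, f_end)} kHz >= Nyquist {nyq_khz} kHz")
    n = int(round(dur * 1e-3 * sample_rate))
    if n < 2:
        raise ValueError("pulse shorter than two samples")
    t = np.arange(n) / sample_rate
    dur_s = dur * 1e-3
    f0, f1 = f_start * 1000.0, f_end * 1000.0
    phase = 2.0 * np.pi * (f0 * t + (f1 - f0) / (2.0 * dur_s) * t ** 2)
    envelope = get_window("hann", n, fftbins=False)  # symmetric: zero ends
    return np.cos(phase) * envelope


def _analysis_params() -> DetectorParams:
    return DetectorParams()


def _noise_floor_reference(noise: np.ndarray, sample_rate: int,
                           params: DetectorParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin CFAR floor (dB) of a noise bed, from its first <=0.25 s."""
    n = min(noise.size, int(0.25 * sample_rate))
    spec = compute_spectrogram(Recording(noise[:n], sample_rate),
                               fft_size=params.fft_size,
                               overlap_fraction=params.fft_overlap,
                               db_floor=params.db_floor)
    p = spec.power_db.astype(np.float64)
    floor = p.mean(axis=0) + params.floor_k * p.std(axis=0)
    return floor, spec.bin_freqs


def _pulse_peak(pulse: np.ndarray, sample_rate: int,
                params: DetectorParams) -> tuple[float, int]:
    """Peak STFT power (dB) of a unit pulse and the bin where it occurs."""
    pad = np.zeros(params.fft_size)
    spec = compute_spectrogram(Recording(np.concatenate([pad, pulse, pad]), sample_rate),
                               fft_size=params.fft_size,
                               overlap_fraction=params.fft_overlap,
                               db_floor=params.db_floor)
    flat = int(np.argmax(spec.power_db))
    frame, bin_ = np.unravel_index(flat, spec.power_db.shape)
    return float(spec.power_db[frame, bin_]), int(bin_)


def _mix_pulse(samples: np.ndarray, pulse: np.ndarray, onset_s: float,
               floor_db: np.ndarray, snr_db: float, sample_rate: int,
               params: DetectorParams) -> None:
    """Scale a unit pulse to the target SNR and add it in place."""
    peak_db, bin_ = _pulse_peak(pulse, sample_rate, params)
    amp = 10.0 ** ((floor_db[bin_] + snr_db - peak_db) / 20.0)
    # broadband events need large time-domain gain to reach a target peak-bin
    # SNR; cap the mixed amplitude well below full scale to avoid clipping
    peak_abs = float(np.max(np.abs(pulse)))
    if amp * peak_abs > 0.5:
        amp = 0.5 / peak_abs
    i0 = int(round(onset_s * sample_rate))
    i1 = min(i0 + pulse.size, samples.size)
    samples[i0:i1] += amp * pulse[: i1 - i0]


def _noise_bed(rng: np.random.Generator, n: int, sigma: float,
               color: str = "white") -> np.ndarray:
    noise = rng.normal(0.0, sigma, n)
    if color == "pink":
        # -3 dB/octave shaping via cumulative filtering in the Fourier domain
        spec = np.fft.rfft(noise)
        f = np.fft.rfftfreq(n)
        f[0] = f[1]
        spec /= np.sqrt(f / f[1])
        noise = np.fft.irfft(spec, n)
        noise *= sigma / noise.std()
    elif color != "white":
        raise ValueError(f"unknown noise color: {color}")
    return noise


def synth_buzz_recording(
    spec: BuzzSpec,
    noise_floor: float = DEFAULT_NOISE_SIGMA,
    duration: float = 2.0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    noise_color: str = "white",
) -> tuple[Recording, np.ndarray]:
    """Synthesize one feeding-buzz recording; returns exact pulse onsets (s)."""
    if spec.onset + spec.span_s > duration:
        raise ValueError(
            f"buzz spanning {spec.span_s:.3f} s at onset {spec.onset:.3f} s "
            f"does not fit in {duration} s"
        )
    params = _analysis_params()
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    samples = _noise_bed(rng, n, noise_floor, noise_color)
    floor_db, _ = _noise_floor_reference(samples, sample_rate, params)

    onsets = spec.onset + np.concatenate([[0.0], np.cumsum(spec.ipis_ms())]) / 1000.0
    for onset_s, dur_ms in zip(onsets, spec.durations_ms()):
        pulse = synth_pulse(spec.f_start, spec.f_end, dur_ms, sample_rate)
        _mix_pulse(samples, pulse, onset_s, floor_db, spec.snr_db, sample_rate, params)
    rec = Recording(samples, sample_rate, source_id=f"buzz_seed{seed}")
    return rec, onsets


def synth_nonbuzz_recording(
    subtype: str,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    duration: float = 2.0,
    noise_floor: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
    snr_db: float = 20.0,
    guild: str = "high",
    base_ipi_ms: float = 100.0,
    noise_color: str = "white",
) -> tuple[Recording, np.ndarray]:
    """Synthesize a non-buzz recording; returns event onset times (s).

    search_phase: 3-8 ms FM pulses at base_ipi_ms with <= 5 % jitter whose
    sign alternates between consecutive intervals (regular sequences in real
    recordings wobble around the repetition rate rather than drifting).
    clicks: 0.15 ms broadband bursts at irregular 5-50 ms intervals.
    noise: stationary noise only.
    """
    if subtype not in _NONBUZZ_SUBTYPES:
        raise ValueError(f"unknown subtype {subtype!r}; expected one of {_NONBUZZ_SUBTYPES}")
    params = _analysis_params()
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    samples = _noise_bed(rng, n, noise_floor, noise_color)

    if subtype == "noise":
        return (Recording(samples, sample_rate, source_id=f"noise_seed{seed}"),
                np.empty(0))

    floor_db, _ = _noise_floor_reference(samples, sample_rate, params)
    onsets: list[float] = []
    if subtype == "search_phase":
        f_hi, f_lo = (45.0, 31.0) if guild == "high" else (32.0, 20.0)
        t = 0.15
        k = 0
        while True:
            dur_ms = float(rng.uniform(3.0, 8.0))
            if t + dur_ms / 1000.0 > duration - 0.05:
                break
            pulse = synth_pulse(f_hi, f_lo, dur_ms, sample_rate)
            _mix_pulse(samples, pulse, t, floor_db, snr_db, sample_rate, params)
            onsets.append(t)
            jitter = 0.04 * (-1.0 if k % 2 else 1.0) + float(rng.uniform(-0.01, 0.01))
            t += base_ipi_ms * (1.0 + jitter) / 1000.0
            k += 1
    else:  # clicks
        t = 0.1
        while True:
            dur_ms = 0.15
            if t + dur_ms / 1000.0 > duration - 0.05:
                break
            burst = rng.normal(0.0, 1.0, int(round(dur_ms * 1e-3 * sample_rate)))
            burst *= get_window("hann", burst.size, fftbins=False)
            burst /= np.max(np.abs(burst))
            _mix_pulse(samples, burst, t, floor_db, snr_db, sample_rate, params)
            onsets.append(t)
            t += float(rng.uniform(5.0, 50.0)) / 1000.0
    rec = Recording(samples, sample_rate, source_id=f"{subtype}_seed{seed}")
    return rec, np.asarray(onsets)


@dataclass
class CorpusManifest:
    """Ground-truth ledger of a synthesized corpus (one row per WAV)."""

    frame: pd.DataFrame
    root: Path | None = None

    COLUMNS = ("path", "label", "subtype", "guild", "snr_db", "n_pulses",
               "pulse_times", "seed")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")

    def write(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read(cls, path) -> "CorpusManifest":
        return cls(pd.read_csv(path, dtype={"pulse_times": str}, keep_default_na=False),
                   root=Path(path).parent)


def _burst_span(spec: BuzzSpec) -> float:
    return spec.span_s


def synth_corpus(
    n_buzz: int,
    n_nonbuzz: int,
    out_dir,
    seed: int = 0,
    guild_mix: float = 0.5,
    snr_range: tuple[float, float] = (8.0, 25.0),
    duration: float = 2.0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    noise_floor: float = DEFAULT_NOISE_SIGMA,
) -> CorpusManifest:
    """Write a labelled corpus of WAV files plus ``manifest.csv``.

    Buzz/non-buzz counts are as requested; non-buzz subtypes cycle through
    search_phase, clicks and noise.  ``guild_mix`` is the fraction of tonal
    recordings assigned to the low-frequency guild (terminal frequency below
    30 kHz); broadband clicks and pure noise carry no guild.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    file_seeds = np.random.SeedSequence(seed).generate_state(n_buzz + n_nonbuzz) & 0x7FFFFFFF

    rows = []
    for i in range(n_buzz):
        low = i < round(n_buzz * guild_mix)
        guild = "low" if low else "high"
        f_start, f_end = (34.0, 24.0) if low else (48.0, 36.0)
        snr = float(master.uniform(*snr_range))
        span = BuzzSpec(f_start=f_start, f_end=f_end).span_s
        max_onset = duration - span - 0.2
        spec = BuzzSpec(f_start=f_start, f_end=f_end, snr_db=snr,
                        onset=float(master.uniform(0.3, max(0.31, max_onset))))
        fseed = int(file_seeds[i])
        rec, onsets = synth_buzz_recording(spec, noise_floor, duration,
                                           sample_rate, seed=fseed)
        name = f"buzz_{i:04d}.wav"
        write_wav(rec, out_dir / name)
        rows.append({
            "path": name, "label": "buzz", "subtype": "buzz", "guild": guild,
            "snr_db": snr, "n_pulses": spec.n_pulses,
            "pulse_times": ";".join(f"{t:.6f}" for t in onsets), "seed": fseed,
        })

    for j in range(n_nonbuzz):
        subtype = _NONBUZZ_SUBTYPES[j % len(_NONBUZZ_SUBTYPES)]
        guild = ""
        if subtype == "search_phase":
            guild = "low" if j < round(n_nonbuzz * guild_mix) else "high"
        snr = float(master.uniform(*snr_range))
        fseed = int(file_seeds[n_buzz + j])
        rec, onsets = synth_nonbuzz_recording(
            subtype, sample_rate, duration, noise_floor, seed=fseed,
            snr_db=snr, guild=guild or "high",
        )
        name = f"nonbuzz_{subtype}_{j:04d}.wav"
        write_wav(rec, out_dir / name)
        rows.append({
            "path": name, "label": "non-buzz", "subtype": subtype, "guild": guild,
            "snr_db": snr, "n_pulses": len(onsets),
            "pulse_times": ";".join(f"{t:.6f}" for t in onsets), "seed": fseed,
        })

    manifest = CorpusManifest(pd.DataFrame(rows, columns=list(CorpusManifest.COLUMNS)),
                              root=out_dir)
    manifest.write(out_dir / "manifest.csv")
    return manifest


def synth_burst_recording(
    n_bursts: int,
    duration: float,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    snr_range: tuple[float, float] = (15.0, 30.0),
    dur_range_ms: tuple[float, float] = (0.5, 2.0),
    freq_range_khz: tuple[float, float] = (16.0, 49.0),
    min_gap_ms: float = 60.0,
    noise_floor: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
) -> tuple[Recording, pd.DataFrame]:
    """Isolated constant-frequency tone bursts in noise, for detector checks.

    Returns the recording and a table of ground truth (onset_s, freq_khz,
    dur_ms, snr_db) for injection-oracle tests of recall and SNR calibration.
    """
    params = _analysis_params()
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    samples = _noise_bed(rng, n, noise_floor)
    floor_db, _ = _noise_floor_reference(samples, sample_rate, params)

    slots = np.linspace(0.1, duration - 0.1, n_bursts + 1)[:-1]
    jitter_max = max(0.0, (slots[1] - slots[0]) - min_gap_ms / 1000.0) if n_bursts > 1 else 0.0
    rows = []
    for onset in slots:
        onset = float(onset + rng.uniform(0, jitter_max))
        f = float(rng.uniform(*freq_range_khz))
        d = float(rng.uniform(*dur_range_ms))
        s = float(rng.uniform(*snr_range))
        pulse = synth_pulse(f, f, d, sample_rate)
        _mix_pulse(samples, pulse, onset, floor_db, s, sample_rate, params)
        rows.append({"onset_s": onset, "freq_khz": f, "dur_ms": d, "snr_db": s})
    rec = Recording(samples, sample_rate, source_id=f"bursts_seed{seed}")
    return rec, pd.DataFrame(rows)


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
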