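"""Noise-floor tracking, event extraction and band scanning."""

import numpy as np
import pytest

from batbuzz import (DetectorParams, FrequencyBand, NoiseFloorState, Recording,
                     default_bands, detect_in_band, detections_to_frame,
                     enforce_min_dur_tbe, scan_bands, update_noise_floor,
                     write_label_track)
from batbuzz.audio import compute_spectrogram
from batbuzz.synth import BuzzSpec, synth_burst_recording, synth_buzz_recording

from conftest import make_detection

FS = 384_000


def test_default_bands_tile_15_to_50_khz():
    bands = default_bands()
    assert len(bands) == 7
    assert bands[0].f_lo == 15_000 and bands[-1].f_hi == 50_000
    for a, b in zip(bands, bands[1:]):
        assert a.f_hi == b.f_lo and (a.f_hi - a.f_lo) == 5000


def test_params_validation():
    with pytest.raises(ValueError):
        DetectorParams(min_dur=-1)
    with pytest.raises(ValueError):
        DetectorParams(fft_overlap=1.0)
    with pytest.raises(ValueError):
        DetectorParams(min_dur=100.0, duration_thr=80.0)


# -- noise floor ------------------------------------------------------------

def _noise_frames(n, nb=4, seed=0):
    rng = np.random.default_rng(seed)
    return 10.0 * np.log10(rng.exponential(1.0, (n, nb)))


def test_noise_mean_tracks_running_mean_of_same_frames():
    frames = _noise_frames(200)
    state = NoiseFloorState.from_frames(frames[:40], update_weight=0.02, k=2.5,
                                        max_event_frames=900)
    for fr in frames:
        update_noise_floor(state, fr, in_event=False)
    assert np.all(np.abs(state.mean_db - frames.mean(axis=0)) < 1.0)
    assert np.all(state.floor_db >= state.mean_db)  # CFAR floor sits above mean


def test_floor_frozen_during_short_event():
    frames = _noise_frames(50)
    state = NoiseFloorState.from_frames(frames[:10], 0.02, 2.5, max_event_frames=100)
    before_m = state.mean_db.copy()
    before_f = state.floor_db.copy()
    for fr in frames:
        update_noise_floor(state, fr + 30.0, in_event=True)  # loud event frames
    assert np.array_equal(state.mean_db, before_m)
    assert np.array_equal(state.floor_db, before_f)


def test_floor_updates_resume_past_duration_threshold():
    frames = _noise_frames(10)
    state = NoiseFloorState.from_frames(frames[:5], 0.02, 2.5, max_event_frames=3)
    before = state.mean_db.copy()
    for i, fr in enumerate(frames[:3]):
        update_noise_floor(state, fr, in_event=True)
        assert np.array_equal(state.mean_db, before), f"frozen frame {i}"
    update_noise_floor(state, frames[4], in_event=True)  # 4th in-event frame
    assert not np.array_equal(state.mean_db, before)


def test_update_weight_bounds():
    with pytest.raises(ValueError):
        NoiseFloorState.from_frames(_noise_frames(5), update_weight=0.0, k=1.0,
                                    max_event_frames=1)


# -- single-band detection --------------------------------------------------

def test_silence_yields_no_detections():
    sp = compute_spectrogram(Recording(np.zeros(50_000), FS))
    assert detect_in_band(sp, FrequencyBand(35_000, 40_000), DetectorParams()) == []


def _single_burst_recording():
    rec, truth = synth_burst_recording(
        1, duration=0.8, snr_range=(20.0, 20.0), dur_range_ms=(2.0, 2.0),
        freq_range_khz=(37.5, 37.5), seed=9)
    return rec, float(truth.loc[0, "onset_s"])


def test_single_tone_burst_detected_in_its_band():
    rec, onset = _single_burst_recording()
    sp = compute_spectrogram(rec)
    dets = detect_in_band(sp, FrequencyBand(35_000, 40_000), DetectorParams())
    assert len(dets) == 1
    assert abs(dets[0].start_time - onset) <= 5e-4
    assert 1.0 <= dets[0].duration <= 3.0


def test_same_burst_invisible_to_distant_band():
    rec, _ = _single_burst_recording()
    sp = compute_spectrogram(rec)
    assert detect_in_band(sp, FrequencyBand(25_000, 30_000), DetectorParams()) == []


# -- merging and duration rules --------------------------------------------

def test_merge_empty_input():
    assert enforce_min_dur_tbe([], DetectorParams()) == []


def test_events_closer_than_min_tbe_merge():
    a = make_detection(0.000, 10.0, [38_000] * 5, end_s=0.001)
    b = make_detection(0.002, 14.0, [38_500] * 5, end_s=0.003)
    out = enforce_min_dur_tbe([a, b], DetectorParams())
    assert len(out) == 1
    assert out[0].duration == pytest.approx(3.0)
    assert out[0].snr == 14.0
    assert out[0].freq_track.size == 10


def test_sub_min_dur_event_removed():
    d = make_detection(0.0, 10.0, [38_000], end_s=0.0001)  # 0.1 ms < 0.2 ms
    assert enforce_min_dur_tbe([d], DetectorParams()) == []


def test_unsorted_detections_rejected():
    a = make_detection(0.010, 10.0, [38_000] * 5)
    b = make_detection(0.000, 10.0, [38_000] * 5)
    with pytest.raises(ValueError):
        enforce_min_dur_tbe([a, b], DetectorParams())


# -- band scanning ----------------------------------------------------------

def test_buzz_pulses_recovered_in_terminal_band():
    spec = BuzzSpec(f_start=48.0, f_end=36.0, snr_db=20.0)
    rec, onsets = synth_buzz_recording(spec, seed=3)
    res = scan_bands(rec)
    by_label = {b.label: d for b, d in res.items()}
    assert len(by_label["35-40kHz"]) >= 0.8 * spec.n_pulses
    assert len(by_label["15-20kHz"]) == 0


def test_tiny_recording_maps_every_band_to_empty():
    res = scan_bands(Recording(np.zeros(256), FS))
    assert all(d == [] for d in res.values())


def test_band_above_nyquist_rejected():
    rec = Recording(np.zeros(5000), 48_000)
    with pytest.raises(Exception):
        scan_bands(rec, bands=[FrequencyBand(40_000, 45_000)])


def test_detections_are_bitwise_deterministic():
    rec, _ = synth_buzz_recording(BuzzSpec(), seed=12)
    r1 = scan_bands(rec)
    r2 = scan_bands(rec)
    for band in r1:
        assert len(r1[band]) == len(r2[band])
        for a, b in zip(r1[band], r2[band]):
            assert a.start_time == b.start_time and a.snr == b.snr
            assert np.array_equal(a.freq_track, b.freq_track)
            assert np.array_equal(a.amp_track, b.amp_track)


def test_emitted_detections_satisfy_invariants():
    params = DetectorParams()
    rec, _ = synth_buzz_recording(BuzzSpec(), seed=21)
    for band, dets in scan_bands(rec, params=params).items():
        for d in dets:
            assert d.snr >= params.snr_thr
            assert d.duration >= params.min_dur
            assert np.all((d.freq_track >= band.f_lo) & (d.freq_track < band.f_hi))
            assert d.end_time > d.start_time


def test_detected_snr_calibrated_to_injection():
    """Reported SNR within +-3 dB of injected for isolated in-band bursts."""
    rec, truth = synth_burst_recording(
        30, duration=3.0, snr_range=(10.0, 30.0), freq_range_khz=(36.0, 39.0),
        seed=77)
    dets = [d for lst in scan_bands(rec).values() for d in lst]
    for _, row in truth.iterrows():
        matched = [d.snr for d in dets if abs(d.start_time - row.onset_s) <= 1e-3]
        assert matched, f"burst at {row.onset_s:.3f}s missed"
        assert abs(max(matched) - row.snr_db) <= 3.0


def test_short_noise_stretch_produces_no_events():
    rng = np.random.default_rng(123)
    rec = Recording(rng.normal(0, 0.005, 5 * FS), FS)
    assert sum(len(d) for d in scan_bands(rec).values()) == 0


def test_detections_export_schema(tmp_path):
    rec, _ = synth_buzz_recording(BuzzSpec(), seed=3)
    res = scan_bands(rec)
    df = detections_to_frame(res, source_id="x.wav")
    assert list(df.columns) == ["source_id", "band_lo", "band_hi", "start_s",
                                "end_s", "duration_ms", "snr_db"]
    assert (df["duration_ms"] > 0).all()
    dets = [d for lst in res.values() for d in lst]
    write_label_track(dets, tmp_path / "labels.txt")
    lines = (tmp_path / "labels.txt").read_text().strip().splitlines()
    assert len(lines) == len(dets)
    start, end, _ = lines[0].split("\t")
    assert float(end) > float(start)
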