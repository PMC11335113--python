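"""Window-feature formulas against an independently coded oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from batbuzz import (FEATURE_NAMES, interpulse_intervals, sliding_windows,
                     track_slope_smoothness, window_features, windows_to_frame)
from batbuzz.audio import FrequencyBand

from conftest import make_detection


# --------------------------------------------------------------------------
# independent direct-formula oracle (plain python, no shared code paths)

def _ols(xs, ys):
    n = len(xs)
    xm = sum(xs) / n
    ym = sum(ys) / n
    sxx = sum((x - xm) ** 2 for x in xs)
    sxy = sum((x - xm) * (y - ym) for x, y in zip(xs, ys))
    slope = sxy / sxx
    return slope, ym - slope * xm


def _sd(vals):
    n = len(vals)
    m = sum(vals) / n
    return math.sqrt(sum((v - m) ** 2 for v in vals) / (n - 1))


def oracle_track_slope_smoothness(freqs_hz, times_s):
    f = [v / 1000.0 for v in freqs_hz]
    t = [(v - times_s[0]) * 1000.0 for v in times_s]
    if len(f) < 2:
        return 0.0, 0.0
    slope, intercept = _ols(t, f)
    if len(f) <= 2:
        return slope, 0.0
    resid = [fi - (slope * ti + intercept) for ti, fi in zip(t, f)]
    return slope, math.sqrt(sum(r * r for r in resid) / len(resid))


def oracle_window(dets):
    """The 21 variables computed straight from their definitions."""
    starts = [d.start_time for d in dets]
    ipis = [(b - a) * 1000.0 for a, b in zip(starts, starts[1:])]
    snrs = [d.snr for d in dets]
    slopes, smooths = zip(*(oracle_track_slope_smoothness(d.freq_track, d.frame_times)
                            for d in dets))
    durs = [(d.end_time - d.start_time) * 1000.0 for d in dets]

    out = {}
    out["IPIslope"], out["IPIint"] = _ols([1, 2, 3], ipis)
    out["IPImin"], out["IPImax"] = min(ipis), max(ipis)
    out["IPIavg"] = sum(ipis) / 3
    out["IPIsd"] = _sd(ipis)
    out["IPIvar"] = out["IPIsd"] ** 2
    sigma = max(out["IPIsd"] * 1e-3, 1e-9)
    out["IPIshannon"] = 0.5 * math.log(2 * math.pi * math.e * sigma ** 2)

    if _sd(snrs) == 0.0:
        out["SNRr"] = 0.0
    else:
        slope, intercept = _ols([1, 2, 3, 4], snrs)
        fitted = [slope * x + intercept for x in (1, 2, 3, 4)]
        m = sum(snrs) / 4
        ss_res = sum((y - f) ** 2 for y, f in zip(snrs, fitted))
        ss_tot = sum((y - m) ** 2 for y in snrs)
        out["SNRr"] = 1.0 - (1.0 - (1.0 - ss_res / ss_tot)) * 3.0 / 2.0
    out["SNRmin"], out["SNRmax"] = min(snrs), max(snrs)
    out["SNRavg"] = sum(snrs) / 4
    out["SNRsd"] = _sd(snrs)
    out["SNRvar"] = out["SNRsd"] ** 2
    out["slopeavg"] = sum(slopes) / 4
    out["slopemin"] = min(slopes)
    out["slopesd"] = _sd(slopes)
    out["duravg"] = sum(durs) / 4
    out["dursd"] = _sd(durs)
    out["smoothavg"] = sum(smooths) / 4
    out["smoothvar"] = _sd(smooths) ** 2
    return out


def random_window(rng):
    """Four random detections with increasing start times and random tracks."""
    start = rng.uniform(0, 2.0)
    dets = []
    for _ in range(4):
        n = int(rng.integers(2, 25))
        freqs = rng.uniform(15_000, 50_000, n)
        dets.append(make_detection(start, float(rng.uniform(4, 30)), freqs,
                                   frame_step_s=8.6e-5))
        start += float(rng.uniform(0.003, 0.120))
    return dets


def assert_window_matches_oracle(dets, rtol=1e-9):
    got = window_features(dets).as_dict()
    want = oracle_window(dets)
    for name in FEATURE_NAMES:
        assert got[name] == pytest.approx(want[name], rel=rtol, abs=1e-12), name


def test_features_match_oracle_on_many_random_windows():
    rng = np.random.default_rng(2024)
    for _ in range(300):
        assert_window_matches_oracle(random_window(rng))


# --------------------------------------------------------------------------
# worked examples

def test_ipis_from_starts():
    dets = [make_detection(s, 10.0, [40_000] * 3) for s in (0.0, 0.005, 0.012)]
    assert np.allclose(interpulse_intervals(dets), [5.0, 7.0])
    assert interpulse_intervals(dets[:1]).size == 0


def test_ipi_is_start_to_start_not_end_to_start():
    a = make_detection(0.0, 10.0, [40_000] * 5, end_s=0.002)  # 2 ms long
    b = make_detection(0.005, 10.0, [40_000] * 5)
    assert interpulse_intervals([a, b])[0] == pytest.approx(5.0)


def test_constant_track_has_zero_slope_and_smoothness():
    slope, smooth = track_slope_smoothness([40_000] * 6, np.arange(6) * 1e-4)
    assert slope == pytest.approx(0.0, abs=1e-9)
    assert smooth == pytest.approx(0.0, abs=1e-9)


def test_linear_sweep_slope_exact():
    times = np.linspace(0, 1e-3, 5)
    freqs = np.linspace(50_000, 40_000, 5)
    slope, smooth = track_slope_smoothness(freqs, times)
    assert slope == pytest.approx(-10.0, rel=1e-9)
    assert smooth == pytest.approx(0.0, abs=1e-9)


def test_vee_track_smoothness_hand_value():
    slope, smooth = track_slope_smoothness([50_000, 40_000, 50_000],
                                           [0.0, 1e-4, 2e-4])
    assert slope == pytest.approx(0.0, abs=1e-9)
    assert smooth == pytest.approx(math.sqrt(2 * (10 / 3) ** 2 + (20 / 3) ** 2) / math.sqrt(3),
                                   rel=1e-9)


def _window_with_ipis(ipis_ms, snrs=(10.0, 12.0, 14.0, 16.0)):
    starts = np.concatenate([[0.0], np.cumsum(ipis_ms) / 1000.0])
    return [make_detection(s, snr, [40_000] * 4) for s, snr in zip(starts, snrs)]


def test_constant_ipis_degenerate_stats():
    wf = window_features(_window_with_ipis([5.0, 5.0, 5.0]))
    assert wf.IPIslope == pytest.approx(0.0, abs=1e-12)
    assert wf.IPIsd == pytest.approx(0.0, abs=1e-12)
    assert wf.IPIvar == pytest.approx(0.0, abs=1e-12)
    assert wf.IPImin == pytest.approx(5.0)
    assert wf.IPImax == pytest.approx(5.0)
    assert wf.IPIavg == pytest.approx(5.0)


def test_decreasing_ipis_hand_regression():
    wf = window_features(_window_with_ipis([10.0, 8.0, 6.0]))
    assert wf.IPIavg == pytest.approx(8.0)
    assert wf.IPIslope == pytest.approx(-2.0)
    assert wf.IPIint == pytest.approx(12.0)
    assert wf.IPIsd == pytest.approx(2.0)
    assert wf.IPIvar == pytest.approx(4.0)


def test_ipishannon_closed_form_at_2ms():
    wf = window_features(_window_with_ipis([6.0, 8.0, 10.0]))  # sd exactly 2 ms
    assert wf.IPIsd == pytest.approx(2.0)
    assert wf.IPIshannon == pytest.approx(
        0.5 * math.log(2 * math.pi * math.e * 0.002 ** 2), abs=1e-9)
    assert wf.IPIshannon == pytest.approx(-4.796, abs=1e-3)


def test_perfect_snr_trend_gives_unit_adjusted_r2():
    wf = window_features(_window_with_ipis([5.0, 5.0, 5.0], snrs=(10, 12, 14, 16)))
    assert wf.SNRr == pytest.approx(1.0)


def test_flat_snr_defines_adjusted_r2_zero():
    wf = window_features(_window_with_ipis([5.0, 5.0, 5.0], snrs=(9.0,) * 4))
    assert wf.SNRr == 0.0


def test_window_size_contract():
    with pytest.raises(ValueError):
        window_features(_window_with_ipis([5.0, 5.0, 5.0])[:3])


# --------------------------------------------------------------------------
# window formation and invariances

def test_window_counts():
    rng = np.random.default_rng(1)
    dets = random_window(rng) + random_window(rng)[:3]  # 7 detections total
    dets = sorted(dets, key=lambda d: d.start_time)
    assert len(sliding_windows(dets[:3])) == 0
    assert len(sliding_windows(dets)) == 4  # n - 3


def test_windows_never_mix_bands():
    band_a = FrequencyBand(35_000, 40_000)
    band_b = FrequencyBand(40_000, 45_000)
    dets_a = [make_detection(i * 0.01, 10.0, [37_000] * 3, band=band_a)
              for i in range(4)]
    dets_b = [make_detection(i * 0.01, 10.0, [42_000] * 3, band=band_b)
              for i in range(4)]
    df = windows_to_frame({band_a: dets_a, band_b: dets_b}, source_id="r")
    assert len(df) == 2
    assert set(zip(df["band_lo"], df["band_hi"])) == {(35_000.0, 40_000.0),
                                                      (40_000.0, 45_000.0)}


@given(offset=st.floats(-10.0, 10.0, allow_nan=False))
def test_features_invariant_to_time_shift(offset):
    rng = np.random.default_rng(7)
    dets = random_window(rng)
    shifted = [make_detection(d.start_time + offset, d.snr, d.freq_track,
                              frame_step_s=8.6e-5,
                              end_s=d.end_time + offset) for d in dets]
    a = window_features(dets).as_dict()
    b = window_features(shifted).as_dict()
    for name in FEATURE_NAMES:
        assert a[name] == pytest.approx(b[name], rel=1e-6, abs=1e-9), name


def test_ipishannon_monotone_in_ipi_spread():
    spreads = [0.05, 0.2, 1.0, 2.0, 5.0]  # ipis [8-d, 8, 8+d] have sd exactly d
    shannon = [window_features(_window_with_ipis([8.0 - d, 8.0, 8.0 + d])).IPIshannon
               for d in spreads]
    assert shannon == sorted(shannon)


def test_ipishannon_below_minus_10_iff_sub_10us_spread():
    # sd ~ 5 us -> deeply negative entropy
    tiny = window_features(_window_with_ipis([5.000, 5.005, 5.010]))
    assert tiny.IPIsd < 0.01 and tiny.IPIshannon < -10
    # sd of 0.1 ms -> above the outlier bar
    mild = window_features(_window_with_ipis([5.0, 5.1, 5.2]))
    assert mild.IPIshannon > -10
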