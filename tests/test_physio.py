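"""Cardiac, respiration and skin-conductance feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from physioload.physio import (
    HF_BAND,
    MF_BAND,
    RriSeries,
    detect_r_peaks,
    gaussian_gain,
    hrv_band_power,
    hrv_time_metrics,
    resp_metrics,
    sc_metrics,
)
from physioload.synth.signals import qrs_template

FS = 300.0


def _rri_from_intervals(intervals_ms, t0=0.0):
    times = t0 + np.concatenate([[0.0], np.cumsum(np.asarray(intervals_ms) / 1000.0)])
    return RriSeries(times)


# -- time-domain HRV ---------------------------------------------------------

def test_rmssd_hand_computed():
    mean_rri, rmssd = hrv_time_metrics(_rri_from_intervals([800, 900, 800]))
    assert mean_rri == pytest.approx(2500 / 3)
    assert rmssd == pytest.approx(100.0)  # diffs (100, -100), mean square 10^4


def test_rmssd_degenerate_cases():
    _, rmssd = hrv_time_metrics(_rri_from_intervals([800, 800, 800]))
    assert rmssd == pytest.approx(0.0, abs=1e-9)
    with pytest.warns(UserWarning, match="RMSSD undefined"):
        mean_rri, rmssd = hrv_time_metrics(_rri_from_intervals([700]))
    assert mean_rri == pytest.approx(700.0)
    assert np.isnan(rmssd)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(300, 1500), min_size=2, max_size=40))
def test_rmssd_matches_brute_force(intervals):
    """RMSSD against an explicit loop over successive differences."""
    _, rmssd = hrv_time_metrics(_rri_from_intervals(intervals))
    sq = [(intervals[i + 1] - intervals[i]) ** 2 for i in range(len(intervals) - 1)]
    assert rmssd == pytest.approx(np.sqrt(np.mean(sq)), rel=1e-9)


def test_time_and_offset_invariance():
    iv = [820, 790, 850, 810, 830]
    base = hrv_time_metrics(_rri_from_intervals(iv))
    shifted = hrv_time_metrics(_rri_from_intervals(iv, t0=500.0))
    assert shifted == pytest.approx(base, rel=1e-9)
    _, r1 = hrv_time_metrics(_rri_from_intervals(iv))
    _, r2 = hrv_time_metrics(_rri_from_intervals([v + 100 for v in iv]))
    assert r1 == pytest.approx(r2)


# -- R-peak detection --------------------------------------------------------

def _ecg_from_times(times, duration, fs=FS, noise=0.0, seed=0):
    n = int(duration * fs)
    sig = np.zeros(n)
    tpl = qrs_template(fs)
    half = (len(tpl) - 1) // 2
    for rt in times:
        c = int(round(rt * fs))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        sig[lo:hi] += tpl[lo - (c - half): hi - (c - half)]
    if noise:
        sig += np.random.default_rng(seed).normal(0, noise, n)
    return sig


def test_constant_800ms_rri():
    times = 0.4 + 0.8 * np.arange(74)
    rri = detect_r_peaks(_ecg_from_times(times, 60.0), FS)
    assert abs(len(rri.peak_times) - 75) <= 1
    assert np.allclose(rri.intervals_ms, 800.0, atol=1000.0 / FS)


def test_flat_signal_raises():
    with pytest.raises(ValueError, match="fewer than 2 R-peaks"):
        detect_r_peaks(np.zeros(int(60 * FS)), FS)


def test_detection_matches_generator_truth(one_participant, default_config):
    """Every detected peak within one sample of truth; no misses or extras."""
    fs = default_config.fs_physio
    for rec in one_participant[0].sessions.values():
        det = detect_r_peaks(rec.ecg, fs).peak_times
        truth = rec.truth["r_peaks"]
        assert len(det) == len(truth)
        err_samples = np.abs(np.round(det * fs) - np.round(truth * fs))
        assert err_samples.max() <= 1


# -- spectral HRV ------------------------------------------------------------

def _modulated_rri(freq, duration=300.0, depth=50.0, base=800.0):
    times = [0.0]
    while times[-1] < duration:
        t = times[-1]
        times.append(t + (base + depth * np.sin(2 * np.pi * freq * t)) / 1000.0)
    return RriSeries(np.array(times))


def test_band_power_localizes_modulation_frequency():
    rri_mf = _modulated_rri(0.10)
    mf, hf = hrv_band_power(rri_mf, MF_BAND), hrv_band_power(rri_mf, HF_BAND)
    assert mf > 10 * hf
    rri_hf = _modulated_rri(0.30)
    mf, hf = hrv_band_power(rri_hf, MF_BAND), hrv_band_power(rri_hf, HF_BAND)
    assert hf > 10 * mf


def test_constant_rri_has_no_band_power():
    rri = _rri_from_intervals([800.0] * 200)
    assert hrv_band_power(rri, MF_BAND) == pytest.approx(0.0, abs=1e-12)
    assert hrv_band_power(rri, HF_BAND) == pytest.approx(0.0, abs=1e-12)


def test_short_segment_mid_band_missing():
    rri = _modulated_rri(0.10, duration=20.0)
    with pytest.warns(UserWarning, match="unreliable"):
        assert np.isnan(hrv_band_power(rri, MF_BAND))


# -- respiration -------------------------------------------------------------

def test_breath_interval_of_quarter_hz_sinusoid():
    t = np.arange(int(120 * FS)) / FS
    interval, _ = resp_metrics(np.sin(2 * np.pi * 0.25 * t), FS)
    assert interval == pytest.approx(4.0, rel=1e-3)


def test_modulation_depth_matches_gaussian_filter_gain():
    """Depth of a smoothed sinusoid = 2A x analytic Gaussian gain."""
    amp, freq, sigma = 2.0, 0.25, 0.39
    t = np.arange(int(120 * FS)) / FS
    _, depth = resp_metrics(amp * np.sin(2 * np.pi * freq * t), FS, kernel_width=sigma)
    assert depth == pytest.approx(2 * amp * gaussian_gain(freq, sigma), rel=0.02)


def test_constant_respiration_missing():
    with pytest.warns(UserWarning, match="undefined"):
        interval, depth = resp_metrics(np.ones(int(60 * FS)), FS)
    assert np.isnan(interval) and np.isnan(depth)


# -- skin conductance --------------------------------------------------------

def test_sc_metrics_basic():
    mean, mn = sc_metrics(np.full(1000, 5.0))
    assert mean == 5.0 and mn == 5.0
    rng = np.random.default_rng(0)
    x = rng.normal(5, 1, 1000)
    mean, mn = sc_metrics(x)
    assert mn <= mean
    with pytest.raises(ValueError):
        sc_metrics(np.array([]))


def test_sc_min_near_decay_plateau():
    """Block-onset peak decaying to a plateau: the minimum sits at the plateau."""
    t = np.arange(int(120 * FS)) / FS
    plateau = 4.0
    x = plateau + 1.5 * np.exp(-t / 10.0)
    mean, mn = sc_metrics(x)
    assert mn == pytest.approx(plateau, abs=0.01)
    assert mn < mean


# -- workload direction recovery --------------------------------------------

def test_workload_effect_directions_recovered(default_table):
    """Mean RRI and high-band HRV fall under load for most participants."""
    for col in ("ecg.mean_rri", "ecg.hf_hrv"):
        diffs = []
        for _, g in default_table.groupby("participant"):
            diffs.append(g.loc[g["condition"] == "2-back", col].mean()
                         - g.loc[g["condition"] == "0-back", col].mean())
        assert np.mean(diffs) < 0
        assert np.mean(np.array(diffs) < 0) >= 11 / 14, col
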