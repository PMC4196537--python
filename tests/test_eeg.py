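"""Epoching, artifact rejection, ERP and spectral features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from physioload import SimulationConfig
from physioload.eeg import (
    ALPHA_BAND,
    SPECTRAL_FREQS,
    EpochSet,
    band_log_power,
    epoch,
    erp_features,
    reject_high_variance,
    spectral_features,
)
from physioload.synth import generate_participant
from physioload.synth.signals import p300_template

FS = 256.0


def _epochs_from(data):
    n = data.shape[0]
    return EpochSet(
        data=data, fs=FS, channels=tuple(f"ch{i}" for i in range(data.shape[1])),
        onsets=np.arange(n, dtype=float), condition=np.array([""] * n),
    )


def test_epoch_counts_and_shape():
    rng = np.random.default_rng(0)
    eeg = rng.normal(size=(7, int(200 * FS)))
    onsets = 5.0 + 2.5 * np.arange(48)
    eps = epoch(eeg, FS, onsets)
    assert eps.data.shape == (48, 7, 640)  # 2.5 s x 256 Hz
    # baseline: mean of the first 500 ms is zero per trial and channel
    assert np.allclose(eps.data[:, :, :128].mean(axis=2), 0.0, atol=1e-12)


def test_epoch_constant_baseline_maps_to_zero():
    eeg = np.full((1, int(20 * FS)), 7.5)
    eps = epoch(eeg, FS, np.array([5.0]))
    assert np.allclose(eps.data, 0.0)


def test_epoch_drops_edge_onsets():
    eeg = np.zeros((1, int(10 * FS)))
    with pytest.warns(UserWarning, match="stream edge"):
        eps = epoch(eeg, FS, np.array([0.2, 5.0, 9.9]))
    assert len(eps.onsets) == 1


def test_epoch_recovers_generator_template():
    """Zero-noise simulation: every epoch equals the baseline-shifted ERP."""
    cfg = SimulationConfig(
        n_participants=1, n_sessions=1, eeg_noise_rms=0.0, alpha_amp=0.0,
        theta_amp=0.0, artifact_rate=0.0, eeg_block_jitter=0.0,
        p300_attenuation=0.0, streams=("eeg",),
    )
    bundle, events = generate_participant(cfg, 1, seed=5)
    sev = events[(events["session"] == 1) & events["onset"].notna()]
    eps = epoch(bundle[1].eeg, cfg.fs_eeg, sev["onset"].to_numpy())
    tpl = p300_template(cfg.fs_eeg, amp=cfg.p300_amp)
    expected = np.zeros(eps.data.shape[-1])
    pre = int(0.5 * cfg.fs_eeg)
    expected[pre:pre + tpl.size] = tpl
    expected -= expected[:pre].mean()
    # Pz has template weight 1 (channel index 2)
    assert np.allclose(eps.data[:, 2, :], expected, atol=1e-9)


def test_rejection_rules():
    rng = np.random.default_rng(1)
    data = np.zeros((3, 2, 640))
    data[1] = rng.normal(0, 150.0, size=(2, 640))     # all channels hot
    data[2, 1] = rng.normal(0, 150.0, size=640)       # one channel hot
    eps = reject_high_variance(_epochs_from(data))
    assert eps.keep.tolist() == [True, False, False]  # constant kept, any-channel rule
    with pytest.raises(ValueError, match="all trials rejected"):
        reject_high_variance(_epochs_from(data[1:2]))


def test_rejection_matches_injected_artifacts(one_participant, default_config):
    bundle, events = one_participant
    for s, rec in bundle.sessions.items():
        sev = events[(events["session"] == s) & events["onset"].notna()]
        eps = reject_high_variance(
            epoch(rec.eeg, rec.fs_eeg, sev["onset"].to_numpy())
        )
        rejected = set(np.round(eps.onsets[~eps.keep], 3))
        truth = set(np.round(rec.truth["artifact_onsets"], 3))
        assert rejected == truth


def test_erp_lengths_and_identity():
    rng = np.random.default_rng(2)
    one = rng.normal(size=(1, 7, 640))
    many = np.repeat(one, 5, axis=0)
    v1 = erp_features(_epochs_from(one))
    v5 = erp_features(_epochs_from(many))
    assert v1.shape == (707,)
    assert np.allclose(v1, v5)  # average of identical epochs
    pz_only = erp_features(_epochs_from(one[:, 2:3, :]))
    assert pz_only.shape == (101,)
    with pytest.raises(ValueError, match="no kept trials"):
        eps = _epochs_from(one)
        eps.keep[:] = False
        erp_features(eps)


def test_spectral_dimensions_and_sinusoid_peak():
    t = np.arange(640) / FS
    amp = 5.0
    x = amp * np.sin(2 * np.pi * 10.0 * t)
    power = spectral_features(_epochs_from(np.tile(x, (1, 7, 1))))
    assert power.shape == (7, 37)
    assert np.all(power >= 0)
    peak = power[0].argmax()
    assert SPECTRAL_FREQS[peak] == 10.0
    # Hanning-tapered bin-centred sinusoid: power = A^2/2 (mean square)
    assert power[0, peak] == pytest.approx(amp**2 / 2, rel=1e-3)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(scale=st.floats(0.1, 50.0), seed=st.integers(0, 10**6))
def test_power_scaling_law(scale, seed):
    """Scaling the input by c scales every power value by c^2."""
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(3, 2, 640))
    p1 = spectral_features(_epochs_from(data))
    p2 = spectral_features(_epochs_from(scale * data))
    assert np.allclose(p2, scale**2 * p1, rtol=1e-9)


def test_band_log_power_membership_and_units():
    power = np.ones((7, 37))
    alpha_mask = (SPECTRAL_FREQS >= 8.0) & (SPECTRAL_FREQS <= 13.0)
    theta_mask = (SPECTRAL_FREQS >= 4.0) & (SPECTRAL_FREQS <= 7.5)
    assert alpha_mask.sum() == 11 and theta_mask.sum() == 8
    power[:, alpha_mask] = np.e
    out = band_log_power(power, "alpha")
    assert out.shape == (7,)
    assert np.allclose(out, 1.0)        # ln e = 1
    assert np.allclose(band_log_power(power, "theta"), 0.0)
    assert np.allclose(band_log_power(power, ALPHA_BAND), 1.0)
    # power floor keeps silent channels finite
    assert np.isfinite(band_log_power(np.zeros((1, 37)), "alpha")).all()


def test_rejecting_nothing_changes_nothing():
    rng = np.random.default_rng(3)
    data = rng.normal(scale=5.0, size=(8, 2, 640))
    eps = _epochs_from(data)
    kept = reject_high_variance(eps)
    assert kept.keep.all()
    assert np.allclose(erp_features(eps), erp_features(kept))
    assert np.allclose(spectral_features(eps), spectral_features(kept))
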