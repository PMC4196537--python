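"""EEG epoching, artifact rejection, ERP and spectral features.

Epochs span -0.5 to +2.0 s around each stimulus onset and are baseline
shifted so the mean of the first 500 ms is zero.  Trials whose standard
deviation exceeds 100 uV on any channel are rejected before averaging.
Block features are the trial-averaged ERP (resampled to 100 Hz, samples at
0..1 s inclusive, 101 per channel) and trial-averaged spectral power at 37
frequencies from 2 to 20 Hz in 0.5 Hz steps computed with a single Hanning
taper over the full epoch.  Alpha (8-13 Hz) and theta (4-8 Hz) summaries are
the mean natural-log power over the band's bins.

The 0.5 Hz frequency grid is obtained by zero-padding the 2.5 s tapered
epoch to 4 s (0.25 Hz native resolution) and keeping every second bin, so
the stated frequencies are hit exactly without interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import resample_poly, windows

from physioload.config import EEG_CHANNELS

__all__ = [
    "EpochSet", "SPECTRAL_FREQS", "ALPHA_BAND", "THETA_BAND",
    "epoch", "reject_high_variance", "erp_features", "spectral_features",
    "band_log_power",
]

PRE = 0.5    # s before stimulus onset
POST = 2.0   # s after stimulus onset
ERP_FS = 100.0
#: The 37 analysis frequencies (Hz).
SPECTRAL_FREQS = np.arange(2.0, 20.0 + 0.25, 0.5)
#: Band bin membership: alpha inclusive of both edges, theta half-open at 8 Hz
#: so the two bands do not share a bin.
ALPHA_BAND = (8.0, 13.0)
THETA_BAND = (4.0, 7.5)
POWER_FLOOR = 1e-30  # uV^2, keeps log power finite for degenerate signals

_PAD_LEN = 1024  # 4 s at 256 Hz -> 0.25 Hz bins


@dataclass
class EpochSet:
    """Stimulus-locked epochs with per-trial metadata and keep flags."""

    data: np.ndarray                 # (n_trials, n_channels, n_samples), uV
    fs: float
    channels: tuple[str, ...]
    onsets: np.ndarray               # (n_trials,) s on the session clock
    condition: np.ndarray            # (n_trials,) str
    keep: np.ndarray = field(default=None)  # (n_trials,) bool

    def __post_init__(self) -> None:
        if self.keep is None:
            self.keep = np.ones(len(self.onsets), dtype=bool)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[-1]) / self.fs - PRE

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def subset(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[mask], fs=self.fs, channels=self.channels,
            onsets=self.onsets[mask], condition=self.condition[mask],
            keep=self.keep[mask],
        )


def epoch(
    eeg: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    conditions: np.ndarray | None = None,
    channels: tuple[str, ...] = EEG_CHANNELS,
) -> EpochSet:
    """Cut baseline-shifted epochs (-0.5..+2.0 s) around stimulus onsets.

    Onsets without a full epoch of signal around them are dropped with a
    warning.  The baseline shift subtracts, per trial and channel, the mean
    of the first 500 ms (the pre-stimulus interval).
    """
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    onsets = np.asarray(onsets, dtype=float)
    if conditions is None:
        conditions = np.array([""] * len(onsets))
    n_pre = int(round(PRE * fs))
    n_len = int(round((PRE + POST) * fs))
    starts = np.round(onsets * fs).astype(int) - n_pre
    ok = (starts >= 0) & (starts + n_len <= eeg.shape[1])
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} onset(s) too close to the stream edge",
            stacklevel=2,
        )
    starts, onsets, conditions = starts[ok], onsets[ok], np.asarray(conditions)[ok]
    data = np.stack([eeg[:, s:s + n_len] for s in starts]) if len(starts) else \
        np.empty((0, eeg.shape[0], n_len))
    baseline = data[:, :, :n_pre].mean(axis=2, keepdims=True)
    data = data - baseline
    return EpochSet(data=data, fs=fs, channels=tuple(channels),
                    onsets=onsets, condition=np.asarray(conditions))


def reject_high_variance(epochs: EpochSet, threshold: float = 100.0) -> EpochSet:
    """Flag trials whose SD exceeds ``threshold`` uV on any channel.

    Raises ValueError when every trial would be rejected (downstream block
    averages are then undefined).
    """
    if epochs.data.shape[0] == 0:
        raise ValueError("no epochs to screen")
    sd = epochs.data.std(axis=2, ddof=0)       # (trials, channels)
    keep = ~(sd > threshold).any(axis=1)
    if not keep.any():
        raise ValueError("all trials rejected by the variance criterion")
    out = EpochSet(
        data=epochs.data, fs=epochs.fs, channels=epochs.channels,
        onsets=epochs.onsets, condition=epochs.condition,
        keep=epochs.keep & keep,
    )
    return out


def _resample_100(data: np.ndarray, fs: float) -> np.ndarray:
    """Anti-aliased polyphase resampling to 100 Hz along the last axis."""
    from fractions import Fraction

    frac = Fraction(int(ERP_FS), int(fs)) if float(fs).is_integer() else Fraction(100, 256)
    return resample_poly(data, frac.numerator, frac.denominator, axis=-1)


def erp_features(epochs: EpochSet) -> np.ndarray:
    """Trial-averaged ERP at 100 Hz, samples 0.00..1.00 s, channels concatenated.

    Returns a vector of length ``101 * n_channels`` (e.g. 707 for the full
    montage, 101 for a single channel).
    """
    if epochs.n_kept == 0:
        raise ValueError("no kept trials for the ERP average")
    kept = epochs.data[epochs.keep]
    avg = kept.mean(axis=0)                       # (channels, samples)
    res = _resample_100(avg, epochs.fs)           # grid starts at -0.5 s, step 0.01 s
    i0 = int(round(PRE * ERP_FS))
    erp = res[:, i0:i0 + 101]
    return erp.reshape(-1)


def spectral_features(epochs: EpochSet) -> np.ndarray:
    """Block-averaged Hanning-taper power (uV^2) at the 37 analysis frequencies.

    Power of a bin-centred sinusoid of amplitude ``A`` equals ``A**2 / 2``
    (its mean square); scaling an input by ``c`` scales every value by
    ``c**2``.  Returns shape ``(n_channels, 37)``.
    """
    if epochs.n_kept == 0:
        raise ValueError("no kept trials for the spectral average")
    kept = epochs.data[epochs.keep]               # (trials, channels, samples)
    n = kept.shape[-1]
    win = windows.hann(n, sym=False)
    wsum = win.sum()
    spec = np.fft.rfft(kept * win, n=_PAD_LEN, axis=-1)
    freqs = np.fft.rfftfreq(_PAD_LEN, d=1.0 / epochs.fs)
    idx = np.array([int(round(f * _PAD_LEN / epochs.fs)) for f in SPECTRAL_FREQS])
    assert np.allclose(freqs[idx], SPECTRAL_FREQS)
    power = 2.0 * np.abs(spec[:, :, idx]) ** 2 / wsum**2
    return power.mean(axis=0)


def band_log_power(power: np.ndarray, band: str | tuple[float, float]) -> np.ndarray:
    """Mean natural-log power over a band's bins, per channel.

    ``band`` is ``"alpha"`` (8-13 Hz inclusive, 11 bins), ``"theta"``
    (4-7.5 Hz, 8 bins) or an explicit inclusive ``(lo, hi)`` tuple.  Power
    is floored at ``POWER_FLOOR`` so all-zero inputs stay finite.
    """
    if isinstance(band, str):
        try:
            band = {"alpha": ALPHA_BAND, "theta": THETA_BAND}[band]
        except KeyError:
            raise ValueError(f"unknown band {band!r}; expected 'alpha' or 'theta'") from None
    lo, hi = band
    mask = (SPECTRAL_FREQS >= lo - 1e-9) & (SPECTRAL_FREQS <= hi + 1e-9)
    power = np.atleast_2d(power)
    return np.log(np.maximum(power[:, mask], POWER_FLOOR)).mean(axis=1)
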