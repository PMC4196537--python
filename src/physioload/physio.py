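"""Cardiac, respiration and skin-conductance features per data segment.

Cardiac features come from the R-peak series of the ECG: mean inter-beat
interval (RRI, ms), RMSSD (ms), and mid- (0.07-0.15 Hz) and high-band
(0.15-0.5 Hz) heart-rate-variability power (ms^2) from a Welch spectrum of
the cubic-spline-interpolated, linearly detrended RRI tachogram on a 4 Hz
grid.  Respiration is Gaussian-smoothed (kernel SD 0.39 s) before peak and
trough detection on the first difference; the features are the mean
peak-to-peak interval (s) and the mean peak-minus-trough modulation depth.
Skin conductance contributes the block mean and minimum of the raw samples.

Metrics that cannot be computed on a segment (too few beats or breaths)
propagate as NaN with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d, maximum_filter1d
from scipy.signal import butter, filtfilt, find_peaks, welch

__all__ = [
    "RriSeries", "MF_BAND", "HF_BAND",
    "detect_r_peaks", "hrv_time_metrics", "hrv_band_power",
    "resp_metrics", "sc_metrics",
]

MF_BAND = (0.07, 0.15)
HF_BAND = (0.15, 0.5)
_INTERP_FS = 4.0  # Hz tachogram grid


@dataclass
class RriSeries:
    """R-peak times (s, strictly increasing) and successive intervals (ms)."""

    peak_times: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size >= 2 and not np.all(np.diff(self.peak_times) > 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def intervals_ms(self) -> np.ndarray:
        return np.diff(self.peak_times) * 1000.0

    @property
    def interval_times(self) -> np.ndarray:
        """Time stamp of each interval = time of its closing peak."""
        return self.peak_times[1:]


def detect_r_peaks(ecg: np.ndarray, fs: float, t0: float = 0.0) -> RriSeries:
    """Detect R-peaks: 5-30 Hz band-pass, squaring, adaptive threshold.

    The threshold is half the rolling 2 s maximum of the squared filtered
    signal; candidate peaks respect a 250 ms refractory period and are
    refined to the local maximum of the raw signal within +-50 ms.  Raises
    ValueError when fewer than two peaks are found.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < fs:  # need at least a second of signal
        raise ValueError("segment too short for R-peak detection")
    b, a = butter(2, [5.0, 30.0], btype="band", fs=fs)
    filt = filtfilt(b, a, ecg)
    env = filt**2
    roll = maximum_filter1d(env, size=int(round(2.0 * fs)), mode="nearest")
    floor = 0.05 * env.max() if env.max() > 0 else np.inf
    thresh = np.maximum(0.5 * roll, floor)
    cand, _ = find_peaks(env, distance=int(round(0.25 * fs)))
    cand = cand[env[cand] >= thresh[cand]]
    half = int(round(0.05 * fs))
    peaks = []
    for c in cand:
        lo, hi = max(c - half, 0), min(c + half + 1, ecg.size)
        peaks.append(lo + int(np.argmax(ecg[lo:hi])))
    peaks = np.unique(peaks)
    if peaks.size < 2:
        raise ValueError("fewer than 2 R-peaks detected; RRI undefined")
    return RriSeries(peak_times=t0 + peaks / fs)


def hrv_time_metrics(rri: RriSeries) -> tuple[float, float]:
    """``(mean RRI, RMSSD)`` in ms; RMSSD is NaN with <2 intervals."""
    iv = rri.intervals_ms
    if iv.size == 0:
        warnings.warn("no intervals; mean RRI undefined", stacklevel=2)
        return float("nan"), float("nan")
    mean_rri = float(iv.mean())
    if iv.size < 2:
        warnings.warn("fewer than 2 intervals; RMSSD undefined", stacklevel=2)
        return mean_rri, float("nan")
    d = np.diff(iv)
    return mean_rri, float(np.sqrt(np.mean(d**2)))


def hrv_band_power(rri: RriSeries, band: tuple[float, float]) -> float:
    """Integrated Welch power (ms^2) of the RRI tachogram over ``band``.

    Cubic-spline interpolation onto a uniform 4 Hz grid, linear detrend,
    Hann-window Welch PSD with 60 s segments at 50% overlap (single
    full-length window when the segment is shorter), trapezoidal band
    integral.  Returns NaN with a warning when the segment is shorter than
    two cycles of the band's lower edge.
    """
    times = rri.interval_times
    if times.size < 4:
        warnings.warn("too few intervals for spectral HRV", stacklevel=2)
        return float("nan")
    duration = times[-1] - times[0]
    if duration < 2.0 / band[0]:
        warnings.warn(
            f"segment ({duration:.0f} s) shorter than 2 cycles of {band[0]} Hz; "
            "band power unreliable and reported missing", stacklevel=2,
        )
        return float("nan")
    grid = np.arange(times[0], times[-1], 1.0 / _INTERP_FS)
    x = CubicSpline(times, rri.intervals_ms)(grid)
    x = x - np.polyval(np.polyfit(grid, x, 1), grid)
    nper = min(len(x), int(60 * _INTERP_FS))
    freqs, psd = welch(
        x, fs=_INTERP_FS, window="hann", nperseg=nper,
        noverlap=nper // 2, detrend="linear",
    )
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if mask.sum() < 2:
        return float("nan")
    return float(np.trapezoid(psd[mask], freqs[mask]))


def gaussian_gain(freq: float, sigma: float) -> float:
    """Amplitude gain of a Gaussian smoothing kernel (SD ``sigma`` s) at ``freq`` Hz."""
    return float(np.exp(-2.0 * np.pi**2 * freq**2 * sigma**2))


def resp_metrics(
    resp: np.ndarray, fs: float, kernel_width: float = 0.39,
    kernel_is_fwhm: bool = False,
) -> tuple[float, float]:
    """``(mean breath interval s, modulation depth)`` of a respiration segment.

    ``kernel_width`` is read as the Gaussian SD by default; set
    ``kernel_is_fwhm`` to interpret it as full width at half maximum.
    Peaks and troughs are sign changes of the smoothed first difference with
    a minimum 1 s separation.  NaNs with a warning when fewer than two peaks
    are found.
    """
    resp = np.asarray(resp, dtype=float)
    sigma = kernel_width / (2.0 * np.sqrt(2.0 * np.log(2.0))) if kernel_is_fwhm else kernel_width
    smooth = gaussian_filter1d(resp, sigma=sigma * fs)
    min_sep = int(round(1.0 * fs))
    peaks, _ = find_peaks(smooth, distance=min_sep)
    troughs, _ = find_peaks(-smooth, distance=min_sep)
    if peaks.size < 2:
        warnings.warn("fewer than 2 respiration peaks; metrics undefined", stacklevel=2)
        return float("nan"), float("nan")
    interval = float(np.mean(np.diff(peaks)) / fs)
    depths = []
    for p in peaks:
        later = troughs[troughs > p]
        if later.size:
            depths.append(smooth[p] - smooth[later[0]])
    depth = float(np.mean(depths)) if depths else float("nan")
    return interval, depth


def sc_metrics(sc: np.ndarray) -> tuple[float, float]:
    """``(mean, minimum)`` skin conductance level (uS) of the raw samples."""
    sc = np.asarray(sc, dtype=float)
    if sc.size == 0:
        raise ValueError("empty skin-conductance segment")
    return float(sc.mean()), float(sc.min())
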