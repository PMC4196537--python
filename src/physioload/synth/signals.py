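"""Seeded generators for the five recording streams.

All streams of one session share the session recording clock defined by the
schedule.  Workload enters through the per-condition weight
``SimulationConfig.condition_weight``; time-on-task drift uses the global
experiment clock (seconds since the start of session 1).  Ground truth that
downstream detectors are validated against (artifact trials, R-peak times,
blink and tracking-loss runs) is retained on each session recording.

Signal models (deliberately minimal surrogates, not biophysical):

* EEG: 1/f-shaped background noise, a ~10 Hz alpha oscillation whose
  amplitude falls with workload (largest at Pz), a ~6 Hz theta oscillation
  rising with workload (largest at Fz), a stimulus-locked P300-like raised
  cosine (0.3-0.5 s, largest at Pz) attenuating with workload, and sparse
  high-amplitude artifact trials.
* ECG: QRS-like pulses at cumulative inter-beat intervals; the interval
  shortens with workload and time on task and is modulated at 0.10 and
  0.30 Hz with depth shrinking under workload (mid-/high-band HRV).
* Respiration: smooth oscillation whose rate rises with workload.
* Skin conductance: tonic level rising with workload and drifting upward,
  plus an exponentially decaying peak at each block onset.
* Gaze: per-eye pupil diameter around a workload-dilated baseline, with
  blinks as Poisson events of 2-25 invalid frames (rate falling with
  workload) and occasional longer tracking-loss runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from physioload.config import EEG_CHANNELS, SimulationConfig
from physioload.events import block_table
from physioload.synth.schedule import generate_schedule

__all__ = [
    "SessionRecording", "RawRecordingBundle", "generate_participant",
    "synth_eeg", "synth_ecg", "synth_respiration", "synth_sc", "synth_gaze",
]

# Channel topographies (relative amplitude per channel, order = EEG_CHANNELS:
# Fz, FCz, Pz, C3, C4, F3, F4).
_ALPHA_TOPO = np.array([0.45, 0.55, 1.00, 0.60, 0.60, 0.40, 0.40])
_THETA_TOPO = np.array([1.00, 0.80, 0.45, 0.50, 0.50, 0.75, 0.75])
_P300_TOPO = np.array([0.50, 0.65, 1.00, 0.55, 0.55, 0.45, 0.45])

_STREAM_CODE = {"eeg": 1, "ecg": 2, "sc": 3, "resp": 4, "gaze": 5}


@dataclass
class SessionRecording:
    """All streams of one session plus generator ground truth."""

    session: int
    duration: float
    fs_eeg: float
    fs_physio: float
    fs_gaze: float
    eeg: np.ndarray | None = None          # (7, n) uV
    ecg: np.ndarray | None = None          # (n,) mV
    sc: np.ndarray | None = None           # (n,) uS
    resp: np.ndarray | None = None         # (n,) a.u.
    gaze: pd.DataFrame | None = None       # frame, left/right pupil + validity
    truth: dict = field(default_factory=dict)


@dataclass
class RawRecordingBundle:
    """Per-participant multi-rate signal set across sessions."""

    participant: str
    eeg_channels: tuple[str, ...]
    sessions: dict[int, SessionRecording]

    def __getitem__(self, session: int) -> SessionRecording:
        return self.sessions[session]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _session_blocks(events: pd.DataFrame, session: int) -> pd.DataFrame:
    blocks = block_table(events)
    return blocks[blocks["session"] == session].reset_index(drop=True)


def _weight_envelope(blocks: pd.DataFrame, t: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Per-sample workload weight (0 outside blocks / in baseline)."""
    w = np.zeros_like(t)
    for _, row in blocks.iterrows():
        wt = config.condition_weight(row["condition"])
        if wt:
            w[(t >= row["block_start"]) & (t < row["block_end"])] = wt
    return w


def _block_offset_envelope(
    blocks: pd.DataFrame, t: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Piecewise-constant random per-block offset (slow between-block noise)."""
    out = np.zeros_like(t)
    for _, row in blocks.iterrows():
        out[(t >= row["block_start"]) & (t < row["block_end"])] = rng.normal(0.0, sd)
    return out


def _pink_noise(shape: tuple[int, ...], fs: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with 1/f power shaping (flat below 1 Hz), given RMS."""
    white = rng.standard_normal(shape)
    if rms == 0:
        return np.zeros(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / fs)
    gain = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    gain[0] = 0.0
    shaped = np.fft.irfft(spec * gain, n=shape[-1], axis=-1)
    scale = rms / max(shaped.std(), 1e-12)
    return shaped * scale


def _slow_noise(n: int, fs: float, rms: float, rng: np.random.Generator, tau: float = 5.0) -> np.ndarray:
    """Low-frequency noise with correlation time ``tau`` s, given RMS.

    Generated on a coarse grid (a few points per tau) smoothed with a short
    Gaussian, then linearly interpolated to the sample grid — equivalent in
    spectral content to filtering at full rate but far cheaper for long
    high-rate streams.
    """
    if rms == 0:
        return np.zeros(n)
    fs_lo = max(4.0 / tau, 0.5)
    n_lo = max(int(np.ceil(n / fs * fs_lo)) + 2, 8)
    x = gaussian_filter1d(rng.standard_normal(n_lo), sigma=tau * fs_lo)
    sd = x.std()
    if sd == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    return np.interp(t, np.arange(n_lo) / fs_lo, x) * (rms / sd)


def p300_template(fs: float, amp: float = 1.0) -> np.ndarray:
    """One-cycle raised cosine spanning 0.3-0.5 s post-stimulus."""
    t = np.arange(int(round(0.5 * fs)) + 1) / fs
    tpl = np.zeros_like(t)
    in_win = (t >= 0.3) & (t <= 0.5)
    tpl[in_win] = 0.5 * (1 - np.cos(2 * np.pi * (t[in_win] - 0.3) / 0.2))
    return amp * tpl


# ---------------------------------------------------------------------------
# per-modality generators
# ---------------------------------------------------------------------------

def synth_eeg(
    events: pd.DataFrame, session: int, config: SimulationConfig, seed_seq: np.random.SeedSequence
) -> tuple[np.ndarray, dict]:
    """Generate the 7-channel EEG stream of one session.

    Returns ``(signal (7, n) in uV, truth)`` where truth holds the onset
    times of trials that received an injected artifact.
    """
    rng = np.random.default_rng(seed_seq)
    blocks = _session_blocks(events, session)
    n = int(round(config.session_duration * config.fs_eeg))
    t = np.arange(n) / config.fs_eeg
    sig = _pink_noise((len(EEG_CHANNELS), n), config.fs_eeg, config.eeg_noise_rms, rng)

    w = _weight_envelope(blocks, t, config)

    # oscillations: per-block lognormal amplitude jitter shared across channels
    def osc(freq: float, base_amp: float, mod: np.ndarray, topo: np.ndarray) -> np.ndarray:
        jitter = np.ones_like(t)
        for _, row in blocks.iterrows():
            m = (t >= row["block_start"]) & (t < row["block_end"])
            jitter[m] = rng.lognormal(0.0, config.eeg_block_jitter)
        phase0 = rng.uniform(0, 2 * np.pi, size=len(EEG_CHANNELS))
        # phase random walk: real cortical rhythms decohere within ~1 s, so
        # epochs at a fixed SOA are not mutually phase-locked
        step_sd = np.sqrt(config.osc_phase_diffusion / config.fs_eeg)
        walk = np.cumsum(rng.normal(0.0, step_sd, size=(len(EEG_CHANNELS), n)), axis=1)
        carrier = np.sin(2 * np.pi * freq * t[None, :] + phase0[:, None] + walk)
        return topo[:, None] * (base_amp * mod * jitter)[None, :] * carrier

    alpha_mod = 1.0 - config.alpha_suppression * w
    theta_mod = 1.0 + config.theta_gain * w
    sig += osc(config.alpha_freq, config.alpha_amp, alpha_mod, _ALPHA_TOPO)
    sig += osc(config.theta_freq, config.theta_amp, theta_mod, _THETA_TOPO)

    # stimulus-locked ERP; per-block lognormal amplitude jitter like the
    # oscillations, so block averages carry realistic between-block variance
    tpl = p300_template(config.fs_eeg)
    onsets = events[(events["session"] == session) & events["onset"].notna()]
    erp_jitter = {
        int(b): rng.lognormal(0.0, config.eeg_block_jitter)
        for b in blocks["block"]
    }
    artifact_onsets: list[float] = []
    for _, row in onsets.iterrows():
        i0 = int(round(row["onset"] * config.fs_eeg))
        wt = config.condition_weight(row["condition"])
        amp = (config.p300_amp * (1.0 - config.p300_attenuation * wt)
               * erp_jitter[int(row["block"])])
        seg = tpl[: max(0, min(len(tpl), n - i0))]
        if len(seg):
            sig[:, i0:i0 + len(seg)] += _P300_TOPO[:, None] * amp * seg[None, :]
        if config.artifact_rate > 0 and rng.random() < config.artifact_rate:
            artifact_onsets.append(float(row["onset"]))
            a0 = max(0, i0 - int(round(0.5 * config.fs_eeg)))
            a1 = min(n, i0 + int(round(2.0 * config.fs_eeg)))
            sig[:, a0:a1] += rng.normal(0.0, config.artifact_amp, size=(len(EEG_CHANNELS), a1 - a0))

    return sig, {"artifact_onsets": np.asarray(artifact_onsets)}


def qrs_template(fs: float, width: float = 0.04, amp: float = 1.0) -> np.ndarray:
    """Symmetric QRS-like pulse: raised cosine of the given width (s)."""
    half = int(round(width * fs / 2))
    k = np.arange(-half, half + 1)
    return amp * 0.5 * (1 + np.cos(np.pi * k / half))


def synth_ecg(
    events: pd.DataFrame, session: int, config: SimulationConfig,
    seed_seq: np.random.SeedSequence, t_offset: float = 0.0,
) -> tuple[np.ndarray, dict]:
    """Generate one session's ECG (mV) from a beat-interval model.

    Returns ``(signal, truth)`` with truth holding the exact R-peak times
    (seconds on the session clock).
    """
    rng = np.random.default_rng(seed_seq)
    blocks = _session_blocks(events, session)
    duration = config.session_duration
    n = int(round(duration * config.fs_physio))

    starts = blocks["block_start"].to_numpy()
    ends = blocks["block_end"].to_numpy()
    weights = np.array([config.condition_weight(c) for c in blocks["condition"]])
    offsets = rng.normal(0.0, config.rri_block_sd, size=len(blocks))
    depth_jitter = rng.lognormal(0.0, config.hrv_block_jitter, size=len(blocks))

    def block_idx(tt: float) -> int:
        hit = np.nonzero((tt >= starts) & (tt < ends))[0]
        return int(hit[0]) if hit.size else -1

    beats = [0.3 * rng.random()]
    while beats[-1] < duration:
        tt = beats[-1]
        bi = block_idx(tt)
        wt = weights[bi] if bi >= 0 else 0.0
        boff = offsets[bi] if bi >= 0 else 0.0
        depth = (1.0 - config.hrv_suppression * wt) * (depth_jitter[bi] if bi >= 0 else 1.0)
        rri = (
            config.rri_base
            - config.rri_workload_effect * wt
            - config.rri_drift * (t_offset + tt)
            + boff
            + depth * config.hrv_mf_depth * np.sin(2 * np.pi * 0.10 * tt)
            + depth * config.hrv_hf_depth * np.sin(2 * np.pi * 0.30 * tt)
            + rng.normal(0.0, config.rri_jitter)
        )
        beats.append(tt + max(rri, 0.3))
    r_times = np.array(beats[:-1])

    sig = np.zeros(n)
    tpl = qrs_template(config.fs_physio)
    half = (len(tpl) - 1) // 2
    for rt in r_times:
        c = int(round(rt * config.fs_physio))
        lo, hi = c - half, c + half + 1
        s0, s1 = max(lo, 0), min(hi, n)
        if s1 > s0:
            sig[s0:s1] += tpl[s0 - lo: s1 - lo]
    sig += rng.normal(0.0, 0.02, size=n)  # mV-scale measurement noise
    return sig, {"r_peaks": r_times}


def synth_respiration(
    events: pd.DataFrame, session: int, config: SimulationConfig,
    seed_seq: np.random.SeedSequence, t_offset: float = 0.0,
) -> tuple[np.ndarray, dict]:
    """Generate one session's respiration belt signal (a.u.)."""
    rng = np.random.default_rng(seed_seq)
    blocks = _session_blocks(events, session)
    n = int(round(config.session_duration * config.fs_physio))
    t = np.arange(n) / config.fs_physio
    w = _weight_envelope(blocks, t, config)
    boff = _block_offset_envelope(blocks, t, config.resp_rate_block_sd, rng)
    rate = config.resp_rate_base * (
        1.0 + config.resp_rate_gain * w + boff + config.resp_rate_drift * (t_offset + t)
    )
    phase = 2 * np.pi * np.cumsum(rate) / config.fs_physio + rng.uniform(0, 2 * np.pi)
    sig = config.resp_amp * np.sin(phase)
    if config.resp_noise:
        sig = sig + rng.normal(0.0, config.resp_noise, size=n)
    return sig, {"rate_envelope": rate}


def synth_sc(
    events: pd.DataFrame, session: int, config: SimulationConfig,
    seed_seq: np.random.SeedSequence, t_offset: float = 0.0,
) -> tuple[np.ndarray, dict]:
    """Generate one session's skin conductance (uS): tonic + block-onset phasic."""
    rng = np.random.default_rng(seed_seq)
    blocks = _session_blocks(events, session)
    n = int(round(config.session_duration * config.fs_physio))
    t = np.arange(n) / config.fs_physio
    w = _weight_envelope(blocks, t, config)
    tonic = (
        config.sc_base
        + config.sc_gain * w
        + config.sc_drift * (t_offset + t)
        + _block_offset_envelope(blocks, t, config.sc_block_sd, rng)
        + _slow_noise(n, config.fs_physio, config.sc_noise, rng)
    )
    phasic = np.zeros(n)
    for t0 in blocks["block_start"]:
        m = t >= t0
        phasic[m] += config.sc_phasic_amp * np.exp(-(t[m] - t0) / config.sc_phasic_tau)
    return tonic + phasic, {"tonic_level": tonic}


def synth_gaze(
    events: pd.DataFrame, session: int, config: SimulationConfig,
    seed_seq: np.random.SeedSequence, t_offset: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Generate one session's gaze frames (60 Hz).

    Returns ``(frame table, truth)``; truth holds the injected blink runs
    (start frame, length) and the >25-frame tracking-loss runs.
    """
    rng = np.random.default_rng(seed_seq)
    blocks = _session_blocks(events, session)
    n = int(round(config.session_duration * config.fs_gaze))
    t = np.arange(n) / config.fs_gaze
    w = _weight_envelope(blocks, t, config)
    level = (
        config.pupil_base
        + config.pupil_gain * w
        + config.pupil_drift * (t_offset + t)
        + _block_offset_envelope(blocks, t, config.pupil_block_sd, rng)
        + _slow_noise(n, config.fs_gaze, config.pupil_noise, rng)
    )
    left = level + rng.normal(0.0, 0.01, size=n)
    right = level + rng.normal(0.0, 0.01, size=n)
    valid = np.ones(n, dtype=bool)

    boff = _block_offset_envelope(blocks, t, config.blink_rate_block_sd, rng)
    # floor at a quarter of the base rate: subjects rarely stop blinking
    blink_rate = config.blink_rate_base * np.maximum(
        1.0 - config.blink_rate_suppression * w + boff, 0.25
    )  # blinks / min
    hazard = blink_rate / 60.0 / config.fs_gaze  # per frame

    occupied = np.zeros(n, dtype=bool)  # invalid or buffer frames

    def try_place(start: int, length: int) -> bool:
        lo, hi = max(start - 1, 0), min(start + length + 1, n)
        if start + length > n or occupied[lo:hi].any():
            return False
        occupied[lo:hi] = True
        valid[start:start + length] = False
        return True

    losses: list[tuple[int, int]] = []
    n_loss = rng.poisson(config.tracking_loss_rate * config.session_duration / 60.0)
    for _ in range(n_loss):
        start = int(rng.integers(0, max(n - 60, 1)))
        length = int(rng.integers(26, 61))
        if try_place(start, length):
            losses.append((start, length))

    blinks: list[tuple[int, int]] = []
    draws = rng.random(n)
    durations = rng.integers(2, 26, size=n)
    for i in np.nonzero(draws < hazard)[0]:
        if try_place(int(i), int(durations[i])):
            blinks.append((int(i), int(durations[i])))
    blinks.sort()

    gaze = pd.DataFrame({
        "frame": np.arange(n),
        "left_pupil": np.where(valid, left, np.nan),
        "left_valid": valid.astype(int),
        "right_pupil": np.where(valid, right, np.nan),
        "right_valid": valid.astype(int),
    })
    return gaze, {"blinks": blinks, "losses": losses}


# ---------------------------------------------------------------------------
# participant-level composition
# ---------------------------------------------------------------------------

def generate_participant(
    config: SimulationConfig,
    participant_index: int,
    seed: int | None = None,
) -> tuple[RawRecordingBundle, pd.DataFrame]:
    """Generate one participant's full recording bundle and event log.

    Deterministic given ``(config, participant_index, seed)``; ``seed``
    defaults to ``config.seed``.  Only the streams named in
    ``config.streams`` are generated (the rest stay ``None``).
    """
    seed = config.seed if seed is None else seed
    pid = f"P{participant_index:02d}"
    events = generate_schedule(
        config, seed=int(np.random.SeedSequence([seed, participant_index]).generate_state(1)[0] % (2**31)),
        participant=pid,
    )
    sessions: dict[int, SessionRecording] = {}
    for session in range(1, config.n_sessions + 1):
        t_offset = (session - 1) * config.session_duration
        rec = SessionRecording(
            session=session, duration=config.session_duration,
            fs_eeg=config.fs_eeg, fs_physio=config.fs_physio, fs_gaze=config.fs_gaze,
        )

        def sseq(stream: str) -> np.random.SeedSequence:
            return np.random.SeedSequence(
                [seed, participant_index, session, _STREAM_CODE[stream]]
            )

        if "eeg" in config.streams:
            rec.eeg, truth = synth_eeg(events, session, config, sseq("eeg"))
            rec.truth.update(truth)
        if "ecg" in config.streams:
            rec.ecg, truth = synth_ecg(events, session, config, sseq("ecg"), t_offset)
            rec.truth.update(truth)
        if "sc" in config.streams:
            rec.sc, truth = synth_sc(events, session, config, sseq("sc"), t_offset)
            rec.truth.update(truth)
        if "resp" in config.streams:
            rec.resp, truth = synth_respiration(events, session, config, sseq("resp"), t_offset)
            rec.truth.update(truth)
        if "gaze" in config.streams:
            rec.gaze, truth = synth_gaze(events, session, config, sseq("gaze"), t_offset)
            rec.truth.update(truth)
        sessions[session] = rec

    bundle = RawRecordingBundle(participant=pid, eeg_channels=EEG_CHANNELS, sessions=sessions)
    return bundle, events
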