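"""Feature-table assembly, segmentation, train/test split and standardization.

One row of the feature table is one workload data segment (a full 2-min
block, or a 30 s quarter of it) of one participant, keyed by participant,
session, block, sub-segment, condition and the segment's mid-time on the
task-time axis.  Feature columns are organized in the three sensor groups:

* EEG: ``eeg.<ch>.erp.<ms>`` (101 samples x 7 channels), ``eeg.<ch>.pow.<f>``
  (37 frequencies x 7 channels), ``eeg.<ch>.alpha``, ``eeg.<ch>.theta``
* Physiology: ``sc.mean``, ``sc.min``, ``resp.freq``, ``resp.depth``,
  ``ecg.mean_rri``, ``ecg.rmssd``, ``ecg.mf_hrv``, ``ecg.hf_hrv``
* Eye: ``eye.pupil``, ``eye.blink_rate``, ``eye.blink_dur``

plus the ``time`` feature: the segment's mid-time in seconds of cumulative
workload-task time (baseline blocks, breaks and rating periods do not
advance this clock, so the first 2-min block has mid-time 60 s and the
second 180 s).

The train/test split follows the simulated-online protocol: sessions 1-3
train, session 4 test.  Standardization (z-scoring) uses training means and
SDs only; the identical transform is applied to test rows, and a column
constant in training maps to zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from physioload import eeg as eeg_mod
from physioload import eye as eye_mod
from physioload import physio
from physioload.config import EEG_CHANNELS, WORKLOAD_CONDITIONS, SimulationConfig
from physioload.events import block_table
from physioload.synth.signals import RawRecordingBundle, generate_participant

__all__ = [
    "META_COLUMNS", "feature_columns", "select_features", "decompose_features",
    "extract_features", "build_feature_table", "mid_time",
    "split_train_test", "standardize",
]

META_COLUMNS = ["participant", "session", "block", "subseg", "condition", "mid_time"]

_ERP_MS = [int(round(t)) for t in np.arange(0, 1001, 10)]

ERP_COLS = {ch: [f"eeg.{ch}.erp.{ms}" for ms in _ERP_MS] for ch in EEG_CHANNELS}
POW_COLS = {ch: [f"eeg.{ch}.pow.{f:.1f}" for f in eeg_mod.SPECTRAL_FREQS] for ch in EEG_CHANNELS}
ALPHA_COLS = {ch: f"eeg.{ch}.alpha" for ch in EEG_CHANNELS}
THETA_COLS = {ch: f"eeg.{ch}.theta" for ch in EEG_CHANNELS}

PHYSIO_COLS = [
    "sc.mean", "sc.min", "resp.freq", "resp.depth",
    "ecg.mean_rri", "ecg.rmssd", "ecg.mf_hrv", "ecg.hf_hrv",
]
EYE_COLS = ["eye.pupil", "eye.blink_rate", "eye.blink_dur"]


def _flat(d: dict[str, list[str]]) -> list[str]:
    return [c for ch in EEG_CHANNELS for c in d[ch]]


#: Named feature sets mirroring the feature/sensor/sensor-group table.
#: EEG sensor-level and group-level sets are "ERP + spectral power".
_REGISTRY: dict[str, list[str]] = {
    "erp": _flat(ERP_COLS),
    "power": _flat(POW_COLS),
    "alpha": [ALPHA_COLS[ch] for ch in EEG_CHANNELS],
    "theta": [THETA_COLS[ch] for ch in EEG_CHANNELS],
    "erp_pz": ERP_COLS["Pz"],
    "power_pz": POW_COLS["Pz"],
    "alpha_pz": [ALPHA_COLS["Pz"]],
    "theta_fz": [THETA_COLS["Fz"]],
    "eeg": _flat(ERP_COLS) + _flat(POW_COLS),          # sensor group, 966
    "pz": ERP_COLS["Pz"] + POW_COLS["Pz"],             # single electrode, 138
    "sc": PHYSIO_COLS[0:2],
    "resp": PHYSIO_COLS[2:4],
    "ecg": PHYSIO_COLS[4:8],
    "physiology": list(PHYSIO_COLS),
    "eye": list(EYE_COLS),
    "all": None,  # filled below
    "time": ["time"],
}
_REGISTRY["all"] = _REGISTRY["eeg"] + _REGISTRY["physiology"] + _REGISTRY["eye"]
for _c in PHYSIO_COLS + EYE_COLS:
    _REGISTRY[_c] = [_c]

#: Atomic features (single table rows) each named set decomposes into for
#: decision-level fusion: one classifier per atom, probabilities averaged.
_ATOMS: dict[str, list[str]] = {
    "eeg": ["erp", "power"],
    "pz": ["erp_pz", "power_pz"],
    "physiology": list(PHYSIO_COLS),
    "sc": PHYSIO_COLS[0:2],
    "resp": PHYSIO_COLS[2:4],
    "ecg": PHYSIO_COLS[4:8],
    "eye": list(EYE_COLS),
    "all": ["erp", "power"] + PHYSIO_COLS + EYE_COLS,
}


def feature_columns(config: SimulationConfig | None = None) -> list[str]:
    """All feature column names in canonical order (EEG, Physiology, Eye, time)."""
    return _REGISTRY["all"] + _REGISTRY["alpha"] + _REGISTRY["theta"] + ["time"]


def select_features(spec: str, include_time: bool = False) -> list[str]:
    """Resolve a feature specification to an ordered column list.

    ``spec`` names a feature, sensor or sensor group from the feature table
    (e.g. ``"eeg"``, ``"pz"``, ``"alpha"``, ``"sc.mean"``) or a ``+``-joined
    concatenation (``"eeg+eye"``); matching is case-insensitive.  Sets that
    include alpha or theta never also include the raw power columns.
    """
    cols: list[str] = []
    for part in str(spec).split("+"):
        key = part.strip().lower()
        if key not in _REGISTRY:
            raise KeyError(
                f"unknown feature spec {part!r}; valid names: "
                + ", ".join(sorted(k for k in _REGISTRY if _REGISTRY[k]))
            )
        cols.extend(c for c in _REGISTRY[key] if c not in cols)
    if include_time and "time" not in cols:
        cols.append("time")
    return cols


def decompose_features(spec: str, include_time: bool = False) -> list[list[str]]:
    """Atomic feature subsets of a spec, for decision-level fusion."""
    atoms: list[str] = []
    for part in str(spec).split("+"):
        key = part.strip().lower()
        atoms.extend(_ATOMS.get(key, [key]))
    if include_time:
        atoms.append("time")
    return [select_features(a) for a in atoms]


# ---------------------------------------------------------------------------
# segmentation and assembly
# ---------------------------------------------------------------------------

def mid_time(block_rank: int, subseg: int, segment_length: float, block_duration: float = 120.0) -> float:
    """Mid-time (s) of a segment on the cumulative workload-task-time axis.

    ``block_rank`` counts workload blocks from 0 across all sessions in
    chronological order; baseline blocks and inter-block periods do not
    advance the clock.
    """
    return block_rank * block_duration + subseg * segment_length + segment_length / 2.0


def extract_features(
    bundle: RawRecordingBundle,
    events: pd.DataFrame,
    config: SimulationConfig,
    segment_length: float = 120.0,
) -> pd.DataFrame:
    """Per-segment feature rows for one participant.

    ``segment_length`` must divide the block duration; 120 gives one row per
    workload block, 30 gives four.  Only features of the streams present in
    the bundle are produced.
    """
    n_sub = config.block_duration / segment_length
    if abs(n_sub - round(n_sub)) > 1e-9:
        raise ValueError("segment_length must divide block_duration")
    n_sub = int(round(n_sub))

    blocks = block_table(events)
    work = blocks[blocks["condition"].isin(WORKLOAD_CONDITIONS)].sort_values(
        ["session", "block"]).reset_index(drop=True)

    rows: list[dict] = []
    for session in sorted(bundle.sessions):
        rec = bundle.sessions[session]
        s_events = events[(events["session"] == session) & events["onset"].notna()]
        s_work = work[work["session"] == session]

        epochs = None
        if rec.eeg is not None and len(s_events):
            epochs = eeg_mod.epoch(
                rec.eeg, rec.fs_eeg,
                s_events["onset"].to_numpy(), s_events["condition"].to_numpy(),
                channels=bundle.eeg_channels,
            )
            epochs = eeg_mod.reject_high_variance(epochs)
        rri_session = None
        if rec.ecg is not None:
            try:
                rri_session = physio.detect_r_peaks(rec.ecg, rec.fs_physio)
            except ValueError:
                warnings.warn(f"{bundle.participant} s{session}: R-peak detection failed")
        blinks_session = eye_mod.detect_blinks(rec.gaze) if rec.gaze is not None else None

        for _, brow in s_work.iterrows():
            rank = int(work[(work["session"] == brow["session"]) &
                            (work["block"] == brow["block"])].index[0])
            for sub in range(n_sub):
                t0 = brow["block_start"] + sub * segment_length
                t1 = t0 + segment_length
                row: dict = dict(
                    participant=bundle.participant, session=int(session),
                    block=int(brow["block"]), subseg=sub,
                    condition=brow["condition"],
                    mid_time=mid_time(rank, sub, segment_length, config.block_duration),
                )
                row["time"] = row["mid_time"]

                if epochs is not None:
                    m = (epochs.onsets >= t0 - 1e-9) & (epochs.onsets < t1 - 1e-9)
                    seg_ep = epochs.subset(m)
                    if seg_ep.n_kept == 0:
                        raise ValueError(
                            f"{bundle.participant} s{session} block {brow['block']}: "
                            "all trials rejected; EEG block averages undefined"
                        )
                    erp = eeg_mod.erp_features(seg_ep).reshape(len(EEG_CHANNELS), -1)
                    pow_ = eeg_mod.spectral_features(seg_ep)
                    alpha = eeg_mod.band_log_power(pow_, "alpha")
                    theta = eeg_mod.band_log_power(pow_, "theta")
                    for ci, ch in enumerate(EEG_CHANNELS):
                        row.update(zip(ERP_COLS[ch], erp[ci]))
                        row.update(zip(POW_COLS[ch], pow_[ci]))
                        row[ALPHA_COLS[ch]] = alpha[ci]
                        row[THETA_COLS[ch]] = theta[ci]

                if rri_session is not None:
                    pm = (rri_session.peak_times >= t0) & (rri_session.peak_times < t1)
                    seg_rri = physio.RriSeries(rri_session.peak_times[pm])
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        mean_rri, rmssd = physio.hrv_time_metrics(seg_rri)
                        row["ecg.mean_rri"] = mean_rri
                        row["ecg.rmssd"] = rmssd
                        row["ecg.mf_hrv"] = physio.hrv_band_power(seg_rri, physio.MF_BAND)
                        row["ecg.hf_hrv"] = physio.hrv_band_power(seg_rri, physio.HF_BAND)

                if rec.resp is not None:
                    i0, i1 = int(round(t0 * rec.fs_physio)), int(round(t1 * rec.fs_physio))
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        freq, depth = physio.resp_metrics(rec.resp[i0:i1], rec.fs_physio)
                    row["resp.freq"] = freq
                    row["resp.depth"] = depth

                if rec.sc is not None:
                    i0, i1 = int(round(t0 * rec.fs_physio)), int(round(t1 * rec.fs_physio))
                    row["sc.mean"], row["sc.min"] = physio.sc_metrics(rec.sc[i0:i1])

                if rec.gaze is not None:
                    f0, f1 = int(round(t0 * rec.fs_gaze)), int(round(t1 * rec.fs_gaze))
                    seg_blinks = [b for b in blinks_session if f0 <= b.start < f1]
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        pupil, rate, dur = eye_mod.eye_metrics(
                            rec.gaze.iloc[f0:f1], seg_blinks, duration=segment_length
                        )
                    row["eye.pupil"] = pupil
                    row["eye.blink_rate"] = rate
                    row["eye.blink_dur"] = dur

                rows.append(row)
    return pd.DataFrame(rows)


def build_feature_table(
    config: SimulationConfig,
    seed: int | None = None,
    segment_length: float = 120.0,
    participants: int | None = None,
) -> pd.DataFrame:
    """Simulate all participants and assemble the group feature table."""
    n = config.n_participants if participants is None else participants
    tables = []
    for p in range(1, n + 1):
        bundle, events = generate_participant(config, p, seed=seed)
        tables.append(extract_features(bundle, events, config, segment_length))
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# split and standardization
# ---------------------------------------------------------------------------

def split_train_test(
    table: pd.DataFrame, n_sessions: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sessions 1..n-1 train, the last session tests (simulated online)."""
    present = set(table["session"].unique())
    missing = set(range(1, n_sessions + 1)) - present
    if missing:
        raise ValueError(f"missing session(s) {sorted(missing)}; cannot split")
    train = table[table["session"] < n_sessions].copy()
    test = table[table["session"] == n_sessions].copy()
    return train, test


def standardize(
    train: pd.DataFrame, test: pd.DataFrame, columns: list[str]
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Z-score ``columns`` with training statistics; apply the same to test.

    Returns ``(X_train, X_test, params)`` where params holds the training
    mean and SD per column.  Columns with zero training SD transform to 0.
    """
    mu = train[columns].mean(axis=0).to_numpy()
    sd = train[columns].std(axis=0, ddof=0).to_numpy()
    safe = np.where(sd > 0, sd, 1.0)
    xtr = (train[columns].to_numpy() - mu) / safe
    xte = (test[columns].to_numpy() - mu) / safe
    zero = sd == 0
    xtr[:, zero] = 0.0
    xte[:, zero] = 0.0
    params = pd.DataFrame({"column": columns, "mean": mu, "sd": sd})
    return xtr, xte, params
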