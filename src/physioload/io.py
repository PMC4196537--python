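"""Plain-text persistence for recordings and feature tables.

Signals use a small native TSV format: comment header lines carrying the
sampling rate and channel names, then one row per sample.  Gaze frames and
event logs are plain TSV; feature tables are CSV with a JSON sidecar
mapping each column to (sensor group, sensor, feature, index).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from physioload import dataset as ds
from physioload.config import EEG_CHANNELS
from physioload.events import read_events_tsv, write_events_tsv
from physioload.synth.signals import RawRecordingBundle, SessionRecording

__all__ = [
    "write_signal_tsv", "read_signal_tsv", "write_gaze_tsv", "read_gaze_tsv",
    "write_bundle", "read_bundle", "write_feature_table", "read_feature_table",
]


def write_signal_tsv(path, data: np.ndarray, fs: float, channels) -> None:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    with open(path, "w") as fh:
        fh.write(f"# fs={fs:g}\n")
        fh.write("# channels=" + ",".join(channels) + "\n")
        np.savetxt(fh, data.T, fmt="%.6f", delimiter="\t")


def read_signal_tsv(path) -> tuple[np.ndarray, float, list[str]]:
    with open(path) as fh:
        fs = float(fh.readline().split("=", 1)[1])
        channels = fh.readline().split("=", 1)[1].strip().split(",")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2).T
    return data, fs, channels


def write_gaze_tsv(path, gaze: pd.DataFrame) -> None:
    out = gaze.copy()
    for col in ("left_pupil", "right_pupil"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


def read_gaze_tsv(path) -> pd.DataFrame:
    gaze = pd.read_csv(path, sep="\t")
    for col in ("left_pupil", "right_pupil"):
        gaze[col] = pd.to_numeric(gaze[col], errors="coerce")
    return gaze


def write_bundle(outdir, bundle: RawRecordingBundle, events: pd.DataFrame) -> None:
    """Persist one participant's streams and event log under ``outdir``."""
    outdir = Path(outdir) / bundle.participant
    outdir.mkdir(parents=True, exist_ok=True)
    write_events_tsv(events, outdir / "events.tsv")
    for s, rec in bundle.sessions.items():
        tag = f"s{s}"
        if rec.eeg is not None:
            write_signal_tsv(outdir / f"{tag}_eeg.tsv", rec.eeg, rec.fs_eeg, bundle.eeg_channels)
        for name, sig in (("ecg", rec.ecg), ("sc", rec.sc), ("resp", rec.resp)):
            if sig is not None:
                write_signal_tsv(outdir / f"{tag}_{name}.tsv", sig, rec.fs_physio, [name])
        if rec.gaze is not None:
            write_gaze_tsv(outdir / f"{tag}_gaze.tsv", rec.gaze)


def read_bundle(pdir) -> tuple[RawRecordingBundle, pd.DataFrame]:
    """Load a participant directory written by :func:`write_bundle`."""
    pdir = Path(pdir)
    events = read_events_tsv(pdir / "events.tsv")
    sessions: dict[int, SessionRecording] = {}
    for s in sorted(events["session"].unique()):
        tag = f"s{s}"
        rec = SessionRecording(session=int(s), duration=float("nan"),
                               fs_eeg=256.0, fs_physio=300.0, fs_gaze=60.0)
        p = pdir / f"{tag}_eeg.tsv"
        if p.exists():
            rec.eeg, rec.fs_eeg, _ = read_signal_tsv(p)
        for name in ("ecg", "sc", "resp"):
            p = pdir / f"{tag}_{name}.tsv"
            if p.exists():
                sig, rec.fs_physio, _ = read_signal_tsv(p)
                setattr(rec, name, sig[0])
        p = pdir / f"{tag}_gaze.tsv"
        if p.exists():
            rec.gaze = read_gaze_tsv(p)
        sessions[int(s)] = rec
    return RawRecordingBundle(
        participant=pdir.name, eeg_channels=EEG_CHANNELS, sessions=sessions
    ), events


def _column_sidecar() -> dict[str, dict]:
    meta: dict[str, dict] = {}
    for ch in EEG_CHANNELS:
        for i, c in enumerate(ds.ERP_COLS[ch]):
            meta[c] = {"group": "EEG", "sensor": ch, "feature": "erp", "index": i}
        for i, c in enumerate(ds.POW_COLS[ch]):
            meta[c] = {"group": "EEG", "sensor": ch, "feature": "power", "index": i}
        meta[ds.ALPHA_COLS[ch]] = {"group": "EEG", "sensor": ch, "feature": "alpha", "index": 0}
        meta[ds.THETA_COLS[ch]] = {"group": "EEG", "sensor": ch, "feature": "theta", "index": 0}
    sensors = {"sc": "skin conductance electrodes", "resp": "respiration belt",
               "ecg": "ECG electrodes", "eye": "eye camera"}
    for c in ds.PHYSIO_COLS:
        meta[c] = {"group": "Physiology", "sensor": sensors[c.split(".")[0]],
                   "feature": c.split(".")[1], "index": 0}
    for c in ds.EYE_COLS:
        meta[c] = {"group": "Eye", "sensor": sensors["eye"],
                   "feature": c.split(".")[1], "index": 0}
    meta["time"] = {"group": "Time", "sensor": "clock", "feature": "time", "index": 0}
    return meta


def write_feature_table(path, table: pd.DataFrame) -> None:
    """Feature table to CSV with a ``<path>.columns.json`` sidecar."""
    path = Path(path)
    table.to_csv(path, index=False)
    sidecar = {c: m for c, m in _column_sidecar().items() if c in table.columns}
    with open(path.with_suffix(path.suffix + ".columns.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant": str})
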