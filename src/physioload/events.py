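"""Event-log container and tab-separated persistence.

An event log is a pandas DataFrame with one row per stimulus presentation
(workload blocks) or one marker row per baseline block, carrying the block
bookkeeping needed by every downstream module:

``participant, session, block, condition, block_start, block_end,
onset, letter, is_target``

Times are seconds on the session recording clock; ``session`` and ``block``
are 1-based; baseline rows have an empty letter and a missing onset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["EVENT_COLUMNS", "block_table", "write_events_tsv", "read_events_tsv"]

EVENT_COLUMNS = [
    "participant", "session", "block", "condition",
    "block_start", "block_end", "onset", "letter", "is_target",
]


def block_table(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse an event log to one row per block (schedule view).

    Rows are ordered by (participant, session, block) and keep the block
    condition and boundaries plus the stimulus count.
    """
    grp = events.groupby(["participant", "session", "block"], sort=True)
    out = grp.agg(
        condition=("condition", "first"),
        block_start=("block_start", "first"),
        block_end=("block_end", "first"),
        n_stimuli=("onset", lambda s: int(s.notna().sum())),
        n_targets=("is_target", "sum"),
    ).reset_index()
    return out


def write_events_tsv(events: pd.DataFrame, path) -> None:
    """Write an event log as tab-separated text, times to 6 decimals."""
    out = events.loc[:, EVENT_COLUMNS].copy()
    for col in ("block_start", "block_end", "onset"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    """Read an event log written by :func:`write_events_tsv`."""
    events = pd.read_csv(
        path, sep="\t",
        dtype={"participant": str, "letter": str},
        keep_default_na=False,
        na_values={"onset": [""], "block_start": [""], "block_end": [""]},
    )
    events["letter"] = events["letter"].fillna("")
    for col in ("block_start", "block_end", "onset"):
        events[col] = pd.to_numeric(events[col], errors="coerce")
    events["is_target"] = events["is_target"].astype(int)
    events["session"] = events["session"].astype(int)
    events["block"] = events["block"].astype(int)
    return events.loc[:, EVENT_COLUMNS]


def stimulus_rows(events: pd.DataFrame) -> pd.DataFrame:
    """Only the rows that correspond to actual letter presentations."""
    return events[events["onset"].notna()]


def _check_block(block: pd.DataFrame, soa: float) -> None:
    onsets = block["onset"].dropna().to_numpy()
    if onsets.size and not np.all(np.diff(onsets) > 0):
        raise ValueError("stimulus onsets must be strictly increasing")
    if onsets.size and not np.allclose(np.diff(onsets), soa):
        raise ValueError("stimulus onsets must be spaced by the SOA")


def validate_events(events: pd.DataFrame, soa: float) -> None:
    """Check the structural invariants of an event log (raises ValueError)."""
    for _, block in events.groupby(["participant", "session", "block"]):
        _check_block(block, soa)
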