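"""Pseudorandom n-back block schedules and letter sequences.

Each session starts with a fixation baseline block and continues with two
repetitions of each workload condition, ordered so that (a) every condition
appears once in each half of the session and (b) two blocks of the same
condition are never adjacent.  Letters are drawn from the English consonants
(vowels excluded to discourage chunking); in the 0-back condition the target
letter is ``x``, in the n-back conditions a letter is a target when it
matches the letter n steps back.  Exactly one third of the letters in every
block are targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from physioload.config import WORKLOAD_CONDITIONS, SimulationConfig
from physioload.events import EVENT_COLUMNS

__all__ = ["generate_schedule", "CONSONANTS"]

#: English consonants (the 0-back target 'x' included).
CONSONANTS = tuple("bcdfghjklmnpqrstvwxyz")

_MAX_TRIES = 1000


def _block_order(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Workload-block condition order for one session."""
    conds = list(WORKLOAD_CONDITIONS)
    for _ in range(_MAX_TRIES):
        if config.reps_per_condition == 2:
            first = list(rng.permutation(conds))
            second = list(rng.permutation(conds))
            order = first + second
        else:
            order = list(rng.permutation(conds * config.reps_per_condition))
        if all(a != b for a, b in zip(order, order[1:])):
            return order
    raise RuntimeError(
        "could not build a schedule satisfying the adjacency constraint; "
        "the configuration is likely impossible"
    )


def _letters(condition: str, n: int, n_targets: int, rng: np.random.Generator) -> tuple[list[str], list[int]]:
    """A letter sequence with exactly ``n_targets`` targets under n-back rules."""
    back = {"0-back": 0, "1-back": 1, "2-back": 2}[condition]
    first_allowed = back  # a target needs `back` letters of history (0-back: any)
    if n - first_allowed < n_targets:
        raise RuntimeError("too many targets for the block length")
    for _ in range(_MAX_TRIES):
        positions = set(rng.choice(np.arange(first_allowed, n), size=n_targets, replace=False).tolist())
        letters: list[str] = []
        ok = True
        for i in range(n):
            if i in positions:
                if back == 0:
                    letters.append("x")
                else:
                    letters.append(letters[i - back])
            else:
                forbidden = {"x"} if back == 0 else set()
                if back > 0 and i >= back:
                    forbidden.add(letters[i - back])
                choices = [c for c in CONSONANTS if c not in forbidden]
                letters.append(choices[rng.integers(len(choices))])
        # sanity: recount targets under the n-back rule
        is_target = _target_flags(letters, back)
        if sum(is_target) == n_targets:
            return letters, is_target
        ok = False  # noqa: F841  (resample on accidental-target miscount)
    raise RuntimeError("could not build a letter sequence with the required targets")


def _target_flags(letters: list[str], back: int) -> list[int]:
    if back == 0:
        return [int(c == "x") for c in letters]
    return [int(i >= back and letters[i] == letters[i - back]) for i in range(len(letters))]


def generate_schedule(
    config: SimulationConfig,
    seed: int,
    participant: str = "P01",
) -> pd.DataFrame:
    """Generate one participant's event log for all sessions.

    Returns a DataFrame with one row per stimulus (plus one marker row per
    baseline block); deterministic given ``(config, seed)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB10C]))
    rows: list[dict] = []
    slot = config.block_duration + config.inter_block_gap
    for session in range(1, config.n_sessions + 1):
        order = ["baseline"] + _block_order(config, rng)
        for b, condition in enumerate(order, start=1):
            start = (b - 1) * slot
            end = start + config.block_duration
            base = dict(
                participant=participant, session=session, block=b,
                condition=condition, block_start=start, block_end=end,
            )
            if condition == "baseline":
                rows.append({**base, "onset": np.nan, "letter": "", "is_target": 0})
                continue
            letters, flags = _letters(
                condition, config.letters_per_block, config.n_targets_per_block, rng
            )
            for i, (letter, flag) in enumerate(zip(letters, flags)):
                rows.append({
                    **base,
                    "onset": start + i * config.soa,
                    "letter": letter,
                    "is_target": flag,
                })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
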