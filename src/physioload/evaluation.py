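"""Group-level evaluation: protocol runs, exact binomial statistics, reports.

The simulated-online protocol trains one classifier per participant on
sessions 1-3 and scores the session-4 segments; group performance is the
mean fraction correct over participants.  Under a random classifier each of
the ``n_total`` pooled test segments is an independent Bernoulli(0.5), so
the group mean is tested with a one-tailed exact binomial test
(``P(X >= k)``, integer summation, no normal approximation).  The s.e.m. of
an accuracy is ``sqrt(a(1-a)/n_total)``.  Pairwise configuration
comparisons use an exact sign-flip permutation test on per-participant
accuracy differences.  No multiple-testing correction is applied by
default; Bonferroni-adjusted significance levels can be derived from
:func:`significance_threshold` with a divided alpha.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from physioload import dataset as ds
from physioload import models as md

__all__ = [
    "RunConfig", "binomial_p", "significance_threshold", "sem_binomial",
    "pairwise_compare", "evaluate_participant", "run_protocol", "report_table",
]

PAIRS = {"2v0": ("0-back", "2-back"), "2v1": ("1-back", "2-back"), "1v0": ("0-back", "1-back")}


# ---------------------------------------------------------------------------
# exact binomial machinery
# ---------------------------------------------------------------------------

def binomial_p(mean_accuracy: float, n_total: int) -> float:
    """One-tailed exact binomial p: ``P(X >= k)`` for ``X ~ Bin(n, 0.5)``.

    ``mean_accuracy`` must be representable as ``k / n_total`` with integer
    ``k`` (guards against rounding upstream).
    """
    if n_total < 1:
        raise ValueError("n_total must be positive")
    k_float = mean_accuracy * n_total
    k = round(k_float)
    if abs(k_float - k) > 1e-6 * max(n_total, 1):
        raise ValueError(
            f"accuracy {mean_accuracy} is not a multiple of 1/{n_total}"
        )
    if k <= 0:
        return 1.0
    tail = sum(comb(n_total, i) for i in range(k, n_total + 1))
    return float(tail / 2**n_total)


def significance_threshold(n_total: int, alpha: float) -> float | None:
    """Smallest accuracy ``k/n_total`` with an exact p at or below ``alpha``.

    Returns None when even a perfect score is not significant (the level is
    unattainable at this n).
    """
    if n_total < 1 or not 0 < alpha < 1:
        raise ValueError("need n_total >= 1 and 0 < alpha < 1")
    for k in range(n_total + 1):
        if binomial_p(k / n_total, n_total) <= alpha:
            return k / n_total
    return None


def sem_binomial(accuracy: float, n_total: int) -> float:
    """Binomial standard error of the mean accuracy."""
    if not 0 <= accuracy <= 1:
        raise ValueError("accuracy must lie in [0, 1]")
    return float(np.sqrt(accuracy * (1.0 - accuracy) / n_total))


def pairwise_compare(acc_a, acc_b) -> float:
    """Exact one-sided sign-flip permutation p for "A more accurate than B".

    ``acc_a`` and ``acc_b`` are per-participant accuracies of the same
    participants under two configurations.  All ``2**n`` sign assignments of
    the paired differences are enumerated (n <= 20); the p-value is the
    fraction of assignments whose mean difference is at least the observed
    one.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("mismatched per-participant accuracy vectors")
    if a.size > 20:
        raise ValueError("exhaustive sign-flip enumeration limited to 20 participants")
    d = a - b
    observed = d.mean()
    signs = np.array(list(itertools.product([1.0, -1.0], repeat=d.size)))
    null = (signs * d).mean(axis=1)
    return float(np.mean(null >= observed - 1e-12))


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """One model configuration of the evaluation grid."""

    features: str = "eeg"                  # feature / sensor / group spec
    model: str = "svm"                     # "svm" | "enet"
    fusion: str = "feature"                # "feature" | "decision"
    pair: str = "2v0"                      # "2v0" | "2v1" | "1v0"
    segment_length: float = 120.0
    include_time: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pair not in PAIRS:
            raise ValueError(f"unknown pair {self.pair!r}")
        if self.model not in ("svm", "enet"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.fusion not in ("feature", "decision"):
            raise ValueError(f"unknown fusion {self.fusion!r}")
        if self.fusion == "decision" and self.model != "enet":
            raise ValueError("decision-level fusion requires elastic-net probabilities")

    @property
    def label(self) -> str:
        time = "+time" if self.include_time else ""
        return (f"{self.features}{time}|{self.model}|{self.fusion}|{self.pair}"
                f"|{self.segment_length:g}s")


def _model_spec(config: RunConfig) -> md.ModelSpec:
    kind = "svm_linear" if config.model == "svm" else "elastic_net_logistic"
    return md.ModelSpec(kind=kind, seed=config.seed)


def evaluate_participant(
    ptable: pd.DataFrame, config: RunConfig
) -> float | None:
    """Fraction of last-session segments classified correctly, or None when
    the participant has missing values in the selected columns."""
    low, high = PAIRS[config.pair]
    rows = ptable[ptable["condition"].isin((low, high))]
    columns = ds.select_features(config.features, config.include_time)
    if rows[columns].isna().any().any():
        return None
    train_rows, test_rows = ds.split_train_test(rows)
    y_train = (train_rows["condition"] == high).to_numpy().astype(int)
    y_test = (test_rows["condition"] == high).to_numpy().astype(int)
    groups = (train_rows["session"].astype(str) + "." + train_rows["block"].astype(str)).to_numpy()
    spec = _model_spec(config)

    if config.fusion == "feature":
        xtr, xte, _ = ds.standardize(train_rows, test_rows, columns)
        model = md.train(spec, xtr, y_train, groups=groups)
        preds = md.predict(model, xte)
    else:
        prob_rows: list[np.ndarray] = []
        for cols in ds.decompose_features(config.features, config.include_time):
            xtr, xte, _ = ds.standardize(train_rows, test_rows, cols)
            model = md.train(spec, xtr, y_train, groups=groups)
            prob_rows.append(np.array([p.probability for p in md.predict(model, xte)]))
        prob_matrix = np.stack(prob_rows, axis=1)  # (test rows, atoms)
        preds = [md.fuse_decision(r) for r in prob_matrix]

    labels = np.array([p.label for p in preds])
    return float((labels == y_test).mean())


def run_protocol(table: pd.DataFrame, configs, progress: bool = False) -> pd.DataFrame:
    """Evaluate a grid of configurations on a group feature table.

    Returns one row per configuration with per-participant accuracies,
    group mean, pooled n, exact binomial p, s.e.m. and exclusions.
    """
    if isinstance(configs, RunConfig):
        configs = [configs]
    records = []
    for config in configs:
        accs: dict[str, float] = {}
        excluded: list[str] = []
        for pid, ptable in table.groupby("participant", sort=True):
            acc = evaluate_participant(ptable, config)
            if acc is None:
                excluded.append(pid)
            else:
                accs[pid] = acc
        if excluded:
            warnings.warn(
                f"{config.label}: excluded {excluded} (missing features)", stacklevel=2
            )
        if not accs:
            raise ValueError(f"{config.label}: no usable participants")
        acc_values = np.array(list(accs.values()))
        # segments per participant in the last session
        any_pid = next(iter(accs))
        k = _test_segments(table, any_pid, config)
        n_total = k * len(accs)
        mean_acc = float(acc_values.mean())
        records.append({
            "config": config.label,
            "features": config.features, "model": config.model,
            "fusion": config.fusion, "pair": config.pair,
            "segment_length": config.segment_length,
            "include_time": config.include_time,
            "n_participants": len(accs),
            "excluded": ",".join(excluded),
            "segments_per_participant": k,
            "n_total": n_total,
            "mean_accuracy": mean_acc,
            "p_value": binomial_p(mean_acc, n_total),
            "sem": sem_binomial(mean_acc, n_total),
            "threshold_05": significance_threshold(n_total, 0.05),
            "threshold_01": significance_threshold(n_total, 0.01),
            "per_participant": accs,
        })
    return pd.DataFrame(records)


def _test_segments(table: pd.DataFrame, pid: str, config: RunConfig) -> int:
    low, high = PAIRS[config.pair]
    ptable = table[(table["participant"] == pid)
                   & table["condition"].isin((low, high))]
    last = ptable["session"].max()
    return int((ptable["session"] == last).sum())


# ---------------------------------------------------------------------------
# figure-style report tables
# ---------------------------------------------------------------------------

SINGLE_FEATURES = (
    "erp", "power", "alpha", "theta", "erp_pz", "alpha_pz", "theta_fz",
    "sc.mean", "sc.min", "resp.freq", "resp.depth",
    "ecg.mean_rri", "ecg.rmssd", "ecg.mf_hrv", "ecg.hf_hrv",
    "eye.pupil", "eye.blink_rate", "eye.blink_dur",
)

SENSOR_GROUPS = ("eeg", "physiology", "eye")
GROUP_COMBOS = (
    "eeg", "physiology", "eye",
    "eeg+physiology", "eeg+eye", "physiology+eye",
    "eeg+physiology+eye",
)


def report_table(table: pd.DataFrame, style: str, **kwargs) -> pd.DataFrame:
    """Run and tabulate one of the standard report layouts.

    ``style``: ``"features"`` (each single feature x SVM/elastic net),
    ``"groups"`` (sensor-group combinations x SVM/enet/decision fusion) or
    ``"time"`` (sensor groups and their union, with and without the time
    feature).  Extra keyword arguments override RunConfig fields.
    """
    configs: list[RunConfig] = []
    if style == "features":
        for feat in SINGLE_FEATURES:
            for model in ("svm", "enet"):
                configs.append(RunConfig(features=feat, model=model, **kwargs))
    elif style == "groups":
        for feat in GROUP_COMBOS:
            configs.append(RunConfig(features=feat, model="svm", **kwargs))
            configs.append(RunConfig(features=feat, model="enet", **kwargs))
            configs.append(RunConfig(features=feat, model="enet", fusion="decision", **kwargs))
    elif style == "time":
        for feat in ("eeg", "physiology", "eye", "eeg+physiology+eye"):
            for include_time in (False, True):
                configs.append(RunConfig(features=feat, model="svm",
                                         include_time=include_time, **kwargs))
    else:
        raise ValueError(f"unknown report style {style!r}")
    return run_protocol(table, configs)
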