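"""Model/Results front-end for the workload-classification protocol.

``WorkloadClassification`` is constructed from a segment-level feature table
(one row per workload segment, as produced by
:func:`physioload.dataset.build_feature_table` or loaded from CSV) together
with one model configuration; ``fit()`` runs the simulated-online protocol
— per participant: split by session, standardize on the training sessions,
train, score the last session — and returns a ``WorkloadResults`` carrying
per-participant and group accuracies, the exact binomial p-value against
chance, the binomial s.e.m., and the significance thresholds.

Example
-------
>>> from physioload import SimulationConfig, build_feature_table, WorkloadClassification
>>> table = build_feature_table(SimulationConfig(n_participants=4), seed=7)
>>> res = WorkloadClassification(table, features="eeg", model="svm").fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from physioload import evaluation as ev

__all__ = ["WorkloadClassification", "WorkloadResults"]


class WorkloadClassification:
    """One workload-classification model configuration over a feature table.

    Parameters
    ----------
    table:
        Segment-level feature table for all participants.
    features:
        Feature / sensor / sensor-group spec (e.g. ``"eeg"``, ``"pz"``,
        ``"eeg+eye"``, ``"sc.mean"``).
    model:
        ``"svm"`` (linear SVM) or ``"enet"`` (elastic-net logistic).
    fusion:
        ``"feature"`` (concatenation) or ``"decision"`` (probability
        averaging over per-feature elastic-net models).
    pair:
        Condition contrast: ``"2v0"``, ``"2v1"`` or ``"1v0"``.
    include_time:
        Append the task-time feature.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        features: str = "eeg",
        model: str = "svm",
        fusion: str = "feature",
        pair: str = "2v0",
        include_time: bool = False,
        seed: int = 0,
    ) -> None:
        self.table = table
        seg = float(np.median(np.asarray(
            table.groupby(["participant", "session", "block"])["subseg"].nunique()
        )))
        segment_length = 120.0 / seg if seg else 120.0
        self.config = ev.RunConfig(
            features=features, model=model, fusion=fusion, pair=pair,
            segment_length=segment_length, include_time=include_time, seed=seed,
        )

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "WorkloadClassification":
        return cls(table, **kwargs)

    def fit(self) -> "WorkloadResults":
        report = ev.run_protocol(self.table, self.config)
        return WorkloadResults(model=self, _row=report.iloc[0])


@dataclass
class WorkloadResults:
    """Fitted protocol outcome for one configuration."""

    model: WorkloadClassification
    _row: pd.Series

    # -- primary quantities --------------------------------------------------
    @property
    def accuracies(self) -> dict[str, float]:
        """Per-participant fraction of last-session segments correct."""
        return dict(self._row["per_participant"])

    @property
    def mean_accuracy(self) -> float:
        return float(self._row["mean_accuracy"])

    @property
    def n_total(self) -> int:
        return int(self._row["n_total"])

    @property
    def p_value(self) -> float:
        return float(self._row["p_value"])

    @property
    def sem(self) -> float:
        return float(self._row["sem"])

    @property
    def excluded(self) -> list[str]:
        return [p for p in str(self._row["excluded"]).split(",") if p]

    def significance_threshold(self, alpha: float = 0.05) -> float | None:
        return ev.significance_threshold(self.n_total, alpha)

    def compare(self, other: "WorkloadResults") -> float:
        """Exact sign-flip permutation p for "this beats other" (paired)."""
        mine, theirs = self.accuracies, other.accuracies
        common = sorted(set(mine) & set(theirs))
        if not common:
            raise ValueError("no common participants to compare")
        return ev.pairwise_compare([mine[p] for p in common],
                                   [theirs[p] for p in common])

    def summary(self) -> str:
        cfg = self.model.config
        thr05 = self.significance_threshold(0.05)
        thr01 = self.significance_threshold(0.01)
        lines = [
            "Workload classification (simulated online)",
            "=" * 44,
            f"features:        {cfg.features}"
            + (" + time" if cfg.include_time else ""),
            f"model / fusion:  {cfg.model} / {cfg.fusion}",
            f"contrast:        {cfg.pair}   segments: {cfg.segment_length:g} s",
            f"participants:    {len(self.accuracies)}"
            + (f"   excluded: {','.join(self.excluded)}" if self.excluded else ""),
            f"test segments:   {self.n_total} pooled"
            f" ({self._row['segments_per_participant']} per participant)",
            "-" * 44,
            f"mean accuracy:   {self.mean_accuracy:.3f}  (s.e.m. {self.sem:.3f})",
            f"binomial p:      {self.p_value:.4g}  (one-tailed, chance 0.5)",
            f"alpha=0.05 level: {thr05 if thr05 is None else format(thr05, '.3f')}"
            f"   alpha=0.01 level: {thr01 if thr01 is None else format(thr01, '.3f')}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar plot of per-participant accuracies with chance and alpha lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        accs = self.accuracies
        ax.bar(range(len(accs)), list(accs.values()), color="#4878a8")
        ax.axhline(0.5, color="k", lw=0.8, label="chance")
        thr = self.significance_threshold(0.05)
        if thr is not None:
            ax.axhline(thr, color="r", lw=0.8, ls="--", label="p=0.05")
        ax.set_xticks(range(len(accs)), list(accs), rotation=90, fontsize=7)
        ax.set_ylabel("accuracy")
        ax.set_ylim(0, 1.05)
        ax.set_title(self.model.config.label)
        ax.legend(fontsize=7)
        return ax
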