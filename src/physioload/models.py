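"""Individually trained classifiers and fusion rules.

Two model kinds are supported: a linear support-vector machine (C = 1, the
"standard" model; labels only) and elastic-net-penalized logistic
regression (mixing 0.5, penalty strength chosen by leave-one-block-out
cross-validation on the training rows over a 20-point log grid, ties broken
toward stronger regularization), which supplies class probabilities.

Fusion: at the feature level the per-set design matrices are concatenated
column-wise and a single model is trained; at the decision level one
elastic-net model is trained per atomic feature and the "high workload"
probabilities are averaged, the label being high iff the mean exceeds 0.5
(a tie maps to low).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

__all__ = [
    "ModelSpec", "TrainedModel", "Prediction",
    "train", "predict", "fuse_decision", "fuse_features",
]

_DEFAULT_GRID = tuple(np.logspace(-3, 3, 20))


@dataclass(frozen=True)
class ModelSpec:
    """Classifier kind and hyperparameters."""

    kind: str = "svm_linear"                    # or "elastic_net_logistic"
    svm_cost: float = 1.0
    enet_l1_ratio: float = 0.5
    enet_c_grid: tuple[float, ...] = _DEFAULT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("svm_linear", "elastic_net_logistic"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not self.enet_c_grid:
            raise ValueError("empty hyperparameter grid")


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    n_features: int
    classes: tuple[int, int] = (0, 1)           # 0 = low, 1 = high workload

    @property
    def has_probabilities(self) -> bool:
        return self.spec.kind == "elastic_net_logistic"


@dataclass(frozen=True)
class Prediction:
    label: int                                  # 0 low / 1 high
    probability: float | None = None            # P(high); elastic net only


def _enet(c: float, spec: ModelSpec) -> LogisticRegression:
    # a float l1_ratio selects the elastic-net penalty
    return LogisticRegression(
        solver="saga", l1_ratio=spec.enet_l1_ratio,
        C=c, max_iter=5000, tol=1e-4, random_state=spec.seed,
    )


def train(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
) -> TrainedModel:
    """Fit a classifier on standardized training data (deterministic per seed).

    ``y`` codes low workload as 0 and high as 1.  For the elastic net,
    ``groups`` identifies training blocks for the leave-one-block-out
    selection of the penalty strength (defaults to leave-one-row-out).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X and y are misaligned")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 training rows per class")

    if spec.kind == "svm_linear":
        est = SVC(kernel="linear", C=spec.svm_cost)
        est.fit(X, y)
        return TrainedModel(spec=spec, estimator=est, n_features=X.shape[1])

    groups = np.arange(len(y)) if groups is None else np.asarray(groups)
    uniq = np.unique(groups)
    scores = []
    for c in spec.enet_c_grid:
        correct = 0
        total = 0
        for g in uniq:
            tr, te = groups != g, groups == g
            if len(np.unique(y[tr])) < 2:
                continue
            m = _enet(c, spec).fit(X[tr], y[tr])
            correct += int((m.predict(X[te]) == y[te]).sum())
            total += int(te.sum())
        scores.append(correct / total if total else 0.0)
    # smaller C = stronger regularization; prefer it on ties
    best = int(np.argmin([-s for s in scores]))  # first max; grid ascends in C
    est = _enet(spec.enet_c_grid[best], spec).fit(X, y)
    return TrainedModel(spec=spec, estimator=est, n_features=X.shape[1])


def predict(model: TrainedModel, X: np.ndarray) -> list[Prediction]:
    """One prediction per row; elastic net emits P(high workload).

    The label is high iff the probability strictly exceeds 0.5 (a boundary
    row maps to low).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: model has {model.n_features}, X has {X.shape}"
        )
    if model.has_probabilities:
        p = model.estimator.predict_proba(X)[:, 1]
        return [Prediction(label=int(pi > 0.5), probability=float(pi)) for pi in p]
    labels = model.estimator.predict(X)
    return [Prediction(label=int(l)) for l in labels]


def fuse_decision(probabilities) -> Prediction:
    """Average per-model P(high); label high iff the mean exceeds 0.5."""
    probabilities = list(probabilities)
    if not probabilities:
        raise ValueError("decision fusion needs at least one probability")
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    mean = float(p.mean())
    return Prediction(label=int(mean > 0.5), probability=mean)


def fuse_features(*matrices: np.ndarray) -> np.ndarray:
    """Column-wise concatenation of row-aligned design matrices."""
    mats = [np.atleast_2d(np.asarray(m, dtype=float)) for m in matrices]
    n_rows = {m.shape[0] for m in mats}
    if len(n_rows) != 1:
        raise ValueError("design matrices are not row-aligned")
    return np.concatenate(mats, axis=1)
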