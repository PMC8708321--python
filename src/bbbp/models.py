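"""Model configurations, probability prediction, ROC-AUC and trial runner.

Two models are used throughout: a random forest (90 trees, depth 10) and a
small feed-forward network (three 256-unit hidden layers, sigmoid output,
batch size 32, 100 epochs).  The network is realized with scikit-learn's
``MLPClassifier`` (relu/adam); the originally described SELU activation and
AdaMax optimizer are not available in scikit-learn and the substitution is a
documented approximation.

Scores are reported in the ``mean(std)`` convention where the parenthesized
integer gives the standard deviation in units of the last printed digit:
mean 0.760, std 0.010 at three decimals prints as ``0.760(10)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier

from .errors import UndefinedMetricError
from .scaffold_split import SplitIndices


@dataclass(frozen=True)
class ModelConfig:
    """Immutable model specification; fully determines a fit up to backend RNG.

    For ``kind='dnn'``: ``hidden_layers`` layers of ``units`` units, trained
    with minibatches of ``batch_size`` for ``epochs`` epochs, no early
    stopping.  For ``kind='rf'``: ``n_trees`` trees of depth ``max_depth``
    with the library's default feature subsampling (sqrt).
    """

    kind: str = "rf"  # {"rf", "dnn"}
    n_trees: int = 90
    max_depth: int = 10
    hidden_layers: int = 3
    units: int = 256
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("rf", "dnn"):
            raise ValueError(f"unknown model kind {self.kind!r}")


DNN_CONFIG = ModelConfig(kind="dnn")
RF_CONFIG = ModelConfig(kind="rf")


def make_estimator(config: ModelConfig, seed: int | None = None):
    seed = config.seed if seed is None else seed
    if config.kind == "rf":
        return RandomForestClassifier(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            random_state=seed,
        )
    return MLPClassifier(
        hidden_layer_sizes=(config.units,) * config.hidden_layers,
        batch_size=config.batch_size,
        max_iter=config.epochs,
        solver="adam",
        early_stopping=False,
        random_state=seed,
    )


def _check_two_classes(y: np.ndarray, what: str) -> None:
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError(f"{what} contains a single class")


def train_predict(
    config: ModelConfig,
    X_train: np.ndarray,
    y_train: Sequence[int],
    X_eval: np.ndarray,
    seed: int | None = None,
):
    """Fit the configured model and return positive-class probabilities.

    Returns ``(probabilities, fitted_estimator)``.  Training labels must
    contain both classes (ROC-AUC is undefined downstream otherwise).
    """
    y_train = np.asarray(y_train)
    _check_two_classes(y_train, "training labels")
    est = make_estimator(config, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence warnings at fixed epochs
        est.fit(np.asarray(X_train, dtype=float), y_train)
        probs = est.predict_proba(np.asarray(X_eval, dtype=float))[:, 1]
    return probs, est


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Probability a random positive outscores a random negative, ties = 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    _check_two_classes(labels, "labels")
    return float(roc_auc_score(labels, scores))


def format_mean_std(mean: float, std: float, decimals: int = 3) -> str:
    """Format as e.g. 0.760(10): std expressed in the last printed digits."""
    return f"{mean:.{decimals}f}({int(round(std * 10 ** decimals))})"


@dataclass
class TrialResult:
    """Per-split ROC-AUC over repeated trials, with mean(std) summaries."""

    roc_auc_train: list[float] = field(default_factory=list)
    roc_auc_valid: list[float] = field(default_factory=list)
    roc_auc_test: list[float] = field(default_factory=list)
    config: ModelConfig | None = None
    base_seed: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.roc_auc_test)

    def mean(self, split: str) -> float:
        return float(np.mean(getattr(self, f"roc_auc_{split}")))

    def std(self, split: str) -> float:
        scores = getattr(self, f"roc_auc_{split}")
        return float(np.std(scores)) if len(scores) > 1 else 0.0

    def formatted(self, split: str, decimals: int = 3) -> str:
        return format_mean_std(self.mean(split), self.std(split), decimals)

    def summary(self) -> dict:
        return {
            split: {
                "scores": list(getattr(self, f"roc_auc_{split}")),
                "mean": self.mean(split),
                "std": self.std(split),
                "formatted": self.formatted(split),
            }
            for split in ("train", "valid", "test")
        }


def run_trials(
    config: ModelConfig,
    X: np.ndarray,
    y: Sequence[int],
    split: SplitIndices,
    n_trials: int = 5,
    base_seed: int | None = None,
) -> TrialResult:
    """Repeat train/evaluate ``n_trials`` times and aggregate per-split scores.

    The stochastic network uses seed ``base+i`` for trial i; the random
    forest reuses the base seed every trial, making its trial-to-trial
    standard deviation exactly 0 (the reported scores carry "(0)").
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    base = config.seed if base_seed is None else base_seed
    result = TrialResult(config=replace(config, seed=base), base_seed=base)
    for i in range(n_trials):
        seed = base if config.kind == "rf" else base + i
        probs_train, est = train_predict(config, X[split.train], y[split.train], X[split.train], seed)
        result.roc_auc_train.append(roc_auc(y[split.train], probs_train))
        for name, idx in (("valid", split.valid), ("test", split.test)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                probs = est.predict_proba(X[idx])[:, 1]
            getattr(result, f"roc_auc_{name}").append(roc_auc(y[idx], probs))
    return result
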