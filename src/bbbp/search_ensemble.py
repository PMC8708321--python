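"""Greedy forward descriptor search and power-mean probability ensembling.

Forward search grows a descriptor set one name at a time: at each step every
unselected descriptor is scored by training a fresh model on the current
selection plus that candidate (training rows only) and evaluating ROC-AUC on
the validation rows — or on the pooled training+validation rows — and the
argmax is appended.  The held-out test rows are never read; an access guard
turns any attempted read into an error rather than a silent leak.

The ensemble combines member probability vectors with the n-th power mean
((1/k) sum p_i^n)^(1/n).  Small exponents (the working default is n = 1/32)
push the combined score toward the most pessimistic member, which improves
ranking when members disagree asymmetrically.  Optional clipping snaps
near-certain probabilities to exactly 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .descriptors import DescriptorMatrix
from .errors import AccessGuardError, UndefinedMetricError
from .models import ModelConfig, DNN_CONFIG, roc_auc, train_predict
from .scaffold_split import SplitIndices


class RowAccessGuard:
    """Array view that refuses to serve forbidden (test) rows."""

    def __init__(self, values: np.ndarray, forbidden: Sequence[int]):
        self._values = np.asarray(values, dtype=float)
        self._forbidden = frozenset(int(i) for i in forbidden)

    def rows(self, indices: Sequence[int], columns: Sequence[int] | None = None) -> np.ndarray:
        bad = self._forbidden.intersection(int(i) for i in indices)
        if bad:
            raise AccessGuardError(
                f"attempted to read held-out test rows: {sorted(bad)[:10]}"
            )
        block = self._values[np.asarray(list(indices), dtype=int)]
        if columns is not None:
            block = block[:, np.asarray(list(columns), dtype=int)]
        return block


@dataclass
class ForwardSearchState:
    """Outcome of a forward search: the selection path and its score history."""

    selected: list[str] = field(default_factory=list)
    criterion: str = "validation"
    history: list[float] = field(default_factory=list)
    stopped_reason: str = "max_steps"


def _criterion_score(
    config: ModelConfig,
    guard: RowAccessGuard,
    y: np.ndarray,
    split: SplitIndices,
    columns: list[int],
    criterion: str,
    seed: int,
    tv_mode: str,
) -> float:
    X_train = guard.rows(split.train, columns)
    y_train = y[split.train]
    if criterion == "validation":
        probs, _ = train_predict(config, X_train, y_train, guard.rows(split.valid, columns), seed)
        return roc_auc(y[split.valid], probs)
    if criterion == "train_plus_validation":
        eval_idx = list(split.train) + list(split.valid)
        probs, _ = train_predict(config, X_train, y_train, guard.rows(eval_idx, columns), seed)
        if tv_mode == "pooled":
            return roc_auc(y[eval_idx], probs)
        n_tr = len(split.train)
        return 0.5 * (
            roc_auc(y[split.train], probs[:n_tr]) + roc_auc(y[split.valid], probs[n_tr:])
        )
    raise UndefinedMetricError(f"unknown criterion {criterion!r}")


def forward_search(
    matrix: DescriptorMatrix,
    labels: Sequence[int],
    split: SplitIndices,
    criterion: str = "validation",
    config: ModelConfig = DNN_CONFIG,
    max_steps: int = 15,
    epsilon: float = 1e-3,
    repeats: int = 3,
    base_seed: int = 0,
    tv_mode: str = "pooled",
) -> ForwardSearchState:
    """Greedy forward selection of descriptors by model ROC-AUC.

    Candidate scores are averaged over ``repeats`` seeded fits.  A candidate
    is appended only if it improves the best score by at least ``epsilon``;
    two consecutive non-improving steps end the search (``saturated``),
    otherwise it runs to ``max_steps``.  Test rows are guarded: any read
    raises :class:`~bbbp.errors.AccessGuardError`.
    """
    names = matrix.descriptor_names
    y = np.asarray(labels)
    guard = RowAccessGuard(matrix.values, forbidden=split.test)
    state = ForwardSearchState(criterion=criterion)
    selected_cols: list[int] = []
    best = -np.inf
    strikes = 0

    for _ in range(max_steps):
        candidate_scores: list[tuple[float, int]] = []
        for j in range(len(names)):
            if j in selected_cols:
                continue
            cols = selected_cols + [j]
            scores = [
                _criterion_score(config, guard, y, split, cols, criterion,
                                 base_seed + r, tv_mode)
                for r in range(repeats)
            ]
            candidate_scores.append((float(np.mean(scores)), j))
        if not candidate_scores:
            state.stopped_reason = "saturated"
            break
        # argmax; ties broken by column order
        best_score, best_j = max(candidate_scores, key=lambda t: (t[0], -t[1]))
        if best_score - best < epsilon and state.selected:
            strikes += 1
            if strikes >= 2:
                state.stopped_reason = "saturated"
                break
            continue
        strikes = 0
        best = best_score
        selected_cols.append(best_j)
        state.selected.append(names[best_j])
        state.history.append(best_score)
    return state


@dataclass
class EnsembleSpec:
    """Aligned member probability vectors plus combination parameters."""

    members: list[np.ndarray]
    n: float = 1.0 / 32.0
    clip_low: float = 0.02
    clip_high: float = 0.98
    clipping: bool = False

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.n == 0:
            raise ValueError("power exponent n must be nonzero")
        self.members = [np.asarray(m, dtype=float) for m in self.members]
        lengths = {len(m) for m in self.members}
        if len(lengths) != 1:
            raise ValueError(f"member vectors differ in length: {sorted(lengths)}")
        for m in self.members:
            if np.any((m < 0) | (m > 1)):
                raise ValueError("member probabilities must lie in [0, 1]")

    def combine(self) -> np.ndarray:
        combined = power_mean(self.members, self.n)
        if self.clipping:
            combined = clip(combined, self.clip_low, self.clip_high)
        return combined


def power_mean(members: Sequence[np.ndarray], n: float) -> np.ndarray:
    """Elementwise n-th power mean of probability vectors.

    n = 1 is the arithmetic mean.  For 0 < n < 1 a member value of 0 is
    handled by 0^n = 0 (no singularity).  Output stays within [min, max] of
    the members.
    """
    if n == 0:
        raise ValueError("power exponent n must be nonzero")
    stack = np.vstack([np.asarray(m, dtype=float) for m in members])
    if n == 1:
        return stack.mean(axis=0)
    with np.errstate(divide="ignore"):
        return np.power(np.power(stack, n).mean(axis=0), 1.0 / n)


def clip(probabilities: Sequence[float], low: float = 0.02, high: float = 0.98) -> np.ndarray:
    """Snap near-certain probabilities: p < low -> 0, p > high -> 1."""
    p = np.asarray(probabilities, dtype=float).copy()
    p[p < low] = 0.0
    p[p > high] = 1.0
    return p
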