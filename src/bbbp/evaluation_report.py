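"""Confidence intervals, feature importance and descriptive tables.

The confidence interval over resampled scaffold splits is a Student-t
interval on the mean of the per-split ROC-AUC scores.  The descriptive
tables summarize the chemistry behind the labels: per-quantity positive/
negative histograms with Lipinski rule-of-five violation flags, and the
penetration ratio cross-tabulated by aliphatic-heterocycle count and
non-tertiary aliphatic OH count (the "glucose-likeness" table).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import NotFittedError
from sklearn.utils.validation import check_is_fitted

from .errors import SchemaError

LIPINSKI_RULES = {
    # quantity -> strict upper bound; a violation is value > bound
    "NumHDonors": 5,
    "NumHAcceptors": 10,
    "MolWt": 500,
    "MolLogP": 5,
}


@dataclass
class ConfidenceInterval:
    """t-interval on the mean of per-split scores."""

    scores: list[float]
    mean: float
    level: float
    lower: float
    upper: float

    def rounded(self, decimals: int = 3) -> tuple[float, float]:
        return (round(self.lower, decimals), round(self.upper, decimals))


def confidence_interval(scores: Sequence[float], level: float = 0.95) -> ConfidenceInterval:
    """Mean +/- t_{level, k-1} * s / sqrt(k) over k >= 2 scores.

    Zero-variance scores give a degenerate interval at the mean.  The
    interval is not truncated to [0, 1].
    """
    scores = [float(s) for s in scores]
    k = len(scores)
    if k < 2:
        raise ValueError("confidence interval requires at least 2 scores")
    if min(scores) == max(scores):  # exactly degenerate, no rounding residue
        v = scores[0]
        return ConfidenceInterval(scores=scores, mean=v, level=level, lower=v, upper=v)
    mean = float(np.mean(scores))
    s = float(np.std(scores, ddof=1))
    half = float(stats.t.ppf(0.5 + level / 2.0, df=k - 1) * s / np.sqrt(k))
    return ConfidenceInterval(
        scores=scores, mean=mean, level=level, lower=mean - half, upper=mean + half
    )


def feature_importance(rf_model, descriptor_names: Sequence[str], top_k: int = 50) -> list[tuple[str, float]]:
    """Impurity-based importances of a fitted random forest, descending."""
    try:
        check_is_fitted(rf_model)
    except NotFittedError as exc:
        raise ValueError("feature_importance requires a fitted model") from exc
    importances = np.asarray(rf_model.feature_importances_, dtype=float)
    if len(importances) != len(descriptor_names):
        raise ValueError("descriptor_names do not match the model's feature count")
    order = np.argsort(-importances, kind="stable")
    return [(descriptor_names[i], float(importances[i])) for i in order[:top_k]]


def _require_columns(frame: pd.DataFrame, names: Sequence[str]) -> None:
    missing = [n for n in names if n not in frame.columns]
    if missing:
        raise SchemaError(f"missing descriptor column(s): {', '.join(missing)}")


def lipinski_violations(frame: pd.DataFrame) -> pd.DataFrame:
    """Boolean violation flags per molecule for the four rule-of-five bounds.

    Bounds are strict: a molecule at exactly the threshold (e.g. MolWt 500)
    does not violate.
    """
    _require_columns(frame, LIPINSKI_RULES)
    return pd.DataFrame(
        {name: frame[name] > bound for name, bound in LIPINSKI_RULES.items()},
        index=frame.index,
    )


def lipinski_table(frame: pd.DataFrame, labels: Sequence[int]) -> dict[str, pd.DataFrame]:
    """Positive/negative distributions for each rule-of-five quantity.

    Returns one table per quantity with per-value (donors, acceptors) or
    per-bin (MolWt, MolLogP) positive and negative counts, plus a
    ``violations`` table of per-rule violation counts.
    """
    _require_columns(frame, LIPINSKI_RULES)
    labels = np.asarray(labels)
    out: dict[str, pd.DataFrame] = {}
    for name in ("NumHDonors", "NumHAcceptors"):
        values = frame[name].astype(int)
        table = (
            pd.DataFrame({"value": values, "label": labels})
            .groupby("value")["label"]
            .agg(positive="sum", total="count")
        )
        table["negative"] = table["total"] - table["positive"]
        out[name] = table[["positive", "negative"]]
    for name, width in (("MolWt", 50.0), ("MolLogP", 1.0)):
        bins = np.floor(frame[name] / width) * width
        table = (
            pd.DataFrame({"bin": bins, "label": labels})
            .groupby("bin")["label"]
            .agg(positive="sum", total="count")
        )
        table["negative"] = table["total"] - table["positive"]
        out[name] = table[["positive", "negative"]]
    flags = lipinski_violations(frame)
    out["violations"] = pd.DataFrame(
        {
            "violations": flags.sum(axis=0),
            "positive_violations": flags[labels == 1].sum(axis=0),
            "negative_violations": flags[labels == 0].sum(axis=0),
        }
    )
    return out


def bbbp_ratio_table(
    frame: pd.DataFrame,
    labels: Sequence[int],
    max_heterocycles: int = 5,
) -> pd.DataFrame:
    """Penetration ratio by (aliphatic heterocycle count, aliphatic OH count).

    Rows are keyed by ``NumAliphaticHeterocycles`` (capped at
    ``max_heterocycles``, i.e. a "5+" row) and raw ``fr_Al_OH_noTert``
    counts; binning of OH counts is left to presentation.  Cell counts sum
    to the dataset size.
    """
    _require_columns(frame, ["NumAliphaticHeterocycles", "fr_Al_OH_noTert"])
    labels = np.asarray(labels)
    het = frame["NumAliphaticHeterocycles"].astype(int).clip(upper=max_heterocycles)
    oh = frame["fr_Al_OH_noTert"].astype(int)
    table = (
        pd.DataFrame({"heterocycles": het, "aliphatic_oh": oh, "label": labels})
        .groupby(["heterocycles", "aliphatic_oh"])["label"]
        .agg(positive="sum", total="count")
    )
    table["negative"] = table["total"] - table["positive"]
    table["ratio"] = table["positive"] / table["total"]
    return table[["positive", "negative", "ratio"]]
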