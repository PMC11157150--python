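"""Correlation-filtered stepwise forward feature selection.

Features are added greedily: at each step the candidates are the unselected
features whose absolute Pearson correlation with every already-selected
feature stays below the threshold (default 0.9, so redundant near-copies
can never co-occur in the selection); each candidate is scored by the
cross-validated accuracy of the behaviour classifier trained on the
selected set plus that candidate, and the best one is appended.  A
feature's *contribution* is the accuracy gain of its step; the first
feature's contribution is its gain over the majority-class baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import DEFAULT_HYPERPARAMS, Hyperparams, cross_validate

DEFAULT_K = 5
DEFAULT_CORRELATION_THRESHOLD = 0.9


@dataclass(frozen=True)
class SelectionResult:
    """Ordered selected features with their per-step accuracy contributions."""

    features: tuple[str, ...]
    contributions: tuple[float, ...]
    baseline_accuracy: float
    final_accuracy: float
    correlation_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "step": np.arange(1, len(self.features) + 1),
                "contribution": self.contributions,
            }
        )


def select_features(
    features: pd.DataFrame,
    labels,
    k: int = DEFAULT_K,
    threshold: float = DEFAULT_CORRELATION_THRESHOLD,
    cv_folds: int = 5,
    hp: Hyperparams = DEFAULT_HYPERPARAMS,
    seed: int = 0,
    candidate_columns: list[str] | None = None,
) -> SelectionResult:
    """Greedy forward selection under the pairwise-correlation constraint.

    Stops after ``k`` features or when no admissible candidate remains
    (then returns a shorter list with a warning).  Reproducible given
    ``seed``; by construction ``baseline + sum(contributions)`` equals the
    final cross-validated accuracy of the selected model.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("feature selection requires >= 2 behaviour classes")

    cols = list(candidate_columns or features.select_dtypes("number").columns)
    corr = features[cols].corr().abs()
    baseline = pd.Series(labels).value_counts(normalize=True).iloc[0]

    selected: list[str] = []
    contributions: list[float] = []
    current_acc = baseline
    while len(selected) < k:
        candidates = [
            c
            for c in cols
            if c not in selected
            and all(corr.loc[c, s] < threshold for s in selected)
        ]
        if not candidates:
            warnings.warn(
                f"only {len(selected)} admissible features below the "
                f"|r| < {threshold} constraint; requested {k}"
            )
            break
        scores = {
            c: cross_validate(
                features, labels, selected + [c], hp=hp, folds=cv_folds, seed=seed
            ).accuracy
            for c in candidates
        }
        best = max(scores, key=lambda c: (scores[c], -candidates.index(c)))
        contributions.append(scores[best] - current_acc)
        current_acc = scores[best]
        selected.append(best)

    result = SelectionResult(
        features=tuple(selected),
        contributions=tuple(contributions),
        baseline_accuracy=float(baseline),
        final_accuracy=float(current_acc),
        correlation_threshold=threshold,
    )
    _assert_constraint(result, corr)
    return result


def _assert_constraint(result: SelectionResult, corr: pd.DataFrame) -> None:
    for i, a in enumerate(result.features):
        for b in result.features[:i]:
            if corr.loc[a, b] >= result.correlation_threshold:
                raise AssertionError(
                    f"selected pair ({a}, {b}) violates |r| < "
                    f"{result.correlation_threshold}"
                )
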