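"""Feature selection: correlation filtering plus stepwise forward selection.

Two complementary reduction steps.  The *filter* removes redundant features:
while any pair of remaining features has absolute Pearson correlation above a
cutoff, the pair with the largest |r| is examined and the member with the
larger mean absolute correlation to all other remaining features is dropped.
The *wrapper* applies stepwise forward selection (SFS): in each round, every
remaining candidate is added in turn to the already-selected set, a
gradient-boosted tree classifier is trained on that set and scored by seeded
stratified k-fold cross-validation, and the candidate with the highest
overall accuracy joins the selection.

A compact feature set improves interpretability, reduces overfitting risk,
and makes on-board (tracker-side) feature computation feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .model import Hyperparameters, cv_accuracy

__all__ = ["SelectionResult", "correlation_filter", "sfs_select"]


@dataclass
class SelectionResult:
    """Outcome of a stepwise forward selection run.

    ``accuracy_matrix`` has one row per SFS round and one column per
    candidate feature; entry ``(r, j)`` is the cross-validated overall
    accuracy of the already-selected set plus candidate ``j`` in round
    ``r``.  Once a feature is selected its entries in all later rows are 0.
    ``selected`` lists the chosen names in selection order;
    ``filtered_out`` lists names removed by the correlation filter before
    SFS began (empty when the filter was off).
    """

    accuracy_matrix: np.ndarray
    candidate_names: list[str]
    selected: list[str]
    filtered_out: list[str] = field(default_factory=list)

    @property
    def best_per_round(self) -> np.ndarray:
        """Cumulative best accuracy: the maximum of each round's row."""
        return self.accuracy_matrix.max(axis=1)

    def individual_accuracies(self) -> np.ndarray:
        """Round-1 (single-feature) accuracy of each selected feature."""
        cols = [self.candidate_names.index(name) for name in self.selected]
        return self.accuracy_matrix[0, cols]

    def to_dict(self) -> dict:
        return {
            "candidates": self.candidate_names,
            "accuracy_matrix": self.accuracy_matrix.tolist(),
            "selected": self.selected,
            "filtered_out": self.filtered_out,
            "best_per_round": self.best_per_round.tolist(),
        }


def _abs_corr(values: np.ndarray) -> np.ndarray:
    """|Pearson r| matrix with zero-variance features treated as uncorrelated."""
    sd = values.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[~np.isfinite(corr)] = 0.0  # zero-variance columns
    corr[:, sd == 0] = 0.0
    corr[sd == 0, :] = 0.0
    np.fill_diagonal(corr, 0.0)
    return np.abs(corr)


def correlation_filter(ft: pd.DataFrame, cutoff: float = 0.9) -> list[str]:
    """Names surviving iterative removal of over-correlated features.

    While any remaining pair has |r| above ``cutoff``, the pair with the
    largest |r| is found and the member with the larger mean absolute
    correlation to the other remaining features is removed (ties remove the
    later column).  Surviving names are returned in original column order;
    every surviving pairwise |r| is at most ``cutoff``.  Zero-variance
    features have all their correlations treated as 0 and are never removed.
    """
    if not 0 < cutoff <= 1:
        raise ParameterError(f"cutoff must be in (0, 1], got {cutoff}")
    names = list(ft.columns)
    if len(names) < 2:
        return names
    if len(ft) < 3:
        raise ParameterError(
            f"need at least 3 segments to estimate correlations, got {len(ft)}"
        )
    corr = _abs_corr(ft.to_numpy(dtype=float))
    alive = list(range(len(names)))
    while len(alive) > 1:
        sub = corr[np.ix_(alive, alive)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= cutoff:
            break
        # mean |r| with the other remaining features, self excluded
        mean_i = sub[i].sum() / (len(alive) - 1)
        mean_j = sub[j].sum() / (len(alive) - 1)
        drop = i if mean_i > mean_j else j
        del alive[drop]
    return [names[i] for i in alive]


def sfs_select(
    ft: pd.DataFrame,
    labels: Sequence[str],
    no_features: int = 5,
    seed: int = 0,
    filter: bool = False,
    cutoff: float = 0.9,
    n_splits: int = 5,
    hp: Hyperparameters | None = None,
) -> SelectionResult:
    """Stepwise forward selection scored by a gradient-boosted classifier.

    Runs ``no_features`` rounds.  In round ``r`` each unselected candidate is
    evaluated by training the default classifier (10 boosting rounds) on the
    selected set plus that candidate and scoring it with seeded stratified
    ``n_splits``-fold cross-validation; the candidate with the highest
    overall accuracy is added (ties break to the leftmost column).  When
    ``filter`` is on, the correlation filter runs first and removed names
    are reported in ``filtered_out``.
    """
    if no_features < 1:
        raise ParameterError(f"no_features must be >= 1, got {no_features}")
    hp = hp or Hyperparameters()
    filtered_out: list[str] = []
    candidates = list(ft.columns)
    if filter:
        kept = set(correlation_filter(ft, cutoff=cutoff))
        filtered_out = [c for c in candidates if c not in kept]
        candidates = [c for c in candidates if c in kept]
        ft = ft[candidates]
    if no_features > len(candidates):
        raise ParameterError(
            f"no_features={no_features} exceeds the {len(candidates)} "
            "candidate features"
        )
    acc = np.zeros((no_features, len(candidates)))
    selected: list[str] = []
    remaining = list(range(len(candidates)))
    for r in range(no_features):
        for j in remaining:
            cols = selected + [candidates[j]]
            acc[r, j] = cv_accuracy(
                ft[cols], labels, hp, seed=seed, n_splits=n_splits
            )
        best = remaining[int(np.argmax(acc[r, remaining]))]
        selected.append(candidates[best])
        remaining.remove(best)
    return SelectionResult(
        accuracy_matrix=acc,
        candidate_names=candidates,
        selected=selected,
        filtered_out=filtered_out,
    )
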