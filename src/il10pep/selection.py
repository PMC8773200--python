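"""Permutation-importance ("classic") feature selection.

A configured tree ensemble is fitted on the training data and each
column's importance is the mean accuracy drop over ``n_repeats`` random
shuffles of that column (scikit-learn's permutation importance). Negative
importances are clipped to zero, columns are sorted by descending
importance (ties by column name), and the kept set is the minimal prefix
whose cumulative *normalised* importance reaches the threshold
(default 0.9).

The cumulative rule is this package's operationalisation of a
"selection threshold"; a keep-fraction alternative (top ``ceil(t * m)``
columns) is available as ``mode="fraction"``.

Selection must only ever see training data; the pipeline enforces this by
refitting selection inside each cross-validation fold and never on the
holdout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance

from .classifiers import make_classifier
from .errors import ConfigError, SelectionError, ValidationError

__all__ = ["SelectionResult", "select_features", "top_k_report"]


@dataclass
class SelectionResult:
    """Ordered kept columns plus the full importance map."""

    kept: list[str]
    importances: dict[str, float]
    threshold: float
    n_repeats: int
    seed: int
    mode: str = "cumulative"

    @property
    def ranking(self) -> list[tuple[str, float]]:
        """All columns sorted by (importance desc, name asc)."""
        return sorted(self.importances.items(), key=lambda kv: (-kv[1], kv[0]))


def _rank(importances: dict[str, float]) -> list[tuple[str, float]]:
    return sorted(importances.items(), key=lambda kv: (-kv[1], kv[0]))


def kept_columns(importances: dict[str, float], threshold: float,
                 mode: str = "cumulative") -> list[str]:
    """Apply the keep rule to an importance map (importances >= 0)."""
    ranked = _rank(importances)
    total = sum(v for _, v in ranked)
    if total <= 0:
        raise SelectionError(
            "all permutation importances are zero; lower the threshold or "
            "disable selection"
        )
    if mode == "cumulative":
        kept, cum = [], 0.0
        for name, imp in ranked:
            kept.append(name)
            cum += imp / total
            if cum >= threshold - 1e-12:
                break
        return kept
    if mode == "fraction":
        m = int(np.ceil(threshold * len(ranked)))
        return [name for name, _ in ranked[:m]]
    raise ConfigError(f"unknown selection mode {mode!r}")


def select_features(features: pd.DataFrame, labels, threshold: float = 0.9,
                    n_repeats: int = 5, seed: int = 123,
                    estimator_spec: str = "extra_trees",
                    estimator_params: dict | None = None,
                    mode: str = "cumulative") -> SelectionResult:
    """Rank columns by permutation importance and keep a minimal subset.

    Deterministic given (data, seed, n_repeats). Raising the threshold
    never shrinks the kept set.
    """
    if not 0 < threshold <= 1:
        raise ConfigError(f"threshold must be in (0, 1], got {threshold}")
    y = np.asarray(labels, dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValidationError("selection needs both classes present")
    est = make_classifier(estimator_spec, estimator_params, seed=seed)
    est.fit(features.to_numpy(), y)
    perm = permutation_importance(
        est, features.to_numpy(), y, scoring="accuracy",
        n_repeats=n_repeats, random_state=seed, n_jobs=1,
    )
    importances = {
        name: float(max(imp, 0.0))
        for name, imp in zip(features.columns, perm.importances_mean)
    }
    kept = kept_columns(importances, threshold, mode)
    return SelectionResult(kept=kept, importances=importances,
                           threshold=threshold, n_repeats=n_repeats,
                           seed=seed, mode=mode)


def top_k_report(result: SelectionResult, k: int = 10
                 ) -> list[tuple[str, float]]:
    """First *k* (name, importance) pairs of the ranking, for reporting."""
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    ranked = [(n, result.importances[n]) for n in result.kept]
    if k > len(ranked):
        warnings.warn(
            f"requested top {k} but only {len(ranked)} features kept; "
            "returning all", RuntimeWarning, stacklevel=2,
        )
        return ranked
    return ranked[:k]
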