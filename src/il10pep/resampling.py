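"""SMOTE minority oversampling on feature matrices (re-implemented).

For each minority row, ``percent/100`` synthetic rows are generated by
picking one of its *k* nearest minority neighbours (Euclidean distance,
self excluded, ties broken by row index) and interpolating

    synthetic = original + u * (neighbour - original)

with ``u`` drawn uniformly from the *open* interval (0, 1). The minority
class count is therefore multiplied by ``1 + percent/100`` (100% doubles
it); majority rows and all original minority rows pass through verbatim,
originals first, synthetic rows appended and flagged.

The neighbour search runs on a min-max [0,1] normalised copy of the
features (fitted on the data passed in); interpolation happens in the
original feature space — for an affine per-feature rescaling the two are
equivalent, and originals stay bit-identical.

``k_neighbors="percent"`` sets k = percent/100 (the literal reading of the
oversampling-percentage rule, k = 1 at 100%); the classic SMOTE default
k = 5 is available and recommended outside replication runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigError, ResamplingError, ValidationError

__all__ = ["SmoteConfig", "ResampledData", "smote"]


@dataclass(frozen=True)
class SmoteConfig:
    percent: int = 100
    k_neighbors: int | str = "percent"
    seed: int = 123
    normalize_before: bool = True

    def __post_init__(self) -> None:
        if self.percent < 100 or self.percent % 100 != 0:
            raise ConfigError(
                f"percent must be a multiple of 100 and >= 100, got "
                f"{self.percent}"
            )
        if self.k_neighbors != "percent" and (
                not isinstance(self.k_neighbors, int) or self.k_neighbors < 1):
            raise ConfigError(
                f"k_neighbors must be 'percent' or a positive integer, got "
                f"{self.k_neighbors!r}"
            )

    @property
    def k(self) -> int:
        return self.percent // 100 if self.k_neighbors == "percent" \
            else int(self.k_neighbors)

    def replace(self, **kw) -> "SmoteConfig":
        return replace(self, **kw)


@dataclass
class ResampledData:
    """Original rows first (verbatim), synthetic rows appended and flagged."""

    features: pd.DataFrame
    labels: np.ndarray
    synthetic_flags: np.ndarray


def smote(features: pd.DataFrame, labels,
          config: SmoteConfig | None = None) -> ResampledData:
    """Oversample the minority class of a feature matrix.

    The minority class is the label with fewer rows (ties: class 1).
    Reproducible from ``config.seed``.
    """
    if config is None:
        config = SmoteConfig()
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("features must be finite for SMOTE")
    y = np.asarray(labels, dtype=np.int64)
    if y.size != len(features):
        raise ValidationError("labels length must match feature rows")
    counts = {c: int(np.sum(y == c)) for c in (0, 1)}
    minority = 1 if counts[1] <= counts[0] else 0
    min_idx = np.flatnonzero(y == minority)
    k = config.k
    if min_idx.size < k + 1:
        raise ResamplingError(
            f"minority class has {min_idx.size} rows; k={k} SMOTE needs at "
            f"least {k + 1}"
        )

    Xn = X
    if config.normalize_before:
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        Xn = (X - lo) / span

    minority_feats = Xn[min_idx]
    dist = cdist(minority_feats, minority_feats)
    np.fill_diagonal(dist, np.inf)
    # stable argsort => neighbour ties broken by row index
    neighbour_order = np.argsort(dist, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(config.seed)
    n_new = config.percent // 100
    synth_rows, synth_ids = [], []
    for row_pos, row_i in enumerate(min_idx):
        for j in range(n_new):
            nbr = min_idx[neighbour_order[row_pos, rng.integers(k)]]
            u = rng.uniform()
            while u <= 0.0 or u >= 1.0:  # open interval (0, 1)
                u = rng.uniform()
            synth_rows.append(X[row_i] + u * (X[nbr] - X[row_i]))
            synth_ids.append(f"{features.index[row_i]}.s{j + 1}")

    synth = pd.DataFrame(np.asarray(synth_rows), index=synth_ids,
                         columns=features.columns)
    synth.index.name = features.index.name
    out_feats = pd.concat([features, synth])
    out_labels = np.concatenate([y, np.full(len(synth_rows), minority,
                                            dtype=np.int64)])
    flags = np.concatenate([np.zeros(y.size, dtype=bool),
                            np.ones(len(synth_rows), dtype=bool)])
    return ResampledData(out_feats, out_labels, flags)
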