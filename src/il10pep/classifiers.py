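"""Pluggable tree-ensemble classifier backends.

Three named configurations mirror the benchmark study's top models:

``extra_trees``
    scikit-learn :class:`ExtraTreesClassifier` with the published
    hyper-parameters (200 estimators, gini, depth 6, min split 7,
    min leaf 4, no bootstrap, balanced-subsample class weights, seed 123).
``gradient_boosted_trees_a``
    LightGBM with its published configuration (gbdt, 100 estimators,
    31 leaves, learning rate 0.1).
``gradient_boosted_trees_b``
    XGBoost as a second, symmetric-depth gradient-boosted variant
    (depth 6, 1000 rounds, learning rate 0.01).

These are external implementations configured here, not re-implemented
tree code. A small randomised grid tuner is provided as an optional extra.
"""

from __future__ import annotations

from typing import Any, Mapping

from sklearn.ensemble import ExtraTreesClassifier
from sklearn.model_selection import RandomizedSearchCV

from .errors import ConfigError

#: Published hyper-parameters of the extremely-randomized-trees model.
EXTRA_TREES_DEFAULTS: dict[str, Any] = dict(
    n_estimators=200,
    criterion="gini",
    max_depth=6,
    min_samples_split=7,
    min_samples_leaf=4,
    min_weight_fraction_leaf=0.0,
    max_features=1.0,
    max_leaf_nodes=None,
    min_impurity_decrease=0.0,
    bootstrap=False,
    oob_score=False,
    n_jobs=1,
    random_state=123,
    verbose=0,
    warm_start=False,
    class_weight="balanced_subsample",
    ccp_alpha=0.0,
    max_samples=None,
)

LIGHTGBM_DEFAULTS: dict[str, Any] = dict(
    boosting_type="gbdt",
    class_weight=None,
    colsample_bytree=1.0,
    importance_type="split",
    learning_rate=0.1,
    max_depth=-1,
    min_child_samples=20,
    min_child_weight=0.001,
    min_split_gain=0.0,
    n_estimators=100,
    n_jobs=1,
    num_leaves=31,
    objective=None,
    random_state=123,
    reg_alpha=0.0,
    reg_lambda=0.0,
    subsample=1.0,
    subsample_for_bin=200000,
    subsample_freq=0,
    verbose=-1,
)

XGBOOST_DEFAULTS: dict[str, Any] = dict(
    max_depth=6,
    n_estimators=1000,
    learning_rate=0.01,
    subsample=0.8,
    reg_lambda=3.0,
    tree_method="hist",
    random_state=123,
    n_jobs=1,
    eval_metric="logloss",
)

CLASSIFIER_DEFAULTS: dict[str, dict[str, Any]] = {
    "extra_trees": EXTRA_TREES_DEFAULTS,
    "gradient_boosted_trees_a": LIGHTGBM_DEFAULTS,
    "gradient_boosted_trees_b": XGBOOST_DEFAULTS,
}

#: Small documented grids for the optional random search tuner.
TUNING_GRIDS: dict[str, dict[str, list]] = {
    "extra_trees": {
        "n_estimators": [100, 200, 400],
        "max_depth": [4, 6, 8, None],
        "min_samples_split": [2, 5, 7],
        "min_samples_leaf": [1, 2, 4],
    },
    "gradient_boosted_trees_a": {
        "n_estimators": [50, 100, 200],
        "num_leaves": [15, 31, 63],
        "learning_rate": [0.05, 0.1, 0.2],
    },
    "gradient_boosted_trees_b": {
        "n_estimators": [200, 500, 1000],
        "max_depth": [4, 6, 8],
        "learning_rate": [0.01, 0.05, 0.1],
    },
}


def make_classifier(name: str, params: Mapping[str, Any] | None = None,
                    seed: int | None = None):
    """Instantiate a named backend with its defaults, optional overrides
    and (if given) a seed overriding ``random_state``."""
    if name not in CLASSIFIER_DEFAULTS:
        raise ConfigError(
            f"unknown classifier {name!r}; supported: "
            f"{sorted(CLASSIFIER_DEFAULTS)}"
        )
    kwargs = dict(CLASSIFIER_DEFAULTS[name])
    if params:
        kwargs.update(params)
    if seed is not None:
        kwargs["random_state"] = seed
    if name == "extra_trees":
        return ExtraTreesClassifier(**kwargs)
    if name == "gradient_boosted_trees_a":
        from lightgbm import LGBMClassifier
        return LGBMClassifier(**kwargs)
    from xgboost import XGBClassifier
    return XGBClassifier(**kwargs)


def random_grid_search(name: str, X, y, n_iter: int = 10, cv: int = 5,
                       seed: int = 123):
    """Optional randomised grid search over the documented small grid;
    returns the fitted :class:`RandomizedSearchCV` object."""
    est = make_classifier(name, seed=seed)
    search = RandomizedSearchCV(
        est, TUNING_GRIDS[name], n_iter=n_iter, cv=cv, scoring="accuracy",
        random_state=seed, n_jobs=1,
    )
    return search.fit(X, y)
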