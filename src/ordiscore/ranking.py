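"""Variable ranking by multiclass random-forest importance.

The ordinal outcome is treated as an unordered multiclass label; predictors are
ranked by mean decrease in impurity (Gini importance) from a random forest
trained on the training set. The ranking only orders candidates for the
parsimony sweep — the forest itself is never used for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .data import OrdinalData

__all__ = ["VariableRanking", "rank_variables"]


@dataclass(frozen=True)
class VariableRanking:
    """Predictors ordered by descending random-forest importance."""

    variables: tuple[str, ...]
    importances: tuple[float, ...]
    n_trees: int
    seed: int

    def __post_init__(self):
        imp = np.asarray(self.importances)
        if np.any(imp < 0) or np.any(np.diff(imp) > 0):
            raise ValueError("importances must be non-negative and non-increasing")

    def top(self, k: int) -> list[str]:
        return list(self.variables[:k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.variables) + 1),
                "variable": self.variables,
                "importance": self.importances,
            }
        )


def _encode(data: OrdinalData) -> tuple[np.ndarray, list[str], list[int]]:
    """Design matrix for the forest.

    Ordered categoricals (interval-categorized continuous variables) are encoded
    by their interval index, which preserves the monotone structure the
    categorization created; other categoricals are one-hot encoded and their
    dummy importances later summed per source variable.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    owner: list[int] = []  # index into data.predictors per encoded column
    for pi, var in enumerate(data.predictors):
        s = data.df[var]
        if s.isna().any():
            raise ValueError(f"variable {var!r} has missing values; impute first")
        if isinstance(s.dtype, pd.CategoricalDtype) and s.dtype.ordered:
            cols.append(s.cat.codes.to_numpy(dtype=float))
            names.append(var)
            owner.append(pi)
        elif data.is_categorical(var):
            dummies = pd.get_dummies(s.astype("category"))
            for lvl in dummies.columns:
                cols.append(dummies[lvl].to_numpy(dtype=float))
                names.append(f"{var}={lvl}")
                owner.append(pi)
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(var)
            owner.append(pi)
    return np.column_stack(cols), names, owner


def rank_variables(
    train: OrdinalData,
    n_trees: int = 100,
    seed: int = 0,
    max_features="sqrt",
    min_leaf_fraction: float = 0.005,
) -> VariableRanking:
    """Rank predictors by Gini importance to a multiclass random forest.

    Ties are broken by original column order. ``max_features`` is passed to the
    forest; ``None`` (all features at every split) makes the importance values
    invariant to predictor column order. ``min_leaf_fraction`` sets the minimum
    leaf size as a fraction of the sample: fully grown trees spend most of
    their impurity reduction on deep, essentially random splits, which spreads
    Gini importance evenly over signal and noise candidates; a small minimum
    leaf keeps the importances driven by population-level structure. Set it to
    ``1`` (one case) to recover fully grown trees.
    """
    if len(train.predictors) < 1:
        raise ValueError("need at least one predictor to rank")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    y = train.y
    if np.unique(y).size < 2:
        raise ValueError("outcome has a single category; cannot rank")
    X, _, owner = _encode(train)
    leaf = min_leaf_fraction if 0 < min_leaf_fraction < 1 else int(min_leaf_fraction)
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=seed,
        max_features=max_features,
        min_samples_leaf=leaf,
        n_jobs=1,
    )
    rf.fit(X, y)
    agg = np.zeros(len(train.predictors))
    np.add.at(agg, owner, rf.feature_importances_)
    # stable sort on descending importance => ties keep column order
    order = np.argsort(-agg, kind="stable")
    return VariableRanking(
        variables=tuple(train.predictors[i] for i in order),
        importances=tuple(float(agg[i]) for i in order),
        n_trees=n_trees,
        seed=seed,
    )
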