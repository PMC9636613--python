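"""Cohort container, stratified splitting, imputation and variable categorization.

The pipeline operates on tabular cohorts: one row per case, mixed
continuous/categorical predictors, and an ordinal outcome coded with integers
``1..J``. Continuous predictors are discretized into half-open intervals at
training-set quantiles so that every downstream predictor is categorical and
can carry an integer partial score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING_LEVEL = "missing"

__all__ = [
    "OrdinalData",
    "DataSplit",
    "CutoffScheme",
    "split_data",
    "impute_median",
    "compute_cutoffs",
    "apply_cutoffs",
    "interval_labels",
]


def _fmt(v: float) -> str:
    """Render a cutoff value the way it appears in scoring tables (no trailing zeros)."""
    return f"{v:g}"


def level_strings(s: pd.Series) -> np.ndarray:
    """Canonical string form of a level column; numeric levels lose trailing zeros
    so that e.g. int 1 and float 1.0 name the same category."""
    if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
        return np.array([f"{v:g}" for v in s.to_numpy()], dtype=object)
    return s.astype(str).to_numpy(dtype=object)


@dataclass(frozen=True)
class OrdinalData:
    """A cohort with named predictors and an ordinal outcome coded 1..J.

    Parameters
    ----------
    df : DataFrame
        One row per case. Must contain ``outcome`` plus every predictor column.
    outcome : str
        Name of the ordinal outcome column (integer categories ``1..J``).
    predictors : list of str, optional
        Predictor columns. Defaults to every column except the outcome.
    categorical : list of str, optional
        Predictors to treat as categorical regardless of dtype. Non-numeric
        columns are always categorical.
    """

    df: pd.DataFrame
    outcome: str
    predictors: tuple[str, ...] = ()
    categorical: tuple[str, ...] = ()
    n_categories: int = field(default=0)

    def __post_init__(self):
        df = self.df
        if self.outcome not in df.columns:
            raise ValueError(f"outcome column {self.outcome!r} not in data")
        preds = tuple(self.predictors) or tuple(c for c in df.columns if c != self.outcome)
        if self.outcome in preds:
            raise ValueError("outcome column cannot be a predictor")
        if len(set(preds)) != len(preds):
            raise ValueError("duplicate predictor names")
        missing = [c for c in preds if c not in df.columns]
        if missing:
            raise ValueError(f"predictor columns not in data: {missing}")
        y = df[self.outcome].to_numpy()
        if np.any(pd.isna(y)):
            raise ValueError("outcome contains missing values")
        yi = y.astype(np.int64)
        if not np.array_equal(yi, y.astype(float)):
            raise ValueError("outcome categories must be integers")
        if yi.size:
            J = int(self.n_categories) or int(yi.max())
            if yi.min() < 1 or yi.max() > J:
                raise ValueError(f"outcome values must lie in 1..{J}")
        else:  # empty subsets (e.g. a zero-ratio split) are allowed
            J = int(self.n_categories)
        object.__setattr__(self, "predictors", preds)
        object.__setattr__(self, "categorical", tuple(self.categorical))
        object.__setattr__(self, "n_categories", J)

    # -- convenience ---------------------------------------------------------
    @property
    def y(self) -> np.ndarray:
        return self.df[self.outcome].to_numpy(dtype=np.int64)

    @property
    def n(self) -> int:
        return len(self.df)

    def is_categorical(self, col: str) -> bool:
        if col in self.categorical:
            return True
        return not pd.api.types.is_numeric_dtype(self.df[col])

    @property
    def continuous_predictors(self) -> list[str]:
        return [c for c in self.predictors if not self.is_categorical(c)]

    @property
    def categorical_predictors(self) -> list[str]:
        return [c for c in self.predictors if self.is_categorical(c)]

    def subset(self, idx: np.ndarray) -> "OrdinalData":
        return replace(self, df=self.df.iloc[idx].reset_index(drop=True))

    def with_df(self, df: pd.DataFrame) -> "OrdinalData":
        return replace(self, df=df)

    def select(self, predictors: list[str]) -> "OrdinalData":
        cols = list(predictors) + [self.outcome]
        return replace(
            self,
            df=self.df[cols],
            predictors=tuple(predictors),
            categorical=tuple(c for c in self.categorical if c in predictors),
        )


@dataclass(frozen=True)
class DataSplit:
    """Row-index partition into train/validation/test, stratified by outcome."""

    train_idx: np.ndarray
    valid_idx: np.ndarray
    test_idx: np.ndarray
    ratios: tuple[float, float, float]
    seed: int


def split_data(data: OrdinalData, ratios=(0.7, 0.1, 0.2), seed: int = 0) -> DataSplit:
    """Stratified train/validation/test split.

    Within each outcome category the rows are shuffled and allocated to the
    three sets by largest-remainder apportionment, so each set's per-category
    count is within one row of ``n_category * ratio``.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ValueError("ratios must be three non-negative proportions")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    y = data.y
    n_nonzero = sum(r > 0 for r in ratios)
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for cat in np.unique(y):
        idx = np.flatnonzero(y == cat)
        if len(idx) < max(3, n_nonzero):
            raise ValueError(
                f"outcome category {cat} has {len(idx)} rows; need at least "
                f"{max(3, n_nonzero)} for a {n_nonzero}-way split"
            )
        idx = rng.permutation(idx)
        counts = _apportion(len(idx), ratios)
        stops = np.cumsum(counts)
        parts[0].append(idx[: stops[0]])
        parts[1].append(idx[stops[0]: stops[1]])
        parts[2].append(idx[stops[1]: stops[2]])
    train, valid, test = (np.sort(np.concatenate(p)) for p in parts)
    return DataSplit(train, valid, test, ratios, seed)


def _apportion(n: int, ratios: tuple[float, ...]) -> np.ndarray:
    """Integer allocation of n items to ratios by largest remainder (ties: earlier set)."""
    exact = np.asarray(ratios) * n
    counts = np.floor(exact).astype(int)
    rem = n - counts.sum()
    if rem:
        # stable argsort => earlier set wins ties
        order = np.argsort(-(exact - counts), kind="stable")
        counts[order[:rem]] += 1
    return counts


def impute_median(reference: OrdinalData, target: OrdinalData) -> OrdinalData:
    """Fill missing values in ``target`` using ``reference`` column medians.

    Continuous columns get the reference median; categorical columns get an
    explicit ``"missing"`` level so that a score can attach to "unknown".
    """
    df = target.df.copy()
    for col in target.predictors:
        if target.is_categorical(col):
            if df[col].isna().any():
                if isinstance(df[col].dtype, pd.CategoricalDtype):
                    df[col] = df[col].cat.add_categories([MISSING_LEVEL])
                df[col] = df[col].fillna(MISSING_LEVEL)
        else:
            if df[col].isna().any():
                ref = reference.df[col]
                if not ref.notna().any():
                    raise ValueError(f"column {col!r} is entirely missing in the reference set")
                med = ref.median(skipna=True)
                df[col] = df[col].fillna(med)
    return target.with_df(df)


@dataclass(frozen=True)
class CutoffScheme:
    """Per-variable ordered cutoffs defining half-open categorization intervals.

    ``cutoffs[var] = [c_1 < ... < c_m]`` yields the intervals
    ``"< c_1"``, ``"[c_1, c_2)"``, ..., ``">= c_m"`` (lower-inclusive,
    upper-exclusive). An empty list means a single interval covering all values.
    """

    cutoffs: dict[str, list[float]]
    provenance: dict[str, str] = field(default_factory=dict)  # "auto" | "fine-tuned"

    def __post_init__(self):
        for var, cuts in self.cutoffs.items():
            arr = np.asarray(cuts, dtype=float)
            if arr.size and (not np.all(np.isfinite(arr)) or np.any(np.diff(arr) <= 0)):
                raise ValueError(f"cutoffs for {var!r} must be finite and strictly increasing")

    def labels(self, var: str) -> list[str]:
        return interval_labels(self.cutoffs[var])

    def override(self, overrides: dict[str, list[float]]) -> "CutoffScheme":
        cuts = {k: list(v) for k, v in self.cutoffs.items()}
        prov = dict(self.provenance)
        for var, c in overrides.items():
            if var not in cuts:
                raise KeyError(f"no cutoff entry for variable {var!r}")
            cuts[var] = [float(x) for x in c]
            prov[var] = "fine-tuned"
        return CutoffScheme(cuts, prov)

    def to_json(self) -> str:
        return json.dumps(
            {"cutoffs": self.cutoffs, "provenance": self.provenance}, indent=2, sort_keys=True
        )

    @classmethod
    def from_json(cls, text: str) -> "CutoffScheme":
        d = json.loads(text)
        return cls({k: list(map(float, v)) for k, v in d["cutoffs"].items()}, d.get("provenance", {}))


def interval_labels(cutoffs: list[float]) -> list[str]:
    """Interval labels in the ``"< A"``, ``"[A, B)"``, ``">= B"`` dialect."""
    cuts = [float(c) for c in cutoffs]
    if not cuts:
        return ["all"]
    labels = [f"< {_fmt(cuts[0])}"]
    labels += [f"[{_fmt(a)}, {_fmt(b)})" for a, b in zip(cuts[:-1], cuts[1:])]
    labels.append(f">= {_fmt(cuts[-1])}")
    return labels


def compute_cutoffs(
    train: OrdinalData,
    quantile_ranks=(0.05, 0.20, 0.80, 0.95),
) -> CutoffScheme:
    """Quantile-based cutoffs for every continuous predictor of the training set.

    Quantiles use linear interpolation between order statistics
    (``h = (n-1)p + 1``, numpy's default). Duplicate cutoffs and cutoffs whose
    left interval contains no training value are dropped (the interval is
    merged rightward) to avoid sparse categories under skewed distributions.
    """
    ranks = np.asarray(quantile_ranks, dtype=float)
    if ranks.size and (np.any(np.diff(ranks) <= 0) or ranks.min() <= 0 or ranks.max() >= 1):
        raise ValueError("quantile_ranks must be strictly increasing within (0, 1)")
    cutoffs: dict[str, list[float]] = {}
    for var in train.continuous_predictors:
        x = train.df[var].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        if x.size == 0:
            raise ValueError(f"variable {var!r} has no non-missing training values")
        cuts = np.unique(np.quantile(x, ranks)) if ranks.size else np.array([])
        cutoffs[var] = _prune_sparse(x, list(cuts))
    prov = {v: "auto" for v in cutoffs}
    return CutoffScheme(cutoffs, prov)


def _prune_sparse(x: np.ndarray, cuts: list[float]) -> list[float]:
    """Drop any cutoff whose left interval is empty on the training values."""
    changed = True
    while changed and cuts:
        changed = False
        for i, c in enumerate(cuts):
            lo = -np.inf if i == 0 else cuts[i - 1]
            if not np.any((x >= lo) & (x < c)):
                del cuts[i]
                changed = True
                break
    return cuts


def apply_cutoffs(data: OrdinalData, scheme: CutoffScheme) -> OrdinalData:
    """Replace continuous columns by ordered categorical interval labels.

    Values below the first cutoff fall in the first interval; values at or
    above the last cutoff in the last (lower-inclusive, upper-exclusive
    everywhere). Categorical columns pass through unchanged.
    """
    df = data.df.copy()
    cat_cols = list(data.categorical)
    for var in data.continuous_predictors:
        if var not in scheme.cutoffs:
            raise KeyError(f"variable {var!r} has no entry in the cutoff scheme")
        x = df[var].to_numpy(dtype=float)
        if np.any(np.isnan(x)):
            raise ValueError(f"variable {var!r} still has missing values; impute first")
        cuts = np.asarray(scheme.cutoffs[var], dtype=float)
        labels = interval_labels(list(cuts))
        idx = np.searchsorted(cuts, x, side="right")
        df[var] = pd.Categorical.from_codes(idx, categories=labels, ordered=True)
        cat_cols.append(var)
    return replace(data, df=df, categorical=tuple(dict.fromkeys(cat_cols)))
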