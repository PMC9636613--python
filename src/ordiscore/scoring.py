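"""Integer point-score derivation from a fitted proportional odds model.

After releveling so that every coefficient is non-negative, coefficients are
normalized by the smallest strictly positive coefficient across all predictors
and rounded half-away-from-zero to integers ("partial scores", 0 at each
reference level). A case's total score is the sum of its partial scores, and a
lookup table maps total-score intervals to the observed outcome-category
proportions in the training set, so a clinician can read predicted risks off a
checklist-style table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CutoffScheme, OrdinalData, apply_cutoffs, interval_labels, level_strings
from .pom import POMResults, fit_pom

__all__ = [
    "ScoringTable",
    "LookupTable",
    "derive_partial_scores",
    "rescale_scores",
    "build_lookup",
    "build_scoring_table",
    "fine_tune",
]


def _round_half_away(x: np.ndarray | float) -> np.ndarray | int:
    """Round halves away from zero (0.5 -> 1); bankers' rounding would change tables."""
    arr = np.asarray(x, dtype=float)
    out = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    return out.astype(int) if out.ndim else int(out)


@dataclass(frozen=True)
class ScoringTable:
    """Per-predictor map from level to non-negative integer partial score.

    ``scores[var][level]`` is the integer partial score; each predictor's
    reference level scores exactly 0. ``max_total`` is the sum over predictors
    of the per-predictor maximum, i.e. the largest attainable total score.
    """

    scores: dict[str, dict[str, int]]
    references: dict[str, str]
    cutoff_scheme: CutoffScheme | None = None
    rescale_target: int | None = None

    def __post_init__(self):
        for var, smap in self.scores.items():
            if any(s < 0 or int(s) != s for s in smap.values()):
                raise ValueError(f"partial scores for {var!r} must be non-negative integers")
            if smap.get(self.references[var], None) != 0:
                raise ValueError(f"reference level of {var!r} must score 0")

    @property
    def max_total(self) -> int:
        return int(sum(max(smap.values()) for smap in self.scores.values()))

    @property
    def predictors(self) -> list[str]:
        return list(self.scores)

    # -- scoring -------------------------------------------------------------
    def total_score(self, record) -> int:
        """Total score of a single record (dict, Series, or one-row frame)."""
        if isinstance(record, pd.DataFrame):
            if len(record) != 1:
                raise ValueError("total_score expects a single record; use score() for frames")
            record = record.iloc[0]
        return int(self.score(pd.DataFrame([dict(record)]))[0])

    def score(self, records: pd.DataFrame, coerce: bool = False) -> np.ndarray:
        """Integer total scores for a frame of records.

        Columns covered by the table's cutoff scheme may be given either as
        raw numeric values (categorized on the fly) or as interval labels.
        """
        total = np.zeros(len(records), dtype=int)
        for var, smap in self.scores.items():
            vals = self._levels_of(records, var)
            col = np.empty(len(vals), dtype=int)
            for i, v in enumerate(vals):
                if v in smap:
                    col[i] = smap[v]
                elif coerce:
                    col[i] = 0
                else:
                    raise KeyError(f"unseen level {v!r} for variable {var!r}")
            total += col
        return total

    def _levels_of(self, records: pd.DataFrame, var: str) -> np.ndarray:
        """Level labels for one column, categorizing raw numeric values if needed."""
        s = records[var]
        scheme = self.cutoff_scheme
        if (
            scheme is not None
            and var in scheme.cutoffs
            and pd.api.types.is_numeric_dtype(s)
            and not isinstance(s.dtype, pd.CategoricalDtype)
        ):
            x = s.to_numpy(dtype=float)
            if np.any(np.isnan(x)):
                raise ValueError(f"variable {var!r} has missing values; impute first")
            cuts = np.asarray(scheme.cutoffs[var], dtype=float)
            labels = np.array(interval_labels(list(cuts)), dtype=object)
            return labels[np.searchsorted(cuts, x, side="right")]
        return level_strings(s)

    # -- rendering -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variable": var, "interval": lvl, "partial_score": s}
            for var, smap in self.scores.items()
            for lvl, s in smap.items()
        ]
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [f"{'Variable':<32}{'Interval':<20}{'Partial score':>13}"]
        for var, smap in self.scores.items():
            for i, (lvl, s) in enumerate(smap.items()):
                lines.append(f"{var if i == 0 else '':<32}{lvl:<20}{s:>13d}")
        lines.append(f"{'Maximum total score':<52}{self.max_total:>13d}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "scores": self.scores,
                "references": self.references,
                "rescale_target": self.rescale_target,
                "max_total": self.max_total,
                "cutoffs": self.cutoff_scheme.cutoffs if self.cutoff_scheme else None,
                "cutoff_provenance": self.cutoff_scheme.provenance if self.cutoff_scheme else None,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoringTable":
        d = json.loads(text)
        scheme = None
        if d.get("cutoffs") is not None:
            scheme = CutoffScheme(d["cutoffs"], d.get("cutoff_provenance") or {})
        return cls(
            {v: {l: int(s) for l, s in m.items()} for v, m in d["scores"].items()},
            d["references"],
            scheme,
            d.get("rescale_target"),
        )


def derive_partial_scores(fit: POMResults, cutoff_scheme: CutoffScheme | None = None) -> ScoringTable:
    """Integer partial scores from a releveled fit (all coefficients >= 0).

    Every coefficient is divided by the smallest strictly positive coefficient
    across *all* predictors and rounded half-away-from-zero, so the weakest
    non-reference effect scores exactly 1 and references stay 0.
    """
    all_coefs = np.array([c for cmap in fit.coef.values() for c in cmap.values()])
    if np.any(all_coefs < -1e-9):
        raise ValueError("derive_partial_scores requires a releveled fit (all coefficients >= 0)")
    positive = all_coefs[all_coefs > 0]
    if positive.size == 0:
        raise ValueError("all coefficients are zero; the model carries no signal to score")
    unit = positive.min()
    scores = {
        var: {lvl: int(_round_half_away(max(c, 0.0) / unit)) for lvl, c in cmap.items()}
        for var, cmap in fit.coef.items()
    }
    return ScoringTable(scores, dict(fit.references), cutoff_scheme)


def rescale_scores(table: ScoringTable, target: int) -> ScoringTable:
    """Rescale partial scores so the maximum attainable total is about ``target``.

    Each score is multiplied by ``target / max_total`` and re-rounded
    half-away-from-zero; zeros are preserved and within-predictor ordering is
    unchanged. The resulting maximum can land slightly below ``target`` because
    of rounding.
    """
    cur = table.max_total
    if cur == 0:
        raise ValueError("cannot rescale a table whose maximum total score is 0")
    if target == cur:
        return ScoringTable(table.scores, table.references, table.cutoff_scheme, target)
    factor = target / cur
    scores = {
        var: {lvl: int(_round_half_away(s * factor)) for lvl, s in smap.items()}
        for var, smap in table.scores.items()
    }
    zeroed = [var for var, smap in scores.items() if max(smap.values()) == 0]
    if zeroed:
        import warnings

        warnings.warn(
            f"rescale target {target} leaves predictors with all-zero scores: {zeroed}",
            stacklevel=2,
        )
    return ScoringTable(scores, table.references, table.cutoff_scheme, target)


# --------------------------------------------------------------------------- #
# lookup table


@dataclass(frozen=True)
class LookupTable:
    """Total-score intervals mapped to observed outcome-category proportions.

    ``breaks`` are the interior integer cutpoints; the intervals
    ``"< b1", "[b1, b2)", ..., ">= bm"`` partition the achievable score range
    ``[0, max_total]``. ``probs[i, j]`` is the training proportion of outcome
    category ``j+1`` in interval ``i``; rows sum to 1.
    """

    breaks: tuple[int, ...]
    counts: tuple[int, ...]
    probs: np.ndarray = field(repr=False)
    max_total: int = 0

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape[0] != len(self.breaks) + 1:
            raise ValueError("need one probability row per interval")
        if np.any(probs < 0) or not np.allclose(probs.sum(axis=1), 1.0):
            raise ValueError("interval probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "probs", probs)

    @property
    def labels(self) -> list[str]:
        return interval_labels(list(self.breaks))

    def bin_index(self, scores) -> np.ndarray:
        return np.searchsorted(np.asarray(self.breaks), np.asarray(scores), side="right")

    def predict_proba(self, scores) -> np.ndarray:
        """Per-row category probabilities read off the lookup table."""
        return self.probs[self.bin_index(scores)]

    def to_frame(self) -> pd.DataFrame:
        J = self.probs.shape[1]
        df = pd.DataFrame({"interval": self.labels, "n": self.counts})
        for j in range(J):
            df[f"p_{j + 1}"] = self.probs[:, j]
        return df

    def to_json(self) -> str:
        return json.dumps(
            {
                "breaks": list(self.breaks),
                "counts": list(self.counts),
                "probs": self.probs.tolist(),
                "max_total": self.max_total,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LookupTable":
        d = json.loads(text)
        return cls(
            tuple(d["breaks"]), tuple(d["counts"]), np.asarray(d["probs"]), d["max_total"]
        )


def build_lookup(table: ScoringTable, train: OrdinalData, bins=10) -> LookupTable:
    """Group training cases by total-score interval and tabulate outcome proportions.

    ``bins`` is either the number of equal-frequency bins of the training score
    distribution (default 10) or an explicit list of integer cutpoints. Bins
    left empty on the training set are merged into the interval to their right.
    """
    scores = table.score(train.df)
    if scores.size == 0:
        raise ValueError("no scoreable training rows")
    J = train.n_categories
    y = train.y
    if isinstance(bins, int):
        qs = np.quantile(scores, np.arange(1, bins) / bins)
        cand = sorted(set(int(np.ceil(q)) for q in qs))
    else:
        cand = sorted(set(int(b) for b in bins))
    cand = [b for b in cand if 0 < b <= table.max_total]
    breaks = _prune_empty_bins(scores, cand)
    idx = np.searchsorted(np.asarray(breaks), scores, side="right")
    n_bins = len(breaks) + 1
    counts = np.bincount(idx, minlength=n_bins)
    probs = np.zeros((n_bins, J))
    for b in range(n_bins):
        sel = idx == b
        if counts[b]:
            probs[b] = np.bincount(y[sel], minlength=J + 1)[1:] / counts[b]
        else:  # achievable-but-unpopulated top interval: fall back to neighbor
            probs[b] = probs[b - 1]
    return LookupTable(tuple(breaks), tuple(int(c) for c in counts), probs, table.max_total)


def _prune_empty_bins(scores: np.ndarray, breaks: list[int]) -> list[int]:
    """Drop cutpoints whose left bin has no training case (merge rightward)."""
    breaks = list(breaks)
    changed = True
    while changed and breaks:
        changed = False
        for i, b in enumerate(breaks):
            lo = -np.inf if i == 0 else breaks[i - 1]
            if not np.any((scores >= lo) & (scores < b)):
                del breaks[i]
                changed = True
                break
    # ensure the last (open-ended) bin is populated too
    while breaks and not np.any(scores >= breaks[-1]):
        del breaks[-1]
    return breaks


# --------------------------------------------------------------------------- #
# end-to-end derivation and fine-tuning


def build_scoring_table(
    train_imputed: OrdinalData,
    scheme: CutoffScheme,
    rescale_target: int | None = 100,
) -> tuple[ScoringTable, POMResults, OrdinalData]:
    """Categorize -> fit POM -> relevel -> derive -> (rescale).

    Returns the scoring table, the releveled fit it came from, and the
    categorized training set (for lookup-table construction).
    """
    cat_train = apply_cutoffs(train_imputed, scheme)
    fit = fit_pom(cat_train)
    if not fit.converged:
        raise RuntimeError("proportional odds fit did not converge on the training set")
    releveled = fit.relevel_positive()
    table = derive_partial_scores(releveled, cutoff_scheme=scheme)
    if rescale_target is not None and table.max_total != rescale_target:
        table = rescale_scores(table, rescale_target)
    return table, releveled, cat_train


def fine_tune(
    cutoff_overrides: dict[str, list[float]],
    train_imputed: OrdinalData,
    scheme: CutoffScheme,
    rescale_target: int | None = 100,
) -> tuple[ScoringTable, POMResults, OrdinalData]:
    """Re-derive the score with user-chosen cutoffs for selected variables.

    Overridden variables are re-categorized with the given cutoffs (e.g.
    10-year age bands instead of quantile intervals), the model is refitted on
    the training set, and partial scores are re-derived and re-scaled.
    Variables without overrides keep their automatic cutoffs.
    """
    for var, cuts in cutoff_overrides.items():
        arr = np.asarray(cuts, dtype=float)
        if np.any(np.diff(arr) <= 0):
            raise ValueError(f"override cutoffs for {var!r} must be strictly increasing")
        x = train_imputed.df[var].to_numpy(dtype=float)
        idx = np.searchsorted(arr, x, side="right")
        for k, label in enumerate(interval_labels(list(arr))):
            if not np.any(idx == k):
                raise ValueError(
                    f"override for {var!r} leaves training interval {label!r} empty"
                )
    tuned = scheme.override(cutoff_overrides)
    return build_scoring_table(train_imputed, tuned, rescale_target)
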