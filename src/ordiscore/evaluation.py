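"""Model selection (parsimony sweep) and final evaluation of a scoring model.

The parsimony sweep grows the scoring model one ranked variable at a time and
records the validation-set mAUC of each k-variable model, producing the data
behind the parsimony plot used to pick a sparse model. The final model is
evaluated on the test set by mAUC and generalized c-index, each with a BCa
bootstrap interval, and by a calibration table comparing lookup-table predicted
risks with observed test-set proportions per score interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CutoffScheme, OrdinalData
from .metrics import BootstrapCI, bootstrap_ci, gen_cindex, mean_auc
from .ranking import VariableRanking
from .scoring import LookupTable, ScoringTable, build_scoring_table

__all__ = [
    "ParsimonyResult",
    "EvalReport",
    "parsimony",
    "select_variables",
    "evaluate",
    "calibration_report",
]


@dataclass(frozen=True)
class ParsimonyResult:
    """Validation mAUC of the k-variable scoring model, for k = 1..max_k."""

    table: pd.DataFrame  # columns: k, variable, mauc
    ranking: VariableRanking

    def best_k(self) -> int:
        t = self.table.dropna(subset=["mauc"])
        return int(t.loc[t["mauc"].idxmax(), "k"])

    def plot(self, ax=None):
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        t = self.table
        ax.bar(t["k"], t["mauc"], color="steelblue")
        ax.set_xticks(t["k"])
        ax.set_xticklabels(t["variable"], rotation=60, ha="right", fontsize=8)
        ax.set_xlabel("variable added (cumulative model size)")
        ax.set_ylabel("validation mAUC")
        ax.set_title("Parsimony plot")
        lo = max(0.0, np.nanmin(t["mauc"].to_numpy()) - 0.05)
        ax.set_ylim(lo, min(1.0, np.nanmax(t["mauc"].to_numpy()) + 0.02))
        return ax


def parsimony(
    ranking: VariableRanking,
    train_imputed: OrdinalData,
    valid_imputed: OrdinalData,
    scheme: CutoffScheme,
    max_k: int | None = None,
    ks: list[int] | None = None,
) -> ParsimonyResult:
    """Grow the scoring model along the ranking, scoring each size on validation.

    Each k-variable model runs the full derivation (categorize, fit POM,
    relevel, integer partial scores, unrescaled — metrics are invariant to the
    rescaling) on the training set; its validation mAUC uses the rounded total
    score. A size whose fit does not converge (or degenerates to all-zero
    coefficients) is recorded as NaN and skipped in the plot.

    ``ks`` evaluates only the given model sizes (e.g. ``[3, 22]`` to compare a
    sparse model against the all-variable model without fitting every size in
    between); by default every size from 1 to ``max_k`` is evaluated.
    """
    K = len(ranking.variables)
    max_k = K if max_k is None else int(max_k)
    if max_k > K:
        raise ValueError(f"max_k={max_k} exceeds the {K} ranked variables")
    sizes = list(range(1, max_k + 1)) if ks is None else sorted(set(int(k) for k in ks))
    if ks is not None and (sizes[0] < 1 or sizes[-1] > K):
        raise ValueError(f"ks must lie in [1, {K}]")
    rows = []
    for k in sizes:
        vars_k = ranking.top(k)
        mauc = np.nan
        try:
            table, _, _ = build_scoring_table(
                train_imputed.select(vars_k), scheme, rescale_target=None
            )
            scores = table.score(valid_imputed.df, coerce=True)
            mauc, _ = mean_auc(scores, valid_imputed.y)
        except (RuntimeError, ValueError):
            pass
        rows.append({"k": k, "variable": ranking.variables[k - 1], "mauc": mauc})
    return ParsimonyResult(pd.DataFrame(rows), ranking)


def select_variables(
    result: ParsimonyResult | VariableRanking,
    k: int,
    include=(),
    exclude=(),
) -> list[str]:
    """Top-k ranked variables with manual include/exclude edits, rank order kept."""
    ranking = result.ranking if isinstance(result, ParsimonyResult) else result
    ranked = list(ranking.variables)
    unknown = [v for v in list(include) + list(exclude) if v not in ranked]
    if unknown:
        raise ValueError(f"unknown variable names: {unknown}")
    chosen = set(ranked[:k]) | set(include)
    chosen -= set(exclude)
    if not chosen:
        raise ValueError("variable selection is empty after edits")
    return [v for v in ranked if v in chosen]


@dataclass(frozen=True)
class EvalReport:
    """Discrimination metrics with bootstrap intervals for one scoring model."""

    mauc: float
    per_dichotomy: dict[int, float]
    cindex: float
    mauc_ci: BootstrapCI
    cindex_ci: BootstrapCI
    n_boot: int
    seed: int

    def summary(self) -> str:
        def ci(b: BootstrapCI) -> str:
            return f"{b.point:.3f} ({b.lower:.3f}, {b.upper:.3f})"

        dich = ", ".join(f"AUC(Y>{j})={a:.3f}" for j, a in self.per_dichotomy.items())
        return (
            f"mAUC (95% CI): {ci(self.mauc_ci)}\n"
            f"Generalized c-index (95% CI): {ci(self.cindex_ci)}\n"
            f"Per-dichotomy: {dich}\n"
            f"Bootstrap: B={self.n_boot}, seed={self.seed}"
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "mauc": self.mauc,
                "per_dichotomy_auc": {str(j): a for j, a in self.per_dichotomy.items()},
                "gen_cindex": self.cindex,
                "mauc_ci": [self.mauc_ci.lower, self.mauc_ci.upper],
                "gen_cindex_ci": [self.cindex_ci.lower, self.cindex_ci.upper],
                "n_boot": self.n_boot,
                "seed": self.seed,
            },
            indent=2,
        )


def evaluate(
    scores,
    outcome,
    n_boot: int = 100,
    seed: int = 0,
    level: float = 0.95,
    accelerated: bool = True,
) -> EvalReport:
    """mAUC and generalized c-index of a score, with BCa bootstrap intervals."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=np.int64)
    mauc, per = mean_auc(scores, y)
    ci_m = bootstrap_ci(
        lambda s, o: mean_auc(s, o)[0], scores, y, n_boot, level, seed, accelerated
    )
    ci_c = bootstrap_ci(gen_cindex, scores, y, n_boot, level, seed + 1, accelerated)
    return EvalReport(mauc, per, gen_cindex(scores, y), ci_m, ci_c, n_boot, seed)


def calibration_report(
    table: ScoringTable, lookup: LookupTable, test: OrdinalData
) -> pd.DataFrame:
    """Predicted vs observed per-category risk by lookup score interval.

    Predicted risk is the training proportion stored in the lookup table;
    observed risk is the test-set proportion among cases whose total score
    falls in the interval. One row per (interval, outcome category).
    """
    if test.n == 0:
        raise ValueError("empty test set")
    scores = table.score(test.df, coerce=True)
    idx = lookup.bin_index(scores)
    J = lookup.probs.shape[1]
    y = test.y
    rows = []
    for b, label in enumerate(lookup.labels):
        sel = idx == b
        n_bin = int(sel.sum())
        obs = (
            np.bincount(y[sel], minlength=J + 1)[1:] / n_bin if n_bin else np.full(J, np.nan)
        )
        for j in range(J):
            rows.append(
                {
                    "interval": label,
                    "category": j + 1,
                    "predicted": lookup.probs[b, j],
                    "observed": obs[j],
                    "n": n_bin,
                }
            )
    return pd.DataFrame(rows)


def plot_calibration(report: pd.DataFrame, ax=None):
    """Observed vs predicted risk, one marker per (score interval, category)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    cats = sorted(report["category"].unique())
    markers = ["o", "s", "^", "D", "v", "P"]
    intervals = list(dict.fromkeys(report["interval"]))
    shade = {iv: i / max(1, len(intervals) - 1) for i, iv in enumerate(intervals)}
    for ci, cat in enumerate(cats):
        sub = report[report["category"] == cat]
        ax.scatter(
            sub["predicted"],
            sub["observed"],
            c=[shade[iv] for iv in sub["interval"]],
            cmap="viridis",
            marker=markers[ci % len(markers)],
            label=f"category {cat}",
            edgecolors="k",
            linewidths=0.3,
        )
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("predicted risk (lookup table)")
    ax.set_ylabel("observed risk (test set)")
    ax.legend()
    ax.set_title("Calibration by score interval")
    return ax
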