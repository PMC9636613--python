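"""Ordinal discrimination metrics and bootstrap confidence intervals.

Two metrics evaluate an ordinal risk score:

* **mAUC** — the outcome with J categories is dichotomized at each threshold
  (``Y <= j`` vs ``Y > j``) and the mean of the J-1 binary AUCs is reported.
* **generalized c-index** (Harrell) — the tie-aware proportion of concordant
  pairs among all pairs with different outcome categories.

Both equal 0.5 for a random score and 1 for a perfect ordering, and both are
invariant under strictly increasing transforms of the score. Uncertainty is
quantified with bias-corrected and accelerated (BCa) bootstrap intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

__all__ = ["auc_binary", "mean_auc", "gen_cindex", "bootstrap_ci", "BootstrapCI"]


def auc_binary(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Computed by the rank-sum formula; exact tie handling (each score-tied
    positive/negative pair contributes 1/2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = labels.astype(bool)
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both label classes must be present")
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def mean_auc(scores, outcome) -> tuple[float, dict[int, float]]:
    """Mean dichotomized AUC for an ordinal outcome.

    For each threshold ``j`` in ``1..J-1`` with both sides non-empty, the AUC
    of ``scores`` for predicting ``Y > j`` is computed; the mAUC is the
    arithmetic mean over the computable dichotomies. Returns
    ``(mauc, {j: auc_j})``; dichotomies with an empty side are reported as NaN
    and excluded from the mean.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=np.int64)
    J = int(y.max())
    if np.unique(y).size < 2:
        raise ValueError("outcome must have at least two distinct categories")
    per: dict[int, float] = {}
    vals = []
    for j in range(1, J):
        labels = y > j
        if labels.all() or not labels.any():
            per[j] = float("nan")
            continue
        per[j] = auc_binary(scores, labels)
        vals.append(per[j])
    if not vals:
        raise ValueError("no computable dichotomy")
    return float(np.mean(vals)), per


def gen_cindex(scores, outcome) -> float:
    """Harrell's generalized c-index for ordinal outcomes.

    Over all pairs of cases with *different* outcome categories: a pair is
    concordant (counts 1) when the higher-category case has the higher score,
    counts 1/2 when the scores are tied, and 0 otherwise. Computed from
    per-category-pair rank sums in O(J^2 n log n).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=np.int64)
    cats = np.unique(y)
    if cats.size < 2:
        raise ValueError("outcome must have at least two distinct categories")
    groups = {c: scores[y == c] for c in cats}
    num = 0.0
    den = 0
    for a in range(len(cats)):
        for b in range(a + 1, len(cats)):
            lo, hi = groups[cats[a]], groups[cats[b]]
            ranks = rankdata(np.concatenate([lo, hi]))
            # U = #(hi > lo) + 0.5 #(ties), via the hi group's rank sum
            u = ranks[len(lo):].sum() - len(hi) * (len(hi) + 1) / 2
            num += u
            den += len(lo) * len(hi)
    return float(num / den)


@dataclass(frozen=True)
class BootstrapCI:
    """Point estimate with a bias-corrected (and accelerated) bootstrap interval."""

    point: float
    lower: float
    upper: float
    n_boot: int
    level: float
    n_redrawn: int = 0

    def __iter__(self):
        return iter((self.point, self.lower, self.upper))


def bootstrap_ci(
    metric,
    scores,
    outcome,
    n_boot: int = 100,
    level: float = 0.95,
    seed: int = 0,
    accelerated: bool = True,
) -> BootstrapCI:
    """BCa bootstrap interval for ``metric(scores, outcome)``.

    Cases are resampled with replacement ``n_boot`` times; resamples missing an
    outcome category are redrawn (the count is reported). The bias-correction
    ``z0`` comes from the fraction of replicates below the point estimate and
    the acceleration ``a`` from jackknife skewness; with ``accelerated=False``
    (or a degenerate jackknife) the interval is bias-corrected only, and
    ``z0 = a = 0`` recovers the plain percentile interval.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=np.int64)
    n = scores.size
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    point = float(metric(scores, y))
    cats = np.unique(y)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    redrawn = 0
    failures = 0
    for b in range(n_boot):
        for _ in range(1000):
            idx = rng.integers(0, n, n)
            if np.isin(cats, y[idx]).all():
                break
            redrawn += 1
        try:
            boot[b] = metric(scores[idx], y[idx])
        except ValueError:
            boot[b] = np.nan
            failures += 1
    if failures > n_boot / 2:
        raise ValueError("metric failed on more than half of the bootstrap resamples")
    boot = boot[~np.isnan(boot)]
    if np.allclose(boot, boot[0]) and np.isclose(boot[0], point):
        warnings.warn("degenerate bootstrap distribution; interval collapses to the point")
        return BootstrapCI(point, point, point, n_boot, level, redrawn)

    # bias correction from the bootstrap distribution
    prop = np.mean(boot < point) + 0.5 * np.mean(boot == point)
    z0 = ndtri(np.clip(prop, 1.0 / (len(boot) + 1), 1 - 1.0 / (len(boot) + 1)))

    a = 0.0
    if accelerated:
        jack = _jackknife(metric, scores, y)
        if jack is not None:
            d = jack.mean() - jack
            denom = (d**2).sum() ** 1.5
            if denom > 0:
                a = float((d**3).sum() / (6.0 * denom))

    alpha = (1 - level) / 2
    z_lo, z_hi = ndtri(alpha), ndtri(1 - alpha)
    lo_q = ndtr(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo)))
    hi_q = ndtr(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi)))
    lower, upper = np.quantile(boot, [lo_q, hi_q])
    return BootstrapCI(point, float(lower), float(upper), n_boot, level, redrawn)


def _jackknife(metric, scores: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Leave-one-out metric values; None when some deletion loses a category."""
    n = scores.size
    counts = {c: int((y == c).sum()) for c in np.unique(y)}
    if min(counts.values()) < 2:
        return None
    out = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        out[i] = metric(scores[mask], y[mask])
        mask[i] = True
    return out
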