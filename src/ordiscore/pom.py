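"""Proportional odds (cumulative logit) model for ordinal outcomes.

The model assumes, for outcome :math:`Y` with categories :math:`1..J` and
predictor vector :math:`x`,

.. math:: \\mathrm{logit}\\, P(Y \\le j) = \\theta_j - x^T\\beta,
          \\qquad \\theta_1 < \\dots < \\theta_{J-1},

the McCullagh sign convention: a positive coefficient means higher values of
that predictor shift probability mass toward higher outcome categories, so the
linear predictor :math:`x^T\\beta` itself orders cases by risk. All predictors
are categorical here (continuous variables are interval-categorized upstream)
and enter as one-hot dummies against an explicit reference level.

Maximum likelihood estimation is delegated to statsmodels'
:class:`~statsmodels.miscmodels.ordinal_model.OrderedModel`, which enforces
monotone thresholds by a log-increment reparameterization; this module adds the
categorical design-matrix bookkeeping, closed-form intercept-only fits,
releveling, and prediction on labeled records.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .data import OrdinalData, level_strings

__all__ = ["ProportionalOddsModel", "POMResults", "fit_pom", "pom_loglik", "relevel_positive"]


# --------------------------------------------------------------------------- #
# level bookkeeping


def predictor_levels(data: OrdinalData) -> dict[str, list[str]]:
    """Observed levels per predictor, in categorical order where defined."""
    levels = {}
    for var in data.predictors:
        s = data.df[var]
        if isinstance(s.dtype, pd.CategoricalDtype):
            codes = np.unique(s.cat.codes.to_numpy())
            levels[var] = [str(s.cat.categories[i]) for i in codes if i >= 0]
        else:
            levels[var] = sorted(set(level_strings(s)))
    return levels


def _design(data: OrdinalData, levels: dict[str, list[str]], references: dict[str, str]):
    """One-hot design matrix with the reference level of each predictor dropped."""
    cols, names = [], []
    for var in data.predictors:
        vals = level_strings(data.df[var])
        known = set(levels[var])
        unseen = set(vals) - known
        if unseen:
            raise ValueError(f"variable {var!r} has levels unseen at fit time: {sorted(unseen)}")
        for lvl in levels[var]:
            if lvl == references[var]:
                continue
            cols.append((vals == lvl).astype(float))
            names.append((var, lvl))
    if cols:
        return np.column_stack(cols), names
    return np.empty((data.n, 0)), names


def _intercept_only_theta(y: np.ndarray, J: int) -> np.ndarray:
    """Closed-form MLE of the intercepts with no predictors: logit of cumulative proportions."""
    counts = np.bincount(y, minlength=J + 1)[1:]
    cum = np.cumsum(counts[:-1]) / counts.sum()
    return logit(cum)


# --------------------------------------------------------------------------- #
# the model / results pair


class ProportionalOddsModel:
    """Cumulative logit model on a fully categorical cohort.

    Parameters
    ----------
    data : OrdinalData
        Training cohort; every predictor must be categorical with no missing
        values, every level present in at least one row.
    references : dict, optional
        Reference level per predictor; defaults to each predictor's first level.
    """

    def __init__(self, data: OrdinalData, references: dict[str, str] | None = None):
        for var in data.predictors:
            if not data.is_categorical(var):
                raise ValueError(f"predictor {var!r} is continuous; categorize before fitting")
            if data.df[var].isna().any():
                raise ValueError(f"predictor {var!r} has missing values")
        self.data = data
        self.levels = predictor_levels(data)
        refs = {var: lv[0] for var, lv in self.levels.items()}
        if references:
            for var, r in references.items():
                if r not in self.levels.get(var, ()):
                    raise ValueError(f"reference {r!r} is not a level of {var!r}")
                refs[var] = r
        self.references = refs
        self.J = data.n_categories

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str, **kw) -> "ProportionalOddsModel":
        refs = kw.pop("references", None)
        return cls(OrdinalData(df, outcome, **kw), references=refs)

    def fit(self, maxiter: int = 500, gtol: float = 1e-8) -> "POMResults":
        """Maximum-likelihood fit (BFGS on the unconstrained reparameterization).

        Starting values: intercepts from the intercept-only closed form,
        coefficients zero. Non-convergence (including separation) is reported
        through ``converged`` rather than raised.
        """
        y = self.data.y
        J = self.J
        if np.unique(y).size < 2:
            raise ValueError("outcome must have at least two observed categories")
        X, names = _design(self.data, self.levels, self.references)
        if X.shape[1] == 0:
            theta = _intercept_only_theta(y, J)
            ll = float(pom_loglik(theta, {}, self.data))
            return POMResults(self, theta, {}, ll, True, self.data.n)
        theta0 = _intercept_only_theta(y, J)
        start = np.concatenate(
            [np.zeros(X.shape[1]), [theta0[0]], np.log(np.maximum(np.diff(theta0), 1e-8))]
        )
        sm = OrderedModel(y, X, distr="logit")
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.fit(
                    method="bfgs", start_params=start, maxiter=maxiter, gtol=gtol, disp=False
                )
            converged = bool(res.mle_retvals.get("converged", False)) and np.isfinite(res.llf)
            params = res.params
            llf = float(res.llf)
        except Exception:  # separation / non-finite likelihood
            converged, params, llf = False, start, -np.inf
        k = X.shape[1]
        beta = params[:k]
        with np.errstate(over="ignore"):
            theta = np.concatenate([[params[k]], params[k] + np.cumsum(np.exp(params[k + 1:]))])
        coef: dict[str, dict[str, float]] = {
            var: {self.references[var]: 0.0} for var in self.data.predictors
        }
        for (var, lvl), b in zip(names, beta):
            coef[var][lvl] = float(b)
        # keep level order
        coef = {
            var: {lvl: coef[var][lvl] for lvl in self.levels[var]} for var in self.data.predictors
        }
        return POMResults(self, theta, coef, llf, converged, self.data.n)


@dataclass
class POMResults:
    """Fitted proportional odds model.

    Attributes
    ----------
    theta : ndarray, shape (J-1,)
        Strictly increasing category intercepts.
    coef : dict
        ``coef[var][level]`` — coefficient per predictor level; exactly 0 at
        each predictor's reference level.
    loglik : float
        Maximized log-likelihood.
    converged : bool
        Whether the optimizer met its gradient tolerance.
    """

    model: ProportionalOddsModel
    theta: np.ndarray
    coef: dict[str, dict[str, float]]
    loglik: float
    converged: bool
    n_obs: int
    references: dict[str, str] = field(init=False)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.size > 1 and np.any(np.diff(self.theta) <= 0):
            raise ValueError("intercepts must be strictly increasing")
        self.references = dict(self.model.references)

    # -- prediction ----------------------------------------------------------
    def linear_predictor(self, records: pd.DataFrame, coerce: bool = False) -> np.ndarray:
        """:math:`x^T\\beta` per row; excludes the intercepts."""
        eta = np.zeros(len(records))
        for var, cmap in self.coef.items():
            vals = level_strings(records[var])
            out = np.empty(len(vals))
            for i, v in enumerate(vals):
                if v in cmap:
                    out[i] = cmap[v]
                elif coerce:
                    out[i] = cmap[self.references[var]]
                else:
                    raise KeyError(f"unseen level {v!r} for variable {var!r}")
            eta += out
        return eta

    def predict_cumprob(self, records, coerce: bool = False) -> np.ndarray:
        """Cumulative probabilities ``P(Y <= j)``, shape (n, J-1), increasing in j."""
        records = _as_frame(records)
        eta = self.linear_predictor(records, coerce=coerce)
        return expit(self.theta[None, :] - eta[:, None])

    def predict_catprob(self, records, coerce: bool = False) -> np.ndarray:
        """Category probabilities ``P(Y = j)``, shape (n, J); rows sum to 1."""
        cum = self.predict_cumprob(records, coerce=coerce)
        full = np.column_stack([np.zeros(len(cum)), cum, np.ones(len(cum))])
        return np.diff(full, axis=1)

    # -- releveling ----------------------------------------------------------
    def relevel_positive(self, method: str = "shift") -> "POMResults":
        """Redefine each predictor's reference so every coefficient is >= 0.

        ``method="shift"`` applies the exact reparameterization (subtract each
        predictor's minimum coefficient and absorb the total into the
        intercepts); ``method="refit"`` refits the model with the new
        references. Both leave the likelihood and predictions unchanged.
        """
        if not self.converged:
            raise ValueError("cannot relevel a non-converged fit")
        new_refs = {
            var: min(cmap, key=lambda l: (cmap[l], self.model.levels[var].index(l)))
            for var, cmap in self.coef.items()
        }
        if method == "refit":
            refit_model = ProportionalOddsModel(self.model.data, references=new_refs)
            return refit_model.fit()
        if method != "shift":
            raise ValueError(f"unknown relevel method {method!r}")
        shift_total = 0.0
        new_coef = {}
        for var, cmap in self.coef.items():
            m = cmap[new_refs[var]]
            shift_total += m
            new_coef[var] = {lvl: c - m for lvl, c in cmap.items()}
        new_model = ProportionalOddsModel(self.model.data, references=new_refs)
        return POMResults(
            new_model, self.theta - shift_total, new_coef, self.loglik, True, self.n_obs
        )

    # -- serialization -------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "theta": self.theta.tolist(),
                "coef": self.coef,
                "references": self.references,
                "loglik": self.loglik,
                "converged": self.converged,
                "n_obs": self.n_obs,
            },
            indent=2,
        )

    def summary(self) -> str:
        lines = [
            "Proportional odds model (cumulative logit)",
            f"  n = {self.n_obs}, J = {len(self.theta) + 1}, "
            f"loglik = {self.loglik:.4f}, converged = {self.converged}",
            "  intercepts: " + ", ".join(f"{t:.4f}" for t in self.theta),
        ]
        for var, cmap in self.coef.items():
            lines.append(f"  {var} (ref: {self.references[var]})")
            for lvl, c in cmap.items():
                lines.append(f"    {lvl:<20} {c: .4f}")
        return "\n".join(lines)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    if isinstance(records, pd.Series):
        return records.to_frame().T
    if isinstance(records, dict):
        return pd.DataFrame([records])
    raise TypeError("records must be a DataFrame, Series or dict")


# --------------------------------------------------------------------------- #
# functional surface


def fit_pom(train: OrdinalData, references: dict[str, str] | None = None, **fit_kw) -> POMResults:
    """Fit the proportional odds model to a fully categorical training set."""
    return ProportionalOddsModel(train, references=references).fit(**fit_kw)


def relevel_positive(fit: POMResults, method: str = "shift") -> POMResults:
    """Module-level alias of :meth:`POMResults.relevel_positive`."""
    return fit.relevel_positive(method=method)


def pom_loglik(theta, coef: dict[str, dict[str, float]], data: OrdinalData) -> float:
    """Cumulative-logit log-likelihood at the given parameters.

    ``sum_i log[ F(theta_{y_i} - eta_i) - F(theta_{y_i - 1} - eta_i) ]`` with F
    the logistic CDF, ``theta_0 = -inf``, ``theta_J = +inf`` and
    ``eta_i = x_i^T beta`` assembled from the per-level coefficients. Kept
    independent of the fitting backend so it can audit any fit.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size > 1 and np.any(np.diff(theta) <= 0):
        raise ValueError("theta must be strictly increasing")
    J = theta.size + 1
    y = data.y
    if y.min() < 1 or y.max() > J:
        raise ValueError(f"outcome categories must lie in 1..{J}")
    eta = np.zeros(data.n)
    for var, cmap in coef.items():
        vals = level_strings(data.df[var])
        eta += np.array([cmap[v] for v in vals])
    bounds = np.concatenate([[-np.inf], theta, [np.inf]])
    upper = expit(bounds[y] - eta)
    lower = expit(bounds[y - 1] - eta)
    return float(np.sum(np.log(upper - lower)))
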