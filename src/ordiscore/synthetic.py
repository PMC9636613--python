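"""Synthetic EHR-like cohorts with a known proportional-odds generating process.

Every stage of the pipeline can be tested without external data: covariates are
drawn from simple clinical-flavored marginals (skewed labs, zero-inflated
utilization counts, binary comorbidities, multi-level factors), the ordinal
outcome is drawn from the cumulative logit model

.. math:: P(Y \\le j \\mid x) = F(\\theta_j - x^T\\beta)

with known intercepts and coefficients (larger :math:`x^T\\beta` means higher
categories), and missingness is injected completely at random afterward. The
generator writes a sidecar ground-truth record so tests can check parameter and
ranking recovery.

The ``ehr_preset`` mimics the shape of an emergency-department cohort: about
twenty mixed predictors, an imbalanced 3-category outcome (roughly
0.80/0.12/0.08), a few percent missingness on lab columns, and exactly three
predictors carrying signal. Its numeric parameters are illustrative, not a
reproduction of any real cohort, and live in ``presets.yaml``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .data import OrdinalData

__all__ = ["PredictorSpec", "GeneratorSpec", "gen_cohort", "ehr_preset", "load_preset_spec"]

KINDS = ("normal", "lognormal", "zip_count", "bernoulli", "categorical")


@dataclass(frozen=True)
class PredictorSpec:
    """One covariate: marginal distribution plus its true outcome coefficient.

    ``kind`` is one of ``normal`` (params mu, sd, optional lo/hi clipping),
    ``lognormal`` (mu, sigma of the log), ``zip_count`` (zero-inflated Poisson:
    pi extra zeros, lam), ``bernoulli`` (p), ``categorical`` (levels, probs).
    ``coef`` is a float applied to the raw value for numeric kinds, or a
    per-level dict for ``categorical``.
    """

    name: str
    kind: str
    params: dict
    coef: float | dict = 0.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown predictor kind {self.kind!r}")

    @property
    def is_noise(self) -> bool:
        if isinstance(self.coef, dict):
            return all(c == 0 for c in self.coef.values())
        return self.coef == 0


@dataclass(frozen=True)
class GeneratorSpec:
    """Full specification of a synthetic cohort."""

    n: int
    theta: tuple[float, ...]
    predictors: tuple[PredictorSpec, ...]
    missing_rate: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    outcome: str = "outcome"

    def __post_init__(self):
        th = np.asarray(self.theta, dtype=float)
        if th.size < 1 or (th.size > 1 and np.any(np.diff(th) <= 0)):
            raise ValueError("theta must be non-empty and strictly increasing")
        if not self.predictors:
            raise ValueError("at least one predictor is required")
        for col, r in self.missing_rate.items():
            if not 0 <= r < 1:
                raise ValueError(f"missing rate for {col!r} must be in [0, 1)")
            if col == self.outcome:
                raise ValueError("missingness must never touch the outcome")
        object.__setattr__(self, "theta", tuple(float(t) for t in th))
        object.__setattr__(self, "predictors", tuple(self.predictors))

    @property
    def J(self) -> int:
        return len(self.theta) + 1

    def truth(self) -> dict:
        """Ground-truth record (intercepts, coefficients, noise flags) for tests."""
        return {
            "theta": list(self.theta),
            "coef": {p.name: p.coef for p in self.predictors},
            "noise": [p.name for p in self.predictors if p.is_noise],
            "signal": [p.name for p in self.predictors if not p.is_noise],
            "J": self.J,
        }

    def truth_json(self) -> str:
        return json.dumps(self.truth(), indent=2)


def _draw(p: PredictorSpec, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Returns (column values, per-row contribution to the linear predictor)."""
    prm = p.params
    if p.kind == "normal":
        x = rng.normal(prm["mu"], prm["sd"], n)
        if "lo" in prm or "hi" in prm:
            x = np.clip(x, prm.get("lo", -np.inf), prm.get("hi", np.inf))
        return x, p.coef * x
    if p.kind == "lognormal":
        x = rng.lognormal(prm["mu"], prm["sigma"], n)
        return x, p.coef * x
    if p.kind == "zip_count":
        zero = rng.uniform(size=n) < prm["pi"]
        x = np.where(zero, 0, rng.poisson(prm["lam"], n)).astype(float)
        return x, p.coef * x
    if p.kind == "bernoulli":
        x = rng.binomial(1, prm["p"], n)
        return x, p.coef * x
    # categorical
    levels = list(prm["levels"])
    probs = np.asarray(prm["probs"], dtype=float)
    if probs.size != len(levels) or not np.isclose(probs.sum(), 1.0):
        raise ValueError(f"categorical probs for {p.name!r} must match levels and sum to 1")
    idx = rng.choice(len(levels), size=n, p=probs)
    x = np.array(levels, dtype=object)[idx]
    coefs = np.array([float(p.coef.get(l, 0.0)) for l in levels])
    return x, coefs[idx]


def gen_cohort(spec: GeneratorSpec) -> OrdinalData:
    """Draw a cohort from the generating proportional odds model.

    Deterministic given ``spec.seed``; covariates first, then the outcome from
    the cumulative logit probabilities, then MCAR missingness on the requested
    predictor columns (never the outcome).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(spec.n)
    cols: dict[str, np.ndarray] = {}
    eta = np.zeros(n)
    categorical = []
    for p in spec.predictors:
        x, contrib = _draw(p, n, rng)
        cols[p.name] = x
        eta += contrib
        if p.kind in ("categorical", "bernoulli"):
            categorical.append(p.name)
    theta = np.asarray(spec.theta)
    cum = expit(theta[None, :] - eta[:, None])  # (n, J-1)
    u = rng.uniform(size=n)
    y = 1 + (u[:, None] > cum).sum(axis=1)
    for col, rate in spec.missing_rate.items():
        mask = rng.uniform(size=n) < rate
        vals = cols[col].astype(object) if cols[col].dtype == object else cols[col].astype(float)
        vals[mask] = np.nan
        cols[col] = vals
    df = pd.DataFrame(cols)
    df[spec.outcome] = y
    return OrdinalData(
        df,
        spec.outcome,
        predictors=tuple(p.name for p in spec.predictors),
        categorical=tuple(categorical),
        n_categories=spec.J,
    )


# --------------------------------------------------------------------------- #
# the EHR-style preset


def _load_presets() -> dict:
    with resources.files("ordiscore").joinpath("presets.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_preset_spec(n: int, seed: int = 0, name: str = "ehr") -> GeneratorSpec:
    """GeneratorSpec for a named preset from ``presets.yaml``."""
    cfg = _load_presets()[name]
    preds = tuple(
        PredictorSpec(d["name"], d["kind"], d["params"], d.get("coef", 0.0))
        for d in cfg["predictors"]
    )
    return GeneratorSpec(
        n=n,
        theta=tuple(cfg["theta"]),
        predictors=preds,
        missing_rate=cfg.get("missing_rate", {}),
        seed=seed,
    )


def ehr_preset(n: int, seed: int = 0) -> OrdinalData:
    """An EHR-flavored cohort: ~20 mixed predictors, imbalanced 3-level outcome.

    Three predictors carry signal (prior-year inpatient visits, creatinine,
    age); everything else — vitals, labs, utilization counts, comorbidities, a
    triage factor — is pure noise with true coefficient exactly 0. About 5% of
    lab values are missing completely at random.
    """
    if n < 100:
        raise ValueError("preset cohorts need n >= 100")
    return gen_cohort(load_preset_spec(n, seed))
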