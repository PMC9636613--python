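import numpy as np
import pandas as pd
import pytest

from ordiscore import GeneratorSpec, OrdinalData, PredictorSpec, gen_cohort


@pytest.fixture
def skewed_cohort() -> OrdinalData:
    """A 1000-row cohort with one skewed, one uniform and one binary predictor."""
    rng = np.random.default_rng(42)
    n = 1000
    df = pd.DataFrame(
        {
            "uniform": rng.uniform(0, 100, n),
            "zeroinf": np.where(rng.uniform(size=n) < 0.9, 0.0, rng.poisson(5, n)),
            "flag": rng.binomial(1, 0.3, n),
            "outcome": rng.choice([1, 2, 3], size=n, p=[0.6, 0.3, 0.1]),
        }
    )
    return OrdinalData(df, "outcome", categorical=("flag",))


@pytest.fixture(scope="session")
def three_binary_spec() -> GeneratorSpec:
    """Generating model with beta proportional to (1, 2, 3) on binary predictors."""
    s = 0.4
    return GeneratorSpec(
        n=20000,
        theta=(0.2, 1.5),
        predictors=tuple(
            PredictorSpec(f"x{i}", "bernoulli", {"p": 0.5}, coef=s * i) for i in (1, 2, 3)
        ),
        seed=5,
    )


@pytest.fixture
def binary_cohort(three_binary_spec) -> OrdinalData:
    return gen_cohort(three_binary_spec)


def brute_force_auc(scores, labels) -> float:
    """O(n^2) pair enumeration oracle for the binary AUC."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def brute_force_cindex(scores, outcome) -> float:
    """O(n^2) pair enumeration oracle for the generalized c-index.

    Enumerates every ordered pair with a strictly higher outcome via broadcast
    comparison matrices — a different route from the rank-sum implementation.
    """
    scores = np.asarray(scores, float)
    y = np.asarray(outcome)
    higher = y[:, None] > y[None, :]  # pair (i, j) with y_i > y_j
    den = higher.sum()
    sdiff = scores[:, None] - scores[None, :]
    num = (higher & (sdiff > 0)).sum() + 0.5 * (higher & (sdiff == 0)).sum()
    return float(num / den)
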