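from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from ordiscore import (
    CutoffScheme,
    LookupTable,
    OrdinalData,
    ScoringTable,
    build_lookup,
    build_scoring_table,
    compute_cutoffs,
    derive_partial_scores,
    fine_tune,
    gen_cohort,
    impute_median,
    rescale_scores,
)
from ordiscore.scoring import _round_half_away


def _fake_fit(coef, references):
    """Stand-in carrying just the attributes derive_partial_scores reads."""
    return SimpleNamespace(coef=coef, references=references)


class TestRounding:
    def test_half_away_from_zero(self):
        assert _round_half_away(0.5) == 1
        assert _round_half_away(1.5) == 2
        assert _round_half_away(2.5) == 3  # not bankers' rounding
        assert _round_half_away(-0.5) == -1

    def test_array(self):
        np.testing.assert_array_equal(
            _round_half_away(np.array([0.4, 0.5, 1.49, 1.5])), [0, 1, 1, 2]
        )


class TestDerive:
    def test_worked_example(self):
        # coefficients (0.2, 0.5, 1.0): unit 0.2 -> points (1, 3 [2.5 rounds up], 5)
        fit = _fake_fit(
            {
                "a": {"ref": 0.0, "lo": 0.2},
                "b": {"ref": 0.0, "mid": 0.5, "hi": 1.0},
            },
            {"a": "ref", "b": "ref"},
        )
        table = derive_partial_scores(fit)
        assert table.scores["a"]["lo"] == 1
        assert table.scores["b"]["mid"] == 3
        assert table.scores["b"]["hi"] == 5
        assert table.scores["a"]["ref"] == table.scores["b"]["ref"] == 0
        assert table.max_total == 6

    def test_smallest_positive_coefficient_scores_one(self):
        fit = _fake_fit({"x": {"0": 0.0, "1": 0.37}}, {"x": "0"})
        assert derive_partial_scores(fit).scores["x"]["1"] == 1

    def test_negative_coefficient_rejected(self):
        fit = _fake_fit({"x": {"0": 0.0, "1": -0.3}}, {"x": "0"})
        with pytest.raises(ValueError, match="relevel"):
            derive_partial_scores(fit)

    def test_all_zero_rejected(self):
        fit = _fake_fit({"x": {"0": 0.0, "1": 0.0}}, {"x": "0"})
        with pytest.raises(ValueError, match="zero"):
            derive_partial_scores(fit)


class TestRescale:
    def test_worked_example(self):
        table = ScoringTable(
            {"x": {"a": 0, "b": 1, "c": 3}}, {"x": "a"}
        )
        out = rescale_scores(table, 100)
        # factor 100/3: (0, 1, 3) -> (0, 33, 100)
        assert out.scores["x"] == {"a": 0, "b": 33, "c": 100}
        assert out.max_total == 100
        assert out.rescale_target == 100

    def test_zeros_preserved_and_order_kept(self):
        table = ScoringTable(
            {"x": {"a": 0, "b": 2}, "y": {"p": 0, "q": 5, "r": 9}},
            {"x": "a", "y": "p"},
        )
        out = rescale_scores(table, 50)
        assert out.scores["x"]["a"] == 0 and out.scores["y"]["p"] == 0
        assert out.scores["y"]["q"] < out.scores["y"]["r"]

    def test_identity_when_already_at_target(self):
        table = ScoringTable({"x": {"a": 0, "b": 100}}, {"x": "a"})
        assert rescale_scores(table, 100).scores == table.scores

    def test_warns_when_predictor_zeroed(self):
        table = ScoringTable(
            {"x": {"a": 0, "b": 1}, "y": {"p": 0, "q": 400}}, {"x": "a", "y": "p"}
        )
        with pytest.warns(UserWarning, match="all-zero"):
            out = rescale_scores(table, 10)
        assert max(out.scores["x"].values()) == 0


class TestScoringTable:
    @pytest.fixture()
    def table(self):
        return ScoringTable(
            {"age": {"< 50": 0, "[50, 70)": 2, ">= 70": 5}, "flag": {"0": 0, "1": 3}},
            {"age": "< 50", "flag": "0"},
            CutoffScheme({"age": [50, 70]}),
        )

    def test_total_is_sum_of_partials(self, table):
        assert table.total_score({"age": "[50, 70)", "flag": "1"}) == 5
        assert table.total_score({"age": "< 50", "flag": "0"}) == 0
        assert table.max_total == 8

    def test_raw_numeric_column_categorized_via_scheme(self, table):
        recs = pd.DataFrame({"age": [45.0, 69.9, 70.0], "flag": [1, 0, 1]})
        np.testing.assert_array_equal(table.score(recs), [3, 2, 8])

    def test_unseen_level_raises_unless_coerced(self, table):
        recs = pd.DataFrame({"age": ["< 50"], "flag": ["2"]})
        with pytest.raises(KeyError, match="flag"):
            table.score(recs)
        assert table.score(recs, coerce=True)[0] == 0

    def test_json_round_trip(self, table):
        back = ScoringTable.from_json(table.to_json())
        assert back.scores == table.scores
        assert back.references == table.references
        assert back.cutoff_scheme.cutoffs == {"age": [50, 70]}

    def test_reference_must_score_zero(self):
        with pytest.raises(ValueError, match="reference"):
            ScoringTable({"x": {"a": 1, "b": 2}}, {"x": "a"})

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            ScoringTable({"x": {"a": 0, "b": -1}}, {"x": "a"})


class TestLookup:
    def test_explicit_breaks_proportions(self):
        table = ScoringTable({"x": {"0": 0, "1": 10}}, {"x": "0"})
        df = pd.DataFrame(
            {"x": ["0"] * 6 + ["1"] * 4, "outcome": [1, 1, 1, 1, 2, 3, 2, 3, 3, 3]}
        )
        train = OrdinalData(df, "outcome", categorical=("x",))
        lk = build_lookup(table, train, bins=[5])
        assert lk.breaks == (5,)
        assert lk.counts == (6, 4)
        np.testing.assert_allclose(lk.probs[0], [4 / 6, 1 / 6, 1 / 6])
        np.testing.assert_allclose(lk.probs[1], [0, 1 / 4, 3 / 4])

    def test_predict_proba_reads_row(self):
        lk = LookupTable((5,), (6, 4), np.array([[0.8, 0.2], [0.1, 0.9]]), 10)
        np.testing.assert_allclose(lk.predict_proba([0, 4, 5, 10]).T[0], [0.8, 0.8, 0.1, 0.1])

    def test_empty_bins_merged(self):
        table = ScoringTable({"x": {"0": 0, "1": 10}}, {"x": "0"})
        df = pd.DataFrame({"x": ["0", "1"] * 4, "outcome": [1, 2] * 4})
        train = OrdinalData(df, "outcome", categorical=("x",))
        lk = build_lookup(table, train, bins=[2, 4, 6, 8])
        # only scores 0 and 10 occur: interior cutpoints collapse to one
        assert len(lk.breaks) == 1
        assert all(c > 0 for c in lk.counts)

    def test_rows_sum_to_one_and_risk_monotone_when_signal_strong(self, three_binary_spec):
        data = gen_cohort(replace(three_binary_spec, n=8000, seed=31))
        scheme = compute_cutoffs(data)
        table, _, cat = build_scoring_table(impute_median(data, data), scheme)
        lk = build_lookup(table, cat)
        assert np.allclose(lk.probs.sum(axis=1), 1.0)
        # P(Y = 1) should fall as the score interval rises
        assert lk.probs[0, 0] > lk.probs[-1, 0]

    def test_json_round_trip(self):
        lk = LookupTable((3, 7), (5, 5, 5), np.full((3, 3), 1 / 3), 12)
        back = LookupTable.from_json(lk.to_json())
        assert back.breaks == lk.breaks and back.counts == lk.counts
        np.testing.assert_allclose(back.probs, lk.probs)


class TestBuildAndFineTune:
    def test_integer_ratio_recovery(self, three_binary_spec):
        # beta proportional to (1, 2, 3): with enough data the unrescaled
        # partial scores are exactly (1, 2, 3)
        data = gen_cohort(replace(three_binary_spec, n=100000, seed=13))
        scheme = compute_cutoffs(data)
        table, fit, _ = build_scoring_table(
            impute_median(data, data), scheme, rescale_target=None
        )
        assert fit.converged
        assert [table.scores[f"x{i}"]["1"] for i in (1, 2, 3)] == [1, 2, 3]

    def test_monotone_coef_gives_monotone_scores(self, three_binary_spec):
        data = gen_cohort(replace(three_binary_spec, n=20000, seed=17))
        table, fit, _ = build_scoring_table(
            impute_median(data, data), compute_cutoffs(data)
        )
        for var, cmap in fit.coef.items():
            levels = sorted(cmap, key=cmap.get)
            pts = [table.scores[var][l] for l in levels]
            assert pts == sorted(pts), var

    def test_fine_tune_overrides_one_variable(self, skewed_cohort):
        train = impute_median(skewed_cohort, skewed_cohort)
        scheme = compute_cutoffs(train)
        table, _, _ = fine_tune({"uniform": [25, 50, 75]}, train, scheme)
        assert set(table.scores["uniform"]) == {"< 25", "[25, 50)", "[50, 75)", ">= 75"}
        # untouched variable keeps its automatic intervals
        auto, _, _ = build_scoring_table(train, scheme)
        assert set(table.scores["zeroinf"]) == set(auto.scores["zeroinf"])

    def test_fine_tune_identity_overrides_match_build(self, skewed_cohort):
        train = impute_median(skewed_cohort, skewed_cohort)
        scheme = compute_cutoffs(train)
        a, _, _ = build_scoring_table(train, scheme)
        b, _, _ = fine_tune({"uniform": scheme.cutoffs["uniform"]}, train, scheme)
        assert a.scores == b.scores

    def test_fine_tune_rejects_bad_overrides(self, skewed_cohort):
        train = impute_median(skewed_cohort, skewed_cohort)
        scheme = compute_cutoffs(train)
        with pytest.raises(ValueError, match="increasing"):
            fine_tune({"uniform": [50, 25]}, train, scheme)
        with pytest.raises(ValueError, match="uniform.*empty|empty"):
            fine_tune({"uniform": [1e9, 2e9]}, train, scheme)
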