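"""Relative effects, classification, summaries, and the additive null model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enzevo.config import RunConfig
from enzevo.effects import (
    RelativeEffect,
    StatisticalPreconditionError,
    UndefinedRatioError,
    classify_effect,
    estimate_effect,
    expected_total_change,
    observed_total_change,
    relative_effect,
    significance_test,
    summarize_effects,
)

from conftest import make_records
from oracles import t_test_two_sided_equal_var


class TestRelativeEffect:
    def test_exact_ratio_across_batches(self):
        v = make_records("v", "wt", "s", {"b1": [2.0], "b2": [2.0]})
        p = make_records("wt", "", "s", {"b1": [1.0], "b2": [1.0]})
        eff = relative_effect(v, p)
        assert eff.fold_change == pytest.approx(2.0)
        assert eff.n_batches == 2
        assert eff.paired

    def test_identity(self):
        v = make_records("v", "wt", "s", {"b1": [1.3, 0.9], "b2": [1.1]})
        p = make_records("wt", "", "s", {"b1": [1.3, 0.9], "b2": [1.1]})
        eff = relative_effect(v, p)
        assert eff.fold_change == pytest.approx(1.0)
        assert eff.log10_effect == pytest.approx(0.0, abs=1e-15)

    def test_geometric_mean_of_batch_ratios(self):
        v = make_records("v", "wt", "s", {"b1": [4.0], "b2": [1.0]})
        p = make_records("wt", "", "s", {"b1": [1.0], "b2": [1.0]})
        eff = relative_effect(v, p)
        assert eff.fold_change == pytest.approx(2.0)  # sqrt(4 * 1)
        cfg = RunConfig(batch_agg="arithmetic")
        assert relative_effect(v, p, cfg).fold_change == pytest.approx(2.5)

    def test_od_normalization_enters_ratio(self):
        v = make_records("v", "wt", "s", {"b1": [2.0]}, od600=0.5)  # 4.0 normalized
        p = make_records("wt", "", "s", {"b1": [1.0]}, od600=1.0)
        assert relative_effect(v, p).fold_change == pytest.approx(4.0)

    def test_censored_variant_gives_upper_bound(self):
        v = make_records("v", "wt", "s", {"b1": [0.005]}, detection_limit=0.01,
                         censor="below")
        p = make_records("wt", "", "s", {"b1": [1.0]})
        eff = relative_effect(v, p)
        assert eff.censor_bound == "at_most"
        assert eff.bound == pytest.approx(0.01)
        assert eff.fold_change is None

    def test_censored_parent_is_undefined_ratio(self):
        v = make_records("v", "wt", "s", {"b1": [1.0]})
        p = make_records("wt", "", "s", {"b1": [0.005]}, detection_limit=0.01,
                         censor="below")
        with pytest.raises(UndefinedRatioError):
            relative_effect(v, p)
        eff = estimate_effect(v, p)
        assert eff.effect_class == "untested"

    def test_unpaired_fallback_is_flagged(self):
        v = make_records("v", "wt", "s", {"x1": [2.0, 2.0]})
        p = make_records("wt", "", "s", {"y1": [1.0, 1.0]})
        eff = relative_effect(v, p)
        assert not eff.paired
        assert eff.fold_change == pytest.approx(2.0)

    def test_se_from_batch_dispersion(self):
        v = make_records("v", "wt", "s", {"b1": [10.0], "b2": [1.0], "b3": [10.0]})
        p = make_records("wt", "", "s", {"b1": [1.0], "b2": [1.0], "b3": [1.0]})
        eff = relative_effect(v, p)
        logs = np.log10([10.0, 1.0, 10.0])
        assert eff.se_log10 == pytest.approx(np.std(logs, ddof=1) / math.sqrt(3))


class TestSignificance:
    def test_identical_samples_give_p_one(self):
        v = make_records("v", "wt", "s", {"b1": [1.0, 1.0, 1.0]})
        p = make_records("wt", "", "s", {"b1": [1.0, 1.0, 1.0]})
        assert significance_test(v, p) == 1.0

    def test_matches_hand_computed_t_on_logs(self):
        xv = [10.0, 10.5, 9.6]
        xp = [1.0, 1.02, 0.98]
        v = make_records("v", "wt", "s", {"b1": xv})
        p = make_records("wt", "", "s", {"b1": xp})
        p_impl = significance_test(v, p)
        p_oracle = t_test_two_sided_equal_var(np.log10(xv), np.log10(xp))
        assert p_impl == pytest.approx(p_oracle, rel=1e-12)
        assert p_impl < 0.001

    def test_single_replicate_gives_absent_p(self):
        v = make_records("v", "wt", "s", {"b1": [2.0]})
        p = make_records("wt", "", "s", {"b1": [1.0]})
        assert significance_test(v, p) is None
        assert estimate_effect(v, p).effect_class == "untested"

    def test_welch_and_raw_scale_options(self):
        xv = [10.0, 12.0, 9.0, 11.0]
        xp = [1.0, 1.4, 0.8, 1.1]
        v = make_records("v", "wt", "s", {"b1": xv})
        p = make_records("wt", "", "s", {"b1": xp})
        from scipy import stats

        welch = significance_test(v, p, RunConfig(t_test="welch"))
        assert welch == pytest.approx(
            float(stats.ttest_ind(np.log10(xv), np.log10(xp), equal_var=False).pvalue)
        )
        raw = significance_test(v, p, RunConfig(log_scale=False))
        assert raw == pytest.approx(float(stats.ttest_ind(xv, xp).pvalue))


class TestClassification:
    @pytest.mark.parametrize(
        "fold, p, expected",
        [
            (0.5, 0.001, "deleterious"),
            (2.0, 0.20, "neutral"),  # beyond band but not significant
            (1.0, 0.9, "neutral"),
            (2.0, 0.01, "favorable"),
            (1.25, 0.001, "neutral"),  # significant but within band
            (0.5, None, "untested"),
            (1.1, None, "neutral"),
            (None, 0.01, "untested"),
        ],
    )
    def test_examples(self, fold, p, expected):
        assert classify_effect(fold, p) == expected

    @given(
        fold=st.floats(min_value=0.01, max_value=100.0),
        p=st.sampled_from([0.001, 0.04, 0.05, 0.2, None]),
    )
    @settings(max_examples=200, deadline=None)
    def test_log_scale_symmetry(self, fold, p):
        mirror = {"deleterious": "favorable", "favorable": "deleterious"}
        c = classify_effect(fold, p)
        c_inv = classify_effect(1.0 / fold, p)
        assert c_inv == mirror.get(c, c)


class TestSummary:
    def _effects(self, folds, background="wt", substrate="s", censored=()):
        effs = [
            RelativeEffect(f"m{i}", background, substrate, f, math.log10(f),
                           effect_class=classify_effect(f, 0.01))
            for i, f in enumerate(folds)
        ]
        for j, bound in enumerate(censored):
            effs.append(
                RelativeEffect(f"c{j}", background, substrate, None, None,
                               censor_bound="at_most", bound=bound,
                               effect_class="untested")
            )
        return effs

    def test_trivial_geomean(self):
        s = summarize_effects(self._effects([1.0, 1.0, 1.0]))
        assert s.geometric_mean == pytest.approx(1.0)
        assert s.median == pytest.approx(1.0)

    def test_log_symmetry(self):
        s = summarize_effects(self._effects([0.1, 10.0]))
        assert s.geometric_mean == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        s = summarize_effects(self._effects([0.25, 1.0]))
        assert s.geometric_mean == pytest.approx(0.5)
        assert s.median == pytest.approx(0.625)

    def test_ci_contains_geomean_and_identity(self):
        folds = [0.3, 0.5, 0.8, 1.2, 0.6]
        s = summarize_effects(self._effects(folds))
        lo, hi = s.ci95
        assert lo <= s.geometric_mean <= hi
        assert s.expected_total.value == pytest.approx(
            s.geometric_mean**s.n_in_product, rel=1e-9
        )

    def test_censored_excluded_from_mean_but_counted(self):
        s = summarize_effects(self._effects([0.5, 2.0], censored=[1e-4]))
        assert s.n_effects == 3
        assert s.n_in_product == 2
        assert s.counts["untested"] == 1
        assert s.geometric_mean == pytest.approx(1.0)

    def test_all_censored_flagged(self):
        s = summarize_effects(self._effects([], censored=[1e-3, 1e-4]))
        assert s.geometric_mean is None
        assert "censored" in s.note

    def test_empty_rejected(self):
        with pytest.raises(StatisticalPreconditionError):
            summarize_effects([])


class TestNullModel:
    def test_empty_product_is_one(self):
        assert expected_total_change([]).value == 1.0

    def test_simple_product(self):
        assert expected_total_change([0.5, 0.5]).value == pytest.approx(0.25)

    def test_twenty_six_equal_effects(self):
        # 26 mutations of 0.46-fold each combine to ~1.7e-9 under additivity
        res = expected_total_change([0.46] * 26)
        assert res.value == pytest.approx(10.0 ** (26 * math.log10(0.46)), rel=1e-12)
        assert res.value == pytest.approx(1.705e-9, rel=1e-3)

    def test_censored_bound_propagates(self):
        effs = [
            RelativeEffect("a", "wt", "s", 0.5, math.log10(0.5)),
            RelativeEffect("b", "wt", "s", None, None, censor_bound="at_most",
                           bound=0.01),
        ]
        res = expected_total_change(effs)
        assert res.kind == "at_most"
        assert res.value == pytest.approx(0.005)

    @given(
        st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=1, max_size=40)
    )
    @settings(max_examples=300, deadline=None)
    def test_identity_with_geometric_mean(self, folds):
        total = expected_total_change(folds).value
        geomean = 10.0 ** float(np.mean(np.log10(folds)))
        assert total == pytest.approx(geomean ** len(folds), rel=1e-9)


class TestObservedTotal:
    def test_examples(self):
        assert observed_total_change(1.0, 1.0) == 1.0
        assert observed_total_change(2.0, 1.0) == 0.5

    def test_chain_consistency(self):
        folds = [10.0, 10.0, 0.5]
        acts = np.cumprod([1.0] + folds)
        assert observed_total_change(acts[0], acts[-1]) == pytest.approx(
            float(np.prod(folds))
        )

    def test_zero_start_rejected(self):
        from enzevo.effects import EffectError

        with pytest.raises(EffectError):
            observed_total_change(0.0, 1.0)


class TestPublishedSummaryConsistency:
    """Self-consistency of printed geometric means vs expected totals.

    With n = 26 mutations, the null-model total must equal geomean^26; for a
    geomean printed to two decimals, the printed total should lie inside the
    interval spanned by (g ± 0.005)^26.
    """

    @pytest.mark.parametrize(
        "geomean, expected_total",
        [(0.46, 1.8e-9), (0.98, 5.8e-1), (1.47, 2.4e4), (0.43, 3.7e-10)],
    )
    def test_rounding_interval_brackets_total(self, geomean, expected_total):
        low = expected_total_change([geomean - 0.005] * 26).value
        high = expected_total_change([geomean + 0.005] * 26).value
        assert low <= expected_total <= high
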