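import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vesselmorph.stats import (
    chi_square_test,
    holm_adjust,
    one_way_anova,
    pairwise_posthoc,
    render_summary_md,
    summarize_cohort,
    summary_frame,
)


class TestOneWayAnova:
    def test_identical_groups_f_zero_p_one(self):
        g = np.array([1.0, 2.0, 3.0])
        f, p = one_way_anova([g, g.copy(), g.copy()])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_sums_of_squares(self):
        # groups {1,2,3},{2,3,4},{3,4,5}: grand mean 3, SS_between = 3*((2-3)^2
        # + (3-3)^2 + (4-3)^2) = 6 on 2 df; SS_within = 6*1 = 6 on 6 df;
        # F = (6/2)/(6/6) = 3
        f, p = one_way_anova([np.array([1., 2., 3.]), np.array([2., 3., 4.]),
                              np.array([3., 4., 5.])])
        assert f == pytest.approx(3.0, abs=1e-12)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        f, p = one_way_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t.statistic ** 2, abs=1e-9)
        assert p == pytest.approx(t.pvalue, abs=1e-9)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1.3, n) for m, n in ((0, 12), (0.4, 18), (1.0, 9))]
        f, p = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_shift_and_scale_invariance_of_f(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, 15) for m in (0, 1, 2)]
        f0, _ = one_way_anova(groups)
        f_shift, _ = one_way_anova([g + 100.0 for g in groups])
        f_scale, _ = one_way_anova([g * 3.5 for g in groups])
        assert f_shift == pytest.approx(f0, rel=1e-9)
        assert f_scale == pytest.approx(f0, rel=1e-9)

    def test_degenerate_zero_within_variance(self):
        same = [np.array([2.0, 2.0]), np.array([2.0, 2.0])]
        assert one_way_anova(same) == (0.0, 1.0)
        diff = [np.array([1.0, 1.0]), np.array([2.0, 2.0])]
        f, p = one_way_anova(diff)
        assert np.isinf(f) and p == 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            one_way_anova([np.array([1.0, 2.0])])
        with pytest.raises(ValueError):
            one_way_anova([np.array([1.0]), np.array([1.0, 2.0])])
        with pytest.raises(ValueError):
            one_way_anova([np.array([1.0, np.nan]), np.array([1.0, 2.0])])


class TestChiSquare:
    def test_uniform_table_is_null(self):
        stat, df, p = chi_square_test([[10, 10], [10, 10]])
        assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_textbook_formula(self):
        # [[20,5],[5,20]]: all expected counts 12.5; sum (O-E)^2/E = 4*56.25/12.5
        stat, df, p = chi_square_test([[20, 5], [5, 20]])
        assert stat == pytest.approx(4 * 56.25 / 12.5, abs=1e-12)
        assert df == 1

    def test_2x2_closed_form(self):
        a, b, c, d = 13.0, 7.0, 4.0, 16.0
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        stat, _, _ = chi_square_test([[a, b], [c, d]])
        assert stat == pytest.approx(closed, abs=1e-9)

    def test_matches_scipy_without_correction(self):
        table = np.array([[30, 12, 8], [14, 22, 9]])
        stat, df, p = chi_square_test(table)
        ref = sps.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic, rel=1e-12)
        assert df == ref.dof
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_test([[0, 0], [5, 5]])


class TestPosthoc:
    def test_identical_groups_all_p_one(self):
        g = {"a": np.array([1.0, 1.0, 1.0]), "b": np.array([1.0, 1.0, 1.0]),
             "c": np.array([1.0, 1.0, 1.0])}
        assert all(p == pytest.approx(1.0) for *_, p in pairwise_posthoc(g))

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 30)
        groups = {"a": base, "b": rng.normal(0, 1, 30), "c": rng.normal(5, 1, 30)}
        res = {frozenset((x, y)): p for x, y, p in pairwise_posthoc(groups)}
        assert res[frozenset(("a", "c"))] < 1e-3
        assert res[frozenset(("b", "c"))] < 1e-3
        assert res[frozenset(("a", "b"))] > 0.05

    def test_holm_properties(self):
        raw = [0.04, 0.001, 0.3, 0.02]
        adj = holm_adjust(raw)
        assert max(adj) >= max(raw)
        order_raw = np.argsort(raw)
        assert np.all(np.diff(np.array(adj)[order_raw]) >= -1e-12)
        assert all(a >= r for a, r in zip(adj, raw))
        assert all(a <= 1.0 for a in adj)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_posthoc({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


class TestSummarize:
    def _records(self):
        rows = []
        for lab, dens in (("g1", [1.0, 2.0, 3.0]), ("g2", [4.0, 5.0, 6.0])):
            for i, d in enumerate(dens):
                rows.append({"eye_id": f"{lab}_{i}", "group_label": lab,
                             "vessel_angle_mean": d * 10, "vessel_density": d,
                             "fractal_dimension": np.nan, "tortuosity": d / 10})
        return pd.DataFrame(rows)

    def test_means_and_sds_match_hand_arithmetic(self):
        summaries = summarize_cohort(self._records())
        by_metric = {s.metric: s for s in summaries}
        dens = {lab: (m, sd) for lab, n, m, sd in by_metric["vessel_density"].groups}
        assert dens["g1"] == (pytest.approx(2.0), pytest.approx(1.0))
        assert dens["g2"] == (pytest.approx(5.0), pytest.approx(1.0))

    def test_all_missing_metric_row_omitted(self):
        summaries = summarize_cohort(self._records())
        assert {s.metric for s in summaries} == {
            "vessel_angle_mean", "vessel_density", "tortuosity"}

    def test_order_invariance(self):
        df = self._records()
        shuffled = df.sample(frac=1.0, random_state=0)
        a = summary_frame(summarize_cohort(df))
        b = summary_frame(summarize_cohort(shuffled))
        pd.testing.assert_frame_equal(a, b)

    def test_rendered_table_contains_means(self):
        md = render_summary_md(summarize_cohort(self._records()))
        assert "Vessel density (%)" in md
        assert "2.000 ± 1.000" in md
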