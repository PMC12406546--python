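import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from octex.stats import (
    DegenerateModelError,
    EndpointSpec,
    InsufficientDataError,
    ancova_group_effect,
    gated_two_sample_test,
    run_full_comparison,
    summarize,
    validate_cohort_table,
)


def make_long_table(base, follow, groups, week_t=8, measure="m", layer="L"):
    rows = []
    for i, (b, f, g) in enumerate(zip(base, follow, groups)):
        rows.append(
            dict(animal_id=f"a{i}", group=g, week=0, layer=layer, measure=measure, value=b)
        )
        rows.append(
            dict(animal_id=f"a{i}", group=g, week=week_t, layer=layer, measure=measure, value=f)
        )
    return pd.DataFrame(rows)


class TestAncova:
    def test_deterministic_separation_recovers_effect(self):
        base = np.arange(10, 30, dtype=float)
        groups = ["control"] * 10 + ["T2D"] * 10
        follow = base + 5.0 * (np.arange(20) >= 10)
        res = ancova_group_effect(make_long_table(base, follow, groups), "m", "L", 8)
        assert res.estimate == pytest.approx(5.0, abs=1e-9)
        assert res.p_value < 1e-12
        assert res.test_name == "ancova" and res.significant

    def test_baseline_adjustment_removes_baseline_imbalance(self, rng):
        # groups differ strongly at baseline but follow-up tracks baseline
        # exactly: the adjusted group difference must be ~0, p not tiny
        base = np.concatenate([rng.normal(100, 5, 12), rng.normal(130, 5, 12)])
        follow = base + rng.normal(0, 1, 24)
        groups = ["control"] * 12 + ["T2D"] * 12
        res = ancova_group_effect(make_long_table(base, follow, groups), "m", "L", 8)
        assert abs(res.estimate) < 2.0
        assert res.p_value > 0.01

    def test_complete_case_drops_missing_baseline(self, rng):
        base = rng.normal(100, 5, 16)
        follow = base + rng.normal(0, 1, 16)
        groups = ["control"] * 8 + ["T2D"] * 8
        table = make_long_table(base, follow, groups)
        table = table[~((table.animal_id == "a0") & (table.week == 0))]
        res = ancova_group_effect(table, "m", "L", 8)
        assert res.n_control == 7 and res.n_dropped == 1

    def test_insufficient_data(self):
        base = np.arange(4.0)
        follow = base + 1
        groups = ["control", "control", "T2D", "T2D"]
        with pytest.raises(InsufficientDataError):
            ancova_group_effect(make_long_table(base, follow, groups), "m", "L", 8)

    def test_degenerate_response(self, rng):
        base = rng.normal(size=12)
        follow = np.zeros(12)
        groups = ["control"] * 6 + ["T2D"] * 6
        with pytest.raises(DegenerateModelError):
            ancova_group_effect(make_long_table(base, follow, groups), "m", "L", 8)

    def test_reduces_to_t_test_without_covariate(self, rng):
        # with baseline values carrying no information and the model
        # refitted on follow-up only, ANCOVA's group p approaches the
        # pooled t-test p; check numerically via a constant baseline fit
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.5, 1, 15)
        t_p = sps.ttest_ind(x, y, equal_var=True).pvalue
        import statsmodels.api as sm

        g = np.r_[np.zeros(15), np.ones(15)]
        fit = sm.OLS(np.r_[x, y], sm.add_constant(g)).fit()
        assert fit.pvalues[1] == pytest.approx(t_p, rel=1e-10)


class TestGatedTest:
    def test_normal_samples_route_to_t_test(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        assert sps.shapiro(x).pvalue > 0.05 and sps.shapiro(y).pvalue > 0.05
        res = gated_two_sample_test(x, y)
        assert res.test_name == "t_test"
        assert res.normality_p is not None

    def test_exponential_sample_routes_to_mann_whitney(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.exponential(1.0, 30)
        assert sps.shapiro(y).pvalue <= 0.05
        res = gated_two_sample_test(x, y)
        assert res.test_name == "mann_whitney"

    def test_identical_samples_not_significant(self, rng):
        x = rng.normal(0, 1, 12)
        res = gated_two_sample_test(x, x.copy())
        assert res.p_value > 0.99
        assert not res.significant
        assert res.estimate == 0.0

    def test_constant_sample_routes_to_mann_whitney(self):
        res = gated_two_sample_test([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert res.test_name == "mann_whitney"
        assert res.normality_p is None

    def test_small_sample_sizes_rejected(self):
        with pytest.raises(InsufficientDataError):
            gated_two_sample_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSummarize:
    def test_hand_values(self):
        table = pd.DataFrame(
            dict(
                animal_id=[f"a{i}" for i in range(5)],
                group="control",
                week=0,
                layer="L",
                measure="m",
                value=[1.0, 2.0, 3.0, 4.0, 5.0],
            )
        )
        s = summarize(table, "m", "L", "control", 0)
        assert (s.median, s.q25, s.q75, s.mean) == (3.0, 2.0, 4.0, 3.0)
        assert s.sem == pytest.approx(math.sqrt(2.5) / math.sqrt(5))
        assert (s.min, s.max, s.n) == (1.0, 5.0, 5)

    def test_single_value(self):
        table = pd.DataFrame(
            dict(animal_id=["a"], group=["T2D"], week=[4], layer=["L"],
                 measure=["m"], value=[7.0])
        )
        s = summarize(table, "m", "L", "T2D", 4)
        assert s.min == s.max == s.median == s.mean == 7.0
        assert math.isnan(s.sem)

    def test_all_equal_values_zero_sem(self):
        table = pd.DataFrame(
            dict(animal_id=list("abc"), group="control", week=0, layer="L",
                 measure="m", value=[4.0, 4.0, 4.0])
        )
        assert summarize(table, "m", "L", "control", 0).sem == 0.0

    def test_empty_cell_raises(self):
        table = pd.DataFrame(columns=["animal_id", "group", "week", "layer", "measure", "value"])
        with pytest.raises(InsufficientDataError):
            summarize(table, "m", "L", "control", 0)


class TestRunFullComparison:
    def _cohort(self, rng, effect=0.0, weeks=(0, 4, 8, 12)):
        rows = []
        for i in range(24):
            group = "control" if i < 12 else "T2D"
            level = rng.normal(100, 5)
            for week in weeks:
                bump = effect if (group == "T2D" and week >= 8) else 0.0
                rows.append(
                    dict(animal_id=f"a{i}", group=group, week=week, layer="IPL",
                         measure="m", value=level + rng.normal(0, 2) + bump)
                )
        return pd.DataFrame(rows)

    def test_result_grid_shape(self, rng):
        res = run_full_comparison(self._cohort(rng), [EndpointSpec("m")])
        assert len(res) == 3  # weeks 4, 8, 12
        assert {r.week for r in res} == {4, 8, 12}

    def test_injected_effect_found_at_late_weeks_only(self, rng):
        res = run_full_comparison(self._cohort(rng, effect=8.0), [EndpointSpec("m")])
        by_week = {r.week: r for r in res}
        assert not by_week[4].significant
        assert by_week[8].significant and by_week[12].significant
        assert by_week[8].estimate > 0

    def test_gated_percent_of_baseline_route(self, rng):
        table = self._cohort(rng)
        spec = EndpointSpec("m", test="gated", as_percent_of_baseline=True)
        res = run_full_comparison(table, [spec])
        assert all(r.test_name in ("t_test", "mann_whitney") for r in res)

    def test_empty_endpoint_list(self, rng):
        assert run_full_comparison(self._cohort(rng), []) == []

    def test_fdr_flag_is_monotone(self, rng):
        table = self._cohort(rng, effect=4.0)
        raw = run_full_comparison(table, [EndpointSpec("m")])
        adj = run_full_comparison(table, [EndpointSpec("m")], fdr=True)
        for r, a in zip(raw, adj):
            assert a.p_value >= r.p_value - 1e-15

    def test_table_validation(self):
        bad = pd.DataFrame(dict(animal_id=["a"], group=["control"], week=[3],
                                layer=["L"], measure=["m"], value=[1.0]))
        with pytest.raises(ValueError, match="weeks"):
            validate_cohort_table(bad)


class TestPowerMonotonicity:
    def test_power_nondecreasing_in_effect_size(self, rng):
        """Empirical ANCOVA power grows with the injected group effect
        (4-point sweep, modest replicate count with a slack-one tolerance)."""
        n = 12
        powers = []
        for effect in (0.0, 1.0, 2.0, 4.0):
            hits = 0
            reps = 120
            for _ in range(reps):
                base = rng.normal(100, 3, 2 * n)
                follow = base + rng.normal(0, 2, 2 * n)
                follow[n:] += effect
                groups = ["control"] * n + ["T2D"] * n
                res = ancova_group_effect(make_long_table(base, follow, groups), "m", "L", 8)
                hits += res.significant
            powers.append(hits / reps)
        assert all(b >= a - 0.05 for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.9
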