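import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from streamtox.effects import (
    ContrastResult,
    SiteDesign,
    classify,
    paired_contrasts,
    percent_difference,
    reference_range,
    singlestep_adjusted_p,
)


def _values(design, rng, shift=None):
    """Balanced replicate values, 5 per site, optional per-site mean shift."""
    rows = []
    for site in design.sites:
        mu = (shift or {}).get(site, 0.0)
        for v in rng.normal(mu, 1.0, size=5):
            rows.append({"site": site, "value": v})
    return pd.DataFrame(rows)


class TestReferenceRange:
    def test_zero_spread_zero_width(self):
        r = reference_range([3.3, 3.3, 3.3])
        assert r.upper - r.lower == pytest.approx(0.0, abs=1e-12)
        assert r.mean == pytest.approx(3.3)

    def test_closed_form_hand_value(self):
        """Four means 1..4 at alpha 0.10: t(0.95,3)=2.3534, s=1.2910,
        sqrt(1+1/4)=1.1180 give a half-width of 3.397."""
        r = reference_range([1, 2, 3, 4], alpha=0.10)
        assert r.mean == pytest.approx(2.5)
        assert r.lower == pytest.approx(-0.897, abs=1e-3)
        assert r.upper == pytest.approx(5.897, abs=1e-3)

    def test_matches_intercept_only_regression_oracle(self):
        """The closed form equals statsmodels' prediction interval from an
        intercept-only OLS fit, across random reference sets."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        for n in (2, 4, 7):
            y = rng.normal(5, 2, size=n)
            fit = sm.OLS(y, np.ones((n, 1))).fit()
            frame = fit.get_prediction(np.ones((1, 1))).summary_frame(alpha=0.10)
            r = reference_range(y, alpha=0.10)
            assert r.lower == pytest.approx(frame["obs_ci_lower"][0], rel=1e-9)
            assert r.upper == pytest.approx(frame["obs_ci_upper"][0], rel=1e-9)

    def test_single_reference_mean_undefined(self):
        r = reference_range([2.0])
        assert not r.defined and math.isnan(r.lower)

    def test_width_shrinks_with_more_references(self):
        narrow = reference_range([1, 2, 3, 4, 1, 2, 3, 4])
        wide = reference_range([1, 2, 3, 4])
        assert narrow.upper - narrow.lower < wide.upper - wide.lower


class TestSinglestepAdjustment:
    def test_single_contrast_is_plain_two_sided_t(self):
        p = singlestep_adjusted_p([2.2], np.eye(1), df=17)
        assert p[0] == pytest.approx(2 * stats.t.sf(2.2, 17), abs=1e-12)

    def test_zero_statistic_gives_p_one(self):
        corr = np.eye(3)
        p = singlestep_adjusted_p([0.0, 1.0, 2.0], corr, df=20)
        assert p[0] == pytest.approx(1.0)

    def test_monotone_nonincreasing_in_t(self):
        corr = 0.3 * np.ones((4, 4)) + 0.7 * np.eye(4)
        t = [0.5, 1.0, 2.0, 3.5]
        p = singlestep_adjusted_p(t, corr, df=30)
        assert all(p[i] >= p[i + 1] for i in range(3))

    def test_permutation_symmetry(self):
        """Relabeling exchangeable contrasts permutes the adjusted p-values."""
        corr = 0.4 * np.ones((3, 3)) + 0.6 * np.eye(3)
        t = np.array([1.2, 2.1, 0.7])
        perm = [2, 0, 1]
        p = singlestep_adjusted_p(t, corr, df=25)
        p_perm = singlestep_adjusted_p(t[perm], corr, df=25)
        assert p[perm] == pytest.approx(p_perm, abs=2e-4)

    def test_adjusted_at_least_raw(self):
        corr = np.eye(5)
        t = [1.5, 2.5, 0.3, 3.0, 1.0]
        p = singlestep_adjusted_p(t, corr, df=36)
        raw = 2 * stats.t.sf(np.abs(t), 36)
        assert (p >= raw - 1e-10).all()


class TestPairedContrasts:
    def test_two_site_design_equals_pooled_t_test(self):
        design = SiteDesign(pairs={"S": "R"})
        rng = np.random.default_rng(11)
        values = _values(design, rng, shift={"S": 1.0})
        (c,) = paired_contrasts(values, design)
        s = values.loc[values.site == "S", "value"]
        r = values.loc[values.site == "R", "value"]
        t_ref, p_ref = stats.ttest_ind(s, r)
        assert c.t == pytest.approx(t_ref)
        assert c.p_adjusted == pytest.approx(p_ref, abs=1e-12)
        assert c.df == 8

    def test_nine_site_design_structure(self, design):
        rng = np.random.default_rng(5)
        values = _values(design, rng)
        results = paired_contrasts(values, design)
        assert [c.contaminated for c in results] == ["S1a", "S1b", "S2", "S3", "S4"]
        # pooled one-way model over 9 sites with 5 replicates each
        assert all(c.df == 36 for c in results)
        assert all(c.p_adjusted >= c.p_raw - 1e-10 for c in results)

    def test_shift_detected_in_right_direction(self, design):
        rng = np.random.default_rng(1)
        values = _values(design, rng, shift={"S1a": -3.0})
        results = {c.contaminated: c for c in paired_contrasts(values, design)}
        assert results["S1a"].p_adjusted < 0.01
        assert results["S1a"].direction == "lower"

    def test_welch_option_runs(self, design):
        rng = np.random.default_rng(2)
        values = _values(design, rng)
        results = paired_contrasts(values, design, variance="welch")
        assert len(results) == 5
        assert all(0 <= c.p_adjusted <= 1 for c in results)

    def test_missing_site_rejected(self, design):
        rng = np.random.default_rng(0)
        values = _values(design, rng)
        with pytest.raises(ValueError, match="S4"):
            paired_contrasts(values[values.site != "S4"], design)


def _contrast(p_adj, estimate=-1.0):
    return ContrastResult(
        metric="m", contaminated="S", reference="R", estimate=estimate,
        t=-2.0, df=36, p_raw=p_adj / 2, p_adjusted=p_adj,
    )


class TestClassification:
    def setup_method(self):
        self.range = reference_range([1, 2, 3, 4], alpha=0.10)

    def test_both_gates_adverse(self):
        c = classify(self.range, _contrast(0.01), site_mean=-2.0)
        assert c.label == "adverse" and c.range_direction == "lower"

    def test_significant_only_some_concern(self):
        c = classify(self.range, _contrast(0.01), site_mean=2.0)
        assert c.label == "some_concern" and not c.outside_range

    def test_outside_only_some_concern(self):
        c = classify(self.range, _contrast(0.40), site_mean=9.0)
        assert c.label == "some_concern" and c.range_direction == "higher"

    def test_neither_no_concern(self):
        c = classify(self.range, _contrast(0.40), site_mean=2.0)
        assert c.label == "no_concern"

    def test_undefined_range_skips_gate_with_note(self):
        r = reference_range([2.0])
        c = classify(r, _contrast(0.01), site_mean=-5.0)
        assert c.label == "some_concern"
        assert any("undefined" in n for n in c.notes)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "cont,ref,expected", [(5, 10, 50.0), (10, 10, 0.0), (2.5, 10, 75.0)]
    )
    def test_raw_scale(self, cont, ref, expected):
        assert percent_difference(cont, ref, scale="raw_mean") == pytest.approx(
            expected
        )

    def test_backtransformed_scale(self):
        # log10 means 1 and 2 are counts 9 and 99: a 90.9% reduction
        assert percent_difference(1.0, 2.0) == pytest.approx(100 * 90 / 99)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0, scale="raw_mean")
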