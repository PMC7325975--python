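"""Tukey HSD and Pearson/Fisher-z against closed forms and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import custress as cs
from custress.errors import InsufficientReplicationError, UndefinedStatisticError


class TestTukey:
    def test_equal_constant_groups_no_signal(self):
        res = cs.anova_tukey({"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0]})
        assert all(p.p_adj == 1.0 for p in res.pairs)

    def test_extreme_separation(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0, 1, 8)
        shifted = rng.normal(100, 1, 8)  # ~100 pooled sds away
        res = cs.anova_tukey({"a": a, "b": b, "c": shifted})
        assert res.pair("a", "c").p_adj < 1e-6
        assert res.pair("b", "c").p_adj < 1e-6

    def test_zero_variance_unequal_means_warns(self):
        with pytest.warns(RuntimeWarning):
            res = cs.anova_tukey({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert res.pairs[0].p_adj <= np.finfo(float).tiny

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = {
            "control": rng.normal(2.0, 0.4, 5),
            "gradual": rng.normal(1.2, 0.4, 5),
            "abrupt": rng.normal(1.6, 0.4, 5),
        }
        res = cs.anova_tukey(groups)
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        sm = pairwise_tukeyhsd(values, labels)
        ours = {
            frozenset((p.group_a, p.group_b)): p.p_adj for p in res.pairs
        }
        for row, p in zip(np.array(sm.summary().data[1:], dtype=object), sm.pvalues):
            key = frozenset((str(row[0]), str(row[1])))
            assert ours[key] == pytest.approx(p, abs=1e-6)

    def test_adjusted_p_not_below_pairwise_t(self, rng):
        """Tukey on k >= 3 groups is conservative relative to the
        unadjusted two-sample t-test using the pooled MSE."""
        for trial in range(10):
            groups = {
                "a": rng.normal(0.0, 1.0, 6),
                "b": rng.normal(0.5, 1.0, 6),
                "c": rng.normal(1.0, 1.0, 6),
            }
            res = cs.anova_tukey(groups)
            for pair in res.pairs:
                t_stat = abs(pair.diff) / (pair.se * np.sqrt(2))
                p_t = 2 * stats.t.sf(t_stat, res.df_error)
                assert pair.p_adj >= p_t - 1e-12

    def test_too_small_groups_rejected(self):
        with pytest.raises(InsufficientReplicationError):
            cs.anova_tukey({"a": [1.0], "b": [1.0, 2.0]})


class TestPearson:
    def test_collinear_data(self):
        x = np.arange(10.0)
        res = cs.pearson_ci(x, 2 * x + 1)
        assert res.r == 1.0
        assert res.p == 0.0

    def test_closed_form_ci(self, rng):
        """CI endpoints equal direct evaluation of the Fisher-z formula."""
        x = rng.normal(size=17)
        y = 0.5 * x + rng.normal(size=17)
        res = cs.pearson_ci(x, y, alpha=0.05)
        z = np.arctanh(res.r)
        half = stats.norm.ppf(0.975) / np.sqrt(17 - 3)
        assert res.ci_low == pytest.approx(np.tanh(z - half), abs=1e-12)
        assert res.ci_high == pytest.approx(np.tanh(z + half), abs=1e-12)
        assert res.ci_low <= res.r <= res.ci_high

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=(2, 20))
        res = cs.pearson_ci(x, y)
        sp = stats.pearsonr(x, y)
        assert res.r == pytest.approx(sp.statistic, abs=1e-12)
        assert res.p == pytest.approx(sp.pvalue, rel=1e-9)
        ci = sp.confidence_interval()
        assert res.ci_low == pytest.approx(ci.low, abs=1e-9)
        assert res.ci_high == pytest.approx(ci.high, abs=1e-9)

    @given(
        a=st.floats(min_value=0.1, max_value=5.0),
        b=st.floats(min_value=-3.0, max_value=3.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_invariance_and_sign_flip(self, a, b):
        rng = np.random.default_rng(99)
        x = rng.normal(size=15)
        y = 0.6 * x + rng.normal(size=15)
        base = cs.pearson_ci(x, y)
        scaled = cs.pearson_ci(a * x + b, y)
        assert scaled.r == pytest.approx(base.r, abs=1e-9)
        flipped = cs.pearson_ci(-x, y)
        assert flipped.r == pytest.approx(-base.r, abs=1e-9)

    def test_type_one_error_calibrated(self):
        """Independent x, y at n = 17: ~5% of 1000 datasets reject at 0.05."""
        rng = np.random.default_rng(1717)
        rej = sum(
            cs.pearson_ci(rng.normal(size=17), rng.normal(size=17)).p < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rej / 1000 <= 0.07

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cs.pearson_ci([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(InsufficientReplicationError):
            cs.pearson_ci([1, 2, 3], [1, 2, 3])
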