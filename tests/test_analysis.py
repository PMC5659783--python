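"""Tests for trial classification, normalization, the complementary
regressions, contrasts, category RT tests, and meta-aggregation."""

import numpy as np
import pandas as pd
import pytest

from vssm import (
    FITTED_PARAMS,
    abs_contrast,
    category_rt_test,
    classify,
    fit_accuracy,
    fit_rt,
    meta_aggregate,
    normalize_values,
)
from vssm.analysis import RegressionTable
from vssm.design import value_pairs
from vssm.simulate import simulate_dataset


def trials(rows):
    df = pd.DataFrame(rows, columns=["v_left", "v_right", "choice", "rt_ms"])
    df.insert(0, "trial", np.arange(1, len(df) + 1))
    df.insert(0, "subject", 1)
    return df


@pytest.fixture(scope="module")
def sca_classified(config):
    design = [(p, 400) for p in value_pairs()]
    df = simulate_dataset(FITTED_PARAMS["SCA"], design, config, seed=314)
    return classify(df, levels=(1, 2, 3, 4))


class TestClassify:
    def test_choice_categories(self):
        df = trials([
            (3, 1, "L", 700),   # greater chosen -> correct
            (2, 2, "R", 800),   # equal values -> indifferent
            (1, 4, "L", 600),   # lesser chosen -> incorrect
        ])
        out = classify(df)
        assert list(out["category"]) == ["correct", "indifferent", "incorrect"]

    def test_contaminants_and_non_responses_are_dropped(self):
        df = trials([(3, 1, "L", 250), (3, 1, "NONE", 0), (3, 1, "R", 700)])
        out = classify(df)
        assert len(out) == 1
        assert out["category"].iloc[0] == "incorrect"

    def test_normalized_design_columns(self):
        df = trials([(1, 4, "R", 700)])
        out = classify(df, levels=(1, 2, 3, 4))
        row = out.iloc[0]
        assert row["greater_n"] == pytest.approx(1.0)
        assert row["lesser_n"] == pytest.approx(0.0)
        assert row["absdiff"] == pytest.approx(1.0)
        assert row["vsum"] == pytest.approx(1.0)
        assert row["rt_s"] == pytest.approx(0.7)


class TestNormalizeValues:
    def test_four_point_scale(self):
        out = normalize_values([1, 2, 3, 4])
        assert np.allclose(out, [0.0, 1 / 3, 2 / 3, 1.0])

    def test_eleven_point_scale_midpoint(self):
        assert normalize_values([6], levels=range(1, 12))[0] == pytest.approx(0.5)

    def test_idempotent_on_normalized_data(self):
        x = np.array([0.0, 0.25, 1.0])
        assert np.allclose(normalize_values(x), x)

    def test_degenerate_scale_is_rejected(self):
        with pytest.raises(ValueError):
            normalize_values([2, 2, 2])


class TestComplementaryParameterizations:
    def test_linear_reparameterization_identity(self, sca_classified):
        """On the same trials, difference/sum OLS coefficients are exact
        half-sums/half-differences of greater/lesser ones."""
        gl, ds = fit_rt(sca_classified, "correct")
        b_g, _ = gl.coef("greater")
        b_l, _ = gl.coef("lesser")
        b_d, _ = ds.coef("absdiff")
        b_s, _ = ds.coef("sum")
        assert b_d == pytest.approx((b_g - b_l) / 2, rel=1e-9)
        assert b_s == pytest.approx((b_g + b_l) / 2, rel=1e-9)
        assert gl.coef("const")[0] == pytest.approx(ds.coef("const")[0],
                                                    rel=1e-9)

    def test_logistic_reparameterization_identity(self, sca_classified):
        gl, ds = fit_accuracy(sca_classified)
        b_g, _ = gl.coef("greater")
        b_l, _ = gl.coef("lesser")
        assert ds.coef("absdiff")[0] == pytest.approx((b_g - b_l) / 2,
                                                      rel=1e-5)
        assert ds.coef("sum")[0] == pytest.approx((b_g + b_l) / 2, rel=1e-5)

    def test_greater_only_effect_mimics_half_sized_difference_and_sum(self):
        """A pure greater-value effect of size c shows up as difference and
        sum effects of c/2 each."""
        rng = np.random.default_rng(5)
        g = rng.choice([0.0, 1 / 3, 2 / 3, 1.0], size=4000)
        l = np.minimum(g, rng.choice([0.0, 1 / 3, 2 / 3, 1.0], size=4000))
        c = -0.30
        y = 1.0 + c * g + 0.01 * rng.standard_normal(4000)
        df = pd.DataFrame({
            "greater_n": g, "lesser_n": l, "absdiff": g - l, "vsum": g + l,
            "rt_s": y, "category": "correct"})
        gl, ds = fit_rt(df, "correct")
        assert gl.coef("greater")[0] == pytest.approx(c, abs=0.01)
        assert ds.coef("absdiff")[0] == pytest.approx(c / 2, abs=0.01)
        assert ds.coef("sum")[0] == pytest.approx(c / 2, abs=0.01)

    def test_logistic_recovery_of_known_coefficients(self):
        """Generate-and-refit: Bernoulli data with known slopes."""
        rng = np.random.default_rng(17)
        levels = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        g = rng.choice(levels, size=20000)
        l = rng.choice(levels, size=20000)
        g, l = np.maximum(g, l), np.minimum(g, l)
        keep = g > l
        g, l = g[keep], l[keep]
        beta = (-0.3, 3.4, -2.9)
        eta = beta[0] + beta[1] * g + beta[2] * l
        y = rng.random(len(eta)) < 1 / (1 + np.exp(-eta))
        df = pd.DataFrame({
            "greater_n": g, "lesser_n": l, "absdiff": g - l, "vsum": g + l,
            "category": np.where(y, "correct", "incorrect")})
        gl, _ = fit_accuracy(df)
        for term, truth in zip(("const", "greater", "lesser"), beta):
            est, se = gl.coef(term)
            assert abs(est - truth) < 2 * se

    def test_constant_rt_gives_zero_normalized_effects(self):
        df = trials([(1, 3, "R", 800), (1, 4, "R", 800), (2, 4, "R", 800),
                     (2, 3, "R", 800), (1, 2, "R", 800), (3, 4, "R", 800)] * 3)
        out = classify(df, levels=(1, 2, 3, 4))
        gl, ds = fit_rt(out, "correct")
        assert gl.coef("greater", normalized=True)[0] == pytest.approx(0.0,
                                                                       abs=1e-9)
        assert ds.coef("sum", normalized=True)[0] == pytest.approx(0.0,
                                                                   abs=1e-9)
        assert gl.coef("const")[0] == pytest.approx(0.8)

    def test_indifferent_fit_has_only_constant_and_sum(self, sca_classified):
        table = fit_rt(sca_classified, "indifferent")
        assert table.terms == ["const", "sum"]

    def test_too_few_trials_is_flagged(self):
        df = trials([(1, 3, "L", 700)] * 3)
        out = classify(df)
        gl, ds = fit_rt(out, "incorrect")
        assert gl.flagged and ds.flagged
        assert np.isnan(gl.est).all()


class TestContrastsAndCategoryTests:
    def test_reported_asymmetry_example(self):
        M, z, p = abs_contrast(3.517, 0.121, -3.038, 0.124)
        assert M == pytest.approx(0.479)
        assert p < 0.05

    def test_equal_magnitudes_give_zero(self):
        M, _, p = abs_contrast(2.0, 0.1, -2.0, 0.1)
        assert M == 0.0 and p == 1.0

    def test_identical_categories_differ_by_zero(self, sca_classified):
        d, _, _ = category_rt_test(sca_classified, "correct", "correct")
        assert d == 0.0

    def test_errors_and_ties_are_slower_than_correct(self, sca_classified):
        """Competing accumulators predict slower incorrect/indifferent RTs."""
        for other in ("incorrect", "indifferent"):
            diff, t, p = category_rt_test(sca_classified, other, "correct")
            assert diff > 0 and p < 0.05

    def test_empty_category_is_rejected(self, sca_classified):
        df = sca_classified[sca_classified["category"] != "incorrect"]
        with pytest.raises(ValueError):
            category_rt_test(df, "incorrect", "correct")


class TestMetaAggregate:
    @staticmethod
    def _table(est, n):
        return RegressionTable(
            outcome="accuracy", parameterization="greater_lesser",
            terms=["const"], est=np.array([est]), se=np.array([0.1]),
            n_trials=n)

    def test_trial_weighted_mean(self):
        out = meta_aggregate([self._table(2.0, 1000), self._table(4.0, 3000)])
        assert out.est[0] == pytest.approx(3.5)
        assert out.n_trials == 4000

    def test_single_table_is_returned_unchanged(self):
        t = self._table(2.0, 100)
        assert meta_aggregate([t]) is t

    def test_permutation_invariance(self):
        tables = [self._table(x, n) for x, n in
                  [(1.0, 500), (2.0, 1500), (5.0, 800)]]
        a = meta_aggregate(tables)
        b = meta_aggregate(tables[::-1])
        assert a.est[0] == pytest.approx(b.est[0])
        assert a.se[0] == pytest.approx(b.se[0])

    def test_mismatched_tables_are_rejected(self):
        other = RegressionTable(
            outcome="rt_correct", parameterization="greater_lesser",
            terms=["const"], est=np.array([1.0]), se=np.array([0.1]),
            n_trials=10)
        with pytest.raises(ValueError):
            meta_aggregate([self._table(1.0, 10), other])
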