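"""Compositional operations: closure, zero replacement, ILR pivots and
the basis-invariance of the one-for-remaining regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from move24 import coda
from move24.coda import (CompositionMentalHealthModel, close,
                         geometric_mean_composition, inverse_pivot_ilr,
                         pivot_ilr, replace_zeros, variation_matrix)

PARTS = coda.PARTS

compositions = st.lists(
    st.floats(min_value=1.0, max_value=1000.0, allow_nan=False), min_size=5,
    max_size=5)


class TestClose:
    def test_hours_to_minutes(self):
        x = close([8, 6.5, 6.9, 0.4, 0.3])
        assert x.sum() == pytest.approx(1440.0)

    def test_idempotent(self):
        x = close([480, 600, 240, 90, 30])
        np.testing.assert_allclose(close(x), x)

    def test_equal_parts(self):
        np.testing.assert_allclose(close([1, 1, 1, 1, 1]), [288] * 5)

    def test_rejects_nonpositive_total(self):
        with pytest.raises(ValueError):
            close([0, 0, 0, 0, 0])


class TestReplaceZeros:
    def test_no_zeros_unchanged(self):
        x = close([480, 600, 240, 90, 30])
        np.testing.assert_allclose(replace_zeros(x, delta=1.0), x)

    def test_zero_becomes_delta_sum_preserved(self):
        x = np.array([480.0, 600.0, 270.0, 90.0, 0.0])
        y = replace_zeros(x, delta=1.0)
        assert y[-1] == pytest.approx(1.0, rel=1e-9)
        assert y.sum() == pytest.approx(1440.0)

    def test_ilr_finite_after_replacement(self):
        y = replace_zeros([700, 600, 130, 10, 0], delta=0.5)
        assert np.all(np.isfinite(pivot_ilr(y, "sleep")))

    def test_delta_too_large_rejected(self):
        with pytest.raises(ValueError):
            replace_zeros([700.0, 600.0, 130.0, 10.0, 0.0], delta=20.0)

    def test_default_delta_is_half_min_positive(self):
        x = np.array([[700, 600, 130, 10, 0.0], [700, 600, 120, 16, 4.0]])
        y = replace_zeros(x)
        # zero VPA replaced by half the smallest positive VPA (= 2), then closed
        assert y[0, -1] == pytest.approx(2.0, rel=1e-6)


class TestGeometricMean:
    def test_identical_compositions(self):
        x = close([480, 600, 240, 90, 30])
        np.testing.assert_allclose(geometric_mean_composition([x, x]), x)

    def test_two_compositions_sqrt_products(self):
        a = close([480, 600, 240, 90, 30])
        b = close([540, 500, 300, 70, 30])
        expected = close(np.sqrt(a * b))
        np.testing.assert_allclose(geometric_mean_composition([a, b]), expected)

    def test_log_space_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(10, 600, size=(20, 5))
        oracle = close(np.exp(np.mean(np.log(x), axis=0)))
        np.testing.assert_allclose(geometric_mean_composition(x), oracle)


class TestVariationMatrix:
    def test_identical_rows_all_zero(self):
        x = np.tile(close([480, 600, 240, 90, 30]), (4, 1))
        np.testing.assert_allclose(variation_matrix(x), np.zeros((5, 5)))

    def test_symmetric_zero_diagonal_and_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(10, 600, size=(30, 5))
        t = variation_matrix(x)
        np.testing.assert_allclose(t, t.T)
        np.testing.assert_allclose(np.diag(t), 0.0)
        # direct log-ratio variance oracle for one off-diagonal entry
        oracle = np.var(np.log(x[:, 0] / x[:, 3]), ddof=1)
        assert t[0, 3] == pytest.approx(oracle)


class TestPivotIlr:
    def test_equal_parts_all_zero(self):
        np.testing.assert_allclose(pivot_ilr([288] * 5, "mpa"), np.zeros(4),
                                   atol=1e-12)

    def test_first_coordinate_formula(self):
        # z1 = sqrt(4/5) ln(sleep / gm(st, lpa, mpa, vpa))
        x = np.array([480.0, 600.0, 240.0, 90.0, 30.0])
        gm = np.prod(x[1:]) ** 0.25
        expected = np.sqrt(4 / 5) * np.log(x[0] / gm)
        assert pivot_ilr(x, "sleep")[0] == pytest.approx(expected)
        assert expected == pytest.approx(1.099, abs=5e-4)

    @given(compositions)
    @settings(max_examples=50, deadline=None)
    def test_bijective(self, parts):
        x = close(parts)
        for pivot in PARTS:
            z = pivot_ilr(x, pivot)
            np.testing.assert_allclose(inverse_pivot_ilr(z, pivot), x,
                                       atol=1e-8)

    @given(compositions, st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariant(self, parts, scale):
        x = np.asarray(parts)
        np.testing.assert_allclose(pivot_ilr(close(x), "st"),
                                   pivot_ilr(close(x * scale), "st"),
                                   atol=1e-9)

    def test_rejects_zero_part(self):
        with pytest.raises(ValueError):
            pivot_ilr([480, 600, 270, 90, 0], "sleep")


class TestClrGradient:
    def test_round_trip_betas(self):
        g = coda.clr_gradient_for_betas({"sleep": -6.0, "st": 4.7})
        assert g.sum() == pytest.approx(0.0, abs=1e-12)
        betas = coda.pivot_beta_from_clr_gradient(g)
        assert betas["sleep"] == pytest.approx(-6.0)
        assert betas["st"] == pytest.approx(4.7)

    def test_gradient_predicts_pivot_coefficients(self):
        # regressing g.ln(x) on any pivot basis must give beta_b on z1
        rng = np.random.default_rng(11)
        x = close(rng.uniform(10, 600, size=(200, 5)))
        g = coda.clr_gradient_for_betas({"sleep": -6.0, "st": 4.7})
        y = np.log(x) @ g
        betas = coda.pivot_beta_from_clr_gradient(g)
        for pivot in PARTS:
            z = pivot_ilr(x, pivot)
            coef = np.linalg.lstsq(
                np.column_stack([np.ones(len(y)), z]), y, rcond=None)[0]
            assert coef[1] == pytest.approx(betas[pivot], abs=1e-8)


def _toy_frame(n=120, seed=2, effect=0.0):
    rng = np.random.default_rng(seed)
    comp = close(np.exp(rng.normal(np.log([500, 520, 300, 70, 15]), 0.15,
                                   size=(n, 5))))
    df = pd.DataFrame(comp, columns=PARTS)
    df["school_id"] = np.repeat(np.arange(6), n // 6)
    df["sex_girl"] = rng.integers(0, 2, n).astype(float)
    df["bmiz"] = rng.normal(0, 1, n)
    z1 = pivot_ilr(comp, "sleep")[:, 0]
    df["y"] = effect * z1 + 0.5 * df["sex_girl"] + rng.normal(0, 2, n)
    return df


class TestCompositionModel:
    def test_loglik_and_omnibus_invariant_across_pivots(self):
        df = _toy_frame(effect=1.5)
        m = CompositionMentalHealthModel.from_dataframe(
            df, "y", covariates=["sex_girl", "bmiz"])
        res = m.fit(stratify_on_sex=False)
        lls = np.array(list(res.loglik_by_pivot.values()))
        assert np.ptp(lls) < 1e-8

    def test_ols_and_cluster_methods_run(self):
        df = _toy_frame()
        m = CompositionMentalHealthModel.from_dataframe(
            df, "y", covariates=["sex_girl"])
        for method in ("ols", "cluster"):
            res = m.fit(method=method, stratify_on_sex=False)
            assert res.method == method
            assert np.isfinite(res.omnibus_p)

    def test_single_school_falls_back_to_ols(self):
        df = _toy_frame()
        df["school_id"] = 0
        m = CompositionMentalHealthModel.from_dataframe(df, "y")
        with pytest.warns(UserWarning):
            res = m.fit(stratify_on_sex=False)
        assert res.method == "ols"

    def test_effect_ci_ordering(self):
        df = _toy_frame(effect=2.0)
        res = CompositionMentalHealthModel.from_dataframe(df, "y").fit(
            stratify_on_sex=False)
        for e in res.effects.values():
            assert e.ci_low <= e.beta <= e.ci_high

    def test_predict_matches_manual_ilr_dot_product(self):
        df = _toy_frame(effect=2.0)
        res = CompositionMentalHealthModel.from_dataframe(
            df, "y", covariates=["sex_girl", "bmiz"]).fit(stratify_on_sex=False)
        new = close([510, 500, 320, 80, 30])
        params = res.params_by_pivot["sleep"]
        z = pivot_ilr(new, "sleep")
        manual = (params["const"]
                  + sum(params[f"z{j+1}"] * z[j] for j in range(4))
                  + params["sex_girl"] * res.covariate_reference["sex_girl"]
                  + params["bmiz"] * res.covariate_reference["bmiz"])
        assert res.predict(new)[0] == pytest.approx(manual)

    def test_summary_mentions_outcome_and_omnibus(self):
        res = CompositionMentalHealthModel.from_dataframe(
            _toy_frame(), "y").fit(stratify_on_sex=False)
        text = res.summary()
        assert "Omnibus" in text and "y" in text
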