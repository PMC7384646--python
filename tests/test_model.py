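"""Conditional likelihood, Newton fit, and design-matrix behaviour."""

import numpy as np
import pandas as pd
import pytest

from casecross.exceptions import (
    ConvergenceError,
    RankDeficiencyError,
    SeparationError,
    ValidationError,
)
from casecross.model import (
    CaseCrossoverModel,
    ConditionalLogit,
    ModelSpec,
    restrict_below_threshold,
)

from conftest import random_matched_sets


def one_covariate_model(y, x, g):
    return ConditionalLogit(y, np.asarray(x, dtype=float), g, exog_names=["x"])


class TestLoglik:
    def test_uniform_at_beta_zero(self):
        m = one_covariate_model([1, 0, 0], [1.0, 0.0, 0.0], [0, 0, 0])
        assert m.loglike([0.0]) == pytest.approx(np.log(1 / 3), abs=1e-12)

    def test_closed_form_at_log2(self):
        # case x=1, referents x=0,0: l(ln 2) = ln(2/4) = -ln 2
        m = one_covariate_model([1, 0, 0], [1.0, 0.0, 0.0], [0, 0, 0])
        assert m.loglike([np.log(2.0)]) == pytest.approx(-np.log(2.0), abs=1e-12)

    def test_zero_beta_closed_form_many_sets(self, rng):
        y, x, g = random_matched_sets(rng, 40, beta=0.7)
        m = one_covariate_model(y, x, g)
        sizes = np.bincount(g.astype(int))
        assert m.loglike([0.0]) == pytest.approx(-np.log(sizes).sum(), rel=1e-12)

    def test_finite_for_extreme_beta(self, rng):
        y, x, g = random_matched_sets(rng, 10, beta=0.0)
        m = one_covariate_model(y, x, g)
        for b in (-500.0, 500.0):
            assert np.isfinite(m.loglike([b]))

    def test_set_constant_offsets_leave_likelihood_unchanged(self, rng):
        y, x, g = random_matched_sets(rng, 30, beta=0.4)
        m1 = one_covariate_model(y, x, g)
        offsets = rng.normal(0, 50, 30)[g.astype(int)]
        m2 = one_covariate_model(y, x + offsets, g)
        for b in (-1.0, 0.0, 0.3, 2.0):
            assert m2.loglike([b]) == pytest.approx(m1.loglike([b]), rel=1e-10)


class TestDerivatives:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradient_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        y, x, g = random_matched_sets(rng, 25, beta=0.5)
        X = np.column_stack([x, rng.normal(0, 1, len(x))])
        m = ConditionalLogit(y, X, g)
        beta = rng.normal(0, 0.5, 2)
        grad = m.score(beta)
        h = 1e-6
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            fd = (m.loglike(beta + e) - m.loglike(beta - e)) / (2 * h)
            assert grad[j] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_hessian_negative_semidefinite(self, seed):
        rng = np.random.default_rng(seed)
        y, x, g = random_matched_sets(rng, 25, beta=0.5)
        X = np.column_stack([x, rng.normal(0, 1, len(x))])
        m = ConditionalLogit(y, X, g)
        for _ in range(5):
            H = m.hessian(rng.normal(0, 1, 2))
            assert (np.linalg.eigvalsh(H) <= 1e-8).all()


class TestFit:
    def test_symmetric_sets_give_zero(self):
        y = [1, 0, 1, 0]
        x = [1.0, 0.0, 0.0, 1.0]
        g = [0, 0, 1, 1]
        res = one_covariate_model(y, x, g).fit()
        assert res.params[0] == pytest.approx(0.0, abs=1e-8)
        assert res.converged

    def test_matches_grid_search_argmax(self, rng):
        y, x, g = random_matched_sets(rng, 50, beta=0.8)
        m = one_covariate_model(y, x, g)
        res = m.fit()
        grid = np.arange(-3.0, 3.0, 1e-4)
        ll = np.array([m.loglike([b]) for b in grid[np.abs(grid - res.params[0]) < 0.01]])
        sub = grid[np.abs(grid - res.params[0]) < 0.01]
        assert abs(sub[ll.argmax()] - res.params[0]) <= 1e-4

    def test_single_pair_separates(self):
        with pytest.raises(SeparationError) as exc:
            one_covariate_model([1, 0], [1.0, 0.0], [0, 0]).fit()
        assert exc.value.column == "x"

    def test_covariance_positive_definite_and_symmetric(self, rng):
        y, x, g = random_matched_sets(rng, 100, beta=0.3)
        res = one_covariate_model(y, x, g).fit()
        C = res.cov_params_arr
        assert np.allclose(C, C.T)
        assert (np.linalg.eigvalsh(C) > 0).all()

    def test_paired_fit_depends_only_on_within_pair_differences(self, rng):
        # with one referent per set, only x_case - x_ref matters
        n = 60
        diffs = rng.normal(0, 1, n)
        base1 = rng.normal(0, 5, n)
        base2 = rng.normal(0, 5, n)
        y = np.tile([1.0, 0.0], n)
        g = np.repeat(np.arange(n), 2)
        x1 = np.column_stack([base1 + diffs, base1]).ravel()
        x2 = np.column_stack([base2 + diffs, base2]).ravel()
        r1 = one_covariate_model(y, x1, g).fit()
        r2 = one_covariate_model(y, x2, g).fit()
        assert r1.params[0] == pytest.approx(r2.params[0], abs=1e-8)

    def test_validation_of_malformed_sets(self):
        with pytest.raises(ValidationError):
            ConditionalLogit([1, 1, 0], np.ones((3, 1)), [0, 0, 0])  # two cases
        with pytest.raises(ValidationError):
            ConditionalLogit([1], np.ones((1, 1)), [0])  # no referent


class TestWald:
    def test_null_coefficient_gives_p_one(self, rng):
        y = [1, 0, 1, 0]
        x = [1.0, 0.0, 0.0, 1.0]
        res = one_covariate_model(y, x, [0, 0, 1, 1]).fit()
        z, p = res.wald_test("x")
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_z_at_1p96_gives_p_05(self, rng):
        y, x, g = random_matched_sets(rng, 400, beta=0.5)
        res = one_covariate_model(y, x, g).fit()
        # direct check of the transform: z = beta / se, p = 2 Phi(-|z|)
        z, p = res.wald_test(0)
        assert z == pytest.approx(res.params[0] / res.bse[0])
        from scipy.stats import norm

        assert p == pytest.approx(2 * norm.sf(abs(z)), abs=1e-12)


class TestStatsmodelsAgreement:
    def test_coefficients_and_ses_match_reference(self, rng):
        import statsmodels.api as sm

        y, x, g = random_matched_sets(rng, 300, beta=0.6)
        x2 = rng.normal(0, 1, len(x))
        X = np.column_stack([x, x2])
        ours = ConditionalLogit(y, X, g, exog_names=["x1", "x2"]).fit()
        ref = sm.ConditionalLogit(y, X, groups=g).fit(
            disp=False, method="newton", maxiter=200, tol=1e-12
        )
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.bse, ref.bse, atol=1e-6)
        assert ours.llf == pytest.approx(ref.llf, abs=1e-8)


class TestDesignConstruction:
    def test_modifier_main_effect_raises_rank_deficiency(self, small_design):
        from casecross.model import _WEEKDAYS  # noqa: F401

        df = small_design.copy()
        y = df["is_case"].to_numpy()
        X = np.column_stack(
            [df["pm25_window"].to_numpy(), df["pct_black"].to_numpy()]
        )
        with pytest.raises(RankDeficiencyError) as exc:
            ConditionalLogit(y, X, df["record_id"].to_numpy(), exog_names=["pm", "pct_black"])
        assert "pct_black" in exc.value.columns

    def test_duplicated_column_raises_rank_deficiency(self, small_design):
        df = small_design
        X = np.column_stack([df["pm25_window"], df["pm25_window"] * 2.0])
        with pytest.raises(RankDeficiencyError):
            ConditionalLogit(df["is_case"], X, df["record_id"], exog_names=["a", "b"])

    def test_exposure_estimate_invariant_to_temperature_centering(self, small_design):
        res_c = CaseCrossoverModel(small_design, ModelSpec(center_temperature=True)).fit()
        res_u = CaseCrossoverModel(small_design, ModelSpec(center_temperature=False)).fit()
        k = res_c.exog_names.index("pm25_window")
        assert res_c.params[k] == pytest.approx(res_u.params[k], rel=1e-6, abs=1e-10)
        assert res_c.bse[k] == pytest.approx(res_u.bse[k], rel=1e-6)

    def test_design_columns_named_and_complete(self, small_design):
        model = CaseCrossoverModel(small_design, ModelSpec(modifier="pct_black"))
        assert model._mod.exog_names == [
            "pm25_window",
            "dow_Monday", "dow_Tuesday", "dow_Wednesday", "dow_Thursday",
            "dow_Friday", "dow_Saturday",
            "temp_c", "temp_c_sq",
            "pm25_window:pct_black",
        ]

    def test_unknown_modifier_column_rejected(self, small_design):
        with pytest.raises(ValidationError):
            CaseCrossoverModel(small_design, ModelSpec(modifier="not_a_column"))


class TestRestriction:
    def toy_design(self):
        rows = []
        # five sets of 1 case + 2 referents; sets 0 and 3 have case days > 35
        for s in range(5):
            case_pm = 40.0 if s in (0, 3) else 20.0
            rows.append((f"r{s}", 1, case_pm))
            rows.append((f"r{s}", 0, 10.0))
            rows.append((f"r{s}", 0, 12.0))
        return pd.DataFrame(rows, columns=["record_id", "is_case", "pm25_day"])

    def test_case_day_above_threshold_drops_whole_set(self):
        out, log = restrict_below_threshold(self.toy_design(), threshold=35.0)
        assert log["sets_dropped_case_day"] == 2
        assert out["record_id"].nunique() == 3

    def test_all_below_threshold_unchanged(self):
        design = self.toy_design()
        design["pm25_day"] = 5.0
        out, log = restrict_below_threshold(design, threshold=35.0)
        pd.testing.assert_frame_equal(out, design)

    def test_referent_day_above_threshold_only_removes_that_day(self):
        design = self.toy_design()
        design.loc[(design["record_id"] == "r1") & (design["pm25_day"] == 12.0), "pm25_day"] = 50.0
        out, log = restrict_below_threshold(design, threshold=35.0)
        assert log["days_removed"] == 3
        assert (out[out["record_id"] == "r1"]["is_case"] == [1, 0]).all()

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValidationError):
            restrict_below_threshold(self.toy_design(), threshold=0.0)


def test_nonconvergence_raises_with_diagnostics(rng):
    y, x, g = random_matched_sets(rng, 50, beta=0.5)
    with pytest.raises(ConvergenceError):
        one_covariate_model(y, x, g).fit(maxiter=1)
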