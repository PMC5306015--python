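"""GLM contract, AICc machinery, candidate design and Cade averaging."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import farmscape as fs
from farmscape.design_matrix import AnalysisMatrix
from farmscape.multimodel_inference import (
    RankDeficientError,
    aicc,
    akaike_weights,
    enumerate_stage1,
    fit_glm,
    partial_sd,
    stage1_screen,
    stage2_average,
    standardized_coefficients,
    vif,
)


def _matrix(X: pd.DataFrame, y, mode="spatial_T0", group="all") -> AnalysisMatrix:
    y = pd.Series(np.asarray(y), index=X.index, name="richness")
    return AnalysisMatrix(X=X, y=y, mode=mode, group=group)


def _random_matrix(rng, n=60, p=4, mode="spatial_T0"):
    X = pd.DataFrame(
        rng.standard_normal((n, p)) * 0.4,
        columns=[f"x{i}" for i in range(p)],
        index=[f"s{i:03d}" for i in range(n)],
    )
    eta = 1.5 + 0.8 * X["x0"]
    if mode == "spatial_T0":
        y = rng.poisson(np.exp(eta))
    else:
        y = eta + rng.standard_normal(n)
    return _matrix(X, y, mode=mode)


class TestFitGlm:
    def test_poisson_intercept_only_is_log_mean(self):
        X = pd.DataFrame(index=["a", "b", "c"])
        fit = fit_glm(_matrix(X, [2, 4, 6]), [])
        assert fit.params["const"] == pytest.approx(math.log(4), abs=1e-8)

    def test_gaussian_equals_closed_form_ols(self, rng):
        mat = _random_matrix(rng, n=40, p=2, mode="temporal")
        fit = fit_glm(mat, ["x0", "x1"])
        design = np.column_stack([np.ones(40), mat.X[["x0", "x1"]].to_numpy()])
        beta = np.linalg.solve(design.T @ design, design.T @ mat.y.to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)
        # exact profile-ML log-likelihood
        rss = float(np.sum((mat.y.to_numpy() - design @ beta) ** 2))
        llf = -0.5 * 40 * (math.log(2 * math.pi) + math.log(rss / 40) + 1)
        assert fit.llf == pytest.approx(llf, abs=1e-8)
        assert fit.k == 4  # intercept + 2 slopes + sigma

    def test_poisson_simulation_recovery_within_3_se(self):
        rng = np.random.default_rng(11)
        n = 500
        X = pd.DataFrame({"x0": rng.standard_normal(n)}, index=[f"s{i}" for i in range(n)])
        y = rng.poisson(np.exp(0.5 + 0.3 * X["x0"]))
        fit = fit_glm(_matrix(X, y), ["x0"])
        res = sm.GLM(y, np.column_stack([np.ones(n), X["x0"]]),
                     family=sm.families.Poisson()).fit()
        se = res.bse
        assert abs(fit.params["const"] - 0.5) < 3 * se[0]
        assert abs(fit.params["x0"] - 0.3) < 3 * se[1]

    def test_rank_deficiency_names_columns(self, rng):
        mat = _random_matrix(rng, n=30, p=2)
        mat.X["dup"] = 2 * mat.X["x0"]
        with pytest.raises(RankDeficientError, match="dup|x0"):
            fit_glm(mat, ["x0", "x1", "dup"])

    def test_too_few_observations_raises(self, rng):
        mat = _random_matrix(rng, n=4, p=3)
        with pytest.raises(ValueError, match="n="):
            fit_glm(mat, ["x0", "x1", "x2"])


class TestInformationCriteria:
    def test_aicc_direct_evaluation(self):
        assert aicc(-50, 3, 73) == pytest.approx(106 + 24 / 69, abs=1e-10)
        assert aicc(-50, 3, 73) == pytest.approx(106.3478, abs=1e-4)

    def test_aicc_converges_to_aic(self):
        assert abs(aicc(-50, 3, 10**8) - (106.0)) < 1e-6

    def test_aicc_equal_inputs_equal_outputs_and_domain(self):
        assert aicc(-10, 2, 50) == aicc(-10, 2, 50)
        with pytest.raises(ValueError):
            aicc(-10, 9, 10)

    def test_weights_uniform_for_equal_aicc(self):
        np.testing.assert_allclose(akaike_weights([5.0, 5.0, 5.0]), [1 / 3] * 3)

    def test_weights_delta_two(self):
        w = akaike_weights([100.0, 102.0])
        np.testing.assert_allclose(w, [0.7311, 0.2689], atol=1e-4)

    def test_weights_shift_invariant_and_sum_to_one(self, rng):
        a = rng.uniform(100, 140, 10)
        w1, w2 = akaike_weights(a), akaike_weights(a + 17.3)
        np.testing.assert_allclose(w1, w2, atol=1e-12)
        assert abs(w1.sum() - 1.0) < 1e-12


class TestCandidateDesign:
    def test_six_sets_give_63_candidates_each_in_32(self):
        cands = enumerate_stage1(fs.DEFAULT_VARIABLE_SETS)
        assert len(cands) == 63
        for name in fs.DEFAULT_VARIABLE_SETS:
            assert sum(name in combo for combo, _ in cands) == 32

    @pytest.mark.parametrize("m,expect_total,expect_each", [(3, 7, 4), (1, 1, 1)])
    def test_small_set_counts(self, m, expect_total, expect_each):
        sets = {f"S{i}": (f"v{i}",) for i in range(m)}
        cands = enumerate_stage1(sets)
        assert len(cands) == expect_total
        assert sum("S0" in combo for combo, _ in cands) == expect_each

    def test_overlapping_sets_raise(self):
        with pytest.raises(ValueError, match="appears in sets"):
            enumerate_stage1({"A": ("v1",), "B": ("v1", "v2")})

    def test_screen_invariant_to_set_ordering(self, rng):
        mat = _random_matrix(rng, n=50, p=6)
        sets = {"A": ("x0", "x1"), "B": ("x2", "x3"), "C": ("x4", "x5")}
        imp1, _ = stage1_screen(mat, sets)
        imp2, _ = stage1_screen(mat, dict(reversed(list(sets.items()))))
        merged = imp1.set_index("set").join(imp2.set_index("set"), rsuffix="_r")
        np.testing.assert_allclose(merged["w_plus"], merged["w_plus_r"], atol=1e-12)


class TestStandardization:
    def test_vif_orthogonal_and_correlated(self):
        n = 50
        u = np.sin(np.arange(n))
        u = (u - u.mean()) / u.std(ddof=1)
        e = np.cos(3 * np.arange(n))
        e = e - e.mean()
        e -= (e @ u) / (u @ u) * u          # exactly orthogonal to u
        e /= e.std(ddof=1)
        X = pd.DataFrame({"a": u, "b": e})
        assert vif(X, "a") == pytest.approx(1.0, abs=1e-10)
        Xc = pd.DataFrame({"a": u, "b": 0.8 * u + 0.6 * e})  # sample r = 0.8
        assert vif(Xc, "a") == pytest.approx(1 / (1 - 0.64), abs=1e-8)

    def test_vif_lone_predictor_is_one(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 4.0, 8.0]})
        assert vif(X, "a") == 1.0

    def test_perfect_collinearity_raises(self):
        x = np.arange(10, dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            vif(pd.DataFrame({"a": x, "b": 2 * x}), "b")

    def test_partial_sd_lone_predictor(self):
        x = np.array([0, 2.0] * 5)
        x = x * (2.0 / x.std(ddof=1))        # sample SD exactly 2
        X = pd.DataFrame({"a": x})
        assert partial_sd(X, "a", n=10) == pytest.approx(2 * math.sqrt(9 / 8), abs=1e-10)
        assert partial_sd(X, "a", n=10) == pytest.approx(2.1213, abs=1e-4)

    def test_partial_sd_symmetric_for_orthogonal_equal_sd(self):
        n = 8
        u = np.array([1, -1] * 4, dtype=float)
        v = np.array([1, 1, -1, -1] * 2, dtype=float)
        X = pd.DataFrame({"a": u, "b": v})
        assert partial_sd(X, "a") == pytest.approx(partial_sd(X, "b"), abs=1e-12)

    def test_partial_sd_requires_n_gt_p(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="n="):
            partial_sd(X, "a")

    def test_standardized_coefficients_affine_invariant(self, rng):
        mat = _random_matrix(rng, n=60, p=3)
        fit = fit_glm(mat, ["x0", "x1", "x2"])
        sc = standardized_coefficients(fit, mat)
        X2 = mat.X.copy()
        X2["x1"] = 5.0 * X2["x1"] - 2.0
        mat2 = _matrix(X2, mat.y.to_numpy())
        sc2 = standardized_coefficients(fit_glm(mat2, ["x0", "x1", "x2"]), mat2)
        np.testing.assert_allclose(sc.to_numpy(), sc2.to_numpy(), atol=1e-8)


class TestStage2Averaging:
    def test_lone_variable_inherits_model_coefficient(self, rng):
        mat = _random_matrix(rng, n=40, p=1)
        avg = stage2_average(mat, ["x0"])
        fit = fit_glm(mat, ["x0"])
        expected = standardized_coefficients(fit, mat)["x0"]
        row = avg.table.set_index("variable").loc["x0"]
        assert row["coefficient"] == pytest.approx(expected, abs=1e-12)

    def test_max_magnitude_variable_has_importance_one(self, rng):
        mat = _random_matrix(rng, n=60, p=3)
        fit = fit_glm(mat, ["x0", "x1", "x2"])
        sc = standardized_coefficients(fit, mat)
        imp = sc.abs() / sc.abs().max()
        assert imp.max() == 1.0
        assert (imp <= 1.0).all()

    def test_weights_sum_to_one_and_null_included(self, rng):
        mat = _random_matrix(rng, n=60, p=3)
        avg = stage2_average(mat, ["x0", "x1", "x2"])
        assert avg.n_models == 8  # 2^3 subsets incl. null
        assert abs(sum(f.weight for f in avg.fits) - 1.0) < 1e-12

    def test_variable_cap_refuses(self, rng):
        mat = _random_matrix(rng, n=60, p=3)
        with pytest.raises(ValueError, match="variable_cap"):
            stage2_average(mat, [f"v{i}" for i in range(25)])

    def test_strong_variable_outranks_null_variables(self):
        rng = np.random.default_rng(5)
        imps = []
        for rep in range(20):
            n = 73
            X = pd.DataFrame(
                rng.standard_normal((n, 4)) * 0.5,
                columns=["strong", "n1", "n2", "n3"],
                index=[f"s{i}" for i in range(n)],
            )
            y = rng.poisson(np.exp(1.8 + 0.9 * X["strong"]))
            avg = stage2_average(_matrix(X, y), list(X.columns))
            imps.append(avg.table.set_index("variable")["importance"])
        mean_imp = pd.concat(imps, axis=1).mean(axis=1)
        assert mean_imp["strong"] > mean_imp[["n1", "n2", "n3"]].max()

    def test_dispersion_near_one_for_poisson_truth(self):
        rng = np.random.default_rng(9)
        disp = []
        for rep in range(30):
            X = pd.DataFrame({"x0": rng.standard_normal(73) * 0.5},
                             index=[f"s{i}" for i in range(73)])
            y = rng.poisson(np.exp(1.5 + 0.6 * X["x0"]))
            disp.append(fit_glm(_matrix(X, y), ["x0"]).dispersion)
        assert np.mean(disp) == pytest.approx(1.0, abs=0.15)
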