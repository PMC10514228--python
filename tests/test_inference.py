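"""Fit statistic, fit indices, Wald tests, sex analyses, model ladder."""
import numpy as np
import pytest

from twinpath import (GROUPS, GeneratingModel, LadderEntry, PhenotypeCodebook,
                      build_cpm_spec, build_ipm_spec, fit_indices, fit_wls,
                      model_ladder, polychoric_matrix, preset_ladder,
                      sandwich_covariance, saturated_spec, sex_covariate_adjustment,
                      sex_difference_test, simulate_dataset, univariate_ace_spec,
                      wald_test)
from twinpath import test_statistic as overall_fit_test
from twinpath.estimation import population_moments
from tests.conftest import ipm_generator
from tests.test_simulate import univariate_generator


class TestTestStatistic:
    def test_saturated_spec_is_exact_with_zero_df(self, shrunken_generator, codebook5):
        ds = simulate_dataset(shrunken_generator.scaled(0.2), seed=13)
        moms = [polychoric_matrix(ds, g) for g in GROUPS]
        fit = fit_wls(saturated_spec(codebook5.names), moms, weight_mode="identity")
        assert fit.f_min < 1e-12
        T, df, p = overall_fit_test(fit)
        assert (T, df, p) == (0.0, 0, None)

    def test_misspecified_model_rejected_at_scale(self, codebook3):
        """Fitting a no-genetics model to strongly additive data must reject."""
        decomposition = {"pom": (0.6, 0.2, 0.0, 0.0), "cannabis": (0.5, 0.3, 0.0, 0.0),
                         "cocaine": (0.55, 0.25, 0.0, 0.0)}
        prev = {"pom": 0.3, "cannabis": 0.6, "cocaine": 0.2}
        gen = ipm_generator(codebook3, decomposition, prev,
                            {g: 5000 for g in GROUPS})
        ds = simulate_dataset(gen, seed=31)
        moms = [polychoric_matrix(ds, g, acov="bootstrap", n_boot=200, seed=5)
                for g in GROUPS]
        no_a = build_ipm_spec(codebook3, 0, 1, 1,
                              drops=[f"as:{n}" for n in codebook3.names])
        fit = fit_wls(no_a, moms, n_starts=3)
        T, df, p = overall_fit_test(fit)
        assert p < 1e-6


class TestFitIndices:
    def test_published_first_row_convention(self):
        """chi2(399) = 424.584 at N = 7164, G = 4 gives RMSEA 0.006."""
        fi = fit_indices(424.584, 399, 7164, 4, 5000.0, 440)
        assert round(fi.rmsea, 3) == 0.006
        assert fi.meets_rmsea

    def test_perfect_fit_floor(self):
        fi = fit_indices(399.0, 399, 7164, 4, 5000.0, 440)
        assert fi.rmsea == 0.0
        assert fi.cfi == 1.0

    def test_degenerate_baseline_guards(self):
        fi = fit_indices(100.0, 120, 1000, 4, 100.0, 120)
        assert fi.cfi == 1.0

    def test_rmsea_monotone_in_t(self):
        vals = [fit_indices(t, 100, 2000, 4, 900.0, 120).rmsea
                for t in (80, 100, 130, 200, 400)]
        assert vals == sorted(vals)
        assert vals[0] == 0.0

    def test_cfi_bounded(self):
        for t in (50.0, 150.0, 900.0, 5000.0):
            fi = fit_indices(t, 100, 2000, 4, 800.0, 120)
            assert 0.0 <= fi.cfi <= 1.0

    def test_zero_df_flagged_undefined(self):
        fi = fit_indices(0.0, 0, 1000, 4, 100.0, 10)
        assert fi.p_value is None and np.isnan(fi.rmsea)


class TestWald:
    @pytest.fixture(scope="class")
    def converged_fit(self, calib3_generator, calib3_spec):
        ds = simulate_dataset(calib3_generator, seed=77)
        moms = [polychoric_matrix(ds, g, acov="bootstrap", n_boot=200, seed=2)
                for g in GROUPS]
        fit = fit_wls(calib3_spec, moms, n_starts=3, seed=0)
        sandwich_covariance(fit)
        return fit

    def test_satisfied_restriction_gives_zero(self, converged_fit):
        theta = converged_fit.theta
        R = np.zeros((1, len(theta)))
        R[0, 0] = 1.0
        res = wald_test(converged_fit, R, r=[theta[0]])
        assert res.W == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_single_restriction_is_squared_z(self, converged_fit):
        k = converged_fit.spec.param_index("a1:cocaine")
        se = np.sqrt(converged_fit.cov[k, k])
        res = wald_test(converged_fit, ["a1:cocaine"])
        assert res.W == pytest.approx((converged_fit.theta[k] / se) ** 2, rel=1e-10)

    def test_invariant_under_restriction_permutation(self, converged_fit):
        names = ["a1:pom", "e1:cocaine"]
        w1 = wald_test(converged_fit, names)
        w2 = wald_test(converged_fit, names[::-1])
        assert w1.W == pytest.approx(w2.W, rel=1e-10)

    def test_rank_deficient_r_rejected(self, converged_fit):
        R = np.zeros((2, converged_fit.spec.n_free))
        R[0, 0] = R[1, 0] = 1.0
        with pytest.raises(ValueError, match="row rank"):
            wald_test(converged_fit, R)


class TestSexAnalyses:
    def test_single_sex_dataset_rejected(self):
        gm = univariate_generator(0.4, 0.2, n=500, groups=("MZM", "DZM"))
        ds = simulate_dataset(gm, seed=1)
        with pytest.raises(ValueError, match="male and female"):
            sex_difference_test(ds, "x")

    def test_power_direction_for_true_sex_difference(self):
        """W is larger on average when male and female a-paths truly differ
        (31% vs 51%, the published cannabis-style contrast)."""
        sizes = {g: 3000 for g in GROUPS}
        w_eq, w_diff = [], []
        for seed in range(8):
            gm_m = univariate_generator(0.31, 0.33, n=3000)
            gm_f = univariate_generator(0.51, 0.27, n=3000)
            ds = simulate_dataset(gm_m, seed=seed, gm_female=gm_f)
            w_diff.append(sex_difference_test(ds, "x").wald.W)
            ds_eq = simulate_dataset(univariate_generator(0.4, 0.3, n=3000),
                                     seed=100 + seed)
            w_eq.append(sex_difference_test(ds_eq, "x").wald.W)
        assert np.median(w_diff) > np.median(w_eq)

    def test_covariate_beta_zero_leaves_decomposition_unchanged(self):
        ds = simulate_dataset(univariate_generator(0.4, 0.2, tau=0.4, n=2000), seed=5)
        spec = univariate_ace_spec("x")
        adj = sex_covariate_adjustment(ds, spec)
        moms = [polychoric_matrix(ds, g) for g in GROUPS]
        plain = fit_wls(spec, moms)
        assert np.allclose(adj.fit.decomposition.proportions,
                           plain.decomposition.proportions, atol=1e-8)
        assert abs(adj.effects["beta"].iloc[0]) < 0.1

    def test_covariate_recovers_threshold_shift(self):
        """A generated male-female threshold gap maps to beta of the right
        sign and the stated variance-explained formula."""
        gm_m = univariate_generator(0.4, 0.2, tau=0.0, n=4000)
        gm_f = univariate_generator(0.4, 0.2, tau=0.46, n=4000)
        ds = simulate_dataset(gm_m, seed=8, gm_female=gm_f)
        adj = sex_covariate_adjustment(ds, univariate_ace_spec("x"))
        beta = adj.effects["beta"].iloc[0]
        assert beta > 0  # males endorse more
        assert beta == pytest.approx(0.46, abs=0.1)
        v_s = 0.25
        assert adj.effects["var_explained"].iloc[0] == pytest.approx(
            beta**2 * v_s / (beta**2 * v_s + 1), abs=1e-6)


class TestLadder:
    def test_preset_rows_named_and_ordered_like_published_table(self):
        names = [e.name for e in preset_ladder()]
        assert names == [
            "IP 2-2-2", "IP 2-2-1", "IP 2-1-2", "IP 1-2-2", "IP 1-2-1",
            "IP 1-1-2", "IP 0-2-2", "IP 1-1-1", "IP 0-1-1", "IP 1-0-1",
            "IP 1-1-0", "IP 0-0-1", "IP 1-0-0", "IP 1-0-1 (reduced)",
            "CP-1", "CP-1 (reduced)"]
        drops = dict(preset_ladder()[13].drop)["IP 1-0-1"]
        assert len(drops) == 17  # published reduced-model Wald df

    def test_toy_ladder_nesting_and_report(self, calib3_generator, codebook3):
        ds = simulate_dataset(calib3_generator, seed=55)
        ipm = build_ipm_spec(codebook3, 1, 1, 1)
        cpm = build_cpm_spec(codebook3)
        entries = [
            LadderEntry("IP 1-1-1", ipm),
            LadderEntry("IP 1-0-1", build_ipm_spec(codebook3, 1, 0, 1),
                        ("IP 1-1-1",),
                        {"IP 1-1-1": ipm.general_factor_params("c", 0)}),
            LadderEntry("CP-1", cpm),
        ]
        res = model_ladder(ds, entries, seed=3, n_boot=200)
        frame = res.to_frame()
        assert list(frame["model"]) == ["IP 1-1-1", "IP 1-0-1", "CP-1"]
        fits = {r.name: r.fit for r in res.rows}
        # the common pathway model is nested in the one-factor-per-component
        # independent pathway model, so it can never fit better
        assert fits["CP-1"].f_min >= fits["IP 1-1-1"].f_min - 1e-10
        assert np.isfinite(frame.loc[1, "wald_chi2"])
        assert res.to_text()

    def test_comparison_skipped_when_fuller_missing_or_nonconverged(self, codebook3,
                                                                    calib3_generator):
        ds = simulate_dataset(calib3_generator, seed=56)
        entries = [LadderEntry("IP 1-0-1", build_ipm_spec(codebook3, 1, 0, 1),
                               ("ghost",), {"ghost": ("a1:pom",)})]
        res = model_ladder(ds, entries, seed=1, n_boot=100)
        vs, wr, note = res.rows[0].comparisons[0]
        assert wr is None and "not converged" in note
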