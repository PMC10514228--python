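"""Stage-2 WLS fitting, sandwich covariance, and the BCa bootstrap."""
import numpy as np
import pytest

from twinpath import (GROUPS, bootstrap_ci, build_cpm_spec, build_ipm_spec,
                      falconer_estimates, fit_wls, polychoric_matrix,
                      sandwich_covariance, simulate_dataset, univariate_ace_spec)
from twinpath.estimation import population_moments, stacked_gamma
from tests.test_simulate import univariate_generator


def _perturbed_moments(spec, theta, noise, seed):
    moms = population_moments(spec, theta, variances=1e-4)
    rng = np.random.default_rng(seed)
    for gm in moms:
        gm.values = gm.values + noise * rng.standard_normal(len(gm.values))
    return moms


class TestFitWls:
    def test_exactly_identified_univariate_equals_falconer(self):
        spec = univariate_ace_spec("x")
        moms = population_moments(spec, [np.sqrt(0.6), np.sqrt(0.2)])
        for gm, v in zip(moms, (0.8, 0.8, 0.5, 0.5)):
            assert gm.values[0] == pytest.approx(v)
        fit = fit_wls(spec, moms, weight_mode="identity")
        oracle = falconer_estimates(0.8, 0.5)
        assert fit.theta[0] ** 2 == pytest.approx(oracle.a2, abs=1e-8)
        assert fit.theta[1] ** 2 == pytest.approx(oracle.c2, abs=1e-8)
        assert fit.f_min < 1e-12

    def test_not_identified_raises_before_optimizing(self, codebook3):
        spec = build_ipm_spec(codebook3, 2, 2, 2)  # 21 free parameters
        moms = population_moments(spec, spec.default_start() * 0.5, groups=("MZM",))
        with pytest.raises(ValueError, match="not identified"):
            fit_wls(spec, moms, weight_mode="identity")  # only 9 moments

    def test_single_zygosity_not_separable(self):
        spec = univariate_ace_spec("x")
        moms = population_moments(spec, [0.6, 0.3], groups=("MZM", "MZF"))
        with pytest.raises(ValueError, match="MZ and DZ"):
            fit_wls(spec, moms)

    def test_nested_model_never_fits_better(self, codebook3):
        """Adding free parameters cannot increase the minimized discrepancy."""
        full = build_ipm_spec(codebook3, 1, 1, 1)
        nested = build_ipm_spec(codebook3, 1, 0, 1,
                                drops=[f"cs:{n}" for n in codebook3.names])
        theta = full.default_start() * 0.8
        moms = _perturbed_moments(full, theta, 0.03, seed=4)
        fit_n = fit_wls(nested, moms, weight_mode="identity", n_starts=4)
        emb = np.zeros(full.n_free)
        for i, name in enumerate(nested.free_names):
            emb[full.param_index(name)] = fit_n.theta[i]
        fit_f = fit_wls(full, moms, weight_mode="identity", n_starts=4,
                        extra_starts=[emb])
        assert fit_f.f_min <= fit_n.f_min + 1e-10

    def test_invariant_to_phenotype_and_twin_ordering(self, shrunken_generator,
                                                      shrunken_spec, codebook5):
        ds = simulate_dataset(shrunken_generator.scaled(0.25), seed=21)
        moms = [polychoric_matrix(ds, g) for g in GROUPS]
        fit = fit_wls(shrunken_spec, moms, seed=0)
        # twin relabelling
        moms_sw = [polychoric_matrix(ds.swap_twins(), g) for g in GROUPS]
        fit_sw = fit_wls(shrunken_spec, moms_sw, seed=0)
        assert np.allclose(fit.theta, fit_sw.theta, atol=1e-8)
        # phenotype reordering
        order = list(codebook5.names)[::-1]
        ds_r = ds.select_phenotypes(order)
        drops = [f"as:{n}" for n in order if n not in ("pom", "sedatives_rx")]
        drops += [f"cs:{n}" for n in order]
        spec_r = build_ipm_spec(codebook5.subset(order), 1, 0, 1, drops=drops)
        fit_r = fit_wls(spec_r, [polychoric_matrix(ds_r, g) for g in GROUPS], seed=0)
        for name in spec_r.free_names:
            assert abs(fit_r.theta[spec_r.param_index(name)]) == pytest.approx(
                abs(fit.theta[shrunken_spec.param_index(name)]), abs=1e-6)

    def test_diagonal_and_full_weights_agree_at_population_moments(self, codebook3):
        spec = build_ipm_spec(codebook3, 1, 0, 1,
                              drops=[f"cs:{n}" for n in codebook3.names])
        theta = spec.canonicalize(spec.default_start() * 0.85)
        moms = population_moments(spec, theta, variances=1e-4)
        for gm in moms:
            gm.acov = np.diag(gm.variances)
        fd = fit_wls(spec, moms, weight_mode="diagonal")
        ff = fit_wls(spec, moms, weight_mode="full")
        assert np.allclose(fd.theta, theta, atol=1e-6)
        assert np.allclose(ff.theta, theta, atol=1e-6)

    def test_f_zero_iff_moments_reproducible(self, codebook3):
        spec = build_ipm_spec(codebook3, 1, 0, 1,
                              drops=[f"cs:{n}" for n in codebook3.names])
        theta = spec.canonicalize(spec.default_start() * 0.85)
        exact = population_moments(spec, theta)
        assert fit_wls(spec, exact, weight_mode="identity").f_min < 1e-12
        noisy = _perturbed_moments(spec, theta, 0.05, seed=8)
        assert fit_wls(spec, noisy, weight_mode="identity").f_min > 1e-6


class TestSandwich:
    def test_full_weight_reduces_to_inverse_information_form(self, codebook3):
        """With W = Gamma^-1 the sandwich collapses to (D' Gamma^-1 D)^-1."""
        spec = build_ipm_spec(codebook3, 1, 0, 1,
                              drops=["as:pom", "as:cannabis", "as:cocaine"]
                              + [f"cs:{n}" for n in codebook3.names])
        theta = spec.canonicalize(spec.default_start() * 0.9)
        moms = _perturbed_moments(spec, theta, 0.01, seed=3)
        rng = np.random.default_rng(0)
        for gm in moms:
            m = len(gm.values)
            A = rng.standard_normal((m, m)) * 0.01
            gm.acov = 1e-4 * np.eye(m) + A @ A.T
        fit = fit_wls(spec, moms, weight_mode="full")
        from twinpath.estimation import _stacked_jacobian, _weight_matrix
        V = sandwich_covariance(fit)
        D = _stacked_jacobian(spec, fit.theta, fit.moments)[fit.mask]
        G = stacked_gamma(fit.moments, fit.mask)
        direct = np.linalg.inv(D.T @ np.linalg.inv(G) @ D)
        assert np.allclose(V, direct, rtol=1e-6, atol=1e-10)

    def test_se_calibration_univariate(self):
        """Sandwich se of the a-path tracks the empirical replicate sd."""
        spec = univariate_ace_spec("x")
        gm = univariate_generator(0.4, 0.2, tau=0.3, n=3000)
        a_hats, ses = [], []
        for seed in range(120):
            ds = simulate_dataset(gm, seed=seed)
            moms = [polychoric_matrix(ds, g) for g in GROUPS]
            fit = fit_wls(spec, moms, n_starts=2, seed=0)
            V = sandwich_covariance(fit)
            a_hats.append(fit.theta[0])
            ses.append(np.sqrt(V[0, 0]))
        assert np.std(a_hats) == pytest.approx(np.mean(ses), rel=0.15)


class TestBootstrap:
    def test_degenerate_resampler_gives_zero_width(self):
        ds = simulate_dataset(univariate_generator(0.4, 0.2, tau=0.5, n=400), seed=2)
        br = bootstrap_ci(ds, univariate_ace_spec("x"), B=100, seed=1,
                         resampler=lambda rng, d: d)
        assert np.allclose(br.lower, br.point, atol=1e-12)
        assert np.allclose(br.upper, br.point, atol=1e-12)

    def test_same_seed_identical_intervals(self):
        ds = simulate_dataset(univariate_generator(0.4, 0.2, tau=0.5, n=300), seed=2)
        b1 = bootstrap_ci(ds, univariate_ace_spec("x"), B=100, seed=9)
        b2 = bootstrap_ci(ds, univariate_ace_spec("x"), B=100, seed=9)
        assert np.array_equal(b1.lower, b2.lower)
        assert np.array_equal(b1.upper, b2.upper)

    def test_small_b_rejected_and_warned(self):
        ds = simulate_dataset(univariate_generator(0.4, 0.2, tau=0.5, n=300), seed=2)
        with pytest.raises(ValueError):
            bootstrap_ci(ds, univariate_ace_spec("x"), B=50, seed=1)
        br = bootstrap_ci(ds, univariate_ace_spec("x"), B=120, seed=1)
        assert any("1000" in w for w in br.warnings)

    def test_interval_brackets_point_for_interior_parameters(self):
        ds = simulate_dataset(univariate_generator(0.45, 0.2, tau=0.0, n=1500), seed=4)
        br = bootstrap_ci(ds, univariate_ace_spec("x"), B=200, seed=3)
        i = br.names.index("specific_a:x")
        assert br.lower[i] <= br.point[i] <= br.upper[i]
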