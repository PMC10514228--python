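"""Structural specs, expectation algebra, standardization, Falconer oracle."""
import numpy as np
import pytest

from twinpath import (PhenotypeCodebook, bivariate_cholesky_spec, build_cpm_spec,
                      build_ipm_spec, expected_correlation_matrix, falconer_estimates,
                      standardize, univariate_ace_spec)
from twinpath.estimation import _stacked_jacobian, _stacked_sigma, population_moments
from twinpath.simulate import atr_codebook


@pytest.fixture(scope="module")
def cb11():
    return atr_codebook()


def random_admissible_theta(spec, seed):
    rng = np.random.default_rng(seed)
    return spec.canonicalize(spec.default_start() * rng.uniform(0.4, 1.0, spec.n_free))


class TestSpecBuilders:
    def test_two_factor_class_pattern_masks(self, cb11):
        spec = build_ipm_spec(cb11, 2, 2, 2, pattern="by_class_tag")
        a1 = spec.general_factor_params("a", 0)
        a2 = spec.general_factor_params("a", 1)
        assert len(a1) == 3 and len(a2) == 8  # prescription vs illicit split
        assert all(n.split(":")[1] in ("pom", "stimulants_rx", "sedatives_rx") for n in a1)

    def test_echelon_identification_counts(self, cb11):
        # second factor loses one loading for identification: p + (p-1) per component
        spec = build_ipm_spec(cb11, 2, 2, 2)
        assert spec.n_free == 3 * (11 + 10) + 2 * 11

    def test_one_one_one_free_parameter_count(self, cb11):
        spec = build_ipm_spec(cb11, 1, 1, 1)
        assert spec.n_free == 3 * 11 + 2 * 11  # 3p general + specific a and c

    def test_reduced_spec_drops(self, cb11):
        from twinpath.inference import _reduced_101_drops
        spec = build_ipm_spec(cb11, 1, 0, 1, drops=_reduced_101_drops(cb11))
        assert len(_reduced_101_drops(cb11)) == 17  # matches the published 17-df drop
        assert "e1:cannabis" not in spec.free_names
        assert "as:pom" in spec.free_names and "as:heroin" not in spec.free_names
        assert "cs:cannabis" in spec.free_names and "cs:pom" not in spec.free_names

    def test_specific_e_cannot_be_dropped(self, cb11):
        with pytest.raises(ValueError, match="specific e"):
            build_ipm_spec(cb11, 1, 1, 1, drops=["es:pom"])

    def test_class_pattern_needs_two_factors(self, cb11):
        with pytest.raises(ValueError):
            build_ipm_spec(cb11, 1, 1, 1, pattern="by_class_tag")

    def test_unknown_drop_rejected(self, cb11):
        with pytest.raises(ValueError, match="unknown"):
            build_ipm_spec(cb11, 1, 1, 1, drops=["a9:pom"])


class TestExpectedCorrelations:
    def test_univariate_ace_cross_twin_entries(self):
        spec = univariate_ace_spec("pom")
        theta = [np.sqrt(0.37), np.sqrt(0.10)]
        mz = expected_correlation_matrix(spec, theta, "MZ")
        dz = expected_correlation_matrix(spec, theta, "DZ")
        assert mz[0, 1] == pytest.approx(0.47)
        assert dz[0, 1] == pytest.approx(0.285)

    def test_specific_only_spec_has_zero_cross_trait(self, codebook3):
        spec = build_ipm_spec(codebook3, 0, 0, 0)
        theta = random_admissible_theta(spec, 0)
        mz = expected_correlation_matrix(spec, theta, "MZ")
        p = 3
        off = ~np.eye(p, dtype=bool)
        assert np.allclose(mz[:p, :p][off], 0.0)        # within cross-trait
        cross = mz[:p, p:]
        assert np.allclose(cross[off], 0.0)             # cross-twin cross-trait
        sa = spec._specifics(theta, "a")
        sc = spec._specifics(theta, "c")
        assert np.allclose(np.diag(cross), sa**2 + sc**2)

    def test_cpm_cross_twin_cross_trait_identity(self):
        cb = PhenotypeCodebook(["u", "v"])
        spec = build_cpm_spec(cb)
        theta = np.zeros(spec.n_free)
        theta[spec.param_index("aF")] = 0.6
        theta[spec.param_index("cF")] = 0.5
        theta[spec.param_index("lam:u")] = 0.7
        theta[spec.param_index("lam:v")] = 0.8
        mz = expected_correlation_matrix(spec, theta, "MZ")
        assert mz[0, 3] == pytest.approx(0.7 * 0.8 * (0.6**2 + 0.5**2))

    @pytest.mark.parametrize("builder,seed", [
        (lambda cb: build_ipm_spec(cb, 2, 2, 2), 1),
        (lambda cb: build_ipm_spec(cb, 1, 1, 1), 2),
        (lambda cb: build_cpm_spec(cb), 3),
    ])
    def test_symmetric_unit_diagonal_psd(self, cb11, builder, seed):
        spec = builder(cb11)
        for s in range(seed, seed + 5):
            theta = random_admissible_theta(spec, s)
            for z in ("MZ", "DZ"):
                m = expected_correlation_matrix(spec, theta, z)
                assert np.allclose(m, m.T)
                assert np.allclose(np.diag(m), 1.0)
                assert np.linalg.eigvalsh(m).min() >= -1e-10

    def test_mz_minus_dz_is_half_the_genetic_block(self, cb11):
        spec = build_ipm_spec(cb11, 1, 1, 1)
        theta = random_admissible_theta(spec, 9)
        p = spec.p
        mz = expected_correlation_matrix(spec, theta, "MZ")[:p, p:]
        dz = expected_correlation_matrix(spec, theta, "DZ")[:p, p:]
        A, _, _, _ = spec.component_matrices(theta)
        assert np.allclose(mz - dz, 0.5 * A, atol=1e-12)

    def test_cpm_nested_in_one_factor_ipm(self, codebook3):
        """Every common pathway solution has an equivalent independent
        pathway representation with loadings lambda * (a_F, c_F, e_F)."""
        cpm = build_cpm_spec(codebook3)
        theta = np.zeros(cpm.n_free)
        aF, cF = 0.6, 0.5
        eF = np.sqrt(1 - aF**2 - cF**2)
        lam = [0.7, 0.8, 0.5]
        theta[cpm.param_index("aF")] = aF
        theta[cpm.param_index("cF")] = cF
        for n, l in zip(codebook3.names, lam):
            theta[cpm.param_index(f"lam:{n}")] = l
            theta[cpm.param_index(f"as:{n}")] = 0.3
        ipm = build_ipm_spec(codebook3, 1, 1, 1)
        ti = np.zeros(ipm.n_free)
        for n, l in zip(codebook3.names, lam):
            ti[ipm.param_index(f"a1:{n}")] = l * aF
            ti[ipm.param_index(f"c1:{n}")] = l * cF
            ti[ipm.param_index(f"e1:{n}")] = l * eF
            ti[ipm.param_index(f"as:{n}")] = 0.3
        for z in ("MZ", "DZ"):
            assert np.allclose(expected_correlation_matrix(cpm, theta, z),
                               expected_correlation_matrix(ipm, ti, z), atol=1e-12)

    def test_unit_variance_violation_rejected(self):
        spec = univariate_ace_spec("x")
        with pytest.raises(ValueError, match="unit"):
            expected_correlation_matrix(spec, [0.9, 0.9], "MZ")


class TestJacobian:
    @pytest.mark.parametrize("builder,seed", [
        (lambda cb: build_ipm_spec(cb, 2, 2, 2), 10),
        (lambda cb: build_cpm_spec(cb), 11),
        (lambda cb: bivariate_cholesky_spec("pom", "heroin"), 12),
        (lambda cb: univariate_ace_spec("pom"), 13),
    ])
    def test_analytic_jacobian_matches_central_differences(self, cb11, builder, seed):
        spec = builder(cb11)
        theta = random_admissible_theta(spec, seed)
        moms = population_moments(spec, theta)
        J = _stacked_jacobian(spec, theta, moms)
        eps = 1e-6
        for q in range(spec.n_free):
            tp, tm = theta.copy(), theta.copy()
            tp[q] += eps
            tm[q] -= eps
            col = (_stacked_sigma(spec, tp, moms) - _stacked_sigma(spec, tm, moms)) / (2 * eps)
            assert np.allclose(J[:, q], col, atol=1e-6)


class TestStandardize:
    def test_cpm_through_factor_shares_match_printed_percentages(self, cb11):
        """lambda^2 x factor shares reproduce the published through-factor
        variance percentages for heroin (38/27/15) and opioid misuse (12/8/5)."""
        spec = build_cpm_spec(cb11)
        theta = np.zeros(spec.n_free)
        theta[spec.param_index("aF")] = np.sqrt(0.47)
        theta[spec.param_index("cF")] = np.sqrt(0.34)
        for n in cb11.names:
            theta[spec.param_index(f"lam:{n}")] = 0.5
        theta[spec.param_index("lam:heroin")] = np.sqrt(0.80)
        theta[spec.param_index("lam:pom")] = np.sqrt(0.25)
        dec = standardize(spec, theta)
        assert dec[("heroin", "general_a")] == pytest.approx(0.376, abs=1e-9)
        assert round(100 * dec[("heroin", "general_a")]) == 38
        assert round(100 * dec[("heroin", "general_c")]) == 27
        assert round(100 * dec[("heroin", "general_e")]) == 15
        assert dec[("pom", "general_c")] == pytest.approx(0.085, abs=1e-9)
        # 0.085 prints as 8% (half-to-even at the exact .5 boundary)
        assert (round(round(100 * dec[("pom", "general_a")], 9)),
                round(round(100 * dec[("pom", "general_c")], 9)),
                round(round(100 * dec[("pom", "general_e")], 9))) == (12, 8, 5)

    def test_proportions_sum_to_one(self, cb11):
        for seed, builder in ((0, lambda: build_ipm_spec(cb11, 1, 1, 1)),
                              (1, lambda: build_cpm_spec(cb11))):
            spec = builder()
            dec = standardize(spec, random_admissible_theta(spec, seed))
            assert np.allclose(dec.proportions.sum(axis=1), 1.0, atol=1e-8)
            assert dec.proportions.min() >= 0


class TestFalconer:
    @pytest.mark.parametrize("r_mz,r_dz,expect", [
        (0.8, 0.5, (0.6, 0.2, 0.2)),
        (0.47, 0.285, (0.37, 0.10, 0.53)),
        (0.5, 0.25, (0.5, 0.0, 0.5)),
    ])
    def test_closed_form(self, r_mz, r_dz, expect):
        res = falconer_estimates(r_mz, r_dz)
        assert (res.a2, res.c2, res.e2) == pytest.approx(expect)
        assert not res.boundary

    def test_negative_component_flagged_not_truncated(self):
        res = falconer_estimates(0.3, 0.05)
        assert res.c2 == pytest.approx(-0.2)
        assert res.boundary
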