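"""Stage-1 estimators: thresholds, tetrachorics, group moment matrices."""
import warnings

import numpy as np
import pytest

from twinpath import (GroupMoments, estimate_threshold, polychoric_matrix,
                      simulate_dataset, tetrachoric_ml, tetrachoric_oracle)
from twinpath._bvn import bvn_cdf
from tests.test_simulate import univariate_generator


class TestBvnCdf:
    def test_matches_generic_integrator(self):
        """Owen's-T route vs scipy's Genz integrator (independent oracle)."""
        from scipy.stats import multivariate_normal
        rng = np.random.default_rng(1)
        for _ in range(50):
            h, k = rng.uniform(-3, 3, 2)
            r = rng.uniform(-0.995, 0.995)
            ref = multivariate_normal(mean=[0, 0], cov=[[1, r], [r, 1]]).cdf([h, k])
            assert bvn_cdf(h, k, r) == pytest.approx(ref, abs=5e-8)

    def test_closed_form_at_zero_thresholds(self):
        assert bvn_cdf(0.0, 0.0, 0.5) == pytest.approx(0.25 + np.arcsin(0.5) / (2 * np.pi))


class TestThreshold:
    def test_balanced_vector_gives_zero(self):
        x = np.array([0.0] * 50 + [1.0] * 50)
        tau, se = estimate_threshold(x)
        assert tau == 0.0

    def test_printed_prevalence_quantile(self):
        x = np.array([1.0] * 779 + [0.0] * 9221)
        tau, se = estimate_threshold(x)
        assert tau == pytest.approx(1.4193, abs=5e-4)

    def test_degenerate_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_threshold(np.zeros(100))

    def test_delta_method_se_matches_simulation(self):
        """Empirical sd of tau-hat within 15% of the delta-method se at n=1e4."""
        rng = np.random.default_rng(4)
        p, n = 0.0779, 10_000
        taus = []
        for _ in range(300):
            x = (rng.random(n) < p).astype(float)
            taus.append(estimate_threshold(x)[0])
        _, se = estimate_threshold((np.arange(n) < round(p * n)).astype(float))
        assert np.std(taus) == pytest.approx(se, rel=0.15)


class TestTetrachoricML:
    def test_independence_table(self):
        res = tetrachoric_ml([[25, 25], [25, 25]])
        assert res.r == pytest.approx(0.0, abs=1e-7)

    def test_closed_form_half(self):
        # zero thresholds with P(++) = 1/4 + arcsin(rho)/(2pi) = 1/3 at rho = 0.5
        res = tetrachoric_ml([[400, 200], [200, 400]])
        assert res.r == pytest.approx(0.5, abs=1e-9)
        assert not res.corrected

    def test_perfect_concordance_clamped_and_flagged(self):
        res = tetrachoric_ml([[500, 0], [0, 500]])
        assert res.corrected
        assert res.r > 0.999

    def test_negative_counts_rejected_weights_allowed(self):
        with pytest.raises(ValueError):
            tetrachoric_ml([[10, -1], [5, 5]])
        assert np.isfinite(tetrachoric_ml([[10.5, 4.2], [3.3, 9.9]]).r)

    def test_agrees_with_grid_search_oracle(self):
        """ML solve vs brute-force grid/integration oracle on random tables."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            p1, p2 = rng.uniform(0.05, 0.95, 2)
            rho = rng.uniform(-0.9, 0.9)
            n = 1000
            p11 = float(bvn_cdf(*-np.array([_tau(p1), _tau(p2)]), rho))
            tab = np.round(n * np.array([[p11, p1 - p11],
                                         [p2 - p11, 1 - p1 - p2 + p11]]))
            tab = np.maximum(tab, 1)
            assert tetrachoric_ml(tab).r == pytest.approx(tetrachoric_oracle(tab), abs=1e-6)


def _tau(p):
    from scipy.special import ndtri
    return -ndtri(p)


class TestPolychoricMatrix:
    def test_twin_order_and_row_order_invariance(self, shrunken_generator):
        ds = simulate_dataset(shrunken_generator.scaled(0.2), seed=3)
        perm = np.random.default_rng(0).permutation(ds.n_pairs)
        shuffled = ds.subset_pairs(perm)
        for g in ("MZM", "DZM"):
            ref = polychoric_matrix(ds, g)
            assert np.allclose(ref.values, polychoric_matrix(ds.swap_twins(), g).values,
                               equal_nan=True)
            assert np.allclose(ref.values, polychoric_matrix(shuffled, g).values,
                               equal_nan=True)

    def test_missing_group_rejected(self, shrunken_generator):
        ds = simulate_dataset(shrunken_generator.scaled(0.05), seed=3)
        sub = ds.subset_pairs(ds.groups != "MZM")
        with pytest.raises(ValueError, match="not present"):
            polychoric_matrix(sub, "MZM")

    def test_degenerate_phenotype_dropped_or_strict_error(self):
        gm = univariate_generator(0.3, 0.2, tau=-8.0, n=200, groups=("MZM", "DZM"))
        ds = simulate_dataset(gm, seed=1)  # everyone endorses
        with pytest.warns(UserWarning, match="dropped"):
            res = polychoric_matrix(ds, "MZM")
        assert res.dropped == ("x",)
        assert np.isnan(res.values).all()
        with pytest.raises(ValueError, match="degenerate"):
            polychoric_matrix(ds, "MZM", strict=True)

    def test_corr_matrix_blocks(self, shrunken_generator):
        ds = simulate_dataset(shrunken_generator.scaled(0.3), seed=9)
        gm = polychoric_matrix(ds, "MZF")
        p = len(gm.phenotypes)
        c = gm.corr
        assert np.allclose(c[:p, :p], c[p:, p:], equal_nan=True)  # twin blocks equal
        assert np.allclose(c, c.T, equal_nan=True)
        assert np.all(np.diag(c) == 1.0)
        finite = c[np.isfinite(c)]
        assert finite.min() >= -1 and finite.max() <= 1

    def test_json_round_trip(self, shrunken_generator, tmp_path):
        ds = simulate_dataset(shrunken_generator.scaled(0.1), seed=2)
        gm = polychoric_matrix(ds, "DZF")
        path = tmp_path / "m.json"
        gm.to_json(path)
        back = GroupMoments.from_json(path)
        assert back.group == gm.group
        assert np.allclose(back.values, gm.values, equal_nan=True)
        assert np.allclose(back.corr, gm.corr, equal_nan=True)

    def test_bootstrap_acov_consistent_with_information(self, shrunken_generator):
        """Bootstrap moment variances track the analytic (information) ones."""
        ds = simulate_dataset(shrunken_generator.scaled(0.5), seed=6)
        gm = polychoric_matrix(ds, "MZM", acov="bootstrap", n_boot=300, seed=1)
        bvar = np.diag(gm.acov)
        ok = np.isfinite(bvar) & np.isfinite(gm.variances)
        ratio = bvar[ok] / gm.variances[ok]
        assert 0.5 < np.median(ratio) < 2.0
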