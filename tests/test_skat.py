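"""SKAT-O statistic algebra, null model, PCA, permutation calibration."""

from itertools import combinations

import numpy as np
import pytest

from exomod.skat import (
    SkatConfig,
    _prepare_gene,
    adaptive_maf_threshold,
    fit_null_model,
    genotype_pca,
    skat_o_test,
    skat_q,
    skat_weights,
)
from exomod.datatypes import GenotypeMatrix, MISSING


def rare_genotypes(rng, n, m, carriers=(1, 3)):
    g = np.zeros((n, m), dtype=np.int16)
    for j in range(m):
        k = int(rng.integers(carriers[0], carriers[1] + 1))
        g[rng.choice(n, size=k, replace=False), j] = 1
    return g


class TestAdaptiveThreshold:
    @pytest.mark.parametrize(
        "n,expected",
        [(82, 0.0780868809), (79, 0.0795557284), (59, 0.0920574618),
         (81, 0.0785674201), (84, 0.0771516750), (114, 0.0662266179),
         (50, 0.1)],
    )
    def test_values(self, n, expected):
        assert adaptive_maf_threshold(n) == pytest.approx(expected, abs=1e-9)
        assert adaptive_maf_threshold(n) == pytest.approx(1 / np.sqrt(2 * n), abs=1e-15)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            adaptive_maf_threshold(1)


class TestNullModel:
    def test_balanced_intercept_only(self):
        y = np.array([1.0] * 10 + [0.0] * 10)
        null = fit_null_model(y)
        assert np.allclose(null.mu, 0.5, atol=1e-8)
        assert np.allclose(null.weights, 0.25, atol=1e-8)

    def test_residuals_sum_to_zero(self, rng):
        y = (rng.random(60) < 0.4).astype(float)
        cov = rng.normal(size=(60, 3))
        null = fit_null_model(y, cov)
        assert abs(null.residuals.sum()) < 1e-8

    def test_separation_falls_back_with_warning(self):
        y = np.array([1.0] * 8 + [0.0] * 8)
        cov = y.copy()  # covariate identical to phenotype: separation
        with pytest.warns(RuntimeWarning, match="ridge"):
            null = fit_null_model(y, cov)
        assert null.method == "ridge"
        assert np.all((null.mu > 0) & (null.mu < 1))

    def test_rank_deficient_covariates_rejected(self):
        y = np.array([1.0, 0.0] * 5)
        cov = np.ones((10, 1))  # collinear with the intercept
        with pytest.raises(ValueError, match="rank"):
            fit_null_model(y, cov)


class TestGenotypePca:
    def _matrix(self, dosages):
        n, m = dosages.shape
        return GenotypeMatrix(
            [f"S{i}" for i in range(n)],
            [f"chr1:{100 + j}:A:G" for j in range(m)],
            dosages,
        )

    def test_two_clusters_separate_on_pc1(self, rng):
        a = rng.binomial(2, 0.9, size=(15, 40))
        b = rng.binomial(2, 0.1, size=(15, 40))
        m = self._matrix(np.vstack([a, b]).astype(np.int16))
        scores = genotype_pca(m, 2)
        pc1 = scores[:, 0]
        assert (pc1[:15].min() > pc1[15:].max()) or (pc1[:15].max() < pc1[15:].min())

    def test_scores_orthogonal(self, rng):
        m = self._matrix(rng.binomial(2, 0.3, size=(25, 60)).astype(np.int16))
        scores = genotype_pca(m, 4)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_k_zero_is_empty_block(self, rng):
        m = self._matrix(rng.binomial(2, 0.3, size=(10, 5)).astype(np.int16))
        assert genotype_pca(m, 0).shape == (10, 0)

    def test_constant_matrix_rejected(self):
        m = self._matrix(np.zeros((10, 5), dtype=np.int16))
        with pytest.raises(ValueError):
            genotype_pca(m, 1)

    def test_deterministic_including_sign(self, rng):
        m = self._matrix(rng.binomial(2, 0.2, size=(20, 30)).astype(np.int16))
        s1, s2 = genotype_pca(m, 3), genotype_pca(m, 3)
        assert np.array_equal(s1, s2)


class TestSkatStatistic:
    def test_limiting_cases_match_direct_computation(self, rng):
        # rho = 0 is the weighted variance-component score; rho = 1 the
        # weighted burden score -- both recomputed independently.
        n = 40
        g_raw = rare_genotypes(rng, n, 5)
        y = np.array([1.0] * 20 + [0.0] * 20)
        cfg = SkatConfig(n_permutations=100, seed=1)
        res = skat_o_test(g_raw, y, None, cfg, rng=np.random.default_rng(0))
        g, maf = _prepare_gene(g_raw, cfg, adaptive_maf_threshold(n))
        w = skat_weights(maf, cfg.weight_beta)
        r = y - y.mean()
        s = g.T @ r
        q_skat = float(np.sum(w ** 2 * s ** 2))
        q_burden = float(np.sum(w * s) ** 2)
        assert res.q_rho[0.0] == pytest.approx(q_skat, abs=1e-10)
        assert res.q_rho[1.0] == pytest.approx(q_burden, abs=1e-10)

    def test_rho_one_equal_weights_is_allele_count_burden(self, rng):
        # With flat weights the burden limit is the squared score of the
        # simple allele-count collapsing test, (1' G' r)^2.
        n = 30
        g_raw = rare_genotypes(rng, n, 4)
        y = np.array([1.0] * 15 + [0.0] * 15)
        cfg = SkatConfig(n_permutations=100, seed=1, weight_beta=(1.0, 1.0))
        res = skat_o_test(g_raw, y, None, cfg, rng=np.random.default_rng(0))
        g, _ = _prepare_gene(g_raw, cfg, adaptive_maf_threshold(n))
        r = y - y.mean()
        direct = float((g.sum(axis=1) @ r) ** 2)
        assert res.q_rho[1.0] == pytest.approx(direct, abs=1e-10)

    def test_single_variant_collapses_grid(self, rng):
        n = 30
        g = np.zeros((n, 1), dtype=np.int16)
        g[[2, 11], 0] = 1
        y = np.array([1.0] * 15 + [0.0] * 15)
        cfg = SkatConfig(n_permutations=200, seed=1, min_rare_variants=1)
        res = skat_o_test(g, y, None, cfg, rng=np.random.default_rng(1))
        q = np.array(list(res.q_rho.values()))
        assert np.ptp(q) <= 1e-10 * max(q.max(), 1.0)

    def test_common_variants_filtered_out(self, rng):
        n = 30
        g = rng.binomial(2, 0.5, size=(n, 4)).astype(np.int16)
        y = np.array([1.0] * 15 + [0.0] * 15)
        cfg = SkatConfig(n_permutations=100, seed=0)
        assert skat_o_test(g, y, None, cfg, rng=np.random.default_rng(2)) is None

    def test_low_call_rate_variants_dropped(self, rng):
        n = 40
        g = rare_genotypes(rng, n, 3)
        g[: int(0.2 * n), 1] = MISSING  # call rate 0.8 < 0.9 cutoff
        y = np.array([1.0] * 20 + [0.0] * 20)
        cfg = SkatConfig(n_permutations=100, seed=0)
        res = skat_o_test(g, y, None, cfg, rng=np.random.default_rng(3))
        assert res.n_rare == 2


class TestPermutationCalibration:
    def test_exhaustive_equals_enumeration_oracle(self, rng):
        n = 6
        g_raw = np.zeros((n, 3), dtype=np.int16)
        g_raw[0, 0] = 1
        g_raw[4, 1] = 1
        g_raw[2, 2] = 1
        g_raw[5, 0] = 1
        y = np.array([1.0] * 3 + [0.0] * 3)
        cfg = SkatConfig(n_permutations=100, seed=0, min_rare_variants=1)
        res = skat_o_test(g_raw, y, None, cfg, exhaustive=True)
        assert res.n_perm == 20

        g, maf = _prepare_gene(g_raw, cfg, adaptive_maf_threshold(n))
        w = skat_weights(maf, cfg.weight_beta)
        rhos = cfg.rho_grid
        assigns = list(combinations(range(n), 3))

        def q_of(y_vec):
            r = y_vec - y_vec.mean()
            s = g.T @ r
            qs, qb = float(np.sum(w ** 2 * s ** 2)), float(np.sum(w * s) ** 2)
            return {rho: (1 - rho) * qs + rho * qb for rho in rhos}

        q_all = []
        for subset in assigns:
            y_vec = np.zeros(n)
            y_vec[list(subset)] = 1.0
            q_all.append(q_of(y_vec))

        def min_p(qd):
            return min(
                np.mean([qa[rho] >= qd[rho] for qa in q_all]) for rho in rhos
            )

        m_obs = min_p(q_of(y))
        oracle = np.mean([min_p(qd) <= m_obs for qd in q_all])
        assert res.p_empirical == oracle

    def test_p_resolution_is_permutation_count(self, rng):
        # An overwhelming signal pins p to its resolution floor 1/(1+B);
        # doubling B moves it by less than 2/(1+B).
        n = 50
        g = np.zeros((n, 6), dtype=np.int16)
        for j in range(6):
            g[rng.choice(25, size=4, replace=False), j] = 1  # carriers all cases
        y = np.array([1.0] * 25 + [0.0] * 25)
        ps = {}
        for b in (1_000, 2_000):
            cfg = SkatConfig(n_permutations=b, seed=9)
            res = skat_o_test(g, y, None, cfg, rng=np.random.default_rng(9))
            ps[b] = res.p_empirical
        assert ps[1_000] == pytest.approx(1 / 1_001)
        assert ps[2_000] == pytest.approx(1 / 2_001)
        assert abs(ps[1_000] - ps[2_000]) <= 2 / 1_001
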