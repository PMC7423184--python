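"""SNP z statistic, gene aggregation, permutation machinery."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from exomod.datatypes import CohortDesign, GenotypeMatrix, MISSING, VariantSite
from exomod.differentiation import (
    DiffConfig,
    _t_from_counts,
    gene_diff_statistic,
    permutation_p,
    run_differentiation,
    snp_z,
    snp_z_site,
    gene_permutation_test,
)


class TestSnpZ:
    def test_closed_form_value(self):
        # p_A = 5/50, p_B = 0/50, F = 0:
        # z = 0.1 / sqrt(0.05 * 0.95 * (1/50 + 1/50)) = 2.2941...
        z = snp_z(5, 50, 0, 50)
        assert z == pytest.approx(0.1 / np.sqrt(0.05 * 0.95 * 0.04), rel=1e-9)
        assert z == pytest.approx(2.294157, abs=1e-6)

    def test_equal_frequencies_give_zero(self):
        assert snp_z(10, 40, 10, 40) == 0.0

    def test_fixed_pooled_frequency_gives_zero(self):
        assert snp_z(50, 50, 50, 50) == 0.0
        assert snp_z(0, 50, 0, 50) == 0.0

    def test_drift_inflates_variance_monotonically(self):
        zs = [abs(snp_z(5, 50, 0, 50, drift_factor=f)) for f in (0.0, 0.1, 0.5, 0.9)]
        assert all(a > b for a, b in zip(zs, zs[1:]))

    def test_site_wrapper_uses_group_counts(self):
        site = VariantSite(
            "chr1", 100, "A", "G",
            alt_counts={"stroke": 5, "random": 0},
            called_counts={"stroke": 50, "random": 50},
        )
        assert snp_z_site(site, "stroke", "random") == snp_z(5, 50, 0, 50)

    def test_uncalled_group_rejected(self):
        with pytest.raises(ValueError):
            snp_z(0, 0, 1, 10)


class TestGeneStatistic:
    def test_sum_of_squares(self):
        assert gene_diff_statistic([2.0]) == 4.0
        assert gene_diff_statistic([0.0, 0.0]) == 0.0

    def test_matches_brute_force(self, rng):
        alt_a = rng.integers(0, 20, size=30)
        alt_b = rng.integers(0, 20, size=30)
        t = _t_from_counts(alt_a, np.full(30, 50), alt_b, np.full(30, 44), 0.05)
        brute = sum(
            snp_z(a, 50, b, 44, 0.05) ** 2 for a, b in zip(alt_a, alt_b)
        )
        assert float(t) == pytest.approx(brute, abs=1e-12)


def _toy_matrix(rng, n_a=3, n_b=3, k=4):
    samples = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    table = pd.DataFrame(
        {"sample_id": samples, "group": ["stroke"] * n_a + ["random"] * n_b,
         "age": [20] * (n_a + n_b)}
    )
    cohort = CohortDesign(table)
    dosages = rng.integers(0, 3, size=(n_a + n_b, k)).astype(np.int16)
    keys = [f"chr1:{100 + i}:A:G" for i in range(k)]
    return GenotypeMatrix(samples, keys, dosages), cohort


class TestPermutation:
    def test_exhaustive_equals_enumeration_oracle(self, rng):
        matrix, cohort = _toy_matrix(rng)
        d = matrix.dosages
        labels = np.array([True] * 3 + [False] * 3)
        cfg = DiffConfig(n_permutations=100, seed=0)
        t_obs, k, p_emp, _, n_perm = permutation_p(d, labels, cfg, exhaustive=True)
        assert n_perm == 20

        def t_of(lab):
            called = d != MISSING
            alt = np.where(called, d, 0)
            return float(
                _t_from_counts(
                    alt[lab].sum(axis=0), 2 * called[lab].sum(axis=0),
                    alt[~lab].sum(axis=0), 2 * called[~lab].sum(axis=0), 0.0,
                )
            )

        ts = []
        for subset in combinations(range(6), 3):
            lab = np.zeros(6, dtype=bool)
            lab[list(subset)] = True
            ts.append(t_of(lab))
        oracle = np.mean([t >= t_of(labels) for t in ts])
        assert p_emp == oracle

    def test_extreme_rank_gives_floor_p(self):
        # A huge planted difference: T_obs beats every permutation.
        rng = np.random.default_rng(0)
        n = 40
        d = np.zeros((n, 6), dtype=np.int16)
        d[: n // 2] = 2
        labels = np.array([True] * (n // 2) + [False] * (n // 2))
        cfg = DiffConfig(n_permutations=200, seed=1)
        _, _, p_emp, _, _ = permutation_p(d, labels, cfg, rng=rng)
        assert p_emp == pytest.approx(1 / 201)

    def test_label_swap_invariance(self, rng):
        matrix, cohort = _toy_matrix(rng, n_a=6, n_b=5, k=8)
        cfg = DiffConfig(n_permutations=300, seed=5)
        site_idx = list(range(8))
        r1 = gene_permutation_test("G", matrix, cohort, site_idx, ("stroke", "random"), cfg)
        r2 = gene_permutation_test("G", matrix, cohort, site_idx, ("random", "stroke"), cfg)
        assert r1.t_obs == pytest.approx(r2.t_obs, abs=1e-12)
        assert r1.p_empirical == r2.p_empirical

    def test_permutation_p_floor_and_range(self, rng):
        matrix, cohort = _toy_matrix(rng, n_a=10, n_b=10, k=5)
        cfg = DiffConfig(n_permutations=100, seed=2)
        res = gene_permutation_test("G", matrix, cohort, list(range(5)),
                        ("stroke", "random"), cfg)
        assert 1 / 101 <= res.p_empirical <= 1.0

    def test_tiny_groups_rejected(self):
        d = np.zeros((3, 2), dtype=np.int16)
        labels = np.array([True, False, False])
        with pytest.raises(ValueError):
            permutation_p(d, labels, DiffConfig(n_permutations=100, seed=0))


class TestRunDifferentiation:
    def test_table_shape_and_determinism(self, rng):
        matrix, cohort = _toy_matrix(rng, n_a=8, n_b=8, k=12)
        assignments = {"GA": [0, 1, 2, 3], "GB": [4, 5, 6, 7], "GC": []}
        cfg = DiffConfig(n_permutations=200, seed=3)
        df1 = run_differentiation(matrix, assignments, cohort,
                                  [("stroke", "random")], cfg)
        df2 = run_differentiation(matrix, assignments, cohort,
                                  [("stroke", "random")], cfg)
        assert list(df1.gene) == ["GA", "GB"]  # empty region omitted
        assert df1.equals(df2)
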