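"""Unit and property tests of the synthetic-cohort generator."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import binom

from exomod.datatypes import MISSING
from exomod.simulate import (
    NeSchedule,
    PredictorModel,
    SimConfig,
    make_cohort,
    make_gene_models,
    simulate_cohort,
    simulate_genotypes,
    simulate_prediction_profiles,
    simulate_site_frequencies,
)


class TestNeSchedule:
    def test_drift_factor_closed_form(self):
        sched = NeSchedule(((100, 10_000), (50, 1_000)))
        expected = 1.0 - np.exp(-(100 / 20_000 + 50 / 2_000))
        assert sched.drift_factor == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("epochs", [(), ((0, 100),), ((10, 0),), ((-1, 5),)])
    def test_invalid_epochs_rejected(self, epochs):
        with pytest.raises(ValueError):
            NeSchedule(tuple(epochs))


class TestConfigValidation:
    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError, match="theta"):
            SimConfig(theta=-1.0)

    def test_zero_theta_gives_zero_sites(self):
        cfg = SimConfig(theta=0.0, n_genes=5, variants_per_gene=(0, 100), seed=1)
        freqs = simulate_site_frequencies(cfg)
        assert all(len(f) == 0 for f in freqs)

    def test_delta_bounds_enforced(self):
        with pytest.raises(ValueError, match="delta"):
            SimConfig(planted_diff={"G01": (("stroke", "random"), 0.7)},
                      n_genes=5)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_per_group={"random": 1, "control": 10})


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        cfg = SimConfig(n_genes=4, theta=20, seed=7,
                        n_per_group={"random": 6, "control": 6})
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert np.array_equal(a.matrix.dosages, b.matrix.dosages)
        assert a.matrix.variant_keys == b.matrix.variant_keys
        assert a.variants.equals(b.variants)
        ka = list(a.profiles)[0]
        assert a.profiles[ka].verdicts == b.profiles[ka].verdicts

    def test_different_seed_differs(self):
        cfg = SimConfig(n_genes=4, theta=20, seed=7,
                        n_per_group={"random": 6, "control": 6})
        other = dataclasses.replace(cfg, seed=8)
        a, b = simulate_cohort(cfg), simulate_cohort(other)
        assert not np.array_equal(a.matrix.dosages, b.matrix.dosages)


class TestSiteFrequencies:
    def test_variant_counts_within_range(self):
        cfg = SimConfig(n_genes=20, theta=30, variants_per_gene=(10, 40), seed=3)
        freqs = simulate_site_frequencies(cfg)
        assert all(10 <= len(f) <= 40 for f in freqs)

    def test_singleton_doubleton_ratio_matches_neutral_law(self):
        # E[xi_i] proportional to 1/i: after folding on a 2N grid the
        # singleton:doubleton weight ratio is (1/1 + 1/(2N-1)) / (1/2 + 1/(2N-2)).
        cfg = SimConfig(n_genes=200, theta=60, variants_per_gene=(2, 500), seed=11)
        genes = make_gene_models(cfg)
        freqs = np.concatenate(simulate_site_frequencies(cfg, genes))
        assert len(freqs) >= 10_000
        two_n = cfg.freq_grid_haploids
        counts = np.rint(freqs * two_n).astype(int)
        minor = np.minimum(counts, two_n - counts)
        n1, n2 = np.sum(minor == 1), np.sum(minor == 2)
        expected_ratio = (1 + 1 / (two_n - 1)) / (0.5 + 1 / (two_n - 2))
        # 3 Monte-Carlo SE on the ratio via error propagation
        ratio = n1 / n2
        se = ratio * np.sqrt(1 / n1 + 1 / n2)
        assert abs(ratio - expected_ratio) < 3 * se


class TestGenotypes:
    def test_fixed_frequency_gives_homozygous_alt(self):
        cfg = SimConfig(n_per_group={"random": 5, "control": 5})
        cohort = make_cohort(cfg)
        matrix, _ = simulate_genotypes([np.array([1.0, 1.0])], cohort, seed=0)
        assert (matrix.dosages == 2).all()

    def test_missing_rate_injected_as_sentinel(self):
        cfg = SimConfig(n_per_group={"random": 30, "control": 30})
        cohort = make_cohort(cfg)
        matrix, _ = simulate_genotypes(
            [np.full(200, 0.3)], cohort, seed=1, missing_rate=0.1
        )
        frac = (matrix.dosages == MISSING).mean()
        assert 0.07 < frac < 0.13

    def test_planted_shift_is_unbiased(self):
        # delta = 0.3 at base frequency 0.05, 25 per group: the mean observed
        # group difference over many sites estimates delta without bias.
        cfg = SimConfig(n_per_group={"stroke": 25, "long_survivor": 25})
        cohort = make_cohort(cfg)
        n_sites = 500
        matrix, _ = simulate_genotypes(
            [np.full(n_sites, 0.05)],
            cohort,
            planted_diff={"G0001": (("stroke", "long_survivor"), 0.3)},
            seed=4,
        )
        d = matrix.dosages
        p_a = d[cohort.indices_of("stroke")].mean(axis=0) / 2
        p_b = d[cohort.indices_of("long_survivor")].mean(axis=0) / 2
        diff = (p_a - p_b).mean()
        se = np.std(p_a - p_b) / np.sqrt(n_sites)
        assert abs(diff - 0.3) < 3 * se

    def test_null_z_scores_standardized(self):
        # Under delta = 0 the two-group frequency z has mean ~0, variance ~1.
        from exomod.differentiation import snp_z

        cfg = SimConfig(n_per_group={"stroke": 50, "long_survivor": 50})
        cohort = make_cohort(cfg)
        rng = np.random.default_rng(8)
        base = rng.uniform(0.2, 0.5, size=1000)
        matrix, _ = simulate_genotypes([base], cohort, seed=5)
        d = matrix.dosages
        ia, ib = cohort.indices_of("stroke"), cohort.indices_of("long_survivor")
        zs = []
        for j in range(d.shape[1]):
            z = snp_z(d[ia, j].sum(), 2 * len(ia), d[ib, j].sum(), 2 * len(ib))
            zs.append(z)
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.1
        assert 0.85 < zs.var() < 1.15


class TestPredictionProfiles:
    def test_perfect_predictors(self):
        model = PredictorModel(sensitivity=1.0, specificity=1.0, correlation=0.0)
        truth = np.array([True] * 10 + [False] * 10)
        profiles = simulate_prediction_profiles(truth, model, seed=1)
        counts = [p.damaging_count for p in profiles]
        assert counts[:10] == [21] * 10
        assert counts[10:] == [0] * 10

    def test_high_correlation_concentrates_verdicts(self):
        model = PredictorModel(sensitivity=0.7, specificity=0.7, correlation=0.999)
        truth = np.array([True] * 500)
        profiles = simulate_prediction_profiles(truth, model, seed=2)
        counts = np.array([p.damaging_count for p in profiles])
        assert np.mean(np.isin(counts, (0, 21))) > 0.9

    def test_consensus_rate_matches_binomial_tail(self):
        # Independent predictors: P(>= 17 damaging of 21) is a binomial tail.
        model = PredictorModel(sensitivity=0.9, specificity=0.9, correlation=0.0)
        n = 10_000
        profiles = simulate_prediction_profiles(np.ones(n, dtype=bool), model, seed=3)
        rate = np.mean([p.damaging_count >= 17 for p in profiles])
        expected = binom.sf(16, 21, 0.9)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rate - expected) < 3 * se

    def test_siphy_distributions_separated(self):
        model = PredictorModel()
        truth = np.array([True] * 200 + [False] * 200)
        profiles = simulate_prediction_profiles(truth, model, seed=4)
        s = np.array([p.siphy29 for p in profiles])
        assert s[:200].mean() > s[200:].mean() + 4


class TestCohortTable:
    def test_paper_group_sizes_give_163_samples(self):
        cohort = make_cohort(SimConfig())
        assert len(cohort.samples) == 163
        sizes = cohort.group_sizes()
        assert sizes == {"random": 56, "control": 58,
                         "long_survivor": 26, "stroke": 23}

    def test_long_survivors_older_than_forty(self):
        cohort = make_cohort(SimConfig(seed=9))
        ls = cohort.table[cohort.table.group == "long_survivor"]
        assert (ls.age > 40).all()
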