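"""Simulator calibration: Balding-Nichols moments, LD, admixture, h2, GWAS."""

import numpy as np
import pytest
from scipy import stats as sps

from transprs.synthetic_data import (
    SimulationConfig,
    balding_nichols,
    simulate_admixed,
    simulate_frequencies,
    simulate_genotypes,
    simulate_gwas,
    simulate_phenotype,
    variant_table,
)


class TestBaldingNichols:
    def test_zero_divergence_returns_ancestral_exactly(self):
        rng = np.random.default_rng(0)
        p0 = np.array([0.3, 0.5, 0.9])
        assert np.array_equal(balding_nichols(p0, 0.0, rng), p0)

    def test_variance_matches_closed_form(self):
        # Var = F * p0 * (1 - p0) for the Beta parameterization
        rng = np.random.default_rng(1)
        draws = balding_nichols(np.full(50_000, 0.5), 0.2, rng)
        expected = 0.2 * 0.5 * 0.5
        assert abs(draws.var() - expected) / expected < 0.05
        assert abs(draws.mean() - 0.5) < 0.01

    def test_high_divergence_is_bimodal(self):
        rng = np.random.default_rng(2)
        draws = balding_nichols(np.full(20_000, 0.5), 0.95, rng)
        assert np.mean((draws > 0.4) & (draws < 0.6)) < 0.05

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError):
            balding_nichols(np.array([0.5]), 1.0, np.random.default_rng(0))


class TestConfig:
    def test_pairwise_fst_recovered_from_per_population(self):
        cfg = SimulationConfig(fst_matrix=0.12, seed=1)
        per_pop = cfg.per_population_fst()
        # additive reconstruction: F_i + F_j ~ configured pairwise value
        for i in range(3):
            for j in range(i + 1, 3):
                assert per_pop[i] + per_pop[j] == pytest.approx(0.12, abs=1e-9)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_variants=5, n_blocks=10)
        with pytest.raises(ValueError):
            SimulationConfig(block_rho=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(fst_matrix=1.5)

    def test_blocks_partition_variants(self):
        cfg = SimulationConfig(n_variants=103, n_blocks=7)
        bounds = cfg.block_bounds()
        covered = [i for a, b in bounds for i in range(a, b)]
        assert covered == list(range(103))


class TestGenotypes:
    def test_frequency_matrix_shape_and_range(self, small_config, small_freqs):
        assert small_freqs.shape == (2, small_config.n_variants)
        assert np.all((small_freqs > 0) & (small_freqs < 1))

    def test_dosage_mean_tracks_frequency(self, small_config, small_freqs):
        panel = simulate_genotypes(small_freqs[0], 1500, small_config, seed=[3, 1])
        f = small_freqs[0]
        se = np.sqrt(2 * f * (1 - f) / 1500)
        dev = np.abs(panel.dosages.mean(axis=0) - 2 * f)
        # allow a small fraction of 3-SE excursions across 200 variants
        assert np.mean(dev <= 3 * se + 0.02) > 0.97

    @staticmethod
    def _adjacent_corr(panel, cfg):
        x = panel.dosages.astype(float)
        x = x - x.mean(axis=0)
        sd = x.std(axis=0)
        within, between = [], []
        bounds = cfg.block_bounds()
        starts = {a for a, _ in bounds}
        for j in range(cfg.n_variants - 1):
            if sd[j] == 0 or sd[j + 1] == 0:
                continue
            r = (x[:, j] * x[:, j + 1]).mean() / (sd[j] * sd[j + 1])
            (between if (j + 1) in starts else within).append(r)
        return np.array(within), np.array(between)

    def test_no_ld_limit(self, small_freqs):
        cfg = SimulationConfig(n_variants=200, n_blocks=5, block_rho=0.0, seed=4)
        panel = simulate_genotypes(small_freqs[0], 1000, cfg, seed=[4, 1])
        within, _ = self._adjacent_corr(panel, cfg)
        assert np.mean(np.abs(within)) < 0.05

    def test_strong_ld_within_blocks_none_between(self):
        # moderate frequencies so the thresholded-Gaussian correlation stays
        # comparable to the latent rho (extreme MAF deflates genotype r)
        rng = np.random.default_rng(55)
        freqs = rng.uniform(0.2, 0.8, 200)
        cfg = SimulationConfig(n_variants=200, n_blocks=5, block_rho=0.9, seed=5)
        panel = simulate_genotypes(freqs, 2000, cfg, seed=[5, 1])
        within, between = self._adjacent_corr(panel, cfg)
        assert within.mean() > 0.5
        assert np.abs(between).max() < 0.15
        # tetrachoric Monte-Carlo oracle for the first adjacent pair
        z1 = rng.standard_normal(200_000)
        z2 = 0.9 * z1 + np.sqrt(1 - 0.81) * rng.standard_normal(200_000)
        from scipy.special import ndtri

        h1 = (z1 < ndtri(freqs[0])) & True
        h2 = (z2 < ndtri(freqs[1])) & True
        r_oracle = np.corrcoef(h1, h2)[0, 1]  # haplotype corr = dosage corr
        x = panel.dosages
        r_obs = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
        assert r_obs == pytest.approx(r_oracle, abs=0.08)

    def test_too_few_individuals_rejected(self, small_config, small_freqs):
        with pytest.raises(ValueError):
            simulate_genotypes(small_freqs[0], 1, small_config)

    def test_fixed_seed_reproduces_panel(self, small_config, small_freqs):
        a = simulate_genotypes(small_freqs[0], 50, small_config, seed=[9, 9])
        b = simulate_genotypes(small_freqs[0], 50, small_config, seed=[9, 9])
        assert np.array_equal(a.dosages, b.dosages)


class TestAdmixture:
    def test_degenerate_dirichlet_matches_pure_population(self, small_config, small_freqs):
        panel = simulate_admixed(small_freqs, 1500, (1.0, 0.0), small_config, seed=[6, 1])
        f_obs = panel.allele_frequencies()
        resid = f_obs - small_freqs[0]
        se = np.sqrt(small_freqs[0] * (1 - small_freqs[0]) / (2 * 1500))
        assert np.mean(np.abs(resid) <= 4 * se + 0.02) > 0.97

    def test_mean_ancestry_matches_dirichlet_mean(self, small_config, small_freqs):
        panel = simulate_admixed(small_freqs, 3000, (1.0, 1.0), small_config, seed=[6, 2])
        props = panel.sample_meta[["anc_EUR", "anc_AFR"]].to_numpy()
        assert np.allclose(props.mean(axis=0), 0.5, atol=0.02)
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_single_population_rejected(self, small_config, small_freqs):
        with pytest.raises(ValueError):
            simulate_admixed(small_freqs[:1], 100, (1.0,), small_config)


class TestPhenotype:
    def test_null_heritability_gives_independent_phenotype(self, small_freqs):
        cfg = SimulationConfig(n_variants=200, n_blocks=5, h2=0.0, p_causal=0.05, seed=7)
        panel = simulate_genotypes(small_freqs[0], 2000, cfg, seed=[7, 1])
        simulate_phenotype(panel, cfg, seed=[7, 2])
        # squared correlation with any genetic score ~ 0
        g = panel.dosages.astype(float) @ np.ones(200)
        r = np.corrcoef(g, panel.phenotype)[0, 1]
        assert r**2 < 0.01

    def test_realized_h2_within_sampling_error(self):
        cfg = SimulationConfig(n_variants=2000, n_blocks=40, h2=0.25, p_causal=0.03, seed=8)
        freqs = simulate_frequencies(cfg)
        panel = simulate_genotypes(freqs[0], 5000, cfg, seed=[8, 1])
        trait = simulate_phenotype(panel, cfg, seed=[8, 2])
        g = panel.dosages.astype(float) @ trait.effects_per_allele
        r2 = np.corrcoef(g, panel.phenotype)[0, 1] ** 2
        assert 0.21 <= r2 <= 0.29

    def test_identical_seed_identical_phenotype(self, small_config, small_freqs):
        p1 = simulate_genotypes(small_freqs[0], 100, small_config, seed=[9, 1])
        p2 = simulate_genotypes(small_freqs[0], 100, small_config, seed=[9, 1])
        simulate_phenotype(p1, small_config, seed=[9, 2])
        simulate_phenotype(p2, small_config, seed=[9, 2])
        assert np.array_equal(p1.phenotype, p2.phenotype)

    def test_too_sparse_architecture_rejected(self, small_config, small_freqs):
        cfg = SimulationConfig(n_variants=200, n_blocks=5, p_causal=0.001, seed=1)
        panel = simulate_genotypes(small_freqs[0], 100, cfg, seed=[1, 1])
        with pytest.raises(ValueError):
            simulate_phenotype(panel, cfg)


class TestGwas:
    def test_null_trait_type_one_error(self, small_freqs):
        cfg = SimulationConfig(n_variants=200, n_blocks=200, block_rho=0.0, h2=0.0, p_causal=0.05, seed=10)
        freqs = simulate_frequencies(cfg)
        rates = []
        for s in range(5):
            panel = simulate_genotypes(freqs[0], 1000, cfg, seed=[10, s])
            simulate_phenotype(panel, cfg, seed=[10, 100 + s])
            stats = simulate_gwas(panel)
            rates.append((stats.usable().df["p"] < 0.05).mean())
        assert 0.03 <= np.mean(rates) <= 0.07

    def test_z_noncentrality_for_planted_effect(self):
        # one variant with true standardized effect 0.1 at N = 10 000 -> z ~ 10
        rng = np.random.default_rng(12)
        n = 10_000
        from tests.conftest import make_panel

        x = rng.binomial(2, 0.5, size=(n, 1)).astype(float)
        xs = (x[:, 0] - x[:, 0].mean()) / x[:, 0].std()
        y = 0.1 * xs + rng.normal(0, np.sqrt(1 - 0.01), n)
        panel = make_panel(x, phenotype=y)
        stats = simulate_gwas(panel)
        z = (stats.df["beta"] / stats.df["se"]).iloc[0]
        assert abs(z - 10.0) < 3.0

    def test_z_matches_marginal_correlation(self, gwas_bundle):
        panel, _, stats = gwas_bundle
        x = panel.dosages.astype(float)
        y = panel.phenotype
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        r = (xc * yc[:, None]).mean(axis=0) / (x.std(axis=0) * y.std())
        z = (stats.df["beta"] / stats.df["se"]).to_numpy()
        t_from_r = r * np.sqrt((panel.n_samples - 2) / (1 - r**2))
        assert np.allclose(z, t_from_r, rtol=1e-8)

    def test_monomorphic_flagged_not_dropped(self):
        from tests.conftest import make_panel

        rng = np.random.default_rng(13)
        x = rng.binomial(2, 0.4, size=(200, 3)).astype(float)
        x[:, 1] = 2.0  # monomorphic
        panel = make_panel(x, phenotype=rng.normal(size=200))
        stats = simulate_gwas(panel)
        assert len(stats) == 3
        assert stats.df.loc[1, "flag"] == "monomorphic"
        assert np.isnan(stats.df.loc[1, "beta"])
        assert len(stats.usable()) == 2

    def test_permuted_phenotype_recentres_betas(self, gwas_bundle):
        panel, _, stats = gwas_bundle
        rng = np.random.default_rng(14)
        shuffled = panel.phenotype.copy()
        rng.shuffle(shuffled)
        orig = panel.phenotype
        try:
            panel.phenotype = shuffled
            null_stats = simulate_gwas(panel)
        finally:
            panel.phenotype = orig
        z = (null_stats.usable().df["beta"] / null_stats.usable().df["se"]).to_numpy()
        assert abs(z.mean()) < 3.0 / np.sqrt(len(z))


def test_variant_table_is_deterministic_and_valid(small_config):
    a = variant_table(small_config)
    b = variant_table(small_config)
    assert a.equals(b)
    assert (a["allele_a"] != a["allele_b"]).all()
    assert a["variant_id"].is_unique
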