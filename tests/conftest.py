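import numpy as np
import pandas as pd
import pytest

from transprs.synthetic_data import (
    SimulationConfig,
    simulate_frequencies,
    simulate_genotypes,
    simulate_gwas,
    simulate_phenotype,
    variant_table,
)


@pytest.fixture(scope="session")
def small_config():
    """Fast configuration: 200 variants in 5 blocks, 2 populations."""
    return SimulationConfig(
        n_variants=200,
        n_blocks=5,
        block_rho=0.6,
        fst_matrix=0.15,
        populations=(("EUR", 300), ("AFR", 300)),
        admixture_alpha=(1.0, 1.0),
        p_causal=0.05,
        h2=0.3,
        n_gwas=2000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_freqs(small_config):
    return simulate_frequencies(small_config)


@pytest.fixture(scope="session")
def gwas_bundle(small_config, small_freqs):
    """(panel, trait, sumstats) from one small GWAS simulation."""
    panel = simulate_genotypes(small_freqs[0], small_config.n_gwas, small_config, seed=[11, 1])
    trait = simulate_phenotype(panel, small_config, seed=[11, 2])
    stats = simulate_gwas(panel)
    return panel, trait, stats


def make_ld(D, freqs=None, label="toy", shrinkage_lambda=0.0, windows=None):
    """Hand-built LDReference around explicit correlation matrices."""
    from transprs.ldref import LDReference

    if windows is None:
        D = np.asarray(D, dtype=float)
        m = D.shape[0]
        windows, matrices = [(0, m)], [D]
    else:
        matrices = [np.asarray(d, dtype=float) for d in D]
        m = windows[-1][1]
    vm = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 100,
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    f = np.full(m, 0.5) if freqs is None else np.asarray(freqs, dtype=float)
    return LDReference(
        windows=windows,
        matrices=matrices,
        variant_meta=vm,
        freqs=f,
        source_populations=[(label, 0)],
        shrinkage_lambda=shrinkage_lambda,
        label=label,
    )


def spike_slab_posterior_mean(b, n_gwas, m, p, h2):
    """Closed-form no-LD posterior mean of the point-normal model (oracle)."""
    b = np.asarray(b, dtype=float)
    sigma2 = h2 / (m * p)
    shrink = 1.0 / (1.0 + 1.0 / (n_gwas * sigma2))
    mu = shrink * b
    log_odds = np.log((1.0 - p) / p) + 0.5 * np.log(1.0 + n_gwas * sigma2) - 0.5 * n_gwas * mu * b
    return mu / (1.0 + np.exp(np.clip(log_odds, -700, 700)))


def make_panel(dosages, alleles_a=None, alleles_b=None, phenotype=None, population="POP"):
    """Hand-built GenotypePanel from a dosage matrix (tests convenience)."""
    from transprs.synthetic_data import GenotypePanel

    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    vm = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 100,
            "allele_a": list(alleles_a) if alleles_a is not None else ["A"] * m,
            "allele_b": list(alleles_b) if alleles_b is not None else ["G"] * m,
        }
    )
    sm = pd.DataFrame({"sample_id": [f"s{i + 1}" for i in range(n)], "population": population})
    return GenotypePanel(dosages, vm, sm, phenotype=phenotype, label=population)
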