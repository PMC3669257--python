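import numpy as np
import pandas as pd
import pytest

from seqgwas import (
    SimConfig,
    block_adjusted_means,
    estimate_kinship,
    filter_variants,
    fit_null_reml,
    scan,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_sim():
    """An 80-accession, 1000-variant simulated study with a causal signal."""
    cfg = SimConfig(
        n_accessions=80,
        n_variants=1000,
        n_chromosomes=2,
        chrom_length_bp=300_000,
        seed=5,
        n_causal=5,
        h2_causal=0.4,
        h2_polygenic=0.2,
        missing_rate=0.1,
    )
    G, truth = simulate_genotypes(cfg)
    P, truth = simulate_phenotypes(G, truth, cfg)
    return cfg, G, truth, P


@pytest.fixture(scope="session")
def scanned(small_sim):
    """Filtered genotypes, kinship, null fit, and a full scan of small_sim."""
    cfg, G, truth, P = small_sim
    means = block_adjusted_means(P, "trait")
    y = means["adjusted_mean"].reindex(G.accession_ids)
    Gf = filter_variants(G, min_maf=0.02, min_called=50)
    K = estimate_kinship(Gf, snps_per_chrom=300, seed=1)
    vc = fit_null_reml(y.to_numpy(), K)
    S = scan(y.to_numpy(), Gf, K, vc)
    return Gf, K, vc, y, S


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def balanced_phenotypes(n_acc=6, n_blocks=3, block_effects=None, seed=0):
    """Small balanced RCB phenotype table with known structure."""
    rng = np.random.default_rng(seed)
    acc_means = rng.normal(size=n_acc)
    b = np.zeros(n_blocks) if block_effects is None else np.asarray(block_effects)
    rows = []
    for i in range(n_acc):
        for j in range(n_blocks):
            rows.append((f"A{i}", f"B{j}", "t", acc_means[i] + b[j]))
    return pd.DataFrame(rows, columns=["accession", "block", "trait", "value"])
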