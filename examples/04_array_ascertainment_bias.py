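"""In silico SNP-array experiment: candidate overlap and ascertainment bias.

Designs reduced-representation genotyping platforms from a 26-accession
discovery panel (one common SNP per 1-kb window plus random fillers),
re-runs the association scan restricted to platform SNPs, and measures
(i) how many platform candidates land near the sequence-based candidates
and (ii) how strongly the platform-tagged candidates skew toward common
alleles.
"""

import numpy as np

from seqgwas import (
    SimConfig,
    block_adjusted_means,
    design_platform,
    estimate_kinship,
    filter_variants,
    fit_null_reml,
    maf_bias_report,
    overlap_report,
    scan,
    scan_platform,
    select_candidates,
    simulate_genotypes,
    simulate_phenotypes,
    subsample_discovery_panel,
)

cfg = SimConfig(
    n_accessions=200, n_variants=8000, n_chromosomes=4, chrom_length_bp=5_000_000,
    block_length_bp=10_000, n_causal=25, h2_causal=0.5, h2_polygenic=0.2,
    maf_effect_alpha=0.3, seed=42,
)
G, truth = simulate_genotypes(cfg)
P, truth = simulate_phenotypes(G, truth, cfg)
ys = block_adjusted_means(P, "trait")["adjusted_mean"].reindex(G.accession_ids)
Gf = filter_variants(G, min_maf=0.02, min_called=100)
K = estimate_kinship(Gf, snps_per_chrom=1000, seed=1)
vc = fit_null_reml(ys.to_numpy(), K)
S = scan(ys.to_numpy(), Gf, K, vc)
seq200 = select_candidates(S, 200, trait="trait")

panel = subsample_discovery_panel(Gf, 26, seed=7)
# the window size keeps the platform a small fraction of all assayed SNPs,
# matching the real thinning ratio of a 250K array against full sequence
scans, plat_cands = [], []
for r in range(10):
    d = design_platform(Gf, panel, window_bp=100_000, target_size=200, seed=100 + r)
    Sp = scan_platform(ys.to_numpy(), Gf, K, vc, d, min_called=100, full_scan=S)
    scans.append(Sp)
    plat_cands.append(select_candidates(Sp, 50))

print("overlap of platform candidates with the top-200 sequence candidates")
print("(mean [min-max] platform candidates within distance, over 10 platforms):")
for _, row in overlap_report(scans, seq200).iterrows():
    print(f"  top {int(row.top_n):>2} within {int(row.distance_bp):>6} bp: "
          f"{row['mean']:.1f} [{int(row['min'])}-{int(row['max'])}]")

bias = maf_bias_report(S, seq200, plat_cands)
def rare_frac(h):
    tot = sum(h.values())
    return (h["maf_02_05"] + h["maf_05_10"]) / tot if tot else float("nan")

print("\nfraction of SNPs with MAF < 10%:")
print(f"  all assayed SNPs:            {rare_frac(bias['all_snps']):.2f}")
print(f"  sequence candidates:         {rare_frac(bias['sequence_candidates']):.2f}")
print(f"  platform candidates:         {rare_frac(bias['platform_candidates']):.2f}")
print(f"  platform-tagged seq cands:   {rare_frac(bias['tagged_sequence_candidates']):.2f}")
print("(tagged sequence candidates losing rare alleles is the ascertainment "
      "bias a discovery-panel MAF threshold imposes)")
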