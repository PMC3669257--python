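"""Synthetic genotype/phenotype/annotation generator for inbred GWAS panels.

Emulates the statistical structure of a selfing-plant association panel:
fully homozygous accessions, haplotype-block LD, subpopulation structure
inducing non-trivial kinship, a rare-skewed allele-frequency spectrum,
sparse causal variants with tunable MAF-effect coupling, a polygenic
background with covariance proportional to kinship, additive greenhouse
block effects, and independent genotype missingness.  Ground truth is
recorded for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import yaml

from .genotype_io import MISSING, GenotypeMatrix, compute_maf, make_variant_table


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


#: second Beta parameter of the derived-allele-frequency density; with the
#: default maf_spectrum_shape this puts the post-filter (MAF >= 0.02)
#: genome-wide mean MAF near 0.09
_MAF_BETA_B = 7.0

#: Dirichlet concentration of per-subpopulation founder-haplotype weights;
#: values < 1 differentiate subpopulations (non-trivial kinship structure)
_FOUNDER_DIRICHLET_CONC = 0.3


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the study design this package targets: ~200 selfed
    accessions in a few admixed subpopulations, LD blocks of a few kb,
    a rare-skewed MAF spectrum (post-filter mean MAF ~ 0.09), eight
    randomized complete greenhouse blocks.
    """

    n_accessions: int = 200
    n_subpops: int = 3
    admixture_weights: tuple = None  # uniform over subpops if None
    n_chromosomes: int = 8
    chrom_length_bp: int = 1_000_000
    n_variants: int = 20_000
    block_length_bp: int = 3_000  # LD extends an average of ~3 kb
    n_founder_haplotypes_per_block: int = 32
    maf_spectrum_shape: float = 0.2  # Beta(shape, _MAF_BETA_B) derived frequency
    missing_rate: float = 0.15
    n_causal: int = 20
    effect_scale: float = 1.0
    maf_effect_alpha: float = 0.0  # |beta| ~ [p(1-p)]^(-alpha)
    h2_causal: float = 0.3
    h2_polygenic: float = 0.3
    n_blocks: int = 8  # greenhouse blocks
    block_effect_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.admixture_weights is None:
            self.admixture_weights = tuple([1.0 / self.n_subpops] * self.n_subpops)
        self.admixture_weights = tuple(float(w) for w in self.admixture_weights)
        for name in (
            "n_accessions", "n_subpops", "n_chromosomes", "chrom_length_bp",
            "n_variants", "block_length_bp", "n_founder_haplotypes_per_block",
            "n_blocks",
        ):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive count")
        if len(self.admixture_weights) != self.n_subpops:
            raise ConfigError("admixture_weights length must equal n_subpops")
        if abs(sum(self.admixture_weights) - 1.0) > 1e-8 or min(self.admixture_weights) < 0:
            raise ConfigError("admixture_weights must be probabilities summing to 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be a probability in [0, 1)")
        if self.maf_spectrum_shape <= 0:
            raise ConfigError("maf_spectrum_shape must be positive")
        if self.n_causal < 0 or self.n_causal > self.n_variants:
            raise ConfigError("n_causal must be in [0, n_variants]")
        if not (0.0 <= self.h2_causal < 1.0):
            raise ConfigError("h2_causal must be a proportion in [0, 1)")
        if not (0.0 <= self.h2_polygenic < 1.0):
            raise ConfigError("h2_polygenic must be a proportion in [0, 1)")
        if self.h2_causal + self.h2_polygenic >= 1.0:
            raise ConfigError("h2_causal + h2_polygenic must be < 1")
        if self.block_effect_sd < 0:
            raise ConfigError("block_effect_sd must be non-negative")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigError("seed is mandatory in the config file")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


@dataclasses.dataclass
class GroundTruth:
    """What the simulator actually planted, for recovery tests."""

    causal_variant_ids: list = dataclasses.field(default_factory=list)
    causal_effects: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0)
    )
    true_h2_causal: float = 0.0
    true_among_accession_fraction: float = 0.0
    subpop_assignment: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0, dtype=int)
    )
    true_calls: np.ndarray | None = None  # pre-missingness genotype matrix

    def __post_init__(self) -> None:
        if len(self.causal_variant_ids) != len(self.causal_effects):
            raise ValueError("causal id and effect lists disagree in length")


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, GroundTruth]:
    """Simulate a homozygous accession x variant call matrix.

    Haplotype-block mosaic model: each chromosome is cut into windows of
    ``block_length_bp``; each window carries ``n_founder_haplotypes_per_block``
    founder haplotypes whose alleles are Bernoulli draws from a rare-skewed
    Beta(shape, 1) derived-allele frequency.  Each accession inherits, per
    window, one founder haplotype drawn from its subpopulation's Dirichlet
    founder weights — accessions sharing a founder are identical across the
    window (strong LD), and subpopulation-specific weights induce kinship
    structure.  Missing calls are placed independently at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_accessions, config.n_variants

    # variant positions, split evenly across chromosomes
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    chroms, poss = [], []
    for c in range(config.n_chromosomes):
        k = int(per_chrom[c])
        if k > config.chrom_length_bp:
            raise ConfigError("n_variants exceeds chrom_length_bp capacity")
        pos = np.sort(rng.choice(config.chrom_length_bp, size=k, replace=False)) + 1
        chroms.extend([f"chr{c + 1}"] * k)
        poss.extend(pos.tolist())
    variants = make_variant_table(chroms, poss)
    chrom_arr = variants["chrom"].to_numpy()
    pos_arr = variants["pos"].to_numpy()

    # LD-block id per variant (chromosome-qualified window index)
    window = (pos_arr - 1) // config.block_length_bp
    block_key = pd.Series(chrom_arr).astype(str) + "#" + pd.Series(window).astype(str)
    block_id, block_labels = pd.factorize(block_key)
    n_blocks_ld = len(block_labels)
    H = config.n_founder_haplotypes_per_block

    # target derived-allele frequencies: rare-skewed Beta(shape, _MAF_BETA_B)
    f = rng.beta(config.maf_spectrum_shape, _MAF_BETA_B, size=m)

    # subpopulation assignment and per-(subpop, block) founder weights
    subpop = rng.choice(config.n_subpops, size=n, p=config.admixture_weights)
    founder_weights = rng.dirichlet(
        np.full(H, _FOUNDER_DIRICHLET_CONC), size=(config.n_subpops, n_blocks_ld)
    )
    global_weights = np.tensordot(
        np.asarray(config.admixture_weights), founder_weights, axes=(0, 0)
    )  # (n_blocks_ld, H)

    # founder alleles by weighted-prefix assignment: founders, visited in a
    # per-variant random order, carry the derived allele while their
    # cumulative (admixture-averaged) weight stays below f; the founder
    # straddling f carries it with the matching fractional probability, so
    # E[population frequency] = f and the realized spectrum tracks the
    # configured density up to the founder-weight granularity.
    perm = np.argsort(rng.random((m, H)), axis=1)  # (m, H) founder visit order
    W = global_weights[block_id[:, None], perm]  # weights in visit order
    Csum = np.cumsum(W, axis=1)
    full = Csum <= f[:, None]
    n_full = full.sum(axis=1)
    carrier = full.copy()
    partial = n_full < H
    j = np.clip(n_full, 0, H - 1)
    prev = np.where(n_full > 0, Csum[np.arange(m), j - 1], 0.0)
    frac = np.clip((f - prev) / W[np.arange(m), j], 0.0, 1.0)
    take = partial & (rng.random(m) < frac)
    carrier[np.arange(m), j] = np.where(take, True, carrier[np.arange(m), j])
    founder_alleles = np.zeros((H, m), dtype=np.int8)
    rows = perm.ravel()
    cols = np.repeat(np.arange(m), H)
    founder_alleles[rows, cols] = carrier.ravel()

    # per accession per block: inherited founder index
    u = rng.random((n, n_blocks_ld))
    cum = np.cumsum(founder_weights, axis=2)  # (subpop, block, H)
    founder_of = (u[:, :, None] > cum[subpop]).sum(axis=2)  # (n, n_blocks_ld)

    true_calls = founder_alleles[founder_of[:, block_id], np.arange(m)]
    calls = true_calls.copy()
    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        calls[miss] = MISSING

    acc_ids = [f"ACC{i:04d}" for i in range(n)]
    G = compute_maf(GenotypeMatrix(acc_ids, variants, calls))

    # plant causal variants among polymorphic, reasonably common sites
    truth = GroundTruth(subpop_assignment=subpop, true_calls=true_calls)
    if config.n_causal > 0:
        p_true = true_calls.mean(axis=0)
        maf_true = np.minimum(p_true, 1 - p_true)
        eligible = np.flatnonzero(maf_true >= 0.02)
        if len(eligible) < config.n_causal:
            eligible = np.flatnonzero(maf_true > 0)
        if len(eligible) < config.n_causal:
            raise ConfigError(
                "n_causal exceeds the number of polymorphic variants simulated"
            )
        causal_idx = np.sort(rng.choice(eligible, size=config.n_causal, replace=False))
        p = p_true[causal_idx]
        mag = config.effect_scale * (p * (1 - p)) ** (-config.maf_effect_alpha)
        signs = rng.choice([-1.0, 1.0], size=config.n_causal)
        truth.causal_variant_ids = list(variants.index[causal_idx])
        truth.causal_effects = signs * mag
    return G, truth


def simulate_phenotypes(
    G: GenotypeMatrix,
    truth: GroundTruth,
    config: SimConfig,
    trait: str = "trait",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate replicate-level trait values y = sum(beta*x) + g + b + e.

    Variance components are defined on the accession-mean scale: the causal
    and polygenic parts are rescaled so their realized among-accession
    variances equal ``h2_causal`` and ``h2_polygenic``, and the accession
    mean of the residual has variance 1 - h2_causal - h2_polygenic (the
    replicate-level residual SD is sqrt(n_blocks) times larger).  Additive
    greenhouse-block effects are shared by all accessions within a block.
    Realized variance fractions are written back into ``truth``.
    """
    if config.h2_causal + config.h2_polygenic >= 1.0:
        raise ConfigError("h2_causal + h2_polygenic must be < 1")
    missing_causal = set(truth.causal_variant_ids) - set(G.variants.index)
    if missing_causal:
        raise ValueError(f"causal variants absent from G: {sorted(missing_causal)[:5]}")
    rng = np.random.default_rng(config.seed + 1_000_003)
    n, B = G.n_accessions, config.n_blocks

    calls_true = truth.true_calls if truth.true_calls is not None else np.where(
        G.calls == MISSING, 0, G.calls
    )

    # causal genetic values, rescaled to among-accession variance h2_causal
    c = np.zeros(n)
    effects = np.asarray(truth.causal_effects, dtype=float).copy()
    if len(truth.causal_variant_ids) > 0 and config.h2_causal > 0:
        cidx = G.variants.index.get_indexer(pd.Index(truth.causal_variant_ids))
        X = calls_true[:, cidx].astype(float)
        raw = X @ effects
        sd = raw.std()
        if sd > 0:
            scale = np.sqrt(config.h2_causal) / sd
            c = (raw - raw.mean()) * scale
            effects = effects * scale

    # polygenic background: covariance proportional to the realized GRM
    g = np.zeros(n)
    if config.h2_polygenic > 0:
        p = calls_true.mean(axis=0)
        poly = (p > 0) & (p < 1)
        Z = calls_true[:, poly] - p[poly]
        K = (Z @ Z.T) / max(poly.sum(), 1)
        w, V = np.linalg.eigh(K)
        w = np.clip(w, 0, None)
        g = V @ (np.sqrt(w) * rng.standard_normal(n))
        sd = g.std()
        if sd > 0:
            g = (g - g.mean()) * (np.sqrt(config.h2_polygenic) / sd)

    h2_e = 1.0 - config.h2_causal - config.h2_polygenic
    e = rng.standard_normal((n, B)) * np.sqrt(h2_e * B)
    b = rng.standard_normal(B) * config.block_effect_sd

    y = c[:, None] + g[:, None] + b[None, :] + e  # (n, B)

    records = pd.DataFrame(
        {
            "accession": np.repeat(G.accession_ids, B),
            "block": np.tile([f"B{j + 1}" for j in range(B)], n),
            "trait": trait,
            "value": y.ravel(),
        }
    )

    v_c = float(np.var(c))
    v_g = float(np.var(g))
    v_e_mean = float(np.var(e.mean(axis=1)))
    v_e_rep = float(np.var(e))
    truth.causal_effects = effects
    denom = v_c + v_g + v_e_mean
    truth.true_h2_causal = v_c / denom if denom > 0 else 0.0
    among = v_c + v_g
    truth.true_among_accession_fraction = (
        among / (among + v_e_rep) if among + v_e_rep > 0 else 0.0
    )
    return records, truth


def subsample_discovery_panel(
    G: GenotypeMatrix, d: int, seed: int
) -> list[str]:
    """Draw ``d`` distinct accession ids as a SNP-discovery panel."""
    if d > G.n_accessions:
        raise ValueError(f"d={d} exceeds the {G.n_accessions} accessions available")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(G.n_accessions, size=d, replace=False))
    return [G.accession_ids[i] for i in idx]


def simulate_annotation(
    config: SimConfig,
    n_genes: int,
    frac_specific: float,
    seed: int,
    tissues: tuple[str, ...] = ("nodule", "root", "leaf"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tile chromosomes with non-overlapping gene intervals plus expression.

    A fraction ``frac_specific`` of genes is flagged as expressed only in
    the nodule and/or root tissues; the rest express in leaf as well.
    Returns (annotation, expression): BED-like gene intervals (0-based
    half-open) and a long-format gene x tissue expressed-flag table.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    if not (0.0 <= frac_specific <= 1.0):
        raise ValueError("frac_specific must be in [0, 1]")
    if not {"nodule", "root"} <= set(tissues) or len(tissues) < 3:
        raise ValueError("tissues must include nodule, root, and at least one other")
    rng = np.random.default_rng(seed)

    per_chrom = np.full(config.n_chromosomes, n_genes // config.n_chromosomes)
    per_chrom[: n_genes % config.n_chromosomes] += 1
    rows = []
    gid = 0
    for ci in range(config.n_chromosomes):
        k = int(per_chrom[ci])
        if k == 0:
            continue
        slot = config.chrom_length_bp // k
        glen = max(1, int(slot * 0.6))  # genes cover ~60% of each slot, with gaps
        for j in range(k):
            start = j * slot + int(rng.integers(0, max(1, slot - glen)))
            rows.append((f"gene{gid:05d}", f"chr{ci + 1}", start, start + glen))
            gid += 1
    annotation = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])

    specific = rng.random(n_genes) < frac_specific
    expr_rows = []
    for i, gene in enumerate(annotation["gene_id"]):
        if specific[i]:
            which = rng.integers(0, 3)  # nodule only / root only / both
            flags = {
                "nodule": which in (0, 2),
                "root": which in (1, 2),
            }
            for t in tissues:
                expr_rows.append((gene, t, int(flags.get(t, False))))
        else:
            for t in tissues:
                expr_rows.append((gene, t, int(rng.random() < 0.8 or t == tissues[-1])))
    expression = pd.DataFrame(expr_rows, columns=["gene_id", "tissue", "expressed"])
    return annotation, expression
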