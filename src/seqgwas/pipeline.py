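"""Stage orchestration: run the analysis end to end with one seed and manifest.

Stages (in dependency order): simulate -> filter -> phenotypes -> scan ->
candidates -> variance -> array_sim -> report.  Each stage writes TSV/JSON
artifacts into the output directory plus a manifest entry recording inputs,
parameters, the derived stage seed, and content hashes; deterministic
stages reproduce identical hashes on rerun.  All randomness flows from the
single config seed through per-stage seeds derived by stable hashing of
the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import architecture, genotype_io, lmm, phenotypes, platform, synthdata, variance

log = logging.getLogger("seqgwas")

STAGES = ["simulate", "filter", "phenotypes", "scan", "candidates", "variance", "array_sim", "report"]

_DEPS = {
    "simulate": [],
    "filter": ["genotypes.vcf"],
    "phenotypes": ["phenotypes.tsv"],
    "scan": ["genotypes_filtered.tsv", "accession_means.tsv"],
    "candidates": ["scan.tsv"],
    "variance": ["scan.tsv", "genotypes_filtered.tsv", "accession_means.tsv", "kinship.tsv"],
    "array_sim": ["scan.tsv", "genotypes_filtered.tsv", "accession_means.tsv", "kinship.tsv"],
    "report": ["scan.tsv"],
}


class StageDependencyError(RuntimeError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Shared run configuration; defaults follow the reference analysis."""

    out_dir: str = "seqgwas_out"
    seed: int = 0
    trait: str = "trait"
    min_maf: float = 0.02
    min_called: int = 100
    kinship_snps_per_chrom: int = 5000
    k_candidates: int = 200
    k_regression: int = 50
    n_randomizations: int = 20
    n_platforms: int = 100
    panel_size: int = 26
    platform_window_bp: int = 1000
    platform_maf_min: float = 0.10
    platform_target_size: int = 250_000
    sim: synthdata.SimConfig | None = None
    genotypes_path: str | None = None  # external inputs; otherwise simulated
    phenotypes_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise synthdata.ConfigError("seed is mandatory in the run config")
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            sim_raw.setdefault("seed", cfg.seed)
            cfg.sim = synthdata.SimConfig(**sim_raw)
        return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Derived per-stage seed: stable hash of the stage name, below 2^31."""
    return (seed ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(out: Path, stage: str, names: list[str]) -> None:
    missing = [n for n in names if not (out / n).exists()]
    if missing:
        raise StageDependencyError(
            f"stage '{stage}' requires artifacts from earlier stages: {missing}"
        )


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in order; return the artifact manifest."""
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in (stages or STAGES)]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}

    for stage in stages:
        log.info("[%s] starting", stage)
        _require(out, stage, _DEPS[stage])
        written = _STAGE_FN[stage](config, out)
        manifest[stage] = {
            "seed": stage_seed(config.seed, stage),
            "parameters": {
                k: v for k, v in dataclasses.asdict(config).items()
                if isinstance(v, (int, float, str, type(None)))
            },
            "artifacts": {name: _sha256(out / name) for name in written},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.info("[%s] wrote %s", stage, ", ".join(written))
    return manifest


# --- stage implementations --------------------------------------------------


def _stage_simulate(config: RunConfig, out: Path) -> list[str]:
    sim = config.sim or synthdata.SimConfig(seed=stage_seed(config.seed, "simulate"))
    G, truth = synthdata.simulate_genotypes(sim)
    P, truth = synthdata.simulate_phenotypes(G, truth, sim, trait=config.trait)
    genotype_io.write_vcf(G, out / "genotypes.vcf")
    phenotypes.write_phenotypes(P, out / "phenotypes.tsv")
    ann, expr = synthdata.simulate_annotation(
        sim, n_genes=max(100, sim.n_variants // 20), frac_specific=0.04,
        seed=stage_seed(config.seed, "annotation"),
    )
    ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
    expr.to_csv(out / "expression.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(json.dumps({
        "causal_variant_ids": list(truth.causal_variant_ids),
        "causal_effects": [float(b) for b in truth.causal_effects],
        "true_h2_causal": truth.true_h2_causal,
        "true_among_accession_fraction": truth.true_among_accession_fraction,
    }, indent=2))
    return ["genotypes.vcf", "phenotypes.tsv", "annotation.tsv", "expression.tsv", "ground_truth.json"]


def _stage_filter(config: RunConfig, out: Path) -> list[str]:
    src = config.genotypes_path or out / "genotypes.vcf"
    G = genotype_io.read_genotypes(src, format="vcf")
    min_called = min(config.min_called, G.n_accessions)
    G = genotype_io.filter_variants(G, min_maf=config.min_maf, min_called=min_called)
    genotype_io.write_tsv(G, out / "genotypes_filtered.tsv")
    return ["genotypes_filtered.tsv"]


def _stage_phenotypes(config: RunConfig, out: Path) -> list[str]:
    src = config.phenotypes_path or out / "phenotypes.tsv"
    P = phenotypes.read_phenotypes(src)
    means = phenotypes.block_adjusted_means(P, config.trait)
    means.to_csv(out / "accession_means.tsv", sep="\t")
    part = phenotypes.variance_partition(P, config.trait)
    (out / "variance_partition.json").write_text(json.dumps(part, indent=2))
    return ["accession_means.tsv", "variance_partition.json"]


def _load_filtered(out: Path):
    G = genotype_io.read_genotypes(out / "genotypes_filtered.tsv", format="tsv")
    means = pd.read_csv(out / "accession_means.tsv", sep="\t", index_col=0)
    common = [a for a in G.accession_ids if a in means.index]
    G = G.subset_accessions(common)
    y = means.loc[common, "adjusted_mean"].to_numpy(dtype=float)
    return G, y


def _stage_scan(config: RunConfig, out: Path) -> list[str]:
    G, y = _load_filtered(out)
    K = lmm.estimate_kinship(
        G, snps_per_chrom=config.kinship_snps_per_chrom,
        seed=stage_seed(config.seed, "kinship"),
    )
    pd.DataFrame(K.values, index=K.accession_ids, columns=K.accession_ids).to_csv(
        out / "kinship.tsv", sep="\t"
    )
    vc = lmm.fit_null_reml(y, K)
    S = lmm.scan(y, G, K, vc)
    S.to_csv(out / "scan.tsv", sep="\t")
    exp, obs, lam = lmm.qq_data(S) if S["p"].notna().sum() >= 100 else (None, None, float("nan"))
    (out / "scan_summary.json").write_text(json.dumps({
        "sigma2_g": vc.sigma2_g, "sigma2_e": vc.sigma2_e, "delta": vc.delta,
        "log_restricted_likelihood": vc.log_restricted_likelihood,
        "lambda_gc": lam, "n_tested": int(S["p"].notna().sum()),
    }, indent=2))
    return ["kinship.tsv", "scan.tsv", "scan_summary.json"]


def _read_scan(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "scan.tsv", sep="\t", index_col=0, dtype={"chrom": str})


def _stage_candidates(config: RunConfig, out: Path) -> list[str]:
    S = _read_scan(out)
    written = []
    for k in sorted({config.k_regression, config.k_candidates}):
        C = architecture.select_candidates(S, k, trait=config.trait)
        C.table.to_csv(out / f"candidates_top{k}.tsv", sep="\t")
        written.append(f"candidates_top{k}.tsv")
    G = genotype_io.read_genotypes(out / "genotypes_filtered.tsv", format="tsv")
    C50 = architecture.select_candidates(S, config.k_regression, trait=config.trait)
    L = architecture.ld_matrix(G, C50)
    summary = {
        "ld_not_in_ld": {str(t): v for t, v in architecture.ld_summary(L).items()},
        "maf_bins_top200": architecture.maf_bins(
            architecture.select_candidates(S, config.k_candidates).table["maf"]
        ),
        "maf_effect_correlation_top200": architecture.maf_effect_correlation(
            architecture.select_candidates(S, config.k_candidates)
        ),
    }
    (out / "architecture_summary.json").write_text(json.dumps(summary, indent=2))
    written.append("architecture_summary.json")
    return written


def _load_kinship(out: Path) -> lmm.KinshipMatrix:
    df = pd.read_csv(out / "kinship.tsv", sep="\t", index_col=0)
    return lmm.KinshipMatrix(list(df.index), df.to_numpy(), n_snps_used=-1)


def _stage_variance(config: RunConfig, out: Path) -> list[str]:
    G, y = _load_filtered(out)
    K = _load_kinship(out)
    S = _read_scan(out)
    ys = pd.Series(y, index=G.accession_ids)
    C = architecture.select_candidates(S, config.k_regression, trait=config.trait)
    emp = variance.stepwise_regression(variance.candidate_design(ys, G, C), config.trait)
    null = variance.randomization_null(
        ys, G, K, R=config.n_randomizations, k=config.k_regression,
        seed=stage_seed(config.seed, "variance"), trait=config.trait,
    )
    adj = variance.adjusted_r2(emp.r2, null.mean_r2)
    (out / "variance_explained.json").write_text(json.dumps({
        "trait": config.trait,
        "empirical_r2": emp.r2,
        "retained_snps": len(emp.retained_variants),
        "null_mean_r2": null.mean_r2,
        "null_sd_r2": null.sd_r2,
        "adjusted_r2": adj["adjusted"],
        "null_r2_values": null.r2_values,
    }, indent=2))
    return ["variance_explained.json"]


def _stage_array_sim(config: RunConfig, out: Path) -> list[str]:
    G, y = _load_filtered(out)
    K = _load_kinship(out)
    S = _read_scan(out)
    vc = lmm.fit_null_reml(y, K)
    seed0 = stage_seed(config.seed, "array_sim")
    panel = synthdata.subsample_discovery_panel(G, min(config.panel_size, G.n_accessions), seed0)
    seq200 = architecture.select_candidates(S, config.k_candidates, trait=config.trait)
    scans, cands = [], []
    for r in range(config.n_platforms):
        design = platform.design_platform(
            G, panel, window_bp=config.platform_window_bp,
            panel_maf_min=config.platform_maf_min,
            target_size=min(config.platform_target_size, G.n_variants),
            seed=seed0 + 1 + r,
        )
        Sp = platform.scan_platform(
            y, G, K, vc, design, min_maf=config.min_maf,
            min_called=min(config.min_called, G.n_accessions),
            full_scan=S,
        )
        scans.append(Sp)
        cands.append(architecture.select_candidates(Sp, config.k_regression))
    overlap = platform.overlap_report(scans, seq200)
    overlap.to_csv(out / "platform_overlap.tsv", sep="\t", index=False)
    bias = platform.maf_bias_report(S, seq200, cands)
    (out / "platform_maf_bias.json").write_text(json.dumps(bias, indent=2))
    return ["platform_overlap.tsv", "platform_maf_bias.json"]


def _stage_report(config: RunConfig, out: Path) -> list[str]:
    S = _read_scan(out)
    C = architecture.select_candidates(S, config.k_candidates, trait=config.trait)
    architecture.manhattan_table(S, C).to_csv(out / "manhattan.tsv", sep="\t", index=False)
    return ["manhattan.tsv"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "phenotypes": _stage_phenotypes,
    "scan": _stage_scan,
    "candidates": _stage_candidates,
    "variance": _stage_variance,
    "array_sim": _stage_array_sim,
    "report": _stage_report,
}
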