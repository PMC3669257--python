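"""In silico reduced-representation SNP platforms and ascertainment-bias reports.

A platform emulates a fixed-content genotyping array designed from a small
deeply-sequenced discovery panel: one randomly chosen common SNP (panel
MAF above a threshold) per 1-kb window that harbours an eligible site,
topped up with random filler SNPs to the target size.  Re-running the
association scan restricted to platform SNPs and comparing its candidates
with the sequence-based candidates quantifies how much reduced
representation distorts GWAS results, and how strongly the recovered
candidates are biased toward common variants.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .architecture import CandidateSet, maf_bins, select_candidates
from .genotype_io import GenotypeMatrix, compute_maf, filter_variants
from .lmm import KinshipMatrix, VarianceComponents, scan


@dataclasses.dataclass
class PlatformDesign:
    panel_accessions: list[str]
    window_bp: int
    panel_maf_min: float
    target_size: int
    window_snp_ids: list[str]
    filler_snp_ids: list[str]
    seed: int

    @property
    def snp_ids(self) -> list[str]:
        return self.window_snp_ids + self.filler_snp_ids

    def __post_init__(self) -> None:
        if set(self.window_snp_ids) & set(self.filler_snp_ids):
            raise ValueError("window and filler SNP sets overlap")


def design_platform(
    G: GenotypeMatrix,
    panel_ids: list[str],
    window_bp: int = 1000,
    panel_maf_min: float = 0.10,
    target_size: int = 250_000,
    seed: int = 0,
) -> PlatformDesign:
    """Design one in silico platform from a discovery panel.

    Panel MAF is computed over the panel accessions only; eligibility is
    strict (panel MAF > ``panel_maf_min``).  One eligible SNP is drawn
    uniformly from each window (``floor((pos-1)/window_bp)`` per
    chromosome) that contains at least one, then fillers are drawn
    uniformly without replacement from the remaining eligible SNPs up to
    ``target_size``.  If too few eligible SNPs exist the platform is
    truncated with a warning.
    """
    missing = set(panel_ids) - set(G.accession_ids)
    if missing:
        raise KeyError(f"panel accessions absent: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)

    panel = compute_maf(G.subset_accessions(list(panel_ids)))
    panel_maf = panel.variants["maf"].to_numpy()
    eligible = np.flatnonzero(np.nan_to_num(panel_maf, nan=-1.0) > panel_maf_min)

    chroms = G.variants["chrom"].to_numpy()
    pos = G.variants["pos"].to_numpy()
    window = (pos - 1) // window_bp

    window_pick = []
    key = pd.DataFrame({"chrom": chroms[eligible], "window": window[eligible], "idx": eligible})
    for _, grp in key.groupby(["chrom", "window"], sort=True):
        window_pick.append(int(grp["idx"].iloc[rng.integers(0, len(grp))]))
    window_pick = sorted(window_pick)

    remaining = np.setdiff1d(eligible, window_pick)
    n_fill = target_size - len(window_pick)
    if n_fill < 0:
        raise ValueError(
            f"target_size {target_size} is below the {len(window_pick)} eligible windows"
        )
    if n_fill > len(remaining):
        warnings.warn(
            f"only {len(remaining)} eligible fillers for {n_fill} slots; "
            "platform truncated",
            stacklevel=2,
        )
        n_fill = len(remaining)
    fillers = np.sort(rng.choice(remaining, size=n_fill, replace=False)) if n_fill else np.empty(0, int)

    ids = G.variants.index
    return PlatformDesign(
        panel_accessions=list(panel_ids),
        window_bp=window_bp,
        panel_maf_min=panel_maf_min,
        target_size=target_size,
        window_snp_ids=[ids[i] for i in window_pick],
        filler_snp_ids=[ids[i] for i in fillers],
        seed=seed,
    )


def scan_platform(
    y: np.ndarray,
    G: GenotypeMatrix,
    K: KinshipMatrix,
    vc: VarianceComponents,
    design: PlatformDesign,
    min_maf: float = 0.02,
    min_called: int = 100,
    full_scan: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Association scan restricted to platform SNPs.

    Applies the same full-sample filters (MAF and call count) to the
    platform subset under the identical P3D model.  When the full-sequence
    scan is supplied, platform results are extracted from it, so p-values
    of shared SNPs are bit-identical to the full scan; otherwise the
    subset is scanned with the same variance components and rotation.
    """
    present = [v for v in design.snp_ids if v in G.variants.index]
    sub = filter_variants(G.subset_variants(present), min_maf=min_maf, min_called=min_called)
    if sub.n_variants == 0:
        raise ValueError("platform is empty after the association filters")
    if full_scan is not None:
        out = full_scan.loc[full_scan.index.intersection(sub.variants.index)]
        return out.sort_values(["chrom", "pos"], kind="mergesort")
    return scan(y, sub, K, vc)


def overlap_report(
    platform_scans: list[pd.DataFrame],
    sequence_candidates: CandidateSet,
    tops=(20, 50),
    distances=(1000, 20_000),
) -> pd.DataFrame:
    """Candidate overlap between platform replicates and sequence candidates.

    For each platform replicate and each (top_n, distance) cell, counts
    the top-n platform candidates whose nearest top-200 sequence candidate
    on the same chromosome lies within ``distance`` bp (inclusive).
    Returns min/mean/max over replicates per cell.
    """
    seq = sequence_candidates.table
    seq_by_chrom = {c: g["pos"].to_numpy() for c, g in seq.groupby("chrom")}
    rows = []
    for top_n in tops:
        for d in distances:
            counts = []
            for S in platform_scans:
                cand = select_candidates(S, top_n).table
                c = 0
                for _, r in cand.iterrows():
                    near = seq_by_chrom.get(r["chrom"])
                    if near is not None and np.abs(near - r["pos"]).min() <= d:
                        c += 1
                counts.append(c)
            counts = np.asarray(counts)
            rows.append(
                (top_n, d, counts.min(), counts.mean(), counts.max(), len(counts))
            )
    return pd.DataFrame(
        rows, columns=["top_n", "distance_bp", "min", "mean", "max", "n_platforms"]
    )


def maf_bias_report(
    all_snps: pd.DataFrame,
    seq_candidates: CandidateSet,
    platform_candidates: list[CandidateSet],
    tag_distance: int = 1000,
) -> dict:
    """MAF-bin histograms exposing ascertainment bias.

    Four populations on the standard 2-5% / 5-10% / >10% grid: all assayed
    SNPs, sequence-based candidates, pooled platform candidates, and the
    "tagged" sequence candidates lying within ``tag_distance`` of at least
    one platform candidate (pooled over platforms and over replicates).
    """
    seq = seq_candidates.table
    plat_mafs = np.concatenate(
        [c.table["maf"].to_numpy() for c in platform_candidates]
    ) if platform_candidates else np.empty(0)

    tagged_mask = np.zeros(len(seq), dtype=bool)
    plat_pos = {}
    for c in platform_candidates:
        for chrom, grp in c.table.groupby("chrom"):
            plat_pos.setdefault(chrom, []).append(grp["pos"].to_numpy())
    plat_pos = {c: np.concatenate(v) for c, v in plat_pos.items()}
    for i, (_, r) in enumerate(seq.iterrows()):
        near = plat_pos.get(r["chrom"])
        if near is not None and np.abs(near - r["pos"]).min() <= tag_distance:
            tagged_mask[i] = True

    return {
        "all_snps": maf_bins(all_snps["maf"].dropna()),
        "sequence_candidates": maf_bins(seq["maf"]),
        "platform_candidates": maf_bins(plat_mafs),
        "tagged_sequence_candidates": maf_bins(seq.loc[tagged_mask, "maf"]),
    }
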