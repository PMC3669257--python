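"""Candidate-SNP selection and genetic-architecture statistics.

Covers the descriptive layer on top of the association scan: top-K
candidate lists with deterministic tie-breaking, pairwise LD (r^2) among
candidates and the fraction of candidates free of mutual LD, MAF binning
on the 2-5% / 5-10% / >10% grid, the MAF-vs-effect-size correlation,
assignment of candidate SNPs to genes (containing gene, else nearest on
the chromosome; named genes within a 10-kb window), and the
hypergeometric enrichment of tissue-specific expression among tagged
genes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix

MAF_BIN_EDGES = (0.02, 0.05, 0.10, 0.5)
MAF_BIN_LABELS = ("maf_02_05", "maf_05_10", "maf_10_50")


@dataclasses.dataclass
class CandidateSet:
    """Top-k variants by ascending p, ties broken by (chrom, pos)."""

    trait: str
    k: int
    table: pd.DataFrame  # index variant_id; columns chrom,pos,maf,beta,se,p
    truncated: bool = False  # fewer than k valid p-values were available

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table.index)


def select_candidates(S: pd.DataFrame, k: int, trait: str = "") -> CandidateSet:
    """Deterministic top-k candidates under the (p, chrom, pos) ordering."""
    valid = S.dropna(subset=["p"])
    ordered = valid.sort_values(["p", "chrom", "pos"], kind="mergesort")
    truncated = len(ordered) < k
    return CandidateSet(trait=trait, k=k, table=ordered.head(k).copy(), truncated=truncated)


def ld_matrix(
    G: GenotypeMatrix, C: CandidateSet, min_complete: int = 10
) -> pd.DataFrame:
    """Pairwise r^2 between candidate call vectors, pairwise-complete.

    r^2 is the squared Pearson correlation over accessions called at both
    variants; pairs with fewer than ``min_complete`` complete observations
    are flagged undefined (NaN).  Diagonal is 1.
    """
    ids = C.variant_ids
    missing = set(ids) - set(G.variants.index)
    if missing:
        raise KeyError(f"candidates absent from genotype matrix: {sorted(missing)[:5]}")
    sub = G.subset_variants(ids)
    calls = sub.calls.astype(float)
    obs = calls != MISSING
    X = np.where(obs, calls, np.nan)
    k = len(ids)
    r2 = np.full((k, k), np.nan)
    for i in range(k):
        xi = X[:, i]
        for j in range(i, k):
            both = ~np.isnan(xi) & ~np.isnan(X[:, j])
            if both.sum() < min_complete:
                continue
            a, b = xi[both], X[both, j]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                r2[i, j] = r2[j, i] = np.nan
                continue
            r = np.corrcoef(a, b)[0, 1]
            r2[i, j] = r2[j, i] = r * r
    np.fill_diagonal(r2, 1.0)
    return pd.DataFrame(r2, index=ids, columns=ids)


def ld_summary(L: pd.DataFrame, thresholds=(0.8, 0.3)) -> dict:
    """Proportion of candidates not in LD with any other candidate.

    For each threshold t, the fraction of candidates whose maximum
    off-diagonal r^2 (NaNs ignored) is < t.
    """
    vals = L.to_numpy(dtype=float).copy()
    np.fill_diagonal(vals, np.nan)
    with np.errstate(all="ignore"):
        max_off = np.nanmax(vals, axis=1)
    max_off = np.where(np.isnan(max_off), 0.0, max_off)  # isolated candidate
    return {t: float((max_off < t).mean()) for t in thresholds}


def maf_effect_correlation(C: CandidateSet, signed: bool = False) -> tuple[float, float]:
    """Pearson correlation between candidate MAF and effect size |beta|.

    Effect size is the predicted phenotypic difference between the two
    SNP variants, i.e. |beta| for 0/1 genotypes; set ``signed`` to
    correlate raw beta instead.  Returns (r, two-sided p) or (nan, nan)
    when either vector has zero variance.
    """
    if len(C) < 3:
        raise ValueError("need >= 3 candidates for a correlation")
    maf = C.table["maf"].to_numpy(dtype=float)
    eff = C.table["beta"].to_numpy(dtype=float)
    if not signed:
        eff = np.abs(eff)
    if maf.std() == 0 or eff.std() == 0:
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(maf, eff)
    return float(r), float(p)


def maf_bins(mafs) -> dict:
    """Counts on the [0.02,0.05), [0.05,0.10), [0.10,0.5] MAF grid."""
    m = np.asarray(mafs, dtype=float)
    if (m < MAF_BIN_EDGES[0]).any():
        raise ValueError("MAF below 0.02 present — variant filter was not applied")
    if (m > 0.5).any():
        raise ValueError("MAF above 0.5 present")
    counts = {
        MAF_BIN_LABELS[0]: int(((m >= 0.02) & (m < 0.05)).sum()),
        MAF_BIN_LABELS[1]: int(((m >= 0.05) & (m < 0.10)).sum()),
        MAF_BIN_LABELS[2]: int((m >= 0.10).sum()),
    }
    return counts


def tag_genes(C: CandidateSet, A: pd.DataFrame) -> pd.DataFrame:
    """Assign each candidate SNP to a gene.

    A SNP inside a gene interval (0-based half-open, so 1-based position
    ``pos`` is inside iff start < pos <= end) tags that gene; an
    intergenic SNP tags the nearest gene on the same chromosome (distance
    to the closer interval boundary).  Equidistant ties go to the gene
    with the smaller start coordinate and are flagged.  Chromosomes
    without genes yield an unassigned flag.

    Returns a DataFrame indexed by variant id with columns
    ``gene_id, distance, tie, unassigned``.
    """
    rows = []
    genes_by_chrom = {c: g.sort_values("start") for c, g in A.groupby("chrom")}
    for vid, row in C.table.iterrows():
        genes = genes_by_chrom.get(row["chrom"])
        if genes is None or len(genes) == 0:
            rows.append((vid, None, np.nan, False, True))
            continue
        pos0 = row["pos"] - 1  # 0-based coordinate of the SNP
        start = genes["start"].to_numpy()
        end = genes["end"].to_numpy()
        inside = (pos0 >= start) & (pos0 < end)
        dist = np.where(inside, 0, np.minimum(np.abs(start - pos0), np.abs(pos0 - (end - 1))))
        order = np.lexsort((start, dist))
        best = order[0]
        tie = bool(len(order) > 1 and dist[order[1]] == dist[best])
        rows.append((vid, genes["gene_id"].iloc[best], int(dist[best]), tie, False))
    return pd.DataFrame(
        rows, columns=["variant_id", "gene_id", "distance", "tie", "unassigned"]
    ).set_index("variant_id")


def named_gene_hits(
    C: CandidateSet, named: pd.DataFrame, window: int = 10_000
) -> pd.DataFrame:
    """All (candidate, named gene) pairs within ``window`` bp.

    Distance is 0 inside the gene, else the gap to the nearer interval
    boundary; pairs at exactly ``window`` bp count as hits.
    """
    rows = []
    for vid, row in C.table.iterrows():
        pos0 = row["pos"] - 1
        for _, g in named[named["chrom"] == row["chrom"]].iterrows():
            if g["start"] <= pos0 < g["end"]:
                d = 0
            else:
                d = int(min(abs(g["start"] - pos0), abs(pos0 - (g["end"] - 1))))
            if d <= window:
                rows.append((vid, g["gene_id"], d))
    return pd.DataFrame(rows, columns=["variant_id", "gene_id", "distance"])


def is_specific(E: pd.DataFrame, focal_tissues=("nodule", "root")) -> pd.Series:
    """Gene-level flag: expressed in >=1 focal tissue and in no other."""
    wide = E.pivot_table(index="gene_id", columns="tissue", values="expressed", fill_value=0)
    focal = [t for t in focal_tissues if t in wide.columns]
    others = [t for t in wide.columns if t not in focal_tissues]
    return (wide[focal].sum(axis=1) > 0) & (wide[others].sum(axis=1) == 0)


def specificity_enrichment(
    tagged_genes: list,
    E: pd.DataFrame,
    universe_size: int,
    universe_specific: int,
) -> dict:
    """Hypergeometric upper-tail enrichment of tissue-specific genes.

    Counts how many of the tagged genes show nodule/root-specific
    expression and returns P(X >= observed) for drawing the tagged sample
    without replacement from a universe of ``universe_size`` genes of
    which ``universe_specific`` are specific.
    """
    n = len(tagged_genes)
    if n > universe_size:
        raise ValueError("sample larger than the gene universe")
    if not (0 <= universe_specific <= universe_size):
        raise ValueError("inconsistent specific-gene counts")
    spec = is_specific(E)
    observed = int(sum(bool(spec.get(g, False)) for g in tagged_genes))
    p = hypergeom_tail(observed, universe_size, universe_specific, n)
    return {"observed": observed, "sample": n, "p_value": p}


def hypergeom_tail(observed: int, N: int, K: int, n: int) -> float:
    """Exact upper tail P(X >= observed), X ~ Hypergeometric(N, K, n)."""
    if observed <= 0:
        return 1.0
    return float(stats.hypergeom.sf(observed - 1, N, K, n))


def candidate_maf_anova(maf_lists: dict) -> dict:
    """One-way fixed-effects F test of mean candidate MAF across traits."""
    groups = [np.asarray(v, dtype=float) for v in maf_lists.values() if len(v) > 1]
    if len(groups) < 2:
        raise ValueError("need >= 2 traits with >= 2 candidates each")
    F, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return {"F": float(F), "p_value": float(p), "df": (df1, df2)}


def maf_mean_permutation_test(
    candidate_maf, genomewide_maf, n_perm: int = 1000, seed: int = 0
) -> dict:
    """Two-sample permutation test for mean candidate MAF vs genome-wide.

    Two-sided p-value for the difference in means under random relabeling.
    """
    a = np.asarray(candidate_maf, float)
    b = np.asarray(genomewide_maf, float)
    rng = np.random.default_rng(seed)
    obs = a.mean() - b.mean()
    pool = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        d = pool[: len(a)].mean() - pool[len(a):].mean()
        if abs(d) >= abs(obs) - 1e-15:
            count += 1
    return {"diff": float(obs), "p_value": (count + 1) / (n_perm + 1)}


def manhattan_table(S: pd.DataFrame, C: CandidateSet | None = None) -> pd.DataFrame:
    """Plot-ready table: chrom, pos, -log10 p, candidate flag, MAF bin."""
    out = S[["chrom", "pos", "maf"]].copy()
    out["neglog10_p"] = -np.log10(S["p"])
    cand = set(C.variant_ids) if C is not None else set()
    out["candidate"] = [vid in cand for vid in S.index]
    edges = [-np.inf, 0.05, 0.10, np.inf]
    out["maf_bin"] = pd.cut(S["maf"], edges, labels=MAF_BIN_LABELS, right=False)
    return out
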