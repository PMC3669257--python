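"""Genotype containers, VCF/TSV interchange, and variant-level filters.

Genotypes for inbred (selfed) accessions are haploid-coded: 0 (reference
allele), 1 (alternate allele), or -1 (missing).  Heterozygous calls are a
contract violation — inbred lines carry no heterozygous sites — and are
rejected on input.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

MISSING = -1

#: columns of the variant table, in canonical order
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "maf", "n_called"]


class GenotypeDataError(ValueError):
    """Malformed genotype data (heterozygote, multi-allelic record, ...)."""


@dataclasses.dataclass
class GenotypeMatrix:
    """Accessions x biallelic variants with inbred {0,1,missing} coding.

    Attributes
    ----------
    accession_ids
        Ordered unique accession labels (rows of ``calls``).
    variants
        DataFrame with columns ``chrom, pos, ref, alt, maf, n_called``,
        sorted by (chrom, pos); ``pos`` is 1-based.  ``maf``/``n_called``
        are NaN/0 until :func:`compute_maf` runs.
    calls
        int8 array of shape (n_accessions, n_variants); -1 is missing.
    """

    accession_ids: list[str]
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.accession_ids), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.variants)} variants"
            )
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("accession ids are not unique")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise GenotypeDataError("calls contain codes outside {0, 1, missing}")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> pd.Index:
        return self.variants.index

    def subset_variants(self, mask_or_ids) -> "GenotypeMatrix":
        """Return a copy restricted to a boolean mask or list of variant ids."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray)) and np.asarray(
            mask_or_ids
        ).dtype == bool:
            mask = np.asarray(mask_or_ids)
            idx = np.flatnonzero(mask)
        else:
            idx = self.variants.index.get_indexer(pd.Index(mask_or_ids))
            if (idx < 0).any():
                missing = pd.Index(mask_or_ids)[idx < 0]
                raise KeyError(f"variant ids not present: {list(missing[:5])}")
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            variants=self.variants.iloc[idx].copy(),
            calls=self.calls[:, idx].copy(),
        )

    def subset_accessions(self, ids: list[str]) -> "GenotypeMatrix":
        pos = [self.accession_ids.index(a) for a in ids]
        return GenotypeMatrix(
            accession_ids=list(ids),
            variants=self.variants.copy(),
            calls=self.calls[pos, :].copy(),
        )


def _variant_index(variants: pd.DataFrame) -> pd.Index:
    return pd.Index(
        variants["chrom"].astype(str) + ":" + variants["pos"].astype(str),
        name="variant_id",
    )


def make_variant_table(
    chrom, pos, ref=None, alt=None
) -> pd.DataFrame:
    """Assemble a canonical variant table sorted by (chrom, pos)."""
    n = len(pos)
    tab = pd.DataFrame(
        {
            "chrom": pd.Series(chrom, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
            "ref": pd.Series(ref if ref is not None else ["A"] * n, dtype=str),
            "alt": pd.Series(alt if alt is not None else ["T"] * n, dtype=str),
            "maf": np.nan,
            "n_called": 0,
        }
    )
    if (tab["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    tab = tab.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    tab.index = _variant_index(tab)
    return tab


def compute_maf(G: GenotypeMatrix) -> GenotypeMatrix:
    """Fill ``maf`` and ``n_called`` from the call matrix (in place).

    MAF is computed over called genotypes only: min(f_alt, 1 - f_alt).
    Variants with no calls get ``maf = NaN`` (undefined flag).
    """
    called = G.calls != MISSING
    n_called = called.sum(axis=0)
    alt_count = np.where(called, G.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_alt = np.where(n_called > 0, alt_count / np.maximum(n_called, 1), np.nan)
    maf = np.minimum(f_alt, 1.0 - f_alt)
    G.variants["maf"] = maf
    G.variants["n_called"] = n_called.astype(np.int64)
    return G


def filter_variants(
    G: GenotypeMatrix, min_maf: float = 0.02, min_called: int = 100
) -> GenotypeMatrix:
    """Apply the inclusion filters: MAF >= min_maf and called in >= min_called.

    Both boundaries are inclusive.  Variants with undefined MAF (no calls)
    are removed.  Variant order is preserved; filtering is idempotent.
    """
    if min_called > G.n_accessions:
        raise ValueError(
            f"min_called={min_called} exceeds the {G.n_accessions} accessions present"
        )
    if G.variants["maf"].isna().all() and G.n_variants > 0 and G.variants["n_called"].eq(0).all():
        compute_maf(G)
    maf = G.variants["maf"].to_numpy()
    n_called = G.variants["n_called"].to_numpy()
    keep = (~np.isnan(maf)) & (maf >= min_maf) & (n_called >= min_called)
    return G.subset_variants(keep)


# ---------------------------------------------------------------------------
# interchange formats


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from VCF (haploid or homozygous-diploid GT) or TSV."""
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {format!r} (expected 'vcf' or 'tsv')")


def _decode_gt(gt: tuple, record) -> int:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return MISSING
    if len(set(alleles)) > 1:
        raise GenotypeDataError(
            f"heterozygous call at {record.chrom}:{record.pos}: GT={gt} "
            "(inbred lines must be homozygous)"
        )
    return int(alleles[0])


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        chroms, poss, refs, alts, rows = [], [], [], [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise GenotypeDataError(
                    f"record at {rec.chrom}:{rec.pos} is not biallelic"
                )
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            rows.append([_decode_gt(s["GT"], rec) for s in rec.samples.values()])
    variants = make_variant_table(chroms, poss, refs, alts)
    calls = np.array(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0), np.int8)
    # make_variant_table sorts; realign calls to sorted order
    order = variants.index.get_indexer(
        pd.Index([f"{c}:{p}" for c, p in zip(chroms, poss)])
    )
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    G = GenotypeMatrix(samples, variants, calls[:, inv] if rows else calls)
    return compute_maf(G)


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write haploid-GT VCF ('.' for missing)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(G.variants["chrom"]):
            end = int(G.variants.loc[G.variants["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={end + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.accession_ids)
            + "\n"
        )
        code = {0: "0", 1: "1", MISSING: "."}
        for j, (vid, row) in enumerate(G.variants.iterrows()):
            gts = "\t".join(code[int(c)] for c in G.calls[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{vid}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


def _read_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["chrom", "pos", "ref", "alt"]
    acc_cols = [c for c in df.columns if c not in meta_cols]
    variants = make_variant_table(df["chrom"], df["pos"], df["ref"], df["alt"])
    calls = df[acc_cols].to_numpy(dtype=float)
    bad = ~(np.isnan(calls) | np.isin(calls, (0.0, 1.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeDataError(
            f"invalid genotype code {calls[i, j]!r} for accession {acc_cols[j]}"
        )
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8).T
    order = variants.index.get_indexer(
        pd.Index(df["chrom"].astype(str) + ":" + df["pos"].astype(str))
    )
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    G = GenotypeMatrix(acc_cols, variants, calls[:, inv])
    return compute_maf(G)


def write_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    """Rectangular TSV: variant rows, accession columns, 'NA' for missing."""
    df = G.variants[["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    calls = G.calls.astype(object).T
    for i, acc in enumerate(G.accession_ids):
        col = G.calls[i].astype(object)
        col[G.calls[i] == MISSING] = np.nan
        df[acc] = col
    del calls
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
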