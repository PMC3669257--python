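"""Kinship estimation and the expedited mixed-linear-model association scan.

The scan follows the EMMAX / P3D recipe: variance components of the null
model y = mu + g + e, with g ~ N(0, sigma2_g K), are estimated once by
restricted maximum likelihood via an eigendecomposition of the kinship
matrix K, then held fixed while every variant is tested by generalized
least squares in the rotated (whitened) coordinate system.  This trades
per-variant exactness for a single spectral decomposition, the standard
expedient for dense genome scans.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import MISSING, GenotypeMatrix


@dataclasses.dataclass
class KinshipMatrix:
    """Allele-sharing (identity-in-state) relatedness between accessions."""

    accession_ids: list[str]
    values: np.ndarray  # symmetric, in [0, 1], diagonal 1
    n_snps_used: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match accession count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("kinship matrix is not symmetric")


@dataclasses.dataclass
class VarianceComponents:
    """REML variance parameters of the null mixed model."""

    sigma2_g: float
    sigma2_e: float
    delta: float  # sigma2_e / sigma2_g
    log_restricted_likelihood: float


def estimate_kinship(
    G: GenotypeMatrix, snps_per_chrom: int = 5000, seed: int = 0
) -> KinshipMatrix:
    """IBS kinship from a per-chromosome random sample of variants.

    Samples up to ``snps_per_chrom`` variants without replacement from each
    chromosome, then computes, for every accession pair, the proportion of
    sampled variants at which both are called and carry the same allele
    (pairwise-complete).  Diagonal is 1 by construction.
    """
    if G.n_variants == 0:
        raise ValueError("no variants available for kinship estimation")
    rng = np.random.default_rng(seed)
    chosen = []
    for chrom in pd.unique(G.variants["chrom"]):
        idx = np.flatnonzero((G.variants["chrom"] == chrom).to_numpy())
        k = min(snps_per_chrom, len(idx))
        chosen.append(np.sort(rng.choice(idx, size=k, replace=False)))
    idx = np.concatenate(chosen)

    calls = G.calls[:, idx].astype(float)
    called = calls != MISSING
    calls_z = np.where(called, calls, 0.0)
    called_f = called.astype(float)
    # matches = #(both called, equal) = #(both 1) + #(both 0)
    both_called = called_f @ called_f.T
    both_alt = calls_z @ calls_z.T
    ref_z = np.where(called, 1.0 - calls, 0.0)
    both_ref = ref_z @ ref_z.T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(both_called > 0, (both_alt + both_ref) / both_called, np.nan)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    if np.isnan(K).any():
        raise ValueError("some accession pairs share no called sampled variants")
    return KinshipMatrix(list(G.accession_ids), K, n_snps_used=len(idx), seed=seed)


def _reml_neg_loglik(log_delta: float, lam: np.ndarray, eta: np.ndarray) -> float:
    """-2x restricted log-likelihood profile in delta (variance ratio).

    ``lam`` are eigenvalues of the kinship restricted to the residual space
    of the intercept, ``eta`` the correspondingly rotated phenotype.
    """
    delta = np.exp(log_delta)
    denom = lam + delta
    q = len(eta)
    sigma2_g = float((eta**2 / denom).sum() / q)
    ll = -0.5 * (q * np.log(2 * np.pi * sigma2_g) + np.log(denom).sum() + q)
    return -ll


def fit_null_reml(
    y: np.ndarray, K: KinshipMatrix, tol: float = 1e-8
) -> VarianceComponents:
    """REML fit of y = mu + g + e with g ~ N(0, sigma2_g K).

    One-dimensional Brent search on log(delta) in [-10, 10] after projecting
    out the intercept and rotating into the eigenbasis of the projected
    kinship matrix.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need >= 10 accessions for the null REML fit")
    if not np.isfinite(y).all():
        raise ValueError("phenotype vector contains non-finite values")
    Kv = K.values
    w_k = np.linalg.eigvalsh(Kv)
    # pairwise-complete IBS can dip slightly below PSD; repair small noise,
    # reject anything that looks structurally indefinite
    if w_k.min() < -0.05 * max(1.0, w_k.max()):
        raise ValueError(f"kinship matrix is not PSD (min eigenvalue {w_k.min():.3g})")

    # restrict to the orthogonal complement of the intercept
    ones = np.ones((n, 1))
    P = np.eye(n) - ones @ ones.T / n
    KP = P @ Kv @ P
    w, U = np.linalg.eigh((KP + KP.T) / 2.0)
    keep = np.argsort(w)[1:]  # drop the intercept's null direction
    lam = np.clip(w[keep], 0.0, None)
    eta = U[:, keep].T @ y

    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(-10.0, 10.0),
        args=(lam, eta),
        method="bounded",
        options={"xatol": tol},
    )
    delta = float(np.exp(res.x))
    q = len(eta)
    sigma2_g = float((eta**2 / (lam + delta)).sum() / q)
    return VarianceComponents(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_g * delta,
        delta=delta,
        log_restricted_likelihood=float(-res.fun),
    )


def scan(
    y: np.ndarray,
    G: GenotypeMatrix,
    K: KinshipMatrix,
    vc: VarianceComponents,
) -> pd.DataFrame:
    """P3D association scan: per-variant GLS with fixed variance components.

    Missing genotypes are mean-imputed to the variant's allele frequency
    (scan only; ``n_used`` reports the non-missing count).  For each variant
    the model y = a + b*x + eps with Var(eps) = sigma2_g K + sigma2_e I is
    fitted by GLS via one global whitening rotation; the two-sided p-value
    comes from t = beta/se on n-2 degrees of freedom.

    Returns a DataFrame aligned with ``G.variants`` with columns
    ``chrom, pos, maf, n_used, beta, se, p``; monomorphic-after-imputation
    variants get NaN beta/se/p (excluded from candidate selection).
    """
    y = np.asarray(y, dtype=float)
    n, m = G.n_accessions, G.n_variants
    if len(y) != n:
        raise ValueError("phenotype length does not match accession count")

    V = vc.sigma2_g * K.values + vc.sigma2_e * np.eye(n)
    w, U = np.linalg.eigh((V + V.T) / 2.0)
    floor = 1e-10 * max(w.max(), 1.0)
    if w.max() <= 0:
        raise ValueError("total covariance matrix is not positive definite")
    w = np.clip(w, floor, None)
    A = (U / np.sqrt(w)).T  # whitener: A V A' = I

    calls = G.calls.astype(float)
    called = calls != MISSING
    n_used = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_used > 0, np.where(called, calls, 0.0).sum(axis=0) / np.maximum(n_used, 1), np.nan)
    X = np.where(called, calls, freq[None, :])

    yt = A @ y
    ot = A @ np.ones(n)
    Xt = A @ X

    # per-variant 2x2 weighted normal equations, vectorized
    s_oo = float(ot @ ot)
    s_oy = float(ot @ yt)
    s_yy = float(yt @ yt)
    s_ox = ot @ Xt  # (m,)
    s_xy = yt @ Xt
    s_xx = (Xt * Xt).sum(axis=0)

    det = s_oo * s_xx - s_ox**2
    mono = (np.nanmax(np.abs(X - X.mean(axis=0)), axis=0) < 1e-12) | (det <= 1e-12 * np.maximum(s_oo * s_xx, 1e-300)) | ~np.isfinite(freq)
    det_safe = np.where(mono, 1.0, det)
    beta = (s_oo * s_xy - s_ox * s_oy) / det_safe
    alpha = (s_xx * s_oy - s_ox * s_xy) / det_safe
    rss = s_yy - alpha * s_oy - beta * s_xy
    df = n - 2
    sigma2 = np.clip(rss, 0.0, None) / df
    se = np.sqrt(sigma2 * s_oo / det_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    beta[mono] = np.nan
    se[mono] = np.nan
    p[mono] = np.nan

    out = pd.DataFrame(
        {
            "chrom": G.variants["chrom"].to_numpy(),
            "pos": G.variants["pos"].to_numpy(),
            "maf": G.variants["maf"].to_numpy(),
            "n_used": n_used.astype(np.int64),
            "beta": beta,
            "se": se,
            "p": p,
        },
        index=G.variants.index,
    )
    return out


def qq_data(S: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, float]:
    """Expected vs observed -log10 p quantiles and the genomic-inflation factor.

    lambda_gc is the ratio of the median observed 1-df chi-square statistic
    to the median of the chi-square(1) reference distribution (0.4549...).
    """
    p = S["p"].dropna().to_numpy()
    m = len(p)
    if m < 100:
        raise ValueError("need >= 100 tested variants for q-q diagnostics")
    obs = -np.log10(np.sort(p))  # p ascending -> -log10 descending
    exp = -np.log10(np.arange(1, m + 1) / (m + 1))
    chi = stats.chi2.isf(p, df=1)
    lambda_gc = float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
    return exp, obs, lambda_gc


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p * m)."""
    if not (0.0 < p <= 1.0):
        raise ValueError("p must lie in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def kinship_pc_variance(K: KinshipMatrix, n_pcs: int = 10) -> np.ndarray:
    """Fraction of kinship variance along the top principal components.

    Descriptive only — no PC covariates enter the association model.
    """
    Kc = K.values - K.values.mean(axis=0, keepdims=True)
    Kc = Kc - Kc.mean(axis=1, keepdims=True)
    w = np.sort(np.linalg.eigvalsh((Kc + Kc.T) / 2.0))[::-1]
    w = np.clip(w, 0.0, None)
    return w[:n_pcs] / w.sum()
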