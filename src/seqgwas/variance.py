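"""Variance explained by top candidates, with a permutation winner's-curse null.

Candidates selected by a genome scan and then evaluated on the same data
overstate the variance they explain (the Beavis effect / winner's curse).
This module reproduces the randomization correction: the top-50 candidate
multiple regression (missing genotype treated as a third state, backwards
stepwise AIC simplification) is re-run on phenotypes randomly reassigned
to accessions, and the empirical r^2 is rescaled against the null mean —
adjusted = (r^2 - mean_null) / (1 - mean_null) — under the assumption that
the truly explainable variance is uniformly distributed between the null
mean and one.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .architecture import CandidateSet, maf_bins, maf_effect_correlation, select_candidates
from .genotype_io import MISSING, GenotypeMatrix
from .lmm import KinshipMatrix, fit_null_reml, scan


@dataclasses.dataclass
class CandidateDesign:
    """Design matrix for the top-candidate regression.

    Each candidate contributes a 3-level categorical predictor
    {0, 1, missing} encoded as up to two indicator columns (level 0 is the
    reference); zero-variance and collinear columns are dropped and
    recorded.
    """

    y: np.ndarray
    X: np.ndarray  # (n_obs, n_columns), no intercept column
    columns: list[str]
    candidate_of: list[str]  # candidate id owning each column
    dropped: list[str]  # log of dropped columns with reasons


@dataclasses.dataclass
class RegressionReport:
    trait: str
    retained_variants: list
    r2: float
    aic: float
    n_candidates_in: int


@dataclasses.dataclass
class NullDistribution:
    n_randomizations: int
    r2_values: list
    maf_bin_counts: list  # per replicate, dict on the standard MAF grid (top 200)
    maf_effect_corr_top50: list
    maf_effect_corr_top200: list

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2_values))

    @property
    def sd_r2(self) -> float:
        return float(np.std(self.r2_values, ddof=1)) if len(self.r2_values) > 1 else 0.0


def candidate_design(
    y: pd.Series, G: GenotypeMatrix, C: CandidateSet
) -> CandidateDesign:
    """Build the missing-as-state indicator design for the candidate set.

    ``y`` is a Series of block-adjusted accession means indexed by
    accession id; accessions lacking a phenotype are dropped.
    """
    acc = [a for a in G.accession_ids if a in y.index and np.isfinite(y[a])]
    rows = [G.accession_ids.index(a) for a in acc]
    yv = y.loc[acc].to_numpy(dtype=float)

    cols, names, owner, dropped = [], [], [], []
    sub = G.subset_variants(C.variant_ids)
    for j, vid in enumerate(sub.variants.index):
        calls = sub.calls[rows, j]
        for level, suffix in ((1, "alt"), (MISSING, "mis")):
            col = (calls == level).astype(float)
            if col.std() == 0:
                dropped.append(f"{vid}:{suffix} (zero variance)")
                continue
            cols.append(col)
            names.append(f"{vid}:{suffix}")
            owner.append(vid)

    X = np.column_stack(cols) if cols else np.empty((len(acc), 0))
    # drop collinear columns greedily by rank contribution (QR with pivoting)
    if X.shape[1] > 1:
        keep = _independent_columns(np.column_stack([np.ones(len(acc)), X]))
        keep = [k - 1 for k in keep if k > 0]  # re-index without the intercept
        for i in range(X.shape[1]):
            if i not in keep:
                dropped.append(f"{names[i]} (collinear)")
        X = X[:, keep]
        names = [names[i] for i in keep]
        owner = [owner[i] for i in keep]
    return CandidateDesign(y=yv, X=X, columns=names, candidate_of=owner, dropped=dropped)


def _independent_columns(M: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    from scipy.linalg import qr

    if M.shape[1] == 0:
        return []
    _, R, piv = qr(M, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * max(diag[0], 1e-300)).sum())
    return sorted(piv[:rank].tolist())


def _gaussian_aic(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """(AIC, r^2) of the OLS fit of y on [1, X], R stepAIC convention.

    AIC = n*log(RSS/n) + 2*(p + 1) up to an additive constant (p columns
    including the intercept; +1 for the error variance).
    """
    n = len(y)
    D = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * (D.shape[1] + 1)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return aic, r2


def stepwise_regression(
    design: CandidateDesign, trait: str = ""
) -> RegressionReport:
    """Backwards stepwise AIC at whole-candidate granularity.

    Starts from the full model and repeatedly removes the candidate (all
    of its columns together) whose removal lowers AIC most, stopping when
    no removal lowers AIC.  If the initial model is not estimable
    (observations <= parameters), lowest-ranked candidates are pre-pruned
    until it is; the report records the number entering.
    """
    y = design.y
    order = list(dict.fromkeys(design.candidate_of))  # preserves p-rank order
    col_of = {c: [i for i, o in enumerate(design.candidate_of) if o == c] for c in order}

    active = list(order)
    # pre-prune worst-ranked candidates until the full model is estimable
    while active and len(y) <= sum(len(col_of[c]) for c in active) + 2:
        active.pop()

    def fit(cands):
        idx = [i for c in cands for i in col_of[c]]
        return _gaussian_aic(y, design.X[:, idx])

    current_aic, current_r2 = fit(active)
    improved = True
    while improved and active:
        improved = False
        best = None
        for c in active:
            trial = [x for x in active if x != c]
            aic, r2 = fit(trial)
            if aic < current_aic - 1e-10 and (best is None or aic < best[1]):
                best = (c, aic, r2)
        if best is not None:
            active.remove(best[0])
            current_aic, current_r2 = best[1], best[2]
            improved = True
    return RegressionReport(
        trait=trait,
        retained_variants=active,
        r2=float(current_r2),
        aic=float(current_aic),
        n_candidates_in=len(order),
    )


def randomization_null(
    y: pd.Series,
    G: GenotypeMatrix,
    K: KinshipMatrix,
    R: int = 20,
    k: int = 50,
    seed: int = 0,
    trait: str = "",
) -> NullDistribution:
    """Winner's-curse null: R phenotype randomizations through the full pipeline.

    For each replicate the block-adjusted phenotype values are randomly
    reassigned to accessions (genotypes intact), the mixed-model scan is
    re-run (variance components re-fitted), the top-k candidates enter the
    missing-as-state stepwise regression, and the resulting r^2, top-200
    MAF-bin counts, and MAF-effect correlations (top 50 and top 200) are
    recorded.  These are approximate nulls: the kinship term makes the
    data not fully exchangeable.
    """
    rng = np.random.default_rng(seed)
    acc_order = [a for a in G.accession_ids if a in y.index]
    yv = y.loc[acc_order].to_numpy(dtype=float)

    r2s, bin_counts, corr50, corr200 = [], [], [], []
    for _ in range(R):
        perm = rng.permutation(len(yv))
        y_perm = pd.Series(yv[perm], index=acc_order)
        vc = fit_null_reml(y_perm.to_numpy(), K)
        S = scan(y_perm.to_numpy(), G, K, vc)
        top50 = select_candidates(S, k, trait=trait)
        top200 = select_candidates(S, 200, trait=trait)
        report = stepwise_regression(candidate_design(y_perm, G, top50), trait)
        r2s.append(report.r2)
        bin_counts.append(maf_bins(top200.table["maf"]))
        corr50.append(maf_effect_correlation(top50)[0])
        corr200.append(maf_effect_correlation(top200)[0])
    return NullDistribution(
        n_randomizations=R,
        r2_values=r2s,
        maf_bin_counts=bin_counts,
        maf_effect_corr_top50=corr50,
        maf_effect_corr_top200=corr200,
    )


def adjusted_r2(empirical_r2: float, null_mean_r2: float) -> dict:
    """Rescale r^2 above the randomization-null mean.

    adjusted = (empirical - null_mean) / (1 - null_mean); negative when the
    empirical value falls below the null mean.
    """
    if null_mean_r2 >= 1.0:
        raise ValueError("null mean r^2 must be < 1")
    adj = (empirical_r2 - null_mean_r2) / (1.0 - null_mean_r2)
    return {
        "empirical_r2": float(empirical_r2),
        "null_mean_r2": float(null_mean_r2),
        "adjusted": float(adj),
    }
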