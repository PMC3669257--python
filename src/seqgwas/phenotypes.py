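"""Block-adjusted accession means and among-accession variance partitions.

Replicated trait measurements from a randomized complete block design are
reduced to least-squares means per accession (block differences removed),
the quantity all downstream association stages operate on.  A one-way
random-effects variance partition (method of moments) estimates the
fraction of trait variance attributable to accessions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["accession", "block", "trait", "value"]


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "block": str, "trait": str})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    return df


def write_phenotypes(P: pd.DataFrame, path) -> None:
    P[REQUIRED_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def _trait_records(P: pd.DataFrame, trait: str) -> pd.DataFrame:
    if trait not in set(P["trait"]):
        raise ValueError(f"trait {trait!r} not present in the phenotype table")
    sub = P.loc[(P["trait"] == trait) & P["value"].notna()].copy()
    dup = sub.duplicated(subset=["accession", "block"])
    if dup.any():
        raise ValueError("multiple records for one (accession, block, trait) cell")
    return sub


def _fit_accession_block(sub: pd.DataFrame):
    """Least-squares fit of value = accession + block (blocks effect-coded).

    Returns (accession labels, accession coefficients, block labels,
    block effects summing to zero).  With sum-to-zero block effects the
    accession coefficient is its least-squares mean.
    """
    acc, acc_lab = pd.factorize(sub["accession"], sort=True)
    blk, blk_lab = pd.factorize(sub["block"], sort=True)
    n_obs, a, B = len(sub), len(acc_lab), len(blk_lab)
    if B < 2:
        raise ValueError("need >= 2 blocks to separate block effects")
    X = np.zeros((n_obs, a + B - 1))
    X[np.arange(n_obs), acc] = 1.0
    for j in range(B - 1):
        X[blk == j, a + j] = 1.0
        X[blk == B - 1, a + j] = -1.0  # sum-to-zero constraint
    y = sub["value"].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    blk_eff = np.append(coef[a:], -coef[a:].sum())
    return acc_lab, coef[:a], blk_lab, blk_eff


def block_adjusted_means(P: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Least-squares means per accession after removing block differences.

    Fits the additive fixed-effects model value = accession + block and
    returns each accession's coefficient under a sum-to-zero constraint on
    block effects (block effects averaged out).  Handles unbalanced data
    via the normal equations.

    Returns a DataFrame indexed by accession with columns
    ``adjusted_mean`` and ``n_replicates``.
    """
    sub = _trait_records(P, trait)
    acc_lab, acc_coef, _, _ = _fit_accession_block(sub)
    counts = sub.groupby("accession").size().reindex(acc_lab).to_numpy()
    return pd.DataFrame(
        {"adjusted_mean": acc_coef, "n_replicates": counts},
        index=pd.Index(acc_lab, name="accession"),
    )


def encode_flowering(dates) -> np.ndarray:
    """Encode flowering dates as ranks 1..9 plus 10 for never-flowered.

    ``dates`` is a sequence of per-replicate scoring dates (any orderable
    values); NaN/None marks plants that never flowered.  Observed distinct
    dates map to 1..k (k <= 9) in chronological order; never-flowered maps
    to 10.  The output feeds block_adjusted_means untransformed.
    """
    s = pd.Series(list(dates))
    flowered = s.notna()
    distinct = np.sort(s[flowered].unique())
    if len(distinct) > 9:
        raise ValueError(
            f"{len(distinct)} distinct flowering dates exceed the 9-date scoring scheme"
        )
    rank = {d: i + 1 for i, d in enumerate(distinct)}
    out = np.full(len(s), 10.0)
    out[flowered.to_numpy()] = [rank[d] for d in s[flowered]]
    return out


def variance_partition(P: pd.DataFrame, trait: str) -> dict:
    """Among/within accession variance components, blocks removed first.

    Block effects from the additive accession+block fit are subtracted,
    then a one-way random-effects method-of-moments decomposition is
    applied to the residual values grouped by accession:
    ``sigma2_within = MS_within`` and
    ``sigma2_among = max(0, (MS_among - MS_within) / n0)`` with ``n0`` the
    standard unbalanced-design replicate coefficient
    ``(N - sum(n_i^2)/N) / (a - 1)``.
    """
    sub = _trait_records(P, trait)
    acc_lab, _, blk_lab, blk_eff = _fit_accession_block(sub)
    blk_map = dict(zip(blk_lab, blk_eff))
    resid = sub["value"].to_numpy(dtype=float) - sub["block"].map(blk_map).to_numpy()

    groups = pd.Series(resid).groupby(sub["accession"].to_numpy())
    n_i = groups.size().to_numpy(dtype=float)
    if (n_i >= 2).sum() < 2:
        raise ValueError("need >= 2 accessions with >= 2 replicates")
    means = groups.mean().to_numpy()
    N, a = n_i.sum(), len(n_i)
    grand = resid.mean()
    ss_among = float((n_i * (means - grand) ** 2).sum())
    ss_within = float(groups.apply(lambda g: ((g - g.mean()) ** 2).sum()).sum())
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / (N - a)
    n0 = (N - (n_i**2).sum() / N) / (a - 1)
    sigma2_within = ms_within
    sigma2_among = max(0.0, (ms_among - ms_within) / n0)
    total = sigma2_among + sigma2_within
    return {
        "sigma2_among": sigma2_among,
        "sigma2_within": sigma2_within,
        "proportion_among": sigma2_among / total if total > 0 else 0.0,
    }


def trait_correlation_matrix(P: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between traits' block-adjusted accession means."""
    traits = sorted(P["trait"].unique())
    means = {t: block_adjusted_means(P, t)["adjusted_mean"] for t in traits}
    return pd.DataFrame(means).corr()
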