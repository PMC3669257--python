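import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqgwas import (
    KinshipMatrix,
    SimConfig,
    bonferroni_adjust,
    block_adjusted_means,
    estimate_kinship,
    filter_variants,
    fit_null_reml,
    qq_data,
    scan,
    simulate_genotypes,
    simulate_phenotypes,
)
from seqgwas.genotype_io import MISSING, GenotypeMatrix, compute_maf, make_variant_table
from seqgwas.lmm import _reml_neg_loglik


def matrix(calls):
    calls = np.asarray(calls, dtype=np.int8)
    return compute_maf(
        GenotypeMatrix(
            [f"A{i}" for i in range(calls.shape[0])],
            make_variant_table(["chr1"] * calls.shape[1], list(range(1, calls.shape[1] + 1))),
            calls,
        )
    )


class TestKinship:
    def test_identical_and_opposite_accessions(self):
        calls = np.zeros((3, 20), dtype=np.int8)
        calls[1] = calls[0]
        calls[2] = 1 - calls[0]
        calls[0, :10] = 1
        calls[1, :10] = 1
        calls[2, :10] = 0
        K = estimate_kinship(matrix(calls), snps_per_chrom=100, seed=0)
        assert K.values[0, 1] == pytest.approx(1.0)
        assert K.values[0, 2] == pytest.approx(0.0)

    def test_matches_double_loop_oracle(self, rng):
        calls = rng.integers(0, 2, size=(10, 100)).astype(np.int8)
        G = matrix(calls)
        K = estimate_kinship(G, snps_per_chrom=100, seed=0)
        for i in range(10):
            for j in range(10):
                expected = np.mean(calls[i] == calls[j])
                assert K.values[i, j] == pytest.approx(expected)

    def test_missing_pairwise_complete(self, rng):
        calls = rng.integers(0, 2, size=(6, 200)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.3] = MISSING
        G = matrix(calls)
        K = estimate_kinship(G, snps_per_chrom=200, seed=0)
        i, j = 1, 4
        both = (calls[i] != MISSING) & (calls[j] != MISSING)
        assert K.values[i, j] == pytest.approx(
            np.mean(calls[i, both] == calls[j, both])
        )

    def test_reproducible_per_seed(self, scanned):
        Gf = scanned[0]
        K1 = estimate_kinship(Gf, snps_per_chrom=50, seed=7)
        K2 = estimate_kinship(Gf, snps_per_chrom=50, seed=7)
        np.testing.assert_array_equal(K1.values, K2.values)

    def test_no_variants_rejected(self, small_sim):
        _, G, _, _ = small_sim
        empty = G.subset_variants(np.zeros(G.n_variants, dtype=bool))
        with pytest.raises(ValueError):
            estimate_kinship(empty, seed=0)


class TestNullReml:
    def test_identity_kinship_total_variance(self, rng):
        n = 200
        y = rng.normal(0, 1.5, size=n)
        K = KinshipMatrix([f"A{i}" for i in range(n)], np.eye(n), 0)
        vc = fit_null_reml(y, K)
        total = vc.sigma2_g + vc.sigma2_e  # V = (sg+se) I under K = I
        assert total == pytest.approx(np.var(y, ddof=1), rel=0.1)

    def test_delta_recovery_on_structured_kinship(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            # strongly related families identify the variance ratio well
            fam = rng.integers(0, 40, n)
            Kv = 0.9 * (fam[:, None] == fam[None, :]) + 0.1 * np.eye(n)
            L = np.linalg.cholesky(Kv + 1e-9 * np.eye(n))
            y = L @ rng.normal(size=n) + rng.normal(size=n)  # sg = se = 1
            K = KinshipMatrix([f"A{i}" for i in range(n)], Kv, 0)
            vc = fit_null_reml(y, K)
            hits += 0.5 <= vc.delta <= 2.0
        assert hits >= 18

    def test_optimum_beats_delta_grid(self, scanned):
        _, K, vc, y, _ = scanned
        yv = y.to_numpy()
        n = len(yv)
        ones = np.ones((n, 1))
        P = np.eye(n) - ones @ ones.T / n
        KP = P @ K.values @ P
        w, U = np.linalg.eigh((KP + KP.T) / 2)
        keep = np.argsort(w)[1:]
        lam = np.clip(w[keep], 0, None)
        eta = U[:, keep].T @ yv
        for delta in (0.1, 1.0, 10.0):
            assert vc.log_restricted_likelihood >= -_reml_neg_loglik(
                np.log(delta), lam, eta
            ) - 1e-6

    def test_nonfinite_phenotype_rejected(self, scanned):
        _, K, _, y, _ = scanned
        bad = y.to_numpy().copy()
        bad[0] = np.nan
        with pytest.raises(ValueError):
            fit_null_reml(bad, K)


class TestScan:
    def test_identity_kinship_reduces_to_ols(self, rng):
        n, m = 60, 40
        calls = rng.integers(0, 2, size=(n, m)).astype(np.int8)
        G = matrix(calls)
        y = rng.normal(size=n)
        K = KinshipMatrix(G.accession_ids, np.eye(n), 0)
        vc = fit_null_reml(y, K)
        S = scan(y, G, K, vc)
        for j in range(m):
            x = calls[:, j].astype(float)
            if x.std() == 0:
                continue
            res = stats.linregress(x, y)
            assert S["beta"].iloc[j] == pytest.approx(res.slope, abs=1e-8)
            assert S["p"].iloc[j] == pytest.approx(res.pvalue, abs=1e-8)

    def test_matches_explicit_inverse_gls_oracle(self, rng):
        # brute-force oracle: per-variant GLS with an explicit V^{-1}
        n, m = 50, 200
        cfg = SimConfig(
            n_accessions=n, n_variants=m, n_chromosomes=2, chrom_length_bp=100_000,
            seed=17, n_causal=3, h2_causal=0.3, h2_polygenic=0.3, missing_rate=0.1,
        )
        G, truth = simulate_genotypes(cfg)
        P, truth = simulate_phenotypes(G, truth, cfg)
        y = (
            block_adjusted_means(P, "trait")["adjusted_mean"]
            .reindex(G.accession_ids)
            .to_numpy()
        )
        Gf = filter_variants(G, min_maf=0.02, min_called=30)
        K = estimate_kinship(Gf, snps_per_chrom=100, seed=3)
        vc = fit_null_reml(y, K)
        S = scan(y, Gf, K, vc)

        V = vc.sigma2_g * K.values + vc.sigma2_e * np.eye(n)
        Vinv = np.linalg.inv(V)
        calls = Gf.calls.astype(float)
        called = calls != MISSING
        for j in range(Gf.n_variants):
            x = calls[:, j].copy()
            freq = x[called[:, j]].mean()
            x[~called[:, j]] = freq
            X = np.column_stack([np.ones(n), x])
            XtVi = X.T @ Vinv
            coef = np.linalg.solve(XtVi @ X, XtVi @ y)
            resid = y - X @ coef
            sigma2 = (resid @ Vinv @ resid) / (n - 2)
            se = np.sqrt(sigma2 * np.linalg.inv(XtVi @ X)[1, 1])
            t = coef[1] / se
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert S["beta"].iloc[j] == pytest.approx(coef[1], abs=1e-6)
            assert S["se"].iloc[j] == pytest.approx(se, abs=1e-6)
            assert S["p"].iloc[j] == pytest.approx(p, abs=1e-6)

    def test_invariant_to_variant_and_accession_order(self, scanned):
        Gf, K, vc, y, S = scanned
        # accession order: permute rows of everything consistently
        perm = np.random.default_rng(1).permutation(Gf.n_accessions)
        ids = [Gf.accession_ids[i] for i in perm]
        G2 = Gf.subset_accessions(ids)
        K2 = KinshipMatrix(ids, K.values[np.ix_(perm, perm)], K.n_snps_used)
        S2 = scan(y.to_numpy()[perm], G2, K2, vc)
        np.testing.assert_allclose(S2["p"].to_numpy(), S["p"].to_numpy(), atol=1e-8)

    def test_allele_recoding_flips_beta_only(self, scanned):
        Gf, K, vc, y, S = scanned
        G2 = Gf.subset_variants(list(Gf.variants.index[:20]))
        flipped = G2.calls.copy()
        mask = flipped != MISSING
        flipped[mask] = 1 - flipped[mask]
        G3 = compute_maf(GenotypeMatrix(G2.accession_ids, G2.variants.copy(), flipped))
        S3 = scan(y.to_numpy(), G3, K, vc)
        S2 = scan(y.to_numpy(), G2, K, vc)
        np.testing.assert_allclose(S3["beta"].to_numpy(), -S2["beta"].to_numpy(), atol=1e-8)
        np.testing.assert_allclose(S3["se"].to_numpy(), S2["se"].to_numpy(), atol=1e-8)
        np.testing.assert_allclose(S3["p"].to_numpy(), S2["p"].to_numpy(), atol=1e-8)

    def test_monomorphic_variant_flagged(self, rng):
        calls = rng.integers(0, 2, size=(30, 3)).astype(np.int8)
        calls[:, 1] = 0
        G = matrix(calls)
        y = rng.normal(size=30)
        K = KinshipMatrix(G.accession_ids, np.eye(30), 0)
        S = scan(y, G, K, fit_null_reml(y, K))
        assert np.isnan(S["p"].iloc[1])
        assert S["p"].drop(S.index[1]).notna().all()


class TestQQ:
    def test_uniform_grid_lambda_one(self):
        m = 1000
        S = pd.DataFrame(
            {"p": np.arange(1, m + 1) / (m + 1), "chrom": "chr1", "pos": range(m)}
        )
        _, _, lam = qq_data(S)
        assert lam == pytest.approx(1.0, abs=1e-2)

    def test_too_few_pvalues_rejected(self):
        S = pd.DataFrame({"p": [0.5], "chrom": ["chr1"], "pos": [1]})
        with pytest.raises(ValueError):
            qq_data(S)

    def test_confounding_inflates_lambda_without_kinship(self):
        lam_no, lam_yes = [], []
        for seed in range(10):
            cfg = SimConfig(
                n_accessions=150, n_variants=2000, n_chromosomes=2,
                chrom_length_bp=300_000, seed=seed, n_causal=0,
                h2_causal=0.0, h2_polygenic=0.8, n_subpops=2,
            )
            G, truth = simulate_genotypes(cfg)
            P, truth = simulate_phenotypes(G, truth, cfg)
            y = (
                block_adjusted_means(P, "trait")["adjusted_mean"]
                .reindex(G.accession_ids)
                .to_numpy()
            )
            Gf = filter_variants(G, min_maf=0.02, min_called=90)
            K = estimate_kinship(Gf, snps_per_chrom=1000, seed=0)
            KI = KinshipMatrix(K.accession_ids, np.eye(len(y)), 0)
            S0 = scan(y, Gf, KI, fit_null_reml(y, KI))
            S1 = scan(y, Gf, K, fit_null_reml(y, K))
            lam_no.append(qq_data(S0)[2])
            lam_yes.append(qq_data(S1)[2])
        assert np.mean(lam_no) > 1.2
        assert 0.9 <= np.mean(lam_yes) <= 1.1


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, m, expected",
        [
            (3e-9, 6_344_526, 3e-9 * 6_344_526),
            (0.5, 1, 0.5),
            (0.1, 100, 1.0),
        ],
    )
    def test_worked_examples(self, p, m, expected):
        assert bonferroni_adjust(p, m) == pytest.approx(expected)

    def test_genomewide_top_hit_survives_correction(self):
        assert bonferroni_adjust(3e-9, 6_344_526) < 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_adjust(0.5, 0)
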