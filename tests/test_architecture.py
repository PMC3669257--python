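import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqgwas import (
    SimConfig,
    ld_matrix,
    ld_summary,
    maf_bins,
    maf_effect_correlation,
    named_gene_hits,
    select_candidates,
    simulate_genotypes,
    specificity_enrichment,
    tag_genes,
)
from seqgwas.architecture import (
    CandidateSet,
    candidate_maf_anova,
    hypergeom_tail,
    is_specific,
    maf_mean_permutation_test,
)
from seqgwas.genotype_io import MISSING, GenotypeMatrix, compute_maf, make_variant_table


def cand(df, trait="t", k=None):
    return CandidateSet(trait=trait, k=k or len(df), table=df)


def scan_frame(p, chrom=None, pos=None, maf=None, beta=None):
    m = len(p)
    df = pd.DataFrame(
        {
            "chrom": chrom or ["chr1"] * m,
            "pos": pos or list(range(1, m + 1)),
            "maf": maf if maf is not None else np.full(m, 0.2),
            "n_used": 50,
            "beta": beta if beta is not None else np.ones(m),
            "se": 1.0,
            "p": p,
        }
    )
    df.index = pd.Index(
        [f"{c}:{q}" for c, q in zip(df["chrom"], df["pos"])], name="variant_id"
    )
    return df


class TestSelectCandidates:
    def test_k1_returns_global_minimum(self):
        S = scan_frame([0.5, 0.01, 0.3])
        assert select_candidates(S, 1).variant_ids == ["chr1:2"]

    def test_tie_broken_by_position(self):
        S = scan_frame([0.01, 0.01, 0.5], pos=[30, 10, 20])
        ids = select_candidates(S, 2).variant_ids
        assert ids == ["chr1:10", "chr1:30"]

    def test_invariant_to_input_order(self, scanned):
        S = scanned[4]
        shuffled = S.sample(frac=1.0, random_state=0)
        a = select_candidates(S, 50).variant_ids
        b = select_candidates(shuffled, 50).variant_ids
        assert a == b

    def test_nan_pvalues_excluded_and_truncation_flagged(self):
        S = scan_frame([0.1, np.nan, 0.2])
        C = select_candidates(S, 5)
        assert len(C) == 2 and C.truncated


class TestLD:
    def test_identical_and_complementary_vectors(self, rng):
        base = rng.integers(0, 2, 40).astype(np.int8)
        calls = np.column_stack([base, base, 1 - base])
        G = compute_maf(
            GenotypeMatrix(
                [f"A{i}" for i in range(40)],
                make_variant_table(["chr1"] * 3, [1, 2, 3]),
                calls,
            )
        )
        S = scan_frame([0.01, 0.02, 0.03])
        L = ld_matrix(G, cand(S))
        assert L.iloc[0, 1] == pytest.approx(1.0)
        assert L.iloc[0, 2] == pytest.approx(1.0)  # r = -1, r^2 = 1

    def test_independent_variants_low_mean_r2(self, rng):
        calls = rng.integers(0, 2, size=(200, 15)).astype(np.int8)
        G = compute_maf(
            GenotypeMatrix(
                [f"A{i}" for i in range(200)],
                make_variant_table(["chr1"] * 15, list(range(1, 16))),
                calls,
            )
        )
        S = scan_frame(np.linspace(0.01, 0.1, 15))
        L = ld_matrix(G, cand(S))
        off = L.to_numpy()[~np.eye(15, dtype=bool)]
        assert np.nanmean(off) < 0.03

    def test_allele_recoding_leaves_r2_unchanged(self, scanned):
        Gf, _, _, _, S = scanned
        C = select_candidates(S, 10)
        L1 = ld_matrix(Gf, C)
        flipped = Gf.subset_variants(C.variant_ids)
        mask = flipped.calls != MISSING
        flipped.calls[mask] = 1 - flipped.calls[mask]
        L2 = ld_matrix(compute_maf(flipped), cand(flipped.variants.join(C.table[["beta", "se", "p"]]), k=10))
        np.testing.assert_allclose(L1.to_numpy(), L2.to_numpy(), atol=1e-10)

    def test_too_few_complete_pairs_flagged(self):
        calls = np.array([[0, MISSING], [1, MISSING], [MISSING, 0], [MISSING, 1]] * 3, dtype=np.int8)
        G = compute_maf(
            GenotypeMatrix(
                [f"A{i}" for i in range(12)],
                make_variant_table(["chr1", "chr1"], [1, 2]),
                calls,
            )
        )
        L = ld_matrix(G, cand(scan_frame([0.01, 0.02])))
        assert np.isnan(L.iloc[0, 1])

    def test_absent_candidate_rejected(self, scanned):
        Gf = scanned[0]
        S = scan_frame([0.01], chrom=["chrX"], pos=[999])
        with pytest.raises(KeyError):
            ld_matrix(Gf, cand(S))


class TestLDSummary:
    def test_extremes(self):
        ids = ["a", "b", "c"]
        allone = pd.DataFrame(np.ones((3, 3)), index=ids, columns=ids)
        assert ld_summary(allone) == {0.8: 0.0, 0.3: 0.0}
        indep = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        assert ld_summary(indep) == {0.8: 1.0, 0.3: 1.0}

    def test_hand_enumerated_mixed_case(self):
        # max off-diagonal r2 per candidate: {0.9, 0.9, 0.5, 0.5, 0.1, 0.1} ->
        # build 3 pairs with r2 0.9, 0.5, 0.1
        ids = list("abcdef")
        M = np.eye(6)
        for (i, j), v in zip([(0, 1), (2, 3), (4, 5)], [0.9, 0.5, 0.1]):
            M[i, j] = M[j, i] = v
        L = pd.DataFrame(M, index=ids, columns=ids)
        out = ld_summary(L)
        assert out[0.8] == pytest.approx(4 / 6)
        assert out[0.3] == pytest.approx(2 / 6)


class TestMafEffect:
    def test_linearly_decreasing_effect_gives_minus_one(self):
        maf = np.linspace(0.05, 0.45, 10)
        S = scan_frame(np.linspace(0.01, 0.1, 10), maf=maf, beta=1.0 - maf)
        r, p = maf_effect_correlation(cand(S))
        assert r == pytest.approx(-1.0)

    def test_constant_maf_undefined(self):
        S = scan_frame([0.01, 0.02, 0.03], maf=[0.2, 0.2, 0.2])
        r, p = maf_effect_correlation(cand(S))
        assert np.isnan(r)

    def test_agrees_with_scipy_reference(self, scanned):
        S = scanned[4]
        C = select_candidates(S, 50)
        r, p = maf_effect_correlation(C)
        rr, pp = stats.pearsonr(C.table["maf"], C.table["beta"].abs())
        assert (r, p) == (pytest.approx(rr), pytest.approx(pp))


class TestMafBins:
    @pytest.mark.parametrize(
        "mafs, expected",
        [
            ([0.02, 0.049], (2, 0, 0)),
            ([0.05, 0.099, 0.10], (0, 2, 1)),
            ([0.5], (0, 0, 1)),
        ],
    )
    def test_boundary_contract(self, mafs, expected):
        out = maf_bins(mafs)
        assert tuple(out.values()) == expected

    def test_counts_sum_to_input_size(self, rng):
        mafs = rng.uniform(0.02, 0.5, 500)
        assert sum(maf_bins(mafs).values()) == 500

    def test_uniform_maf_analytic_fractions(self, rng):
        mafs = rng.uniform(0.02, 0.5, 10_000)
        out = np.array(list(maf_bins(mafs).values())) / 10_000
        np.testing.assert_allclose(out, [0.0625, 0.1042, 0.8333], atol=0.02)

    def test_below_filter_floor_rejected(self):
        with pytest.raises(ValueError):
            maf_bins([0.01])


class TestGeneTagging:
    ann = pd.DataFrame(
        {
            "gene_id": ["gX", "gY"],
            "chrom": ["chr1", "chr1"],
            "start": [1000, 2000],
            "end": [1500, 2500],
        }
    )

    def test_inside_gene(self):
        S = scan_frame([0.01], pos=[1200])
        out = tag_genes(cand(S), self.ann)
        assert out["gene_id"].iloc[0] == "gX" and out["distance"].iloc[0] == 0

    def test_nearest_gene_wins(self):
        # SNP at 1-based 1601 -> 0-based 1600: 101 bp right of gX end-1, 400 left of gY
        S = scan_frame([0.01], pos=[1601])
        out = tag_genes(cand(S), self.ann)
        assert out["gene_id"].iloc[0] == "gX"

    def test_equidistant_tie_flagged_smaller_start(self):
        # gX ends at 1499 (last base), gY starts at 2000; 0-based 1750 is not
        # equidistant, use midpoint 1749.5 -> pick integer case: gap 250/250
        S = scan_frame([0.01], pos=[1750])
        out = tag_genes(cand(S), self.ann)
        d_x = 1749 - 1499
        d_y = 2000 - 1749
        if d_x == d_y:
            assert out["tie"].iloc[0] and out["gene_id"].iloc[0] == "gX"
        else:  # document the asymmetric case explicitly
            assert out["gene_id"].iloc[0] == ("gX" if d_x < d_y else "gY")

    def test_no_genes_on_chromosome_unassigned(self):
        S = scan_frame([0.01], chrom=["chr9"], pos=[5])
        out = tag_genes(cand(S), self.ann)
        assert out["unassigned"].iloc[0]

    def test_named_gene_window_boundaries(self):
        named = pd.DataFrame(
            {"gene_id": ["gN"], "chrom": ["chr1"], "start": [100_000], "end": [101_000]}
        )
        hits_in = named_gene_hits(cand(scan_frame([0.01], pos=[90_002])), named)
        hits_out = named_gene_hits(cand(scan_frame([0.01], pos=[89_998])), named)
        assert len(hits_in) == 1  # 9,999 bp away
        assert len(hits_out) == 0  # 10,003 bp away

    def test_snp_in_two_windows_reported_twice(self):
        named = pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "chrom": ["chr1", "chr1"],
                "start": [0, 12_000],
                "end": [1_000, 13_000],
            }
        )
        hits = named_gene_hits(cand(scan_frame([0.01], pos=[6_000])), named)
        assert sorted(hits["gene_id"]) == ["gA", "gB"]


class TestEnrichment:
    expr = pd.DataFrame(
        {
            "gene_id": ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3,
            "tissue": ["nodule", "root", "leaf"] * 3,
            "expressed": [1, 0, 0, 1, 1, 1, 0, 0, 1],
        }
    )

    def test_specificity_definition(self):
        spec = is_specific(self.expr)
        assert spec["g1"] and not spec["g2"] and not spec["g3"]

    def test_zero_observed_gives_p_one(self):
        out = specificity_enrichment(["g2", "g3"], self.expr, 100, 10)
        assert out["p_value"] == 1.0

    def test_sample_equals_universe(self):
        out = specificity_enrichment(["g1", "g2"], self.expr, 2, 1)
        assert out["observed"] == 1 and out["p_value"] == pytest.approx(1.0)

    def test_matches_brute_force_summation(self):
        # oracle: direct pmf summation over the tail for a small universe
        from math import comb

        N, K, n, obs = 500, 40, 20, 5
        brute = sum(
            comb(K, k) * comb(N - K, n - k) / comb(N, n)
            for k in range(obs, min(K, n) + 1)
        )
        assert hypergeom_tail(obs, N, K, n) == pytest.approx(brute, rel=1e-10)

    def test_headline_enrichment_below_threshold(self):
        assert hypergeom_tail(8, 21_000, 850, 20) <= 0.001

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            specificity_enrichment(["g1"] * 5, self.expr, 3, 1)


class TestTraitLevelMafComparisons:
    def test_anova_detects_shifted_trait(self, rng):
        lists = {
            "t1": rng.uniform(0.02, 0.2, 200),
            "t2": rng.uniform(0.02, 0.2, 200),
            "t3": rng.uniform(0.2, 0.5, 200),
        }
        out = candidate_maf_anova(lists)
        assert out["p_value"] < 1e-6
        assert out["df"] == (2, 597)

    def test_permutation_test_nominal_under_null(self, rng):
        rejections = 0
        pool = rng.uniform(0.02, 0.5, 600)
        for i in range(40):
            idx = np.random.default_rng(i).permutation(600)
            p = maf_mean_permutation_test(
                pool[idx[:50]], pool[idx[50:]], n_perm=200, seed=i
            )["p_value"]
            rejections += p < 0.05
        assert rejections <= 6  # ~nominal 5% rate
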