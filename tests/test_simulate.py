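"""Haplotype panels, genotype sampling, phenotype models, preprocessing."""
import numpy as np
import pytest

from ridgesig import (DiseaseModel, GenotypeMatrix, ScenarioConfig,
                      ValidationError, build_haplotype_panel,
                      build_coalescent_panel, choose_window, designate_causal,
                      preprocess, sample_genotypes, simulate_binary_phenotype,
                      simulate_continuous_phenotype,
                      simulate_null_binary_phenotype, simulate_replicate)


def pairwise_r2(hap, i, j):
    return np.corrcoef(hap[:, i], hap[:, j])[0, 1] ** 2


class TestCopyingPanel:
    def test_independence_limit(self):
        panel = build_haplotype_panel(H=5000, M=40, ld_decay=0.0,
                                      dup_fraction=0.0, seed=1)
        r2 = [pairwise_r2(panel.haplotypes, i, j)
              for i in range(40) for j in range(i + 1, 40)]
        assert np.mean(r2) < 0.01

    def test_full_copying_limit(self):
        panel = build_haplotype_panel(H=500, M=10, ld_decay=1.0,
                                      dup_fraction=0.0, seed=2)
        for j in range(1, 10):
            np.testing.assert_array_equal(panel.haplotypes[:, j],
                                          panel.haplotypes[:, 0])

    def test_ld_decays_with_distance(self, copying_panel):
        hap = copying_panel.haplotypes
        M = copying_panel.n_snps
        adj = np.mean([pairwise_r2(hap, i, i + 1) for i in range(M - 1)])
        far = np.mean([pairwise_r2(hap, i, i + 50) for i in range(M - 50)])
        assert adj > far

    def test_maf_in_range_and_reproducible(self, copying_panel):
        assert ((copying_panel.pop_maf > 0) & (copying_panel.pop_maf <= 0.5)).all()
        again = build_haplotype_panel(H=4000, M=300, seed=101)
        np.testing.assert_array_equal(copying_panel.haplotypes, again.haplotypes)

    def test_duplicate_columns_occur(self):
        panel = build_haplotype_panel(H=2000, M=200, dup_fraction=0.2, seed=3)
        hap = panel.haplotypes
        dup = any((hap[:, j] == hap[:, j - 1]).all() for j in range(1, 200))
        assert dup


class TestCoalescentPanel:
    def test_realistic_structure(self, small_coalescent_panel):
        p = small_coalescent_panel
        assert ((p.pop_maf > 0) & (p.pop_maf <= 0.5)).all()
        # most sites are rare (coalescent frequency spectrum)
        assert np.median(p.pop_maf) < 0.05
        # r^2 with a common focal SNP spans low to (near-)perfect
        common = np.argmax(p.pop_maf)
        r2 = np.array([pairwise_r2(p.haplotypes, common, j)
                       for j in range(p.n_snps) if j != common])
        assert r2.max() > 0.8 and r2.min() < 0.05

    def test_reproducible(self):
        a = build_coalescent_panel(n_haplotypes=200, sequence_length=2e4, seed=9)
        b = build_coalescent_panel(n_haplotypes=200, sequence_length=2e4, seed=9)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)


class TestCausalAndWindows:
    def test_single_eligible_snp_is_chosen(self, copying_panel):
        vals, counts = np.unique(copying_panel.pop_maf, return_counts=True)
        target = vals[counts == 1][0]
        only = int(np.where(copying_panel.pop_maf == target)[0][0])
        idx = designate_causal(copying_panel,
                               maf_range=(target - 1e-12, target + 1e-12))
        assert idx.tolist() == [only]

    def test_ten_causal_distinct_in_range(self, copying_panel):
        idx = designate_causal(copying_panel, maf_range=(0.05, 0.45),
                               n_causal=10, seed=4)
        assert len(set(idx)) == 10
        assert ((copying_panel.pop_maf[idx] >= 0.05)
                & (copying_panel.pop_maf[idx] <= 0.45)).all()

    def test_seed_contract(self, copying_panel):
        a = designate_causal(copying_panel, (0.05, 0.45), 5, seed=7)
        b = designate_causal(copying_panel, (0.05, 0.45), 5, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_no_eligible_raises(self, copying_panel):
        with pytest.raises(ValidationError, match="range"):
            designate_causal(copying_panel, maf_range=(0.49, 0.499))

    def test_window_contains_causal(self, copying_panel):
        for seed in range(5):
            w = choose_window(copying_panel, 20, causal_index=150, seed=seed)
            assert len(w) == 20 and 150 in w


class TestGenotypeSampling:
    def test_identical_haplotypes_give_constant_genotype(self):
        hap = np.tile(np.array([[0, 1, 1, 0]], dtype=np.int8), (2, 1))
        panel = build_haplotype_panel(H=10, M=4, seed=0)
        panel.haplotypes = hap
        panel.pop_maf = np.array([0.4, 0.4, 0.4, 0.4])
        G = sample_genotypes(panel, 6, seed=1)
        np.testing.assert_array_equal(G.values, np.tile(2.0 * hap[0], (6, 1)))

    def test_sample_maf_converges(self, copying_panel):
        n = 4000
        G = sample_genotypes(copying_panel, n, seed=5)
        p = copying_panel.pop_maf
        tol = 3 * np.sqrt(p * (1 - p) / (2 * n)) + 1e-9
        # allele-1 frequency in the sample tracks the population frequency
        freq = G.values.mean(axis=0) / 2
        assert (np.abs(freq - p) < tol).mean() > 0.98

    def test_hardy_weinberg_proportions(self, copying_panel):
        n = 5000
        G = sample_genotypes(copying_panel, n, seed=6)
        j = int(np.argmax(copying_panel.pop_maf))
        p = copying_panel.pop_maf[j]
        counts = np.bincount(G.values[:, j].astype(int), minlength=3) / n
        expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        assert np.abs(counts - expected).max() < 4 * np.sqrt(expected * (1 - expected) / n).max()


class TestContinuousPhenotypes:
    def test_null_moments(self, copying_panel):
        G = sample_genotypes(copying_panel, 5000, seed=7)
        y = simulate_continuous_phenotype(G, None, mode="null", seed=8)
        assert abs(y.y.mean()) < 0.05 and abs(y.y.std() - 1) < 0.05

    def test_single_causal_mean_structure(self):
        values = np.zeros((200, 2))
        values[100:, 0] = 2.0
        G = GenotypeMatrix(values=values, snp_ids=["a", "b"])
        y = simulate_continuous_phenotype(G, [0], mode="single", seed=9).y
        assert y[:100].mean() == pytest.approx(1.0, abs=0.35)  # 1 + 2*0
        assert y[100:].mean() == pytest.approx(5.0, abs=0.35)  # 1 + 2*2

    def test_multi_causal_model(self, copying_panel):
        G = sample_genotypes(copying_panel, 300, seed=10)
        y = simulate_continuous_phenotype(G, [0, 5], mode="multi",
                                          effect_size=1.0, seed=11).y
        resid = y - (G.values[:, 0] + G.values[:, 5])
        assert abs(resid.std() - 1.0) < 0.15

    def test_mode_mismatch_rejected(self, copying_panel):
        G = sample_genotypes(copying_panel, 10, seed=1)
        with pytest.raises(ValidationError):
            simulate_continuous_phenotype(G, [1, 2], mode="single")
        with pytest.raises(ValidationError):
            simulate_continuous_phenotype(G, [1], mode="null")


class TestDiseaseModel:
    def test_penetrance_formulas_direct_substitution(self):
        f0, f1, f2 = DiseaseModel(K=0.1, r=2.0).penetrances(0.1)
        assert f0 == pytest.approx(0.1 / (1 - 0.2 + 0.4))  # = 1/12
        assert f1 == pytest.approx(2 * f0)
        assert f2 == pytest.approx(2 * 2 * f0 - f0)  # = 3 f0

    def test_no_effect_limit(self):
        f = DiseaseModel(K=0.2, r=1.0).penetrances(0.3)
        assert f == pytest.approx((0.2, 0.2, 0.2))

    def test_invalid_penetrance_named(self):
        with pytest.raises(ValidationError, match="penetrance"):
            DiseaseModel(K=0.6, r=2.0).penetrances(0.05)

    def test_case_rate_tracks_penetrance(self, copying_panel):
        # unascertained cohort: empirical case rate per genotype ~= f_k
        disease = DiseaseModel(K=0.1, r=2.0)
        causal = int(designate_causal(copying_panel, (0.2, 0.45), seed=12)[0])
        p = float(copying_panel.pop_maf[causal])
        f = np.array(disease.penetrances(p))
        rng = np.random.default_rng(13)
        G = sample_genotypes(copying_panel, 20000, seed=14)
        k = G.values[:, causal].astype(int)
        case = rng.random(20000) < f[k]
        for kk in (0, 1, 2):
            n_k = (k == kk).sum()
            assert abs(case[k == kk].mean() - f[kk]) < 4 * np.sqrt(f[kk] * (1 - f[kk]) / n_k)
        prev = ((1 - p) ** 2 * f[0] + 2 * p * (1 - p) * f[1] + p**2 * f[2])
        assert prev == pytest.approx(disease.K, rel=0.02)

    def test_ascertained_sample_balanced_and_enriched(self, copying_panel):
        causal = int(designate_causal(copying_panel, (0.2, 0.45), seed=15)[0])
        G, y = simulate_binary_phenotype(copying_panel, causal,
                                         DiseaseModel(K=0.1, r=2.0), 400, seed=16)
        assert y.y.sum() == 200
        pos = int(np.where(G.snp_ids == f"snp{causal}")[0][0])
        maf_cases = G.values[y.y == 1, pos].mean() / 2
        maf_controls = G.values[y.y == 0, pos].mean() / 2
        assert maf_cases > maf_controls

    def test_null_binary(self):
        y = simulate_null_binary_phenotype(4000, seed=17)
        assert set(np.unique(y.y)) == {0.0, 1.0}
        assert abs(y.y.mean() - 0.5) < 0.03


class TestPreprocess:
    def test_invariant_column_dropped(self):
        G = GenotypeMatrix(values=np.column_stack([np.full(5, 2.0), [0, 1, 2, 1, 0]]),
                           snp_ids=["inv", "ok"])
        with pytest.warns(UserWarning, match="invariant"):
            out = preprocess(G)
        assert list(out.snp_ids) == ["ok"]
        assert out.source_index.tolist() == [1]

    def test_standardisation(self):
        G = GenotypeMatrix(values=np.array([[0.0], [1.0], [2.0]]), snp_ids=["s"])
        out = preprocess(G)
        assert out.values.mean() == pytest.approx(0.0, abs=1e-10)
        assert out.values.std() == pytest.approx(1.0, abs=1e-10)

    def test_mean_imputation(self):
        G = GenotypeMatrix(values=np.array([[0.0], [np.nan], [2.0]]), snp_ids=["s"])
        out = preprocess(G)
        # imputed value 1.0 => column (0,1,2) standardised
        np.testing.assert_allclose(out.values.ravel(),
                                   np.array([0, 1, 2]) / np.std([0, 1, 2]) - np.sqrt(1.5),
                                   atol=1e-10)

    def test_all_invariant_raises(self):
        G = GenotypeMatrix(values=np.full((4, 2), 1.0), snp_ids=["a", "b"])
        with pytest.raises(ValidationError, match="invariant"):
            preprocess(G)


class TestReplicates:
    def test_reproducible_and_causal_in_window(self, small_coalescent_panel):
        cfg = ScenarioConfig(n=50, m=20, effect_model="single", seed=3)
        G1, y1, c1 = simulate_replicate(small_coalescent_panel, cfg,
                                        np.random.SeedSequence(3))
        G2, y2, c2 = simulate_replicate(small_coalescent_panel, cfg,
                                        np.random.SeedSequence(3))
        np.testing.assert_array_equal(G1.values, G2.values)
        np.testing.assert_array_equal(y1.y, y2.y)
        assert c1.tolist() == c2.tolist()
        assert 0 <= c1[0] < 20

    def test_multi_causal_replicate(self, small_coalescent_panel):
        cfg = ScenarioConfig(n=50, m=100, effect_model="multi", n_causal=5,
                             maf_range=(0.05, 0.3), seed=4)
        G, y, causal = simulate_replicate(small_coalescent_panel, cfg,
                                          np.random.SeedSequence(4))
        assert len(causal) == 5 and y.kind == "continuous"

    def test_binary_single_causal_replicate(self, small_coalescent_panel):
        cfg = ScenarioConfig(n=60, m=20, phenotype_kind="binary",
                             effect_model="single", maf_range=(0.05, 0.3), seed=5)
        G, y, causal = simulate_replicate(small_coalescent_panel, cfg,
                                          np.random.SeedSequence(5))
        assert y.kind == "binary" and y.y.sum() == 30
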