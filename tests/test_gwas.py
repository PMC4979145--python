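"""QC, mixed-model scan, genomic control, FDR and variance explained."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rfikit.gwas import (
    chromwise_fdr,
    genomic_control,
    hwe_exact_test,
    mixed_model_scan,
    qc_filter,
    snp_variance_explained,
)
from rfikit.simulate import (
    GenotypeMatrix,
    SimConfig,
    simulate_genotypes,
    simulate_polygenic_trait,
)
from rfikit.varcomp import genomic_kinship


def _gm(dosage):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    snps = pd.DataFrame(
        {"snp_id": [f"snp{j}" for j in range(m)], "chrom": 1, "pos": np.arange(m) * 1000 + 1}
    )
    return GenotypeMatrix(dosage=dosage, samples=[f"s{i}" for i in range(n)], snps=snps)


class TestQC:
    def test_monomorphic_snp_removed_by_maf(self):
        dosage = np.column_stack([np.zeros(20), np.tile([0, 1, 2, 1], 5)])
        _, report = qc_filter(_gm(dosage))
        assert report.removed_maf == 1
        assert report.n_snps_out == 1

    def test_low_call_rate_snp_removed(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(40, 3)).astype(float)
        dosage[:5, 0] = np.nan  # 87.5% call rate
        _, report = qc_filter(_gm(dosage))
        assert report.removed_snp_callrate == 1

    def test_planted_failures_match_hand_enumeration(self):
        rng = np.random.default_rng(1)
        n, m = 40, 6
        dosage = rng.integers(0, 3, size=(n, m)).astype(float)
        dosage[:, 0] = 0.0  # monomorphic -> MAF
        dosage[: n // 2, 1] = np.nan  # 50% call rate -> SNP call filter
        dosage[:, 2] = np.tile([0, 2], n // 2)  # no hets -> HWE failure
        G, report = qc_filter(_gm(dosage), hwe_p_min=1e-3)
        assert report.removed_snp_callrate == 1
        assert report.removed_maf == 1
        assert report.removed_hwe == 1
        assert report.n_snps_out == 3

    def test_all_removed_raises(self):
        dosage = np.zeros((30, 2))
        with pytest.raises(ValueError, match="every SNP"):
            qc_filter(_gm(dosage))

    def test_hwe_exact_matches_enumeration_oracle(self):
        # brute-force enumeration of het-count probabilities at fixed allele count
        from math import comb

        n, rare = 20, 14
        def prob(het):
            homr = (rare - het) // 2
            homc = n - het - homr
            return (
                2**het * comb(n, het) * comb(n - het, homr) * comb(n - het - homr, homc)
            )

        hets = [h for h in range(rare + 1) if (rare - h) % 2 == 0]
        weights = {h: prob(h) for h in hets}
        total = sum(weights.values())
        for obs_het in (2, 6, 10):
            p_enum = sum(w for h, w in weights.items() if w <= weights[obs_het]) / total
            homr = (rare - obs_het) // 2
            p = hwe_exact_test(obs_het, homr, n - obs_het - homr)
            assert p == pytest.approx(p_enum, rel=1e-9)


class TestScan:
    def test_chi2_matches_dense_gls_oracle(self):
        cfg = SimConfig(n_individuals=30, n_snps=50, chrom_lengths=(90_000,), seed=9)
        G = simulate_genotypes(cfg)
        rng = np.random.default_rng(9)
        y, _ = simulate_polygenic_trait(G, 0.35, 10, 8.36, rng)
        Gq, _ = qc_filter(G)
        K = genomic_kinship(Gq)
        assoc = mixed_model_scan(y, Gq, K)
        nf = assoc.attrs["null_fit"]
        n = 30
        V = nf.sigma_a2 * (K.phi + 1e-8 * np.eye(n)) + nf.sigma_e2 * np.eye(n)
        Vinv = np.linalg.inv(V)
        dose = np.asarray(Gq.dosage, float)
        freq = dose.mean(0) / 2
        dose[:, freq > 0.5] = 2 - dose[:, freq > 0.5]
        order = {s: j for j, s in enumerate(Gq.snps["snp_id"])}
        for i in range(len(assoc)):
            X = np.column_stack([np.ones(n), dose[:, order[assoc["snp_id"].iloc[i]]]])
            XtVX = X.T @ Vinv @ X
            beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
            se = np.sqrt(np.linalg.inv(XtVX)[1, 1])
            assert assoc["chi2"].iloc[i] == pytest.approx((beta[1] / se) ** 2, abs=1e-6)

    def test_scan_invariant_to_phenotype_shift(self, small_genotypes):
        rng = np.random.default_rng(3)
        y, _ = simulate_polygenic_trait(small_genotypes, 0.35, 20, 8.36, rng)
        K = genomic_kinship(small_genotypes)
        a1 = mixed_model_scan(y, small_genotypes, K)
        a2 = mixed_model_scan(y + 1000.0, small_genotypes, K)
        assert np.allclose(a1["chi2"], a2["chi2"], atol=1e-6)

    def test_planted_qtl_detected(self):
        # MC power oracle: one QTL at ~9.5% phenotypic variance, n=426
        hits = 0
        reps = 20
        for seed in range(reps):
            cfg = SimConfig(
                n_individuals=426, n_snps=300, chrom_lengths=(50_000_000,), seed=200 + seed
            )
            G = simulate_genotypes(cfg)
            rng = np.random.default_rng(300 + seed)
            j = rng.integers(0, G.n_snps)
            dose = np.asarray(G.dosage[:, j], float)
            g = (dose - dose.mean()) / dose.std()
            y = np.sqrt(0.095) * g + np.sqrt(1 - 0.095) * rng.standard_normal(426)
            K = genomic_kinship(G)
            assoc = mixed_model_scan(y, G, K)
            p_at_qtl = assoc.set_index("snp_id").loc[G.snps["snp_id"].iloc[j], "p_raw"]
            hits += p_at_qtl < 1e-4
        assert hits / reps >= 0.8


class TestGenomicControl:
    def test_lambda_one_when_median_is_null_median(self):
        chi2 = np.array([0.1, 0.4549364, 2.0])
        with pytest.warns(UserWarning):
            gc = genomic_control(chi2)
        assert gc.lambda_gc == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(gc.p_corrected, stats.chi2.sf(chi2, 1))

    def test_scale_equivariance(self, rng):
        chi2 = rng.chisquare(1, 500)
        gc1 = genomic_control(chi2)
        gc2 = genomic_control(2.0 * chi2)
        assert gc2.lambda_gc == pytest.approx(2.0 * gc1.lambda_gc, rel=1e-9)
        assert np.allclose(gc2.chi2_corrected, gc1.chi2_corrected, atol=1e-9)

    def test_null_lambda_near_one(self, rng):
        chi2 = rng.chisquare(1, 10_000)
        gc = genomic_control(chi2)
        assert 0.95 <= gc.lambda_gc <= 1.05

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            genomic_control(np.array([np.nan]))


class TestChromwiseFDR:
    def test_single_snp_fdr_equals_p(self):
        out = chromwise_fdr(np.array([0.03]), np.array([1]))
        assert out["fdr_value"].iloc[0] == pytest.approx(0.03)

    def test_hand_step_up_oracle(self):
        out = chromwise_fdr(np.array([0.001, 0.002, 0.03]), np.array([1, 1, 1]))
        assert np.allclose(out["fdr_value"], [0.003, 0.003, 0.03])

    def test_statsmodels_cross_check_per_chromosome(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 200)
        chrom = rng.integers(1, 4, 200)
        out = chromwise_fdr(p, chrom)
        for c in (1, 2, 3):
            mask = chrom == c
            _, q_sm, _, _ = multipletests(p[mask], method="fdr_bh")
            assert np.allclose(out.loc[mask, "fdr_value"], q_sm, atol=1e-12)

    def test_monotone_after_step_up_property(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, 50)
            out = chromwise_fdr(p, np.ones(50))
            order = np.argsort(p)
            fdr_sorted = out["fdr_value"].to_numpy()[order]
            assert np.all(np.diff(fdr_sorted) >= -1e-15)
            # equals the reverse cumulative minimum of the raw m*P(i)/i values
            raw = np.minimum(p[order] * 50 / np.arange(1, 51), 1.0)
            expect = np.minimum.accumulate(raw[::-1])[::-1]
            assert np.allclose(fdr_sorted, expect, atol=1e-15)

    def test_tier_flags_and_significance(self):
        out = chromwise_fdr(np.array([1e-6, 0.2]), np.array([1, 1]))
        assert bool(out["significant"].iloc[0]) and not bool(out["significant"].iloc[1])
        assert bool(out["fdr_le_5pct"].iloc[0])


class TestVarianceExplained:
    def test_y_equal_to_dosage_gives_100(self):
        d = np.tile([0.0, 1.0, 2.0], 12)
        var_pct, _ = snp_variance_explained(d.copy(), d)
        assert var_pct == pytest.approx(100.0)

    def test_null_r2_matches_2df_expectation(self, rng):
        # E[R^2] ~ 2/(n-1) for an unrelated genotype factor with 3 classes
        vals = []
        for _ in range(200):
            d = rng.integers(0, 3, 1000).astype(float)
            y = rng.standard_normal(1000)
            v, _ = snp_variance_explained(y, d)
            vals.append(v)
        assert np.mean(vals) == pytest.approx(100 * 2 / 999, rel=0.25)

    def test_twelve_bird_hand_ols_oracle(self):
        d = np.array([0.0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        y = np.array([3.0, 4, 5, 4, 6, 7, 6, 7, 9, 8, 9, 10])
        grand = y.mean()
        ssb = sum(4 * (y[d == k].mean() - grand) ** 2 for k in (0, 1, 2))
        sst = ((y - grand) ** 2).sum()
        var_pct, addvar = snp_variance_explained(y, d, ebv=y * 0.5)
        assert var_pct == pytest.approx(100 * ssb / sst, abs=1e-9)
        assert addvar == pytest.approx(var_pct, abs=1e-9)  # ebv is affine in y

    def test_constant_dosage_raises(self):
        with pytest.raises(ValueError):
            snp_variance_explained(np.arange(10.0), np.ones(10))
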