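"""Two-locus EM, D' confidence bounds, Gabriel blocks, LD decay."""

import numpy as np
import pandas as pd
import pytest

from rfikit.ld import (
    HaploBlock,
    block_haplotype_frequencies,
    dprime_confidence_interval,
    dprime_likelihood_grid,
    gabriel_blocks,
    ld_decay_profile,
    pairwise_ld,
    _genotype_table,
    _loglik_from_freqs,
)
from rfikit.simulate import SimConfig, simulate_genotypes


def _genotypes_from_hap_freqs(f, n, rng):
    """Draw unphased genotypes from two-locus haplotype frequencies (HWE)."""
    haps = [(1, 1), (1, 0), (0, 1), (0, 0)]
    idx = rng.choice(4, size=2 * n, p=f)
    h = np.array([haps[i] for i in idx])
    g = h[0::2] + h[1::2]
    return g[:, 0].astype(float), g[:, 1].astype(float)


class TestPairwiseEM:
    def test_complete_ld_gives_dprime_and_r2_one(self, rng):
        g1, g2 = _genotypes_from_hap_freqs([0.3, 0.0, 0.0, 0.7], 500, rng)
        pair = pairwise_ld(g1, g2)
        assert pair.Dprime == pytest.approx(1.0, abs=1e-9)
        assert pair.r2 == pytest.approx(1.0, abs=1e-9)

    def test_independent_snps_null_d(self, rng):
        p, q = 0.3, 0.4
        f = [p * q, p * (1 - q), (1 - p) * q, (1 - p) * (1 - q)]
        g1, g2 = _genotypes_from_hap_freqs(f, 10_000, rng)
        pair = pairwise_ld(g1, g2)
        se = np.sqrt(p * (1 - p) * q * (1 - q) / (2 * 10_000))
        assert abs(pair.D) < 3 * se

    def test_em_matches_dense_likelihood_grid_oracle(self, rng):
        # fixed genotype table with double-het ambiguity
        g1 = np.array([0, 0, 1, 1, 1, 1, 2, 2, 1, 0, 2, 1], dtype=float)
        g2 = np.array([0, 1, 0, 1, 1, 2, 1, 2, 1, 0, 2, 2], dtype=float)
        pair = pairwise_ld(g1, g2)
        table = _genotype_table(g1, g2)

        # brute-force grid over f11 at fixed margins
        pa, pb = pair.p_a, pair.p_b
        best_ll, best_f11 = -np.inf, None
        for f11 in np.linspace(max(0, pa + pb - 1), min(pa, pb), 200_001):
            f = np.array([f11, pa - f11, pb - f11, 1 - pa - pb + f11])
            if np.any(f < 0):
                continue
            ll = _loglik_from_freqs(table, f)
            if ll > best_ll:
                best_ll, best_f11 = ll, f11
        assert pair.hap_freqs[0] == pytest.approx(best_f11, abs=1e-6)

    def test_em_loglik_monotone_asserted(self, rng):
        # the EM loop itself asserts monotonicity; exercise it on noisy data
        g1 = rng.integers(0, 3, 200).astype(float)
        g2 = rng.integers(0, 3, 200).astype(float)
        pairwise_ld(g1, g2)

    def test_dprime_invariant_to_allele_relabel(self, rng):
        f = [0.45, 0.05, 0.1, 0.4]
        g1, g2 = _genotypes_from_hap_freqs(f, 400, rng)
        a = pairwise_ld(g1, g2)
        b = pairwise_ld(2 - g1, g2)
        assert a.Dprime == pytest.approx(b.Dprime, abs=1e-9)
        assert a.r2 == pytest.approx(b.r2, abs=1e-9)


class TestDprimeCI:
    def test_perfect_ld_pair_is_strong(self, rng):
        g1, g2 = _genotypes_from_hap_freqs([0.4, 0.0, 0.0, 0.6], 200, rng)
        pair = pairwise_ld(g1, g2)
        pair = dprime_confidence_interval(pair, g1, g2)
        assert pair.strong_ld

    def test_bounds_match_independent_profile_oracle(self, rng):
        g1, g2 = _genotypes_from_hap_freqs([0.35, 0.05, 0.15, 0.45], 150, rng)
        pair = pairwise_ld(g1, g2)
        pair = dprime_confidence_interval(pair, g1, g2)

        # independently coded profile: normalized likelihood percentiles
        table = _genotype_table(g1, g2)
        grid = np.arange(0, 1.0005, 0.001)
        pa, pb = pair.p_a, pair.p_b
        sign = 1 if pair.D >= 0 else -1
        dmax = min(pa * (1 - pb), (1 - pa) * pb) if sign > 0 else min(pa * pb, (1 - pa) * (1 - pb))
        lls = []
        for dp in grid:
            D = sign * dp * dmax
            f = np.array([pa * pb + D, pa * (1 - pb) - D, (1 - pa) * pb - D, (1 - pa) * (1 - pb) + D])
            lls.append(_loglik_from_freqs(table, np.clip(f, 0, None)))
        like = np.exp(np.array(lls) - max(lls))
        like /= like.sum()
        cum = np.cumsum(like)
        low = grid[np.searchsorted(cum, 0.05)]
        high = grid[np.searchsorted(cum, 0.95)]
        assert pair.ci_low == pytest.approx(low, abs=1e-3)
        assert pair.ci_high == pytest.approx(high, abs=1e-3)

    def test_tiny_noisy_sample_is_not_strong(self, rng):
        g1 = np.array([0, 1, 2, 1, 0, 2, 1, 1, 0, 2], dtype=float)
        g2 = np.array([1, 0, 1, 2, 1, 0, 2, 1, 1, 0], dtype=float)
        pair = pairwise_ld(g1, g2)
        pair = dprime_confidence_interval(pair, g1, g2)
        assert not pair.strong_ld
        assert pair.ci_high - pair.ci_low > 0.2


class TestGabrielBlocks:
    def _snps(self, positions):
        return pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(len(positions))], "chrom": 1, "pos": positions}
        )

    def test_all_strong_pairs_form_single_block(self, rng):
        hap = (rng.random(600) < 0.35).astype(int)
        dosage = np.column_stack([hap[:300] + hap[300:]] * 5).astype(float)
        blocks = gabriel_blocks(dosage, self._snps([100, 200, 300, 400, 500]))
        assert len(blocks) == 1
        assert blocks[0].n_snps == 5

    def test_no_strong_pairs_no_blocks(self, rng):
        dosage = rng.integers(0, 3, size=(300, 5)).astype(float)
        blocks = gabriel_blocks(dosage, self._snps([100, 200, 300, 400, 500]))
        assert blocks == []

    def test_weak_pair_inside_run_matches_enumeration_oracle(self, rng):
        # 6 SNPs: 0-3 in perfect LD, SNP 4 independent, SNP 5 copies 4
        hap_a = (rng.random(800) < 0.4).astype(int)
        hap_b = (rng.random(800) < 0.3).astype(int)
        cols = [hap_a, hap_a, hap_a, hap_a, hap_b, hap_b]
        dosage = np.column_stack([h[:400] + h[400:] for h in cols]).astype(float)
        snps = self._snps([100, 200, 300, 400, 500, 600])
        blocks = gabriel_blocks(dosage, snps)

        # exhaustive enumeration oracle over all (i, j) candidate regions
        from rfikit.ld import _informative

        maf = np.minimum(dosage.mean(0) / 2, 1 - dosage.mean(0) / 2)
        pos = snps["pos"].to_numpy()
        strong, informative = {}, {}
        for i in range(6):
            for j in range(i + 1, 6):
                pr = pairwise_ld(dosage[:, i], dosage[:, j])
                pr = dprime_confidence_interval(pr, dosage[:, i], dosage[:, j])
                informative[(i, j)] = _informative(maf[i], maf[j], pr)
                strong[(i, j)] = pr.strong_ld
        cands = []
        for i in range(6):
            for j in range(i + 1, 6):
                pairs = [(a, b) for a in range(i, j + 1) for b in range(a + 1, j + 1)]
                inf = [p for p in pairs if informative[p]]
                if inf and sum(strong[p] for p in inf) / len(inf) > 0.95:
                    cands.append((i, j))
        cands.sort(key=lambda ij: (-(pos[ij[1]] - pos[ij[0]]), ij[0]))
        used = set()
        expected = []
        for i, j in cands:
            if any(k in used for k in range(i, j + 1)):
                continue
            used.update(range(i, j + 1))
            expected.append((int(pos[i]), int(pos[j]), j - i + 1))
        got = sorted((b.start, b.end, b.n_snps) for b in blocks)
        assert got == sorted(expected)
        assert any(b.n_snps == 4 for b in blocks)  # the perfect-LD run

    def test_blocks_never_overlap(self):
        cfg = SimConfig(n_individuals=300, n_snps=25, chrom_lengths=(45_000,), seed=13)
        G = simulate_genotypes(cfg)
        blocks = gabriel_blocks(np.asarray(G.dosage, float), G.snps)
        spans = sorted((b.start, b.end) for b in blocks)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2


class TestDecayProfile:
    def test_bin_means_in_unit_interval(self, small_genotypes):
        prof = ld_decay_profile(small_genotypes)
        vals = prof["mean_r2"].dropna()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_empty_bin_reports_nan(self):
        cfg = SimConfig(n_individuals=100, n_snps=4, chrom_lengths=(4_000,), seed=14)
        G = simulate_genotypes(cfg)
        prof = ld_decay_profile(G)
        assert np.isnan(prof["mean_r2"].iloc[-1])


class TestBlockHaplotypes:
    def test_all_homozygous_equals_direct_counts(self):
        dosage = np.array([[0, 0, 0], [2, 2, 2], [2, 2, 2], [0, 0, 0]], dtype=float)
        freqs = block_haplotype_frequencies(dosage)
        assert freqs == {"000": pytest.approx(0.5), "111": pytest.approx(0.5)}

    def test_two_snp_block_consistent_with_pairwise_em(self, rng):
        f = [0.35, 0.15, 0.1, 0.4]
        g1, g2 = _genotypes_from_hap_freqs(f, 300, rng)
        pair = pairwise_ld(g1, g2)
        freqs = block_haplotype_frequencies(np.column_stack([g1, g2]), prune=0.0)
        assert freqs["11"] == pytest.approx(pair.hap_freqs[0], abs=1e-9)
        assert freqs["10"] == pytest.approx(pair.hap_freqs[1], abs=1e-9)

    def test_three_snp_ambiguity_matches_grid_oracle(self, rng):
        # small sample, EM vs a dense simplex search restricted to seen haplotypes
        dosage = np.array(
            [[1, 1, 0], [1, 1, 1], [2, 1, 1], [0, 1, 1], [1, 2, 1], [2, 2, 2], [0, 0, 0], [1, 1, 1]],
            dtype=float,
        )
        freqs = block_haplotype_frequencies(dosage, prune=0.0)

        from itertools import product

        def pairs_for(g):
            het = [k for k in range(3) if g[k] == 1]
            base = [1 if v == 2 else 0 for v in g]
            out = []
            for assign in product([0, 1], repeat=max(len(het) - 1, 0)):
                h1, h2 = list(base), list(base)
                bits = (0,) + assign if het else ()
                for k, bit in zip(het, bits):
                    h1[k] = bit
                    h2[k] = 1 - bit
                out.append((tuple(h1), tuple(h2)))
            return out

        genos = [tuple(int(v) for v in row) for row in dosage]
        hapset = sorted({h for g in genos for pr in pairs_for(g) for h in pr})

        def loglik(fvec):
            f = dict(zip(hapset, fvec))
            ll = 0.0
            for g in genos:
                tot = sum(
                    f[h1] * f[h2] * (1 if h1 == h2 else 2) for h1, h2 in pairs_for(g)
                )
                ll += np.log(max(tot, 1e-300))
            return ll

        rng2 = np.random.default_rng(2)
        best = -np.inf
        best_f = None
        for _ in range(20000):
            f = rng2.dirichlet(np.ones(len(hapset)))
            ll = loglik(f)
            if ll > best:
                best, best_f = ll, f
        em_vec = np.array([freqs.get("".join(map(str, h)), 0.0) for h in hapset])
        assert loglik(em_vec) >= best - 1e-4
        # and the EM point is a local maximum of the simplex likelihood
        rng3 = np.random.default_rng(3)
        ll_em = loglik(em_vec)
        for _ in range(200):
            pert = em_vec + rng3.normal(0, 0.01, em_vec.size)
            pert = np.clip(pert, 1e-9, None)
            pert /= pert.sum()
            assert loglik(pert) <= ll_em + 1e-9

    def test_block_cap_raises(self):
        with pytest.raises(ValueError, match="12-SNP"):
            block_haplotype_frequencies(np.zeros((4, 13)))

    def test_frequencies_form_simplex(self, rng):
        dosage = rng.integers(0, 3, size=(100, 4)).astype(float)
        freqs = block_haplotype_frequencies(dosage, prune=0.0)
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-9)
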