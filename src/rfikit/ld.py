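"""Linkage disequilibrium and haplotype-block machinery.

Two-locus haplotype frequencies are estimated from unphased genotypes by
EM over the double-heterozygote ambiguity; from them D, D' and r² follow.
"Strong LD" uses the Gabriel criterion: the one-sided 95 % likelihood
bounds of |D'| must exceed 0.98 (upper) and 0.70 (lower).  Blocks are
regions where more than 95 % of the informative SNP pairs are in strong
LD, resolved greedily longest-span-first.  Multilocus block haplotype
frequencies use the same EM generalized over phase configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "LDPair",
    "HaploBlock",
    "pairwise_ld",
    "dprime_confidence_interval",
    "gabriel_blocks",
    "ld_decay_profile",
    "block_haplotype_frequencies",
]

DEFAULT_BINS_KB = ((0, 20), (20, 40), (40, 60), (60, 80), (80, 100))


@dataclass
class LDPair:
    hap_freqs: np.ndarray  # (f11, f10, f01, f00); index 1 = coded allele
    D: float
    Dprime: float
    r2: float
    p_a: float
    p_b: float
    n: int
    converged: bool
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    strong_ld: bool = False
    degenerate: bool = False


@dataclass
class HaploBlock:
    chrom: int
    snp_ids: list[str]
    start: int
    end: int
    haplotypes: dict[str, float] = field(default_factory=dict)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def _dmax(D: float, pa: float, pb: float) -> float:
    if D >= 0:
        return min(pa * (1 - pb), (1 - pa) * pb)
    return min(pa * pb, (1 - pa) * (1 - pb))


def _genotype_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts, complete observations only."""
    ok = ~(np.isnan(g1) | np.isnan(g2))
    a = g1[ok].astype(int)
    b = g2[ok].astype(int)
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (a, b), 1)
    return table


def _loglik_from_freqs(table: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table under HWE.

    ``f`` = (f11, f10, f01, f00).  The double heterozygote mixes the two
    phase resolutions.
    """
    f11, f10, f01, f00 = np.clip(f, 1e-300, None)
    # genotype probabilities from random union of gametes
    P = np.empty((3, 3))
    P[2, 2] = f11 * f11
    P[2, 1] = 2 * f11 * f10
    P[2, 0] = f10 * f10
    P[1, 2] = 2 * f11 * f01
    P[1, 1] = 2 * (f11 * f00 + f10 * f01)
    P[1, 0] = 2 * f10 * f00
    P[0, 2] = f01 * f01
    P[0, 1] = 2 * f01 * f00
    P[0, 0] = f00 * f00
    with np.errstate(divide="ignore"):
        ll = np.where(table > 0, table * np.log(np.clip(P, 1e-300, None)), 0.0)
    return float(ll.sum())


def pairwise_ld(g1: np.ndarray, g2: np.ndarray, max_iter: int = 1000, tol: float = 1e-12) -> LDPair:
    """Two-locus EM haplotype frequencies and LD coefficients.

    ``g1``/``g2`` are dosages (0/1/2, NaN = missing) of the coded allele
    at each SNP.  Both must be polymorphic among complete observations.
    The EM log-likelihood is asserted non-decreasing; failure to converge
    in ``max_iter`` iterations is flagged, not fatal.
    """
    table = _genotype_table(np.asarray(g1, float), np.asarray(g2, float))
    n = int(table.sum())
    if n == 0:
        raise ValueError("no complete genotype observations")
    pa = float((2 * table[2, :].sum() + table[1, :].sum()) / (2 * n))
    pb = float((2 * table[:, 2].sum() + table[:, 1].sum()) / (2 * n))
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic SNP in LD computation")

    # known haplotype contributions (everything except the double het)
    c11 = 2 * table[2, 2] + table[2, 1] + table[1, 2]
    c10 = 2 * table[2, 0] + table[2, 1] + table[1, 0]
    c01 = 2 * table[0, 2] + table[0, 1] + table[1, 2]
    c00 = 2 * table[0, 0] + table[0, 1] + table[1, 0]
    ndh = table[1, 1]

    f = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        frac = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        counts = np.array(
            [c11 + ndh * frac, c10 + ndh * (1 - frac), c01 + ndh * (1 - frac), c00 + ndh * frac],
            dtype=float,
        )
        f_new = counts / (2 * n)
        delta = np.abs(f_new - f).max()
        f = f_new
        ll = _loglik_from_freqs(table, f)
        assert ll >= ll_prev - 1e-9, "EM log-likelihood decreased"
        if delta < tol:
            converged = True
            break
        ll_prev = ll

    pa_hat = f[0] + f[1]
    pb_hat = f[0] + f[2]
    D = float(f[0] - pa_hat * pb_hat)
    dmax = _dmax(D, pa_hat, pb_hat)
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    denom = pa_hat * (1 - pa_hat) * pb_hat * (1 - pb_hat)
    r2 = D * D / denom if denom > 0 else 0.0
    return LDPair(
        hap_freqs=f,
        D=D,
        Dprime=float(min(dprime, 1.0)),
        r2=float(min(r2, 1.0)),
        p_a=float(pa_hat),
        p_b=float(pb_hat),
        n=n,
        converged=converged,
    )


def dprime_likelihood_grid(
    table: np.ndarray, pa: float, pb: float, sign: int, grid_step: float = 0.001
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized likelihood of |D'| over a 0..1 grid at fixed allele freqs."""
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    dmax = _dmax(float(sign), pa, pb)
    D = sign * grid * dmax
    f11 = np.clip(pa * pb + D, 1e-300, None)
    f10 = np.clip(pa * (1 - pb) - D, 1e-300, None)
    f01 = np.clip((1 - pa) * pb - D, 1e-300, None)
    f00 = np.clip((1 - pa) * (1 - pb) + D, 1e-300, None)
    P = np.empty((grid.size, 3, 3))
    P[:, 2, 2] = f11 * f11
    P[:, 2, 1] = 2 * f11 * f10
    P[:, 2, 0] = f10 * f10
    P[:, 1, 2] = 2 * f11 * f01
    P[:, 1, 1] = 2 * (f11 * f00 + f10 * f01)
    P[:, 1, 0] = 2 * f10 * f00
    P[:, 0, 2] = f01 * f01
    P[:, 0, 1] = 2 * f01 * f00
    P[:, 0, 0] = f00 * f00
    lls = np.einsum("ab,gab->g", table.astype(float), np.log(np.clip(P, 1e-300, None)))
    like = np.exp(lls - lls.max())
    like /= like.sum()
    return grid, like


def dprime_confidence_interval(
    pair: LDPair, g1: np.ndarray | None = None, g2: np.ndarray | None = None,
    table: np.ndarray | None = None, grid_step: float = 0.001
) -> LDPair:
    """One-sided 95 % likelihood bounds on |D'| (Gabriel-style).

    The likelihood of the genotype table is profiled over |D'| in 0..1
    (allele frequencies fixed at their MLEs, D keeping the estimated
    sign), normalized to a unit mass; the bounds are the 5th and 95th
    percentiles.  ``strong_ld`` requires upper >= 0.98 and lower >= 0.70.
    Degenerate frequencies yield ``strong_ld=False`` with a flag.
    """
    if table is None:
        if g1 is None or g2 is None:
            raise ValueError("need either genotype vectors or a genotype table")
        table = _genotype_table(np.asarray(g1, float), np.asarray(g2, float))
    pa, pb = pair.p_a, pair.p_b
    if min(pa, 1 - pa, pb, 1 - pb) <= 0:
        pair.degenerate = True
        pair.strong_ld = False
        return pair
    sign = 1 if pair.D >= 0 else -1
    grid, like = dprime_likelihood_grid(table, pa, pb, sign, grid_step)
    cum = np.cumsum(like)
    pair.ci_low = float(grid[np.searchsorted(cum, 0.05)])
    pair.ci_high = float(grid[np.searchsorted(cum, 0.95)])
    pair.strong_ld = bool(pair.ci_high >= 0.98 and pair.ci_low >= 0.70)
    return pair


def _informative(maf_a: float, maf_b: float, pair: LDPair, min_maf: float = 0.05) -> bool:
    return maf_a >= min_maf and maf_b >= min_maf and pair.converged and not pair.degenerate


def gabriel_blocks(
    dosage: np.ndarray,
    snps: pd.DataFrame,
    max_span_bp: int = 500_000,
    strong_fraction: float = 0.95,
    min_maf: float = 0.05,
) -> list[HaploBlock]:
    """Gabriel-criterion haplotype blocks along one chromosome.

    Every candidate contiguous run of SNPs (span <= ``max_span_bp``) is
    scored by the fraction of its informative pairs (MAF >= ``min_maf``
    at both SNPs, EM converged) in strong LD; runs with fraction >
    ``strong_fraction`` are accepted greedily, longest physical span
    first (ties: leftmost), skipping overlaps.  Block haplotype
    frequencies are filled in by the multilocus EM.
    """
    pos = snps["pos"].to_numpy()
    if not np.all(np.diff(pos) > 0):
        raise ValueError("map positions must be strictly increasing")
    m = dosage.shape[1]
    freq = np.nanmean(dosage, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)

    strong = {}
    informative = {}
    for i in range(m):
        for j in range(i + 1, m):
            if pos[j] - pos[i] > max_span_bp:
                break
            try:
                pair = pairwise_ld(dosage[:, i], dosage[:, j])
            except ValueError:
                informative[(i, j)] = False
                continue
            pair = dprime_confidence_interval(pair, dosage[:, i], dosage[:, j])
            informative[(i, j)] = _informative(maf[i], maf[j], pair, min_maf)
            strong[(i, j)] = pair.strong_ld

    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if pos[j] - pos[i] > max_span_bp:
                break
            pairs = [(a, b) for a in range(i, j + 1) for b in range(a + 1, j + 1)]
            inf_pairs = [p for p in pairs if informative.get(p, False)]
            if not inf_pairs:
                continue
            frac = sum(strong.get(p, False) for p in inf_pairs) / len(inf_pairs)
            if frac > strong_fraction:
                candidates.append((i, j))

    candidates.sort(key=lambda ij: (-(pos[ij[1]] - pos[ij[0]]), ij[0]))
    used = np.zeros(m, dtype=bool)
    blocks: list[HaploBlock] = []
    for i, j in candidates:
        if used[i : j + 1].any():
            continue
        used[i : j + 1] = True
        haps = (
            block_haplotype_frequencies(dosage[:, i : j + 1])
            if (j - i + 1) <= 12
            else {}
        )
        blocks.append(
            HaploBlock(
                chrom=int(snps["chrom"].iloc[i]),
                snp_ids=list(snps["snp_id"].iloc[i : j + 1]),
                start=int(pos[i]),
                end=int(pos[j]),
                haplotypes=haps,
            )
        )
    blocks.sort(key=lambda b: b.start)
    return blocks


def ld_decay_profile(
    G,
    bins_kb: tuple[tuple[float, float], ...] = DEFAULT_BINS_KB,
) -> pd.DataFrame:
    """Mean r² of intra-chromosomal SNP pairs per physical-distance bin.

    r² is the squared Pearson correlation of genotype dosages (the
    composite measure; equal to the haplotype r² under HWE).  Bins are
    half-open ``[low, high)`` in kb; an empty bin reports NaN.
    """
    sums = np.zeros(len(bins_kb))
    counts = np.zeros(len(bins_kb), dtype=np.int64)
    edges = np.array([b[0] * 1000 for b in bins_kb] + [bins_kb[-1][1] * 1000])
    max_d = edges[-1]

    for c in pd.unique(G.snps["chrom"]):
        mask = (G.snps["chrom"] == c).to_numpy()
        pos = G.snps["pos"].to_numpy()[mask]
        dose = np.nan_to_num(np.asarray(G.dosage, float)[:, mask])
        sd = dose.std(axis=0)
        keep = sd > 0
        pos, dose, sd = pos[keep], dose[:, keep], sd[keep]
        z = (dose - dose.mean(axis=0)) / sd
        n_ind = z.shape[0]
        mm = z.shape[1]
        for i in range(mm):
            j_hi = np.searchsorted(pos, pos[i] + max_d, side="right")
            if j_hi <= i + 1:
                continue
            r = (z[:, i] @ z[:, i + 1 : j_hi]) / n_ind
            dist = pos[i + 1 : j_hi] - pos[i]
            which = np.searchsorted(edges, dist, side="right") - 1
            ok = (which >= 0) & (which < len(bins_kb))
            np.add.at(sums, which[ok], (r**2)[ok])
            np.add.at(counts, which[ok], 1)

    mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_low_kb": [b[0] for b in bins_kb],
            "bin_high_kb": [b[1] for b in bins_kb],
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )


def block_haplotype_frequencies(
    dosage_block: np.ndarray, max_iter: int = 1000, tol: float = 1e-12, prune: float = 0.01
) -> dict[str, float]:
    """Multilocus haplotype frequencies by EM over phase configurations.

    ``dosage_block`` is individuals x SNPs (<= 12 SNPs; the phase state
    space doubles per heterozygous site).  Individuals with a missing
    call in the block are dropped.  Haplotypes are reported as strings of
    0/1 (1 = coded allele); frequencies below ``prune`` are omitted from
    the report (the remainder is not renormalized).
    """
    dosage_block = np.asarray(dosage_block, dtype=float)
    n_snps = dosage_block.shape[1]
    if n_snps > 12:
        raise ValueError("block exceeds the 12-SNP EM cap; split the block")
    complete = ~np.isnan(dosage_block).any(axis=1)
    geno = dosage_block[complete].astype(int)
    if geno.shape[0] == 0:
        raise ValueError("no complete observations in block")

    # enumerate compatible (ordered) haplotype pairs per distinct genotype
    def pairs_for(g: tuple[int, ...]) -> list[tuple[tuple, tuple]]:
        het = [k for k, gv in enumerate(g) if gv == 1]
        base1 = [1 if gv == 2 else 0 for gv in g]
        base2 = list(base1)
        out = []
        for assign in product([0, 1], repeat=max(len(het) - 1, 0)):
            h1, h2 = list(base1), list(base2)
            bits = (0,) + assign if het else ()
            for k, bit in zip(het, bits):
                h1[k] = bit
                h2[k] = 1 - bit
            out.append((tuple(h1), tuple(h2)))
        return out

    uniq, inv_counts = {}, {}
    for row in map(tuple, geno):
        inv_counts[row] = inv_counts.get(row, 0) + 1
    for g in inv_counts:
        uniq[g] = pairs_for(g)

    hap_set = sorted({h for plist in uniq.values() for pair in plist for h in pair})
    f = {h: 1.0 / len(hap_set) for h in hap_set}
    n = geno.shape[0]
    ll_prev = -np.inf
    for _ in range(max_iter):
        counts = {h: 0.0 for h in hap_set}
        ll = 0.0
        for g, cnt in inv_counts.items():
            plist = uniq[g]
            weights = np.array([f[h1] * f[h2] * (1 if h1 == h2 else 2) for h1, h2 in plist])
            tot = weights.sum()
            if tot <= 0:
                weights = np.ones(len(plist))
                tot = weights.sum()
            ll += cnt * np.log(max(tot, 1e-300))
            weights /= tot
            for (h1, h2), wgt in zip(plist, weights):
                counts[h1] += cnt * wgt
                counts[h2] += cnt * wgt
        delta = 0.0
        for h in hap_set:
            f_new = counts[h] / (2 * n)
            delta = max(delta, abs(f_new - f[h]))
            f[h] = f_new
        assert ll >= ll_prev - 1e-9, "EM log-likelihood decreased"
        if delta < tol:
            break
        ll_prev = ll

    return {
        "".join(map(str, h)): freq for h, freq in sorted(f.items()) if freq >= prune
    }
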