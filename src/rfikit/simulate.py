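"""Synthetic cohorts for the residual-feed-intake pipeline.

Three generators with a shared deterministic seeding discipline:

* :func:`simulate_genotypes` — biallelic SNP dosages in Hardy–Weinberg
  equilibrium with distance-decaying linkage disequilibrium,
* :func:`simulate_growth_and_intake` — per-bird linear growth trajectories
  and daily feed intake built from the Koch expected-intake model, with a
  polygenic RFI of configurable heritability,
* :func:`simulate_counts` — negative-binomial RNA-seq gene counts for two
  RFI-divergent groups.

Every generator returns ground truth alongside the data so downstream
estimators can be tested against the values that were actually planted.

LD model
--------
Haplotypes are produced by thresholding a latent stationary Gaussian
Markov field: along a chromosome the latent value follows an
Ornstein–Uhlenbeck chain with correlation ``exp(-d/L)`` over a gap of
``d`` bp, and the allele at a site is the indicator that the latent value
falls below the per-site quantile of its configured allele frequency.
Marginals are therefore exactly Bernoulli(p) per haplotype, genotypes are
the sum of two independent haplotypes (HWE holds by construction), and
pairwise LD decays monotonically with physical distance regardless of how
many SNPs lie in between.  ``L`` is a single calibration knob; the shipped
default reproduces a mean-r² decay profile of roughly 0.3 at short range,
0.2 at 40–60 kb and below 0.15 at 80–100 kb.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

__all__ = [
    "SimConfig",
    "CountsConfig",
    "SimTruth",
    "GenotypeMatrix",
    "simulate_genotypes",
    "simulate_polygenic_trait",
    "simulate_bivariate_traits",
    "simulate_growth_and_intake",
    "simulate_counts",
    "write_run_manifest",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the genotype/phenotype generators.

    Defaults mirror a desk-scale version of a 40-day feeding trial on a
    slow-growing layer-type line: 426 genotyped birds in six pens (pens
    nested in sex, three male then three female), 5,000 SNPs on five
    chromosomes at ~1.8 kb spacing, RFI heritability 0.35 and a
    phenotypic RFI standard deviation of 8.36 g/day.
    """

    n_individuals: int = 426
    n_snps: int = 5000
    chrom_lengths: tuple[int, ...] = (1_800_000,) * 5
    maf_range: tuple[float, float] = (0.02, 0.5)
    maf_beta: tuple[float, float] = (0.5, 1.0)  # Beta shape of the MAF spectrum
    ld_scale_L: float = 240_000.0  # bp; exponential decay scale of latent corr
    site_noise: float = 0.0  # per-site prob of an independent allele redraw
    h2_rfi: float = 0.35
    n_qtl: int = 20  # oligogenic: top QTLs explain a few percent of variance each
    h2_adg: float = 0.32
    h2_start_weight: float = 0.56
    pen_effects: tuple[float, ...] = (-3.0, 0.0, 3.0, -3.0, 0.0, 3.0)  # g/day
    sex_effect: float = 0.0  # g/day added to male birds' expected intake
    koch_coeffs: tuple[float, float, float] = (5.0, 0.3, 1.25)  # b0, b1, b2
    growth_noise_sd: float = 25.0  # g, day-level body-weight noise
    rfi_sd: float = 8.36  # g/day, total (genetic + environmental) RFI sd
    feed_noise_sd: float = 10.0  # g/day, day-level intake noise
    adg_mean: float = 28.0  # g/day
    adg_sd: float = 3.0
    start_weight_mean: tuple[float, float] = (794.0, 760.0)  # male, female (g)
    start_weight_sd: float = 100.0
    test_days: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.h2_rfi <= 1.0):
            raise ConfigurationError("h2_rfi must lie in [0, 1]")
        if self.ld_scale_L <= 0:
            raise ConfigurationError("ld_scale_L must be positive")
        if not self.chrom_lengths or any(c <= 0 for c in self.chrom_lengths):
            raise ConfigurationError("chrom_lengths must be non-empty and positive")
        for name in ("n_individuals", "n_snps", "n_qtl", "test_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        if len(self.pen_effects) % 2 != 0:
            raise ConfigurationError("pen_effects must have an even length (pens nested in sex)")


@dataclass(frozen=True)
class CountsConfig:
    """Parameters for the two-group RNA-seq count generator.

    Defaults emulate a 2-vs-2 liver RNA-seq contrast between RFI-divergent
    birds: ~23 M mapped reads per library and a negative-binomial
    dispersion of 0.05, typical for biological replicates drawn from a
    single closed line.
    """

    n_genes: int = 10_000
    n_per_group: int = 2
    de_fraction: float = 0.02
    fold_change: float = 4.0
    dispersion: float = 0.05  # NB: var = mu + dispersion * mu^2
    lib_size_mean: float = 2.3e7
    lib_size_cv: float = 0.1
    length_log_mean: float = 7.5  # log bp; median gene length ~1.8 kb
    length_log_sd: float = 0.6
    abundance_log_sd: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ConfigurationError("de_fraction must lie in [0, 1]")
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise ConfigurationError("n_genes and n_per_group must be positive")
        if self.fold_change <= 0:
            raise ConfigurationError("fold_change must be positive")


@dataclass
class SimTruth:
    """Ground truth emitted by the generators.

    ``qtl`` has columns (snp_id, effect) on the trait scale per copy of the
    coded allele; ``breeding_values`` is indexed by individual.  For count
    data ``de_fold_change`` holds the true low/high fold change per gene
    (exactly 1 for non-DE genes).
    """

    qtl: pd.DataFrame | None = None
    breeding_values: pd.Series | None = None
    bird_params: pd.DataFrame | None = None
    de_fold_change: pd.Series | None = None


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs minor-allele dosage with a SNP map.

    ``dosage`` is float (NaN marks a missing call); ``snps`` has columns
    (snp_id, chrom, pos) sorted by (chrom, pos).
    """

    dosage: np.ndarray
    samples: list[str]
    snps: pd.DataFrame

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the coded allele, ignoring missing calls."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage[:, mask],
            samples=list(self.samples),
            snps=self.snps.loc[mask].reset_index(drop=True),
        )

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage[mask, :],
            samples=[s for s, keep in zip(self.samples, mask) if keep],
            snps=self.snps.copy(),
        )


def _snp_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """Evenly spaced positions with uniform jitter inside each cell.

    Guarantees strictly increasing, unique positions and an average
    spacing of length/n bp.
    """
    spacing = length / n
    jitter = rng.uniform(0.05, 0.95, size=n)
    pos = np.floor((np.arange(n) + jitter) * spacing).astype(np.int64) + 1
    return pos


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate HWE genotypes with exponentially decaying LD.

    Per-SNP coded-allele frequencies are drawn uniformly from
    ``config.maf_range``; haplotypes are generated independently per
    individual by the latent Ornstein–Uhlenbeck threshold scheme described
    in the module docstring, so genotype frequencies follow
    Hardy–Weinberg proportions at the configured frequency.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps
    lengths = np.asarray(config.chrom_lengths, dtype=np.int64)

    # Allocate SNPs proportionally to chromosome length, at least 1 each.
    raw = lengths / lengths.sum() * m
    counts = np.maximum(1, np.floor(raw).astype(int))
    while counts.sum() < m:
        counts[np.argmax(raw - counts)] += 1
    while counts.sum() > m:
        counts[np.argmax(counts)] -= 1

    lo, hi = config.maf_range
    # chip-like MAF spectrum, skewed toward rare alleles
    p = lo + (hi - lo) * rng.beta(config.maf_beta[0], config.maf_beta[1], size=m)
    thresholds = ndtri(p)

    dosage = np.empty((n, m), dtype=np.float32)
    chrom_col = np.empty(m, dtype=np.int64)
    pos_col = np.empty(m, dtype=np.int64)
    start = 0
    for c, (length, m_c) in enumerate(zip(lengths, counts), start=1):
        pos = _snp_positions(rng, int(length), int(m_c))
        sl = slice(start, start + m_c)
        chrom_col[sl] = c
        pos_col[sl] = pos

        a = np.exp(-np.diff(pos) / config.ld_scale_L)
        b = np.sqrt(1.0 - a * a)
        z = rng.standard_normal((2 * n, m_c))
        for k in range(1, m_c):
            z[:, k] = a[k - 1] * z[:, k - 1] + b[k - 1] * z[:, k]
        hap = (z < thresholds[sl]).astype(np.int8)  # bool+bool would OR, not add
        if config.site_noise > 0:
            # recurrent-mutation-like redraws: cap short-range LD below 1
            noisy = rng.random((2 * n, m_c)) < config.site_noise
            indep = rng.random((2 * n, m_c)) < p[sl]
            hap = np.where(noisy, indep.astype(np.int8), hap)
        dosage[:, sl] = (hap[0::2] + hap[1::2]).astype(np.float32)
        start += m_c

    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{c}_{p}" for c, p in zip(chrom_col, pos_col)],
            "chrom": chrom_col,
            "pos": pos_col,
        }
    )
    samples = [f"bird{i+1:04d}" for i in range(n)]
    return GenotypeMatrix(dosage=dosage, samples=samples, snps=snps)


def simulate_polygenic_trait(
    G: GenotypeMatrix,
    h2: float,
    n_qtl: int,
    total_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, SimTruth]:
    """Simulate a polygenic trait with *exact* in-sample heritability.

    QTL positions are sampled without replacement, effects are drawn
    N(0,1) and the genetic values rescaled so the realized (ddof=0)
    variance ratio Var(BV)/Var(y) equals ``h2`` exactly; the environmental
    deviation is made orthogonal to the breeding values in-sample.  This
    calibration-by-construction keeps downstream recovery tests honest:
    the estimator is judged against the variance that was actually
    planted.
    """
    if n_qtl > G.n_snps:
        raise ConfigurationError("n_qtl exceeds the number of simulated SNPs")
    n = G.n_individuals
    qtl_idx = np.sort(rng.choice(G.n_snps, size=n_qtl, replace=False))
    beta = rng.standard_normal(n_qtl)
    Z = np.nan_to_num(G.dosage[:, qtl_idx].astype(np.float64))
    Z = Z - Z.mean(axis=0)
    g = Z @ beta
    g -= g.mean()
    g_sd = g.std()
    scale_g = 0.0 if h2 == 0 or g_sd == 0 else np.sqrt(h2) * total_sd / g_sd
    g *= scale_g
    beta *= scale_g

    e = rng.standard_normal(n)
    e -= e.mean()
    if g_sd > 0 and g.std() > 0:
        e -= g * (e @ g) / (g @ g)  # exact in-sample orthogonality
    e_sd = e.std()
    if h2 < 1.0 and e_sd > 0:
        e *= np.sqrt(1.0 - h2) * total_sd / e_sd
    else:
        e[:] = 0.0
    y = g + e

    truth = SimTruth(
        qtl=pd.DataFrame(
            {"snp_id": G.snps["snp_id"].to_numpy()[qtl_idx], "effect": beta}
        ),
        breeding_values=pd.Series(g, index=G.samples, name="bv"),
    )
    return y, truth


def simulate_bivariate_traits(
    G: GenotypeMatrix,
    h2: tuple[float, float],
    r_g: float,
    n_qtl: int,
    rng: np.random.Generator,
    r_e: float = 0.0,
) -> tuple[np.ndarray, SimTruth]:
    """Two traits with exact in-sample genetic correlation ``r_g``.

    Genetic values come from shared QTLs with correlated effect pairs; the
    realized n×2 genetic and environmental blocks are whitened and
    re-colored so the sample covariance matrices hit the targets exactly
    (unit phenotypic variances).  Returns an (n, 2) array.
    """
    if n_qtl > G.n_snps:
        raise ConfigurationError("n_qtl exceeds the number of simulated SNPs")
    n = G.n_individuals
    qtl_idx = np.sort(rng.choice(G.n_snps, size=n_qtl, replace=False))
    Z = np.nan_to_num(G.dosage[:, qtl_idx].astype(np.float64))
    Z = Z - Z.mean(axis=0)
    B = rng.standard_normal((n_qtl, 2))
    Gv = Z @ B

    def _color(M: np.ndarray, cov: np.ndarray) -> np.ndarray:
        M = M - M.mean(axis=0)
        S = (M.T @ M) / n
        W = np.linalg.cholesky(np.linalg.inv(S))
        return M @ W @ np.linalg.cholesky(cov).T

    g_cov = np.array(
        [
            [h2[0], r_g * np.sqrt(h2[0] * h2[1])],
            [r_g * np.sqrt(h2[0] * h2[1]), h2[1]],
        ]
    )
    e_cov = np.array(
        [
            [1 - h2[0], r_e * np.sqrt((1 - h2[0]) * (1 - h2[1]))],
            [r_e * np.sqrt((1 - h2[0]) * (1 - h2[1])), 1 - h2[1]],
        ]
    )
    Gv = _color(Gv, g_cov)
    E = rng.standard_normal((n, 2))
    E -= Gv @ np.linalg.solve(Gv.T @ Gv, Gv.T @ E)  # orthogonal to genetics
    E = _color(E, e_cov)
    Y = Gv + E
    truth = SimTruth(
        breeding_values=pd.Series(Gv[:, 0], index=G.samples, name="bv_trait1"),
        bird_params=pd.DataFrame(Gv, index=G.samples, columns=["bv1", "bv2"]),
    )
    return Y, truth


def simulate_growth_and_intake(
    G: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate longitudinal body-weight and feed records for each bird.

    Daily body weight follows a bird-specific line
    ``BW = intercept + ADG * DOT + noise`` with DOT coded 1..test_days.
    Daily feed is the Koch expectation ``b0 + b1*MMBW + b2*ADG`` plus the
    bird's true RFI (polygenic, heritability ``h2_rfi``), its pen and sex
    effects, and day-level noise.  Pens are nested in sex: the first half
    of ``pen_effects`` are male pens, the second half female; birds are
    assigned round-robin.

    Returns a long-format record table (bird_id, sex, pen, dot,
    body_weight_g, feed_g) and the ground truth (per-bird intercept, ADG,
    true RFI, breeding values, QTL effects).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = G.n_individuals
    n_pens = len(config.pen_effects)
    pens = np.arange(n) % n_pens
    sex = np.where(pens < n_pens // 2, "M", "F")  # pens nested in sex

    # growth is itself heritable, so ADFI inherits genetic variance from
    # MMBW and ADG on top of the RFI component (keeps r_g(RFI, ADFI) < 1)
    adg_dev, _ = simulate_polygenic_trait(G, config.h2_adg, config.n_qtl, config.adg_sd, rng)
    adg = config.adg_mean + adg_dev
    start_mean = np.where(
        sex == "M", config.start_weight_mean[0], config.start_weight_mean[1]
    )
    sw_dev, _ = simulate_polygenic_trait(
        G, config.h2_start_weight, config.n_qtl, config.start_weight_sd, rng
    )
    intercept = start_mean + sw_dev - adg  # BW at DOT=0

    rfi_true, truth = simulate_polygenic_trait(
        G, config.h2_rfi, config.n_qtl, config.rfi_sd, rng
    )

    b0, b1, b2 = config.koch_coeffs
    mid_day = (config.test_days + 2) // 2  # day 21 of a 40-day test
    mbw_true = intercept + adg * mid_day
    mmbw_true = np.power(np.clip(mbw_true, 1e-9, None), 0.75)
    pen_eff = np.asarray(config.pen_effects)[pens]
    sex_eff = np.where(sex == "M", config.sex_effect, 0.0)
    expected_feed = b0 + b1 * mmbw_true + b2 * adg + rfi_true + pen_eff + sex_eff

    days = np.arange(1, config.test_days + 1)
    bw = (
        intercept[:, None]
        + adg[:, None] * days[None, :]
        + rng.normal(0.0, config.growth_noise_sd, size=(n, config.test_days))
    )
    feed = expected_feed[:, None] + rng.normal(
        0.0, config.feed_noise_sd, size=(n, config.test_days)
    )
    feed = np.clip(feed, 0.0, None)

    records = pd.DataFrame(
        {
            "bird_id": np.repeat(G.samples, config.test_days),
            "sex": np.repeat(sex, config.test_days),
            "pen": np.repeat(pens + 1, config.test_days),
            "dot": np.tile(days, n),
            "body_weight_g": bw.ravel(),
            "feed_g": feed.ravel(),
        }
    )
    truth.bird_params = pd.DataFrame(
        {
            "bird_id": G.samples,
            "sex": sex,
            "pen": pens + 1,
            "intercept": intercept,
            "adg": adg,
            "mbw": mbw_true,
            "mmbw": mmbw_true,
            "rfi_true": rfi_true,
            "pen_effect": pen_eff,
            "sex_effect": sex_eff,
        }
    )
    return records, truth


def simulate_counts(config: CountsConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Negative-binomial gene counts for a high-RFI vs low-RFI contrast.

    Counts are Gamma–Poisson draws with ``var = mu + dispersion * mu²``.
    A ``de_fraction`` of genes receives the configured fold change in the
    low-RFI group (half up, half down).  The returned table carries
    gene_id, length_bp and one column per sample named ``H1..`` / ``L1..``;
    per-sample library sizes are stored in ``table.attrs['lib_sizes']``
    and group labels in ``table.attrs['groups']``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    g, k = config.n_genes, config.n_per_group
    lengths = np.round(np.exp(rng.normal(config.length_log_mean, config.length_log_sd, g)))
    lengths = np.clip(lengths, 150, None).astype(np.int64)
    abundance = np.exp(rng.normal(0.0, config.abundance_log_sd, g))

    n_de = int(round(config.de_fraction * g))
    fc = np.ones(g)
    if n_de > 0:
        de_idx = rng.choice(g, size=n_de, replace=False)
        up = rng.random(n_de) < 0.5
        fc[de_idx] = np.where(up, config.fold_change, 1.0 / config.fold_change)

    samples = [f"H{i+1}" for i in range(k)] + [f"L{i+1}" for i in range(k)]
    groups = {s: ("high" if s.startswith("H") else "low") for s in samples}
    lib_sizes = {
        s: float(
            max(1.0, rng.normal(config.lib_size_mean, config.lib_size_cv * config.lib_size_mean))
        )
        for s in samples
    }

    rel_high = abundance * lengths
    rel_high = rel_high / rel_high.sum()
    rel_low = abundance * fc * lengths
    rel_low = rel_low / rel_low.sum()

    data = {}
    shape = 1.0 / config.dispersion
    for s in samples:
        rel = rel_high if groups[s] == "high" else rel_low
        mu = lib_sizes[s] * rel
        lam = rng.gamma(shape, mu * config.dispersion)
        data[s] = rng.poisson(lam).astype(np.int64)

    table = pd.DataFrame({"gene_id": [f"gene{i+1:05d}" for i in range(g)], "length_bp": lengths, **data})
    table.attrs["lib_sizes"] = lib_sizes
    table.attrs["groups"] = groups
    truth = SimTruth(de_fold_change=pd.Series(fc, index=table["gene_id"], name="fold_change"))
    return table, truth


def simulate_gene_models(
    chrom_lengths: tuple[int, ...],
    n_genes: int,
    seed: int = 0,
    mean_gene_bp: int = 8000,
):
    """Toy gene models laid round-robin across the simulated chromosomes.

    Pipeline plumbing for end-to-end runs on synthetic data: genes get
    ids matching the count generator (gene00001, ...), random strand,
    two exons and a 3'/5' UTR each.  Not a model of real gene
    architecture.
    """
    from .annotate import GeneModel

    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    lengths = np.asarray(chrom_lengths, dtype=np.int64)
    genes = []
    per_chrom = np.zeros(len(lengths), dtype=int)
    raw = lengths / lengths.sum() * n_genes
    per_chrom = np.maximum(1, np.floor(raw).astype(int))
    while per_chrom.sum() < n_genes:
        per_chrom[np.argmax(raw - per_chrom)] += 1
    while per_chrom.sum() > n_genes:
        per_chrom[np.argmax(per_chrom)] -= 1

    gid = 1
    for c, (length, k) in enumerate(zip(lengths, per_chrom), start=1):
        slots = np.linspace(1, max(int(length) - mean_gene_bp, 2), k, dtype=np.int64)
        for start in slots:
            span = int(rng.integers(mean_gene_bp // 2, mean_gene_bp * 2))
            end = min(int(start) + span, int(length))
            strand = "+" if rng.random() < 0.5 else "-"
            utr_len = min(max(span // 20, 10), max((end - int(start)) // 4, 1))
            mid = (int(start) + end) // 2
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:05d}",
                    chrom=str(c),
                    start=int(start),
                    end=end,
                    strand=strand,
                    exons=((int(start), mid), (min(mid + 50, end), end)),
                    utr5=((int(start), int(start) + utr_len),) if strand == "+" else ((end - utr_len, end),),
                    utr3=((end - utr_len, end),) if strand == "+" else ((int(start), int(start) + utr_len),),
                )
            )
            gid += 1
    return genes


def write_run_manifest(path: str | Path, config, extra: dict | None = None) -> None:
    """Record the generator configuration and seeds as JSON."""
    payload = {"config": dataclasses.asdict(config)}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
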