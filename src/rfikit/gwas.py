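"""Kinship-adjusted single-marker association scan.

The model is ``Y = Xb + Sa + Zu + e`` with a polygenic effect
``u ~ N(0, K*sigma_G2)`` and residual ``e ~ N(0, I*sigma_e2)``.  The scan
is two-step: the null variance components are estimated once by REML,
then every SNP receives a generalized-least-squares Wald test of its
dosage term under the fixed null covariance ``V = K*s_G2 + I*s_e2``
(EMMAX-style).  Residual stratification is absorbed by genomic control
(lambda = median chi2 / 0.4549), significance is declared at
``p < 1e-4`` after lambda correction, and SNPs are additionally ranked by
a chromosome-wise step-up false discovery rate ``m*P(i)/i``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .varcomp import KinshipMatrix, VarCompResult, _eigen, reml_univariate

__all__ = [
    "QCReport",
    "GCResult",
    "qc_filter",
    "hwe_exact_test",
    "mixed_model_scan",
    "genomic_control",
    "chromwise_fdr",
    "snp_variance_explained",
    "snp_set_variance_explained",
]

NULL_CHI2_MEDIAN = 0.4549364  # median of the 1-df chi-square distribution


@dataclass
class QCReport:
    n_snps_in: int
    n_ind_in: int
    removed_snp_callrate: int
    removed_ind_callrate: int
    removed_maf: int
    removed_hwe: int
    n_snps_out: int
    n_ind_out: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class GCResult:
    lambda_gc: float
    p_corrected: np.ndarray
    chi2_corrected: np.ndarray


def hwe_exact_test(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact Hardy–Weinberg test p-value (Wigginton et al. recursion).

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one, conditional on the allele counts.
    """
    n = n_het + n_hom_rare + n_hom_common
    rare = 2 * n_hom_rare + n_het
    if rare > n:  # orient to the rarer allele
        rare = 2 * n - rare
    if n == 0:
        return 1.0
    mid = rare * (2 * n - rare) // (2 * n)
    if (mid % 2) != (rare % 2):
        mid += 1
    probs = np.zeros(rare + 1)
    probs[mid] = 1.0
    # downward recursion: P(het-2) / P(het) = het*(het-1) / (4*homr*homc) inverted
    het = mid
    homr = (rare - mid) // 2
    homc = n - het - homr
    while het >= 2:
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (homr + 1) * (homc + 1))
        het -= 2
        homr += 1
        homc += 1
    het, homr, homc = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while het <= rare - 2:
        probs[het + 2] = probs[het] * 4.0 * homr * homc / ((het + 2.0) * (het + 1.0))
        het += 2
        homr -= 1
        homc -= 1
    probs /= probs.sum()
    obs = n_het
    return float(min(1.0, probs[probs <= probs[obs] * (1 + 1e-12)].sum()))


def qc_filter(
    G,
    min_call_rate_snp: float = 0.95,
    min_call_rate_ind: float = 0.95,
    min_maf: float = 0.01,
    hwe_p_min: float = 1e-6,
) -> tuple[object, QCReport]:
    """Iterative genotype quality control.

    Removal order: SNP call rate, individual call rate, minor-allele
    frequency, Hardy–Weinberg exact test; counts are reported per step.
    Raises if no SNP survives.
    """
    dosage = np.array(G.dosage, dtype=float)
    n0, m0 = dosage.shape

    snp_cr = 1.0 - np.isnan(dosage).mean(axis=0)
    keep_snp = snp_cr >= min_call_rate_snp
    removed_snp_cr = int((~keep_snp).sum())
    dosage = dosage[:, keep_snp]

    ind_cr = 1.0 - np.isnan(dosage).mean(axis=1) if dosage.shape[1] else np.ones(n0)
    keep_ind = ind_cr >= min_call_rate_ind
    removed_ind = int((~keep_ind).sum())
    dosage = dosage[keep_ind, :]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(dosage, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep_maf = np.nan_to_num(maf) >= min_maf
    removed_maf = int((~keep_maf).sum())
    dosage = dosage[:, keep_maf]

    keep_hwe = np.ones(dosage.shape[1], dtype=bool)
    for j in range(dosage.shape[1]):
        col = dosage[:, j]
        col = col[~np.isnan(col)]
        n_het = int((col == 1).sum())
        n_aa = int((col == 2).sum())
        n_bb = int((col == 0).sum())
        if hwe_exact_test(n_het, n_aa, n_bb) < hwe_p_min:
            keep_hwe[j] = False
    removed_hwe = int((~keep_hwe).sum())
    dosage = dosage[:, keep_hwe]

    if dosage.shape[1] == 0:
        raise ValueError("quality control removed every SNP")

    snp_mask = keep_snp.copy()
    snp_mask[keep_snp] = keep_maf
    snp_mask2 = snp_mask.copy()
    snp_mask2[snp_mask] = keep_hwe
    G_out = G.subset_snps(snp_mask2).subset_individuals(keep_ind)
    G_out.dosage = dosage

    report = QCReport(
        n_snps_in=m0,
        n_ind_in=n0,
        removed_snp_callrate=removed_snp_cr,
        removed_ind_callrate=removed_ind,
        removed_maf=removed_maf,
        removed_hwe=removed_hwe,
        n_snps_out=dosage.shape[1],
        n_ind_out=dosage.shape[0],
    )
    return G_out, report


def mixed_model_scan(
    y: np.ndarray,
    G,
    K: KinshipMatrix | np.ndarray,
    X: np.ndarray | None = None,
    null_fit: VarCompResult | None = None,
) -> pd.DataFrame:
    """Two-step mixed-model scan (null REML, then per-SNP GLS Wald tests).

    ``X`` defaults to an intercept; pass pre-adjusted (transformed) RFI
    when fixed effects were already removed.  Effects are reported for the
    minor allele; missing dosages are mean-imputed per SNP; monomorphic
    columns are kept in the output but flagged ``skipped``.

    Returns a table with snp_id, chrom, pos, maf, effect, se, chi2,
    p_raw, skipped — sorted by (chrom, pos).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)

    d, U = _eigen(K)
    if null_fit is None:
        null_fit = reml_univariate(y, X, K, eigen=(d, U))
    v = null_fit.sigma_a2 * d + null_fit.sigma_e2
    w = 1.0 / v

    dosage = np.array(G.dosage, dtype=float)
    freq = np.nanmean(dosage, axis=0) / 2.0
    nan_mask = np.isnan(dosage)
    if nan_mask.any():
        dosage[nan_mask] = (2.0 * freq)[np.where(nan_mask)[1]]
    flip = freq > 0.5  # report the minor allele's effect
    dosage[:, flip] = 2.0 - dosage[:, flip]
    maf = np.minimum(freq, 1.0 - freq)
    skipped = dosage.std(axis=0) == 0

    yt = U.T @ y
    Xt = U.T @ X
    St = U.T @ dosage

    # residualize the rotated dosages and phenotype against the fixed effects
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    XtWX_inv = np.linalg.inv(XtWX)
    proj_y = Xt @ (XtWX_inv @ (Xw.T @ yt))
    ry = yt - proj_y
    proj_S = Xt @ (XtWX_inv @ (Xw.T @ St))
    rS = St - proj_S

    sws = np.einsum("ij,ij->j", rS * w[:, None], rS)
    swy = (rS * w[:, None]).T @ ry
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = swy / sws
        se = np.sqrt(1.0 / sws)
        chi2 = effect * effect / (se * se)
    effect[skipped] = np.nan
    se[skipped] = np.nan
    chi2[skipped] = np.nan
    p_raw = stats.chi2.sf(chi2, df=1)

    out = G.snps.copy()
    out["maf"] = maf
    out["effect"] = effect
    out["se"] = se
    out["chi2"] = chi2
    out["p_raw"] = p_raw
    out["skipped"] = skipped
    out.attrs["null_fit"] = null_fit
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def genomic_control(chi2: np.ndarray) -> GCResult:
    """Genomic-control correction of a vector of 1-df chi-square statistics.

    ``lambda = median(chi2) / 0.4549364``; corrected p-values come from
    ``chi2 / lambda`` on 1 df.  Lambda is reported to three decimals in
    the pipeline outputs but kept at full precision here.
    """
    chi2 = np.asarray(chi2, dtype=float)
    valid = np.isfinite(chi2)
    if not valid.any():
        raise ValueError("empty chi-square vector")
    if valid.sum() < 100:
        warnings.warn("fewer than 100 statistics: lambda is noisy", stacklevel=2)
    lam = float(np.median(chi2[valid]) / NULL_CHI2_MEDIAN)
    corrected = chi2 / lam
    p = stats.chi2.sf(corrected, df=1)
    return GCResult(lambda_gc=lam, p_corrected=p, chi2_corrected=corrected)


def chromwise_fdr(
    p: np.ndarray,
    chrom: np.ndarray,
    tier_1: float = 0.05,
    tier_2: float = 0.10,
    sig_threshold: float = 1e-4,
    per_chromosome: bool = True,
) -> pd.DataFrame:
    """Chromosome-wise step-up FDR ``m*P(i)/i`` with monotonicity.

    Within each chromosome (or genome-wide when ``per_chromosome=False``)
    p-values are sorted ascending, ``m*P(i)/i`` is computed with m the
    number of SNPs in the group, the cumulative minimum is taken from the
    largest rank down (step-up), and values are capped at 1.  Tier flags
    mark FDR <= 5 % and <= 10 %; ``significant`` marks p below the
    genome-wide threshold (1e-4 by default, applied to the supplied —
    lambda-corrected — p-values).
    """
    p = np.asarray(p, dtype=float)
    chrom = np.asarray(chrom)
    fdr = np.full(p.shape, np.nan)
    groups = [chrom == c for c in pd.unique(chrom)] if per_chromosome else [np.ones(p.size, bool)]
    for mask in groups:
        idx = np.where(mask & np.isfinite(p))[0]
        if idx.size == 0:
            continue
        m = idx.size
        order = idx[np.argsort(p[idx], kind="stable")]
        raw = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(raw[::-1])[::-1]
        fdr[order] = np.minimum(stepped, 1.0)
    return pd.DataFrame(
        {
            "fdr_value": fdr,
            "fdr_le_5pct": fdr <= tier_1,
            "fdr_le_10pct": fdr <= tier_2,
            "significant": np.nan_to_num(p, nan=1.0) < sig_threshold,
        }
    )


def snp_variance_explained(
    y: np.ndarray, dosage: np.ndarray, ebv: np.ndarray | None = None
) -> tuple[float, float]:
    """Percent variance explained by a SNP's genotype classes.

    Fits ``y = mu + SNP + e`` with the genotype as a fixed class effect
    (up to 2 df) and reports 100*R².  When breeding values are supplied
    the same computation on them gives the share of additive variance.
    Raises on a constant dosage.
    """
    dosage = np.asarray(dosage, dtype=float)
    valid = ~np.isnan(dosage)
    classes = np.unique(dosage[valid])
    if classes.size < 2:
        raise ValueError("constant dosage: variance explained undefined")

    def _r2(resp: np.ndarray) -> float:
        resp = np.asarray(resp, dtype=float)
        mask = valid & ~np.isnan(resp)
        r, g = resp[mask], dosage[mask]
        grand = r.mean()
        ss_tot = float(np.sum((r - grand) ** 2))
        if ss_tot == 0:
            return 0.0
        ss_between = sum(
            len(r[g == c]) * (r[g == c].mean() - grand) ** 2 for c in np.unique(g)
        )
        return 100.0 * float(ss_between) / ss_tot

    var_pct = _r2(y)
    addvar_pct = _r2(ebv) if ebv is not None else float("nan")
    return var_pct, addvar_pct


def snp_set_variance_explained(y: np.ndarray, dosages: np.ndarray) -> float:
    """Percent variance of ``y`` explained by a SNP set in a joint OLS fit.

    Unlike summing single-SNP R² values — which double-counts SNPs in
    mutual LD — the joint fit attributes shared signal once.  Returns
    100*R² of the multiple regression of y on all dosage columns
    (mean-imputed, plus intercept).
    """
    y = np.asarray(y, dtype=float)
    D = np.array(dosages, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    col_mean = np.nanmean(D, axis=0)
    nan_mask = np.isnan(D)
    if nan_mask.any():
        D[nan_mask] = col_mean[np.where(nan_mask)[1]]
    X = np.column_stack([np.ones(y.size), D])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 100.0 * (1.0 - float(resid @ resid) / ss_tot)
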