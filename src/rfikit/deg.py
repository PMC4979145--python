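"""RPKM expression and differential expression between RFI-divergent groups.

Expression is quantified as RPKM = 1e9 * count / (total_mapped * length).
With two libraries per group, counts are pooled within group; each gene's
p-value comes from an exact conditional binomial test of the pooled
counts against the pooled library totals, q-values from
Benjamini–Hochberg, and a gene is called differentially expressed when
q < 0.05 and |log2 fold change| >= 1.  Genes expressed in exactly one
group (zero pooled counts on one side, RPKM >= 1 on the other) are
reported as group-specific rather than with a numeric fold change.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["compute_rpkm", "call_degs", "mirna_target_consistency"]


def compute_rpkm(count, gene_length_bp, total_mapped):
    """Reads per kilobase of transcript per million mapped reads.

    ``rpkm = 1e9 * count / (total_mapped * length)``; accepts scalars or
    arrays (broadcasting).  Zero lengths or library sizes are errors.
    """
    count = np.asarray(count, dtype=float)
    length = np.asarray(gene_length_bp, dtype=float)
    total = np.asarray(total_mapped, dtype=float)
    if np.any(length <= 0):
        raise ValueError("gene length must be positive")
    if np.any(total <= 0):
        raise ValueError("total mapped reads must be positive")
    return 1e9 * count / (total * length)


def _exact_two_proportion_p(c1: int, n1: float, c2: int, n2: float) -> float:
    """Exact conditional test of equal proportions c1/n1 vs c2/n2.

    Conditions on the total count: under the null, c1 ~ Binomial(c1+c2,
    n1/(n1+n2)).  Two-sided p by the minimum-likelihood method.
    """
    total = int(c1 + c2)
    if total == 0:
        return 1.0
    return float(stats.binomtest(int(c1), total, n1 / (n1 + n2)).pvalue)


def call_degs(
    table: pd.DataFrame,
    groups: dict[str, str] | None = None,
    lib_sizes: dict[str, float] | None = None,
    q_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
    pseudocount: float = 0.5,
    specific_rpkm_floor: float = 1.0,
) -> pd.DataFrame:
    """Call differentially expressed genes between high- and low-RFI groups.

    ``table`` columns: gene_id, length_bp, one column per sample;
    ``groups`` maps sample -> {"high", "low"} and ``lib_sizes`` maps
    sample -> total mapped reads (both default to ``table.attrs``).
    log2fc is low-vs-high from pooled RPKM with ``pseudocount`` added to
    the pooled counts.  Status values: up_in_low, down_in_low,
    group_specific_low, group_specific_high, not_de.
    """
    groups = groups if groups is not None else table.attrs.get("groups")
    lib_sizes = lib_sizes if lib_sizes is not None else table.attrs.get("lib_sizes")
    if groups is None or lib_sizes is None:
        raise ValueError("sample->group and sample->library-size maps are required")
    high = [s for s, g in groups.items() if g == "high"]
    low = [s for s, g in groups.items() if g == "low"]
    if not high or not low:
        raise ValueError("need at least one sample per group")

    length = table["length_bp"].to_numpy(dtype=float)
    if np.any(length <= 0):
        warnings.warn("genes with non-positive length skipped", stacklevel=2)
    keep = length > 0
    sub = table.loc[keep].reset_index(drop=True)
    length = length[keep]

    c_high = sub[high].to_numpy(dtype=float).sum(axis=1)
    c_low = sub[low].to_numpy(dtype=float).sum(axis=1)
    n_high = float(sum(lib_sizes[s] for s in high))
    n_low = float(sum(lib_sizes[s] for s in low))

    rpkm_high = compute_rpkm(c_high, length, n_high)
    rpkm_low = compute_rpkm(c_low, length, n_low)
    log2fc = np.log2(
        compute_rpkm(c_low + pseudocount, length, n_low)
        / compute_rpkm(c_high + pseudocount, length, n_high)
    )

    p = np.array(
        [
            _exact_two_proportion_p(int(cl), n_low, int(ch), n_high)
            for cl, ch in zip(c_low, c_high)
        ]
    )
    _, q, _, _ = multipletests(p, method="fdr_bh")

    spec_low = (c_high == 0) & (rpkm_low >= specific_rpkm_floor)
    spec_high = (c_low == 0) & (rpkm_high >= specific_rpkm_floor)
    de = (q < q_max) & (np.abs(log2fc) >= min_abs_log2fc) & ~spec_low & ~spec_high

    status = np.full(len(sub), "not_de", dtype=object)
    status[de & (log2fc > 0)] = "up_in_low"
    status[de & (log2fc < 0)] = "down_in_low"
    status[spec_low] = "group_specific_low"
    status[spec_high] = "group_specific_high"

    return pd.DataFrame(
        {
            "gene_id": sub["gene_id"],
            "length_bp": length.astype(np.int64),
            "count_high": c_high.astype(np.int64),
            "count_low": c_low.astype(np.int64),
            "rpkm_mean_high": rpkm_high,
            "rpkm_mean_low": rpkm_low,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "status": status,
        }
    )


def mirna_target_consistency(
    degs: pd.DataFrame,
    target_lists: dict[str, list[str]],
    mirna_direction: dict[str, str],
) -> pd.DataFrame:
    """Check miRNA/target expression directions for negative regulation.

    For each (miRNA, target) with the target in the DEG set and a known
    miRNA direction ("up_in_low"/"down_in_low"), the pair is consistent
    with negative regulation iff the directions are opposite.  Unknown
    gene ids are reported with verdict "target_not_de", not fatal.
    """
    direction = dict(zip(degs["gene_id"], degs["status"]))
    up_like = {"up_in_low", "group_specific_low"}
    down_like = {"down_in_low", "group_specific_high"}
    rows = []
    for mirna, targets in target_lists.items():
        mdir = mirna_direction.get(mirna)
        for gene in targets:
            tdir = direction.get(gene)
            if mdir is None:
                verdict = "mirna_direction_unknown"
            elif tdir is None or tdir == "not_de":
                verdict = "target_not_de"
            else:
                m_up = mdir in up_like
                t_up = tdir in up_like
                if mdir not in up_like | down_like or tdir not in up_like | down_like:
                    verdict = "target_not_de"
                else:
                    verdict = "consistent" if m_up != t_up else "inconsistent"
            rows.append(
                {"mirna": mirna, "target": gene, "mirna_status": mdir, "target_status": tdir, "verdict": verdict}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["mirna", "target"]).reset_index(drop=True)
    return out
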