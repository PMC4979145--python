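"""End-to-end pipeline: simulate → growth → rfi → varcomp → gwas → ld → deg → integrate.

Each stage reads its inputs from and writes its outputs to a single run
directory with fixed filenames, so stages can be re-run individually and
a missing upstream artifact produces an error naming the stage that
should have made it.  All randomness flows from the single seed in the
run configuration; re-running an unchanged configuration reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import deg as deg_mod
from . import gwas as gwas_mod
from . import io as io_mod
from . import ld as ld_mod
from . import rfi as rfi_mod
from . import varcomp as vc_mod
from .growth import fit_cohort
from .simulate import (
    CountsConfig,
    SimConfig,
    simulate_counts,
    simulate_gene_models,
    simulate_genotypes,
    simulate_growth_and_intake,
)

logger = logging.getLogger("rfikit")

STAGES = ["simulate", "growth", "rfi", "varcomp", "gwas", "ld", "deg", "integrate"]

FILES = {
    "genotypes": "genotypes.vcf",
    "phenotypes": "phenotypes.csv",
    "counts": "counts.tsv",
    "counts_meta": "counts_meta.json",
    "annotation": "annotation.gff3",
    "truth_birds": "truth_birds.tsv",
    "truth_qtl": "truth_qtl.tsv",
    "truth_de": "truth_de.tsv",
    "traits": "traits.tsv",
    "contrast": "contrast.tsv",
    "rfi_audit": "rfi_audit.json",
    "kinship": "kinship.tsv",
    "varcomp": "varcomp.json",
    "qc_report": "qc_report.json",
    "assoc": "assoc.tsv",
    "manhattan": "manhattan.tsv",
    "ld_decay": "ld_decay.tsv",
    "blocks": "blocks.tsv",
    "degs": "degs.tsv",
    "mirna": "mirna_consistency.tsv",
    "capture50": "capture_50kb.tsv",
    "capture500": "capture_500kb.tsv",
    "overlap": "overlap.tsv",
    "manifest": "manifest.json",
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips losslessly via YAML."""

    outdir: str = "rfikit_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    counts: dict = field(default_factory=dict)  # CountsConfig overrides
    r2_flag_threshold: float = 0.80
    mid_day: int = 21
    fixed_effect_alpha: float = 0.01
    qc_min_call_rate_snp: float = 0.95
    qc_min_call_rate_ind: float = 0.95
    qc_min_maf: float = 0.01
    qc_hwe_p_min: float = 1e-6
    sig_threshold: float = 1e-4
    fdr_tier_1: float = 0.05
    fdr_tier_2: float = 0.10
    q_max: float = 0.05
    min_abs_log2fc: float = 1.0
    flank_kb_narrow: float = 50.0
    flank_kb_wide: float = 500.0
    ld_block_max_snps: int = 40
    mirna_target_files: dict = field(default_factory=dict)  # miRNA -> gene-list path
    mirna_directions: dict = field(default_factory=dict)  # miRNA -> up_in_low/down_in_low

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
        for frac in (self.q_max, self.fdr_tier_1, self.fdr_tier_2, self.sig_threshold):
            if not (0 < frac < 1):
                raise PipelineError("thresholds must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _require(outdir: Path, key: str, producer: str) -> Path:
    path = outdir / FILES[key]
    if not path.exists():
        raise PipelineError(
            f"missing input {path.name}: run the '{producer}' stage first"
        )
    return path


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        info = _STAGE_FUNCS[stage](config, outdir)
        dt = time.perf_counter() - t0
        logger.info("stage %-9s done in %.2f s", stage, dt)
        manifest["stages"][stage] = info
    (outdir / FILES["manifest"]).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def _stage_simulate(config: RunConfig, outdir: Path) -> dict:
    sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
    counts_cfg = CountsConfig(**{"seed": config.seed, **config.counts})
    G = simulate_genotypes(sim_cfg)
    records, truth = simulate_growth_and_intake(G, sim_cfg)
    counts, ctruth = simulate_counts(counts_cfg)
    # realistic gene density (~1 per 50 kb); remaining count-table genes
    # live off the simulated chromosomes and never overlap a SNP flank
    n_annotated = min(counts_cfg.n_genes, sum(sim_cfg.chrom_lengths) // 50_000)
    genes = simulate_gene_models(sim_cfg.chrom_lengths, n_annotated, seed=config.seed)

    io_mod.write_vcf(G, outdir / FILES["genotypes"])
    io_mod.write_ped_map(G, outdir / "genotypes")
    io_mod.write_phenotypes_csv(records, outdir / FILES["phenotypes"])
    counts.to_csv(outdir / FILES["counts"], sep="\t", index=False)
    (outdir / FILES["counts_meta"]).write_text(
        json.dumps(
            {"groups": counts.attrs["groups"], "lib_sizes": counts.attrs["lib_sizes"]},
            indent=2,
        )
    )
    ann.write_gff3(genes, outdir / FILES["annotation"])
    truth.bird_params.to_csv(outdir / FILES["truth_birds"], sep="\t", index=False)
    truth.qtl.to_csv(outdir / FILES["truth_qtl"], sep="\t", index=False)
    ctruth.de_fold_change.to_frame().to_csv(outdir / FILES["truth_de"], sep="\t")
    return {
        "seed": config.seed,
        "n_individuals": G.n_individuals,
        "n_snps": G.n_snps,
        "n_genes": counts_cfg.n_genes,
        "digests": {k: _digest(outdir / FILES[k]) for k in ("genotypes", "phenotypes", "counts")},
    }


def _stage_growth(config: RunConfig, outdir: Path) -> dict:
    records = io_mod.read_phenotypes_csv(_require(outdir, "phenotypes", "simulate"))
    traits = fit_cohort(records, mid_day=config.mid_day, r2_flag_threshold=config.r2_flag_threshold)
    traits.to_csv(outdir / FILES["traits"], sep="\t", index=False)
    return {"n_birds": len(traits), "n_low_fit": int(traits["low_fit_flag"].sum())}


def _stage_rfi(config: RunConfig, outdir: Path) -> dict:
    traits = pd.read_csv(_require(outdir, "traits", "growth"), sep="\t")
    koch, rfi = rfi_mod.fit_koch_rfi(traits)
    traits["rfi"] = rfi
    p_sex, p_pen, adjusted = rfi_mod.test_fixed_effects_and_adjust(
        rfi, traits["sex"].to_numpy(), traits["pen"].to_numpy(), alpha=config.fixed_effect_alpha
    )
    traits["rfi_adjusted"] = adjusted
    a2_before, p_before = rfi_mod.anderson_darling_test(adjusted)
    z, family, params = rfi_mod.johnson_transform(adjusted)
    a2_after, p_after = rfi_mod.anderson_darling_test(z)
    traits["rfi_transformed"] = z
    traits.to_csv(outdir / FILES["traits"], sep="\t", index=False)
    contrast = rfi_mod.divergent_group_contrast(traits)
    contrast.to_csv(outdir / FILES["contrast"], sep="\t", index=False)
    audit = {
        "koch": dataclasses.asdict(koch),
        "p_sex": p_sex,
        "p_pen": p_pen,
        "ad_before": {"A2_star": a2_before, "p": p_before},
        "ad_after": {"A2_star": a2_after, "p": p_after},
        "johnson_family": family,
        "johnson_params": params,
    }
    (outdir / FILES["rfi_audit"]).write_text(json.dumps(audit, indent=2, default=float) + "\n")
    return {"koch_b": [koch.b0, koch.b1, koch.b2], "p_sex": p_sex, "p_pen": p_pen,
            "johnson_family": family, "ad_p_after": p_after}


def _load_genotypes_for_analysis(config: RunConfig, outdir: Path):
    G = io_mod.read_vcf(_require(outdir, "genotypes", "simulate"))
    return gwas_mod.qc_filter(
        G,
        min_call_rate_snp=config.qc_min_call_rate_snp,
        min_call_rate_ind=config.qc_min_call_rate_ind,
        min_maf=config.qc_min_maf,
        hwe_p_min=config.qc_hwe_p_min,
    )


def _aligned_traits(traits: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    aligned = traits.set_index("bird_id").loc[samples].reset_index()
    return aligned


def _stage_varcomp(config: RunConfig, outdir: Path) -> dict:
    traits = pd.read_csv(_require(outdir, "traits", "growth"), sep="\t")
    if "rfi" not in traits.columns:
        raise PipelineError("traits.tsv lacks RFI: run the 'rfi' stage first")
    G, _ = _load_genotypes_for_analysis(config, outdir)
    traits = _aligned_traits(traits, G.samples)
    K = vc_mod.genomic_kinship(G)
    K.to_tsv(outdir / FILES["kinship"])
    X = _fixed_effects_design(traits)
    uni = vc_mod.reml_univariate(traits["rfi"].to_numpy(), X, K)
    biv = vc_mod.reml_bivariate(
        traits["rfi"].to_numpy(), traits["adfi"].to_numpy(), X, K
    )
    result = {
        "rfi_h2": uni.h2,
        "rfi_h2_se": uni.se_h2,
        "sigma_a2": uni.sigma_a2,
        "sigma_e2": uni.sigma_e2,
        "converged": uni.converged,
        "rg_rfi_adfi": biv.r_g,
        "rg_se": biv.se_rg,
        "g_cov": biv.g_cov.tolist(),
        "r_cov": biv.r_cov.tolist(),
    }
    (outdir / FILES["varcomp"]).write_text(json.dumps(result, indent=2) + "\n")
    return {"rfi_h2": uni.h2, "rg_rfi_adfi": biv.r_g}


def _fixed_effects_design(traits: pd.DataFrame) -> np.ndarray:
    """Intercept + sex + pen dummies, dropping collinear columns.

    Pens are nested in sex, so the sex dummy is a linear combination of
    the pen dummies; rank-deficient columns are removed greedily.
    """
    sex_d = pd.get_dummies(traits["sex"], drop_first=True, dtype=float)
    pen_d = pd.get_dummies(traits["pen"].astype(str), drop_first=True, dtype=float)
    cols = [np.ones(len(traits))] + [sex_d[c].to_numpy() for c in sex_d] + [
        pen_d[c].to_numpy() for c in pen_d
    ]
    X = np.column_stack(cols[:1])
    for col in cols[1:]:
        cand = np.column_stack([X, col])
        if np.linalg.matrix_rank(cand) > X.shape[1]:
            X = cand
    return X


def _stage_gwas(config: RunConfig, outdir: Path) -> dict:
    traits = pd.read_csv(_require(outdir, "traits", "growth"), sep="\t")
    if "rfi_transformed" not in traits.columns:
        raise PipelineError("traits.tsv lacks transformed RFI: run the 'rfi' stage first")
    G, report = _load_genotypes_for_analysis(config, outdir)
    (outdir / FILES["qc_report"]).write_text(json.dumps(report.as_dict(), indent=2) + "\n")
    traits = _aligned_traits(traits, G.samples)
    y = traits["rfi_transformed"].to_numpy()
    K = vc_mod.genomic_kinship(G)

    assoc = gwas_mod.mixed_model_scan(y, G, K)  # fixed effects pre-adjusted
    null_fit = assoc.attrs["null_fit"]  # concat below drops DataFrame attrs
    gc = gwas_mod.genomic_control(assoc["chi2"].to_numpy())
    assoc["p_gc"] = gc.p_corrected
    fdr = gwas_mod.chromwise_fdr(
        assoc["p_gc"].to_numpy(),
        assoc["chrom"].to_numpy(),
        tier_1=config.fdr_tier_1,
        tier_2=config.fdr_tier_2,
        sig_threshold=config.sig_threshold,
    )
    assoc = pd.concat([assoc, fdr], axis=1)

    ebv = vc_mod.blup_ebv(y, None, K, null_fit)
    var_pct = np.full(len(assoc), np.nan)
    addvar_pct = np.full(len(assoc), np.nan)
    sig_idx = np.where(assoc["significant"].to_numpy())[0]
    snp_order = {s: j for j, s in enumerate(G.snps["snp_id"])}
    for i in sig_idx:
        j = snp_order[assoc["snp_id"].iloc[i]]
        try:
            var_pct[i], addvar_pct[i] = gwas_mod.snp_variance_explained(
                y, G.dosage[:, j], ebv=ebv
            )
        except ValueError:
            continue
    assoc["var_pct"] = var_pct
    assoc["addvar_pct"] = addvar_pct
    # set-level share of additive variance: naive sum double-counts SNPs in
    # LD, the joint fit attributes shared signal once — both are reported
    addvar_sum = float(np.nansum(addvar_pct[sig_idx])) if sig_idx.size else 0.0
    if sig_idx.size:
        cols = [snp_order[assoc["snp_id"].iloc[i]] for i in sig_idx]
        addvar_joint = gwas_mod.snp_set_variance_explained(ebv, G.dosage[:, cols])
    else:
        addvar_joint = 0.0
    assoc.to_csv(outdir / FILES["assoc"], sep="\t", index=False)
    manhattan = assoc[["chrom", "pos", "p_gc"]].copy()
    manhattan["neglog10_p"] = -np.log10(manhattan["p_gc"])
    manhattan.to_csv(outdir / FILES["manhattan"], sep="\t", index=False)
    return {
        "lambda_gc": round(gc.lambda_gc, 3),
        "n_snps_tested": int((~assoc["skipped"]).sum()),
        "n_significant": int(assoc["significant"].sum()),
        "addvar_pct_sum": addvar_sum,
        "addvar_pct_joint": addvar_joint,
    }


def _stage_ld(config: RunConfig, outdir: Path) -> dict:
    G, _ = _load_genotypes_for_analysis(config, outdir)
    assoc_path = outdir / FILES["assoc"]
    if not assoc_path.exists():
        raise PipelineError("missing input assoc.tsv: run the 'gwas' stage first")
    assoc = pd.read_csv(assoc_path, sep="\t")

    decay = ld_mod.ld_decay_profile(G)
    decay.to_csv(outdir / FILES["ld_decay"], sep="\t", index=False)

    sig = assoc[assoc["significant"]]
    blocks_rows = []
    if len(sig):
        top_chrom = sig["chrom"].value_counts().idxmax()
        span = sig.loc[sig["chrom"] == top_chrom, "pos"]
        lo, hi = span.min() - 20_000, span.max() + 20_000
        mask = (
            (G.snps["chrom"] == top_chrom) & G.snps["pos"].between(lo, hi)
        ).to_numpy()
        idx = np.where(mask)[0][: config.ld_block_max_snps]
        if idx.size >= 2:
            blocks = ld_mod.gabriel_blocks(
                np.asarray(G.dosage, float)[:, idx],
                G.snps.iloc[idx].reset_index(drop=True),
            )
            for b in blocks:
                blocks_rows.append(
                    {
                        "chrom": b.chrom,
                        "start": b.start,
                        "end": b.end,
                        "n_snps": b.n_snps,
                        "snp_ids": ",".join(b.snp_ids),
                        "haplotypes": ";".join(f"{h}:{f:.4f}" for h, f in b.haplotypes.items()),
                    }
                )
    pd.DataFrame(
        blocks_rows, columns=["chrom", "start", "end", "n_snps", "snp_ids", "haplotypes"]
    ).to_csv(outdir / FILES["blocks"], sep="\t", index=False)
    return {"n_blocks": len(blocks_rows), "decay_bins": decay["mean_r2"].round(4).tolist()}


def _stage_deg(config: RunConfig, outdir: Path) -> dict:
    counts = pd.read_csv(_require(outdir, "counts", "simulate"), sep="\t")
    meta = json.loads(_require(outdir, "counts_meta", "simulate").read_text())
    degs = deg_mod.call_degs(
        counts,
        groups=meta["groups"],
        lib_sizes=meta["lib_sizes"],
        q_max=config.q_max,
        min_abs_log2fc=config.min_abs_log2fc,
    )
    degs.to_csv(outdir / FILES["degs"], sep="\t", index=False)
    info = {"n_genes": len(degs), "n_de": int((degs["status"] != "not_de").sum())}
    if config.mirna_target_files:
        targets = {
            m: Path(p).read_text().split() for m, p in config.mirna_target_files.items()
        }
        consistency = deg_mod.mirna_target_consistency(degs, targets, config.mirna_directions)
        consistency.to_csv(outdir / FILES["mirna"], sep="\t", index=False)
        info["n_mirna_pairs"] = len(consistency)
    return info


def _stage_integrate(config: RunConfig, outdir: Path) -> dict:
    assoc_path = outdir / FILES["assoc"]
    if not assoc_path.exists():
        raise PipelineError("missing input assoc.tsv: run the 'gwas' stage first")
    degs_path = outdir / FILES["degs"]
    if not degs_path.exists():
        raise PipelineError("missing input degs.tsv: run the 'deg' stage first")
    assoc = pd.read_csv(assoc_path, sep="\t")
    degs = pd.read_csv(degs_path, sep="\t")
    genes = ann.load_gff3(_require(outdir, "annotation", "simulate"))

    sig = assoc[assoc["significant"]][["snp_id", "chrom", "pos"]].reset_index(drop=True)
    relations = [
        ann.classify_snp_gene_relation(str(s.chrom), int(s.pos), genes)
        for s in sig.itertuples(index=False)
    ]
    sig = sig.assign(
        nearest_gene=[r[0] for r in relations], relation=[r[1] for r in relations]
    )
    cap50 = ann.flank_gene_capture(sig, genes, flank_kb=config.flank_kb_narrow)
    cap500 = ann.flank_gene_capture(sig, genes, flank_kb=config.flank_kb_wide)
    overlap = ann.gwas_deg_overlap(cap500, degs)
    sig.to_csv(outdir / "snp_gene_relations.tsv", sep="\t", index=False)
    cap50.to_csv(outdir / FILES["capture50"], sep="\t", index=False)
    cap500.to_csv(outdir / FILES["capture500"], sep="\t", index=False)
    overlap.to_csv(outdir / FILES["overlap"], sep="\t", index=False)
    return {
        "n_significant_snps": len(sig),
        "n_captured_50kb": int(cap50["gene_id"].nunique()) if len(cap50) else 0,
        "n_captured_500kb": int(cap500["gene_id"].nunique()) if len(cap500) else 0,
        "n_overlap_genes": int(overlap["gene_id"].nunique()) if len(overlap) else 0,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "growth": _stage_growth,
    "rfi": _stage_rfi,
    "varcomp": _stage_varcomp,
    "gwas": _stage_gwas,
    "ld": _stage_ld,
    "deg": _stage_deg,
    "integrate": _stage_integrate,
}
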