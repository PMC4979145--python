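# rfikit

Quantitative-genetics toolkit for **residual feed intake (RFI)** in
poultry: growth-curve-derived feeding traits, Koch-model RFI, REML
heritability and genetic correlations, kinship-adjusted single-marker
GWAS with genomic control and chromosome-wise FDR, D′-confidence
haplotype blocks, RPKM differential expression, and positional
integration of GWAS hits with differentially expressed genes.

It is written for animal-breeding researchers who want a tested,
reusable implementation of this analysis chain, driven by a
synthetic-data generator that plants known truth (QTL effects, breeding
values, fold changes) so every estimator can be validated end to end.

## The model

Feed efficiency is measured as the residual of the Koch expected-intake
regression. Each bird's growth over a 40-day test is fit as
`BW = μ + a·DOT + e` (DOT = day of test, `a` = average daily gain, ADG);
mid-test body weight MBW is the prediction at day 21 and MMBW = MBW^0.75
is its metabolic scaling. With ADFI the mean daily feed intake,

```
ADFI = b0 + b1·MMBW + b2·ADG + RFI
```

so RFI is, by OLS construction, phenotypically independent of body size
and growth. After adjusting for significant pen/sex effects and a
Johnson transformation toward normality, RFI is analysed under the
animal model `y = Xb + Za + e`, `a ~ N(0, K·σ²_A)`, with K a VanRaden
genomic kinship (or pedigree NRM). The GWAS is the two-step mixed-model
scan: null variance components by REML, then a per-SNP GLS Wald test
under `V = K·σ̂²_A + I·σ̂²_E`, genomic-control correction
`λ = median(χ²)/0.4549`, a genome-wide threshold of p < 10⁻⁴, and
chromosome-wise step-up FDR `m·P(i)/i`. Differential expression between
RFI-divergent groups uses `RPKM = 10⁹·C/(N·L)` with calls at
Benjamini–Hochberg q < 0.05 and |log₂FC| ≥ 1.

## Worked example

Run the full pipeline on the shipped desk-scale preset (426 birds, 5,000
SNPs on five chromosomes, 40-day trial, six pens nested in sex, RFI
h² = 0.35):

```bash
rfikit -v all --outdir run1 --seed 1
```

which writes `traits.tsv`, `contrast.tsv`, `varcomp.json`, `assoc.tsv`,
`manhattan.tsv`, `blocks.tsv`, `degs.tsv`, `overlap.tsv` and
`manifest.json` into `run1/`. The manifest for seed 1 ends with:

```
"rfi":      {"p_sex": 0.622, "p_pen": 0.0063, "johnson_family": "SB", ...}
"varcomp":  {"rfi_h2": 0.378, "rg_rfi_adfi": 0.830}
"gwas":     {"lambda_gc": 0.849, "n_significant": 30,
             "addvar_pct_sum": 468.0, "addvar_pct_joint": 55.9}
"ld":       {"n_blocks": 8, "decay_bins": [0.317, 0.244, 0.192, 0.153, 0.123]}
"integrate":{"n_captured_50kb": 7, "n_captured_500kb": 28, "n_overlap_genes": 3}
```

Reading this: the pen effect on RFI is significant (p < 0.01) while sex
is not, so only pen means are subtracted; the cohort heritability
estimate (0.378) brackets the planted 0.35; 30 SNPs pass the 10⁻⁴
threshold and jointly explain ~56 % of the additive variance (the naive
per-SNP sum, 468 %, double-counts SNPs in LD — both numbers are
reported); mean r² decays from 0.32 at short range to 0.12 at
80–100 kb; and 3 of the genes within 500 kb of significant SNPs are
also differentially expressed between high- and low-RFI birds.

Every stage is also a library call — see `rfikit.growth.fit_cohort`,
`rfikit.rfi.fit_koch_rfi`, `rfikit.varcomp.reml_univariate`,
`rfikit.gwas.mixed_model_scan`, `rfikit.ld.gabriel_blocks`,
`rfikit.deg.call_degs`, `rfikit.annotate.flank_gene_capture`.

## Layout

- `src/rfikit/simulate.py` — genotype / phenotype / RNA-seq generators with planted truth
- `src/rfikit/growth.py`, `rfi.py` — growth fits, Koch RFI, Anderson–Darling, Johnson transform
- `src/rfikit/varcomp.py` — kinship matrices, univariate/bivariate REML, BLUP
- `src/rfikit/gwas.py` — QC, mixed-model scan, genomic control, chromosome-wise FDR
- `src/rfikit/ld.py` — two-locus EM, D′ confidence bounds, Gabriel blocks, decay profile
- `src/rfikit/deg.py`, `annotate.py` — RPKM/DEG calling, GFF3 gene models, flank capture
- `src/rfikit/pipeline.py`, `cli.py` — stage orchestration and the `rfikit` command
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
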