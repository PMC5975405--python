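# spermethyl

A toolkit for multi-scale comparison of sperm and somatic-cell DNA
methylomes, built around the analysis designs used to characterize the
pronounced hypomethylation of bull sperm: global CCGG methylation by the
luminometric methylation assay (LUMA), in-silico MspI digestion and
reduced-representation (RR) genome prediction, RRBS differential
methylation at single-CpG resolution, MeDIP-chip promoter-array
enrichment analysis, and a shared downstream layer that isolates
sperm-specific differential units and classifies their direction.

Because the original study's biological samples and multi-gigabase
genomes are not shippable, the package includes a first-class synthetic
data generator that emulates the statistical structure those analyses
assume — a small annotated genome with CpG islands, tandem satellite
arrays and rDNA-like repeats, a latent per-CpG methylome with sperm
hypomethylation planted at satellites, rDNA and germline-gene promoters,
beta-binomial bisulfite counts, dye-swap tiling-array log-ratios and
pyrogram peak signals — so every stage is testable end to end.

## The statistics at the core

**LUMA.** Genomic DNA is cleaved by HpaII (methylation-sensitive) and
MspI (insensitive) in separate reactions, each with EcoRI as an internal
standard. With pyrogram peak signals `CG` (digested CCGG ends) and `AT`
(EcoRI ends),

```
Methylation% = 100 − 100 · mean(CG_HpaII / AT_HpaII) / mean(CG_MspI / AT_MspI)
```

with duplicates averaged per enzyme before the ratio.

**RRBS branch.** MspI cuts C^CGG; fragments with both MspI ends and
genomic length in [40, 290] bp form the RR genome. Per-CpG counts are
filtered to 5–500 reads in every sample (inclusive), categorized as
hypo (<20%), intermediate (20–80%) or hyper (>80%) methylated, and a
CpG is a DMC between two tissues when a two-sided Fisher exact test on
pooled counts survives Benjamini–Hochberg at q ≤ 0.05, the tissue-mean
difference is ≥ 25 points, and all replicates agree in direction.

**MeDIP branch.** A probe is enriched when its dye-swap mean
log2(IP/input) ≥ 1. NEpi — the fraction of promoter *p*'s probes
enriched in sample *i* — feeds clustering and PCA. Regions of interest
are clusters of ≥3 probes enriched in ≥1 sample (one-gap tolerated);
per region, Pr_tissue is the mean fraction of enriched member probes,
and a region is a DMR when a Fisher test on probe-sample enrichment
observations survives BH at q ≤ 0.05 with |ΔPr| ≥ 0.25.

**Specificity layer.** Three pairwise differential sets A (sperm vs
somatic 1), B (sperm vs somatic 2) and C (somatic vs somatic) partition
into 7 Venn territories; sperm-specific units are (A∩B)\C. With
d1 = value(somatic1) − value(sperm) and d2 likewise, units with both
differences positive are hypomethylated in sperm, both negative
hypermethylated, opposite signs discordant.

## Worked example

```
$ spermethyl --seed 7 simulate --outdir fixtures
$ spermethyl luma --signals fixtures/luma.tsv
s1      48.61
s2      46.33
s3      74.98
s4      73.34
```

The four simulated samples were generated at true global methylation of
45.5, 46.0, 74.8 and 75.2% (two sperm-like, two somatic-like); the
printed LUMA percentages recover them within assay noise.

```
$ spermethyl rrbs --counts fixtures/cpg_counts.tsv --samples samples.tsv \
    --pair fibroblast,sperm --pair monocyte,sperm --pair fibroblast,monocyte \
    --out dmcs
{"fibroblast_vs_sperm": 3180, "monocyte_vs_sperm": 3360, "fibroblast_vs_monocyte": 178}
```

Far more CpGs are differential between sperm and either somatic type
than between the two somatic types — the planted sperm signal.

```
$ spermethyl specificity \
    --dm-a dmcs/dmc_fibroblast_vs_sperm.tsv \
    --dm-b dmcs/dmc_monocyte_vs_sperm.tsv \
    --dm-c dmcs/dmc_fibroblast_vs_monocyte.tsv --out specific
{"specific_units": 3066, "hypo_in_sperm": 1.0, "hyper_in_sperm": 0.0, "discordant": 0.0}
```

3066 DMCs are specific to the sperm-vs-somatic comparisons, and all of
them lie in the upper-right corner of the difference plane: less
methylated in sperm than in both somatic cell types.

The same flow works in the library API; see `docs/methods.md` for the
model behind each stage and `tests/` for worked library-level examples.

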