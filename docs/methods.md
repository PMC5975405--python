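# Methods

This note documents the models and procedures implemented in
`spermethyl`, the defaults they use, and the design decisions taken
where a convention was genuinely open.

## Coordinates and formats

All coordinates are 0-based half-open internally. BED is consumed
as-is; GFF (1-based inclusive) is converted at the read boundary. CpG
dyads are keyed by the plus-strand C position; minus-strand count
records are shifted to the dyad position and summed, which maximizes
coverage and matches the dominant bisulfite-pipeline convention. TSV
tables carry explicit schemas (`cpg_counts`, `probe_log2`,
`luma_signals`, `pyro_replicates`) validated on read and write.

## In-silico digestion and the RR genome

MspI recognizes CCGG and cuts after the first C. CCGG is its own
reverse complement, so one forward scan finds all sites; N never
matches. Fragments run between consecutive cuts; contig-end stubs have
only one MspI end and are excluded from the reduced-representation
genome, since a real RRBS fragment requires two ligatable MspI ends.
Size selection is inclusive at both bounds (default 40–290 bp of
genomic insert). Two corollaries of the cut rule are enforced as
invariants: fragments plus stubs tile each contig exactly, and every
retained fragment's sequence starts with `CGG` and ends with `C` — an
intact CCGG can never survive inside a fragment, so the RR summary
counts the flanking sites a fragment overlaps.

## Annotation

Three independent axes, each a total function of the query:

* **Gene context** — promoter-TSS (−1000 to +100 bp of the TSS,
  strand-oriented), TTS (−100 to +1000 bp), exon, intron, intergenic.
  Overlapping categories resolve by the precedence
  promoter-TSS > TTS > exon > intron (HOMER-style); the underlying
  window definitions list categories without stating a precedence, and
  promoter status is the biologically prioritized call.
* **CpG-density context** — CGI, shore (≤2 kb from a CGI), shelve
  (≤2 kb from a shore), open sea. An interval belongs to a class when
  ≥75% of its length overlaps it; the classes are tested CGI-ward
  first. Point queries (single CpG/CCGG sites) use membership — the
  degenerate 75% case at width 1. A query straddling a class boundary
  can satisfy no rule and falls to open sea; this is the literal
  consequence of the per-class 75% rule and is deliberate.
* **Repeat overlap** — the repeat class if ≥1 bp overlaps any repeat,
  whatever the extent; ties resolve to the largest overlap, then
  alphabetically.

Shore and shelve bands are computed from merged CGIs, with overlaps
between bands resolved in favor of the CGI-ward class.

## LUMA

Each reaction's CG signal is normalized by its own EcoRI AT signal;
duplicates are averaged per enzyme *on normalized signals*, then the
HpaII/MspI ratio is taken (the two orders differ only under noise; the
formula's wording — the average signal per enzyme after EcoRI
normalization — fixes this one). Output is clamped to [0, 100]: noise
can push the raw formula slightly outside, and the clamp is documented
rather than silent.

## Resampling statistics

The permutation test uses the difference of means (independent) or the
mean of paired differences (paired), two-sided. When the permutation
space (label splits or sign flips) is no larger than `n_perm` it is
enumerated exhaustively and the p-value is exact; otherwise Monte-Carlo
sampling with the add-one correction p = (b+1)/(B+1), which guarantees
p > 0 and valid type-I control. Constant pooled data yields p = 1, not
an error. Default `n_perm` is 100,000.

The balanced bootstrap draws `balance_to` values with replacement per
group each round (default: the smallest group size) and reports 2.5/97.5
percentile intervals of group means and pairwise differences — the check
that group-size imbalance does not drive observed differences.

The parametric suite applies Welch's t (2 groups) and one-way ANOVA with
Tukey HSD (≥2 groups), plus a compact letter display built by
insert-and-absorb so that groups sharing a letter are not significantly
different at α = 0.05.

Pyrosequencing replicates pass QC when their range is ≤ 5 percentage
points (absolute points, not relative) after discarding at most one
outlier, with at least two replicates remaining; the tolerance applies
to repeat runs by selecting the tightest admissible subset. CpGs with no
passing subset are flagged `needs_repeat` rather than imputed.

## RRBS differential analysis

Coverage strata are inclusive: a CpG with more than 500 reads in any
sample goes to the over-coverage stratum (dominated in practice by
multi-copy sequence); among the rest, differential analysis keeps CpGs
with 5–500 reads in **every** sample. Categories: hypo < 20%,
intermediate 20–80% (both ends included), hyper > 80%. Tissue means
average the replicate percentages; pair differences subtract tissue
means.

DMC criteria are a reconstruction of "stringent" calling — the exact
original thresholds are not published in the main text — and every knob
is exposed in `AnalysisConfig`:

1. two-sided Fisher exact on pooled per-tissue (methylated,
   unmethylated) counts, Benjamini–Hochberg q ≤ 0.05 over the tested
   CpGs;
2. |tissue-mean difference| ≥ 25 percentage points;
3. replicate concordance: every cross-tissue replicate pair difference
   shares the sign of the tissue-mean difference (the strictest natural
   reading of per-replicate agreement; it guards against calls driven
   by a single replicate).

Repeat-consensus summaries average per-CpG percentages *unweighted*
within each repeat × sample × coverage class (5–500 vs >500); empty
classes are reported missing, never zero.

## MeDIP-chip analysis

The probe-level enrichment call, the region rule and the DMR test
reconstruct an array-analysis procedure whose original internals are not
available; all three are configuration-first.

* Enrichment: dye-swap mean log2(IP/input) ≥ 1.0 — the single most
  consequential free parameter.
* NEpi = enriched probes of promoter p in sample i / probes of p.
* Regions of interest: maximal runs of probes enriched in ≥1 sample,
  ≥3 members, at most one consecutive non-enriched probe tolerated
  inside, never spanning promoter tiles; regions start and end on an
  enriched probe.
* DMR: Fisher exact on the 2×2 (enriched, not-enriched) ×
  (tissue A, tissue B) table of probe-sample observations — probes
  within a region are treated as exchangeable, a simplification that
  keeps the test oracle-checkable — with BH q ≤ 0.05 and |ΔPr| ≥ 0.25.

## Specificity layer

Venn territories are exact set operations; sperm-specific units are
(A∩B)\C. Direction classification calls a unit hypomethylated in sperm
only when **both** somatic-minus-sperm differences are strictly
positive; a zero difference is discordant, so ties can never inflate
the headline class (they are vanishingly rare in continuous data).
Correlation clustering is average-linkage on 1 − Pearson distance;
PCA runs on the centered matrix via SVD. The cross-platform
intersection takes CpG dyad plus-strand positions inside any DMR
interval under half-open containment.

## Synthetic data generator

The generator is the package's study-conditions definition, not a
tuning dial. Defaults:

* **Genome** — 2 contigs × 100 kb, 12 genes per contig (1.5–3 kb, 2–4
  exons, random strand), CpG islands over 60% of promoters as ~1 kb
  CpG-rich stretches (CG dinucleotide probability 0.25, giving ~5× the
  background CpG density) spanning the core promoter, two tandem
  satellite arrays per contig, one rDNA-like array (10 × 300 bp
  CpG-rich units with MspI sites at fixed offsets), three LINE and
  three SINE intervals; mildly AT-rich background. Features are placed
  without overlap in seeded random order; all generators are
  byte-deterministic given their seed.
* **Satellite monomer** — a 58 bp CpG- and CCGG-containing tandem unit.
  The monomer length matters: with one MspI site per copy a tandem
  array digests into monomer-length fragments, so the unit must exceed
  the 40 bp size-selection bound for satellites to be visible to the
  RRBS branch at all, as they are in real reduced-representation data
  of satellite-rich genomes. The sequence is configurable.
* **Methylome** — per CpG and cell type (sperm, fibroblast, monocyte,
  liver), μ ~ Beta with mean set by (target class, cell type) and
  concentration 100. Base means: satellite/rDNA 0.85, germline
  promoters 0.75, unmethylated CGI promoters 0.08, methylated CGI
  promoters 0.75, background 0.80. Sperm sits Δ = 40 percentage points
  below somatic at the hypomethylation targets (satellites, rDNA,
  germline promoters — 15% of genes, drawn among CGI-promoter genes).
  Somatic-only effects (monocyte and liver hypomethylated at 3% of
  background CpGs and 8% of CGI genes) and a small
  sperm-hypermethylated promoter class (4% of CGI genes) exist so the
  Venn exclusion and direction proportions are non-trivial.
* **RRBS counts** — negative-binomial totals (mean 60, size 10; the
  CpG-dense regions RRBS enriches are deeply covered in practice), 2%
  of CpGs pushed ~30× deeper to exercise the >500 stratum, binomial
  methylated counts with over- and under-conversion error both 0.005
  (double bisulfite conversion keeps both small); two replicates per
  cell type.
* **MeDIP probes** — promoter windows (TSS −2000/+1360, strand-
  oriented) tiled into 16 probes; probe log-ratio ~ Normal(α·m·c, σ)
  with α = 3, σ = 0.3, m the mean latent methylation over the probe's
  CpGs and c its CpG count scaled by the array maximum; two dye-swap
  replicates; sample layout 4 sperm / 3 fibroblast / 4 liver.
* **LUMA** — signals proportional to total CCGG (MspI) and its
  unmethylated fraction (HpaII), EcoRI-normalized, with unit-mean
  log-normal noise per reaction (CV 0.05) and independent duplicates.

What the generator does **not** emulate: read-level sequencing error
and mapping ambiguity, array spatial artifacts and normalization
internals, copy-number variation, between-individual biological
variability beyond the beta prior, and genome-scale repeat complexity.
Passing tests therefore demonstrate that the pipeline recovers effects
of the planted size and structure under clean mapping — not performance
on real libraries.

## Numerical choices and degenerate inputs

Fisher exact tests use the exact conditional two-sided convention
(summing hypergeometric probabilities no larger than the observed
table's); BH adjustment is applied within each tested family (the CpGs
or regions of one comparison; the feature-distribution table as a
whole). Permutation hit counting uses a 1e-12 slack so ties count as
extreme. Zero-variance inputs raise explicit degenerate-input errors in
the parametric suite and ordination; an empty region list yields an
empty DMR table, not an error. LUMA raises on a zero MspI signal.

## Problem sizes

Tests and the acceptance script run the full pipeline on the 200 kb
default genome (~12,000 CpG dyads, ~4,000 in the RR genome after
coverage filtering, ~380 array probes), 100 random 50 kb contigs for
the digestion oracle, 1,000 null simulations for permutation
calibration and 20 seeded repeats for null control of the callers —
sizes at which every Monte-Carlo criterion has comfortable margin while
a complete run stays in the tens of seconds.

## Known limitations

The DMC/DMR criteria are declared reconstructions; swapping in other
thresholds is a config change, not a code change. The MeDIP DMR test
ignores within-region probe correlation, which makes it anti-
conservative on strongly autocorrelated arrays; the planted-recovery
and null-control checks bound this in the simulated regime only. The
gene-axis precedence and the open-sea fallback for boundary-straddling
queries are conventions, stated above, not universal standards.
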