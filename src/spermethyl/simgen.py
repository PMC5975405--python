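"""Synthetic genomes, methylomes and assay data with planted effects.

The generator emulates the statistical structure the downstream analyses
assume: a small multi-contig genome carrying gene models, CpG islands,
tandem satellite arrays and rDNA-like repeat units; a latent per-CpG,
per-cell-type methylome in which sperm is hypomethylated at satellites,
rDNA and the promoters of "germline" genes; per-CpG bisulfite count
tables with beta-binomial noise; promoter-tiling microarray log-ratios
with dye-swap replicates; and pyrogram peak signals for the global
methylation assay.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .digest_annotate import RRGenome, find_cpg_positions
from .iokit import AnnotationSet, Gene, GenomicInterval, write_bed, write_genome, write_table
from .luma_stats import LumaRun

logger = logging.getLogger("spermethyl")

# 58-bp CpG- and CCGG-containing tandem unit. One MspI site per copy, so
# a tandem array digests into 58-bp fragments that pass the default
# 40-290 bp reduced-representation size window.
DEFAULT_SATELLITE_MONOMER = (
    "GGAATCCGGAATGGAATCGAAAT" "GGAATCGAAATGGAATCGAAATGGAATCGAAATGG"
)

_BASES = np.array(list("ACGT"))
_BG_WEIGHTS = np.array([0.3, 0.2, 0.2, 0.3])  # mildly AT-rich background


class PlacementError(RuntimeError):
    """Features cannot be placed without overlap at the requested density."""


# ---------------------------------------------------------------------------
# Genome generation

def _random_seq(rng: np.random.Generator, length: int, weights: np.ndarray = _BG_WEIGHTS) -> str:
    return "".join(rng.choice(_BASES, size=length, p=weights))


def _cpg_rich_seq(rng: np.random.Generator, length: int, cg_prob: float = 0.25) -> str:
    """CpG-island-like sequence: CG dinucleotides interleaved with random bases."""
    parts: list[str] = []
    n = 0
    while n < length:
        if rng.random() < cg_prob:
            parts.append("CG")
            n += 2
        else:
            parts.append(str(rng.choice(_BASES)))
            n += 1
    return "".join(parts)[:length]


def _rdna_unit(rng: np.random.Generator, length: int = 300) -> str:
    """An rDNA-like repeat unit: GC/CpG-rich with MspI sites at fixed offsets."""
    seq = list(_cpg_rich_seq(rng, length, cg_prob=0.15))
    for off in (10, length // 2):
        seq[off:off + 4] = "CCGG"
    return "".join(seq)


@dataclass
class GenomeParams:
    """Layout of the synthetic genome."""

    n_contigs: int = 2
    contig_len: int = 100_000
    genes_per_contig: int = 12
    cgi_fraction: float = 0.6
    satellite_monomer: str = DEFAULT_SATELLITE_MONOMER
    satellite_copies: int = 100
    satellite_arrays_per_contig: int = 2
    rdna_copies: int = 10
    rdna_unit_len: int = 300
    lines_per_contig: int = 3
    sines_per_contig: int = 3

    def __post_init__(self) -> None:
        if self.contig_len < 10_000:
            raise ValueError("contig_len must be >= 10 kb")
        if "CG" not in self.satellite_monomer or "CCGG" not in self.satellite_monomer:
            raise ValueError("satellite monomer must contain >=1 CpG and >=1 CCGG")


def generate_genome(
    params: GenomeParams | None = None, seed: int = 0
) -> tuple[dict[str, str], AnnotationSet]:
    """Generate a synthetic multi-contig genome with typed annotations.

    Features (gene models with exons, CpG islands over a fraction of
    promoters, tandem satellite arrays, an rDNA-like array, LINE and
    SINE intervals) are placed without overlap along each contig in a
    seeded random order. Deterministic given the seed.
    """
    if params is None:
        params = GenomeParams()
    rng = np.random.default_rng(seed)
    rdna_unit = _rdna_unit(rng, params.rdna_unit_len)
    sat_array = params.satellite_monomer * params.satellite_copies

    genome: dict[str, str] = {}
    genes: list[Gene] = []
    cgis: list[GenomicInterval] = []
    repeats: list[GenomicInterval] = []
    gene_counter = 0

    for ci in range(params.n_contigs):
        contig = f"chr{ci + 1}"
        seq = list(_random_seq(rng, params.contig_len))

        requests: list[str] = (
            ["gene"] * params.genes_per_contig
            + ["satellite"] * params.satellite_arrays_per_contig
            + ["rDNA"]
            + ["LINE"] * params.lines_per_contig
            + ["SINE"] * params.sines_per_contig
        )
        rng.shuffle(requests)

        cursor = 2000
        for kind in requests:
            cursor += int(rng.integers(300, 1500))
            if kind == "gene":
                cursor += 1200  # clearance for the upstream promoter window
                glen = int(rng.integers(1500, 3000))
                _check_fit(cursor, glen + 600, params.contig_len)
                strand = "+" if rng.random() < 0.5 else "-"
                start, end = cursor, cursor + glen
                gene_id = f"gene{gene_counter:03d}"
                gene_counter += 1
                n_exons = int(rng.integers(2, 5))
                breaks = np.sort(rng.choice(np.arange(start + 50, end - 50), size=2 * n_exons - 2, replace=False))
                bounds = [start, *breaks.tolist(), end]
                exons = tuple((int(bounds[i]), int(bounds[i + 1])) for i in range(0, len(bounds) - 1, 2))
                genes.append(Gene(gene_id, contig, start, end, strand, exons))
                if rng.random() < params.cgi_fraction:
                    # CGI spans the core promoter, inside the promoter
                    # annotation window (-1000/+100 around the TSS)
                    tss = start if strand == "+" else end - 1
                    if strand == "+":
                        cs, ce = tss - 900, tss + 101
                    else:
                        cs, ce = tss - 100, tss + 901
                    seq[cs:ce] = list(_cpg_rich_seq(rng, ce - cs))
                    cgis.append(GenomicInterval(contig, cs, ce, ".", f"cgi_{gene_id}"))
                    cursor = end + (1000 if strand == "-" else 0)
                else:
                    cursor = end
            elif kind == "satellite":
                _check_fit(cursor, len(sat_array), params.contig_len)
                seq[cursor:cursor + len(sat_array)] = list(sat_array)
                repeats.append(GenomicInterval(contig, cursor, cursor + len(sat_array), ".", "satellite"))
                cursor += len(sat_array)
            elif kind == "rDNA":
                arr = rdna_unit * params.rdna_copies
                _check_fit(cursor, len(arr), params.contig_len)
                seq[cursor:cursor + len(arr)] = list(arr)
                repeats.append(GenomicInterval(contig, cursor, cursor + len(arr), ".", "rDNA"))
                cursor += len(arr)
            else:  # LINE / SINE: interspersed repeats, background-like sequence
                rlen = 1000 if kind == "LINE" else 200
                _check_fit(cursor, rlen, params.contig_len)
                repeats.append(GenomicInterval(contig, cursor, cursor + rlen, ".", kind))
                cursor += rlen
        genome[contig] = "".join(seq)

    ann = AnnotationSet(genes=genes, cgis=cgis, repeats=repeats)
    logger.info(
        "generated genome: %d contigs, %d genes, %d CGIs, %d repeats",
        len(genome), len(genes), len(cgis), len(repeats),
    )
    return genome, ann


def _check_fit(cursor: int, length: int, contig_len: int) -> None:
    if cursor + length > contig_len - 1000:
        raise PlacementError(
            "features cannot be placed without overlap at the requested density; "
            "increase contig_len or reduce feature counts"
        )


# ---------------------------------------------------------------------------
# Methylome planting

CELL_TYPES = ("sperm", "fibroblast", "monocyte", "liver")
SOMATIC_EFFECT_TISSUES = ("monocyte", "liver")


@dataclass
class PlantSpec:
    """What to plant in the latent methylome.

    ``hypo_targets`` are the feature classes hypomethylated in sperm by
    ``delta`` percentage points relative to somatic cells. Additional
    somatic-only effects (hypomethylation of monocyte and liver at a
    fraction of background CpGs and of methylated CGI promoters) and a
    small sperm-hypermethylated promoter class give the Venn and
    direction logic non-trivial territory.
    """

    cell_types: tuple[str, ...] = CELL_TYPES
    hypo_targets: frozenset = frozenset({"satellite", "rDNA", "germline_promoter"})
    delta: float = 40.0  # percentage points
    germline_fraction: float = 0.15  # of all genes, drawn among CGI-promoter genes
    methylated_cgi_fraction: float = 0.30  # of CGI genes: methylated in every cell type
    somatic_hypo_promoter_fraction: float = 0.08  # of CGI genes: monocyte+liver hypo
    sperm_hyper_promoter_fraction: float = 0.04  # of CGI genes: methylated in sperm only
    somatic_hypo_cpg_fraction: float = 0.03  # of background CpGs: monocyte+liver hypo
    concentration: float = 100.0  # beta prior concentration
    base_means: dict = field(default_factory=lambda: {
        "satellite": 0.85,
        "rDNA": 0.85,
        "germline_promoter": 0.75,
        "cgi_promoter": 0.08,
        "methylated_promoter": 0.75,
        "background": 0.80,
    })

    def __post_init__(self) -> None:
        if not (0 < self.delta <= 100):
            raise ValueError("delta must be in (0, 100]")
        if self.concentration <= 0:
            raise ValueError("beta concentration must be positive")


@dataclass
class Methylome:
    """Latent truth: per-CpG, per-cell-type methylation level mu in [0, 1].

    ``df`` has one row per CpG dyad (plus-strand position) with its
    planted target class and one ``mu_<cell type>`` column per cell
    type; ``germline_genes`` records which genes carry the germline-
    promoter plant.
    """

    df: pd.DataFrame
    cell_types: tuple[str, ...]
    germline_genes: frozenset = frozenset()

    def mu(self, cell_type: str) -> pd.Series:
        return self.df.set_index(["contig", "pos"])[f"mu_{cell_type}"]

    def positions(self, contig: str) -> np.ndarray:
        return self.df.loc[self.df["contig"] == contig, "pos"].to_numpy()


def _promoter_window(gene: Gene) -> tuple[int, int]:
    t = gene.tss
    if gene.strand == "+":
        return t - 1000, t + 101
    return t - 100, t + 1001


def plant_methylome(
    genome: dict[str, str],
    annotations: AnnotationSet,
    spec: PlantSpec | None = None,
    seed: int = 0,
) -> Methylome:
    """Draw a latent methylome with cell-type-specific planted effects.

    Each CpG dyad is assigned a target class from the annotations; mu is
    drawn independently per CpG and per cell type from a beta prior
    whose mean depends on (class, cell type). For classes in
    ``hypo_targets`` the sperm prior mean sits ``delta`` points below
    the somatic mean; non-target classes share one prior across cell
    types.
    """
    if spec is None:
        spec = PlantSpec()
    rng = np.random.default_rng(seed)

    cgi_gene_ids = {iv.label.removeprefix("cgi_") for iv in annotations.cgis}
    cgi_genes = [g.gene_id for g in annotations.genes if g.gene_id in cgi_gene_ids]
    order = list(rng.permutation(cgi_genes))
    n_germ = round(spec.germline_fraction * len(annotations.genes))
    n_meth = round(spec.methylated_cgi_fraction * len(cgi_genes))
    n_shp = round(spec.somatic_hypo_promoter_fraction * len(cgi_genes))
    n_hyper = round(spec.sperm_hyper_promoter_fraction * len(cgi_genes))
    if n_germ + n_meth + n_shp + n_hyper > len(cgi_genes):
        raise ValueError("not enough CGI-promoter genes for the requested plant fractions")
    germline = frozenset(order[:n_germ])
    methylated = set(order[n_germ:n_germ + n_meth])
    somatic_hypo_prom = set(order[n_germ + n_meth:n_germ + n_meth + n_shp])
    sperm_hyper_prom = set(order[n_germ + n_meth + n_shp:n_germ + n_meth + n_shp + n_hyper])

    class_windows: dict[str, list[tuple[int, int, str]]] = {c: [] for c in genome}
    for rep in annotations.repeats:
        if rep.label in ("satellite", "rDNA"):
            class_windows[rep.contig].append((rep.start, rep.end, rep.label))
    for g in annotations.genes:
        if g.gene_id not in cgi_gene_ids:
            continue
        s, e = _promoter_window(g)
        if g.gene_id in germline:
            cls = "germline_promoter"
        elif g.gene_id in methylated:
            cls = "methylated_promoter"
        elif g.gene_id in somatic_hypo_prom:
            cls = "somatic_hypo_promoter"
        elif g.gene_id in sperm_hyper_prom:
            cls = "sperm_hyper_promoter"
        else:
            cls = "cgi_promoter"
        class_windows[g.contig].append((s, e, cls))

    rows = []
    for contig, seq in genome.items():
        pos = find_cpg_positions(seq)
        cls = np.full(len(pos), "background", dtype=object)
        for s, e, label in class_windows[contig]:
            cls[(pos >= s) & (pos < e)] = label
        rows.append(pd.DataFrame({"contig": contig, "pos": pos, "target": cls}))
    df = pd.concat(rows, ignore_index=True)

    bg = df.index[df["target"] == "background"].to_numpy()
    n_shc = round(spec.somatic_hypo_cpg_fraction * len(bg))
    somatic_idx = rng.choice(bg, size=n_shc, replace=False)
    df.loc[somatic_idx, "target"] = "somatic_hypo_cpg"

    d = spec.delta / 100.0
    kappa = spec.concentration
    bm = spec.base_means
    for ct in spec.cell_types:
        means = np.empty(len(df))
        for cls in df["target"].unique():
            mask = (df["target"] == cls).to_numpy()
            if cls in spec.hypo_targets:
                base = bm[cls]
                m = base - d if ct == "sperm" else base
            elif cls == "somatic_hypo_promoter":
                base = bm["methylated_promoter"]
                m = base - d if ct in SOMATIC_EFFECT_TISSUES else base
            elif cls == "somatic_hypo_cpg":
                base = bm["background"]
                m = base - d if ct in SOMATIC_EFFECT_TISSUES else base
            elif cls == "sperm_hyper_promoter":
                m = bm["methylated_promoter"] if ct == "sperm" else bm["cgi_promoter"]
            else:
                m = bm[cls]
            means[mask] = np.clip(m, 0.01, 0.99)
        df[f"mu_{ct}"] = rng.beta(means * kappa, (1.0 - means) * kappa)

    logger.info("planted methylome: %d CpGs, classes %s", len(df), df["target"].value_counts().to_dict())
    return Methylome(df=df, cell_types=spec.cell_types, germline_genes=germline)


# ---------------------------------------------------------------------------
# RRBS count simulation

def simulate_rrbs_counts(
    methylome: Methylome,
    rr_genome: RRGenome,
    cell_types: tuple[str, ...] = ("sperm", "fibroblast", "monocyte"),
    samples_per_type: int = 2,
    coverage_mean: float = 60.0,
    coverage_dispersion: float = 10.0,
    conversion_error: float = 0.005,
    underconversion_error: float = 0.005,
    over_max_fraction: float = 0.02,
    over_max_multiplier: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-CpG bisulfite count table over the RR genome.

    Only CpGs inside retained reduced-representation fragments receive
    coverage. Totals are negative-binomial (mean ``coverage_mean``,
    size ``coverage_dispersion``); a fraction of CpGs is pushed to
    ``over_max_multiplier`` times the mean coverage to exercise the
    over-coverage stratum. Methylated counts are binomial with success
    probability mu*(1-e) + (1-mu)*e_inv, where e is the over-conversion
    and e_inv the under-conversion error rate.
    """
    if coverage_mean < 1:
        raise ValueError("coverage mean must be >= 1")
    for eps in (conversion_error, underconversion_error):
        if not (0 <= eps <= 0.05):
            raise ValueError("conversion error rates must be in [0, 0.05]")
    if not rr_genome.fragments:
        raise ValueError("empty reduced-representation genome")
    rng = np.random.default_rng(seed)

    rr_keys = {
        (contig, int(p))
        for contig, arr in rr_genome.cpg_positions.items()
        for p in arr
    }
    mask = [
        (c, int(p)) in rr_keys
        for c, p in zip(methylome.df["contig"], methylome.df["pos"])
    ]
    sub = methylome.df.loc[mask].reset_index(drop=True)
    n = len(sub)
    if n == 0:
        raise ValueError("no methylome CpGs fall inside the RR genome")

    deep = rng.random(n) < over_max_fraction
    nb_p = coverage_dispersion / (coverage_dispersion + coverage_mean)
    frames = []
    for ct in cell_types:
        mu = sub[f"mu_{ct}"].to_numpy()
        p_meth = mu * (1 - conversion_error) + (1 - mu) * underconversion_error
        for rep in range(samples_per_type):
            total = rng.negative_binomial(coverage_dispersion, nb_p, size=n)
            total = np.where(deep, np.maximum(1, (total * over_max_multiplier).astype(int)), total)
            covered = total > 0
            meth = np.zeros(n, dtype=int)
            meth[covered] = rng.binomial(total[covered], p_meth[covered])
            frames.append(pd.DataFrame({
                "contig": sub["contig"][covered].to_numpy(),
                "pos": sub["pos"][covered].to_numpy(),
                "strand": "+",
                "sample": f"{ct}_{rep + 1}",
                "meth": meth[covered],
                "total": total[covered],
            }))
    out = pd.concat(frames, ignore_index=True)
    logger.info("simulated RRBS counts: %d rows over %d CpGs", len(out), n)
    return out


def rrbs_sample_map(
    cell_types: tuple[str, ...] = ("sperm", "fibroblast", "monocyte"),
    samples_per_type: int = 2,
) -> dict[str, str]:
    return {f"{ct}_{i + 1}": ct for ct in cell_types for i in range(samples_per_type)}


# ---------------------------------------------------------------------------
# MeDIP-chip probe simulation

MEDIP_SAMPLES_DEFAULT = {"sperm": 4, "fibroblast": 3, "liver": 4}
PROMOTER_TILE_UP, PROMOTER_TILE_DOWN = 2000, 1360  # tiled window around the TSS


def simulate_medip_probes(
    methylome: Methylome,
    annotations: AnnotationSet,
    samples_per_type: dict[str, int] | None = None,
    probes_per_promoter: int = 16,
    alpha: float = 3.0,
    sigma: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate promoter-tiling MeDIP log2(IP/input) ratios with dye swaps.

    Each promoter window (TSS -2000 to +1360, strand-oriented) is tiled
    into ``probes_per_promoter`` probes. A probe's expected log-ratio is
    alpha * m_p * c_p where m_p is the mean latent methylation over the
    CpGs in the probe window and c_p its CpG count scaled to [0, 1] by
    the array-wide maximum; Gaussian noise of sd ``sigma`` is added
    independently to each of the two dye-swap replicates per sample.
    Probes carry a CpG-frequency class (high/intermediate/low tercile).
    """
    if probes_per_promoter < 3:
        raise ValueError("probes_per_promoter must be >= 3")
    if samples_per_type is None:
        samples_per_type = dict(MEDIP_SAMPLES_DEFAULT)
    rng = np.random.default_rng(seed)

    mu_by_ct = {
        ct: methylome.mu(ct) for ct in samples_per_type
    }
    by_contig = {
        contig: grp.set_index("pos") for contig, grp in methylome.df.groupby("contig")
    }

    probes = []
    for g in annotations.genes:
        t = g.tss
        if g.strand == "+":
            w_start, w_end = t - PROMOTER_TILE_UP, t + PROMOTER_TILE_DOWN
        else:
            w_start, w_end = t - PROMOTER_TILE_DOWN, t + PROMOTER_TILE_UP
        w_start = max(0, w_start)
        edges = np.linspace(w_start, w_end, probes_per_promoter + 1).astype(int)
        contig_df = by_contig.get(g.contig)
        for k in range(probes_per_promoter):
            s, e = int(edges[k]), int(edges[k + 1])
            if contig_df is None:
                cpg_pos = np.array([], dtype=int)
            else:
                cpg_pos = contig_df.index.to_numpy()
                cpg_pos = cpg_pos[(cpg_pos >= s) & (cpg_pos < e)]
            probes.append({
                "probe_id": f"{g.gene_id}_p{k:02d}",
                "contig": g.contig,
                "start": s,
                "end": e,
                "promoter_id": g.gene_id,
                "cpg_count": len(cpg_pos),
                "_cpgs": cpg_pos,
            })
    pdf = pd.DataFrame(probes)
    cmax = max(1, int(pdf["cpg_count"].max()))
    pdf["c_scaled"] = pdf["cpg_count"] / cmax
    lo, hi = np.quantile(pdf["cpg_count"], [1 / 3, 2 / 3])
    pdf["cpg_class"] = np.where(
        pdf["cpg_count"] <= lo, "low", np.where(pdf["cpg_count"] <= hi, "intermediate", "high")
    )

    rows = []
    for ct, n_samp in samples_per_type.items():
        mu = mu_by_ct[ct]
        m_p = np.array([
            float(mu.loc[[(c, int(p)) for p in cp]].mean()) if len(cp) else 0.0
            for c, cp in zip(pdf["contig"], pdf["_cpgs"])
        ])
        expected = alpha * m_p * pdf["c_scaled"].to_numpy()
        for i in range(n_samp):
            for rep in ("dye1", "dye2"):
                noise = rng.normal(0.0, sigma, size=len(pdf))
                rows.append(pd.DataFrame({
                    "probe_id": pdf["probe_id"],
                    "contig": pdf["contig"],
                    "start": pdf["start"],
                    "end": pdf["end"],
                    "promoter_id": pdf["promoter_id"],
                    "cpg_class": pdf["cpg_class"],
                    "sample": f"{ct}_{i + 1}",
                    "replicate": rep,
                    "log2_ratio": expected + noise,
                }))
    out = pd.concat(rows, ignore_index=True)
    logger.info("simulated MeDIP probes: %d probes x %d sample-replicates",
                len(pdf), sum(samples_per_type.values()) * 2)
    return out


def medip_sample_map(samples_per_type: dict[str, int] | None = None) -> dict[str, str]:
    if samples_per_type is None:
        samples_per_type = dict(MEDIP_SAMPLES_DEFAULT)
    return {f"{ct}_{i + 1}": ct for ct, n in samples_per_type.items() for i in range(n)}


# ---------------------------------------------------------------------------
# LUMA and pyrosequencing simulation

def simulate_luma_run(
    global_methylation: float,
    total_ccgg: float = 1000.0,
    eco_signal: float = 100.0,
    noise_cv: float = 0.05,
    duplicates: int = 2,
    seed: int = 0,
) -> LumaRun:
    """Simulate pyrogram peak signals for one LUMA sample.

    The MspI-reaction CG signal is proportional to the total CCGG
    content, the HpaII-reaction CG signal to its unmethylated fraction
    (1 - g/100); AT signals come from the shared EcoRI normalizer.
    Multiplicative log-normal noise (unit mean, coefficient of variation
    ``noise_cv``) is applied independently per reaction and duplicate.
    """
    g = global_methylation
    if not (0 <= g <= 100):
        raise ValueError("global methylation must be in [0, 100]")
    if not (0 <= noise_cv < 0.2):
        raise ValueError("noise_cv must be in [0, 0.2)")
    rng = np.random.default_rng(seed)

    def _noisy(value: float, size: int) -> np.ndarray:
        if noise_cv == 0:
            return np.full(size, value)
        sig = np.sqrt(np.log1p(noise_cv**2))
        return value * rng.lognormal(-sig**2 / 2, sig, size=size)

    scale = 0.5  # luminescence units per digested site
    return LumaRun(
        hpaii_cg=_noisy(scale * total_ccgg * (1 - g / 100.0), duplicates),
        hpaii_at=_noisy(eco_signal, duplicates),
        mspi_cg=_noisy(scale * total_ccgg, duplicates),
        mspi_at=_noisy(eco_signal, duplicates),
    )


def simulate_pyro_assay(
    true_percents: dict[str, float],
    replicates: int = 2,
    noise_sd: float = 1.5,
    seed: int = 0,
) -> dict[str, list[float]]:
    """Simulate replicate bisulfite-pyrosequencing percentages per CpG."""
    rng = np.random.default_rng(seed)
    return {
        cpg: list(np.clip(rng.normal(p, noise_sd, size=replicates), 0.0, 100.0))
        for cpg, p in true_percents.items()
    }


# ---------------------------------------------------------------------------
# Fixture writing

def write_fixtures(
    outdir: str | Path,
    genome_params: GenomeParams | None = None,
    plant_spec: PlantSpec | None = None,
    seed: int = 0,
    rr_min_len: int = 40,
    rr_max_len: int = 290,
) -> dict[str, Path]:
    """Generate one full synthetic study and write every fixture file."""
    from .digest_annotate import build_rr_genome

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, ann = generate_genome(genome_params, seed=seed)
    methylome = plant_methylome(genome, ann, plant_spec, seed=seed + 1)
    rr = build_rr_genome(genome, min_len=rr_min_len, max_len=rr_max_len)
    counts = simulate_rrbs_counts(methylome, rr, seed=seed + 2)
    probes = simulate_medip_probes(methylome, ann, seed=seed + 3)

    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_genome(genome, paths["genome"])

    paths["genes"] = outdir / "genes.bed"
    write_bed(
        [GenomicInterval(g.contig, g.start, g.end, g.strand, g.gene_id) for g in ann.genes],
        paths["genes"],
    )
    paths["exons"] = outdir / "exons.bed"
    write_bed(
        [GenomicInterval(g.contig, s, e, g.strand, g.gene_id) for g in ann.genes for s, e in g.exons],
        paths["exons"],
    )
    paths["cgi"] = outdir / "cgi.bed"
    write_bed(ann.cgis, paths["cgi"])
    paths["repeats"] = outdir / "repeats.bed"
    write_bed(ann.repeats, paths["repeats"])

    paths["methylome"] = outdir / "methylome.tsv"
    methylome.df.to_csv(paths["methylome"], sep="\t", index=False)

    paths["cpg_counts"] = outdir / "cpg_counts.tsv"
    write_table(counts, paths["cpg_counts"], schema="cpg_counts")

    paths["probes"] = outdir / "probes.tsv"
    write_table(probes, paths["probes"], schema="probe_log2")

    rng = np.random.default_rng(seed + 4)
    luma_rows = []
    for i, g in enumerate([45.5, 46.0, 74.8, 75.2]):
        run = simulate_luma_run(g, seed=int(rng.integers(2**31)))
        for rep in range(len(run.hpaii_cg)):
            luma_rows.append({
                "sample": f"s{i + 1}", "replicate": rep + 1,
                "hpaii_cg": run.hpaii_cg[rep], "hpaii_at": run.hpaii_at[rep],
                "mspi_cg": run.mspi_cg[rep], "mspi_at": run.mspi_at[rep],
            })
    paths["luma"] = outdir / "luma.tsv"
    write_table(pd.DataFrame(luma_rows), paths["luma"], schema="luma_signals")

    pyro = simulate_pyro_assay({f"cpg{i}": p for i, p in enumerate([10.0, 45.0, 90.0])},
                               seed=seed + 5)
    pyro_rows = [
        {"cpg_id": cpg, "replicate": r + 1, "percent": v}
        for cpg, vals in pyro.items() for r, v in enumerate(vals)
    ]
    paths["pyro"] = outdir / "pyro.tsv"
    write_table(pd.DataFrame(pyro_rows), paths["pyro"], schema="pyro_replicates")
    return paths
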