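"""File formats, configuration and shared domain types.

All coordinates inside the package are 0-based half-open. BED files are
consumed as-is; GFF (1-based, inclusive) is converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("spermethyl")

VALID_STRANDS = {"+", "-", "."}
_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """A file does not conform to its declared format or schema."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


REPEAT_CLASSES = {"satellite", "rDNA", "LINE", "SINE", "other"}


@dataclass(frozen=True)
class Gene:
    """A gene model: span plus exon intervals, 0-based half-open."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene span for {self.gene_id}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside gene span")

    @property
    def tss(self) -> int:
        """Transcription start position (strand-aware, 0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination position (strand-aware, 0-based)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class AnnotationSet:
    """Typed feature intervals: gene models, CpG islands and repeats."""

    genes: list[Gene] = field(default_factory=list)
    cgis: list[GenomicInterval] = field(default_factory=list)
    repeats: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rep in self.repeats:
            if rep.label not in REPEAT_CLASSES:
                raise ValueError(
                    f"repeat class {rep.label!r} not in {sorted(REPEAT_CLASSES)}"
                )


@dataclass
class AnalysisConfig:
    """Pipeline-wide tunable parameters.

    Defaults follow the study design this package models: a 40–290 bp
    reduced-representation size window, the 5–500 read coverage stratum,
    <20% / >80% hypo/hyper methylation categories, and 100,000
    Monte-Carlo permutations.
    """

    rr_min_len: int = 40
    rr_max_len: int = 290
    cov_min: int = 5
    cov_max: int = 500
    hypo_cut: float = 20.0
    hyper_cut: float = 80.0
    n_perm: int = 100_000
    dmc_min_diff: float = 25.0
    q_cut: float = 0.05
    enrichment_log2_cut: float = 1.0
    roi_min_probes: int = 3
    roi_max_gap: int = 1
    pr_min_diff: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rr_min_len < self.rr_max_len:
            raise ValueError("rr_min_len must be < rr_max_len")
        if self.cov_min < 1 or self.cov_min > self.cov_max:
            raise ValueError("need 1 <= cov_min <= cov_max")
        if not (0 < self.hypo_cut < self.hyper_cut < 100):
            raise ValueError("need 0 < hypo_cut < hyper_cut < 100")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.q_cut <= 1):
            raise ValueError("q_cut must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, fh)


# ---------------------------------------------------------------------------
# FASTA

def load_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a dict of uppercased contig sequences."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genome: dict[str, str] = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    if not records:
        raise FormatError(f"empty or headerless FASTA: {path}")
    for i, rec in enumerate(records):
        if not rec.id:
            raise FormatError(f"record {i + 1} in {path} has an empty header")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"record {rec.id!r} in {path} has an empty sequence")
        bad = set(seq) - _ALPHABET
        if bad:
            raise FormatError(f"record {rec.id!r} contains invalid characters {sorted(bad)}")
        if rec.id in genome:
            raise FormatError(f"duplicate contig name {rec.id!r} in {path}")
        genome[rec.id] = seq
    logger.info("loaded %d contigs (%d bp) from %s", len(genome), sum(map(len, genome.values())), path)
    return genome


def write_genome(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED / GFF

def read_bed(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: BED record {i + 1} has fewer than 3 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "."
            try:
                out.append(GenomicInterval(contig, start, end, strand, label))
            except ValueError as exc:
                raise FormatError(f"{path}: BED record {i + 1}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t{iv.strand}\n")


def read_gff(path: str | Path) -> list[GenomicInterval]:
    """Read GFF3/GTF intervals, converting 1-based inclusive to 0-based half-open."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise FormatError(f"{path}: GFF record {i + 1} has fewer than 8 columns")
            contig, _, ftype, start1, end1 = parts[:5]
            strand = parts[6] if parts[6] in VALID_STRANDS else "."
            start, end = int(start1) - 1, int(end1)
            try:
                out.append(GenomicInterval(contig, start, end, strand, ftype))
            except ValueError as exc:
                raise FormatError(f"{path}: GFF record {i + 1}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# TSV schemas

TABLE_SCHEMAS: dict[str, dict[str, type]] = {
    "cpg_counts": {"contig": str, "pos": int, "strand": str, "sample": str, "meth": int, "total": int},
    "probe_log2": {
        "probe_id": str, "contig": str, "start": int, "end": int, "promoter_id": str,
        "cpg_class": str, "sample": str, "replicate": str, "log2_ratio": float,
    },
    "luma_signals": {
        "sample": str, "replicate": int,
        "hpaii_cg": float, "hpaii_at": float, "mspi_cg": float, "mspi_at": float,
    },
    "pyro_replicates": {"cpg_id": str, "replicate": int, "percent": float},
}

# columns a schema tolerates being absent (filled with a default)
_OPTIONAL: dict[str, dict[str, object]] = {"cpg_counts": {"strand": "+"}}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(TABLE_SCHEMAS)}")
    spec = TABLE_SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t")
    optional = _OPTIONAL.get(schema, {})
    for col, default in optional.items():
        if col not in df.columns:
            df[col] = default
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: schema {schema!r} missing required column(s) {missing}")
    df = df[list(spec)].astype(spec)
    _validate_table(df, schema, str(path))
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> None:
    if schema is not None:
        spec = TABLE_SCHEMAS[schema]
        missing = [c for c in spec if c not in df.columns]
        if missing:
            raise FormatError(f"schema {schema!r} missing column(s) {missing}")
        df = df[list(spec)]
        _validate_table(df, schema, str(path))
    df.to_csv(path, sep="\t", index=False)


def _validate_table(df: pd.DataFrame, schema: str, where: str) -> None:
    if schema == "cpg_counts":
        bad = df.index[(df["meth"] < 0) | (df["total"] < df["meth"])]
        if len(bad):
            raise FormatError(f"{where}: methylated count exceeds total at row(s) {list(bad[:5])}")
        if not df["strand"].isin({"+", "-"}).all():
            raise FormatError(f"{where}: cpg_counts strand must be '+' or '-'")
    elif schema == "luma_signals":
        if (df[["hpaii_cg", "hpaii_at", "mspi_cg", "mspi_at"]] < 0).any().any():
            raise FormatError(f"{where}: negative pyrogram signal")
        if (df[["hpaii_at", "mspi_at"]] <= 0).any().any():
            raise FormatError(f"{where}: EcoRI normalizer (AT) signal must be positive")
    elif schema == "pyro_replicates":
        if ((df["percent"] < 0) | (df["percent"] > 100)).any():
            raise FormatError(f"{where}: pyro percent outside [0, 100]")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(level=getattr(logging, level.upper()),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
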