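"""In-silico MspI digestion, reduced-representation genomes and annotation.

MspI recognizes CCGG and cuts after the first C (C^CGG). An in-silico
digest of a genome therefore yields fragments bounded by cut positions
``site_start + 1``; retaining internal fragments within a size window
(default 40-290 bp) gives the reduced-representation (RR) genome — the
set of regions a reduced-representation bisulfite library can observe.

Annotation assigns each query (a point site or an interval) one label on
each of three independent axes:

* gene context — promoter-TSS (−1000 to +100 bp around the TSS), TTS
  (−100 to +1000 bp), exon, intron or intergenic, with precedence in
  that order;
* CpG-density context — CGI, shore (up to 2 kb from a CGI), shelve
  (up to 2 kb from a shore) or open sea; interval queries belong to a
  class when at least 75% of their length overlaps it, point queries by
  membership;
* repeat overlap — the repeat class if the query overlaps a repeat by
  at least one base, whatever the extent of the overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .iokit import AnnotationSet, GenomicInterval

logger = logging.getLogger("spermethyl")

MSPI_MOTIF = "CCGG"
MSPI_CUT_OFFSET = 1  # C^CGG

PROMOTER_UP, PROMOTER_DOWN = 1000, 100  # bp upstream / downstream of TSS
TTS_UP, TTS_DOWN = 100, 1000  # bp upstream / downstream of TTS
SHORE_BP = 2000
SHELVE_BP = 2000
CGI_OVERLAP_FRACTION = 0.75

GENE_CONTEXTS = ["promoter-TSS", "TTS", "exon", "intron", "intergenic"]
CGI_CONTEXTS = ["CGI", "shore", "shelve", "open_sea"]


# ---------------------------------------------------------------------------
# Site scanning and digestion

def find_motif_sites(genome: dict[str, str], motif: str = MSPI_MOTIF) -> dict[str, np.ndarray]:
    """Start positions of all exact occurrences of ``motif`` per contig.

    CCGG is its own reverse complement, so a single forward-strand scan
    covers both strands. N never matches.
    """
    sites: dict[str, np.ndarray] = {}
    for name, seq in genome.items():
        hits = []
        i = seq.find(motif)
        while i != -1:
            hits.append(i)
            i = seq.find(motif, i + 1)
        sites[name] = np.asarray(hits, dtype=np.int64)
    return sites


def find_ccgg_sites(genome: dict[str, str]) -> dict[str, np.ndarray]:
    """Coordinates of all CCGG sites (MspI/HpaII recognition sites)."""
    return find_motif_sites(genome, MSPI_MOTIF)


@dataclass(frozen=True)
class Fragment:
    """A digestion fragment; terminal stubs lack one MspI end."""

    contig: str
    start: int
    end: int
    terminal: bool = False

    def __len__(self) -> int:
        return self.end - self.start


def digest_mspi(genome: dict[str, str], sites: dict[str, np.ndarray] | None = None) -> list[Fragment]:
    """In-silico MspI digest: fragments between consecutive C^CGG cuts.

    Internal fragments run between two cuts; the stubs before the first
    and after the last cut are flagged ``terminal``. Fragments and stubs
    tile each contig exactly.
    """
    if sites is None:
        sites = find_ccgg_sites(genome)
    frags: list[Fragment] = []
    for name, seq in genome.items():
        cuts = sites.get(name, np.array([], dtype=np.int64)) + MSPI_CUT_OFFSET
        length = len(seq)
        if cuts.size == 0:
            frags.append(Fragment(name, 0, length, terminal=True))
            continue
        frags.append(Fragment(name, 0, int(cuts[0]), terminal=True))
        for a, b in zip(cuts[:-1], cuts[1:]):
            frags.append(Fragment(name, int(a), int(b)))
        frags.append(Fragment(name, int(cuts[-1]), length, terminal=True))
    return frags


def find_cpg_positions(seq: str, offset: int = 0) -> np.ndarray:
    """Positions of CpG dyads (the C of each CG) in ``seq``, shifted by ``offset``."""
    hits = []
    i = seq.find("CG")
    while i != -1:
        hits.append(i + offset)
        i = seq.find("CG", i + 1)
    return np.asarray(hits, dtype=np.int64)


@dataclass
class RRGenome:
    """Reduced-representation genome: size-selected internal MspI fragments."""

    fragments: list[Fragment]
    min_len: int
    max_len: int
    cpg_positions: dict[str, np.ndarray] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def contains(self, contig: str, pos: int) -> bool:
        arr = self._starts_ends.get(contig)
        if arr is None:
            return False
        starts, ends = arr
        j = np.searchsorted(starts, pos, side="right") - 1
        return j >= 0 and pos < ends[j]

    @property
    def _starts_ends(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if not hasattr(self, "_se_cache"):
            cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            by_contig: dict[str, list[Fragment]] = {}
            for f in self.fragments:
                by_contig.setdefault(f.contig, []).append(f)
            for contig, fl in by_contig.items():
                fl.sort(key=lambda f: f.start)
                cache[contig] = (
                    np.array([f.start for f in fl]),
                    np.array([f.end for f in fl]),
                )
            self._se_cache = cache
        return self._se_cache


def build_rr_genome(
    genome: dict[str, str],
    fragments: list[Fragment] | None = None,
    min_len: int = 40,
    max_len: int = 290,
    annotations: AnnotationSet | None = None,
) -> RRGenome:
    """Size-select internal MspI fragments into a reduced-representation genome.

    Bounds are inclusive: a fragment is retained when
    ``min_len <= length <= max_len``. Terminal stubs (one MspI end only)
    are never retained. The summary reports fragment count, genome
    fraction covered, CpG and CCGG counts inside the RR genome and, when
    annotations are supplied, per-feature CpG coverage.
    """
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    if fragments is None:
        fragments = digest_mspi(genome)
    kept = [f for f in fragments if not f.terminal and min_len <= len(f) <= max_len]

    cpgs: dict[str, list[int]] = {}
    # a retained fragment never contains an intact CCGG (internal sites
    # would have been cut); count the flanking sites it overlaps instead
    ccgg_sites: set[tuple[str, int]] = set()
    for f in kept:
        seq = genome[f.contig][f.start:f.end]
        cpgs.setdefault(f.contig, []).extend(find_cpg_positions(seq, f.start).tolist())
        ccgg_sites.add((f.contig, f.start - MSPI_CUT_OFFSET))
        ccgg_sites.add((f.contig, f.end - MSPI_CUT_OFFSET))
    n_ccgg = len(ccgg_sites)
    cpg_positions = {c: np.asarray(sorted(v), dtype=np.int64) for c, v in cpgs.items()}

    genome_len = sum(len(s) for s in genome.values())
    covered = sum(len(f) for f in kept)
    summary = {
        "n_fragments": len(kept),
        "bp_covered": covered,
        "genome_fraction": covered / genome_len if genome_len else 0.0,
        "n_cpg": int(sum(len(v) for v in cpg_positions.values())),
        "n_ccgg": n_ccgg,
    }
    if annotations is not None:
        queries = [
            GenomicInterval(c, int(p), int(p) + 1)
            for c, arr in cpg_positions.items() for p in arr
        ]
        if queries:
            ann = annotate_intervals(queries, annotations)
            summary["cpg_gene_context"] = ann["gene_context"].value_counts().to_dict()
            summary["cpg_cgi_context"] = ann["cgi_context"].value_counts().to_dict()
            summary["cpg_repeat_overlap"] = ann["repeat_overlap"].value_counts().to_dict()
    logger.info(
        "RR genome [%d,%d]: %d fragments, %.1f%% of genome, %d CpGs",
        min_len, max_len, summary["n_fragments"], 100 * summary["genome_fraction"], summary["n_cpg"],
    )
    return RRGenome(kept, min_len, max_len, cpg_positions, summary)


# ---------------------------------------------------------------------------
# Annotation

def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


class _Annotator:
    """Precomputed interval indexes over one AnnotationSet."""

    def __init__(self, ann: AnnotationSet):
        self.gene_trees: dict[str, dict[str, IntervalTree]] = {}
        for axis in ("promoter", "tts", "exon", "gene"):
            self.gene_trees[axis] = {}

        def _add(axis: str, contig: str, s: int, e: int) -> None:
            if s < e:
                self.gene_trees[axis].setdefault(contig, IntervalTree()).addi(s, e)

        for g in ann.genes:
            t = g.tss
            if g.strand == "+":
                _add("promoter", g.contig, t - PROMOTER_UP, t + PROMOTER_DOWN + 1)
            else:
                _add("promoter", g.contig, t - PROMOTER_DOWN, t + PROMOTER_UP + 1)
            tt = g.tts
            if g.strand == "+":
                _add("tts", g.contig, tt - TTS_UP, tt + TTS_DOWN + 1)
            else:
                _add("tts", g.contig, tt - TTS_DOWN, tt + TTS_UP + 1)
            for s, e in g.exons:
                _add("exon", g.contig, s, e)
            _add("gene", g.contig, g.start, g.end)

        # CGI / shore / shelve bands from merged CGIs; overlaps between
        # bands resolve in favor of the CGI-ward class.
        cgi_by_contig: dict[str, list[tuple[int, int]]] = {}
        for iv in ann.cgis:
            cgi_by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
        self.cgi_bands: dict[str, dict[str, list[tuple[int, int]]]] = {}
        for contig, ivs in cgi_by_contig.items():
            cgi = _merge(ivs)
            shore_raw = _merge(
                [(max(0, s - SHORE_BP), s) for s, e in cgi] + [(e, e + SHORE_BP) for s, e in cgi]
            )
            shore = _subtract(shore_raw, cgi)
            shelve_raw = _merge(
                [(max(0, s - SHELVE_BP), s) for s, e in shore] + [(e, e + SHELVE_BP) for s, e in shore]
            )
            shelve = _subtract(_subtract(shelve_raw, cgi), shore)
            self.cgi_bands[contig] = {"CGI": cgi, "shore": shore, "shelve": shelve}

        self.repeat_trees: dict[str, IntervalTree] = {}
        for iv in ann.repeats:
            self.repeat_trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end, iv.label)

    # -- per-query labels --------------------------------------------------
    def gene_context(self, q: GenomicInterval) -> str:
        for axis, label in (("promoter", "promoter-TSS"), ("tts", "TTS"), ("exon", "exon")):
            tree = self.gene_trees[axis].get(q.contig)
            if tree is not None and tree.overlap(q.start, q.end):
                return label
        tree = self.gene_trees["gene"].get(q.contig)
        if tree is not None and tree.overlap(q.start, q.end):
            return "intron"
        return "intergenic"

    def cgi_context(self, q: GenomicInterval) -> str:
        bands = self.cgi_bands.get(q.contig)
        if bands is None:
            return "open_sea"
        qlen = len(q)
        for label in ("CGI", "shore", "shelve"):
            ov = _overlap_total(bands[label], q.start, q.end)
            if qlen == 1:
                if ov > 0:
                    return label
            elif ov >= CGI_OVERLAP_FRACTION * qlen:
                return label
        return "open_sea"

    def repeat_overlap(self, q: GenomicInterval) -> str:
        tree = self.repeat_trees.get(q.contig)
        if tree is None:
            return "none"
        hits = tree.overlap(q.start, q.end)
        if not hits:
            return "none"
        # deterministic tie-break: largest overlap, then class name
        best = max(
            hits,
            key=lambda h: (min(h.end, q.end) - max(h.begin, q.start), h.data),
        )
        return best.data


def _subtract(intervals: list[tuple[int, int]], minus: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set-difference of merged, sorted interval lists."""
    out: list[tuple[int, int]] = []
    for s, e in intervals:
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def _overlap_total(intervals: list[tuple[int, int]], start: int, end: int) -> int:
    total = 0
    for s, e in intervals:
        if e <= start:
            continue
        if s >= end:
            break
        total += min(e, end) - max(s, start)
    return total


def annotate_intervals(
    queries: list[GenomicInterval],
    annotations: AnnotationSet,
    known_contigs: set[str] | None = None,
) -> pd.DataFrame:
    """Assign each query one label per annotation axis.

    Returns a DataFrame indexed like ``queries`` with columns
    ``gene_context``, ``cgi_context`` and ``repeat_overlap``.
    """
    if known_contigs is not None:
        for q in queries:
            if q.contig not in known_contigs:
                raise ValueError(f"query on unknown contig {q.contig!r}")
    annot = _Annotator(annotations)
    rows = [
        {
            "contig": q.contig,
            "start": q.start,
            "end": q.end,
            "gene_context": annot.gene_context(q),
            "cgi_context": annot.cgi_context(q),
            "repeat_overlap": annot.repeat_overlap(q),
        }
        for q in queries
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feature distributions

def feature_distribution(
    query_annotations: pd.DataFrame,
    background_annotations: pd.DataFrame,
    axes: tuple[str, ...] = ("gene_context", "cgi_context", "repeat_overlap"),
) -> pd.DataFrame:
    """Per-feature proportions in a query set vs a background, with
    two-sided Fisher exact tests and Benjamini-Hochberg q-values.

    For each feature class the 2x2 table is (in-class vs not) x
    (query vs background). Proportions within each axis sum to 1.
    """
    if len(query_annotations) == 0:
        raise ValueError("empty query set")
    rows = []
    nq, nb = len(query_annotations), len(background_annotations)
    for axis in axes:
        classes = sorted(set(query_annotations[axis]) | set(background_annotations[axis]))
        for cls in classes:
            q_in = int((query_annotations[axis] == cls).sum())
            b_in = int((background_annotations[axis] == cls).sum())
            _, p = fisher_exact([[q_in, nq - q_in], [b_in, nb - b_in]], alternative="two-sided")
            rows.append(
                {
                    "axis": axis,
                    "feature": cls,
                    "query_count": q_in,
                    "background_count": b_in,
                    "query_prop": q_in / nq,
                    "background_prop": b_in / nb,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
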