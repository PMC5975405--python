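"""Shared downstream layer: Venn territories, sperm-specific selection,
direction classification, scatter tables, ordination and the
cross-platform intersection.

Three pairwise differential sets — A (sperm vs somatic 1), B (sperm vs
somatic 2) and C (somatic 1 vs somatic 2) — partition into seven
disjoint Venn territories. The sperm-specific units are (A intersect B)
minus C: differential against both somatic comparators but not between
them. For each such unit the two somatic-minus-sperm differences d1 and
d2 classify its direction: both positive means hypomethylated in sperm,
both negative hypermethylated in sperm, opposite signs (or any exact
zero) discordant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger("spermethyl")

TERRITORIES = ("A_only", "B_only", "C_only", "AB", "AC", "BC", "ABC")


@dataclass
class VennPartition:
    """The 7 disjoint territories of three sets."""

    A_only: frozenset
    B_only: frozenset
    C_only: frozenset
    AB: frozenset  # A and B, not C
    AC: frozenset
    BC: frozenset
    ABC: frozenset

    def counts(self) -> dict[str, int]:
        return {t: len(getattr(self, t)) for t in TERRITORIES}

    @property
    def union(self) -> frozenset:
        out: frozenset = frozenset()
        for t in TERRITORIES:
            out |= getattr(self, t)
        return out


def venn_partition(setA: Iterable[Hashable], setB: Iterable[Hashable], setC: Iterable[Hashable]) -> VennPartition:
    """Exact 7-way partition of three sets of hashable keys."""
    A, B, C = set(setA), set(setB), set(setC)
    return VennPartition(
        A_only=frozenset(A - B - C),
        B_only=frozenset(B - A - C),
        C_only=frozenset(C - A - B),
        AB=frozenset((A & B) - C),
        AC=frozenset((A & C) - B),
        BC=frozenset((B & C) - A),
        ABC=frozenset(A & B & C),
    )


def select_tissue_specific(partition: VennPartition) -> frozenset:
    """Units differential against both somatic comparators but not between
    them: (A intersect B) minus C."""
    return partition.AB


DIRECTION_CLASSES = ("hypo_in_sperm", "hyper_in_sperm", "discordant")


def classify_direction(units: pd.DataFrame) -> tuple[pd.Series, dict[str, float]]:
    """Classify each unit by the signs of its somatic-minus-sperm differences.

    ``units`` must carry columns d1 and d2 (value(somatic1) - value(sperm)
    and value(somatic2) - value(sperm)). Both positive: hypo_in_sperm;
    both negative: hyper_in_sperm; opposite signs or any exact zero:
    discordant. Returns per-unit labels and class proportions (sum 1).
    """
    d1 = units["d1"].to_numpy(dtype=float)
    d2 = units["d2"].to_numpy(dtype=float)
    if not (np.isfinite(d1).all() and np.isfinite(d2).all()):
        raise ValueError("differences must be finite")
    labels = np.where(
        (d1 > 0) & (d2 > 0), "hypo_in_sperm",
        np.where((d1 < 0) & (d2 < 0), "hyper_in_sperm", "discordant"),
    )
    out = pd.Series(labels, index=units.index, name="direction")
    n = len(out)
    props = {c: float((out == c).sum()) / n if n else np.nan for c in DIRECTION_CLASSES}
    return out, props


def scatter_table(units: pd.DataFrame, background_units: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Plot-ready difference table with corner-mass summaries.

    Rows carry (key, d1, d2, layer) with layer in {background, specific};
    the summary reports, per layer, the fraction of units in the
    upper-right corner (d1 > 0 and d2 > 0), lower-left corner, and
    off-diagonal (everything else, zeros included).
    """
    spec = units[["d1", "d2"]].copy()
    spec["layer"] = "specific"
    bg = background_units[["d1", "d2"]].copy()
    bg["layer"] = "background"
    table = pd.concat([bg, spec])

    def _corners(df: pd.DataFrame) -> dict[str, float]:
        n = len(df)
        if n == 0:
            return {"upper_right": np.nan, "lower_left": np.nan, "off_diagonal": np.nan}
        ur = float(((df["d1"] > 0) & (df["d2"] > 0)).sum()) / n
        ll = float(((df["d1"] < 0) & (df["d2"] < 0)).sum()) / n
        return {"upper_right": ur, "lower_left": ll, "off_diagonal": 1.0 - ur - ll}

    summary = {
        "specific": _corners(spec),
        "background": _corners(bg),
    }
    return table, summary


def intersect_platforms(
    dmr_intervals: Sequence[tuple[str, int, int]],
    dmc_positions: Iterable[tuple[str, int]],
    dmr_build: str = "",
    dmc_build: str = "",
) -> set[tuple[str, int]]:
    """CpG keys shared by the two platforms.

    Returns the DMC positions (contig, pos) that fall inside any DMR
    interval; interval containment is half-open on the plus-strand dyad
    position.
    """
    if dmr_build != dmc_build:
        raise ValueError(f"genome build mismatch: {dmr_build!r} vs {dmc_build!r}")
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, s, e in dmr_intervals:
        by_contig.setdefault(contig, []).append((s, e))
    starts_ends = {}
    for contig, ivs in by_contig.items():
        # merge overlapping intervals so one binary search suffices
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts_ends[contig] = (
            np.array([s for s, _ in merged]),
            np.array([e for _, e in merged]),
        )
    out = set()
    for contig, pos in dmc_positions:
        se = starts_ends.get(contig)
        if se is None:
            continue
        starts, ends = se
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        if j >= 0 and pos < ends[j]:
            out.add((contig, int(pos)))
    return out


@dataclass
class OrdinationResult:
    """Hierarchical clustering and PCA of a units x samples matrix."""

    linkage_matrix: np.ndarray
    samples: list[str]
    pc_coords: pd.DataFrame  # samples x PCs
    variance_explained: np.ndarray

    def top_split(self) -> tuple[set[str], set[str]]:
        """The two sample clusters created by the tree's first split."""
        labels = fcluster(self.linkage_matrix, t=2, criterion="maxclust")
        g1 = {s for s, l in zip(self.samples, labels) if l == 1}
        g2 = {s for s, l in zip(self.samples, labels) if l == 2}
        return g1, g2


def descriptive_ordination(matrix: pd.DataFrame) -> OrdinationResult:
    """Average-linkage clustering on correlation distance, plus PCA.

    ``matrix`` is units x samples with no missing values. Distance
    between samples is 1 - Pearson correlation; PCA is run on the
    column-centered sample profiles, reporting coordinates and the
    fraction of variance along each component.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    X = matrix.to_numpy(dtype=float)
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate input: constant matrix")
    corr = np.corrcoef(X.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")

    # PCA over samples: center each unit (row) across samples
    Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples x units
    Xc = Xc - Xc.mean(axis=0, keepdims=True)
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    coords = Xc @ vt.T
    var = svals**2
    var_explained = var / var.sum() if var.sum() > 0 else var
    pc_coords = pd.DataFrame(
        coords, index=matrix.columns, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
    )
    return OrdinationResult(
        linkage_matrix=Z,
        samples=list(matrix.columns),
        pc_coords=pc_coords,
        variance_explained=var_explained,
    )
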