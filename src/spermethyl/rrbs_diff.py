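"""RRBS branch: CpG tables, coverage strata, categorization and DMC calling.

The data model is a per-CpG, per-sample table of (methylated, total)
read counts. Minus-strand records of a CpG dyad are merged into the
plus-strand position by summing counts. Differential analysis keeps
CpGs covered by 5-500 uniquely mapped reads in every sample; CpGs with
more than 500 reads in any sample form a separate stratum dominated in
practice by multi-copy sequence.

A CpG is called differentially methylated (DMC) between two tissues
when (i) a two-sided Fisher exact test on the pooled per-tissue counts
survives Benjamini-Hochberg at q_cut, (ii) the tissue-mean methylation
difference is at least dmc_min_diff percentage points, and (iii) every
cross-tissue replicate pair agrees in direction with the tissue-mean
difference. These criteria are a reconstruction of "stringent" DMC
calling and every threshold is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .iokit import AnalysisConfig

logger = logging.getLogger("spermethyl")


@dataclass
class CpGTable:
    """Wide per-CpG count table.

    ``meth`` and ``total`` are DataFrames indexed by (contig, pos) with
    one column per sample; absent coverage is NaN. ``tissue_of`` maps
    sample name to tissue.
    """

    meth: pd.DataFrame
    total: pd.DataFrame
    tissue_of: dict[str, str]

    @property
    def samples(self) -> list[str]:
        return list(self.total.columns)

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s in self.samples if self.tissue_of[s] == tissue]

    def percents(self) -> pd.DataFrame:
        return 100.0 * self.meth / self.total


def build_cpg_table(records: pd.DataFrame, sample_map: Mapping[str, str]) -> CpGTable:
    """Assemble a CpGTable from long-format count records.

    Records on the minus strand of a CpG dyad (the G position) are
    shifted to the plus-strand C position and summed with any
    plus-strand record there. Duplicate (position, sample) records on
    the same strand are rejected.
    """
    df = records.copy()
    required = {"contig", "pos", "sample", "meth", "total"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count records missing column(s) {sorted(missing)}")
    if "strand" not in df.columns:
        df["strand"] = "+"
    if (df["meth"] > df["total"]).any():
        raise ValueError("methylated count exceeds total")

    dup = df.duplicated(subset=["contig", "pos", "strand", "sample"], keep=False)
    if dup.any():
        key = df.loc[dup, ["contig", "pos", "strand", "sample"]].iloc[0].tolist()
        raise ValueError(f"duplicate count record for {key}")

    df.loc[df["strand"] == "-", "pos"] -= 1  # dyad G -> C position
    merged = df.groupby(["contig", "pos", "sample"], as_index=False)[["meth", "total"]].sum()

    unknown = set(merged["sample"]) - set(sample_map)
    if unknown:
        raise ValueError(f"samples missing from sample map: {sorted(unknown)}")
    meth = merged.pivot(index=["contig", "pos"], columns="sample", values="meth")
    total = merged.pivot(index=["contig", "pos"], columns="sample", values="total")
    logger.info("CpG table: %d dyads x %d samples", len(total), total.shape[1])
    return CpGTable(meth=meth, total=total, tissue_of=dict(sample_map))


def filter_by_coverage(
    table: CpGTable,
    cov_min: int = 5,
    cov_max: int = 500,
    scope: Literal["all_samples", "per_sample"] = "all_samples",
) -> tuple[CpGTable, CpGTable, CpGTable]:
    """Split a table into (kept, dropped, over_max) coverage strata.

    Bounds are inclusive. ``over_max`` collects CpGs whose total exceeds
    ``cov_max`` in any sample; among the rest, ``kept`` requires every
    sample's total within [cov_min, cov_max] when scope is
    ``all_samples``. With scope ``per_sample``, out-of-range
    sample entries are masked instead and a CpG is kept when at least
    one sample remains. The three strata partition the input rows.
    """
    if cov_min > cov_max:
        raise ValueError("cov_min must be <= cov_max")
    total = table.total
    any_over = (total > cov_max).any(axis=1)
    if scope == "all_samples":
        ok = total.notna().all(axis=1) & (total >= cov_min).all(axis=1) & (total <= cov_max).all(axis=1)
        kept_idx = total.index[ok & ~any_over]
        drop_idx = total.index[~ok & ~any_over]
        kept = CpGTable(table.meth.loc[kept_idx], total.loc[kept_idx], table.tissue_of)
        dropped = CpGTable(table.meth.loc[drop_idx], total.loc[drop_idx], table.tissue_of)
    elif scope == "per_sample":
        in_range = (total >= cov_min) & (total <= cov_max)
        masked_meth = table.meth.where(in_range)
        masked_total = total.where(in_range)
        has_any = in_range.any(axis=1)
        kept_idx = total.index[has_any & ~any_over]
        drop_idx = total.index[~has_any & ~any_over]
        kept = CpGTable(masked_meth.loc[kept_idx], masked_total.loc[kept_idx], table.tissue_of)
        dropped = CpGTable(table.meth.loc[drop_idx], total.loc[drop_idx], table.tissue_of)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    over_idx = total.index[any_over]
    over = CpGTable(table.meth.loc[over_idx], total.loc[over_idx], table.tissue_of)
    logger.info(
        "coverage filter [%d,%d] scope=%s: kept %d, dropped %d, over_max %d",
        cov_min, cov_max, scope, len(kept.total), len(dropped.total), len(over.total),
    )
    return kept, dropped, over


@dataclass
class MethylationSummary:
    """Per-sample percentages, category proportions, tissue means and differences."""

    percents: pd.DataFrame  # CpG x sample, in [0, 100]
    categories: pd.DataFrame  # sample x {hypo, intermediate, hyper} proportions
    sample_means: pd.Series
    tissue_means: pd.DataFrame  # CpG x tissue
    tissue_diffs: dict[tuple[str, str], pd.Series]


def summarize_levels(
    table: CpGTable, hypo_cut: float = 20.0, hyper_cut: float = 80.0
) -> MethylationSummary:
    """Methylation percentages, hypo/intermediate/hyper proportions and
    tissue means.

    Category boundaries follow the printed convention: hypo < hypo_cut,
    intermediate in [hypo_cut, hyper_cut], hyper > hyper_cut. Tissue
    means average the per-sample percentages of a tissue's replicates;
    a tissue-pair difference is the difference of those means.
    """
    pct = table.percents()
    cats = {}
    for s in pct.columns:
        v = pct[s].dropna()
        n = len(v)
        cats[s] = {
            "hypo": float((v < hypo_cut).sum()) / n if n else np.nan,
            "intermediate": float(((v >= hypo_cut) & (v <= hyper_cut)).sum()) / n if n else np.nan,
            "hyper": float((v > hyper_cut).sum()) / n if n else np.nan,
        }
    categories = pd.DataFrame(cats).T[["hypo", "intermediate", "hyper"]]

    tissues = sorted(set(table.tissue_of[s] for s in pct.columns))
    tissue_means = pd.DataFrame({
        t: pct[table.samples_of(t)].mean(axis=1) for t in tissues
    })
    diffs = {
        (a, b): tissue_means[a] - tissue_means[b]
        for i, a in enumerate(tissues) for b in tissues[i + 1:]
    }
    return MethylationSummary(
        percents=pct,
        categories=categories,
        sample_means=pct.mean(axis=0),
        tissue_means=tissue_means,
        tissue_diffs=diffs,
    )


def fisher_exact_counts(a_meth: np.ndarray, a_unmeth: np.ndarray,
                        b_meth: np.ndarray, b_unmeth: np.ndarray) -> np.ndarray:
    """Two-sided Fisher exact p for vectors of 2x2 tables."""
    out = np.empty(len(a_meth))
    for i in range(len(a_meth)):
        _, out[i] = stats.fisher_exact(
            [[a_meth[i], a_unmeth[i]], [b_meth[i], b_unmeth[i]]], alternative="two-sided"
        )
    return out


def call_dmcs(
    table: CpGTable,
    tissue_a: str,
    tissue_b: str,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Call differentially methylated cytosines between two tissues.

    Expects a coverage-filtered table (scope ``all_samples``). Returns
    one row per tested CpG with per-tissue means, difference (a - b),
    Fisher p, BH q, the DMC flag and direction sign; the DMC subset can
    be taken with ``df[df.dmc]``.
    """
    if config is None:
        config = AnalysisConfig()
    sa, sb = table.samples_of(tissue_a), table.samples_of(tissue_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each tissue needs at least 2 samples")

    meth, total = table.meth, table.total
    a_meth = meth[sa].sum(axis=1).to_numpy(dtype=int)
    a_tot = total[sa].sum(axis=1).to_numpy(dtype=int)
    b_meth = meth[sb].sum(axis=1).to_numpy(dtype=int)
    b_tot = total[sb].sum(axis=1).to_numpy(dtype=int)

    pct = table.percents()
    mean_a = pct[sa].mean(axis=1)
    mean_b = pct[sb].mean(axis=1)
    diff = mean_a - mean_b

    p = fisher_exact_counts(a_meth, a_tot - a_meth, b_meth, b_tot - b_meth)
    q = multipletests(p, method="fdr_bh")[1]

    # replicate concordance: every cross-tissue replicate pair agrees in
    # direction with the tissue-mean difference
    sign = np.sign(diff.to_numpy())
    concordant = np.ones(len(pct), dtype=bool)
    for s_a in sa:
        for s_b in sb:
            pair = (pct[s_a] - pct[s_b]).to_numpy()
            concordant &= np.sign(pair) == sign

    out = pd.DataFrame({
        "mean_a": mean_a,
        "mean_b": mean_b,
        "diff": diff,
        "p": p,
        "q": q,
        "concordant": concordant,
    }, index=pct.index)
    out["dmc"] = (
        (out["q"] <= config.q_cut)
        & (out["diff"].abs() >= config.dmc_min_diff)
        & out["concordant"]
    )
    out["direction"] = np.where(out["dmc"], np.sign(out["diff"]).astype(int), 0)
    out.attrs["tissue_a"], out.attrs["tissue_b"] = tissue_a, tissue_b
    logger.info("DMCs %s vs %s: %d of %d tested", tissue_a, tissue_b, int(out["dmc"].sum()), len(out))
    return out


def repeat_consensus_summary(
    table: CpGTable, cov_min: int = 5, cov_max: int = 500
) -> pd.DataFrame:
    """Average methylation per repeat consensus, sample and coverage class.

    The table's contigs are repeat consensus sequence names (an
    artificial repeat-library genome). For each (repeat, sample) the
    unweighted mean of per-CpG methylation percentages is computed
    separately for CpGs covered by [cov_min, cov_max] reads and by more
    than cov_max reads; empty classes are absent (not zero).
    """
    rows = []
    pct = table.percents()
    for sample in table.samples:
        tot = table.total[sample]
        for repeat, grp in pct.groupby(level="contig"):
            t = tot.loc[grp.index]
            v = grp[sample]
            in_range = v[(t >= cov_min) & (t <= cov_max)].dropna()
            over = v[t > cov_max].dropna()
            if len(in_range):
                rows.append({"repeat": repeat, "sample": sample,
                             "coverage_class": f"{cov_min}-{cov_max}",
                             "mean_percent": float(in_range.mean()), "n_cpgs": len(in_range)})
            if len(over):
                rows.append({"repeat": repeat, "sample": sample,
                             "coverage_class": f">{cov_max}",
                             "mean_percent": float(over.mean()), "n_cpgs": len(over)})
    return pd.DataFrame(rows)
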