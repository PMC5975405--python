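"""MeDIP-chip branch: probe enrichment, NEpi matrices, regions of interest,
per-tissue enrichment fractions (Pr) and DMR calling.

A probe is called enriched in a sample when the mean log2(IP/input) of
its two dye-swap replicates reaches a threshold (default 1.0). Per
promoter p and sample i, NEpi is the fraction of the promoter's probes
enriched in that sample. Regions of interest are maximal clusters of
probes enriched in at least one sample (>= 3 members, tolerating one
non-enriched probe inside, never spanning promoter tiles). For a region
r, Pr_tissue is the mean over the tissue's samples of the fraction of
member probes enriched; a region is a DMR between two tissues when a
Fisher exact test on the pooled probe-sample enrichment observations
survives BH at q_cut and |delta Pr| reaches pr_min_diff.

The enrichment call, region rule and DMR test are reconstructions of an
array-analysis procedure that is not itself published in detail; every
threshold is configuration-exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .iokit import AnalysisConfig

logger = logging.getLogger("spermethyl")


@dataclass
class EnrichmentMatrix:
    """Boolean probe x sample enrichment calls plus probe metadata."""

    enriched: pd.DataFrame  # index probe_id, columns samples
    probes: pd.DataFrame  # index probe_id: contig, start, end, promoter_id, cpg_class
    tissue_of: dict[str, str]

    @property
    def samples(self) -> list[str]:
        return list(self.enriched.columns)

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s in self.samples if self.tissue_of[s] == tissue]


def call_enriched_probes(
    probe_table: pd.DataFrame,
    tissue_of: dict[str, str],
    log2_cut: float = 1.0,
) -> EnrichmentMatrix:
    """Call probe enrichment from dye-swap log-ratio records.

    A probe is enriched in a sample iff the mean log2 ratio over its
    dye-swap replicates is >= ``log2_cut``. Every probe-sample cell must
    carry both replicates.
    """
    required = {"probe_id", "promoter_id", "sample", "replicate", "log2_ratio"}
    missing = required - set(probe_table.columns)
    if missing:
        raise ValueError(f"probe table missing column(s) {sorted(missing)}")

    rep_counts = probe_table.groupby(["probe_id", "sample"])["replicate"].nunique()
    if rep_counts.min() < 2 or rep_counts.nunique() > 1:
        bad = rep_counts.index[rep_counts != rep_counts.max()][:3].tolist()
        raise ValueError(f"missing dye-swap replicate(s) at {bad}")

    means = probe_table.groupby(["probe_id", "sample"])["log2_ratio"].mean().unstack("sample")
    meta_cols = [c for c in ("contig", "start", "end", "promoter_id", "cpg_class") if c in probe_table.columns]
    probes = probe_table.drop_duplicates("probe_id").set_index("probe_id")[meta_cols]
    if probes["promoter_id"].isna().any():
        raise ValueError("every probe must map to a promoter")
    # keep genomic probe order within each promoter tile
    if {"contig", "start"} <= set(probes.columns):
        probes = probes.sort_values(["contig", "start"])
    means = means.loc[probes.index]
    enriched = means >= log2_cut
    logger.info("enrichment calls: %d probes x %d samples, %.1f%% enriched",
                enriched.shape[0], enriched.shape[1], 100 * enriched.to_numpy().mean())
    return EnrichmentMatrix(enriched=enriched, probes=probes, tissue_of=dict(tissue_of))


def nep_matrix(enrichment: EnrichmentMatrix) -> pd.DataFrame:
    """Normalized number of enriched probes: promoter x sample matrix.

    NEpi = (enriched probes of promoter p in sample i) / (probes of p),
    bounded in [0, 1]. Promoters without probes cannot occur by
    construction (every probe maps to a promoter).
    """
    promoter = enrichment.probes["promoter_id"]
    counts = enrichment.enriched.groupby(promoter).sum()
    totals = promoter.value_counts().sort_index()
    return counts.div(totals, axis=0)


@dataclass(frozen=True)
class Region:
    """A cluster of probes enriched in at least one sample."""

    region_id: str
    promoter_id: str
    contig: str
    start: int
    end: int
    probe_ids: tuple[str, ...]


def find_regions_of_interest(
    enrichment: EnrichmentMatrix,
    min_probes: int = 3,
    max_gap: int = 1,
) -> list[Region]:
    """Maximal runs of enriched-in-any-sample probes within promoter tiles.

    A region starts and ends on an enriched probe, tolerates at most
    ``max_gap`` consecutive non-enriched probes inside, and must contain
    at least ``min_probes`` member probes (gap probes included). Regions
    never span promoter tiles.
    """
    any_enriched = enrichment.enriched.any(axis=1)
    regions: list[Region] = []
    probes = enrichment.probes
    for promoter_id, grp in probes.groupby("promoter_id", sort=True):
        if "start" in grp.columns:
            grp = grp.sort_values("start")
        ids = grp.index.to_numpy()
        flags = any_enriched.loc[ids].to_numpy()
        i = 0
        while i < len(ids):
            if not flags[i]:
                i += 1
                continue
            j = i  # last enriched probe of the run
            k = i + 1
            gap = 0
            while k < len(ids):
                if flags[k]:
                    j = k
                    gap = 0
                else:
                    gap += 1
                    if gap > max_gap:
                        break
                k += 1
            members = ids[i:j + 1]
            if len(members) >= min_probes:
                sub = grp.loc[members]
                regions.append(Region(
                    region_id=f"{promoter_id}_r{len(regions)}",
                    promoter_id=str(promoter_id),
                    contig=str(sub["contig"].iloc[0]) if "contig" in sub else "",
                    start=int(sub["start"].min()) if "start" in sub else 0,
                    end=int(sub["end"].max()) if "end" in sub else 0,
                    probe_ids=tuple(members),
                ))
            i = j + 1
    logger.info("regions of interest: %d (min_probes=%d, max_gap=%d)", len(regions), min_probes, max_gap)
    return regions


def region_pr(region: Region, enrichment: EnrichmentMatrix) -> dict[str, float]:
    """Mean fraction of enriched member probes per tissue (Pr)."""
    tissues = sorted(set(enrichment.tissue_of.values()))
    sub = enrichment.enriched.loc[list(region.probe_ids)]
    out = {}
    for t in tissues:
        samples = enrichment.samples_of(t)
        if not samples:
            raise ValueError(f"tissue {t!r} has no samples")
        out[t] = float(sub[samples].mean(axis=0).mean())
    return out


def call_dmrs(
    regions: list[Region],
    enrichment: EnrichmentMatrix,
    tissue_a: str,
    tissue_b: str,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Call differentially methylated regions between two tissues.

    Per region the 2x2 table counts (enriched, not enriched) probe-sample
    observations for each tissue; a region is a DMR iff the two-sided
    Fisher exact BH q is <= q_cut and |Pr_a - Pr_b| >= pr_min_diff.
    Direction is sign(Pr_a - Pr_b).
    """
    if config is None:
        config = AnalysisConfig()
    sa, sb = enrichment.samples_of(tissue_a), enrichment.samples_of(tissue_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each tissue needs at least 2 samples")
    if not regions:
        return pd.DataFrame(
            columns=["region_id", "promoter_id", "pr_a", "pr_b", "delta_pr", "p", "q", "dmr", "direction"]
        ).set_index("region_id")

    rows = []
    for r in regions:
        sub = enrichment.enriched.loc[list(r.probe_ids)]
        ea = int(sub[sa].to_numpy().sum())
        na = sub[sa].size
        eb = int(sub[sb].to_numpy().sum())
        nb = sub[sb].size
        _, p = stats.fisher_exact([[ea, na - ea], [eb, nb - eb]], alternative="two-sided")
        pr_a = ea / na
        pr_b = eb / nb
        rows.append({
            "region_id": r.region_id, "promoter_id": r.promoter_id,
            "contig": r.contig, "start": r.start, "end": r.end,
            "pr_a": pr_a, "pr_b": pr_b, "delta_pr": pr_a - pr_b, "p": p,
        })
    out = pd.DataFrame(rows).set_index("region_id")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["dmr"] = (out["q"] <= config.q_cut) & (out["delta_pr"].abs() >= config.pr_min_diff)
    out["direction"] = np.where(out["dmr"], np.sign(out["delta_pr"]).astype(int), 0)
    out.attrs["tissue_a"], out.attrs["tissue_b"] = tissue_a, tissue_b
    logger.info("DMRs %s vs %s: %d of %d regions", tissue_a, tissue_b, int(out["dmr"].sum()), len(out))
    return out
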