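"""Global methylation quantification (LUMA) and resampling statistics.

The luminometric methylation assay digests genomic DNA with the
isoschizomers HpaII (methylation-sensitive) and MspI (insensitive) in
separate reactions, each alongside EcoRI to normalize for DNA amount.
Pyrogram C+G peak signals count digested CCGG ends, A+T peaks the EcoRI
AATT ends, and global methylation is

    Methylation% = 100 - 100 * (mean HpaII/EcoRI) / (mean MspI/EcoRI)

with each reaction normalized by its own EcoRI signal and duplicates
averaged per enzyme before the ratio is taken.

The module also provides the small-sample resampling tests used
throughout: two-sample permutation tests (independent or paired, with
exhaustive enumeration whenever the permutation space is small enough),
a balanced bootstrap of group means, a parametric suite (Welch's t,
one-way ANOVA with Tukey HSD and compact letter display), and the
bisulfite-pyrosequencing replicate-consistency rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger("spermethyl")


@dataclass
class LumaRun:
    """Pyrogram peak signals for one sample, one row per duplicate."""

    hpaii_cg: np.ndarray
    hpaii_at: np.ndarray
    mspi_cg: np.ndarray
    mspi_at: np.ndarray

    def __post_init__(self) -> None:
        for name in ("hpaii_cg", "hpaii_at", "mspi_cg", "mspi_at"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        n = len(self.hpaii_cg)
        if any(len(getattr(self, k)) != n for k in ("hpaii_at", "mspi_cg", "mspi_at")):
            raise ValueError("all signal vectors must have one value per duplicate")
        if (self.hpaii_cg < 0).any() or (self.mspi_cg < 0).any():
            raise ValueError("pyrogram CG signals must be non-negative")
        if (self.hpaii_at <= 0).any() or (self.mspi_at <= 0).any():
            raise ValueError("EcoRI (AT) normalizer signals must be positive")


def luma_methylation(run: LumaRun) -> float:
    """Global CCGG methylation percentage from one LUMA run.

    Each reaction's CG signal is normalized by its own EcoRI AT signal,
    duplicates are averaged per enzyme, and the HpaII/MspI ratio of
    those averages gives the unmethylated fraction. The result is
    clamped to [0, 100] (noise can push the raw formula slightly
    outside).
    """
    hpaii = float(np.mean(run.hpaii_cg / run.hpaii_at))
    mspi = float(np.mean(run.mspi_cg / run.mspi_at))
    if mspi == 0:
        raise ZeroDivisionError("MspI normalized signal is zero; methylation undefined")
    return float(np.clip(100.0 - 100.0 * hpaii / mspi, 0.0, 100.0))


# ---------------------------------------------------------------------------
# Permutation tests

def perm_test(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["independent", "paired"] = "independent",
    n_perm: int = 100_000,
    seed: int | None = None,
) -> float:
    """Two-sided two-sample permutation test.

    The statistic is the difference of means (independent) or the mean
    of paired differences (paired). The null is generated by group-label
    shuffles or sign flips. When the full permutation space is no larger
    than ``n_perm`` it is enumerated exhaustively and the p-value is
    exact; otherwise ``n_perm`` Monte-Carlo draws are used with the
    add-one correction p = (#{|T*| >= |T|} + 1) / (n_perm + 1).

    Constant pooled data yields an observed statistic of zero and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    if mode == "paired":
        if len(x) != len(y):
            raise ValueError("paired mode requires equal-length samples")
        return _perm_paired(x, y, n_perm, seed)
    if mode != "independent":
        raise ValueError(f"unknown mode {mode!r}")
    return _perm_independent(x, y, n_perm, seed)


def _perm_independent(x: np.ndarray, y: np.ndarray, n_perm: int, seed: int | None) -> float:
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    obs = abs(x.mean() - y.mean())
    total = comb(n + m, n)
    if total <= n_perm:
        hits = 0
        idx = range(n + m)
        sum_all = pooled.sum()
        for c in combinations(idx, n):
            sx = pooled[list(c)].sum()
            stat = abs(sx / n - (sum_all - sx) / m)
            if stat >= obs - 1e-12:
                hits += 1
        return hits / total
    rng = np.random.default_rng(seed)
    # vectorized label shuffles: argsort of uniform draws
    order = np.argsort(rng.random((n_perm, n + m)), axis=1)
    perm = pooled[order]
    stat = np.abs(perm[:, :n].mean(axis=1) - perm[:, n:].mean(axis=1))
    hits = int((stat >= obs - 1e-12).sum())
    return (hits + 1) / (n_perm + 1)


def _perm_paired(x: np.ndarray, y: np.ndarray, n_perm: int, seed: int | None) -> float:
    d = x - y
    n = len(d)
    obs = abs(d.mean())
    if 2**n <= n_perm:
        signs = np.array(
            [[1 if (k >> i) & 1 else -1 for i in range(n)] for k in range(2**n)], dtype=float
        )
        stat = np.abs((signs * d).mean(axis=1))
        return int((stat >= obs - 1e-12).sum()) / 2**n
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    stat = np.abs((signs * d).mean(axis=1))
    hits = int((stat >= obs - 1e-12).sum())
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Bootstrap

def bootstrap_group_means(
    groups: Mapping[str, Sequence[float]],
    n_boot: int = 2000,
    balance_to: int | None = None,
    seed: int | None = None,
    ci: tuple[float, float] = (2.5, 97.5),
) -> dict:
    """Balanced bootstrap of group means and pairwise mean differences.

    Each bootstrap round draws ``balance_to`` values with replacement
    from every group (default: the smallest group size), removing
    group-size imbalance from the comparison. Reports percentile CIs of
    each group mean and of every pairwise difference.
    """
    labels = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if len(a) == 0:
            raise ValueError(f"group {k!r} is empty")
    if balance_to is None:
        balance_to = min(len(a) for a in arrays.values())
    if balance_to < 2:
        raise ValueError("balance_to must be >= 2")
    rng = np.random.default_rng(seed)
    boot_means = {
        k: arrays[k][rng.integers(0, len(arrays[k]), size=(n_boot, balance_to))].mean(axis=1)
        for k in labels
    }
    out: dict = {"balance_to": balance_to, "groups": {}, "differences": {}}
    for k in labels:
        lo, hi = np.percentile(boot_means[k], ci)
        out["groups"][k] = {
            "mean": float(arrays[k].mean()),
            "boot_mean": float(boot_means[k].mean()),
            "ci": (float(lo), float(hi)),
        }
    for a, b in combinations(labels, 2):
        diff = boot_means[a] - boot_means[b]
        lo, hi = np.percentile(diff, ci)
        out["differences"][(a, b)] = {
            "mean_diff": float(arrays[a].mean() - arrays[b].mean()),
            "ci": (float(lo), float(hi)),
        }
    return out


# ---------------------------------------------------------------------------
# Parametric suite

def _compact_letter_display(labels: list[str], nonsig_pairs: set[frozenset]) -> dict[str, str]:
    """Assign letters so that groups sharing a letter are not significantly
    different (insert-and-absorb algorithm)."""
    letter_sets: list[set[str]] = []
    for lab in labels:
        placed = False
        for s in letter_sets:
            if all(frozenset((lab, other)) in nonsig_pairs for other in s):
                s.add(lab)
                placed = True
        if not placed:
            letter_sets.append({lab})
    # absorb subsets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, s in zip(alphabet, letter_sets):
        for lab in labels:
            if lab in s:
                out[lab] += letter
    return out


def parametric_suite(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> dict:
    """Parametric comparison of group means.

    Two groups: Welch's t-test. Two or more: one-way ANOVA plus Tukey
    HSD pairwise comparisons and a compact letter display (groups
    sharing a letter are not significantly different at ``alpha``).
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("need at least 2 values per group")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("degenerate input: zero variance in all groups")
    out: dict = {"groups": {k: {"n": len(a), "mean": float(a.mean())} for k, a in zip(labels, arrays)}}
    if len(labels) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
        out["welch"] = {"t": float(t), "p": float(p)}
    f, p_anova = stats.f_oneway(*arrays)
    out["anova"] = {"F": float(f), "p": float(p_anova)}
    values = np.concatenate(arrays)
    group_col = np.concatenate([[k] * len(a) for k, a in zip(labels, arrays)])
    tukey = pairwise_tukeyhsd(values, group_col, alpha=alpha)
    pairs: dict[tuple[str, str], float] = {}
    res = tukey.summary().data[1:]
    for row in res:
        g1, g2, _, p_adj = str(row[0]), str(row[1]), row[2], float(row[3])
        pairs[(g1, g2)] = p_adj
    out["tukey"] = pairs
    nonsig = {frozenset(k) for k, p_adj in pairs.items() if p_adj > alpha}
    out["letters"] = _compact_letter_display(labels, nonsig)
    return out


# ---------------------------------------------------------------------------
# Bisulfite-pyrosequencing aggregation

def pyro_aggregate(
    assay: Mapping[str, Sequence[float]], tolerance: float = 5.0
) -> pd.DataFrame:
    """Per-CpG methylation means with the duplicate-consistency rule.

    A replicate set passes quality control when its range does not
    exceed ``tolerance`` percentage points after discarding at most one
    outlying replicate; at least two replicates must remain. Passing
    sets are averaged; CpGs with no passing set are flagged
    ``needs_repeat``. With more than 2 replicates and several admissible
    single-removals, the subset with the smallest range is used.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    rows = []
    for cpg, reps in assay.items():
        vals = np.asarray(reps, dtype=float)
        if len(vals) == 0:
            raise ValueError(f"CpG {cpg!r} has no replicates")
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError(f"CpG {cpg!r}: percentages outside [0, 100]")
        used = _passing_subset(vals, tolerance)
        if used is None:
            rows.append({"cpg": cpg, "mean": np.nan, "n_used": 0, "needs_repeat": True})
        else:
            rows.append({
                "cpg": cpg, "mean": float(used.mean()), "n_used": len(used), "needs_repeat": False,
            })
    return pd.DataFrame(rows).set_index("cpg")


def _passing_subset(vals: np.ndarray, tolerance: float) -> np.ndarray | None:
    if len(vals) >= 2 and np.ptp(vals) <= tolerance:
        return vals
    if len(vals) >= 3:
        best: np.ndarray | None = None
        for i in range(len(vals)):
            sub = np.delete(vals, i)
            if np.ptp(sub) <= tolerance and (best is None or np.ptp(sub) < np.ptp(best)):
                best = sub
        return best
    return None
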