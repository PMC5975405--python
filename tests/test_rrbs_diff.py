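"""CpG tables, coverage strata, categorization, DMC calling, repeat summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from spermethyl import rrbs_diff
from spermethyl.iokit import AnalysisConfig


def make_records(rows):
    return pd.DataFrame(rows, columns=["contig", "pos", "strand", "sample", "meth", "total"])


def simple_table(totals_by_sample, meths_by_sample, tissue_of):
    """One-CpG-per-row table from dicts sample -> list of counts."""
    rows = []
    for sample in totals_by_sample:
        for i, (t, m) in enumerate(zip(totals_by_sample[sample], meths_by_sample[sample])):
            rows.append(("c1", 10 + i, "+", sample, m, t))
    return rrbs_diff.build_cpg_table(make_records(rows), tissue_of)


class TestBuildCpgTable:
    def test_dyad_strand_merge(self):
        recs = make_records([
            ("c1", 100, "+", "s1", 3, 10),
            ("c1", 101, "-", "s1", 2, 8),
        ])
        table = rrbs_diff.build_cpg_table(recs, {"s1": "sperm"})
        assert len(table.total) == 1
        assert table.meth.loc[("c1", 100), "s1"] == 5
        assert table.total.loc[("c1", 100), "s1"] == 18

    def test_single_record(self):
        recs = make_records([("c1", 5, "+", "s1", 1, 4)])
        table = rrbs_diff.build_cpg_table(recs, {"s1": "sperm"})
        assert table.total.shape == (1, 1)

    def test_duplicate_record_rejected(self):
        recs = make_records([
            ("c1", 100, "+", "s1", 3, 10),
            ("c1", 100, "+", "s1", 1, 5),
        ])
        with pytest.raises(ValueError, match="duplicate"):
            rrbs_diff.build_cpg_table(recs, {"s1": "sperm"})

    def test_simgen_round_trip(self, study, rrbs_study):
        # pooled counts reflect the planted methylation within binomial error
        table = rrbs_study.table
        mu = study.methylome.mu("sperm")
        sp = [s for s in table.samples if s.startswith("sperm")]
        pooled_m = table.meth[sp].sum(axis=1)
        pooled_t = table.total[sp].sum(axis=1)
        big = pooled_t >= 80
        emp = (pooled_m[big] / pooled_t[big])
        truth = mu.loc[emp.index]
        assert np.abs(emp - truth).mean() < 0.05


class TestFilterByCoverage:
    def test_low_sample_drops_cpg(self):
        table = simple_table(
            {"a": [4], "b": [10], "c": [10]},
            {"a": [0], "b": [0], "c": [0]},
            {"a": "t1", "b": "t1", "c": "t2"},
        )
        kept, dropped, over = rrbs_diff.filter_by_coverage(table)
        assert len(kept.total) == 0 and len(dropped.total) == 1

    def test_bounds_inclusive(self):
        table = simple_table(
            {"a": [5], "b": [500]}, {"a": [0], "b": [0]}, {"a": "t1", "b": "t2"}
        )
        kept, dropped, over = rrbs_diff.filter_by_coverage(table)
        assert len(kept.total) == 1

    def test_over_max_routed_separately(self):
        table = simple_table(
            {"a": [10], "b": [501]}, {"a": [0], "b": [0]}, {"a": "t1", "b": "t2"}
        )
        kept, dropped, over = rrbs_diff.filter_by_coverage(table)
        assert len(over.total) == 1 and len(kept.total) == 0 and len(dropped.total) == 0

    def test_per_sample_scope_masks_instead_of_dropping(self):
        table = simple_table(
            {"a": [4, 10], "b": [10, 10]}, {"a": [0, 5], "b": [5, 5]},
            {"a": "t1", "b": "t2"},
        )
        kept, dropped, over = rrbs_diff.filter_by_coverage(table, scope="per_sample")
        assert len(kept.total) == 2 and len(dropped.total) == 0
        assert np.isnan(kept.total.loc[("c1", 10), "a"])  # masked low-coverage cell
        assert kept.total.loc[("c1", 10), "b"] == 10

    def test_strata_partition_input(self, rrbs_study):
        table = rrbs_study.table
        kept, dropped, over = rrbs_diff.filter_by_coverage(table)
        idx = set(map(tuple, table.total.index))
        parts = [set(map(tuple, t.total.index)) for t in (kept, dropped, over)]
        assert parts[0] | parts[1] | parts[2] == idx
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])


class TestSummarizeLevels:
    def test_category_boundaries(self):
        # percents 19.9 / 20.0 / 80.0 / 80.1 via counts out of 1000
        table = simple_table(
            {"a": [1000, 1000, 1000, 1000], "b": [10, 10, 10, 10]},
            {"a": [199, 200, 800, 801], "b": [0, 0, 0, 0]},
            {"a": "t1", "b": "t2"},
        )
        summ = rrbs_diff.summarize_levels(table)
        cats = summ.categories.loc["a"]
        assert cats["hypo"] == pytest.approx(0.25)
        assert cats["intermediate"] == pytest.approx(0.50)
        assert cats["hyper"] == pytest.approx(0.25)

    def test_all_zero_sample_fully_hypo(self):
        table = simple_table(
            {"a": [10, 10], "b": [10, 10]}, {"a": [0, 0], "b": [10, 10]},
            {"a": "t1", "b": "t2"},
        )
        summ = rrbs_diff.summarize_levels(table)
        assert summ.categories.loc["a", "hypo"] == 1.0
        assert summ.categories.loc["b", "hyper"] == 1.0

    def test_proportions_sum_to_one(self, rrbs_study):
        summ = rrbs_diff.summarize_levels(rrbs_study.kept)
        np.testing.assert_allclose(summ.categories.sum(axis=1), 1.0, atol=1e-9)

    def test_sperm_bimodality_under_strong_plant(self, study):
        # a strong sperm plant pushes target CpGs into the hypo class,
        # inflating hypo+hyper mass relative to somatic samples
        from spermethyl import simgen

        # somatic targets intermediate (~72%), sperm targets near zero: the
        # intermediate mass moves into the hypo class in sperm only
        spec = simgen.PlantSpec(delta=65.0, base_means={
            "satellite": 0.72, "rDNA": 0.72, "germline_promoter": 0.72,
            "cgi_promoter": 0.08, "methylated_promoter": 0.75, "background": 0.8,
        })
        meth = simgen.plant_methylome(study.genome, study.annotations, spec, seed=55)
        counts = simgen.simulate_rrbs_counts(meth, study.rr, seed=56)
        table = rrbs_diff.build_cpg_table(counts, {"sperm_1": "sperm", "sperm_2": "sperm",
                                                   "fibroblast_1": "fibroblast", "fibroblast_2": "fibroblast",
                                                   "monocyte_1": "monocyte", "monocyte_2": "monocyte"})
        kept, _, _ = rrbs_diff.filter_by_coverage(table)
        summ = rrbs_diff.summarize_levels(kept)
        cats = summ.categories
        sperm = cats.loc[["sperm_1", "sperm_2"]]
        somatic = cats.loc[[s for s in cats.index if not s.startswith("sperm")]]
        assert (sperm["hypo"] + sperm["hyper"]).min() > (somatic["hypo"] + somatic["hyper"]).max()
        assert sperm["intermediate"].max() < somatic["intermediate"].min()

    def test_tissue_means_and_differences(self):
        table = simple_table(
            {"a1": [10], "a2": [10], "b1": [10], "b2": [10]},
            {"a1": [8], "a2": [6], "b1": [2], "b2": [4]},
            {"a1": "tA", "a2": "tA", "b1": "tB", "b2": "tB"},
        )
        summ = rrbs_diff.summarize_levels(table)
        assert summ.tissue_means.loc[("c1", 10), "tA"] == pytest.approx(70.0)
        assert summ.tissue_means.loc[("c1", 10), "tB"] == pytest.approx(30.0)
        assert summ.tissue_diffs[("tA", "tB")].iloc[0] == pytest.approx(40.0)


class TestCallDmcs:
    def test_identical_counts_no_dmcs(self):
        table = simple_table(
            {"a1": [30] * 5, "a2": [30] * 5, "b1": [30] * 5, "b2": [30] * 5},
            {"a1": [15] * 5, "a2": [15] * 5, "b1": [15] * 5, "b2": [15] * 5},
            {"a1": "tA", "a2": "tA", "b1": "tB", "b2": "tB"},
        )
        out = rrbs_diff.call_dmcs(table, "tA", "tB")
        assert out["dmc"].sum() == 0

    def test_extreme_table_fisher_matches_hypergeometric(self):
        table = simple_table(
            {"a1": [15], "a2": [15], "b1": [15], "b2": [15]},
            {"a1": [15], "a2": [15], "b1": [0], "b2": [0]},
            {"a1": "tA", "a2": "tA", "b1": "tB", "b2": "tB"},
        )
        out = rrbs_diff.call_dmcs(table, "tA", "tB")
        # pooled 2x2: (30, 0 / 0, 30); two-sided Fisher = 2 * P(X = 30)
        rv = hypergeom(60, 30, 30)
        expected = 2 * rv.pmf(30)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert bool(out["dmc"].iloc[0]) is True
        assert out["direction"].iloc[0] == 1

    def test_planted_effect_sensitivity_and_fdr(self):
        rng = np.random.default_rng(17)
        n, n_pos = 2000, 200
        mu = np.full(n, 0.6)
        mu_b = mu.copy()
        mu_b[:n_pos] = 0.2  # delta = 40 points
        rows = []
        for sample, tissue, m in [
            ("a1", "tA", mu), ("a2", "tA", mu), ("b1", "tB", mu_b), ("b2", "tB", mu_b),
        ]:
            total = rng.poisson(30, n) + 5
            meth = rng.binomial(total, m)
            for i in range(n):
                rows.append(("c1", i, "+", sample, meth[i], total[i]))
        table = rrbs_diff.build_cpg_table(
            make_records(rows), {"a1": "tA", "a2": "tA", "b1": "tB", "b2": "tB"}
        )
        out = rrbs_diff.call_dmcs(table, "tA", "tB")
        called = set(out.index[out["dmc"]].get_level_values("pos"))
        truth = set(range(n_pos))
        sensitivity = len(called & truth) / n_pos
        fdr = len(called - truth) / max(1, len(called))
        assert sensitivity >= 0.7
        assert fdr <= 0.10

    def test_direction_flips_under_tissue_swap(self):
        table = simple_table(
            {"a1": [30], "a2": [30], "b1": [30], "b2": [30]},
            {"a1": [28], "a2": [27], "b1": [3], "b2": [4]},
            {"a1": "tA", "a2": "tA", "b1": "tB", "b2": "tB"},
        )
        ab = rrbs_diff.call_dmcs(table, "tA", "tB")
        ba = rrbs_diff.call_dmcs(table, "tB", "tA")
        assert ab["dmc"].equals(ba["dmc"])
        assert (ab["direction"] == -ba["direction"]).all()

    def test_null_dmc_rate_controlled(self):
        rng = np.random.default_rng(23)
        cfg = AnalysisConfig()
        ok = 0
        for rep in range(10):
            n = 1000
            mu = rng.beta(8, 2, size=n)
            rows = []
            for sample, tissue in [("a1", "tA"), ("a2", "tA"), ("b1", "tB"), ("b2", "tB")]:
                total = rng.poisson(30, n) + 5
                meth = rng.binomial(total, mu)
                for i in range(n):
                    rows.append(("c1", i, "+", sample, meth[i], total[i]))
            table = rrbs_diff.build_cpg_table(
                make_records(rows), {"a1": "tA", "a2": "tA", "b1": "tB", "b2": "tB"}
            )
            out = rrbs_diff.call_dmcs(table, "tA", "tB", cfg)
            ok += out["dmc"].sum() <= cfg.q_cut * len(out)
        assert ok >= 9

    def test_single_replicate_tissue_rejected(self):
        table = simple_table(
            {"a1": [30], "b1": [30], "b2": [30]},
            {"a1": [15], "b1": [15], "b2": [15]},
            {"a1": "tA", "b1": "tB", "b2": "tB"},
        )
        with pytest.raises(ValueError):
            rrbs_diff.call_dmcs(table, "tA", "tB")


class TestRepeatConsensusSummary:
    def _consensus_table(self):
        rows = [
            ("SAT1", 0, "+", "s1", 1, 10),   # 10%
            ("SAT1", 5, "+", "s1", 3, 10),   # 30%
            ("SAT1", 9, "+", "s1", 500, 1000),  # >500 stratum
            ("RDNA", 2, "+", "s1", 9, 10),
        ]
        return rrbs_diff.build_cpg_table(make_records(rows), {"s1": "sperm"})

    def test_unweighted_average_per_class(self):
        out = rrbs_diff.repeat_consensus_summary(self._consensus_table())
        row = out[(out["repeat"] == "SAT1") & (out["coverage_class"] == "5-500")]
        assert row["mean_percent"].iloc[0] == pytest.approx(20.0)
        over = out[(out["repeat"] == "SAT1") & (out["coverage_class"] == ">500")]
        assert over["mean_percent"].iloc[0] == pytest.approx(50.0)

    def test_empty_class_missing_not_zero(self):
        out = rrbs_diff.repeat_consensus_summary(self._consensus_table())
        rdna = out[out["repeat"] == "RDNA"]
        assert set(rdna["coverage_class"]) == {"5-500"}

    def test_planted_satellite_consensus_recovery(self):
        # sperm mu ~ 0.1 vs somatic mu ~ 0.8 on a satellite consensus
        rng = np.random.default_rng(31)
        rows = []
        for sample, mu in [("sperm_1", 0.1), ("liver_1", 0.8)]:
            for i in range(50):
                t = int(rng.integers(20, 100))
                rows.append(("BTSAT_like", i, "+", sample, int(rng.binomial(t, mu)), t))
        table = rrbs_diff.build_cpg_table(
            make_records(rows), {"sperm_1": "sperm", "liver_1": "liver"}
        )
        out = rrbs_diff.repeat_consensus_summary(table)
        means = out.set_index("sample")["mean_percent"]
        assert means["liver_1"] - means["sperm_1"] >= 50.0
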