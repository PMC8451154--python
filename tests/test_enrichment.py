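"""2x2/stratified enrichment, region overlap, gene scores, variable sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tandem5hmc.datatypes import CpGAnnotation
from tandem5hmc.enrichment import (
    RegionCollection,
    cmh_enrichment,
    fisher_context_enrichment,
    gene_high5hmc_score,
    regionset_enrichment,
    set_overlap,
    variable_cpg_set,
)
from tandem5hmc.exceptions import ConfigurationError, DegenerateDataError, IngestError


def make_annotation(n, contexts=None, probe_types=None, genes=None, positions=None):
    idx = pd.Index([f"cg{i:06d}" for i in range(n)])
    tab = pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "pos": positions if positions is not None else np.arange(n) * 100 + 50,
            "context": contexts if contexts is not None else ["open_sea"] * n,
            "probe_type": probe_types if probe_types is not None else ["II"] * n,
            "gene": genes if genes is not None else ["G0"] * n,
            "tss_distance": [0] * n,
            "enhancer": [False] * n,
            "tfbs": [False] * n,
            "utr5": [False] * n,
        },
        index=idx,
    )
    return CpGAnnotation(tab)


class TestFisher:
    def test_cross_product_odds_ratio(self):
        # a=10, b=90, c=10, d=890 -> OR = 8900/900
        n = 1000
        contexts = ["island"] * 10 + ["open_sea"] * 90 + ["island"] * 10 + ["open_sea"] * 890
        ann = make_annotation(n, contexts=contexts)
        universe = ann.locus_ids
        query = universe[:100]
        row = fisher_context_enrichment(query, universe, ann, "island")
        assert (row.a, row.b, row.c, row.d) == (10, 90, 10, 890)
        assert row.odds_ratio == pytest.approx(8900 / 900)
        assert row.ci_low < row.odds_ratio < row.ci_high

    def test_counts_sum_to_universe(self):
        rng = np.random.default_rng(0)
        contexts = rng.choice(["island", "open_sea"], size=200)
        ann = make_annotation(200, contexts=list(contexts))
        universe = ann.locus_ids
        query = universe[rng.choice(200, 50, replace=False)]
        row = fisher_context_enrichment(query, universe, ann, "island")
        assert row.a + row.b + row.c + row.d == 200

    def test_feature_covering_universe_degenerate(self):
        ann = make_annotation(50, contexts=["island"] * 50)
        universe = ann.locus_ids
        with pytest.raises(DegenerateDataError, match="margin"):
            fisher_context_enrichment(universe[:10], universe, ann, "island")

    def test_query_equal_universe_rejected(self):
        ann = make_annotation(50)
        with pytest.raises(DegenerateDataError, match="complement"):
            fisher_context_enrichment(ann.locus_ids, ann.locus_ids, ann, "open_sea")

    def test_type_i_error_controlled_under_null(self):
        """Random query vs random feature: Fisher p rejects at <= alpha."""
        rng = np.random.default_rng(42)
        n, n_rep, alpha = 300, 1000, 0.05
        rejections = 0
        contexts_pool = np.array(["island", "open_sea"])
        for _ in range(n_rep):
            ann_ctx = contexts_pool[(rng.random(n) < 0.3).astype(int)]
            ann = make_annotation(n, contexts=list(ann_ctx))
            universe = ann.locus_ids
            query = universe[rng.choice(n, 60, replace=False)]
            try:
                row = fisher_context_enrichment(query, universe, ann, "island")
            except DegenerateDataError:
                continue
            rejections += row.p_value < alpha
        # Fisher exact is conservative; allow binomial slack above alpha
        assert rejections / n_rep <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / n_rep)


class TestCMH:
    def test_single_stratum_reduces_to_sample_or(self):
        contexts = ["island"] * 10 + ["open_sea"] * 90 + ["island"] * 10 + ["open_sea"] * 890
        ann = make_annotation(1000, contexts=contexts)
        universe = ann.locus_ids
        query = universe[:100]
        row = cmh_enrichment(query, universe, ann, "island")
        assert row.odds_ratio == pytest.approx(8900 / 900)

    def test_two_identical_strata_keep_common_or(self):
        contexts = (["island"] * 5 + ["open_sea"] * 45 + ["island"] * 20 + ["open_sea"] * 430) * 2
        probe = ["I"] * 500 + ["II"] * 500
        ann = make_annotation(1000, contexts=contexts, probe_types=probe)
        universe = ann.locus_ids
        query = universe[:50].append(universe[500:550])
        single = fisher_context_enrichment(
            universe[:50], universe[:500], ann, "island"
        )
        row = cmh_enrichment(query, universe, ann, "island")
        assert row.odds_ratio == pytest.approx(single.odds_ratio)
        assert len(row.strata) == 2

    def test_two_unequal_strata_match_hand_formula(self):
        # stratum I: (a,b,c,d) = (10,20,30,40); stratum II: (5,5,10,30)
        # MH = (10*40/100 + 5*30/50) / (20*30/100 + 5*10/50) = 7/7 = 1
        ctx_i = ["island"] * 10 + ["open_sea"] * 20 + ["island"] * 30 + ["open_sea"] * 40
        ctx_ii = ["island"] * 5 + ["open_sea"] * 5 + ["island"] * 10 + ["open_sea"] * 30
        ann = make_annotation(150, contexts=ctx_i + ctx_ii, probe_types=["I"] * 100 + ["II"] * 50)
        universe = ann.locus_ids
        query = universe[:30].append(universe[100:110])
        row = cmh_enrichment(query, universe, ann, "island")
        assert row.odds_ratio == pytest.approx(1.0)

    @given(
        a=st.integers(1, 30), b=st.integers(1, 30),
        c=st.integers(1, 30), d=st.integers(1, 30),
    )
    @settings(max_examples=25, deadline=None)
    def test_property_single_stratum_equals_cross_product(self, a, b, c, d):
        contexts = (
            ["island"] * a + ["open_sea"] * b + ["island"] * c + ["open_sea"] * d
        )
        ann = make_annotation(a + b + c + d, contexts=contexts)
        universe = ann.locus_ids
        query = universe[: a + b]
        row = cmh_enrichment(query, universe, ann, "island")
        assert row.odds_ratio == pytest.approx(a * d / (b * c))

    def test_all_strata_degenerate_rejected(self):
        ann = make_annotation(40, contexts=["island"] * 40)
        with pytest.raises(DegenerateDataError):
            cmh_enrichment(ann.locus_ids[:10], ann.locus_ids, ann, "island")


class TestRegionSets:
    def test_counts_match_brute_force_scan(self):
        rng = np.random.default_rng(5)
        positions = rng.choice(100_000, size=1000, replace=False)
        ann = make_annotation(1000, positions=positions)
        universe = ann.locus_ids
        query = universe[rng.choice(1000, 150, replace=False)]
        starts = rng.choice(95_000, size=10, replace=False)
        intervals = [("chr1", int(s), int(s + rng.integers(500, 4000))) for s in starts]
        coll = RegionCollection.from_intervals("rand", intervals)
        rows = regionset_enrichment(query, universe, ann, [coll])
        # brute-force per-locus point-in-interval scan
        inside = {
            locus
            for locus, pos in zip(universe, positions)
            if any(s <= pos < e for _, s, e in intervals)
        }
        qset = set(query)
        a = len(qset & inside)
        c = len(inside - qset)
        assert rows[0].a == a
        assert rows[0].c == c
        assert rows[0].a + rows[0].b + rows[0].c + rows[0].d == 1000

    def test_collection_covering_universe_flagged(self):
        ann = make_annotation(100)
        coll = RegionCollection.from_intervals("all", [("chr1", 0, 10_000_000)])
        rows = regionset_enrichment(ann.locus_ids[:20], ann.locus_ids, ann, [coll])
        assert rows[0].continuity_corrected
        assert np.isnan(rows[0].p_value)

    def test_perfect_separation_continuity_flagged(self):
        positions = list(range(50, 10_050, 100))
        ann = make_annotation(100, positions=positions)
        universe = ann.locus_ids
        query = universe[:10]
        coll = RegionCollection.from_intervals("exact", [("chr1", 0, 1000)])
        rows = regionset_enrichment(query, universe, ann, [coll])
        assert rows[0].a == 10 and rows[0].c == 0
        assert rows[0].continuity_corrected
        assert rows[0].odds_ratio > 1

    def test_chromosome_mismatch_listed(self):
        ann = make_annotation(10)
        coll = RegionCollection.from_intervals("bad", [("chrX", 0, 100)])
        with pytest.raises(IngestError, match="chrX"):
            regionset_enrichment(ann.locus_ids[:2], ann.locus_ids, ann, [coll])

    def test_q_values_bh_across_collections(self):
        rng = np.random.default_rng(6)
        positions = rng.choice(100_000, size=500, replace=False)
        ann = make_annotation(500, positions=positions)
        universe = ann.locus_ids
        query = universe[rng.choice(500, 80, replace=False)]
        colls = [
            RegionCollection.from_intervals(
                f"c{k}",
                [("chr1", int(s), int(s) + 2000) for s in rng.choice(98_000, 5)],
            )
            for k in range(4)
        ]
        rows = regionset_enrichment(query, universe, ann, colls)
        qs = [r.q_value for r in rows if np.isfinite(r.p_value)]
        ps = [r.p_value for r in rows if np.isfinite(r.p_value)]
        assert all(q >= p for q, p in zip(qs, ps))
        assert qs == sorted(qs)


class TestGeneScores:
    def test_simple_proportion(self):
        genes = ["A"] * 20
        ann = make_annotation(20, genes=genes)
        high = ann.locus_ids[:10]
        df = gene_high5hmc_score(high, ann, min_high=10)
        assert len(df) == 1
        assert df.loc[0, "percent_high"] == pytest.approx(50.0)

    def test_below_threshold_excluded(self):
        ann = make_annotation(20, genes=["A"] * 20)
        df = gene_high5hmc_score(ann.locus_ids[:9], ann, min_high=10)
        assert df.empty

    def test_matches_group_by_oracle(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in rng.integers(0, 5, size=200)]
        ann = make_annotation(200, genes=genes)
        high = ann.locus_ids[rng.choice(200, 80, replace=False)]
        df = gene_high5hmc_score(high, ann, min_high=5).set_index("gene")
        tab = ann.table.assign(high=ann.table.index.isin(set(high)))
        oracle = tab.groupby("gene").agg(n=("high", "size"), k=("high", "sum"))
        oracle = oracle[oracle["k"] >= 5]
        assert set(df.index) == set(oracle.index)
        for g in oracle.index:
            assert df.loc[g, "percent_high"] == pytest.approx(
                100 * oracle.loc[g, "k"] / oracle.loc[g, "n"]
            )
        assert (df["percent_high"].diff().dropna() <= 1e-12).all()


class TestSetOverlapAndVariability:
    def test_overlap_identity_and_disjoint(self):
        assert set_overlap({1, 2}, {1, 2})["frac_of_a"] == 1.0
        assert set_overlap({1, 2}, {3})["n_intersection"] == 0

    def test_overlap_half(self):
        res = set_overlap(set(range(1, 101)), set(range(51, 151)))
        assert (res["n_intersection"], res["frac_of_a"], res["frac_of_b"]) == (50, 0.5, 0.5)

    def test_constant_rows_never_selected(self):
        betas = pd.DataFrame(
            {"s1": [0.5, 0.1], "s2": [0.5, 0.9]}, index=["const", "varying"]
        )
        assert list(variable_cpg_set(betas, sd_threshold=0.01)) == ["varying"]

    def test_sd_hand_value(self):
        betas = pd.DataFrame({"s1": [0.0], "s2": [1.0]}, index=["x"])
        sd = betas.std(axis=1, ddof=1).iloc[0]
        assert sd == pytest.approx(np.sqrt(0.5))
        assert list(variable_cpg_set(betas, sd_threshold=0.7)) == ["x"]
        assert list(variable_cpg_set(betas, sd_threshold=0.71)) == []

    def test_top_n_matches_sort_oracle(self):
        rng = np.random.default_rng(8)
        betas = pd.DataFrame(
            rng.uniform(0, 1, size=(50, 6)),
            index=[f"cg{i:04d}" for i in range(50)],
        )
        got = variable_cpg_set(betas, top_n=7)
        sd = betas.std(axis=1, ddof=1)
        oracle = sd.sort_values(ascending=False).index[:7]
        assert set(got) == set(oracle)

    def test_both_arguments_rejected(self):
        betas = pd.DataFrame({"a": [0.1, 0.2], "b": [0.3, 0.4]})
        with pytest.raises(ConfigurationError):
            variable_cpg_set(betas, sd_threshold=0.1, top_n=1)
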