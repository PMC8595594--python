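"""Statistical core: contingency tables, Fisher p, BH, tissue scans."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eqtlpath.catalogs import EqtlCatalog, EqtlRecord, GeneSet, GeneSetCollection
from eqtlpath.enrichment import (
    ContingencyTable,
    bh_adjust,
    build_contingency,
    fisher_one_sided_p,
    run_all,
    scan_tissue,
    select_in_region_egenes,
)
from eqtlpath.regions import (
    GenomicInterval,
    QueryRegionSet,
    Variant,
    build_interval_index,
    build_query_regions,
)


def fisher_enumeration_oracle(t: ContingencyTable) -> float:
    """Exact tail sum over the hypergeometric support, in rational arithmetic."""
    n_hit, n_path, n = t.a + t.b, t.a + t.c, t.universe_size
    if n_hit == 0 or n_path == 0:
        return 1.0
    total = Fraction(0)
    for k in range(t.a, min(n_hit, n_path) + 1):
        total += Fraction(
            math.comb(n_path, k) * math.comb(n - n_path, n_hit - k),
            math.comb(n, n_hit),
        )
    return float(total)


def bh_step_up_oracle(pvals):
    """Direct formula: q_i = min over j >= rank(i) of p_(j) * m / j, capped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order):
        q[i] = min(
            min(pvals[order[j]] * m / (j + 1) for j in range(rank_pos, m)), 1.0
        )
        q[i] = max(q[i], pvals[i])  # exact-arithmetic no-op, guards rounding
    return q


class TestContingency:
    def test_direct_set_arithmetic(self):
        t = build_contingency(
            {"G1", "G2"},
            GeneSet("P", frozenset({"G1", "G3"})),
            frozenset(f"G{i}" for i in range(1, 11)),
        )
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 7)

    def test_no_hits(self):
        t = build_contingency(
            set(), GeneSet("P", frozenset({"G1"})), frozenset({"G1", "G2"})
        )
        assert (t.a, t.b) == (0, 0)

    def test_pathway_genes_outside_universe_excluded(self):
        t = build_contingency(
            {"G1"}, GeneSet("P", frozenset({"G1", "GX"})), frozenset({"G1", "G2"})
        )
        assert t.a + t.c == 1  # GX not in universe, not in margins

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            build_contingency(set(), GeneSet("P", frozenset({"G1"})), frozenset())

    def test_cells_match_elementwise_classification(self, rng):
        for _ in range(50):
            universe = frozenset(f"G{i}" for i in range(int(rng.integers(2, 100))))
            hits = {g for g in universe if rng.random() < 0.3}
            members = {g for g in universe if rng.random() < 0.2} | {"GX"}
            t = build_contingency(hits, GeneSet("P", frozenset(members)), universe)
            cells = [0, 0, 0, 0]
            for g in universe:
                cells[
                    0 if (g in hits and g in members)
                    else 1 if g in hits
                    else 2 if g in members
                    else 3
                ] += 1
            assert (t.a, t.b, t.c, t.d) == tuple(cells)


class TestFisher:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((1, 1, 1, 1), 5 / 6),
            ((2, 0, 0, 2), 1 / 6),
            ((0, 5, 3, 10), 1.0),  # a = 0: P(A >= 0) = 1
        ],
    )
    def test_small_table_examples(self, cells, expected):
        assert fisher_one_sided_p(ContingencyTable(*cells)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_degenerate_margins_give_one(self):
        assert fisher_one_sided_p(ContingencyTable(0, 0, 3, 5)) == 1.0
        assert fisher_one_sided_p(ContingencyTable(0, 4, 0, 5)) == 1.0

    def test_matches_scipy_two_by_two(self, rng):
        from scipy.stats import fisher_exact

        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            t = ContingencyTable(a, b, c, d)
            if a + b == 0 or a + c == 0 or t.universe_size == 0:
                continue
            _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            assert fisher_one_sided_p(t) == pytest.approx(p, rel=1e-9)

    @given(
        st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        if t.universe_size == 0:
            return
        assert fisher_one_sided_p(t) == pytest.approx(
            fisher_enumeration_oracle(t), abs=1e-12
        )

    def test_monotone_in_enrichment(self):
        # moving a hit gene into the pathway can only strengthen enrichment
        for a, b, c, d in [(1, 5, 3, 20), (2, 8, 6, 40), (0, 4, 4, 12)]:
            p_lo = fisher_one_sided_p(ContingencyTable(a, b, c, d))
            p_hi = fisher_one_sided_p(ContingencyTable(a + 1, b - 1, c, d + 1))
            assert p_hi <= p_lo + 1e-15


class TestBh:
    def test_hand_worked_example(self):
        got = bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert got == pytest.approx([0.02, 0.02, 0.04, 0.04], abs=1e-15)

    def test_singleton_identity(self):
        assert bh_adjust([0.3]) == [0.3]

    def test_ties(self):
        assert bh_adjust([0.05, 0.05, 0.05]) == pytest.approx([0.05] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_matches_step_up_oracle_exactly(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 60))
            pvals = [float(p) for p in rng.random(m)]
            assert bh_adjust(pvals) == bh_step_up_oracle(pvals)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        pvals = rng.random(200)
        _, q, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(bh_adjust(pvals), q, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=80))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, pvals):
        q = bh_adjust(pvals)
        assert all(qi >= pi - 1e-15 for qi, pi in zip(q, pvals))
        assert all(qi <= 1.0 for qi in q)
        order = np.argsort(pvals, kind="mergesort")
        q_sorted = np.array(q)[order]
        assert np.all(np.diff(q_sorted) >= -1e-15)


def _toy_catalog(tissue="liver"):
    """3 in-region eQTLs on G1, plus assorted in/out records."""
    records = [
        EqtlRecord("v1", "chr1", 100, "G1", 1e-6, tissue),
        EqtlRecord("v2", "chr1", 150, "G1", 1e-6, tissue),
        EqtlRecord("v3", "chr1", 180, "G1", 1e-6, tissue),
        EqtlRecord("v4", "chr1", 5_000, "G2", 1e-6, tissue),   # out of region
        EqtlRecord("v5", "chr1", 120, "G3", 1e-6, tissue),
        EqtlRecord("v6", "chr2", 100, "G4", 1e-6, tissue),     # wrong chrom
    ]
    return EqtlCatalog(tissue=tissue, records=records)


def _toy_regions():
    return QueryRegionSet("t", [GenomicInterval("chr1", 50, 250)], 0)


class TestSelectInRegion:
    def test_ld_duplicates_collapse_to_one_egene(self):
        hits, counts = select_in_region_egenes(
            _toy_catalog(), build_interval_index(_toy_regions())
        )
        assert hits == frozenset({"G1", "G3"})
        assert counts == {"G1": 3, "G3": 1}

    def test_no_regions_gives_empty_set(self):
        empty = QueryRegionSet("t", [], 0)
        hits, counts = select_in_region_egenes(
            _toy_catalog(), build_interval_index(empty)
        )
        assert hits == frozenset() and counts == {}

    def test_matches_linear_scan_on_synthetic_catalog(self, small_scenario):
        idx = build_interval_index(small_scenario.regions)
        for cat in small_scenario.catalogs.values():
            hits, _ = select_in_region_egenes(cat, idx)
            brute = {
                r.egene
                for r in cat.records
                if any(
                    iv.chrom == r.chrom and iv.contains(r.pos - 1)
                    for iv in small_scenario.regions.intervals
                )
            }
            assert hits == frozenset(brute)


class TestScan:
    def test_single_pathway_adjustment_is_identity(self):
        coll = GeneSetCollection("c", [GeneSet("P", frozenset({"G1", "G2"}))])
        res = scan_tissue(_toy_catalog(), build_interval_index(_toy_regions()), coll)
        assert len(res) == 1 and res[0].p_adj == res[0].p_raw

    def test_hit_genes_and_eqtl_counts_reported(self):
        coll = GeneSetCollection("c", [GeneSet("P", frozenset({"G1", "G2"}))])
        res = scan_tissue(_toy_catalog(), build_interval_index(_toy_regions()), coll)
        assert res[0].hit_genes == ["G1"]
        assert res[0].hit_eqtl_count == 3

    def test_pathway_order_permutation_invariant(self, planted_scenario):
        sc = planted_scenario
        idx = build_interval_index(sc.regions)
        cat = sc.catalogs["tissue1"]
        res = scan_tissue(cat, idx, sc.collection)
        shuffled = GeneSetCollection(
            sc.collection.name, list(reversed(sc.collection.sets))
        )
        res2 = scan_tissue(cat, idx, shuffled)
        key = lambda r: (r.tissue, r.pathway)
        assert {key(r): (r.p_raw, r.p_adj) for r in res} == {
            key(r): (r.p_raw, r.p_adj) for r in res2
        }

    def test_planted_pathway_ranks_first(self, planted_scenario):
        sc = planted_scenario
        res = scan_tissue(
            sc.catalogs["tissue1"],
            build_interval_index(sc.regions),
            sc.collection,
        )
        assert res[0].pathway == "PW001"

    def test_empty_hits_give_p_one(self):
        cat = EqtlCatalog("liver", [EqtlRecord("v", "chr9", 10, "G1", 1e-6, "liver")])
        coll = GeneSetCollection("c", [GeneSet("P", frozenset({"G1"}))])
        res = scan_tissue(cat, build_interval_index(_toy_regions()), coll)
        assert res[0].p_raw == 1.0 and res[0].table.a == 0

    def test_eqtl_counting_unit_classifies_records(self):
        coll = GeneSetCollection("c", [GeneSet("P", frozenset({"G1", "G2"}))])
        res = scan_tissue(
            _toy_catalog(), build_interval_index(_toy_regions()), coll,
            counting_unit="eqtl",
        )
        t = res[0].table
        # universe = catalog genes ∩ collection genes = {G1, G2}; records of
        # G3/G4 fall outside it. a = 3 in-region G1 records; c = 1
        # out-of-region G2 record.
        assert (t.a, t.b, t.c, t.d) == (3, 0, 1, 0)


class TestRunAll:
    def test_result_count_is_pairs_times_pathways(self, small_scenario):
        sc = small_scenario
        half = len(sc.collection.sets) // 2
        colls = [
            GeneSetCollection("c1", sc.collection.sets[:half]),
            GeneSetCollection("c2", sc.collection.sets[half:]),
        ]
        res = run_all(sc.catalogs, sc.regions, colls)
        assert len(res) == len(sc.catalogs) * len(sc.collection.sets)

    def test_composition_equals_independent_scans(self, small_scenario):
        sc = small_scenario
        res = run_all(sc.catalogs, sc.regions, [sc.collection])
        idx = build_interval_index(sc.regions)
        key = lambda r: (r.tissue, r.pathway)
        flat = {}
        for cat in sc.catalogs.values():
            for r in scan_tissue(cat, idx, sc.collection):
                flat[key(r)] = (r.p_raw, r.p_adj)
        assert {key(r): (r.p_raw, r.p_adj) for r in res} == flat

    def test_bh_family_global_pools_all_tests(self, small_scenario):
        sc = small_scenario
        res_pair = run_all(sc.catalogs, sc.regions, [sc.collection], bh_family="per_pair")
        res_glob = run_all(sc.catalogs, sc.regions, [sc.collection], bh_family="global")
        raw = sorted(r.p_raw for r in res_pair)
        assert raw == sorted(r.p_raw for r in res_glob)
        adj_glob = {(r.tissue, r.pathway): r.p_adj for r in res_glob}
        expect = bh_adjust([r.p_raw for r in res_pair])
        manual = dict(
            zip([(r.tissue, r.pathway) for r in res_pair], expect)
        )
        assert adj_glob == pytest.approx(manual)

    def test_requires_inputs(self, small_scenario):
        with pytest.raises(ValueError):
            run_all({}, small_scenario.regions, [small_scenario.collection])
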