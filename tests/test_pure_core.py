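"""The PURE test: overlap restriction, edge labeling, contingency tables,
one-sided Fisher tails, FDR, ranking, and calls."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from pure import core
from pure.core import (
    ContingencyTable,
    build_overlap,
    contingency_for,
    fdr_adjust,
    fisher_one_sided,
    label_edges,
    p_value_h2,
    rank_results,
    significant_set,
)
run_pure = core.test_all
from pure.de import DEGene
from pure.kb import Edge, KnowledgeBase


def enumeration_tail(l, k, m, n, strict=False):
    """Independent oracle: enumerate every 2x2 table with the observed
    margins and sum the exact hypergeometric probabilities of those whose
    first cell is >= l (or > l)."""
    total = l + k + m + n
    r1, c1 = l + k, l + m
    denom = math.comb(total, c1)
    acc = Fraction(0)
    for a in range(0, min(r1, c1) + 1):
        b, c = r1 - a, c1 - a
        d = total - r1 - c1 + a
        if b < 0 or c < 0 or d < 0:
            continue
        if (a > l) if strict else (a >= l):
            acc += Fraction(math.comb(r1, a) * math.comb(total - r1, c1 - a), denom)
    return acc


class TestOverlap:
    def test_restriction_to_de_genes(self, tiny_kb, tiny_de_genes):
        net = build_overlap(tiny_kb, tiny_de_genes)
        # g3, g4 are not DE; g5 is DE but absent from the KB
        assert net.n_edges == 3
        assert net.cdts == ["C1", "C2"]
        assert set(net.genes) == {"g1", "g2"}

    def test_empty_overlap_is_empty_result_not_error(self, tiny_kb):
        net = build_overlap(tiny_kb, [DEGene("zzz", 1, 1.0, 0.01)])
        assert net.n_edges == 0
        assert run_pure(label_edges(net)) == []

    def test_edge_counts_by_hand(self):
        kb = KnowledgeBase(
            edges=[
                Edge("A", "g1", 1), Edge("A", "g2", -1), Edge("A", "g9", 1),
                Edge("B", "g2", 1), Edge("B", "g8", -1),
            ]
        )
        de = [DEGene("g1", 1, 1.0, 0.01), DEGene("g2", -1, -1.0, 0.01)]
        net = build_overlap(kb, de)
        assert net.n_edges == 3 and len(net.cdts) == 2


class TestLabeling:
    @pytest.mark.parametrize(
        "edge_sign, gene_sign, h1",
        [
            (1, 1, True),    # activation edge, up-regulated gene
            (1, -1, False),  # activation edge, down-regulated gene
            (-1, -1, True),  # inhibition edge, down-regulated gene
            (-1, 1, False),
        ],
    )
    def test_sign_agreement_rule(self, edge_sign, gene_sign, h1):
        kb = KnowledgeBase(edges=[Edge("C", "g", edge_sign), Edge("D", "g", 1)])
        de = [DEGene("g", gene_sign, float(gene_sign), 0.01)]
        net = label_edges(build_overlap(kb, de))
        row = net.edges[net.edges.cdt_id == "C"].iloc[0]
        assert bool(row.h1_support) is h1

    def test_labels_partition_edges(self, tiny_kb, tiny_de_genes):
        net = label_edges(build_overlap(tiny_kb, tiny_de_genes))
        h1 = int(net.edges.h1_support.sum())
        h2 = int((~net.edges.h1_support).sum())
        assert h1 + h2 == net.n_edges


class TestContingency:
    def test_single_cdt_owns_all_edges(self):
        kb = KnowledgeBase(
            edges=[Edge("A", f"g{i}", 1) for i in range(3)] + [Edge("A", "g3", -1)]
        )
        de = [DEGene(f"g{i}", 1, 1.0, 0.01) for i in range(4)]
        net = label_edges(build_overlap(kb, de))
        # fisher needs >= 2 CDTs? no: A owns everything, m = n = 0
        t = contingency_for(net, "A")
        assert (t.l, t.k, t.m, t.n) == (3, 1, 0, 0)

    def test_counts_against_direct_membership(self):
        de = [
            DEGene(f"g{i}", 1 if i % 3 else -1, 1.0 if i % 3 else -1.0, 0.01)
            for i in range(12)
        ]
        edges = [
            Edge(c, f"g{i}", 1 if (i + j) % 3 else -1)
            for j, c in enumerate(("A", "B", "C"))
            for i in range(12)
            if (i + ord(c)) % 2
        ]
        kb = KnowledgeBase(edges=edges)
        net = label_edges(build_overlap(kb, de))
        for c in net.cdts:
            t = contingency_for(net, c)
            sub = net.edges[net.edges.cdt_id == c]
            assert t.l == int(sub.h1_support.sum())
            assert t.k == len(sub) - t.l
            assert t.l + t.k + t.m + t.n == net.n_edges
        # summing l over CDTs recovers the H1 edge total
        assert sum(contingency_for(net, c).l for c in net.cdts) == int(
            net.edges.h1_support.sum()
        )

    def test_unknown_cdt_raises(self, tiny_kb, tiny_de_genes):
        net = label_edges(build_overlap(tiny_kb, tiny_de_genes))
        with pytest.raises(KeyError):
            contingency_for(net, "nope")


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((0, 5, 0, 5), 1.0),
            ((2, 0, 0, 3), 0.1),            # C(2,2)C(3,0)/C(5,2)
            ((3, 1, 1, 5), 25 / 210),       # tail over l' in {3, 4}
        ],
    )
    def test_worked_examples(self, table, expected):
        assert fisher_one_sided(ContingencyTable(*table)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_h2_is_column_swap(self):
        assert p_value_h2(ContingencyTable(0, 2, 3, 0)) == pytest.approx(0.1, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(0, 12)] * 4).filter(lambda t: sum(t) >= 1))
    def test_matches_enumeration_and_scipy(self, t):
        table = ContingencyTable(*t)
        p = fisher_one_sided(table)
        assert abs(p - float(enumeration_tail(*t))) < 1e-12
        sp = fisher_exact([[t[0], t[1]], [t[2], t[3]]], alternative="greater")[1]
        assert p == pytest.approx(sp, rel=1e-9, abs=1e-12)
        # swap duality is exact
        assert p_value_h2(table) == fisher_one_sided(table.swapped())
        # double swap returns the original H1 p-value
        assert fisher_one_sided(table.swapped().swapped()) == p

    def test_strict_tail_excludes_observed(self):
        t = ContingencyTable(3, 1, 1, 5)
        assert fisher_one_sided(t, strict=True) == pytest.approx(
            float(enumeration_tail(3, 1, 1, 5, strict=True)), abs=1e-12
        )
        # maximal table: inclusive tail is a valid p, strict tail vanishes
        full = ContingencyTable(4, 0, 0, 6)
        assert fisher_one_sided(full) > 0
        assert fisher_one_sided(full, strict=True) == 0.0

    def test_tail_monotone_in_focal_support(self):
        # grow the focal CDT's support at fixed margins
        total, r1, c1 = 40, 10, 18
        ps = [
            core._tail_p(l, r1, c1, total) for l in range(0, min(r1, c1) + 1)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_large_table_uses_stable_path(self):
        t = ContingencyTable(30, 10, 400, 1000)
        p_big = fisher_one_sided(t)
        sp = fisher_exact([[30, 10], [400, 1000]], alternative="greater")[1]
        assert p_big == pytest.approx(sp, rel=1e-9)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 1)
        with pytest.raises(ValueError):
            fisher_one_sided(ContingencyTable(0, 0, 0, 0))


class TestFDR:
    def test_bh_by_hand(self):
        adj = fdr_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_all_ones_and_singleton(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bh_invariants(self, pvals):
        adj = fdr_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        # permutation equivariance
        perm = np.random.default_rng(0).permutation(len(pvals))
        adj_perm = fdr_adjust(list(np.asarray(pvals)[perm]))
        assert np.allclose(adj_perm, adj[perm])

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestRanking:
    def test_four_way_tie_at_top_ranks_2_5(self):
        ranks = rank_results([0.001, 0.001, 0.001, 0.001, 0.5, 0.7])
        assert list(ranks[:4]) == [2.5] * 4
        assert list(ranks[4:]) == [5.0, 6.0]

    def test_strictly_increasing_gives_1_to_n(self):
        assert list(rank_results([0.1, 0.2, 0.3])) == [1.0, 2.0, 3.0]

    def test_pair_tie(self):
        assert list(rank_results([0.1, 0.1, 0.5])) == [1.5, 1.5, 3.0]

    def test_mapping_form(self):
        ranks = rank_results([("a", 0.2), ("b", 0.1)])
        assert ranks == {"a": 2.0, "b": 1.0}

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_rank_sum_conservation(self, vals):
        n = len(vals)
        assert sum(rank_results(vals)) == pytest.approx(n * (n + 1) / 2)


class TestEndToEnd:
    def _three_cdt_net(self):
        edges = (
            [Edge("DOM", f"g{i}", 1) for i in range(6)]
            + [Edge("X", "g0", -1), Edge("X", "g1", 1)]
            + [Edge("Y", "g2", -1), Edge("Y", "g3", -1)]
        )
        de = [DEGene(f"g{i}", 1, 1.0, 0.01) for i in range(6)]
        return label_edges(build_overlap(KnowledgeBase(edges=edges), de))

    def test_dominant_h1_cdt_attains_min_p(self):
        net = self._three_cdt_net()
        results = run_pure(net)
        assert len(results) == 3
        best = min(results, key=lambda r: r.p_h1)
        assert best.cdt_id == "DOM"

    def test_one_result_per_cdt_even_single_edge(self, tiny_kb, tiny_de_genes):
        net = label_edges(build_overlap(tiny_kb, tiny_de_genes))
        results = run_pure(net)
        assert [r.cdt_id for r in results] == net.cdts

    def test_sign_flip_swaps_hypotheses(self):
        net = self._three_cdt_net()
        flipped = net.flip_gene_signs()
        r1 = {r.cdt_id: r for r in run_pure(net)}
        r2 = {r.cdt_id: r for r in run_pure(flipped)}
        for c in r1:
            assert r1[c].p_h1 == pytest.approx(r2[c].p_h2, abs=1e-15)
            assert r1[c].p_h2 == pytest.approx(r2[c].p_h1, abs=1e-15)

    def test_calls_and_significant_set(self):
        net = self._three_cdt_net()
        results = run_pure(net, alpha=0.05)
        by_id = {r.cdt_id: r for r in results}
        for r in results:
            assert r.fdr_h1 >= r.p_h1 - 1e-15 and r.fdr_h2 >= r.p_h2 - 1e-15
        sig = significant_set(results, alpha=0.05)
        assert {r.cdt_id for r in sig} == {
            r.cdt_id for r in results if min(r.fdr_h1, r.fdr_h2) <= 0.05
        }

    def test_boundary_fdr_is_inclusive(self):
        results = [
            core.CDTTestResult("A", ContingencyTable(1, 0, 0, 1), 0.05, 1.0,
                               fdr_h1=0.05, fdr_h2=1.0),
        ]
        assert significant_set(results, alpha=0.05)[0].cdt_id == "A"

    def test_min_edges_filter(self, tiny_kb, tiny_de_genes):
        net = label_edges(build_overlap(tiny_kb, tiny_de_genes))
        assert len(run_pure(net, min_edges=2)) == 1  # only C1 has 2 overlap edges

    def test_pooled_fdr_mode(self):
        net = self._three_cdt_net()
        pooled = run_pure(net, fdr_mode="pooled")
        per = run_pure(net, fdr_mode="per_hypothesis")
        # same raw p-values either way
        assert [r.p_h1 for r in pooled] == [r.p_h1 for r in per]
        # pooled correction is at least as severe (2x the family size)
        for rp, rq in zip(pooled, per):
            assert rp.fdr_h1 >= rq.fdr_h1 - 1e-12

    def test_results_frame_is_deterministic(self, tiny_kb, tiny_de_genes):
        net = label_edges(build_overlap(tiny_kb, tiny_de_genes))
        f1 = core.results_to_frame(run_pure(net), tiny_kb.cdt_names)
        f2 = core.results_to_frame(run_pure(net), tiny_kb.cdt_names)
        assert f1.equals(f2)
        assert list(f1.columns[:3]) == ["cdt_id", "cdt_name", "n_edges"]
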