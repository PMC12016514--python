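"""Hypergeometric over-representation and multiple-testing correction."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exoscreen.datasets import go_rows_as_map, load_go_term_rows
from exoscreen.enrichment import (
    GOAnnotationMap,
    adjust,
    go_enrichment,
    hypergeom_tail,
)


def enumeration_tail(k, n, K, N):
    """Exact oracle: enumerate all C(N, n) draws as combinations."""
    universe = range(N)
    marked = set(range(K))
    favourable = sum(1 for draw in combinations(universe, n) if len(marked & set(draw)) >= k)
    return Fraction(favourable, comb(N, n))


def comb_tail(k, n, K, N):
    """Second oracle: closed-form sum of hypergeometric pmf terms."""
    return Fraction(
        sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(n, K) + 1)), comb(N, n)
    )


class TestHypergeomTail:
    def test_k_zero_is_one(self):
        assert hypergeom_tail(0, 10, 3, 100) == 1.0

    def test_small_worked_example(self):
        # N=10, K=5, n=4, k=4: C(5,4)*C(5,0)/C(10,4) = 5/210
        expected = enumeration_tail(4, 4, 5, 10)
        assert expected == Fraction(5, 210)
        assert hypergeom_tail(4, 4, 5, 10) == pytest.approx(float(expected), rel=1e-12)

    def test_matches_enumeration_for_small_universes(self):
        for N in (5, 8):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(n + 1):
                        assert hypergeom_tail(k, n, K, N) == pytest.approx(
                            float(enumeration_tail(k, n, K, N)), abs=1e-12
                        )

    def test_non_increasing_in_k(self):
        p = [hypergeom_tail(k, 20, 40, 200) for k in range(21)]
        assert all(a >= b for a, b in zip(p, p[1:]))

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            hypergeom_tail(5, 4, 10, 100)
        with pytest.raises(ValueError):
            hypergeom_tail(1, 2, 200, 100)

    def test_published_row_bound(self):
        # the printed adjusted p for the 15/90 vs 346/7166 row is 0.009;
        # any valid correction can only raise the raw p
        assert hypergeom_tail(15, 90, 346, 7166) <= 0.009


class TestAdjust:
    def test_single_p_unchanged(self):
        for method in ("bonferroni", "bh"):
            assert adjust([0.03], method)[0] == pytest.approx(0.03)

    def test_bonferroni_definition(self):
        assert adjust([0.01, 0.04], "bonferroni").tolist() == pytest.approx([0.02, 0.08])
        assert adjust([0.9, 0.8], "bonferroni").max() == 1.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bh_matches_stepup_oracle(self, p_values):
        p = np.asarray(p_values)
        got = adjust(p, "bh")
        # brute-force BH step-up with monotonicity enforcement
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running = 1.0
        for rank_from_top in range(m - 1, -1, -1):
            i = order[rank_from_top]
            running = min(running, p[i] * m / (rank_from_top + 1))
            adj[i] = running
        assert got == pytest.approx(adj, abs=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            adjust([0.5, 1.5])


def _padded_universe(core, size=7166):
    filler = {f"pad{i:05d}" for i in range(size - len(core))}
    return set(core) | filler


class TestGoEnrichment:
    def test_published_table_fixture_counts(self):
        rows = load_go_term_rows()
        term_map = go_rows_as_map(rows)
        pdr1_union = frozenset().union(
            *(genes for term, genes in term_map.items() if term != "Small molecule metabolic process")
        )
        universe = _padded_universe(frozenset().union(*term_map.values()))
        go_map = GOAnnotationMap(terms=term_map, universe=frozenset(universe))
        results = {r.term: r for r in go_enrichment(pdr1_union, go_map)}
        assert results["Small molecule biosynthetic process"].k == 15

    def test_targets_equal_term_genes_has_minimal_p(self):
        universe = {f"g{i}" for i in range(200)}
        terms = {
            "hit": frozenset(f"g{i}" for i in range(10)),
            "other": frozenset(f"g{i}" for i in range(50, 80)),
        }
        go_map = GOAnnotationMap(terms=terms, universe=frozenset(universe))
        results = go_enrichment(set(terms["hit"]), go_map)
        assert results[0].term == "hit"
        assert results[0].p_raw == min(r.p_raw for r in results)

    def test_planted_enrichment_recovered(self):
        from exoscreen.simulate import simulate_go_map

        universe = [f"g{i:03d}" for i in range(200)]
        targets = universe[:20]
        n_flagged = 0
        n_terms = 0
        for seed in range(10):
            go_map, truth = simulate_go_map(
                universe, targets, n_enriched=3, enrichment_factor=5.0, seed=seed
            )
            results = {r.term: r for r in go_enrichment(set(targets), go_map, alpha=0.1)}
            n_terms += len(truth)
            n_flagged += sum(1 for t in truth if t in results and results[t].enriched)
        assert n_flagged / n_terms >= 0.8  # 5x over-representation is usually detected

    def test_k_zero_terms_excluded_from_family(self):
        universe = frozenset(f"g{i}" for i in range(100))
        hit = frozenset(f"g{i}" for i in range(5))
        miss = frozenset(f"g{i}" for i in range(50, 55))
        one = GOAnnotationMap(terms={"hit": hit}, universe=universe)
        two = GOAnnotationMap(terms={"hit": hit, "miss": miss}, universe=universe)
        r1 = go_enrichment(set(hit), one)
        r2 = go_enrichment(set(hit), two)
        assert len(r2) == 1  # the k=0 term does not appear
        assert r2[0].p_adj == pytest.approx(r1[0].p_adj)  # nor does it inflate m

    def test_targets_outside_universe_dropped_with_warning(self):
        universe = frozenset(f"g{i}" for i in range(20))
        go_map = GOAnnotationMap(
            terms={"t": frozenset(["g1", "g2"])}, universe=universe
        )
        with pytest.warns(RuntimeWarning, match="outside the universe"):
            results = go_enrichment({"g1", "nope"}, go_map)
        assert results[0].n == 1

    def test_map_validation(self):
        with pytest.raises(ValueError):
            GOAnnotationMap(terms={"t": frozenset()}, universe=frozenset({"g"}))
        with pytest.raises(ValueError):
            GOAnnotationMap(terms={"t": frozenset({"x"})}, universe=frozenset({"g"}))

    def test_from_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "go.tsv"
        p.write_text("T1\tg1\nT1\tg2\nT2\tg2\n")
        go_map = GOAnnotationMap.from_tsv(str(p))
        assert go_map.terms == {"T1": frozenset({"g1", "g2"}), "T2": frozenset({"g2"})}
        assert go_map.universe == frozenset({"g1", "g2"})
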