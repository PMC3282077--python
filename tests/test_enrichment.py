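import numpy as np
import pytest

from txrev.enrichment import enrich, hypergeom_tail
from txrev.io import GeneSetCollection

from conftest import hypergeom_enumeration_oracle


class TestHypergeomTail:
    def test_full_overlap_closed_form(self):
        # drawing all 3 special items in 3 draws from 10: 1 / C(10,3) = 1/120
        assert hypergeom_tail(3, 3, 3, 10) == pytest.approx(1 / 120)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_tail(0, 5, 5, 20) == 1.0

    def test_single_draw_single_hit(self):
        assert hypergeom_tail(1, 1, 5, 10) == pytest.approx(0.5)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(4, 3, 5, 10)  # overlap > query
        with pytest.raises(ValueError):
            hypergeom_tail(1, 2, 11, 10)  # set larger than universe

    def test_monotone_decreasing_in_overlap(self):
        ps = [hypergeom_tail(k, 20, 30, 100) for k in range(0, 21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("N", [5, 8])
    def test_matches_enumeration_on_small_universes(self, N):
        for K in range(0, N + 1):
            for n in range(0, N + 1):
                for k in range(0, min(n, K) + 1):
                    assert hypergeom_tail(k, n, K, N) == pytest.approx(
                        hypergeom_enumeration_oracle(k, n, K, N), abs=1e-12
                    )


def _random_collection(rng, universe, n_sets=20, size=50, planted=None):
    sets = {}
    if planted is not None:
        sets["PLANTED"] = frozenset(planted)
    for i in range(n_sets):
        sets[f"DECOY_{i}"] = frozenset(rng.choice(universe, size=size, replace=False))
    return GeneSetCollection(sets)


class TestEnrich:
    def test_planted_set_significant_decoys_not(self):
        rng = np.random.default_rng(6)
        universe = [f"G{i}" for i in range(10_000)]
        planted = universe[:50]
        query = set(universe[:20]) | set(rng.choice(universe[50:], 280, replace=False))
        coll = _random_collection(rng, np.array(universe), n_sets=99, planted=planted)
        res = enrich(query, coll, set(universe))
        sig = set(res.significant["set_name"])
        assert "PLANTED" in sig
        assert len(sig - {"PLANTED"}) <= 1

    def test_min_overlap_rule_dominates_tiny_q(self):
        universe = {f"G{i}" for i in range(1000)}
        coll = GeneSetCollection({"S": frozenset(f"G{i}" for i in range(8))})
        query = {f"G{i}" for i in range(4)}  # overlap 4 of 8, hugely enriched
        res = enrich(query, coll, universe)
        row = res.table.iloc[0]
        assert row["q"] < 1e-6 and not row["significant"]

    def test_size_filters_measured_in_universe(self):
        universe = {f"G{i}" for i in range(100)}
        coll = GeneSetCollection(
            {
                "TOO_SMALL": frozenset(f"G{i}" for i in range(6)),
                "SHRINKS_BELOW": frozenset(list(universe)[:6] + ["X1", "X2", "X3"]),
                "OK": frozenset(f"G{i}" for i in range(20)),
            }
        )
        res = enrich({f"G{i}" for i in range(10)}, coll, universe, min_size=8)
        assert set(res.table["set_name"]) == {"OK"}

    def test_query_genes_outside_universe_dropped(self):
        universe = {f"G{i}" for i in range(50)}
        coll = GeneSetCollection({"S": frozenset(f"G{i}" for i in range(10))})
        res = enrich({"G1", "G2", "NOT_ON_ARRAY"}, coll, universe, min_size=5)
        assert res.query_size == 2

    def test_empty_universe_rejected(self):
        coll = GeneSetCollection({"S": frozenset({"A"})})
        with pytest.raises(ValueError):
            enrich({"A"}, coll, set())

    def test_collection_order_does_not_change_q_values(self):
        rng = np.random.default_rng(12)
        universe = [f"G{i}" for i in range(500)]
        coll = _random_collection(rng, np.array(universe), n_sets=10, size=30)
        reversed_coll = GeneSetCollection(dict(reversed(list(coll.sets.items()))))
        query = set(rng.choice(universe, 60, replace=False))
        a = enrich(query, coll, set(universe)).table.set_index("set_name")["q"]
        b = enrich(query, reversed_coll, set(universe)).table.set_index("set_name")["q"]
        assert (a.sort_index() == b.sort_index()).all()
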