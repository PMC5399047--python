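"""Pathway layer: GMT parsing round trips, exact Fisher tails against a
direct hypergeometric summation oracle, the four-gene pathway BMD rule, and
the shared-gene / membership-count statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txpod.pathways import (
    PathwayDB,
    fisher_enrichment,
    gene_membership_counts,
    load_gmt,
    pathway_bmds,
    regulator_significance,
    shared_gene_counts,
    write_gmt,
)


def _hypergeom_tail_oracle(overlap, N, K, n):
    """Direct summation of P(X >= overlap)."""
    total = 0.0
    for x in range(overlap, min(K, n) + 1):
        total += (
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        )
    return total


class TestGmt:
    def test_duplicate_members_deduplicated(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("P1\tdesc\tg1\tg2\tg2\n")
        assert load_gmt(p) == {"P1": {"g1", "g2"}}

    def test_two_field_line_reports_line_number(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("P1\tdesc\tg1\nBAD\tonlydesc\n")
        with pytest.raises(ValueError, match="2"):
            load_gmt(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            load_gmt(p)

    def test_round_trip(self, tmp_path):
        sets = {"A": {"g1", "g2"}, "B": {"g2", "g3", "g4"}}
        p = tmp_path / "rt.gmt"
        write_gmt(sets, p)
        assert load_gmt(p) == sets


class TestFisher:
    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(100)}
        assert fisher_enrichment({"g0", "g1"}, {"g50", "g51"}, universe) == pytest.approx(1.0)

    def test_pathway_equal_to_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(30)}
        assert fisher_enrichment({"g0"}, universe, universe) == pytest.approx(1.0)

    def test_matches_direct_summation(self):
        universe = [f"g{i}" for i in range(1000)]
        pathway = set(universe[:50])
        selected = set(universe[:15]) | set(universe[500:585])  # overlap 15, n=100
        p = fisher_enrichment(selected, pathway, universe)
        oracle = _hypergeom_tail_oracle(15, 1000, 50, 100)
        assert p == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(
        N=st.integers(20, 2000),
        data=st.data(),
    )
    def test_oracle_property_on_random_tables(self, N, data):
        K = data.draw(st.integers(1, min(N, 80)))
        n = data.draw(st.integers(1, min(N, 80)))
        universe = [f"g{i}" for i in range(N)]
        rng = np.random.default_rng(N * 7919 + K * 31 + n)
        pathway = set(rng.choice(universe, size=K, replace=False))
        selected = set(rng.choice(universe, size=n, replace=False))
        overlap = len(pathway & selected)
        p = fisher_enrichment(selected, pathway, universe)
        assert p == pytest.approx(_hypergeom_tail_oracle(overlap, N, K, n), abs=1e-12)

    def test_monotone_in_selected_members(self):
        universe = [f"g{i}" for i in range(200)]
        pathway = set(universe[:20])
        selected = set(universe[10:40])
        p_before = fisher_enrichment(selected, pathway, universe)
        p_after = fisher_enrichment(selected | {"g0"}, pathway, universe)
        assert p_after <= p_before

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment({"a"}, {"a"}, set())


class TestPathwayBmds:
    def _db(self, sets, universe):
        return PathwayDB.from_sets(sets, universe)

    def test_fewer_than_four_genes_gets_no_bmd(self, ):
        table = pd.DataFrame({"gene": ["a", "b", "c"], "bmd": [1.0, 2.0, 3.0],
                              "bmdl": [0.5, 1.0, 1.5]})
        db = self._db({"P": {"a", "b", "c"}}, {"a", "b", "c"})
        out = pathway_bmds(table, db)
        assert np.isnan(out["bmd"].iloc[0])
        assert out["n_with_bmd"].iloc[0] == 3

    def test_four_genes_mean(self):
        table = pd.DataFrame({"gene": list("abcd"), "bmd": [1.0, 2.0, 3.0, 4.0],
                              "bmdl": [0.5, 1.0, 1.5, 2.0]})
        db = self._db({"P": set("abcd")}, set("abcd"))
        out = pathway_bmds(table, db)
        assert out["bmd"].iloc[0] == pytest.approx(2.5)
        assert out["bmdl"].iloc[0] == pytest.approx(1.25)

    def test_partition_weighted_mean_identity(self, rng):
        genes = [f"g{i}" for i in range(40)]
        bmds = rng.uniform(1, 50, size=40)
        table = pd.DataFrame({"gene": genes, "bmd": bmds, "bmdl": bmds / 2})
        sets = {f"P{j}": set(genes[j * 8:(j + 1) * 8]) for j in range(5)}
        db = self._db(sets, genes)
        out = pathway_bmds(table, db)
        weighted = np.sum(out["bmd"] * out["n_with_bmd"]) / np.sum(out["n_with_bmd"])
        assert weighted == pytest.approx(bmds.mean())

    def test_gene_order_invariance(self, rng):
        genes = [f"g{i}" for i in range(10)]
        bmds = rng.uniform(1, 9, size=10)
        table = pd.DataFrame({"gene": genes, "bmd": bmds, "bmdl": bmds / 2})
        shuffled = table.sample(frac=1.0, random_state=1)
        db = self._db({"P": set(genes)}, genes)
        a = pathway_bmds(table, db)["bmd"].iloc[0]
        b = pathway_bmds(shuffled, db)["bmd"].iloc[0]
        assert a == pytest.approx(b)


class TestSharedGenes:
    def test_disjoint_pathways_share_nothing(self):
        counts = shared_gene_counts({"A": {"x", "y"}, "B": {"u", "v"}})
        assert counts["A"] == 0 and counts["B"] == 0

    def test_hand_enumerated_fixture(self):
        counts = shared_gene_counts(
            {"P1": {"a", "b", "c"}, "P2": {"b", "c", "d"}, "P3": {"c", "e"}}
        )
        assert counts["P1"] == 2
        assert counts["P2"] == 2
        assert counts["P3"] == 1

    def test_universal_gene_increments_every_count(self):
        base = {"P1": {"a", "b"}, "P2": {"c", "d"}, "P3": {"e", "f"}}
        before = shared_gene_counts(base)
        withu = shared_gene_counts({k: v | {"u"} for k, v in base.items()})
        for k in base:
            assert withu[k] == before[k] + 1

    def test_single_pathway_rejected(self):
        with pytest.raises(ValueError):
            shared_gene_counts({"A": {"x"}})


class TestGeneMembership:
    def test_gene_in_no_pathway_counts_zero(self):
        counts = gene_membership_counts(["z"], {"P": {"a"}})
        assert counts["z"] == 0

    def test_bipartite_fixture_equals_incidence_sums(self, rng):
        genes = [f"g{i}" for i in range(12)]
        sets = {
            f"P{j}": {g for g in genes if rng.random() < 0.4} for j in range(6)
        }
        counts = gene_membership_counts(genes, sets)
        for g in genes:
            assert counts[g] == sum(g in s for s in sets.values())

    def test_single_membership_everywhere(self):
        counts = gene_membership_counts(["a", "b"], {"P1": {"a"}, "P2": {"b"}})
        assert counts["a"] == 1 and counts["b"] == 1


class TestRegulators:
    def test_disjoint_targets_give_p_one(self):
        universe = {f"g{i}" for i in range(50)}
        db = PathwayDB.from_sets({}, universe, {"R": {"g40", "g41"}})
        out = regulator_significance({"g0", "g1"}, db)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_identical_target_sets_get_identical_p(self):
        universe = {f"g{i}" for i in range(50)}
        db = PathwayDB.from_sets(
            {}, universe, {"R1": {"g0", "g1", "g2"}, "R2": {"g0", "g1", "g2"}}
        )
        out = regulator_significance({"g0", "g1"}, db).set_index("regulator")
        assert out.loc["R1", "p"] == out.loc["R2", "p"]

    def test_missing_annotations_raise(self):
        db = PathwayDB.from_sets({}, {"a"})
        with pytest.raises(ValueError):
            regulator_significance({"a"}, db)
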