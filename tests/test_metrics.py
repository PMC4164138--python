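"""Node distance, distribution index, Venn groups, appearance order and
persistence metrics."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from gocensus.census import CensusMatrix
from gocensus.metrics import (distribution_index, group_appearance,
                              node_distance, persistence_metrics,
                              term_evo_records, venn_groups,
                              export_scatter_tables)
from gocensus.parsimony import RootedTree


def _rooted(newick, taxa):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return RootedTree(tree=tree, taxa=tuple(taxa), length=0)


def _census(grid, kingdoms, terms=None):
    genomes = [f"g{i}" for i in range(len(grid))]
    terms = terms or [f"GO:{j}" for j in range(len(grid[0]))]
    data = pd.DataFrame(grid, index=genomes, columns=terms)
    return CensusMatrix(data, pd.Series(kingdoms, index=genomes))


class TestNodeDistance:
    def test_pectinate_hand_count(self):
        nd = node_distance(_rooted("(A,(B,(C,D)));", "ABCD"))
        assert nd == {"A": 0.0, "B": 0.5, "C": 1.0, "D": 1.0}

    def test_taxon_count_variant_divides_by_n(self):
        nd = node_distance(_rooted("(A,(B,(C,D)));", "ABCD"),
                           normalization="taxon_count")
        assert nd == {"A": 0.0, "B": 0.25, "C": 0.5, "D": 0.5}

    def test_two_tip_tree_degenerates_to_zero(self):
        nd = node_distance(_rooted("(A,B);", "AB"))
        assert nd == {"A": 0.0, "B": 0.0}

    def test_unrooted_tree_rejected(self):
        tree = dendropy.Tree.get(data="(A,(B,(C,D)));", schema="newick")
        tree.is_rooted = False
        with pytest.raises(ValueError, match="rooted"):
            node_distance(RootedTree(tree=tree, taxa=tuple("ABCD"), length=0))

    def test_extremes_with_root_adjacent_tip(self):
        nd = node_distance(_rooted("(A,((B,E),(C,(D,(F,G)))));", "ABCDEFG"))
        assert nd["A"] == 0.0
        assert max(nd.values()) == 1.0
        assert nd["F"] == nd["G"] == 1.0


class TestDistributionIndex:
    def test_ubiquitous_term_scores_one(self):
        c = _census([[1, 2], [3, 1], [2, 0]], ["A", "B", "E"])
        f = distribution_index(c)
        assert f["GO:0"] == 1.0
        assert f["GO:1"] == pytest.approx(2 / 3)

    def test_subset_restriction(self):
        c = _census([[1, 0], [1, 2], [1, 2]], ["A", "B", "E"])
        f_a = distribution_index(c, ["g0"])
        assert f_a["GO:1"] == 0.0

    def test_empty_subset_errors(self):
        c = _census([[1]], ["A"])
        with pytest.raises(ValueError):
            distribution_index(c, [])

    def test_global_f_is_convex_combination_of_kingdom_f(self, sim_census):
        f_all = distribution_index(sim_census)
        sk = sim_census.superkingdom
        combo = pd.Series(0.0, index=f_all.index)
        for k in ("A", "B", "E"):
            rows = sk[sk == k].index.tolist()
            combo += distribution_index(sim_census, rows) * len(rows)
        combo /= len(sim_census.genomes)
        assert np.allclose(f_all, combo)


class TestVennGroups:
    def test_single_archaeon_presence(self):
        c = _census([[1, 1], [0, 1], [0, 1]], ["A", "B", "E"])
        label, sizes = venn_groups(c)
        assert label["GO:0"] == "A"
        assert label["GO:1"] == "ABE"
        assert sizes["A"] == 1 and sizes["ABE"] == 1

    def test_sizes_partition_all_terms(self, sim_census):
        _, sizes = venn_groups(sim_census)
        assert sum(sizes.values()) == len(sim_census.terms)

    def test_all_zero_column_rejected(self):
        data = pd.DataFrame({"GO:0": [0, 0]}, index=["g0", "g1"])
        c = CensusMatrix.__new__(CensusMatrix)
        c.data = data
        c.superkingdom = pd.Series(["A", "B"], index=["g0", "g1"])
        with pytest.raises(ValueError, match="no presence"):
            venn_groups(c)


class TestGroupAppearance:
    def _records(self, groups_nd):
        rows = []
        for grp, vals in groups_nd.items():
            for i, v in enumerate(vals):
                rows.append({"term": f"GO:{grp}{i}", "nd": v,
                             "f_global": 0.5, "venn_group": grp})
        return pd.DataFrame(rows)

    def test_small_group_has_no_outliers(self):
        summaries, _, _ = group_appearance(
            self._records({"ABE": [0.1, 0.2, 0.3]}))
        assert summaries[0].min_nd == pytest.approx(0.1)
        assert summaries[0].outliers == []

    def test_low_straggler_flagged_by_iqr_rule(self):
        summaries, _, _ = group_appearance(
            self._records({"AB": [0.08, 0.5, 0.52, 0.55, 0.6]}))
        s = summaries[0]
        assert [t for t, _ in s.outliers] == ["GO:AB0"]
        assert s.min_nd == pytest.approx(0.08)
        assert s.min_nd_no_outliers == pytest.approx(0.5)

    def test_appearance_order_excludes_outliers(self):
        records = self._records({
            "ABE": [0.0, 0.05, 0.1],
            "BE": [0.3, 0.32, 0.35],
            # raw minimum is earlier than BE, but it is an outlier
            "AB": [0.08, 0.5, 0.52, 0.55, 0.6]})
        _, order, order_raw = group_appearance(records)
        assert order == ["ABE", "BE", "AB"]
        assert order_raw == ["ABE", "AB", "BE"]

    def test_missing_nd_rejected(self):
        df = self._records({"A": [0.1]})
        df.loc[0, "nd"] = np.nan
        with pytest.raises(ValueError):
            group_appearance(df)


class TestPersistence:
    def test_hand_computed_row(self):
        c = _census([[2, 1]], ["B"])
        p = persistence_metrics(c).iloc[0]
        assert (p["economy"], p["flexibility"]) == (2, 3)
        assert p["robustness"] == pytest.approx(1.5)

    def test_single_copies_give_unit_robustness(self):
        c = _census([[1, 1, 1]], ["E"])
        assert persistence_metrics(c).iloc[0]["robustness"] == 1.0

    def test_empty_genome_flagged(self):
        c = _census([[1, 1], [0, 0]], ["A", "B"])
        p = persistence_metrics(c)
        row = p[p["organism_id"] == "g1"].iloc[0]
        assert row["economy"] == 0
        assert bool(row["robustness_undefined"])
        assert np.isnan(row["robustness"])

    def test_flexibility_at_least_economy(self, sim_census):
        p = persistence_metrics(sim_census)
        assert (p["flexibility"] >= p["economy"]).all()


class TestExports:
    def test_tables_deterministic_and_complete(self, sim_census, tmp_path):
        nd = {t: i / max(1, len(sim_census.terms) - 1)
              for i, t in enumerate(sim_census.terms)}
        records = term_evo_records(sim_census, nd)
        assert len(records) == len(sim_census.terms)
        summaries, _, _ = group_appearance(records)
        persistence = persistence_metrics(sim_census)
        d1, d2 = tmp_path / "one", tmp_path / "two"
        p1 = export_scatter_tables(records, summaries, persistence, str(d1))
        p2 = export_scatter_tables(records, summaries, persistence, str(d2))
        for key in p1:
            assert open(p1[key]).read() == open(p2[key]).read()

    def test_per_kingdom_f_recomputed_by_hand(self, sim_census):
        records = term_evo_records(sim_census, dict.fromkeys(
            sim_census.terms, 0.0)).set_index("term")
        sk = sim_census.superkingdom
        term = sim_census.terms[0]
        rows = sk[sk == "B"].index
        expected = (sim_census.data.loc[rows, term] > 0).mean()
        assert records.loc[term, "f_B"] == pytest.approx(expected)
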