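from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from cernet.cerna import (
    CIRC_MI,
    MI_M,
    CeRNANetwork,
    TargetTable,
    assemble_network,
    derive_co_set,
    direction_consistency_filter,
    intersect_database_support,
    load_target_table,
    normalize_id,
)
from cernet.dge import ValidationError
from cernet.io import TARGET_COLUMNS


def table(rows, kind=MI_M) -> TargetTable:
    return TargetTable(pd.DataFrame(rows, columns=TARGET_COLUMNS), kind)


class TestTargetTable:
    def test_deduplication(self):
        t = table([("a", "b", "db1"), ("a", "b", "db1"), ("a", "c", "db1")])
        assert len(t) == 2

    def test_load_tsv_with_duplicate(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "source_id\ttarget_id\tdatabase\n"
            "a\tb\tdb1\n"
            "a\tb\tdb1\n"
            "a\tc\tdb2\n"
        )
        assert len(load_target_table(path, MI_M)) == 2

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("source_id\ttarget_id\tdatabase\n")
        assert len(load_target_table(path, CIRC_MI)) == 0

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("source_id\ttarget_id\tdatabase\na\tb\tdb1\na\tb\n")
        with pytest.raises(ValidationError, match=":3"):
            load_target_table(path, MI_M)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("from\tto\tdb\na\tb\tdb1\n")
        with pytest.raises(ValidationError, match="header"):
            load_target_table(path, MI_M)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            table([("a", "b", "db1")], kind="nonsense")

    def test_fixture_pair_count_matches_truth(self, default_bundle):
        truth_pairs = set(default_bundle.truth.target_pairs["mi_m"])
        emitted = set(
            map(tuple, default_bundle.mi_m.pairs.itertuples(index=False))
        )
        assert emitted == truth_pairs


class TestDatabaseSupport:
    def test_all_three_rule_keeps_pair(self):
        t = table([("a", "b", "dbA"), ("a", "b", "dbB"), ("a", "b", "dbC")])
        assert intersect_database_support(t, 3) == {("a", "b")}

    def test_distinct_tags_required(self):
        # {dbA, dbA, dbB} has only two distinct tags
        t = table([("a", "b", "dbA"), ("a", "b", "dbA"), ("a", "b", "dbB")])
        assert intersect_database_support(t, 3) == set()

    def test_min_databases_one_is_union(self):
        t = table([("a", "b", "dbA"), ("c", "d", "dbB")])
        assert intersect_database_support(t, 1) == {("a", "b"), ("c", "d")}

    def test_invalid_min_databases(self):
        with pytest.raises(ValidationError):
            intersect_database_support(table([("a", "b", "x")]), 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_table_vs_groupby_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = [
            (f"s{rng.integers(5)}", f"t{rng.integers(5)}", f"db{rng.integers(4)}")
            for _ in range(60)
        ]
        t = table(rows)
        # brute-force: tally distinct tags per pair with plain dicts
        tags = defaultdict(set)
        for s, tg, db in set(rows):
            tags[(s, tg)].add(db)
        for min_db in (1, 2, 3, 4):
            expected = {pair for pair, dbs in tags.items() if len(dbs) >= min_db}
            assert intersect_database_support(t, min_db) == expected

    def test_monotone_in_min_databases(self, default_bundle):
        t = default_bundle.mi_m
        s3 = intersect_database_support(t, 3)
        s2 = intersect_database_support(t, 2)
        s1 = intersect_database_support(t, 1)
        assert s3 <= s2 <= s1


class TestDeriveCoSet:
    def test_plain_intersection(self):
        assert derive_co_set({"a", "b", "c"}, {"b", "c", "d"}) == {"b", "c"}

    def test_disjoint_empty(self):
        assert derive_co_set({"a"}, {"b"}) == set()

    def test_planted_mirnas_in_co_set(self, clean_bundle):
        truth = clean_bundle.truth
        deg_mi = set(truth.planted_degs["mir"])
        circ_targets = {mi for _, mi, _ in truth.target_pairs["circ_mi"]}
        co = derive_co_set(deg_mi, circ_targets)
        assert {mi for _, mi, _ in truth.planted_axes} <= co


class TestAssembleNetwork:
    def test_one_circ_one_mi_two_m(self):
        net = assemble_network(
            {"c1"}, {"mi1"}, {"m1", "m2"},
            {("c1", "mi1")},
            {("mi1", "m1"), ("mi1", "m2")},
        )
        assert net.triplets == [("c1", "mi1", "m1"), ("c1", "mi1", "m2")]
        assert (len(net.ce_circrnas), len(net.ce_mirnas), len(net.ce_mrnas)) == (1, 1, 2)

    def test_mirna_without_mrna_target_absent(self):
        net = assemble_network(
            {"c1"}, {"mi1", "mi2"}, {"m1"},
            {("c1", "mi1"), ("c1", "mi2")},
            {("mi1", "m1")},
        )
        assert "mi2" not in net.ce_mirnas
        assert net.triplets == [("c1", "mi1", "m1")]

    def test_non_deg_nodes_excluded(self):
        net = assemble_network(
            {"c1"}, {"mi1"}, {"m1"},
            {("c1", "mi1"), ("c2", "mi1")},
            {("mi1", "m1"), ("mi1", "m9")},
        )
        assert net.ce_circrnas == {"c1"}
        assert net.ce_mrnas == {"m1"}

    def test_fixture_recovers_planted_axes_exactly(self, clean_bundle):
        truth = clean_bundle.truth
        circ_mi = intersect_database_support(clean_bundle.circ_mi, 1)
        mi_m = intersect_database_support(clean_bundle.mi_m, 3)
        net = assemble_network(
            set(truth.planted_degs["circ"]),
            set(truth.planted_degs["mir"]),
            set(truth.planted_degs["m"]),
            circ_mi, mi_m,
        )
        assert sorted(net.triplets) == sorted(truth.planted_axes)

    def test_node_set_completeness_after_triplet_removal(self, default_bundle):
        truth = default_bundle.truth
        circ_mi = intersect_database_support(default_bundle.circ_mi, 1)
        mi_m = intersect_database_support(default_bundle.mi_m, 3)
        net = assemble_network(
            set(truth.planted_degs["circ"]),
            set(truth.planted_degs["mir"]),
            set(truth.planted_degs["m"]),
            circ_mi, mi_m,
        )
        for drop in range(len(net.triplets)):
            rest = CeRNANetwork([t for i, t in enumerate(net.triplets) if i != drop])
            nodes = rest.ce_circrnas | rest.ce_mirnas | rest.ce_mrnas
            in_triplets = {n for t in rest.triplets for n in t}
            assert nodes == in_triplets  # no orphans by construction


class TestDirectionFilter:
    def _net(self):
        return CeRNANetwork([("c1", "mi1", "m1"), ("c2", "mi2", "m2")])

    def test_sponge_pattern_kept(self):
        directions = {"c1": "down", "mi1": "up", "m1": "down",
                      "c2": "down", "mi2": "down", "m2": "down"}
        filtered = direction_consistency_filter(self._net(), directions)
        assert filtered.triplets == [("c1", "mi1", "m1")]

    def test_up_down_up_kept(self):
        directions = {"c1": "up", "mi1": "down", "m1": "up",
                      "c2": "up", "mi2": "up", "m2": "up"}
        filtered = direction_consistency_filter(self._net(), directions)
        assert filtered.triplets == [("c1", "mi1", "m1")]

    def test_missing_direction_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            direction_consistency_filter(self._net(), {"c1": "down"})

    def test_planted_axes_survive_filter(self, clean_bundle):
        truth = clean_bundle.truth
        directions = {}
        for layer_dirs in truth.planted_degs.values():
            directions.update(layer_dirs)
        net = CeRNANetwork(list(truth.planted_axes))
        filtered = direction_consistency_filter(net, directions)
        assert sorted(filtered.triplets) == sorted(truth.planted_axes)


class TestExports:
    def test_graph_layers_and_edges(self):
        net = CeRNANetwork([("c1", "mi1", "m1")], {"c1": "down"})
        g = net.to_graph()
        assert g.nodes["c1"]["layer"] == "circRNA"
        assert g.nodes["mi1"]["layer"] == "miRNA"
        assert g.nodes["m1"]["layer"] == "mRNA"
        assert g.has_edge("c1", "mi1") and g.has_edge("mi1", "m1")
        assert not g.has_edge("c1", "m1")

    def test_graphml_and_sif_roundtrip(self, tmp_path):
        import networkx as nx

        net = CeRNANetwork([("c1", "mi1", "m1"), ("c1", "mi1", "m2")])
        gml = tmp_path / "net.graphml"
        net.write_graphml(gml)
        loaded = nx.read_graphml(gml)
        assert set(loaded.nodes) == {"c1", "mi1", "m1", "m2"}
        sif = tmp_path / "net.sif"
        net.write_sif(sif)
        lines = sif.read_text().strip().splitlines()
        assert "c1\tsponges\tmi1" in lines
        assert "mi1\ttargets\tm2" in lines

    def test_node_table_directions(self):
        net = CeRNANetwork(
            [("c1", "mi1", "m1")], {"c1": "down", "mi1": "up", "m1": "down"}
        )
        nt = net.node_table().set_index("id")
        assert nt.loc["mi1", "direction"] == "up"


class TestNormalizeId:
    def test_trims_and_folds_mir_prefix(self):
        assert normalize_id("  hsa-MIR-1271-5p ") == "hsa-mir-1271-5p"

    def test_plain_ids_untouched(self):
        assert normalize_id("IGF1R") == "IGF1R"
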