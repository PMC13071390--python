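"""Knowledge-graph loading, path queries, meta-path grouping, pagination."""

import itertools

import numpy as np
import pandas as pd
import pytest

from repurscore import (
    EntityLookupError,
    ValidationError,
    distribution,
    filter_group,
    group_meta_paths,
    load_kg,
    paginate,
    query_paths,
)
from repurscore.kg_paths import KG_COLUMNS, path_signature


def kg_frame(rows):
    """rows: (x_id, x_type, x_name, relation, y_id, y_type, y_name)"""
    return pd.DataFrame(rows, columns=KG_COLUMNS)


TOY = kg_frame([
    ("geneA", "gene/protein", "Gene A", "interacts", "geneB", "gene/protein", "Gene B"),
    ("geneB", "gene/protein", "Gene B", "associated", "dis", "disease", "Psoriasis"),
    ("geneA", "gene/protein", "Gene A", "interacts", "geneC", "gene/protein", "Gene C"),
    ("geneC", "gene/protein", "Gene C", "associated", "dis", "disease", "Psoriasis"),
])


def random_kg(rng, n_nodes=40, edge_prob=0.08):
    types = ["gene/protein", "pathway", "anatomy", "disease"]
    relations = ["assoc", "interacts", "expressed_in"]
    rows = []
    nodes = [(f"n{i}", types[i % 4], f"entity {i % 7}") for i in range(n_nodes)]
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < edge_prob:
            x, y = nodes[i], nodes[j]
            rel = str(rng.choice(relations))
            rows.append((x[0], x[1], x[2], rel, y[0], y[1], y[2]))
    if not rows:  # ensure a non-empty table
        x, y = nodes[0], nodes[1]
        rows.append((x[0], x[1], x[2], "assoc", y[0], y[1], y[2]))
    return kg_frame(rows)


def oracle_paths(df, sources, disease, max_extra_hops=0):
    """Exhaustive depth-bounded DFS over node sequences, independent of the
    engine: the hop bound comes from a hand-rolled BFS, the enumeration from
    a hand-rolled DFS."""
    adj: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        adj.setdefault(r.x_id, set()).add(r.y_id)
        adj.setdefault(r.y_id, set()).add(r.x_id)

    # BFS from the disease for the minimum source-disease distance
    dist = {disease: 0}
    frontier = [disease]
    while frontier:
        nxt_frontier = []
        for node in frontier:
            for nxt in adj.get(node, ()):
                if nxt not in dist:
                    dist[nxt] = dist[node] + 1
                    nxt_frontier.append(nxt)
        frontier = nxt_frontier
    reachable = [s for s in sources if s in dist and s != disease and s in adj]
    if not reachable:
        return []
    bound = min(dist[s] for s in reachable) + max_extra_hops

    all_paths = []

    def dfs(node, path):
        if node == disease:
            all_paths.append(tuple(path))
            return
        if len(path) - 1 >= bound:
            return
        for nxt in adj.get(node, ()):
            if nxt not in path:
                dfs(nxt, path + [nxt])

    for s in reachable:
        dfs(s, [s])
    return sorted(all_paths)


class TestLoadKg:
    def test_shared_node_dedup(self):
        kg = load_kg(kg_frame(TOY.iloc[:2]))
        assert kg.g.number_of_nodes() == 3 and kg.g.number_of_edges() == 2

    def test_duplicate_row_dedupes_to_single_edge(self):
        df = kg_frame(pd.concat([TOY.iloc[:1]] * 2).values.tolist())
        kg = load_kg(df)
        assert kg.g.number_of_edges() == 1
        assert len(kg.g.edges["geneA", "geneB"]["relations"]) == 1

    def test_conflicting_node_attributes_rejected(self):
        bad = TOY.copy()
        bad.loc[2, "x_name"] = "renamed"
        with pytest.raises(ValidationError):
            load_kg(bad)

    def test_round_trip_identity_on_random_graph(self):
        rng = np.random.default_rng(2)
        df = random_kg(rng)
        kg = load_kg(df)
        kg2 = load_kg(kg.to_frame())
        pd.testing.assert_frame_equal(kg.to_frame(), kg2.to_frame())

    def test_polarity_column_preserved(self):
        df = TOY.copy()
        df["polarity"] = ["positive", "negative", "neutral", "positive"]
        kg = load_kg(df)
        res = query_paths(kg, ["geneA"], "dis")
        polarities = {e.polarity for p in res.paths for e in p.edges}
        assert polarities <= {"positive", "negative", "neutral"}

    def test_type_palette_unique_per_type(self):
        kg = load_kg(TOY)
        palette = kg.type_palette
        assert set(palette) == {"gene/protein", "disease"}
        assert len(set(palette.values())) == 2


class TestQueryPaths:
    def test_adjacent_source_single_hop(self):
        kg = load_kg(TOY)
        res = query_paths(kg, ["geneB"], "dis")
        assert [p.nodes for p in res.paths] == [("geneB", "dis")]
        assert res.min_length == 1

    def test_toy_two_length_two_paths(self):
        kg = load_kg(TOY)
        res = query_paths(kg, ["geneA"], "dis")
        assert sorted(p.nodes for p in res.paths) == [
            ("geneA", "geneB", "dis"), ("geneA", "geneC", "dis")
        ]

    def test_excluding_only_connected_source_is_error(self):
        kg = load_kg(TOY)
        with pytest.raises(EntityLookupError):
            query_paths(kg, ["geneA"], "dis", excluded=["geneA"])

    def test_exclusion_with_remaining_source(self):
        kg = load_kg(TOY)
        res = query_paths(kg, ["geneA", "geneB"], "dis", excluded=["geneA"])
        assert [p.nodes for p in res.paths] == [("geneB", "dis")]

    def test_unknown_disease_is_lookup_error(self):
        with pytest.raises(EntityLookupError):
            query_paths(load_kg(TOY), ["geneA"], "nope")

    def test_unreachable_disease_gives_empty_result(self):
        df = pd.concat([
            TOY.iloc[:1],
            kg_frame([("x", "anatomy", "X", "assoc", "dis", "disease", "P")]),
        ])
        kg = load_kg(df)
        res = query_paths(kg, ["geneA"], "dis")
        assert res.paths == [] and res.min_length is None

    def test_edge_direction_annotation(self):
        kg = load_kg(TOY)
        res = query_paths(kg, ["geneA"], "dis")
        for path in res.paths:
            for u, v, edge in zip(path.nodes, path.nodes[1:], path.edges):
                if edge.forward:
                    assert (edge.source_id, edge.target_id) == (u, v)
                else:
                    assert (edge.source_id, edge.target_id) == (v, u)

    def test_cap_sets_truncation_flag(self):
        kg = load_kg(TOY)
        res = query_paths(kg, ["geneA"], "dis", cap=1)
        assert res.truncated and len(res.paths) == 1

    @pytest.mark.parametrize("extra", [0, 1])
    def test_matches_exhaustive_dfs_on_random_graphs(self, extra):
        rng = np.random.default_rng(100 + extra)
        for _ in range(15):
            df = random_kg(rng, n_nodes=int(rng.integers(10, 45)))
            kg = load_kg(df)
            nodes = list(kg.g.nodes)
            sources = [n for n in nodes[:3]]
            disease = nodes[-1]
            expected = oracle_paths(df, sources, disease, max_extra_hops=extra)
            if not expected:
                continue
            res = query_paths(kg, sources, disease, max_extra_hops=extra)
            assert sorted({p.nodes for p in res.paths}) == expected
            lo = res.min_length
            assert all(lo <= p.length <= lo + extra for p in res.paths)


class TestMetaPaths:
    def test_identical_type_paths_group_together(self):
        kg = load_kg(TOY)
        res = query_paths(kg, ["geneA"], "dis")
        groups = group_meta_paths(kg, res.paths)
        assert len(groups) == 1 and groups[0].count == 2
        assert groups[0].signature == (
            "gene/protein", "interacts", "gene/protein", "associated", "disease"
        )

    def test_partition_properties_on_random_graphs(self):
        rng = np.random.default_rng(55)
        for _ in range(10):
            kg = load_kg(random_kg(rng))
            nodes = list(kg.g.nodes)
            try:
                res = query_paths(kg, nodes[:2], nodes[-1], max_extra_hops=1)
            except EntityLookupError:
                continue
            groups = group_meta_paths(kg, res.paths)
            assert sum(g.count for g in groups) == len(res.paths)
            seen = set()
            for g in groups:
                for p in g.paths:
                    assert path_signature(kg, p) == g.signature
                    assert (p.nodes, p.edges) not in seen
                    seen.add((p.nodes, p.edges))
            counts = [g.count for g in groups]
            assert counts == sorted(counts, reverse=True)

    def test_alternate_orders(self):
        rng = np.random.default_rng(7)
        kg = load_kg(random_kg(rng))
        nodes = list(kg.g.nodes)
        res = query_paths(kg, nodes[:3], nodes[-1], max_extra_hops=1)
        by_sig = group_meta_paths(kg, res.paths, order="signature")
        assert [g.signature for g in by_sig] == sorted(g.signature for g in by_sig)
        with pytest.raises(ValidationError):
            group_meta_paths(kg, res.paths, order="nope")


class TestFilterAndDistribution:
    @pytest.fixture()
    def group(self):
        kg = load_kg(TOY)
        res = query_paths(kg, ["geneA"], "dis")
        return kg, group_meta_paths(kg, res.paths)[0]

    def test_empty_query_returns_all(self, group):
        kg, g = group
        assert filter_group(g, 1, "", kg) == g.paths

    def test_single_entity_match(self, group):
        kg, g = group
        hits = filter_group(g, 1, "gene b", kg)
        assert [p.nodes for p in hits] == [("geneA", "geneB", "dis")]

    def test_no_hit_is_empty(self, group):
        kg, g = group
        assert filter_group(g, 1, "zzz", kg) == []

    def test_position_out_of_range(self, group):
        kg, g = group
        with pytest.raises(ValidationError):
            filter_group(g, 3, "", kg)
        with pytest.raises(ValidationError):
            distribution(g, -1, kg)

    def test_distribution_counting_oracle(self, group):
        kg, g = group
        dist = distribution(g, 1, kg)
        assert dist.entries == [("Gene B", 1), ("Gene C", 1)]
        assert sum(c for _, c in dist.entries) == g.count

    def test_distribution_orders_by_count(self):
        rng = np.random.default_rng(19)
        kg = load_kg(random_kg(rng, n_nodes=30, edge_prob=0.15))
        nodes = list(kg.g.nodes)
        res = query_paths(kg, nodes[:3], nodes[-1], max_extra_hops=1)
        for g in group_meta_paths(kg, res.paths):
            for pos in range(g.n_node_positions):
                d = distribution(g, pos, kg)
                counts = [c for _, c in d.entries]
                assert counts == sorted(counts, reverse=True)
                assert sum(counts) == g.count


class TestPaginate:
    def test_pages_partition(self):
        items = list(range(10))
        pages = [paginate(items, 4, i) for i in range(3)]
        assert [len(p) for p in pages] == [4, 4, 2]
        assert sum(pages, []) == items

    def test_page_beyond_end_is_empty(self):
        assert paginate([1, 2], 5, 3) == []

    def test_large_page_size_single_page(self):
        assert paginate([1, 2, 3], 99, 0) == [1, 2, 3]

    def test_bad_page_size(self):
        with pytest.raises(ValidationError):
            paginate([1], 0, 0)
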