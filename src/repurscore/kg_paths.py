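"""Knowledge-graph path queries, meta-path grouping and distributions.

The validation stage of a repurposing review checks whether an MoA-disease
candidate is mechanistically plausible in an independent heterogeneous
knowledge graph (PrimeKG-style: typed nodes such as gene/protein, pathway,
anatomy, disease; typed relations).  The MoA is represented by its target
nodes; the query retrieves *all* simple paths of minimal hop length between
any non-excluded target and the disease node (optionally allowing a few
extra hops), treating edges as undirected for connectivity while recording
each edge's stored direction.

Because hundreds or thousands of shortest paths can exist, results are
grouped into *meta-paths* — sequences of node and relation types — which
partition the path set; each group supports entity filters at any type-node
position, per-position entity distributions, and pagination.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import EntityLookupError, ValidationError

__all__ = [
    "KGraph",
    "PathEdge",
    "Path",
    "PathQueryResult",
    "MetaPathGroup",
    "TypeNodeDistribution",
    "DEFAULT_PATH_CAP",
    "load_kg",
    "query_paths",
    "group_meta_paths",
    "filter_group",
    "distribution",
    "paginate",
]

KG_COLUMNS = ["x_id", "x_type", "x_name", "relation", "y_id", "y_type", "y_name"]

#: hard cap on returned paths; results beyond it set the truncation flag
DEFAULT_PATH_CAP = 10_000

_PALETTE = [
    "indianred", "steelblue", "seagreen", "goldenrod", "orchid",
    "sienna", "teal", "slateblue", "olive", "coral",
    "cadetblue", "rosybrown", "darkkhaki", "plum", "salmon",
    "turquoise", "tan", "thistle", "peru", "lightseagreen",
]


class KGraph:
    """Typed, undirected-for-connectivity knowledge graph.

    Backed by a :class:`networkx.Graph` whose edge attribute ``relations``
    holds the set of stored (directed, typed) relations between the two
    endpoints; parallel relations between one node pair are kept distinct
    there.  Node attributes: ``node_type``, ``name``.
    """

    def __init__(self) -> None:
        self.g = nx.Graph()

    # -- construction --

    def add_node(self, node_id: str, node_type: str, name: str) -> None:
        if node_id in self.g:
            attrs = self.g.nodes[node_id]
            if attrs["node_type"] != node_type or attrs["name"] != name:
                raise ValidationError(
                    f"conflicting attributes for node {node_id!r}: "
                    f"({attrs['node_type']!r}, {attrs['name']!r}) vs "
                    f"({node_type!r}, {name!r})"
                )
            return
        self.g.add_node(node_id, node_type=node_type, name=name)

    def add_edge(
        self,
        x_id: str,
        relation: str,
        y_id: str,
        polarity: str | None = None,
    ) -> None:
        for nid in (x_id, y_id):
            if nid not in self.g:
                raise ValidationError(f"edge endpoint {nid!r} is not a known node")
        if not self.g.has_edge(x_id, y_id):
            self.g.add_edge(x_id, y_id, relations={})
        # key is the stored direction + relation; duplicates dedupe silently
        self.g.edges[x_id, y_id]["relations"][(x_id, relation, y_id)] = polarity

    # -- attribute access --

    def node_type(self, node_id: str) -> str:
        return self.g.nodes[node_id]["node_type"]

    def node_name(self, node_id: str) -> str:
        return self.g.nodes[node_id]["name"]

    @property
    def type_palette(self) -> dict[str, str]:
        types = sorted({d["node_type"] for _, d in self.g.nodes(data=True)})
        return {t: _PALETTE[i % len(_PALETTE)] for i, t in enumerate(types)}

    # -- serialization --

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for u, v, data in self.g.edges(data=True):
            for (x, rel, y), polarity in data["relations"].items():
                row = {
                    "x_id": x, "x_type": self.node_type(x), "x_name": self.node_name(x),
                    "relation": rel,
                    "y_id": y, "y_type": self.node_type(y), "y_name": self.node_name(y),
                }
                if polarity is not None:
                    row["polarity"] = polarity
                rows.append(row)
        df = pd.DataFrame(rows)
        return df.sort_values(list(df.columns)).reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_kg(source) -> KGraph:
    """Load a knowledge graph from an edge list in the PrimeKG column dialect.

    ``source`` is a TSV path or DataFrame with columns
    ``x_id,x_type,x_name,relation,y_id,y_type,y_name`` and an optional
    ``polarity`` column (positive/negative/neutral).  Duplicate rows dedupe
    to a single edge; conflicting type or name for one node id is a
    validation error.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
    missing = set(KG_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"KG table missing columns: {sorted(missing)}")
    kg = KGraph()
    has_polarity = "polarity" in df.columns
    for row in df.itertuples(index=False):
        kg.add_node(str(row.x_id), str(row.x_type), str(row.x_name))
        kg.add_node(str(row.y_id), str(row.y_type), str(row.y_name))
        polarity = None
        if has_polarity and isinstance(row.polarity, str) and row.polarity:
            polarity = row.polarity
        kg.add_edge(str(row.x_id), str(row.relation), str(row.y_id), polarity)
    return kg


@dataclass(frozen=True)
class PathEdge:
    """One traversed edge, keeping the stored direction and polarity."""

    source_id: str       # stored direction, as in the edge list
    relation: str
    target_id: str
    polarity: str | None
    forward: bool        # True when traversal follows the stored direction


@dataclass(frozen=True)
class Path:
    """Alternating node/edge sequence from a query target to the disease."""

    nodes: tuple[str, ...]
    edges: tuple[PathEdge, ...]

    @property
    def length(self) -> int:
        return len(self.edges)


@dataclass
class PathQueryResult:
    paths: list[Path]
    min_length: int | None    # None when the disease is unreachable
    truncated: bool

    def __iter__(self):
        return iter(self.paths)

    def __len__(self) -> int:
        return len(self.paths)


def query_paths(
    kg: KGraph,
    source_targets: Sequence[str],
    disease: str,
    excluded: Iterable[str] = (),
    max_extra_hops: int = 0,
    cap: int = DEFAULT_PATH_CAP,
) -> PathQueryResult:
    """All shortest (or near-shortest) simple paths from MoA targets to a disease.

    The hop bound ``L`` is the minimum undirected distance over all
    non-excluded ``(target, disease)`` pairs; every simple path of length
    at most ``L + max_extra_hops`` from any such target is returned.  Node
    pairs joined by several stored relations yield one path per relation
    choice.  An unreachable disease gives an empty (valid) result; results
    beyond ``cap`` are dropped and flagged via ``truncated``.
    """
    if disease not in kg.g:
        raise EntityLookupError(f"disease node {disease!r} not in the graph")
    excluded = set(excluded)
    sources = [t for t in source_targets if t not in excluded and t in kg.g]
    if not sources:
        raise EntityLookupError(
            "no non-excluded MoA target is present in the graph"
        )

    dist = nx.single_source_shortest_path_length(kg.g, disease)
    reachable = [s for s in sources if s in dist]
    if not reachable:
        return PathQueryResult([], None, False)
    min_len = min(dist[s] for s in reachable)
    bound = min_len + max_extra_hops

    paths: list[Path] = []
    truncated = False
    for src in sorted(reachable):
        if src == disease:
            continue
        for node_seq in nx.all_simple_paths(kg.g, src, disease, cutoff=bound):
            for path in _expand_relations(kg, node_seq):
                if len(paths) >= cap:
                    truncated = True
                    break
                paths.append(path)
            if truncated:
                break
        if truncated:
            break
    return PathQueryResult(paths, min_len, truncated)


def _expand_relations(kg: KGraph, node_seq: Sequence[str]) -> Iterable[Path]:
    """One Path per combination of parallel relations along a node sequence."""
    hop_choices = []
    for u, v in zip(node_seq, node_seq[1:]):
        relations = kg.g.edges[u, v]["relations"]
        hop_choices.append(
            [
                PathEdge(x, rel, y, polarity, forward=(x == u))
                for (x, rel, y), polarity in sorted(
                    relations.items(), key=lambda kv: kv[0]
                )
            ]
        )
    for combo in itertools.product(*hop_choices):
        yield Path(tuple(node_seq), tuple(combo))


@dataclass
class MetaPathGroup:
    """Concrete paths sharing one node-type/relation signature."""

    signature: tuple[str, ...]    # (type_0, rel_0, type_1, ..., type_k)
    paths: list[Path]

    @property
    def count(self) -> int:
        return len(self.paths)

    @property
    def n_node_positions(self) -> int:
        return (len(self.signature) + 1) // 2


def path_signature(kg: KGraph, path: Path) -> tuple[str, ...]:
    sig: list[str] = []
    for i, node in enumerate(path.nodes):
        sig.append(kg.node_type(node))
        if i < len(path.edges):
            sig.append(path.edges[i].relation)
    return tuple(sig)


def group_meta_paths(
    kg: KGraph,
    paths: Iterable[Path],
    order: str = "count",
) -> list[MetaPathGroup]:
    """Partition paths into meta-path groups.

    ``order`` is ``"count"`` (descending path count, ties by signature),
    ``"signature"`` (lexicographic) or ``"length"`` (hops ascending, ties
    by signature).
    """
    groups: dict[tuple[str, ...], list[Path]] = {}
    for p in paths:
        groups.setdefault(path_signature(kg, p), []).append(p)
    result = [MetaPathGroup(sig, ps) for sig, ps in groups.items()]
    if order == "count":
        result.sort(key=lambda g: (-g.count, g.signature))
    elif order == "signature":
        result.sort(key=lambda g: g.signature)
    elif order == "length":
        result.sort(key=lambda g: (len(g.signature), g.signature))
    else:
        raise ValidationError(f"unknown meta-path order {order!r}")
    return result


def _check_position(group: MetaPathGroup, position: int) -> None:
    if not (0 <= position < group.n_node_positions):
        raise ValidationError(
            f"position {position} out of range for a meta-path with "
            f"{group.n_node_positions} type nodes"
        )


def filter_group(
    group: MetaPathGroup, position: int, name_query: str, kg: KGraph
) -> list[Path]:
    """Paths whose entity at a type-node position matches a name query.

    Matching is case-insensitive substring on the entity name; the empty
    query matches every path.
    """
    _check_position(group, position)
    needle = name_query.casefold()
    return [
        p for p in group.paths
        if needle in kg.node_name(p.nodes[position]).casefold()
    ]


@dataclass
class TypeNodeDistribution:
    """Entity frequency at one type-node position of a meta-path group."""

    position: int
    entries: list[tuple[str, int]]   # (entity name, count), count descending


def distribution(
    group: MetaPathGroup, position: int, kg: KGraph
) -> TypeNodeDistribution:
    """Count distinct entities at a type-node position across group paths."""
    _check_position(group, position)
    counter = Counter(kg.node_name(p.nodes[position]) for p in group.paths)
    entries = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return TypeNodeDistribution(position, entries)


def paginate(items: Sequence, page_size: int, page_index: int) -> list:
    """Stable slice of an ordered list; pages partition the input.

    ``page_index`` is 0-based; a page past the end is empty, not an error.
    """
    if page_size < 1:
        raise ValidationError(f"page_size must be >= 1, got {page_size}")
    if page_index < 0:
        raise ValidationError(f"page_index must be >= 0, got {page_index}")
    start = page_size * page_index
    return list(items[start:start + page_size])
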