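"""MeSH-style disease hierarchy with Mscore annotation and sparkline data.

The hierarchy is a polyhierarchical forest addressed by dotted *tree
numbers* (e.g. ``C17.800.859``): a term may occupy several tree positions,
and a position's parent is its address with the last component removed.
Terms carrying a consensus Mscore are selectable; unscored terms remain
visible for navigation only.  For any position, the distribution of Mscores
over all strict descendants (all levels down to the leaves, deduplicated by
term id) is summarized as a fixed-bin histogram over [-1, 1] — the data
behind per-node sparklines in a tree view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import EntityLookupError, ValidationError

__all__ = [
    "OntologyNode",
    "ScoreHistogram",
    "DiseaseForest",
    "load_tree",
    "descendant_histogram",
]


@dataclass
class OntologyNode:
    """A disease term, possibly occupying several tree positions."""

    term_id: str | None           # None for implicit (placeholder) positions
    name: str | None
    tree_numbers: list[str] = field(default_factory=list)
    mscore: float | None = None

    @property
    def selectable(self) -> bool:
        return self.mscore is not None


@dataclass
class ScoreHistogram:
    """Descendant Mscore distribution over [-1, 1], last bin right-closed."""

    bin_edges: list[float]
    counts: list[int]
    n_descendants_scored: int


class DiseaseForest:
    """Forest of tree positions with term annotations.

    ``positions`` maps a dotted address to the term occupying it (or a
    placeholder when no row defined the address but a descendant implied
    it).  Children are derived from addresses alone, so the structure is
    acyclic by construction.
    """

    def __init__(self) -> None:
        self.positions: dict[str, OntologyNode] = {}
        self.terms: dict[str, OntologyNode] = {}

    # -- construction --

    def _ensure_position(self, address: str) -> None:
        if address in self.positions:
            return
        parent = _parent_address(address)
        if parent is not None:
            self._ensure_position(parent)
        if address not in self.positions:
            self.positions[address] = OntologyNode(None, None, [address])

    def add_term(self, term_id: str, name: str, tree_number: str) -> None:
        node = self.terms.get(term_id)
        if node is None:
            node = OntologyNode(term_id, name, [])
            self.terms[term_id] = node
        if tree_number in node.tree_numbers:
            raise ValidationError(
                f"duplicate (term_id, tree_number): ({term_id!r}, {tree_number!r})"
            )
        existing = self.positions.get(tree_number)
        if existing is not None and existing.term_id not in (None, term_id):
            raise ValidationError(
                f"tree number {tree_number!r} claimed by both "
                f"{existing.term_id!r} and {term_id!r}"
            )
        node.tree_numbers.append(tree_number)
        parent = _parent_address(tree_number)
        if parent is not None:
            self._ensure_position(parent)
        self.positions[tree_number] = node

    # -- navigation --

    def roots(self) -> list[str]:
        return sorted(a for a in self.positions if "." not in a)

    def children(self, address: str) -> list[str]:
        prefix = address + "."
        depth = address.count(".") + 1
        return sorted(
            a for a in self.positions
            if a.startswith(prefix) and a.count(".") == depth
        )

    def descendants(self, address: str) -> list[str]:
        """All strictly deeper positions under ``address``."""
        prefix = address + "."
        return sorted(a for a in self.positions if a.startswith(prefix))

    def node_at(self, address: str) -> OntologyNode:
        try:
            return self.positions[address]
        except KeyError:
            raise EntityLookupError(f"no tree position {address!r}") from None

    # -- scoring --

    def annotate_scores(self, scores: Mapping[str, float]) -> None:
        """Attach Mscores by term id; unknown term ids are ignored."""
        for term_id, score in scores.items():
            node = self.terms.get(term_id)
            if node is not None:
                node.mscore = float(score)

    # -- serialization --

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t.term_id, t.name, addr)
            for t in self.terms.values()
            for addr in t.tree_numbers
        ]
        return pd.DataFrame(
            sorted(rows), columns=["term_id", "name", "tree_number"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_nested_dict(self, bins: int = 10) -> list[dict]:
        """Nested JSON-ready tree with per-node descendant histograms."""

        def build(address: str) -> dict:
            node = self.positions[address]
            hist = descendant_histogram(self, address, bins=bins)
            return {
                "tree_number": address,
                "term_id": node.term_id,
                "name": node.name,
                "mscore": node.mscore,
                "selectable": node.selectable,
                "histogram": {
                    "bin_edges": hist.bin_edges,
                    "counts": hist.counts,
                    "n": hist.n_descendants_scored,
                },
                "children": [build(c) for c in self.children(address)],
            }

        return [build(r) for r in self.roots()]


def _parent_address(address: str) -> str | None:
    if "." not in address:
        return None
    return address.rsplit(".", 1)[0]


def load_tree(source) -> DiseaseForest:
    """Load a disease hierarchy from TSV rows (term_id, name, tree_number).

    ``source`` is a path or a DataFrame with those columns.  Addresses whose
    parent has no row are attached through implicit placeholder positions
    (a warning is emitted); duplicate (term_id, tree_number) rows are a
    validation error.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"term_id", "name", "tree_number"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"ontology table missing columns: {sorted(missing)}")

    forest = DiseaseForest()
    for row in df.itertuples(index=False):
        forest.add_term(str(row.term_id), str(row.name), str(row.tree_number))
    orphans = [
        a for a, n in forest.positions.items() if n.term_id is None
    ]
    if orphans:
        warnings.warn(
            f"{len(orphans)} tree position(s) have no term row and were created "
            f"as placeholders (e.g. {orphans[0]!r})",
            stacklevel=2,
        )
    return forest


def descendant_histogram(
    forest: DiseaseForest, address: str, bins: int = 10
) -> ScoreHistogram:
    """Histogram of Mscores over the strict descendants of a tree position.

    Descendants at every level are collected for the given position; a term
    reachable through several descendant positions counts once.  Unscored
    terms are excluded.  Bins partition [-1, 1]; every bin is left-closed
    and the final bin is right-closed, so a score of exactly 1 lands in the
    last bin.
    """
    if bins < 1:
        raise ValidationError(f"bins must be >= 1, got {bins}")
    forest.node_at(address)
    seen: set[str] = set()
    scores: list[float] = []
    for desc in forest.descendants(address):
        node = forest.positions[desc]
        key = node.term_id if node.term_id is not None else f"@{desc}"
        if key in seen:
            continue
        seen.add(key)
        if node.mscore is not None:
            scores.append(node.mscore)
    counts, edges = np.histogram(scores, bins=bins, range=(-1.0, 1.0))
    return ScoreHistogram(
        bin_edges=[float(e) for e in edges],
        counts=[int(c) for c in counts],
        n_descendants_scored=len(scores),
    )
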