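"""Annotate a disease hierarchy with Mscores and summarize descendants.

Generates a small MeSH-style forest, attaches scores to half of its
leaves, and prints each top-level node's descendant-score histogram — the
data behind per-node sparklines in a tree browser.
"""

from repurscore import (
    FixtureSpec,
    descendant_histogram,
    gen_ontology,
    load_tree,
)

spec = FixtureSpec(seed=5, ontology_depth=3, ontology_branching=3,
                   ontology_n_roots=2, scored_leaf_fraction=0.5)
table, scores = gen_ontology(spec)
forest = load_tree(table)
forest.annotate_scores(scores)

print(f"{len(table)} terms, {len(scores)} scored leaves\n")
for root in forest.roots():
    hist = descendant_histogram(forest, root, bins=10)
    bar = "".join(str(min(c, 9)) for c in hist.counts)
    print(f"{root}: n={hist.n_descendants_scored:>2}  bins[-1..1]: {bar}")
    for child in forest.children(root):
        h = descendant_histogram(forest, child, bins=10)
        node = forest.node_at(child)
        own = f"{node.mscore:+.2f}" if node.selectable else "  -  "
        bar = "".join(str(min(c, 9)) for c in h.counts)
        print(f"  {child}: own={own} n={h.n_descendants_scored:>2}  {bar}")

# Each digit string is a 10-bin histogram of strict-descendant Mscores over
# [-1, 1]; a parent's counts always dominate each child's, and unscored
# terms stay navigable but unselectable.
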