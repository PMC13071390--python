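# Methods

## Evidence model

An association binds one MoA (a set of molecular-target identifiers) to
one candidate indication (an ontology term). Evidence arrives as items
`(stream, target, direction, magnitude, payload)` with `direction ∈
{supporting, opposing}` and `magnitude ≥ 0` on the stream's native scale.
The model permits opposing evidence on every stream, including genomics.

**Quantification.** The default quantifier sums magnitudes per direction,
yielding `(q_sup, q_opp)`. It is deliberately simple — production
pipelines quantify each modality with their own (often proprietary)
statistics — and is pluggable per modality via
`register_quantifier(modality, fn)`, so a different quantifier can stand
in front of the unchanged downstream boundaries. Literature evidence is a
single publication corpus quantified twice: the *overall* stream counts
every publication, the *novelty* stream only publications with
`year ≥ novelty_year_cutoff` (default 2021, i.e. a recent five-year
window at the time the default was fixed). Publications count with
uniform magnitude 1 unless items say otherwise.

**Harmonization.** Supporting and opposing quantities are saturated
*independently*, not as a signed net: `h_net = g(q_sup) − g(q_opp)`. This
is what lets a small raw opposition nearly cancel a large raw support —
both saturate toward 1 — and the flow graph exposes exactly that skew
(layer 2 shows the raw ratio, layer 4 the compressed one). Families:

| family | g(q) | notes |
|---|---|---|
| `tanh` (default) | `tanh(q/scale)` | smooth, strictly increasing |
| `hard_clip` | `min(q/scale, 1)` | reaches the bound; ties above `scale` |
| `logistic_symmetric` | `2/(1+e^(−q/scale)) − 1` | logistic re-centred to g(0)=0 |

`scale` is per stream, on the stream's native magnitude scale (defaults in
`default_streams()`: 2 for genomics, 4 for omics effect-size sums, 10/3
for literature overall/novelty — chosen so that typical synthetic
evidence volumes land on the responsive part of the curve). Family and
scale are configurable per stream because sources saturate differently.

**Integration.** `Mscore = Σ_s w_s·h_net,s` with `w_s ≥ 0` used as given
(no normalization to sum 1 — rescaling all weights by c > 0 cannot change
an ordering, so normalization is presentation, not semantics). A stream
configured in the weights but without evidence contributes a zero pair;
a harmonized stream missing from the weights is a configuration error,
because "off" is expressed as weight 0, never by dropping the stream.

## Ranking and what-if comparison

Ranks are competition style (tied rows share the minimal rank; the next
rank skips), matching ordinal bar-chart displays. Scores within 1e−9 are
tied — an absolute epsilon, chosen as strictly a float-noise guard; the
separate `near_ties` report takes a coarser, user-chosen epsilon for
surfacing scientifically negligible score differences. Up to five weight
sets labelled A–E may be compared at once (a hard cap, enforced); the
reference set defines `delta = reference_rank − rank`. Toggling a stream
off zeroes its effective weight while remembering the configured value,
so toggle-off/toggle-on is an exact involution and a toggled-off stream
behaves identically to a configuration in which that stream never
existed.

## Provenance flow graph

Eight layers re-arrange (never re-model) the computation: targets →
stream evidence → saturation functions → harmonized components → weighted
components → supporting/opposing pools → net → Mscore. Choices the layout
forced:

- Layer-2 nodes carry a fixed display size (1.0) because pre-harmonized
  totals are not cross-comparable; the raw total lives in `scalar_value`
  and the opposing fraction in `hatch_fraction`.
- Layer-1/2 link values are per-stream magnitude shares (not item-count
  shares), summing to 1 whenever the stream has evidence — consistent
  with magnitude-sum quantification.
- Layers 4–5 keep one node per (stream, direction) component rather than
  a single |h_net| node, since the polarity pooling of layer 6 needs the
  components; a consumer wanting |h_net| can difference them.
- Layer-3 nodes embed a 50-point sampling of g over [0, 4·scale] so a
  front end can plot the curve without knowing the families.
- Layer 7 records `overlap = opposing_total`, the support cancelled by
  opposition; layer 8 equals the Mscore to 1e−12 by construction (tested
  as a cross-module conservation property).

Flow graphs serialize to JSON at full double precision, so
JSON round-trips are exact identities; deterministic key order makes
re-runs byte-identical. (Rounding to a fixed significant-digit count was
considered and rejected: it breaks the round-trip identity for no
compression benefit at these sizes.)

## Ontology

Tree numbers are dotted addresses forming a forest; a term may occupy
several positions (polyhierarchy). Addresses implied by a child but
missing a term row become placeholder positions with a warning — loading
stays permissive because real vocabularies ship partial exports.
Descendant histograms collect strict descendants of a *position*
(all levels), deduplicate by term id so a term reachable twice under the
same ancestor counts once, exclude unscored terms, and bin over [−1, 1]
with left-closed bins and a right-closed final bin (a score of exactly 1
lands in the last bin). Default 10 bins — small enough for sparklines.
Internal terms and leaves may both carry scores; unscored terms are
navigable but not selectable.

## Name mapping

Normalization: Unicode casefold, tokens reduced to alphanumerics with
internal hyphens kept, token sort. Similarity: normalized Levenshtein on
the normalized forms, `100·(1 − d/max(len))` (edit distance computed with
edlib). Token sorting makes word-order variants exact matches; the
default acceptance threshold is 85 and is configurable — the cut is a
recall/precision dial for the analyst, not a semantic boundary.

## Knowledge-graph validation

Connectivity is undirected — biomedical relations are stored in a
canonical direction, but mechanistic "connection" is symmetric — while
every traversed edge records its stored direction and optional polarity
(positive/negative/neutral; surfaced, never filtered on by default).
The hop bound L is the *global* minimum distance over all non-excluded
(target, disease) pairs, not per source; `max_extra_hops` (default 0)
loosens it explicitly. All simple paths within the bound are returned, to
a hard cap of 10,000 with an explicit truncation flag, since dense graphs
can hold thousands of "shortest" paths. Node pairs joined by several
stored relations expand to one path per relation choice so meta-path
signatures stay well defined. Meta-paths partition the result set by the
(node-type, relation) sequence; default order is count-descending with
lexicographic tie-break, with signature and length orders available.
Filters are case-insensitive substring matches on the entity name at a
type-node position; distributions count entities at a position
(count-descending, name tie-break); pagination is stable slicing.

## Synthetic fixtures

Generators are pure functions of a `FixtureSpec` (seed included):
identical spec ⇒ byte-identical artifacts. They emit paired ground-truth
manifests (quantified pairs, planted paths, leaf scores) so tests compare
engine output against generation-time truth instead of re-deriving it.
Defaults — 5 targets, 50 indications, up to 12 items per stream per
association with 25% opposing evidence, publication years 2005–2025, a
4-type graph of 200 nodes with 3 planted length-3 target→disease paths,
a depth-3 forest — generate in well under a second and are sized for
interactive exploration and fast tests.

The planted-path construction guarantees the minimum target–disease
distance equals the planted length: intermediates are fresh, node-disjoint
nodes, background edges avoid the disease and all planted intermediates,
and the distance is re-verified (with resampling, then a hard error)
anyway. Fixtures aim for *structural* realism — key relationships, edge
cases, payload contracts — not biological realism: effect sizes are
Gaussian draws, p-values uniform, abstracts word salad with well-formed
spans. Passing tests therefore demonstrate correctness of the machinery
on faithfully shaped inputs, not performance of any quantifier on real
omics or literature data.

## Problem sizes and numerics

The test suite checks conservation identities at 1e−12 (sums of ≤ 10
weighted bounded terms; well above double rounding), uses 100 random
associations for flow conservation, 50 random graphs of ≤ 60 nodes
against an independent BFS+DFS oracle, 1,000 random score tables against
a re-ranking oracle, and a 1,000-decoy pool for the name-matching worked
example. The acceptance script evaluates 1.2 million random evidence
pairs (10,000 per derived seed × 10 seeds × 12 family/scale combinations)
against the [−1, 1] harmonization bound. These sizes keep the whole suite
in seconds while leaving the checked properties at full strength.

## Known limitations

- The default quantifier is a magnitude sum; no text-mining or omics
  statistics are included, by design.
- Polyhierarchy deduplication is per queried position: a term under two
  *different* ancestors contributes to both ancestors' histograms.
- Path queries hold all results in memory; the cap bounds this but a
  graph-database backend would be needed at full PrimeKG scale.
- Flow graphs for two indications are exported independently; comparing
  them is left to the consumer (the JSON is stable for juxtaposition).
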