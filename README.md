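# repurscore

Evidence-assessment machinery for reviewing multimodal drug-repurposing
predictions: consensus scoring with explicit provenance, what-if
re-ranking, disease-ontology exploration, fuzzy cross-ontology name
mapping, and knowledge-graph meta-path validation.

## The problem

Indication-expansion pipelines propose new diseases for an existing drug
by combining evidence from heterogeneous sources — genomics,
transcriptomics, proteomics and the literature. Domain experts must then
assess those candidates, which requires seeing *why* a candidate scored
the way it did, probing how robust its rank is to modelling choices, and
validating the proposed mechanism against independent knowledge. This
package is the headless engine for that review: it computes the scores
and every intermediate artifact a reviewer needs, leaving rendering to
any front end.

## The model

For an MoA (a drug's mode of action, represented by its molecular
targets) paired with a candidate indication, each evidence stream *s*
passes through four transformation boundaries:

1. **Collection** — qualitative evidence items, each *supporting* or
   *opposing*, with magnitude ≥ 0 on the stream's native scale.
2. **Quantification** — directional sums give `(q_sup, q_opp)`. The
   literature corpus is quantified twice: *overall* (all publications)
   and *novelty* (publications since a cutoff year).
3. **Harmonization** — each component is bounded by a monotone saturating
   function `g` with `g(0)=0`, `g→1` (default `tanh(q/scale)`), so
   streams become comparable:
   `h_net,s = g_s(q_sup,s) − g_s(q_opp,s) ∈ [−1, 1]`.
4. **Integration** — the consensus score is a weighted sum,

   `Mscore = Σ_s w_s · h_net,s`,

   with `w_s · h_net,s` reported as stream *s*'s contribution.

Around this core the package provides: competition-style ranking with up
to five labelled weight sets and rank deltas against a reference; an
8-layer provenance flow graph that conserves the Mscore exactly while
exposing where opposing evidence cancelled support; MeSH-style tree
loading with descendant-score histograms; token-sorted normalized
Levenshtein matching of disease names across ontologies; and shortest-path
queries over a PrimeKG-style typed graph, grouped into meta-paths with
filters, entity distributions and pagination. A seeded fixture generator
produces every input, so nothing needs downloading.

## Worked example

`examples/01_score_and_rank.py` scores ten synthetic candidates for one
MoA and compares the default weight set A against set B with
transcriptomics toggled off:

```
indication  Mscore(A) rank A rank B  delta
IND006         0.5642      1      2     -1
IND000         0.5347      2      1     +1
IND001         0.4873      3      3     +0
IND005         0.3246      4      4     +0
IND008         0.3154      5      7     -2
...
```

`Mscore(A)` is the weighted sum of bounded per-stream net evidence under
set A (here weights sum to 1, so scores lie in [−1, 1]); `delta` is
`rank_A − rank_B`, so IND008 drops two places when transcriptomics is
removed — its score depends on that stream more than its neighbours' do.
The other examples cover the provenance flow graph and drill-downs
(`02`), ontology histograms (`03`), name mapping (`04`) and
knowledge-graph validation (`05`); each prints the numbers it computes
and a note on how to read them. A thin CLI (`repurscore simulate|score|
rank|flow|paths|map-disease|tree`) wraps the same functions for shell
use.

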