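"""Seeded generators for every input the engine consumes.

The real pipeline's inputs — per-stream evidence tables, a typed knowledge
graph, a disease hierarchy and a stream configuration — are proprietary or
large downloads.  These generators produce structurally faithful stand-ins
so every module is exercisable offline: omics items with signed effect
sizes and p-values, literature items with years and annotation spans inside
generated abstracts, a typed graph with planted target-disease paths of
known length, and a complete b-ary disease forest with scores on a fraction
of leaves.  Each generator is a pure function of its spec (which includes
the seed) and emits a ground-truth manifest alongside its artifact, so
tests can assert engine output against generation-time truth.

Fixtures target structural realism (shapes, key relationships, edge cases),
not biological realism: effect sizes and scores are draws from simple
distributions, not simulations of any assay.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np
import pandas as pd

from .errors import ValidationError
from .evidence_model import (
    Direction,
    EvidenceItem,
    EvidenceStream,
    Modality,
    QuantPair,
    SaturationSpec,
)
from .kg_paths import KGraph

__all__ = [
    "FixtureSpec",
    "default_streams",
    "gen_evidence",
    "gen_kg",
    "gen_ontology",
    "write_fixture_set",
]

_WORDS = (
    "inflammation receptor pathway epidermal cytokine signaling barrier "
    "keratinocyte interleukin expression lesion chronic epithelial immune "
    "response skin tissue mediated upregulated antagonist"
).split()


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one deterministic fixture set.

    Defaults are sized for interactive use: a 5-target MoA scored against
    50 candidate indications, a 4-type graph of ~200 nodes, and a shallow
    disease forest — all generated in well under a second.
    """

    seed: int = 0
    n_targets: int = 5
    n_indications: int = 50
    # evidence
    n_items_per_stream: int = 12
    opposing_fraction: float = 0.25
    novelty_year_cutoff: int = 2021
    year_range: tuple[int, int] = (2005, 2025)
    span_density: float = 0.6          # fraction of abstracts with spans
    # knowledge graph
    kg_node_types: tuple[str, ...] = ("gene/protein", "pathway", "anatomy", "disease")
    kg_nodes_per_type: int = 50
    kg_edge_prob: float = 0.02
    n_planted_paths: int = 3
    planted_length: int = 3
    # ontology
    ontology_depth: int = 3
    ontology_branching: int = 3
    ontology_n_roots: int = 2
    scored_leaf_fraction: float = 0.5


def default_streams() -> dict[str, EvidenceStream]:
    """The five-stream configuration of a multimodal repurposing pipeline."""
    mk = lambda sid, mod, scale, w: EvidenceStream(
        sid, sid.replace("_", " "), mod, SaturationSpec("tanh", scale), w
    )
    return {
        s.stream_id: s
        for s in (
            mk("genomics", Modality.GENOMICS, 2.0, 0.3),
            mk("transcriptomics", Modality.TRANSCRIPTOMICS, 4.0, 0.2),
            mk("proteomics", Modality.PROTEOMICS, 4.0, 0.2),
            mk("literature_overall", Modality.LITERATURE_OVERALL, 10.0, 0.15),
            mk("literature_novelty", Modality.LITERATURE_NOVELTY, 3.0, 0.15),
        )
    }


# --- evidence -------------------------------------------------------------


def _gen_abstract(rng: np.random.Generator) -> str:
    n = int(rng.integers(15, 40))
    return " ".join(rng.choice(_WORDS, size=n))


def _gen_spans(
    rng: np.random.Generator, text: str
) -> list[tuple[int, int, str]]:
    # non-overlapping spans on word boundaries
    words = text.split(" ")
    starts, pos = [], 0
    for w in words:
        starts.append(pos)
        pos += len(w) + 1
    n_spans = int(rng.integers(1, 4))
    idx = sorted(rng.choice(len(words), size=min(n_spans, len(words)), replace=False))
    spans = []
    for i in idx:
        label = str(rng.choice(["target", "disease", "effect"]))
        spans.append((starts[i], starts[i] + len(words[i]), label))
    return spans


def gen_evidence(
    spec: FixtureSpec,
) -> tuple[dict[str, list[EvidenceItem]], dict[str, dict[str, QuantPair]]]:
    """Evidence items per indication, with ground-truth quantified pairs.

    Returns ``(items_by_indication, truth)`` where
    ``truth[indication][stream_id]`` is the QuantPair the engine must
    reproduce.  Omics items carry ``effect_size`` (sign matches direction)
    and ``p_value`` in (0, 1]; literature items are emitted once, under the
    overall stream, and carry year, abstract and spans.  Magnitudes:
    |effect_size| for omics, 1 per publication for literature.
    """
    rng = np.random.default_rng(spec.seed)
    streams = default_streams()
    targets = [f"T{i}" for i in range(spec.n_targets)]
    items_by_ind: dict[str, list[EvidenceItem]] = {}
    truth: dict[str, dict[str, QuantPair]] = {}

    for k in range(spec.n_indications):
        ind = f"IND{k:03d}"
        items: list[EvidenceItem] = []
        truth[ind] = {}
        for sid, stream in streams.items():
            if stream.modality is Modality.LITERATURE_NOVELTY:
                continue  # shares the overall corpus
            n = int(rng.integers(0, spec.n_items_per_stream + 1))
            q_sup = q_opp = 0.0
            nov_sup = nov_opp = 0.0
            for j in range(n):
                target = str(rng.choice(targets))
                opposing = bool(rng.random() < spec.opposing_fraction)
                direction = Direction.OPPOSING if opposing else Direction.SUPPORTING
                if stream.modality in (Modality.TRANSCRIPTOMICS, Modality.PROTEOMICS):
                    effect = float(rng.normal(0, 1.5))
                    effect = abs(effect) if not opposing else -abs(effect)
                    magnitude = abs(effect)
                    payload = {
                        "effect_size": effect,
                        "p_value": float(rng.uniform(1e-6, 1.0)),
                    }
                elif stream.modality is Modality.GENOMICS:
                    magnitude = float(rng.uniform(0.1, 3.0))
                    payload = {}
                else:  # literature_overall: one publication, magnitude 1
                    magnitude = 1.0
                    year = int(rng.integers(*spec.year_range))
                    abstract = _gen_abstract(rng)
                    payload = {
                        "publication_id": f"PMID{k:03d}{j:02d}",
                        "year": year,
                        "abstract": abstract,
                        "spans": (
                            _gen_spans(rng, abstract)
                            if rng.random() < spec.span_density
                            else []
                        ),
                    }
                    if year >= spec.novelty_year_cutoff:
                        if opposing:
                            nov_opp += magnitude
                        else:
                            nov_sup += magnitude
                items.append(EvidenceItem(sid, target, direction, magnitude, payload))
                if opposing:
                    q_opp += magnitude
                else:
                    q_sup += magnitude
            truth[ind][sid] = QuantPair(sid, q_sup, q_opp)
            if stream.modality is Modality.LITERATURE_OVERALL:
                truth[ind]["literature_novelty"] = QuantPair(
                    "literature_novelty", nov_sup, nov_opp
                )
        items_by_ind[ind] = items
    return items_by_ind, truth


def evidence_frame(
    items_by_ind: dict[str, list[EvidenceItem]], moa_id: str = "MOA1"
) -> pd.DataFrame:
    """Flatten generated evidence into the evidence-table layout."""
    rows = []
    for ind, items in items_by_ind.items():
        for i, it in enumerate(items):
            p = it.payload
            spans = p.get("spans") or []
            rows.append({
                "moa_id": moa_id,
                "indication_id": ind,
                "stream_id": it.stream_id,
                "target_id": it.target_id,
                "direction": it.direction.value,
                "magnitude": it.magnitude,
                "effect_size": p.get("effect_size", ""),
                "p_value": p.get("p_value", ""),
                "publication_id": p.get("publication_id", ""),
                "year": p.get("year", ""),
                "abstract": p.get("abstract", ""),
                "spans": json.dumps(spans) if spans else "",
            })
    return pd.DataFrame(rows)


# --- knowledge graph ------------------------------------------------------


def gen_kg(spec: FixtureSpec, max_retries: int = 20) -> tuple[KGraph, dict]:
    """Typed random graph with planted target-disease paths of exact length.

    Plants ``n_planted_paths`` node-disjoint simple paths of exactly
    ``planted_length`` hops from MoA target nodes to one disease node, then
    adds background edges arranged so that no shorter target-disease route
    can exist (background edges never touch the disease, and planted
    intermediates only carry their chain edges).  The minimum distance is
    re-verified; an infeasible spec raises after bounded retries.

    Returns ``(kg, manifest)`` with the manifest listing target node ids,
    the disease id, and each planted path's node sequence.
    """
    if spec.planted_length < 1:
        raise ValidationError("planted_length must be >= 1")
    import networkx as nx

    for attempt in range(max_retries):
        rng = np.random.default_rng(spec.seed + 1000 * attempt)
        kg = KGraph()
        types = list(spec.kg_node_types)
        rel_for = lambda ta, tb: f"{ta.split('/')[0]}_{tb.split('/')[0]}_assoc"

        node_ids: dict[str, list[str]] = {}
        for t in types:
            short = t.split("/")[0][:4]
            node_ids[t] = [f"{short}{i}" for i in range(spec.kg_nodes_per_type)]
            for nid in node_ids[t]:
                kg.add_node(nid, t, f"{t} {nid}")

        gene_type = types[0]
        disease_type = types[-1]
        targets = node_ids[gene_type][: spec.n_targets]
        disease = node_ids[disease_type][0]

        planted: list[list[str]] = []
        # intermediates come from the middle types, node-disjoint across paths
        inter_pool = [
            nid
            for t in types[1:-1]
            for nid in node_ids[t][spec.n_targets:]
        ]
        rng.shuffle(inter_pool)
        pool_iter = iter(inter_pool)
        try:
            for p in range(spec.n_planted_paths):
                src = targets[p % len(targets)]
                chain = [src]
                for _ in range(spec.planted_length - 1):
                    chain.append(next(pool_iter))
                chain.append(disease)
                for u, v in zip(chain, chain[1:]):
                    kg.add_edge(u, rel_for(kg.node_type(u), kg.node_type(v)), v)
                planted.append(chain)
        except StopIteration:
            raise ValidationError(
                "not enough intermediate nodes for the requested planted paths"
            ) from None

        protected = {disease, *(n for ch in planted for n in ch[1:-1])}
        free = [
            nid for t in types for nid in node_ids[t] if nid not in protected
        ]
        # background edges among free nodes only; they cannot shorten any
        # target-disease route because the disease keeps only planted edges
        n_free = len(free)
        n_bg = int(spec.kg_edge_prob * n_free * (n_free - 1) / 2)
        for _ in range(n_bg):
            i, j = rng.integers(0, n_free, size=2)
            if i == j:
                continue
            u, v = free[int(i)], free[int(j)]
            kg.add_edge(u, rel_for(kg.node_type(u), kg.node_type(v)), v)

        if spec.n_planted_paths > 0:
            dmin = min(
                nx.shortest_path_length(kg.g, t, disease)
                for t in targets
                if nx.has_path(kg.g, t, disease)
            )
            if dmin != spec.planted_length:
                continue  # a shortcut slipped in; resample
        manifest = {
            "targets": targets,
            "disease": disease,
            "planted_paths": planted,
            "planted_length": spec.planted_length,
        }
        return kg, manifest
    raise ValidationError(
        "could not generate a shortcut-free graph within the retry budget; "
        "lower kg_edge_prob or planted path count"
    )


# --- ontology -------------------------------------------------------------


def gen_ontology(spec: FixtureSpec) -> tuple[pd.DataFrame, dict[str, float]]:
    """Complete b-ary disease forest with scores on a fraction of leaves.

    Returns the (term_id, name, tree_number) table and the ground-truth
    ``{term_id: mscore}`` map (scores uniform on [-1, 1]).
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple[str, str, str]] = []
    leaves: list[str] = []
    counter = 0

    def descend(address: str, depth: int) -> None:
        nonlocal counter
        term = f"D{counter:05d}"
        counter += 1
        rows.append((term, f"disease {term}", address))
        if depth == spec.ontology_depth:
            leaves.append(term)
            return
        for b in range(spec.ontology_branching):
            descend(f"{address}.{b + 1:03d}", depth + 1)

    for r in range(spec.ontology_n_roots):
        descend(f"C{r + 1:02d}", 0)

    df = pd.DataFrame(rows, columns=["term_id", "name", "tree_number"])
    n_scored = int(round(spec.scored_leaf_fraction * len(leaves)))
    scored = rng.choice(leaves, size=n_scored, replace=False)
    scores = {str(t): float(rng.uniform(-1, 1)) for t in scored}
    return df, scores


# --- bundle writer --------------------------------------------------------


def write_fixture_set(spec: FixtureSpec, out_dir) -> dict[str, str]:
    """Write evidence, KG, ontology, config and manifests under ``out_dir``.

    Returns a map of artifact name to file path.  Identical spec (including
    seed) produces byte-identical files.
    """
    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    items_by_ind, truth = gen_evidence(spec)
    ev = evidence_frame(items_by_ind)
    paths["evidence"] = str(out / "evidence.tsv")
    ev.to_csv(paths["evidence"], sep="\t", index=False)
    paths["quant_truth"] = str(out / "quant_truth.json")
    with open(paths["quant_truth"], "w") as fh:
        json.dump(
            {
                ind: {s: [q.q_supporting, q.q_opposing] for s, q in d.items()}
                for ind, d in truth.items()
            },
            fh, indent=1, sort_keys=True,
        )

    kg, manifest = gen_kg(spec)
    paths["kg"] = str(out / "kg.tsv")
    kg.to_tsv(paths["kg"])
    paths["kg_manifest"] = str(out / "kg_manifest.json")
    with open(paths["kg_manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    onto, scores = gen_ontology(spec)
    paths["ontology"] = str(out / "ontology.tsv")
    onto.to_csv(paths["ontology"], sep="\t", index=False)
    paths["ontology_scores"] = str(out / "ontology_scores.json")
    with open(paths["ontology_scores"], "w") as fh:
        json.dump(scores, fh, indent=1, sort_keys=True)

    config = {
        "streams": [
            {
                "stream_id": s.stream_id,
                "name": s.name,
                "modality": s.modality.value,
                "saturation": {"family": s.saturation.family,
                               "scale": s.saturation.scale},
                "weight": s.default_weight,
            }
            for s in default_streams().values()
        ],
        "novelty_year_cutoff": spec.novelty_year_cutoff,
        "seed": spec.seed,
    }
    paths["config"] = str(out / "config.json")
    with open(paths["config"], "w") as fh:
        json.dump(config, fh, indent=1, sort_keys=True)
    return paths
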