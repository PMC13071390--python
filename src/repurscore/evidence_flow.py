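"""Evidence-provenance flow graph and drill-down views.

The flow graph exposes how a single association's Mscore came to be, as
eight layers tracing the transformation boundaries:

1. **Targets** — one node per molecular target; its size is the normalized
   support the target receives summed across streams.
2. **Stream evidence** — one node per stream, all with the same fixed
   display size (pre-harmonization quantities are not comparable across
   streams); hatching encodes the opposing fraction of the raw evidence.
3. **Saturation functions** — the per-stream squashing function, with a
   plottable sampling of the curve.
4. **Harmonized evidence** — one node per stream and direction, sized by
   the bounded component value.
5. **Weighted evidence** — harmonized components scaled by stream weight.
6. **Polarity pools** — all supporting contributions pooled against all
   opposing ones.
7. **Net aggregate** — supporting minus opposing; the recorded ``overlap``
   is the amount of support cancelled by opposition.
8. **Mscore** — the consensus value and its direction.

Links carry non-negative values; between layers 1 and 2 they give, per
stream, the share of the stream's total evidence magnitude attributed to
each target (shares sum to 1 whenever the stream has evidence).

Drill-downs serve the underlying qualitative evidence: a volcano-plot table
for omics streams (effect size vs -log10 p), a publication list for
literature streams, and annotated abstracts for single publications.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, EntityLookupError
from .evidence_model import (
    Association,
    Direction,
    EvidenceItem,
    EvidenceStream,
    Modality,
    integrate,
    stream_source_ids,
)

__all__ = [
    "FlowNode",
    "FlowLink",
    "FlowGraph",
    "VolcanoPoint",
    "CollectiveEvidenceView",
    "AnnotatedAbstract",
    "LAYER_2_DISPLAY_SIZE",
    "build_flow",
    "drilldown_collective",
    "drilldown_instance",
    "merge_spans",
]

#: fixed display size of every layer-2 node (raw stream totals are not
#: cross-comparable before harmonization; the raw total lives in scalar_value)
LAYER_2_DISPLAY_SIZE = 1.0


@dataclass
class FlowNode:
    layer: int
    ref_id: str
    size: float
    hatch_fraction: float = 0.0
    scalar_value: float = 0.0
    extra: dict = field(default_factory=dict)


@dataclass
class FlowLink:
    from_node: str          # "<layer>:<ref_id>"
    to_node: str
    value: float
    polarity: str           # "supporting" | "opposing"


@dataclass
class FlowGraph:
    layers: dict[int, list[FlowNode]]
    links: list[FlowLink]
    mscore: float
    overlap: float          # support cancelled by opposing evidence (layer 6->7)

    def node(self, layer: int, ref_id: str) -> FlowNode:
        for n in self.layers[layer]:
            if n.ref_id == ref_id:
                return n
        raise EntityLookupError(f"no node {ref_id!r} in layer {layer}")

    # -- serialization (full double precision so a round trip is exact) --

    def to_dict(self) -> dict:
        return {
            "layers": {str(k): [asdict(n) for n in v] for k, v in self.layers.items()},
            "links": [asdict(l) for l in self.links],
            "mscore": self.mscore,
            "overlap": self.overlap,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FlowGraph":
        layers = {
            int(k): [FlowNode(**n) for n in v] for k, v in d["layers"].items()
        }
        links = [FlowLink(**l) for l in d["links"]]
        return cls(layers, links, d["mscore"], d["overlap"])

    @classmethod
    def from_json(cls, s: str) -> "FlowGraph":
        return cls.from_dict(json.loads(s))


def _nid(layer: int, ref_id: str) -> str:
    return f"{layer}:{ref_id}"


def build_flow(
    association: Association,
    streams: Mapping[str, EvidenceStream],
    weights: Mapping[str, float],
) -> FlowGraph:
    """Build the 8-layer provenance flow graph for a scored association.

    ``weights`` are the effective stream weights used for integration (any
    mapping, e.g. ``WeightSet.effective``).  Layer-7/8 values reproduce
    ``integrate`` exactly; the graph is a re-arrangement, not a re-model.
    """
    unknown = set(association.harmonized) - set(weights)
    if unknown:
        raise ConfigurationError(
            f"weights missing for streams {sorted(unknown)}"
        )
    result = integrate(association.harmonized, weights)
    stream_ids = [sid for sid in streams if sid in weights]

    layers: dict[int, list[FlowNode]] = {k: [] for k in range(1, 9)}
    links: list[FlowLink] = []

    # per-stream, per-target magnitude totals split by direction; literature
    # streams share one publication corpus, so an item may feed two streams
    totals: dict[str, float] = {sid: 0.0 for sid in stream_ids}
    by_target: dict[tuple[str, str, Direction], float] = {}
    for sid in stream_ids:
        source_ids = stream_source_ids(sid, streams)
        for item in association.items:
            if item.stream_id not in source_ids:
                continue
            totals[sid] += item.magnitude
            key = (sid, item.target_id, item.direction)
            by_target[key] = by_target.get(key, 0.0) + item.magnitude

    # layer 1: targets, sized by summed normalized share across streams
    target_sizes = {t: 0.0 for t in association.moa_targets}
    for (sid, target, direction), mag in by_target.items():
        if totals[sid] > 0 and target in target_sizes:
            share = mag / totals[sid]
            target_sizes[target] += share
            links.append(
                FlowLink(_nid(1, target), _nid(2, sid), share, direction.value)
            )
    for t in association.moa_targets:
        layers[1].append(FlowNode(1, t, target_sizes[t]))

    for sid in stream_ids:
        q = association.quant.get(sid)
        q_sup = q.q_supporting if q else 0.0
        q_opp = q.q_opposing if q else 0.0
        q_tot = q_sup + q_opp
        spec = streams[sid].saturation
        h = association.harmonized.get(sid)
        h_sup = h.h_supporting if h else 0.0
        h_opp = h.h_opposing if h else 0.0
        w = weights[sid]

        # layer 2: fixed-size stream node, hatched by the opposing fraction
        layers[2].append(
            FlowNode(
                2, sid,
                size=LAYER_2_DISPLAY_SIZE if q_tot > 0 else 0.0,
                hatch_fraction=(q_opp / q_tot) if q_tot > 0 else 0.0,
                scalar_value=q_tot,
            )
        )
        # layer 3: the saturation function, with a plottable curve sample
        xs = np.linspace(0.0, 4.0 * spec.scale, 50)
        layers[3].append(
            FlowNode(
                3, sid, size=1.0, scalar_value=spec.scale,
                extra={
                    "family": spec.family,
                    "curve_x": [float(x) for x in xs],
                    "curve_y": [spec(float(x)) for x in xs],
                },
            )
        )
        if q_sup > 0:
            links.append(FlowLink(_nid(2, sid), _nid(3, sid), q_sup, "supporting"))
        if q_opp > 0:
            links.append(FlowLink(_nid(2, sid), _nid(3, sid), q_opp, "opposing"))

        # layers 4-5: harmonized then weight-scaled components
        for direction, h_val in (("supporting", h_sup), ("opposing", h_opp)):
            ref = f"{sid}/{direction}"
            layers[4].append(FlowNode(4, ref, size=h_val, scalar_value=h_val))
            layers[5].append(FlowNode(5, ref, size=w * h_val, scalar_value=w * h_val))
            if h_val > 0:
                links.append(FlowLink(_nid(3, sid), _nid(4, ref), h_val, direction))
                links.append(FlowLink(_nid(4, ref), _nid(5, ref), w * h_val, direction))
                links.append(
                    FlowLink(_nid(5, ref), _nid(6, direction), w * h_val, direction)
                )

    # layer 6: polarity pools
    layers[6].append(
        FlowNode(6, "supporting", size=result.supporting_total,
                 scalar_value=result.supporting_total)
    )
    layers[6].append(
        FlowNode(6, "opposing", size=result.opposing_total,
                 scalar_value=result.opposing_total)
    )
    # layer 7: net aggregate; the overlap records cancelled support
    net = result.supporting_total - result.opposing_total
    layers[7].append(
        FlowNode(7, "net", size=abs(net), scalar_value=net,
                 extra={"overlap": result.opposing_total})
    )
    if result.supporting_total > 0:
        links.append(
            FlowLink(_nid(6, "supporting"), _nid(7, "net"),
                     result.supporting_total, "supporting")
        )
    if result.opposing_total > 0:
        links.append(
            FlowLink(_nid(6, "opposing"), _nid(7, "net"),
                     result.opposing_total, "opposing")
        )
    # layer 8: the Mscore and its direction
    layers[8].append(
        FlowNode(8, "mscore", size=abs(result.mscore), scalar_value=result.mscore,
                 extra={"direction": "toward" if result.mscore >= 0 else "against"})
    )
    if abs(result.mscore) > 0:
        links.append(
            FlowLink(_nid(7, "net"), _nid(8, "mscore"), abs(result.mscore),
                     "supporting" if result.mscore >= 0 else "opposing")
        )

    return FlowGraph(layers, links, result.mscore, result.opposing_total)


# --- drill-downs ----------------------------------------------------------


@dataclass
class VolcanoPoint:
    target_id: str
    effect_size: float
    neg_log10_p: float
    direction: str
    highlighted: bool


@dataclass
class CollectiveEvidenceView:
    stream_id: str
    kind: str  # "volcano" | "publications"
    points: list[VolcanoPoint] = field(default_factory=list)
    publications: list[dict] = field(default_factory=list)


def drilldown_collective(
    association: Association,
    target_id: str | None,
    stream: EvidenceStream,
    streams: Mapping[str, EvidenceStream] | None = None,
) -> CollectiveEvidenceView:
    """Collective evidence behind one target-stream link of the flow graph.

    For transcriptomics/proteomics streams returns volcano-plot coordinates
    ``(effect_size, -log10 p)`` for *all* of the stream's items, with items
    on ``target_id`` highlighted; ``target_id=None`` selects all links and
    highlights everything.  For literature streams returns the publication
    list (id, year, direction).  Pass the full ``streams`` config so a
    novelty stream can reach the shared literature corpus.
    """
    if streams is not None and stream.stream_id in streams:
        source_ids = stream_source_ids(stream.stream_id, streams)
    else:
        source_ids = {stream.stream_id}
    items = [it for it in association.items if it.stream_id in source_ids]
    if not items:
        raise EntityLookupError(
            f"no evidence link for stream {stream.stream_id!r} in this association"
        )
    if target_id is not None and target_id not in {it.target_id for it in items}:
        raise EntityLookupError(
            f"no link between target {target_id!r} and stream {stream.stream_id!r}"
        )
    if stream.modality in (Modality.TRANSCRIPTOMICS, Modality.PROTEOMICS):
        points = [
            VolcanoPoint(
                target_id=it.target_id,
                effect_size=float(it.payload.get("effect_size", 0.0)),
                neg_log10_p=float(-np.log10(float(it.payload.get("p_value", 1.0)))),
                direction=it.direction.value,
                highlighted=(target_id is None or it.target_id == target_id),
            )
            for it in items
        ]
        return CollectiveEvidenceView(stream.stream_id, "volcano", points=points)
    pubs = [
        {
            "publication_id": it.payload.get("publication_id"),
            "year": it.payload.get("year"),
            "direction": it.direction.value,
            "target_id": it.target_id,
            "highlighted": (target_id is None or it.target_id == target_id),
        }
        for it in items
    ]
    return CollectiveEvidenceView(stream.stream_id, "publications", publications=pubs)


@dataclass
class AnnotatedAbstract:
    text: str
    spans: list[tuple[int, int, str]]

    def highlighted_text(self, start: int, end: int) -> str:
        return self.text[start:end]


def merge_spans(
    spans: Sequence[tuple[int, int, str]], text_length: int
) -> list[tuple[int, int, str]]:
    """Clip spans to the text, then merge overlapping spans of equal label."""
    clipped = sorted(
        (max(0, s), min(text_length, e), lbl)
        for s, e, lbl in spans
        if min(text_length, e) > max(0, s)
    )
    merged: list[tuple[int, int, str]] = []
    for s, e, lbl in clipped:
        if merged and merged[-1][2] == lbl and s <= merged[-1][1]:
            ps, pe, plbl = merged[-1]
            merged[-1] = (ps, max(pe, e), plbl)
        else:
            merged.append((s, e, lbl))
    return merged


def drilldown_instance(item: EvidenceItem) -> AnnotatedAbstract:
    """The annotated abstract behind a single literature evidence item.

    Spans identified by the text-mining step are clipped to the abstract
    and overlapping same-label spans are merged, so consumers can render
    highlights without further validation.
    """
    text = str(item.payload.get("abstract", ""))
    spans = list(item.payload.get("spans", []) or [])
    return AnnotatedAbstract(text, merge_spans(spans, len(text)))
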