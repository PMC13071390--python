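"""Consensus scoring of multimodal drug-repurposing evidence.

A candidate association links a drug's mode of action (MoA, represented by
its molecular targets) to a new indication (a disease term).  Evidence for
the association arrives through independent *streams* — genomics,
transcriptomics, proteomics and literature (split into *overall*, over all
publications, and *novelty*, over recent ones).  Each stream's evidence
passes through four transformation boundaries:

1. **Collection** — qualitative evidence items, each supporting or opposing
   the association with a non-negative magnitude on the stream's native
   scale.
2. **Quantification** — items are reduced to a pair of non-negative
   quantities ``(q_supporting, q_opposing)``.  The default quantifier sums
   magnitudes per direction; alternatives can be registered per modality.
3. **Harmonization** — each quantity is squashed through a monotone
   saturating function ``g`` with ``g(0)=0`` and ``g -> 1``, making streams
   comparable.  The net harmonized evidence ``h_net = g(q_sup) - g(q_opp)``
   lies in ``[-1, 1]``.  Supporting and opposing components are saturated
   *independently*: a small raw opposition can nearly balance a large raw
   support once both saturate, and the flow view exposes exactly this skew.
4. **Integration** — a weighted sum over streams yields the consensus
   *Mscore* together with each stream's signed contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Modality",
    "Direction",
    "SaturationSpec",
    "EvidenceStream",
    "EvidenceItem",
    "QuantPair",
    "HarmonizedPair",
    "Association",
    "IntegrationResult",
    "quantify",
    "saturate",
    "harmonize",
    "integrate",
    "score_association",
    "register_quantifier",
]


class Modality(str, Enum):
    GENOMICS = "genomics"
    TRANSCRIPTOMICS = "transcriptomics"
    PROTEOMICS = "proteomics"
    LITERATURE_OVERALL = "literature_overall"
    LITERATURE_NOVELTY = "literature_novelty"
    CUSTOM = "custom"


class Direction(str, Enum):
    SUPPORTING = "supporting"
    OPPOSING = "opposing"


_SATURATION_FAMILIES = ("tanh", "hard_clip", "logistic_symmetric")


@dataclass(frozen=True)
class SaturationSpec:
    """A bounded monotone squashing function ``g: [0, inf) -> [0, 1)``.

    Families:

    - ``tanh``: ``g(q) = tanh(q / scale)`` (smooth, strictly increasing).
    - ``hard_clip``: ``g(q) = min(q / scale, 1)`` (piecewise linear,
      non-decreasing; reaches the bound exactly).
    - ``logistic_symmetric``: ``g(q) = 2 / (1 + exp(-q / scale)) - 1``,
      the logistic curve re-centred so ``g(0) = 0``.

    ``scale`` sets the evidence quantity at which saturation bites; it is
    expressed on the stream's native magnitude scale.
    """

    family: str = "tanh"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _SATURATION_FAMILIES:
            raise ValidationError(
                f"unknown saturation family {self.family!r}; "
                f"expected one of {_SATURATION_FAMILIES}"
            )
        if not self.scale > 0:
            raise ValidationError(f"saturation scale must be > 0, got {self.scale}")

    def __call__(self, q: float) -> float:
        return saturate(q, self)


@dataclass(frozen=True)
class EvidenceStream:
    """Configuration of one evidence stream."""

    stream_id: str
    name: str = ""
    modality: Modality = Modality.CUSTOM
    saturation: SaturationSpec = field(default_factory=SaturationSpec)
    default_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.default_weight < 0:
            raise ValidationError(
                f"stream {self.stream_id!r}: default_weight must be >= 0"
            )
        if isinstance(self.modality, str) and not isinstance(self.modality, Modality):
            object.__setattr__(self, "modality", Modality(self.modality))
        if not self.name:
            object.__setattr__(self, "name", self.stream_id)


@dataclass(frozen=True)
class EvidenceItem:
    """One piece of qualitative evidence on a stream's native scale.

    ``payload`` carries stream-specific attributes: omics items have
    ``effect_size`` (signed) and ``p_value`` in (0, 1]; literature items
    have ``publication_id``, ``year``, optionally ``abstract`` text and
    ``spans`` — 0-based half-open ``(start, end, label)`` character offsets
    into the abstract.
    """

    stream_id: str
    target_id: str
    direction: Direction
    magnitude: float
    payload: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.direction, str) and not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", Direction(self.direction))
        if self.magnitude < 0:
            raise ValidationError(
                f"evidence magnitude must be >= 0, got {self.magnitude}"
            )
        p = self.payload.get("p_value")
        if p is not None and not (0 < float(p) <= 1):
            raise ValidationError(f"p_value must lie in (0, 1], got {p}")
        abstract = self.payload.get("abstract")
        spans = self.payload.get("spans")
        if spans is not None and abstract is not None:
            n = len(str(abstract))
            for start, end, _label in spans:  # type: ignore[misc]
                if not (0 <= start <= end <= n):
                    raise ValidationError(
                        f"annotation span ({start}, {end}) outside abstract of length {n}"
                    )


@dataclass(frozen=True)
class QuantPair:
    """Quantified evidence of one stream, split by direction."""

    stream_id: str
    q_supporting: float
    q_opposing: float

    def __post_init__(self) -> None:
        if self.q_supporting < 0 or self.q_opposing < 0:
            raise ValidationError("quantified evidence components must be >= 0")


@dataclass(frozen=True)
class HarmonizedPair:
    """Saturated (harmonized) evidence of one stream; ``h_net`` in [-1, 1]."""

    stream_id: str
    h_supporting: float
    h_opposing: float

    @property
    def h_net(self) -> float:
        return self.h_supporting - self.h_opposing


@dataclass
class IntegrationResult:
    mscore: float
    contributions: dict[str, float]
    supporting_total: float
    opposing_total: float


@dataclass
class Association:
    """A scored MoA-indication candidate with full evidence provenance."""

    moa_id: str
    moa_targets: list[str]
    indication_id: str
    items: list[EvidenceItem] = field(default_factory=list)
    quant: dict[str, QuantPair] = field(default_factory=dict)
    harmonized: dict[str, HarmonizedPair] = field(default_factory=dict)
    contributions: dict[str, float] = field(default_factory=dict)
    mscore: float = 0.0


# --- quantification -------------------------------------------------------

Quantifier = Callable[[Sequence[EvidenceItem], EvidenceStream, int], QuantPair]

_QUANTIFIERS: dict[Modality, Quantifier] = {}


def register_quantifier(modality: Modality | str, fn: Quantifier) -> None:
    """Register a custom quantifier for a modality.

    The default quantifier is a signed magnitude sum (novelty streams first
    filter publications by year).  Registering replaces it for that
    modality; pass the default back to restore.
    """
    _QUANTIFIERS[Modality(modality)] = fn


def _default_quantify(
    items: Sequence[EvidenceItem], stream: EvidenceStream, novelty_year_cutoff: int
) -> QuantPair:
    q_sup = 0.0
    q_opp = 0.0
    for item in items:
        if stream.modality is Modality.LITERATURE_NOVELTY:
            year = item.payload.get("year")
            if year is None:
                raise ValidationError(
                    f"literature item {item.target_id!r} lacks a publication year"
                )
            if int(year) < novelty_year_cutoff:
                continue
        if item.direction is Direction.SUPPORTING:
            q_sup += item.magnitude
        else:
            q_opp += item.magnitude
    return QuantPair(stream.stream_id, q_sup, q_opp)


def quantify(
    items: Iterable[EvidenceItem],
    stream: EvidenceStream,
    novelty_year_cutoff: int = 2021,
) -> QuantPair:
    """Reduce a stream's evidence items to a ``(q_supporting, q_opposing)`` pair.

    Items must belong to ``stream`` (by ``stream_id``).  For a
    ``literature_novelty`` stream only publications with
    ``year >= novelty_year_cutoff`` count; ``literature_overall`` counts all.
    """
    items = list(items)
    for item in items:
        if item.stream_id != stream.stream_id:
            raise ConfigurationError(
                f"item with stream_id {item.stream_id!r} passed to stream "
                f"{stream.stream_id!r}"
            )
    fn = _QUANTIFIERS.get(stream.modality, _default_quantify)
    pair = fn(items, stream, novelty_year_cutoff)
    if pair.stream_id != stream.stream_id:
        raise ConfigurationError("quantifier returned a pair for the wrong stream")
    return pair


# --- harmonization --------------------------------------------------------


def saturate(q: float, spec: SaturationSpec) -> float:
    """Apply the saturation function ``g`` of ``spec`` to a quantity ``q >= 0``."""
    if q < 0:
        raise ValidationError(
            f"saturate expects a non-negative quantity, got {q}; "
            "signed evidence must arrive pre-split into a QuantPair"
        )
    x = q / spec.scale
    if spec.family == "tanh":
        return math.tanh(x)
    if spec.family == "hard_clip":
        return min(x, 1.0)
    # logistic_symmetric
    return 2.0 / (1.0 + math.exp(-x)) - 1.0


def harmonize(quant: QuantPair, spec: SaturationSpec) -> HarmonizedPair:
    """Saturate the supporting and opposing components independently."""
    return HarmonizedPair(
        quant.stream_id,
        h_supporting=saturate(quant.q_supporting, spec),
        h_opposing=saturate(quant.q_opposing, spec),
    )


# --- integration ----------------------------------------------------------


def integrate(
    harmonized: Mapping[str, HarmonizedPair],
    weights: Mapping[str, float],
) -> IntegrationResult:
    """Weighted sum of harmonized net evidence: the consensus Mscore.

    ``weights`` maps stream_id to a non-negative weight (a plain mapping or
    a :class:`~repurscore.ranking.WeightSet`'s effective weights).  A stream
    configured in ``weights`` but absent from ``harmonized`` counts as a
    zero pair; a harmonized stream missing from ``weights`` is a
    configuration error (toggling a stream off is done with weight 0, not
    by dropping it).
    """
    weights = dict(weights)
    for stream_id, w in weights.items():
        if w < 0:
            raise ValidationError(f"weight for stream {stream_id!r} must be >= 0")
    unknown = set(harmonized) - set(weights)
    if unknown:
        raise ConfigurationError(
            f"harmonized evidence for streams absent from the weight set: "
            f"{sorted(unknown)}"
        )
    contributions: dict[str, float] = {}
    supporting_total = 0.0
    opposing_total = 0.0
    mscore = 0.0
    for stream_id, w in weights.items():
        pair = harmonized.get(stream_id)
        h_sup = pair.h_supporting if pair is not None else 0.0
        h_opp = pair.h_opposing if pair is not None else 0.0
        contributions[stream_id] = w * (h_sup - h_opp)
        supporting_total += w * h_sup
        opposing_total += w * h_opp
        mscore += contributions[stream_id]
    return IntegrationResult(mscore, contributions, supporting_total, opposing_total)


_LIT_MODALITIES = frozenset({Modality.LITERATURE_OVERALL, Modality.LITERATURE_NOVELTY})


def stream_source_ids(stream_id: str, streams: Mapping[str, EvidenceStream]) -> set[str]:
    """Stream ids whose items feed ``stream_id``.

    Literature streams share one publication corpus: an item tagged with
    any literature stream id feeds both the overall and the novelty stream
    (novelty applies its year filter during quantification).  Every other
    stream consumes only items tagged with its own id.
    """
    stream = streams[stream_id]
    if stream.modality in _LIT_MODALITIES:
        return {sid for sid, s in streams.items() if s.modality in _LIT_MODALITIES}
    return {stream_id}


def score_association(
    moa_id: str,
    moa_targets: Sequence[str],
    indication_id: str,
    items: Iterable[EvidenceItem],
    streams: Mapping[str, EvidenceStream],
    weights: Mapping[str, float] | None = None,
    novelty_year_cutoff: int = 2021,
) -> Association:
    """Run the full pipeline (quantify, harmonize, integrate) for one candidate.

    ``weights`` defaults to each stream's ``default_weight``.  Literature
    items feed both the overall and the novelty stream: an item whose
    ``stream_id`` names either literature stream is quantified under every
    configured literature stream (novelty applies its year filter), mirroring
    how a single publication corpus yields two quantitative values.
    """
    items = list(items)
    known = set(streams)
    for item in items:
        if item.stream_id not in known:
            raise ConfigurationError(
                f"evidence item references unconfigured stream {item.stream_id!r}"
            )
    if weights is None:
        weights = {sid: s.default_weight for sid, s in streams.items()}

    quant: dict[str, QuantPair] = {}
    harmonized: dict[str, HarmonizedPair] = {}
    for sid, stream in streams.items():
        source_ids = stream_source_ids(sid, streams)
        stream_items = [
            it if it.stream_id == sid
            else EvidenceItem(sid, it.target_id, it.direction, it.magnitude, it.payload)
            for it in items
            if it.stream_id in source_ids
        ]
        quant[sid] = quantify(stream_items, stream, novelty_year_cutoff)
        harmonized[sid] = harmonize(quant[sid], stream.saturation)

    result = integrate(harmonized, weights)
    return Association(
        moa_id=moa_id,
        moa_targets=list(moa_targets),
        indication_id=indication_id,
        items=items,
        quant=quant,
        harmonized=harmonized,
        contributions=result.contributions,
        mscore=result.mscore,
    )
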