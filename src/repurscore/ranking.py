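"""Ranking of candidate indications and what-if weight comparison.

For one MoA, every candidate indication is ranked by its consensus Mscore.
Analysts probe the robustness of a ranking by toggling evidence streams on
and off and by defining up to five labelled weight sets (A-E), one of which
is the *reference*; each row then shows its rank under every set and a rank
delta against the reference (positive = the row moved up).

Ranks are competition style: tied rows share the minimal rank and the next
rank skips by the tie-group size (1, 2, 2, 4).  Scores closer than a small
epsilon are treated as tied, and a separate near-tie report surfaces rows
whose score differences are negligible at a coarser, user-chosen epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .errors import ConfigurationError, EntityLookupError, LimitError, ValidationError
from .evidence_model import Association, integrate

__all__ = [
    "WeightSet",
    "RankedRow",
    "RankedTable",
    "MAX_WEIGHT_SETS",
    "TIE_EPSILON",
    "rank",
    "toggle_stream",
    "compare_weight_sets",
    "near_ties",
]

MAX_WEIGHT_SETS = 5
#: scores within this distance are assigned the same competition rank
TIE_EPSILON = 1e-9

_LABELS = "ABCDE"


@dataclass(frozen=True)
class WeightSet:
    """A labelled assignment of non-negative weights to streams.

    Toggling a stream off zeroes its *effective* weight while remembering
    the configured value in ``disabled``, so toggling back on restores the
    set exactly.
    """

    label: str
    weights: Mapping[str, float]
    is_reference: bool = False
    disabled: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.label) != 1 or self.label not in _LABELS:
            raise ValidationError(
                f"weight-set label must be a single letter A-E, got {self.label!r}"
            )
        for sid, w in self.weights.items():
            if w < 0:
                raise ValidationError(f"weight for stream {sid!r} must be >= 0")
        object.__setattr__(self, "weights", dict(self.weights))
        object.__setattr__(self, "disabled", dict(self.disabled))

    @property
    def effective(self) -> dict[str, float]:
        """Weights with toggled-off streams zeroed."""
        return {
            sid: (0.0 if sid in self.disabled else w)
            for sid, w in self.weights.items()
        }


def toggle_stream(weights: WeightSet, stream_id: str, on: bool) -> WeightSet:
    """Return a copy of ``weights`` with ``stream_id`` toggled on or off."""
    if stream_id not in weights.weights:
        raise ConfigurationError(f"unknown stream {stream_id!r} in weight set")
    disabled = dict(weights.disabled)
    if on:
        disabled.pop(stream_id, None)
    else:
        disabled[stream_id] = weights.weights[stream_id]
    return replace(weights, disabled=disabled)


@dataclass
class RankedRow:
    indication_id: str
    mscores: dict[str, float]      # weight-set label -> Mscore
    ranks: dict[str, int]          # weight-set label -> competition rank
    rank_delta: dict[str, int]     # label -> reference_rank - this_rank


@dataclass
class RankedTable:
    moa_id: str
    rows: list[RankedRow]
    #: per weight-set label, the sets of indication ids sharing a rank
    tie_groups: dict[str, list[frozenset[str]]]
    reference_label: str


def _competition_ranks(
    scored: Sequence[tuple[str, float]], epsilon: float = TIE_EPSILON
) -> tuple[dict[str, int], list[frozenset[str]]]:
    """Competition ranks for (indication, score) pairs sorted by caller.

    Ties are chained: a run of consecutive scores each within ``epsilon``
    of the previous one forms one group sharing the minimal rank.
    """
    order = sorted(scored, key=lambda t: (-t[1], t[0]))
    ranks: dict[str, int] = {}
    groups: list[frozenset[str]] = []
    i = 0
    position = 1
    while i < len(order):
        j = i
        while j + 1 < len(order) and order[j][1] - order[j + 1][1] <= epsilon:
            j += 1
        members = [order[k][0] for k in range(i, j + 1)]
        for m in members:
            ranks[m] = position
        if len(members) > 1:
            groups.append(frozenset(members))
        position += len(members)
        i = j + 1
    return ranks, groups


def rank(associations: Sequence[Association], weights: WeightSet) -> RankedTable:
    """Rank candidate indications of one MoA by Mscore under one weight set.

    Rows are ordered by descending Mscore; tied rows keep lexicographic
    indication order for display but share a competition rank.
    """
    return compare_weight_sets(associations, [weights], weights.label)


def compare_weight_sets(
    associations: Sequence[Association],
    sets: Sequence[WeightSet],
    reference_label: str,
) -> RankedTable:
    """Score and rank every association under each weight set.

    At most :data:`MAX_WEIGHT_SETS` sets may be compared at once; labels
    must be unique and ``reference_label`` must name one of them.  Rank
    deltas are ``reference_rank - rank_under_set``, so a positive delta
    means the row climbed relative to the reference.
    """
    if not sets:
        raise ValidationError("at least one weight set is required")
    if len(sets) > MAX_WEIGHT_SETS:
        raise LimitError(
            f"at most {MAX_WEIGHT_SETS} weight sets may be compared, got {len(sets)}"
        )
    labels = [ws.label for ws in sets]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate weight-set labels: {labels}")
    if reference_label not in labels:
        raise EntityLookupError(f"reference label {reference_label!r} not among {labels}")

    moa_ids = {a.moa_id for a in associations}
    if len(moa_ids) > 1:
        raise ConfigurationError(
            f"associations span multiple MoAs: {sorted(moa_ids)}"
        )
    moa_id = next(iter(moa_ids)) if moa_ids else ""

    per_set_scores: dict[str, dict[str, float]] = {}
    per_set_ranks: dict[str, dict[str, int]] = {}
    tie_groups: dict[str, list[frozenset[str]]] = {}
    for ws in sets:
        eff = ws.effective
        scores = {
            a.indication_id: integrate(a.harmonized, eff).mscore
            for a in associations
        }
        per_set_scores[ws.label] = scores
        per_set_ranks[ws.label], tie_groups[ws.label] = _competition_ranks(
            list(scores.items())
        )

    ref_ranks = per_set_ranks[reference_label]
    ref_scores = per_set_scores[reference_label]
    indication_order = sorted(
        (a.indication_id for a in associations),
        key=lambda ind: (-ref_scores[ind], ind),
    )
    rows = [
        RankedRow(
            indication_id=ind,
            mscores={lbl: per_set_scores[lbl][ind] for lbl in labels},
            ranks={lbl: per_set_ranks[lbl][ind] for lbl in labels},
            rank_delta={
                lbl: ref_ranks[ind] - per_set_ranks[lbl][ind] for lbl in labels
            },
        )
        for ind in indication_order
    ]
    return RankedTable(moa_id, rows, tie_groups, reference_label)


def near_ties(
    table: RankedTable, epsilon: float, label: str | None = None
) -> list[frozenset[str]]:
    """Groups of indications whose Mscores differ by less than ``epsilon``.

    Near-ties are easy to overlook in a ranking; this report surfaces runs
    of rows with negligible score differences under one weight set
    (default: the reference set).
    """
    label = label or table.reference_label
    scored = [(row.indication_id, row.mscores[label]) for row in table.rows]
    _ranks, groups = _competition_ranks(scored, epsilon=epsilon)
    return groups
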