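"""Fuzzy cross-ontology disease-name matching (MeSH -> MONDO).

Candidate indication names drawn from MeSH must be located in a knowledge
graph keyed by MONDO names, where the same disease is often written with
different word order, punctuation and casing ("Pneumonia, Bacterial" vs
"bacterial pneumonia").  Names are therefore normalized — Unicode casefold,
punctuation stripped to word characters plus internal hyphens, tokens
sorted — and compared with a normalized Levenshtein similarity on a 0-100
scale; candidates at or above a threshold (default 85) are returned for the
analyst to confirm or discard.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib

from .errors import ValidationError

__all__ = ["MatchCandidate", "DEFAULT_THRESHOLD", "normalize_name",
           "name_similarity", "match_disease"]

DEFAULT_THRESHOLD = 85.0

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+(?:-[0-9A-Za-z]+)*")


@dataclass(frozen=True)
class MatchCandidate:
    query_name: str
    candidate_name: str
    candidate_id: str
    similarity: float
    accepted: bool = True


def normalize_name(name: str) -> str:
    """Casefold, strip punctuation (keeping internal hyphens), sort tokens.

    Idempotent: normalizing a normalized name returns it unchanged.
    """
    tokens = _TOKEN_RE.findall(name.casefold())
    return " ".join(sorted(tokens))


def name_similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity of two names on a 0-100 scale.

    ``100 * (1 - d / max(len))`` over the normalized forms; symmetric in
    its arguments.  Two names normalizing to the empty string are treated
    as identical.
    """
    na, nb = normalize_name(a), normalize_name(b)
    longest = max(len(na), len(nb))
    if longest == 0:
        return 100.0
    dist = edlib.align(na, nb, task="distance", mode="NW")["editDistance"]
    return 100.0 * (1.0 - dist / longest)


def match_disease(
    query: str,
    candidates: Iterable[tuple[str, str]],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[MatchCandidate]:
    """Rank ``(id, name)`` candidates against ``query`` by name similarity.

    Returns candidates scoring at least ``threshold`` (0-100), sorted by
    similarity descending with ties broken by candidate name.  The caller
    presents these to the analyst for curation; nothing is auto-selected
    beyond the threshold cut.
    """
    if not query or not normalize_name(query):
        raise ValidationError("query disease name must be non-empty")
    if not (0 <= threshold <= 100):
        raise ValidationError(f"threshold must lie in [0, 100], got {threshold}")
    results = [
        MatchCandidate(
            query_name=query,
            candidate_name=name,
            candidate_id=cid,
            similarity=name_similarity(query, name),
        )
        for cid, name in candidates
    ]
    kept = [m for m in results if m.similarity >= threshold]
    kept.sort(key=lambda m: (-m.similarity, m.candidate_name))
    return kept
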