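"""Fuzzy-match MeSH-style disease names to MONDO-style candidates.

Names from different ontologies disagree in word order, punctuation and
case; token-sorted normalized Levenshtein similarity recovers the intended
counterpart.
"""

from repurscore import match_disease, normalize_name

candidates = [
    ("MONDO:0005113", "bacterial pneumonia"),
    ("MONDO:0005709", "viral pneumonia"),
    ("MONDO:0005249", "pneumonia"),
    ("MONDO:0004967", "bacterial meningitis"),
    ("MONDO:0011849", "atypical bacterial pneumonia"),
]

query = "Pneumonia, Bacterial"
print(f"query: {query!r}  (normalized: {normalize_name(query)!r})\n")
for m in match_disease(query, candidates, threshold=60):
    print(f"  {m.similarity:6.1f}  {m.candidate_id}  {m.candidate_name}")

# Similarity is 0-100 (100 = identical after normalization); only
# candidates at or above the threshold are returned, sorted best-first,
# for the analyst to confirm or discard.
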