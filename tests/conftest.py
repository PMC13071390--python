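import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from repurscore import (
    Direction,
    EvidenceItem,
    EvidenceStream,
    FixtureSpec,
    Modality,
    SaturationSpec,
    default_streams,
    gen_evidence,
    score_association,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

TARGETS = [f"T{i}" for i in range(5)]


@pytest.fixture(scope="session")
def streams() -> dict[str, EvidenceStream]:
    return default_streams()


@pytest.fixture(scope="session")
def scored_associations(streams):
    """Twelve associations scored from one seeded synthetic evidence set."""
    spec = FixtureSpec(seed=7, n_indications=12)
    items_by_ind, _ = gen_evidence(spec)
    return [
        score_association(
            "MOA1", TARGETS, ind, items, streams,
            novelty_year_cutoff=spec.novelty_year_cutoff,
        )
        for ind, items in items_by_ind.items()
    ]


def random_association(rng: np.random.Generator, streams, n_items: int = 10):
    """A raw random association for conservation-style checks."""
    sids = [s for s in streams if streams[s].modality is not Modality.LITERATURE_NOVELTY]
    items = []
    for _ in range(int(rng.integers(0, n_items + 1))):
        sid = str(rng.choice(sids))
        payload = {}
        if streams[sid].modality is Modality.LITERATURE_OVERALL:
            payload = {"year": int(rng.integers(2000, 2026)),
                       "publication_id": "P"}
            magnitude = 1.0
        else:
            magnitude = float(rng.uniform(0, 5))
        items.append(
            EvidenceItem(
                sid,
                str(rng.choice(TARGETS)),
                Direction.OPPOSING if rng.random() < 0.3 else Direction.SUPPORTING,
                magnitude,
                payload,
            )
        )
    return score_association("MOA1", TARGETS, "IND", items, streams)
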