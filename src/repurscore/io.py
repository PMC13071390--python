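"""Configuration loading and TSV/JSON (de)serialization shared by all modules.

The structured configuration (JSON) declares the evidence streams — id,
modality, saturation family/scale, default weight — plus the novelty year
cutoff and analysis thresholds.  Unknown keys are rejected so typos fail
loudly.  Evidence tables are TSV, keyed by (moa_id, indication_id,
stream_id) with stream-specific payload columns; annotation spans are
0-based half-open character offsets, serialized as JSON in the ``spans``
column (or as ``span_start``/``span_end``/``span_label`` triplets for
single-span rows).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigurationError, ValidationError
from .evidence_model import EvidenceItem, EvidenceStream, Modality, SaturationSpec

__all__ = ["RunConfig", "StreamConfig", "load_config", "load_evidence",
           "dump_json"]


class SaturationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    family: str = "tanh"
    scale: float = 1.0


class StreamConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    stream_id: str
    name: str = ""
    modality: str = "custom"
    saturation: SaturationConfig = Field(default_factory=SaturationConfig)
    weight: float = 1.0

    @field_validator("weight")
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("stream weight must be >= 0")
        return v


class ThresholdConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fuzzy_match: float = 85.0
    tie_epsilon: float = 1e-9
    path_cap: int = 10_000


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    streams: list[StreamConfig]
    novelty_year_cutoff: int = 2021
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    seed: int = 0
    verbosity: str = "info"
    evidence_path: str | None = None
    kg_path: str | None = None
    ontology_path: str | None = None

    def stream_map(self) -> dict[str, EvidenceStream]:
        out: dict[str, EvidenceStream] = {}
        for sc in self.streams:
            if sc.stream_id in out:
                raise ConfigurationError(f"duplicate stream_id {sc.stream_id!r}")
            out[sc.stream_id] = EvidenceStream(
                stream_id=sc.stream_id,
                name=sc.name or sc.stream_id,
                modality=Modality(sc.modality),
                saturation=SaturationSpec(sc.saturation.family, sc.saturation.scale),
                default_weight=sc.weight,
            )
        return out

    def default_weights(self) -> dict[str, float]:
        return {sc.stream_id: sc.weight for sc in self.streams}


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = json.load(fh)
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic error -> package error category
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc


def _opt_float(value) -> float | None:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def load_evidence(
    path, base_dir: str | Path | None = None
) -> dict[tuple[str, str], list[EvidenceItem]]:
    """Load an evidence TSV into items grouped by (moa_id, indication_id).

    Payload columns are optional; ``abstract_file`` references are resolved
    relative to ``base_dir`` (default: the TSV's directory) and the file
    content is attached as the ``abstract`` payload.  Spans are validated
    against the abstract at load time.
    """
    path = Path(path)
    if base_dir is None:
        base_dir = path.parent
    df = pd.read_csv(path, sep="\t", dtype={"moa_id": str, "indication_id": str,
                                            "stream_id": str, "target_id": str})
    required = {"moa_id", "indication_id", "stream_id", "target_id",
                "direction", "magnitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"evidence table missing columns: {sorted(missing)}")

    grouped: dict[tuple[str, str], list[EvidenceItem]] = {}
    for row in df.itertuples(index=False):
        payload: dict[str, object] = {}
        get = lambda col: getattr(row, col, None) if col in df.columns else None
        for col in ("effect_size", "p_value"):
            v = _opt_float(get(col))
            if v is not None:
                payload[col] = v
        pub = get("publication_id")
        if isinstance(pub, str) and pub:
            payload["publication_id"] = pub
        year = _opt_float(get("year"))
        if year is not None:
            payload["year"] = int(year)
        abstract = get("abstract")
        if not (isinstance(abstract, str) and abstract):
            abstract_file = get("abstract_file")
            if isinstance(abstract_file, str) and abstract_file:
                abstract = (Path(base_dir) / abstract_file).read_text()
            else:
                abstract = None
        if abstract is not None:
            payload["abstract"] = abstract
        spans_raw = get("spans")
        if isinstance(spans_raw, str) and spans_raw:
            payload["spans"] = [tuple(s) for s in json.loads(spans_raw)]
        else:
            start, end = _opt_float(get("span_start")), _opt_float(get("span_end"))
            if start is not None and end is not None:
                label = get("span_label") or ""
                payload["spans"] = [(int(start), int(end), str(label))]
        item = EvidenceItem(
            stream_id=str(row.stream_id),
            target_id=str(row.target_id),
            direction=str(row.direction),
            magnitude=float(row.magnitude),
            payload=payload,
        )
        grouped.setdefault((str(row.moa_id), str(row.indication_id)), []).append(item)
    return grouped


def dump_json(obj, path) -> None:
    """Write JSON deterministically (sorted keys, stable float repr)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
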