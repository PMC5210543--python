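"""Evidence data model and validation.

An evidence record is one unit of target-disease evidence from one data
source, carried as a JSON object. Records are validated against the bundled
JSON schema, the datasource/datatype pairing is checked against the
controlled vocabulary, and the disease term must be a node of the loaded
disease ontology. Identifier checks are syntactic (schema patterns) plus
ontology membership — no network lookups. Evidence-code (ECO) terms and
literature references are carried as opaque provenance metadata and never
interpreted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

from . import _schema
from .constants import DATASOURCE_TO_DATATYPE

logger = logging.getLogger(__name__)

_SCHEMA: dict | None = None


def evidence_schema() -> dict:
    """The bundled JSON schema that every evidence record must satisfy."""
    global _SCHEMA
    if _SCHEMA is None:
        ref = resources.files("tdscore.data") / "evidence.schema.json"
        _SCHEMA = json.loads(ref.read_text())
    return _SCHEMA


@dataclass(frozen=True)
class EvidenceRecord:
    evidence_id: str
    target_id: str
    disease_id: str
    datasource: str
    datatype: str
    payload: Mapping = field(default_factory=dict)
    eco_code: str | None = None
    literature_refs: tuple[str, ...] = ()

    def to_json(self) -> str:
        d = asdict(self)
        d["payload"] = dict(self.payload)
        d["literature_refs"] = list(self.literature_refs)
        if d["eco_code"] is None:
            del d["eco_code"]
        return json.dumps(d, sort_keys=True)


@dataclass
class ValidationReport:
    """Outcome of validating a batch: counts plus every recorded violation."""

    n_input: int = 0
    n_valid: int = 0
    errors: list[tuple[int, str, str]] = field(default_factory=list)

    def add_errors(self, index: int, kind: str, messages: Iterable[str]) -> None:
        for msg in messages:
            self.errors.append((index, kind, msg))

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_valid": self.n_valid,
                "errors": [
                    {"record": i, "kind": k, "message": m} for i, k, m in self.errors
                ],
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"{self.n_valid}/{self.n_input} records valid"]
        for i, kind, msg in self.errors:
            lines.append(f"  record {i}: [{kind}] {msg}")
        return "\n".join(lines)


def validate_record(raw: Mapping, ontology) -> EvidenceRecord | list[tuple[str, str]]:
    """Validate one parsed JSON object; return a record or all violations.

    Checks, in order but accumulating rather than short-circuiting where
    possible: schema conformance, datasource/datatype consistency with the
    controlled grouping, and membership of the disease term in ``ontology``
    (anything supporting ``in``).
    """
    errors: list[tuple[str, str]] = [
        ("schema", msg) for msg in _schema.validate(raw, evidence_schema())
    ]

    datasource = raw.get("datasource")
    datatype = raw.get("datatype")
    expected = DATASOURCE_TO_DATATYPE.get(datasource)
    if expected is not None and datatype != expected:
        errors.append(
            (
                "datatype_mismatch",
                f"datasource {datasource!r} belongs to datatype {expected!r}, "
                f"record says {datatype!r}",
            )
        )

    disease = raw.get("disease_id")
    if isinstance(disease, str) and ontology is not None and disease not in ontology:
        errors.append(("unknown_disease", f"disease term {disease!r} not in the loaded ontology"))

    if errors:
        return errors
    return EvidenceRecord(
        evidence_id=raw["evidence_id"],
        target_id=raw["target_id"],
        disease_id=raw["disease_id"],
        datasource=raw["datasource"],
        datatype=raw["datatype"],
        payload=raw.get("payload", {}),
        eco_code=raw.get("eco_code"),
        literature_refs=tuple(raw.get("literature_refs", ())),
    )


def validate_batch(
    lines: Iterable[str] | IO[str],
    ontology,
    duplicate_policy: str = "first-wins",
) -> tuple[list[EvidenceRecord], ValidationReport]:
    """Validate a JSON Lines stream; order-preserving and deterministic.

    Unreadable lines are recorded as errors and processing continues.
    ``duplicate_policy`` handles repeated evidence_ids: ``"first-wins"``
    keeps the first occurrence (logging a warning), ``"error"`` records a
    violation instead.
    """
    if duplicate_policy not in ("first-wins", "error"):
        raise ValueError(f"unknown duplicate policy {duplicate_policy!r}")
    report = ValidationReport()
    records: list[EvidenceRecord] = []
    seen: set[str] = set()
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        report.n_input += 1
        try:
            raw = json.loads(line)
        except json.JSONDecodeError as exc:
            report.add_errors(i, "parse", [str(exc)])
            continue
        result = validate_record(raw, ontology)
        if isinstance(result, list):
            for kind, msg in result:
                report.add_errors(i, kind, [msg])
            continue
        if result.evidence_id in seen:
            if duplicate_policy == "error":
                report.add_errors(
                    i, "duplicate", [f"evidence_id {result.evidence_id!r} already seen"]
                )
            else:
                logger.warning(
                    "duplicate evidence_id %r at line %d dropped (first-wins)",
                    result.evidence_id,
                    i,
                )
            continue
        seen.add(result.evidence_id)
        records.append(result)
        report.n_valid += 1
    return records, report


def read_evidence(path: str | Path, ontology, **kwargs) -> tuple[list[EvidenceRecord], ValidationReport]:
    """validate_batch over a UTF-8 JSON Lines file."""
    with open(path, encoding="utf-8") as fh:
        return validate_batch(fh, ontology, **kwargs)


def write_evidence(records: Iterable[EvidenceRecord], path: str | Path) -> int:
    """Write records as JSON Lines; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")
            n += 1
    return n
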