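"""End-to-end driver: validate -> score -> propagate -> aggregate -> export.

The run produces an association table (TSV and JSON), a machine-readable
manifest reconciling record counts at every stage, and is byte-identical
when re-run on identical inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

from . import __version__
from .aggregate import (
    AggregationConfig,
    AssociationRow,
    associations_to_frame,
    build_associations,
)
from .evidence import read_evidence
from .ontology import load_ontology
from .scoring import ScoringConfig, score_evidence

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    evidence_path: str
    ontology_path: str
    config_path: str | None
    n_input: int = 0
    n_valid: int = 0
    n_scored: int = 0
    n_associations: int = 0
    propagated: bool = True
    normalized: bool = True
    seed: int | None = None
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class RunResult:
    manifest: RunManifest
    associations: list[AssociationRow]
    scores: Mapping[str, "ScoreComponents"] = field(default_factory=dict)  # noqa: F821
    records: list = field(default_factory=list)
    ontology: "DiseaseOntology | None" = None  # noqa: F821


def run(
    evidence_path: str | Path,
    ontology_path: str | Path,
    config_path: str | Path | None = None,
    out_dir: str | Path | None = None,
    propagate: bool = True,
    normalized: bool = True,
    cap: int = 100,
    seed: int | None = None,
) -> RunResult:
    """Run the full pipeline; optionally write the association table,
    validation report and manifest under ``out_dir``."""
    config = ScoringConfig.from_yaml(config_path) if config_path else ScoringConfig()
    agg = AggregationConfig(cap=cap, normalized=normalized)
    ontology = load_ontology(ontology_path)

    records, report = read_evidence(evidence_path, ontology)
    if report.errors:
        logger.warning("validation recorded %d error(s)", len(report.errors))
    if not records:
        logger.warning("no valid evidence records; association table will be empty")

    scores = {rec.evidence_id: score_evidence(rec, config) for rec in records}
    rows = build_associations(
        records, scores, ontology, config, agg, propagate=propagate
    )

    manifest = RunManifest(
        evidence_path=str(evidence_path),
        ontology_path=str(ontology_path),
        config_path=str(config_path) if config_path else None,
        n_input=report.n_input,
        n_valid=report.n_valid,
        n_scored=len(scores),
        n_associations=len(rows),
        propagated=propagate,
        normalized=normalized,
        seed=seed,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame = associations_to_frame(rows)
        frame.to_csv(out / "associations.tsv", sep="\t", index=False, float_format="%.10g")
        frame.to_json(out / "associations.json", orient="records", indent=2)
        (out / "validation_report.json").write_text(report.to_json())
        (out / "manifest.json").write_text(manifest.to_json())

    return RunResult(
        manifest=manifest,
        associations=rows,
        scores=scores,
        records=records,
        ontology=ontology,
    )


def explain(target_id: str, disease_id: str, result: RunResult) -> dict:
    """Evidence breakdown for one association: contributing evidence with
    per-evidence scores, the per-source and per-type tiers, and whether the
    pair is directly annotated or inherited. Empty dict-of-lists when the
    pair has no evidence."""
    row = next(
        (
            r
            for r in result.associations
            if r.target_id == target_id and r.disease_id == disease_id
        ),
        None,
    )
    if row is None:
        return {
            "target_id": target_id,
            "disease_id": disease_id,
            "evidence": [],
            "source_scores": {},
            "datatype_scores": {},
            "overall": 0.0,
            "is_direct": False,
        }
    evidence = []
    for rec in result.records:
        if rec.target_id != target_id:
            continue
        direct = rec.disease_id == disease_id
        # a record contributes iff the pair's term is the record's own term
        # or one of its ancestors (propagation path)
        if not direct and (
            not result.manifest.propagated
            or result.ontology is None
            or disease_id not in result.ontology.ancestors(rec.disease_id)
        ):
            continue
        evidence.append(
            {
                "evidence_id": rec.evidence_id,
                "datasource": rec.datasource,
                "disease_id": rec.disease_id,
                "score": result.scores[rec.evidence_id].final,
                "provenance": "direct" if direct else "inherited",
            }
        )
    return {
        "target_id": target_id,
        "disease_id": disease_id,
        "evidence": evidence,
        "source_scores": dict(row.source_scores),
        "datatype_scores": dict(row.datatype_scores),
        "overall": row.overall,
        "is_direct": row.is_direct,
    }
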