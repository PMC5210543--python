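"""Harmonic-sum aggregation of evidence into association scores.

Evidence scores for a (target, disease) pair are combined at three tiers:
per data source, per data type (similar sources grouped), and overall. At
each tier the scores are sorted in descending order and combined as

    S = s_(1) + s_(2)/2^2 + s_(3)/3^2 + ... + s_(i)/i^2

so replication raises the score while large volumes of weak evidence (text
mining especially) are damped: the sum over constant scores is bounded by
s * pi^2/6 no matter how many records pile up.

Evidence scores are bounded in [0, 1] but the raw harmonic sum is not; by
default every aggregate is divided by the cap-truncated maximum
sum(1/k^2, k<=cap) so association scores stay in [0, 1] and are comparable
across tiers. ``normalized=False`` keeps the raw sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import DATASOURCE_TO_DATATYPE
from .ontology import DiseaseOntology, PropagatedEvidence, propagate_evidence
from .scoring import ScoreComponents, ScoringConfig, score_evidence


@dataclass(frozen=True)
class AggregationConfig:
    """cap: number of descending-sorted terms kept in every harmonic sum;
    normalized: divide by the cap-truncated maximum so aggregates stay in [0, 1]."""

    cap: int = 100
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.cap < 1:
            raise ValueError("cap must be >= 1")


def _sorted_capped_sum(scores: Iterable[float], cap: int) -> float:
    v = np.asarray(list(scores), dtype=float)
    if v.size == 0:
        return 0.0
    v = np.sort(v)[::-1][:cap]
    k = np.arange(1, v.size + 1, dtype=float)
    return float(np.sum(v / k**2))


def harmonic_sum(scores: Iterable[float], cap: int = 100) -> float:
    """Sorted harmonic sum: descending sort, truncate to ``cap`` terms,
    return sum of s_(k)/k^2. Permutation-invariant and monotone
    non-decreasing in every element. Elements must lie in [0, 1] (evidence
    scores are unit-interval by construction)."""
    v = list(scores)
    if any(s < 0 or s > 1 for s in v):
        raise ValueError("harmonic_sum elements must lie in [0, 1]")
    return _sorted_capped_sum(v, cap)


def max_harmonic_sum(cap: int = 100) -> float:
    """Largest achievable capped harmonic sum: sum(1/k^2) for k = 1..cap."""
    k = np.arange(1, cap + 1, dtype=float)
    return float(np.sum(1.0 / k**2))


def normalized_harmonic_sum(scores: Iterable[float], cap: int = 100) -> float:
    """harmonic_sum divided by its cap-truncated maximum; lies in [0, 1] and
    reaches 1 exactly when at least ``cap`` scores equal 1."""
    return harmonic_sum(scores, cap) / max_harmonic_sum(cap)


def _aggregate(scores: Iterable[float], agg: AggregationConfig) -> float:
    # raw-mode tiers may exceed 1 (a raw harmonic sum is bounded by pi^2/6,
    # not 1), so the unit-interval domain check applies only to evidence
    # scores, not to tier aggregates
    total = _sorted_capped_sum(scores, agg.cap)
    if agg.normalized:
        return total / max_harmonic_sum(agg.cap)
    return total


def datasource_score(
    scores: Sequence[ScoreComponents | float],
    datasource: str,
    config: ScoringConfig,
    agg: AggregationConfig = AggregationConfig(),
) -> float:
    """Association score for one (target, disease, datasource): the
    (normalized) harmonic sum of the evidence scores, multiplied by the
    source weight. Clamped into [0, 1] in normalized mode; raw mode keeps
    the unbounded sum (it can legitimately exceed 1)."""
    values = [s.final if isinstance(s, ScoreComponents) else float(s) for s in scores]
    weight = config.source_weights.get(datasource, 1.0)
    weighted = _aggregate(values, agg) * weight
    return min(weighted, 1.0) if agg.normalized else weighted


def datatype_score(
    source_scores: Mapping[str, float],
    agg: AggregationConfig = AggregationConfig(),
) -> dict[str, float]:
    """Group data-source scores by data type, harmonic-sum each group."""
    groups: dict[str, list[float]] = {}
    for source, value in source_scores.items():
        try:
            dt = DATASOURCE_TO_DATATYPE[source]
        except KeyError:
            raise ValueError(f"unknown datasource {source!r}") from None
        groups.setdefault(dt, []).append(value)
    return {dt: _aggregate(values, agg) for dt, values in sorted(groups.items())}


def overall_score(
    datatype_scores: Mapping[str, float],
    agg: AggregationConfig = AggregationConfig(),
) -> float:
    """Combine all data-type scores into the overall association score."""
    return _aggregate(datatype_scores.values(), agg)


@dataclass(frozen=True)
class AssociationRow:
    """Scores for one (target, disease) pair at all three tiers.

    ``is_direct`` is True iff at least one piece of evidence is annotated to
    exactly this disease term (as opposed to inherited from a descendant)."""

    target_id: str
    disease_id: str
    is_direct: bool
    source_scores: Mapping[str, float]
    datatype_scores: Mapping[str, float]
    overall: float
    evidence_count: int


def build_associations(
    records: Sequence,
    scores: Mapping[str, ScoreComponents] | None = None,
    ontology: DiseaseOntology | None = None,
    config: ScoringConfig | None = None,
    agg: AggregationConfig = AggregationConfig(),
    propagate: bool = True,
) -> list[AssociationRow]:
    """Score, propagate and aggregate a batch of evidence records.

    ``scores`` maps evidence_id to precomputed :class:`ScoreComponents`;
    records missing from it (or all of them, when None) are scored here.
    With ``propagate`` (default) every record also contributes to each
    ancestor of its disease term. Output is sorted by (target, disease).
    """
    config = config or ScoringConfig()
    scores = dict(scores or {})
    for rec in records:
        if rec.evidence_id not in scores:
            scores[rec.evidence_id] = score_evidence(rec, config)

    if propagate:
        if ontology is None:
            raise ValueError("propagation requires an ontology")
        entries = propagate_evidence(records, ontology)
    else:
        entries = [PropagatedEvidence(r, r.disease_id, is_direct=True) for r in records]

    grouped: dict[tuple[str, str], list[PropagatedEvidence]] = {}
    for entry in entries:
        grouped.setdefault((entry.record.target_id, entry.effective_disease), []).append(entry)

    rows: list[AssociationRow] = []
    for (target, disease), group in sorted(grouped.items()):
        by_source: dict[str, list[tuple[float, str]]] = {}
        for entry in group:
            sc = scores[entry.record.evidence_id]
            by_source.setdefault(entry.record.datasource, []).append(
                (sc.final, entry.record.evidence_id)
            )
        src_scores = {}
        for source, pairs in sorted(by_source.items()):
            # descending score, ties broken by evidence_id for reproducibility
            pairs.sort(key=lambda p: (-p[0], p[1]))
            src_scores[source] = datasource_score([p[0] for p in pairs], source, config, agg)
        dt_scores = datatype_score(src_scores, agg)
        rows.append(
            AssociationRow(
                target_id=target,
                disease_id=disease,
                is_direct=any(e.is_direct for e in group),
                source_scores=src_scores,
                datatype_scores=dt_scores,
                overall=overall_score(dt_scores, agg),
                evidence_count=len({e.record.evidence_id for e in group}),
            )
        )
    return rows


def associations_to_frame(rows: Sequence[AssociationRow]):
    """Association table as a DataFrame with a frozen column order:
    target_id, disease_id, is_direct, overall, evidence_count, one column
    per data type, one per data source (absent tiers filled with 0)."""
    import pandas as pd

    from .constants import DATASOURCES, DATATYPES

    data = []
    for r in rows:
        row = {
            "target_id": r.target_id,
            "disease_id": r.disease_id,
            "is_direct": r.is_direct,
            "overall": r.overall,
            "evidence_count": r.evidence_count,
        }
        for dt in DATATYPES:
            row[f"datatype.{dt}"] = r.datatype_scores.get(dt, 0.0)
        for src in DATASOURCES:
            row[f"datasource.{src}"] = r.source_scores.get(src, 0.0)
        data.append(row)
    columns = (
        ["target_id", "disease_id", "is_direct", "overall", "evidence_count"]
        + [f"datatype.{dt}" for dt in DATATYPES]
        + [f"datasource.{s}" for s in DATASOURCES]
    )
    return pd.DataFrame(data, columns=columns)
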