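"""Per-evidence association scores for each data source.

Every evidence record receives a score in [0, 1] built from up to three
components — frequency (how often the observation recurs, e.g. study sample
size), severity (magnitude of the effect, e.g. predicted functional
consequence of a variant) and confidence (how trustworthy the observation
is, e.g. the reported p-value). Components that a source does not provide
are simply absent and act as the multiplicative identity.

Unbounded raw quantities (p-values, sample sizes, fold changes) are mapped
onto [0, 1] by saturating normalizers: -log10 rescaling for p-values and a
linear ramp for counts and fold changes, with the saturation points held in
:class:`ScoringConfig`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .constants import DATASOURCES


class ScoringError(ValueError):
    """A payload cannot be scored (missing key or out-of-domain value)."""


@dataclass(frozen=True)
class ScoreComponents:
    """Score of one evidence record, with its components where present."""

    final: float
    frequency: float | None = None
    severity: float | None = None
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.final <= 1.0:
            raise ScoringError(f"final score {self.final} outside [0, 1]")


@dataclass(frozen=True)
class ConsequenceTable:
    """Severity lookup keyed by Sequence Ontology consequence terms.

    ``unknown_policy`` decides what an unlisted term yields: ``"error"``
    raises, ``"default_value"`` returns ``default_value``.
    """

    scores: Mapping[str, float]
    unknown_policy: str = "default_value"
    default_value: float = 0.5

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError("consequence table must be non-empty")
        bad = {t: s for t, s in self.scores.items() if not 0.0 <= s <= 1.0}
        if bad:
            raise ValueError(f"consequence scores outside [0, 1]: {bad}")
        if self.unknown_policy not in ("error", "default_value"):
            raise ValueError(f"unknown_policy {self.unknown_policy!r}")

    def lookup(self, so_term: str) -> float:
        try:
            return self.scores[so_term]
        except KeyError:
            if self.unknown_policy == "error":
                raise ScoringError(f"unknown consequence term {so_term!r}") from None
            return self.default_value

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "ConsequenceTable":
        """Read a two-column TSV (SO term, score); '#' lines are comments."""
        scores: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, value = line.split("\t")
            scores[term] = float(value)
        return cls(scores=scores, **kwargs)


def default_consequence_table() -> ConsequenceTable:
    ref = resources.files("tdscore.data") / "consequences.tsv"
    with resources.as_file(ref) as path:
        return ConsequenceTable.from_tsv(path)


#: Clinical-trial phase -> evidence score (known-drug evidence).
CHEMBL_PHASE_SCORES: dict[int, float] = {0: 0.09, 1: 0.1, 2: 0.2, 3: 0.7, 4: 1.0}

#: Tumor-type category -> evidence score (cancer-driver evidence). Category A:
#: several signals of positive selection; B: known cancer gene with a signal of
#: positive selection; C: signal of positive selection plus functional
#: connection to A/B genes.
INTOGEN_CATEGORY_SCORES: dict[str, float] = {"A": 0.25, "B": 0.5, "C": 0.75}


@dataclass(frozen=True)
class ScoringConfig:
    """Normalization constants, severity table and per-source weights.

    p_floor_gwas / p_floor_expr
        p-value at which the -log10 normalizer saturates to 1 for genetic
        association and differential-expression evidence respectively.
    n_ref
        study sample size at which the sample-size ramp saturates.
    fc_cap
        \\|log2 fold change| at which the expression ramp saturates.
    source_weights
        multiplicative weight applied to each data-source association score
        after aggregation; defaults are 1.0 everywhere except literature
        mining, which is down-weighted (stand-in value, overridable).
    """

    p_floor_gwas: float = 1e-15
    p_floor_expr: float = 1e-10
    n_ref: int = 5000
    fc_cap: float = 10.0
    consequence_table: ConsequenceTable = field(default_factory=default_consequence_table)
    source_weights: Mapping[str, float] = field(
        default_factory=lambda: {s: (0.2 if s == "europepmc" else 1.0) for s in DATASOURCES}
    )

    def __post_init__(self) -> None:
        for name in ("p_floor_gwas", "p_floor_expr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_ref <= 0:
            raise ValueError("n_ref must be positive")
        if self.fc_cap <= 0:
            raise ValueError("fc_cap must be positive")
        if any(w < 0 for w in self.source_weights.values()):
            raise ValueError("source weights must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringConfig":
        """Build a config from a YAML mapping; omitted keys keep defaults.

        Recognized keys mirror the dataclass fields; ``consequence_table``
        is given as a path to a two-column TSV (resolved relative to the
        YAML file), optionally alongside ``consequence_unknown_policy`` and
        ``consequence_default_value``.
        """
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        kwargs: dict = {}
        for key in ("p_floor_gwas", "p_floor_expr", "n_ref", "fc_cap"):
            if key in raw:
                kwargs[key] = raw[key]
        if "consequence_table" in raw:
            table_path = Path(raw["consequence_table"])
            if not table_path.is_absolute():
                table_path = path.parent / table_path
            kwargs["consequence_table"] = ConsequenceTable.from_tsv(
                table_path,
                unknown_policy=raw.get("consequence_unknown_policy", "default_value"),
                default_value=raw.get("consequence_default_value", 0.5),
            )
        if "source_weights" in raw:
            weights = {s: (0.2 if s == "europepmc" else 1.0) for s in DATASOURCES}
            weights.update(raw["source_weights"])
            kwargs["source_weights"] = weights
        return cls(**kwargs)

    def with_weights(self, **weights: float) -> "ScoringConfig":
        merged = dict(self.source_weights)
        merged.update(weights)
        return replace(self, source_weights=merged)


# --- normalizers -----------------------------------------------------------


def normalize_pvalue(p: float, p_floor: float) -> float:
    """Map a p-value to [0, 1] via -log10 rescaling, saturating at p_floor.

    Returns clamp((-log10 p) / (-log10 p_floor), 0, 1); monotone
    non-increasing in p. p = 0 is clipped to p_floor with a warning.
    """
    if p < 0 or p > 1:
        raise ScoringError(f"p-value {p} outside [0, 1]")
    if p == 0:
        warnings.warn("p-value of 0 clipped to the saturation floor", stacklevel=2)
        return 1.0
    score = math.log10(p) / math.log10(p_floor)
    return min(max(score, 0.0), 1.0)


def normalize_sample_size(n: float, n_ref: float) -> float:
    """Linear ramp min(n / n_ref, 1); monotone non-decreasing."""
    if n < 0:
        raise ScoringError(f"sample size {n} is negative")
    return min(n / n_ref, 1.0)


def consequence_score(so_term: str, table: ConsequenceTable) -> float:
    """Severity of a variant's predicted functional consequence."""
    return table.lookup(so_term)


# --- per-source scorers ----------------------------------------------------


def _require(payload: Mapping, *keys: str) -> list:
    missing = [k for k in keys if k not in payload]
    if missing:
        raise ScoringError(f"payload missing required key(s): {', '.join(missing)}")
    return [payload[k] for k in keys]


def score_gwas(payload: Mapping, config: ScoringConfig) -> ScoreComponents:
    """Common-disease genetic association: N(pvalue) x N(sample size) x consequence.

    Confidence is the reported p-value, frequency the case/control sample
    size, severity the predicted functional consequence of the lead variant.
    """
    p, n, term = _require(payload, "pvalue", "sample_size", "so_term")
    confidence = normalize_pvalue(p, config.p_floor_gwas)
    frequency = normalize_sample_size(n, config.n_ref)
    severity = consequence_score(term, config.consequence_table)
    return ScoreComponents(
        final=confidence * frequency * severity,
        frequency=frequency,
        severity=severity,
        confidence=confidence,
    )


def score_consequence_only(payload: Mapping, config: ScoringConfig) -> ScoreComponents:
    """Clinical/somatic variant evidence scored by consequence severity alone."""
    (term,) = _require(payload, "so_term")
    severity = consequence_score(term, config.consequence_table)
    return ScoreComponents(final=severity, severity=severity)


def score_uniprot(payload: Mapping, config: ScoringConfig) -> ScoreComponents:
    """Curator inference: 1.0 for strong evidence of disease involvement, else 0.5."""
    (strong,) = _require(payload, "strong_evidence")
    confidence = 1.0 if strong else 0.5
    return ScoreComponents(final=confidence, confidence=confidence)


def score_curated_one(payload: Mapping, config: ScoringConfig) -> ScoreComponents:
    """Curated pathway / genetic-diagnosis evidence: curator inference score = 1."""
    return ScoreComponents(final=1.0, confidence=1.0)


def score_expression(payload: Mapping, config: ScoringConfig) -> ScoreComponents:
    """Differential expression: N(pvalue) x N(|log2 fold change|) x N(percentile rank)."""
    p, fc, rank = _require(payload, "pvalue", "log2fc", "percentile_rank")
    if not 0 <= rank <= 100:
        raise ScoringError(f"percentile_rank {rank} outside [0, 100]")
    confidence = normalize_pvalue(p, config.p_floor_expr)
    severity = min(abs(fc) / config.fc_cap, 1.0)
    frequency = rank / 100.0
    return ScoreComponents(
        final=confidence * severity * frequency,
        frequency=frequency,
        severity=severity,
        confidence=confidence,
    )


def score_intogen(payload: Mapping, config: ScoringConfig) -> ScoreComponents:
    """Cancer-driver evidence binned by tumor-type category (A/B/C)."""
    (category,) = _require(payload, "category")
    try:
        confidence = INTOGEN_CATEGORY_SCORES[category]
    except KeyError:
        raise ScoringError(f"unknown tumor-type category {category!r}") from None
    return ScoreComponents(final=confidence, confidence=confidence)


def score_chembl(payload: Mapping, config: ScoringConfig) -> ScoreComponents:
    """Known-drug evidence binned by maximum clinical trial phase (0-4)."""
    (phase,) = _require(payload, "max_phase")
    try:
        confidence = CHEMBL_PHASE_SCORES[phase]
    except (KeyError, TypeError):
        raise ScoringError(f"clinical trial phase {phase!r} outside 0..4") from None
    return ScoreComponents(final=confidence, confidence=confidence)


def score_passthrough(payload: Mapping, config: ScoringConfig) -> ScoreComponents:
    """Upstream-computed score (model-organism similarity, literature confidence).

    Consumed as given, clamped into [0, 1] with a warning if outside.
    """
    (score,) = _require(payload, "score")
    if score < 0 or score > 1:
        warnings.warn(f"passthrough score {score} clamped into [0, 1]", stacklevel=2)
        score = min(max(score, 0.0), 1.0)
    return ScoreComponents(final=float(score), confidence=float(score))


_DISPATCH = {
    "gwas_catalog": score_gwas,
    "eva": score_consequence_only,
    "eva_somatic": score_consequence_only,
    "cancer_gene_census": score_consequence_only,
    "uniprot": score_uniprot,
    "gene2phenotype": score_curated_one,
    "reactome": score_curated_one,
    "expression_atlas": score_expression,
    "intogen": score_intogen,
    "chembl": score_chembl,
    "phenodigm": score_passthrough,
    "europepmc": score_passthrough,
}


def score_evidence(record, config: ScoringConfig | None = None) -> ScoreComponents:
    """Score one evidence record, dispatching on its datasource.

    ``record`` is an :class:`~tdscore.evidence.EvidenceRecord` or anything
    with ``datasource`` and ``payload`` attributes.
    """
    config = config or ScoringConfig()
    try:
        scorer = _DISPATCH[record.datasource]
    except KeyError:
        raise ScoringError(f"unknown datasource {record.datasource!r}") from None
    return scorer(record.payload, config)
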