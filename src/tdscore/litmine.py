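"""Literature co-occurrence filtering and document confidence scoring.

Articles arrive pre-annotated: each carries sentence-level target-disease
mention pairs located in the title, the abstract or a named body section
(named-entity recognition is upstream and out of scope). Three heuristic
filters remove likely false positives:

(i)   only Research articles are mined (Reviews, Case Reports etc. are
      dropped);
(ii)  mentions in boilerplate sections — Methods, References,
      Acknowledgement and Funding, Competing Interests, Author
      Contribution, Supplementary — are discarded;
(iii) a pair whose only appearance is a single body-section sentence, with
      no title or abstract mention, is discarded.

Pairs that survive receive a document confidence score: the sum of
section weights over the distinct locations where the pair appears, capped
at 1. Weights are stand-ins (title strongest, then abstract, then Results)
and fully overridable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .constants import DATASOURCE_TO_DATATYPE
from .evidence import EvidenceRecord

Pair = tuple[str, str]  # (target_id, disease_id)

#: Sections whose mentions are always discarded (filter ii).
BANNED_SECTIONS: frozenset[str] = frozenset(
    {
        "methods",
        "references",
        "acknowledgement and funding",
        "competing interests",
        "author contribution",
        "supplementary",
    }
)

#: Default section weights for the document confidence score. Stand-ins,
#: config-overridable; unknown sections fall back to the "others" weight.
DEFAULT_SECTION_WEIGHTS: dict[str, float] = {
    "title": 1.0,
    "abstract": 0.8,
    "results": 0.3,
    "discussion": 0.2,
    "introduction": 0.1,
    "others": 0.05,
}


@dataclass(frozen=True)
class SectionWeights:
    weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SECTION_WEIGHTS)
    )

    def __post_init__(self) -> None:
        bad = {s: w for s, w in self.weights.items() if not 0.0 <= w <= 1.0}
        if bad:
            raise ValueError(f"section weights outside [0, 1]: {bad}")

    def weight(self, section: str) -> float:
        key = section.strip().lower()
        if key in self.weights:
            return self.weights[key]
        return self.weights.get("others", 0.05)


@dataclass(frozen=True)
class Section:
    name: str
    pairs: tuple[Pair, ...]  # one entry per sentence co-occurrence


@dataclass(frozen=True)
class ArticleRecord:
    article_id: str
    article_type: str
    title_mentions: tuple[Pair, ...] = ()
    abstract_mentions: tuple[Pair, ...] = ()
    body: tuple[Section, ...] = ()

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ArticleRecord":
        as_pairs = lambda items: tuple((t, d) for t, d in items)
        return cls(
            article_id=raw["article_id"],
            article_type=raw["article_type"],
            title_mentions=as_pairs(raw.get("title_mentions", ())),
            abstract_mentions=as_pairs(raw.get("abstract_mentions", ())),
            body=tuple(
                Section(name=s["name"], pairs=as_pairs(s.get("pairs", ())))
                for s in raw.get("body", ())
            ),
        )


def filter_article(article: ArticleRecord) -> bool:
    """Filter (i): keep only Research articles (case-insensitive)."""
    return article.article_type.strip().lower() == "research"


def eligible_pairs(
    article: ArticleRecord, banned_sections: frozenset[str] = BANNED_SECTIONS
) -> list[tuple[Pair, str]]:
    """Filter (ii): title/abstract mentions plus body mentions outside the
    banned sections, each tagged with its location."""
    out: list[tuple[Pair, str]] = []
    for pair in article.title_mentions:
        out.append((pair, "title"))
    for pair in article.abstract_mentions:
        out.append((pair, "abstract"))
    for section in article.body:
        if section.name.strip().lower() in banned_sections:
            continue
        for pair in section.pairs:
            out.append((pair, section.name))
    return out


def once_only_filter(
    pairs_with_locations: Sequence[tuple[Pair, str]], article: ArticleRecord
) -> list[tuple[Pair, str]]:
    """Filter (iii): drop a pair whose eligible body occurrences number
    exactly one and which appears in neither title nor abstract."""
    body_counts: dict[Pair, int] = {}
    in_front: set[Pair] = set()
    for pair, location in pairs_with_locations:
        if location in ("title", "abstract"):
            in_front.add(pair)
        else:
            body_counts[pair] = body_counts.get(pair, 0) + 1
    dropped = {
        pair
        for pair, count in body_counts.items()
        if count == 1 and pair not in in_front
    }
    return [(p, loc) for p, loc in pairs_with_locations if p not in dropped]


def document_score(
    locations: Iterable[str], weights: SectionWeights | None = None
) -> float:
    """Confidence of one (target, disease) pair in one article: sum of
    section weights over the distinct locations of its surviving mentions,
    capped at 1. Monotone in mention coverage."""
    weights = weights or SectionWeights()
    distinct = {loc.strip().lower() for loc in locations}
    return min(1.0, sum(weights.weight(loc) for loc in distinct))


def mine_article(
    article: ArticleRecord, weights: SectionWeights | None = None
) -> dict[Pair, float]:
    """Run the (i) -> (ii) -> (iii) pipeline on one article; returns the
    document score per surviving pair (empty for non-Research articles)."""
    if not filter_article(article):
        return {}
    surviving = once_only_filter(eligible_pairs(article), article)
    by_pair: dict[Pair, list[str]] = {}
    for pair, location in surviving:
        by_pair.setdefault(pair, []).append(location)
    return {pair: document_score(locs, weights) for pair, locs in sorted(by_pair.items())}


def mine_corpus(
    articles: Iterable[ArticleRecord], weights: SectionWeights | None = None
) -> list[EvidenceRecord]:
    """One literature evidence record per (article, target, disease) pair
    surviving all filters, in the standard evidence format."""
    records: list[EvidenceRecord] = []
    for article in articles:
        for (target, disease), score in mine_article(article, weights).items():
            records.append(
                EvidenceRecord(
                    evidence_id=f"europepmc:{article.article_id}:{target}:{disease}",
                    target_id=target,
                    disease_id=disease,
                    datasource="europepmc",
                    datatype=DATASOURCE_TO_DATATYPE["europepmc"],
                    payload={"score": score},
                    literature_refs=(article.article_id,),
                )
            )
    return records


def read_articles(path: str | Path) -> list[ArticleRecord]:
    """Read an article corpus from JSON Lines (one ArticleRecord per line)."""
    articles = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            articles.append(ArticleRecord.from_dict(json.loads(line)))
    return articles


def write_articles(articles: Iterable[ArticleRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for a in articles:
            fh.write(
                json.dumps(
                    {
                        "article_id": a.article_id,
                        "article_type": a.article_type,
                        "title_mentions": [list(p) for p in a.title_mentions],
                        "abstract_mentions": [list(p) for p in a.abstract_mentions],
                        "body": [
                            {"name": s.name, "pairs": [list(p) for p in s.pairs]}
                            for s in a.body
                        ],
                    },
                    sort_keys=True,
                )
                + "\n"
            )
            n += 1
    return n
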