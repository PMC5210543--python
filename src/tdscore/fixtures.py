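"""Seeded synthetic fixtures: evidence batches, toy ontologies, gene
annotations and article corpora with known ground truth.

Everything is driven by one integer seed through a single numpy Generator
stream — no global state — so identical configs give byte-identical files.
The generators emit the exact external formats the readers consume
(JSON Lines, TSV edge list, BED6), not just in-memory objects.

Payload distributions (documented contract, relied on by tests):

* gwas_catalog — pvalue log-uniform on [1e-15, 1]; sample_size uniform
  integer on [50, 10000]; so_term uniform over the default consequence
  table terms.
* eva / eva_somatic / cancer_gene_census — so_term as above.
* uniprot — strong_evidence Bernoulli(0.5).
* gene2phenotype / reactome — empty payload.
* expression_atlas — pvalue log-uniform on [1e-10, 1]; log2fc uniform on
  [-10, 10]; percentile_rank uniform on [0, 100].
* intogen — category uniform over {A, B, C}.
* chembl — max_phase uniform integer on [0, 4].
* phenodigm / europepmc — score uniform on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import yaml

from .constants import DATASOURCES, DATASOURCE_TO_DATATYPE
from .evidence import EvidenceRecord, write_evidence
from .litmine import ArticleRecord, Section, write_articles
from .genes import GeneAnnotation
from .ontology import DiseaseOntology, write_ontology_tsv
from .scoring import default_consequence_table

#: The worked propagation chain used throughout the tests: evidence at the
#: most specific term must surface at both broader terms.
ASTHMA_CHAIN = (
    ("EFO:0004591", "childhood onset asthma", "EFO:0000270"),
    ("EFO:0000270", "asthma", "EFO:0009687"),
    ("EFO:0009687", "respiratory system disease", None),
)


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_targets: int = 20
    n_diseases: int = 15
    n_evidence: int = 200
    source_mix: Mapping[str, float] = field(
        default_factory=lambda: {s: 1.0 / len(DATASOURCES) for s in DATASOURCES}
    )
    ontology_depth: int = 3
    branching: int = 2
    n_roots: int = 2
    n_articles: int = 20
    n_genes: int = 30
    contig: str = "chr1"

    def __post_init__(self) -> None:
        if any(v < 0 for v in (self.n_targets, self.n_diseases, self.n_evidence, self.n_articles)):
            raise ValueError("counts must be non-negative")
        total = sum(self.source_mix.values())
        if self.source_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"source_mix proportions sum to {total}, expected 1")
        unknown = set(self.source_mix) - set(DATASOURCES)
        if unknown:
            raise ValueError(f"unknown datasource(s) in source_mix: {sorted(unknown)}")


def generate_ontology(cfg: FixtureConfig) -> DiseaseOntology:
    """Rooted trees of the configured depth and branching, roots flagged as
    therapeutic areas. When depth >= 3 the named asthma chain is included so
    propagation tests have their canonical fixture."""
    graph = nx.DiGraph()
    labels: dict[str, str] = {}
    roots: set[str] = set()
    counter = 0

    def term(i: int) -> str:
        return f"DIS:{i:07d}"

    for r in range(cfg.n_roots):
        root = term(counter)
        counter += 1
        graph.add_node(root)
        labels[root] = f"therapeutic area {r}"
        roots.add(root)
        level = [root]
        for depth in range(1, cfg.ontology_depth):
            nxt = []
            for parent in level:
                for _ in range(cfg.branching):
                    child = term(counter)
                    counter += 1
                    graph.add_edge(child, parent)
                    labels[child] = f"disease {counter}"
                    nxt.append(child)
            level = nxt

    if cfg.ontology_depth >= 3:
        for child, label, parent in ASTHMA_CHAIN:
            graph.add_node(child)
            labels[child] = label
            if parent is not None:
                graph.add_edge(child, parent)
        roots.add("EFO:0009687")

    return DiseaseOntology(graph=graph, labels=labels, therapeutic_area_roots=frozenset(roots))


def _payload(source: str, rng: np.random.Generator, so_terms: list[str]) -> dict:
    if source == "gwas_catalog":
        return {
            "pvalue": float(10 ** rng.uniform(-15, 0)),
            "sample_size": int(rng.integers(50, 10001)),
            "so_term": str(rng.choice(so_terms)),
        }
    if source in ("eva", "eva_somatic", "cancer_gene_census"):
        return {"so_term": str(rng.choice(so_terms))}
    if source == "uniprot":
        return {"strong_evidence": bool(rng.integers(0, 2))}
    if source in ("gene2phenotype", "reactome"):
        return {}
    if source == "expression_atlas":
        return {
            "pvalue": float(10 ** rng.uniform(-10, 0)),
            "log2fc": float(rng.uniform(-10, 10)),
            "percentile_rank": float(rng.uniform(0, 100)),
        }
    if source == "intogen":
        return {"category": str(rng.choice(["A", "B", "C"]))}
    if source == "chembl":
        return {"max_phase": int(rng.integers(0, 5))}
    if source in ("phenodigm", "europepmc"):
        return {"score": float(rng.uniform(0, 1))}
    raise ValueError(f"unknown datasource {source!r}")


def generate_evidence(
    cfg: FixtureConfig, ontology: DiseaseOntology | None = None
) -> list[EvidenceRecord]:
    """Schema-valid evidence records with sources drawn from the configured
    mix and diseases drawn from the ontology's terms."""
    rng = np.random.default_rng(cfg.seed)
    ontology = ontology if ontology is not None else generate_ontology(cfg)
    so_terms = sorted(default_consequence_table().scores)
    targets = [f"ENSG{i:011d}" for i in range(1, cfg.n_targets + 1)]
    diseases = sorted(ontology.graph.nodes)[: max(cfg.n_diseases, 1)]
    sources = sorted(cfg.source_mix)
    probs = np.array([cfg.source_mix[s] for s in sources])

    records = []
    for i in range(cfg.n_evidence):
        source = str(rng.choice(sources, p=probs))
        records.append(
            EvidenceRecord(
                evidence_id=f"ev:{i:06d}",
                target_id=str(rng.choice(targets)),
                disease_id=str(rng.choice(diseases)),
                datasource=source,
                datatype=DATASOURCE_TO_DATATYPE[source],
                payload=_payload(source, rng, so_terms),
                eco_code="ECO:0000000",
            )
        )
    return records


def generate_genes(cfg: FixtureConfig) -> list[GeneAnnotation]:
    """Non-degenerate gene intervals laid along one contig with random
    strands; interval lengths uniform on [500, 5000], gaps on [0, 2000]."""
    rng = np.random.default_rng(cfg.seed + 1)
    genes = []
    pos = 1000
    for i in range(cfg.n_genes):
        length = int(rng.integers(500, 5001))
        genes.append(
            GeneAnnotation(
                gene_id=f"GENE{i:04d}",
                contig=cfg.contig,
                start=pos,
                end=pos + length,
                strand=str(rng.choice(["+", "-"])),
            )
        )
        pos += length + int(rng.integers(0, 2001))
    return genes


def generate_articles(cfg: FixtureConfig) -> list[ArticleRecord]:
    """Corpus with a known survivor count for the literature filters.

    Articles cycle deterministically through five kinds:

    0. Research, pair in title + Results       -> survives
    1. Research, pair twice in Results         -> survives
    2. Research, pair once in Results only     -> dropped by filter (iii)
    3. Research, pair only in Methods          -> dropped by filter (ii)+(iii)
    4. Review, pair in title                   -> dropped by filter (i)

    so exactly ceil(2/5 of the corpus) articles yield evidence. Target and
    disease identifiers rotate with the article index.
    """
    rng = np.random.default_rng(cfg.seed + 2)  # reserved for future jitter
    del rng
    articles = []
    for i in range(cfg.n_articles):
        pair = (f"ENSG{(i % max(cfg.n_targets, 1)) + 1:011d}", "EFO:0000270")
        kind = i % 5
        if kind == 0:
            art = ArticleRecord(
                article_id=f"PMID:{1000 + i}",
                article_type="Research",
                title_mentions=(pair,),
                body=(Section("Results", (pair,)),),
            )
        elif kind == 1:
            art = ArticleRecord(
                article_id=f"PMID:{1000 + i}",
                article_type="Research",
                body=(Section("Results", (pair, pair)),),
            )
        elif kind == 2:
            art = ArticleRecord(
                article_id=f"PMID:{1000 + i}",
                article_type="Research",
                body=(Section("Results", (pair,)),),
            )
        elif kind == 3:
            art = ArticleRecord(
                article_id=f"PMID:{1000 + i}",
                article_type="Research",
                body=(Section("Methods", (pair,)),),
            )
        else:
            art = ArticleRecord(
                article_id=f"PMID:{1000 + i}",
                article_type="Review",
                title_mentions=(pair,),
            )
        articles.append(art)
    return articles


def expected_article_survivors(cfg: FixtureConfig) -> int:
    """Closed-form survivor count for :func:`generate_articles`."""
    full, rem = divmod(cfg.n_articles, 5)
    return 2 * full + min(rem, 2)


def write_bundle(cfg: FixtureConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete fixture bundle: evidence.jsonl, ontology.tsv,
    genes.bed, articles.jsonl and the config echo (config.yaml)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ontology = generate_ontology(cfg)
    paths = {
        "ontology": out / "ontology.tsv",
        "evidence": out / "evidence.jsonl",
        "genes": out / "genes.bed",
        "articles": out / "articles.jsonl",
        "config": out / "config.yaml",
    }
    write_ontology_tsv(ontology, paths["ontology"])
    write_evidence(generate_evidence(cfg, ontology), paths["evidence"])
    with open(paths["genes"], "w") as fh:
        for g in generate_genes(cfg):
            fh.write(f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    write_articles(generate_articles(cfg), paths["articles"])
    cfg_dict = {
        k: (dict(v) if isinstance(v, Mapping) else v)
        for k, v in vars(cfg).items()
    }
    paths["config"].write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
    return paths
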