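"""Disease ontology loading and evidence propagation.

The disease vocabulary is a DAG of terms connected by subclass-of edges
(child -> parent). Evidence annotated to a specific term also supports every
ancestor term: evidence at "childhood onset asthma" supports "asthma" and in
turn "respiratory system disease", so a user browsing the broad term sees
targets whose direct evidence sits deeper in the hierarchy. Designated root
terms act as therapeutic areas, the broad categories used to group
associations.

Only subclass-of edges are traversed. Other inferrable relations (disease
location, cell type, phenotype) are deliberately out of scope; the TSV edge
format reserves no edge-type column for them yet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import obonet


class OntologyError(ValueError):
    pass


@dataclass
class DiseaseOntology:
    """DAG of disease terms with subclass-of edges and therapeutic-area roots."""

    graph: nx.DiGraph  # edges point child -> parent
    labels: dict[str, str] = field(default_factory=dict)
    therapeutic_area_roots: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(f"subclass-of graph contains a cycle: {cycle}")
        for root in self.therapeutic_area_roots:
            parents = list(self.graph.successors(root))
            if parents:
                raise OntologyError(
                    f"therapeutic-area root {root!r} has parents {parents} in the file"
                )

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable via subclass-of edges, excluding ``term`` itself."""
        if term not in self.graph:
            raise OntologyError(f"term {term!r} not in ontology")
        return set(nx.descendants(self.graph, term))  # child->parent edges

    def therapeutic_areas(self, term: str) -> set[str]:
        """Therapeutic-area roots above (or equal to) ``term``."""
        return (self.ancestors(term) | {term}) & self.therapeutic_area_roots

    def label(self, term: str) -> str:
        return self.labels.get(term, term)


def load_ontology(path: str | Path, format: str | None = None) -> DiseaseOntology:
    """Load an ontology from a TSV edge list or an OBO subset.

    ``format`` is ``"tsv"`` or ``"obo"``; inferred from the file suffix when
    omitted. Cycles and dangling edges raise :class:`OntologyError`.
    """
    path = Path(path)
    if format is None:
        format = "obo" if path.suffix == ".obo" else "tsv"
    if format == "tsv":
        return _load_tsv(path)
    if format == "obo":
        return _load_obo(path)
    raise ValueError(f"unknown ontology format {format!r}")


def _load_tsv(path: Path) -> DiseaseOntology:
    """TSV columns: child_id, parent_id, child_label, is_root_flag.

    A row with an empty parent_id declares a node without asserting an edge
    (how roots enter the file). is_root_flag marks therapeutic-area roots.
    """
    graph = nx.DiGraph()
    labels: dict[str, str] = {}
    roots: set[str] = set()
    declared: set[str] = set()
    referenced_parents: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#") or line.startswith("child_id\t"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 4:
            raise OntologyError(f"{path}:{lineno}: expected 4 tab-separated columns")
        child, parent, label, root_flag = fields
        graph.add_node(child)
        declared.add(child)
        if label:
            labels[child] = label
        if parent:
            graph.add_edge(child, parent)
            referenced_parents.add(parent)
        if root_flag.strip().lower() in ("1", "true", "yes"):
            roots.add(child)
    dangling = referenced_parents - declared
    if dangling:
        raise OntologyError(f"edges reference undeclared parent term(s): {sorted(dangling)}")
    return DiseaseOntology(graph=graph, labels=labels, therapeutic_area_roots=frozenset(roots))


def _load_obo(path: Path) -> DiseaseOntology:
    """OBO subset: [Term] stanzas with id, name, is_a; roots carry a
    ``subset: therapeutic_area`` tag (parentless terms are roots if the file
    declares no subsets at all)."""
    multigraph = obonet.read_obo(path)
    graph = nx.DiGraph()
    labels: dict[str, str] = {}
    roots: set[str] = set()
    any_subset = False
    for node, data in multigraph.nodes(data=True):
        graph.add_node(node)
        if "name" in data:
            labels[node] = data["name"]
        subsets = data.get("subset", [])
        if subsets:
            any_subset = True
        if "therapeutic_area" in subsets:
            roots.add(node)
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    if not any_subset:
        roots = {n for n in graph.nodes if graph.out_degree(n) == 0}
    return DiseaseOntology(graph=graph, labels=labels, therapeutic_area_roots=frozenset(roots))


def write_ontology_tsv(ontology: DiseaseOntology, path: str | Path) -> None:
    """Serialize to the 4-column TSV edge-list format."""
    lines = ["child_id\tparent_id\tchild_label\tis_root_flag"]
    for node in sorted(ontology.graph.nodes):
        flag = "1" if node in ontology.therapeutic_area_roots else "0"
        label = ontology.labels.get(node, "")
        parents = sorted(ontology.graph.successors(node))
        if not parents:
            lines.append(f"{node}\t\t{label}\t{flag}")
        else:
            for parent in parents:
                lines.append(f"{node}\t{parent}\t{label}\t{flag}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class PropagatedEvidence:
    """One evidence record attributed to one effective disease term."""

    record: "EvidenceRecord"  # noqa: F821 - import cycle avoided
    effective_disease: str
    is_direct: bool


def propagate_evidence(
    records: Sequence, ontology: DiseaseOntology
) -> list[PropagatedEvidence]:
    """Expand each record to its own disease term plus every ancestor.

    Each record yields one direct entry and one inferred entry per ancestor.
    A given underlying evidence counts at most once per effective disease
    (dedupe by evidence_id), which matters when the DAG offers multiple
    paths to the same ancestor.
    """
    out: list[PropagatedEvidence] = []
    seen: set[tuple[str, str]] = set()
    for rec in records:
        if rec.disease_id not in ontology:
            raise OntologyError(
                f"evidence {rec.evidence_id!r} annotated to unknown term {rec.disease_id!r}"
            )
        key = (rec.evidence_id, rec.disease_id)
        if key not in seen:
            seen.add(key)
            out.append(PropagatedEvidence(rec, rec.disease_id, is_direct=True))
        for ancestor in sorted(ontology.ancestors(rec.disease_id)):
            key = (rec.evidence_id, ancestor)
            if key not in seen:
                seen.add(key)
                out.append(PropagatedEvidence(rec, ancestor, is_direct=False))
    return out
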