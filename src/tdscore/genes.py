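"""Variant-to-gene assignment.

A sequence variant is attributed to the gene whose interval contains it;
an intergenic variant is attributed to the gene with the nearest 5' end
(transcription start side): the ``start`` coordinate for +strand genes and
the last base of the interval for -strand genes. Coordinates are 0-based
half-open throughout; BED input is native, GFF3 is converted on read.
Functional consequence terms are taken as input (annotated upstream, e.g.
by a variant effect predictor), never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .scoring import ConsequenceTable, consequence_score


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """Position of the 5' end: start for +, end-1 for - strand."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class VariantLocus:
    contig: str
    position: int  # 0-based
    so_term: str | None = None
    variant_id: str | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"variant position {self.position} is negative")


class AssignmentError(ValueError):
    pass


def assign_variant(
    v: VariantLocus, genes: Sequence[GeneAnnotation]
) -> tuple[str, str]:
    """Assign a variant to a gene; returns (gene_id, relation).

    Containment wins: a variant inside a gene interval gets that gene with
    relation ``"overlap"`` (ties by smallest start, then gene_id).
    Otherwise the gene on the same contig minimizing |position - 5' end| is
    chosen with relation ``"nearest_5prime"`` (ties by gene_id).
    """
    on_contig = [g for g in genes if g.contig == v.contig]
    if not on_contig:
        raise AssignmentError(f"no gene annotated on contig {v.contig!r}")

    containing = [g for g in on_contig if g.start <= v.position < g.end]
    if containing:
        best = min(containing, key=lambda g: (g.start, g.gene_id))
        return best.gene_id, "overlap"

    best = min(on_contig, key=lambda g: (abs(v.position - g.five_prime), g.gene_id))
    return best.gene_id, "nearest_5prime"


def consequence_for_variant(v: VariantLocus, table: ConsequenceTable) -> float:
    """Severity score of the variant's annotated consequence term; an absent
    term falls back to the table's unknown-term policy."""
    if v.so_term is None:
        if table.unknown_policy == "error":
            raise ValueError(f"variant at {v.contig}:{v.position} has no consequence term")
        return table.default_value
    return consequence_score(v.so_term, table)


def read_genes_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read gene intervals from BED (>=6 columns; name = gene id)."""
    import pyranges as pr

    df = pr.read_bed(str(path), as_df=True)
    return [
        GeneAnnotation(
            gene_id=row.Name,
            contig=str(row.Chromosome),
            start=int(row.Start),
            end=int(row.End),
            strand=str(row.Strand),
        )
        for row in df.itertuples()
    ]


def read_genes_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Read gene features from GFF3 (1-based inclusive, converted to
    0-based half-open). Gene id from the ID attribute."""
    import pyranges as pr

    df = pr.read_gff3(str(path), as_df=True)
    df = df[df.Feature == "gene"]
    return [
        GeneAnnotation(
            gene_id=str(row.ID),
            contig=str(row.Chromosome),
            start=int(row.Start),  # pyranges already converts to 0-based
            end=int(row.End),
            strand=str(row.Strand),
        )
        for row in df.itertuples()
    ]


def read_variants_tsv(path: str | Path) -> list[VariantLocus]:
    """Read variants from TSV: contig, position (0-based), [so_term], [id]."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        out.append(
            VariantLocus(
                contig=fields[0],
                position=int(fields[1]),
                so_term=fields[2] if len(fields) > 2 and fields[2] else None,
                variant_id=fields[3] if len(fields) > 3 and fields[3] else None,
            )
        )
    return out


def read_variants_vcf(path: str | Path) -> list[VariantLocus]:
    """Read variants from a minimal VCF; POS converted to 0-based. A SO
    consequence term may be carried in INFO as ``SO=SO:XXXXXXX``."""
    from cyvcf2 import VCF

    out = []
    for variant in VCF(str(path)):
        so_term = variant.INFO.get("SO")
        out.append(
            VariantLocus(
                contig=variant.CHROM,
                position=variant.POS - 1,
                so_term=so_term,
                variant_id=variant.ID,
            )
        )
    return out
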