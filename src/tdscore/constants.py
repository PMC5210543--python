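"""Controlled vocabularies: data sources, data types and their grouping.

The engine integrates evidence from eleven upstream databases. The European
Variation Archive contributes two distinct evidence streams (germline and
somatic clinical variants) which belong to different data types, so twelve
datasource names are enumerated here.
"""

from __future__ import annotations

# datasource name -> data type
DATASOURCE_TO_DATATYPE: dict[str, str] = {
    "gwas_catalog": "genetic_associations",
    "uniprot": "genetic_associations",
    "eva": "genetic_associations",
    "gene2phenotype": "genetic_associations",
    "cancer_gene_census": "somatic_mutations",
    "eva_somatic": "somatic_mutations",
    "intogen": "somatic_mutations",
    "expression_atlas": "rna_expression",
    "chembl": "drugs",
    "reactome": "affected_pathways",
    "europepmc": "text_mining",
    "phenodigm": "animal_models",
}

DATASOURCES: tuple[str, ...] = tuple(DATASOURCE_TO_DATATYPE)

DATATYPES: tuple[str, ...] = (
    "genetic_associations",
    "somatic_mutations",
    "rna_expression",
    "drugs",
    "affected_pathways",
    "text_mining",
    "animal_models",
)

# data type -> datasources in that group
DATATYPE_TO_DATASOURCES: dict[str, tuple[str, ...]] = {
    dt: tuple(s for s, d in DATASOURCE_TO_DATATYPE.items() if d == dt)
    for dt in DATATYPES
}
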