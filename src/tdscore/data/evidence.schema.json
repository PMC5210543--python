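{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Target-disease evidence record",
  "description": "One unit of target-disease evidence from one data source. The payload carries the source-specific fields the scorer needs; eco_code and literature_refs are opaque provenance metadata.",
  "type": "object",
  "required": ["evidence_id", "target_id", "disease_id", "datasource", "datatype", "payload"],
  "additionalProperties": false,
  "properties": {
    "evidence_id": {"type": "string", "minLength": 1},
    "target_id": {"type": "string", "pattern": "^[A-Za-z0-9][A-Za-z0-9_.:-]*$"},
    "disease_id": {"type": "string", "pattern": "^([A-Za-z][A-Za-z0-9_.]*:[^\\s]+|https?://[^\\s]+)$"},
    "datasource": {
      "type": "string",
      "enum": ["gwas_catalog", "uniprot", "eva", "gene2phenotype", "cancer_gene_census", "eva_somatic", "intogen", "expression_atlas", "chembl", "reactome", "europepmc", "phenodigm"]
    },
    "datatype": {
      "type": "string",
      "enum": ["genetic_associations", "somatic_mutations", "rna_expression", "drugs", "affected_pathways", "text_mining", "animal_models"]
    },
    "eco_code": {"type": "string"},
    "literature_refs": {"type": "array", "items": {"type": "string"}},
    "payload": {"type": "object"}
  }
}
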