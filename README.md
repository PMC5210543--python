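# tdscore

Target-disease evidence integration and association scoring.

Drug discovery starts with a hypothesis: modulating target *T* will alter
disease *D*. The supporting evidence is scattered across databases of very
different kinds — GWAS hits, clinical variants, cancer driver catalogs,
differential expression, approved drugs, curated pathways, animal models
and literature co-occurrence. `tdscore` turns heterogeneous evidence
records into comparable association scores so targets can be ranked against
a disease (and diseases against a target).

The engine:

1. **validates** evidence records (JSON Lines) against a bundled JSON
   schema, a controlled datasource→datatype vocabulary and the loaded
   disease ontology;
2. **scores** each record on [0, 1] with source-specific rules built from
   up to three components — frequency, severity, confidence (e.g. GWAS:
   N(pvalue) × N(sample size) × functional-consequence score; known drugs:
   a clinical-phase binned score);
3. **propagates** evidence up the disease ontology's subclass-of hierarchy
   (evidence at *childhood onset asthma* also supports *asthma* and
   *respiratory system disease*);
4. **aggregates** with the sorted harmonic sum

   S = s₍₁₎ + s₍₂₎/2² + s₍₃₎/3² + … + s₍ᵢ₎/i²,  s₍₁₎ ≥ s₍₂₎ ≥ …

   per data source, per data type and overall, so replication helps but
   sheer volume (text mining!) is damped — the sum over constant scores s
   is bounded by s·π²/6.

Also included: Europe PMC-style literature co-occurrence filtering with a
section-weighted document confidence score, variant-to-gene assignment
(containment first, otherwise nearest gene 5′ end), and seeded synthetic
fixture generators so everything is testable offline. See
[docs/methods.md](docs/methods.md) for the full model description and the
design decisions.

## Worked example

Three evidence records for PDE4D (`ENSG00000113448`) on a three-term asthma
ontology — a phase-4 drug, a GWAS intron hit at the more specific
*childhood onset asthma* term, and a literature co-occurrence score:

```bash
tdscore score evidence.jsonl ontology.tsv
```
```
evidence_id	datasource	score
ev:1	chembl	1
ev:2	gwas_catalog	0.072
ev:3	europepmc	0.9
```

The drug in phase 4 scores 1.0 (the top clinical-phase bin). The GWAS hit
scores 0.8 (p = 1e-12 against a 1e-15 floor) × 0.9 (4500 of 5000 reference
samples) × 0.1 (intron consequence) = 0.072. The literature score passes
through as given.

```bash
tdscore associate evidence.jsonl ontology.tsv --out-dir out --raw-scores
```

`out/associations.tsv` (selected columns):

```
      target_id  disease_id  is_direct  overall  evidence_count  ...genetic_associations  ...drugs  ...text_mining
ENSG00000113448 EFO:0000270       True    1.053               3                    0.072         1            0.18
ENSG00000113448 EFO:0004591       True    0.072               1                    0.072         0            0.00
ENSG00000113448 EFO:0009687      False    1.053               3                    0.072         1            0.18
```

The text-mining tier is 0.9 × 0.2 (the default down-weight for literature
evidence). The overall score at *asthma* is the harmonic sum of the three
data-type scores: 1 + 0.18/4 + 0.072/9 = 1.053 (raw mode; the default
normalized mode divides every aggregate by Σ_{k≤100} 1/k² ≈ 1.635 to keep
scores in [0, 1]). The GWAS record was annotated to *childhood onset
asthma* yet contributes to *asthma* and to the *respiratory system disease*
root — the latter row is marked `is_direct = False` because no evidence is
annotated to it directly.

Other subcommands: `tdscore validate`, `tdscore mine` (literature filters),
`tdscore fixtures` (synthetic bundle), `tdscore explain TARGET DISEASE …`
(per-evidence breakdown of one association).

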