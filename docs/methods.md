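# Methods

## The model

`tdscore` scores the hypothesis that modulating a drug target will affect a
disease, by integrating heterogeneous evidence records — each linking one
target to one disease term from one upstream database — into association
scores at three tiers: per data source, per data type, and overall.

### Per-evidence scores

Every evidence record receives a score in [0, 1] built from up to three
components:

* **frequency** — how often the observation recurs (e.g. GWAS case/control
  sample size, expression percentile rank);
* **severity** — the magnitude of the effect (e.g. the predicted functional
  consequence of a variant, |log2 fold change|);
* **confidence** — how trustworthy the observation is (e.g. the reported
  p-value, a curator's judgement).

Components a source does not provide are absent and act as the
multiplicative identity. The per-source rules are:

| datasource | rule |
|---|---|
| gwas_catalog | N(pvalue) × N(sample size) × consequence score |
| eva, eva_somatic, cancer_gene_census | consequence score |
| uniprot | 1.0 with strong curated evidence, else 0.5 |
| gene2phenotype, reactome | curator inference score = 1 |
| expression_atlas | N(pvalue) × N(\|log2fc\|) × percentile rank / 100 |
| intogen | tumor-type category: A → 0.25, B → 0.5, C → 0.75 |
| chembl | max clinical phase: 0 → 0.09, 1 → 0.1, 2 → 0.2, 3 → 0.7, 4 → 1.0 |
| phenodigm, europepmc | upstream score passed through (clamped with warning) |

**The normalizer N.** Raw quantities are unbounded, so N must map them onto
[0, 1] monotonically. We use:

* p-values: `clamp((-log10 p) / (-log10 p_floor), 0, 1)` — affine in the
  log domain, saturating at a floor (`p_floor_gwas` default 1e-15,
  `p_floor_expr` default 1e-10, roughly the strongest p-values those assay
  classes report in practice). p = 0 is clipped to the floor with a warning
  rather than rejected, since truncated-precision inputs do occur.
* sample size: `min(n / n_ref, 1)` with `n_ref` = 5000 — a well-powered
  GWAS; larger studies gain nothing further.
* fold change: `min(|log2fc| / fc_cap, 1)` with `fc_cap` = 10 (a 1024-fold
  change saturates).

These functional forms are this package's design choice: transparent,
monotone, bounded, and every constant sits in `ScoringConfig`.

**The consequence table.** Severity values per Sequence Ontology term are a
curation product; the bundled table (`tdscore/data/consequences.tsv`) is a
stand-in ordered monotonically by deleteriousness — transcript ablation and
protein-truncating consequences near 1.0, regulatory-region and intergenic
consequences near 0.05–0.1 — and is fully overridable via a two-column TSV
in the config. Unknown terms score 0.5 by default (policy `default_value`);
a strict mode (`error`) is available.

### Aggregation: the sorted harmonic sum

Evidence scores for one (target, disease) pair and one source are sorted in
descending order s(1) ≥ s(2) ≥ … and combined as

    S = s(1) + s(2)/2² + s(3)/3² + … + s(i)/i²

Replication raises the score, but the 1/k² weights bound the contribution of
bulk: for constant evidence score s the sum converges to s·π²/6 ≈ 1.645·s no
matter how many records accumulate — essential for literature mining, where
a popular gene-disease pair can have thousands of co-occurrence records.
The same rule aggregates data-source scores into data-type scores (similar
sources grouped: e.g. cancer_gene_census, eva_somatic and intogen form
`somatic_mutations`) and data-type scores into the overall score.

Numerical choices:

* **Truncation cap.** Sums are truncated to the top `cap` = 100 terms. Terms
  beyond the 100th contribute < s/10⁴ each; the 1000-evidence and
  100-evidence aggregates of identical scores differ by well under 1%.
* **Normalization.** Evidence scores are bounded by 1 but the harmonic sum
  is not. In the default *normalized* mode every aggregate is divided by the
  cap-truncated maximum Σ_{k≤cap} 1/k² ≈ 1.6350, so association scores stay
  in [0, 1], reach 1 exactly when `cap` pieces of perfect evidence exist,
  and are comparable across tiers. *Raw* mode (`--raw-scores`) keeps the
  uncorrected sums; raw tier aggregates may exceed 1 by design, so the
  unit-interval domain check applies to evidence scores only.
* **Ties.** Sorting ties are broken by evidence_id — irrelevant to the sum
  itself but it makes every intermediate ordering reproducible.
* **Source weights** are applied multiplicatively *after* aggregation, at
  the data-source tier (clamped back into [0, 1] in normalized mode). The
  defaults — 1.0 everywhere, 0.2 for europepmc — encode the intent of
  down-weighting text mining relative to experimental evidence; the values
  are stand-ins and config-overridable. Zero-score evidence still counts
  toward `evidence_count` but adds nothing to any sum.

### Ontology propagation

The disease vocabulary is a DAG of terms under subclass-of edges with
designated therapeutic-area roots. Evidence annotated to a term also
supports every ancestor: one record at "childhood onset asthma" yields a
direct association there and inferred associations at "asthma" and
"respiratory system disease". Each evidence_id counts at most once per
effective disease, so diamond-shaped multiple inheritance does not double
count. An association row is *direct* iff at least one record is annotated
to exactly that term. Only subclass-of edges are traversed; location-,
cell-type- and phenotype-based inferred relations are a future extension.
A consequence (tested): in unweighted raw mode every data-source score at an
ancestor dominates the corresponding score at any descendant, because the
ancestor's evidence multiset is a superset.

### Variant-to-gene assignment

A variant inside a gene interval is assigned to that gene (relation
`overlap`; ties by smallest start, then gene_id). An intergenic variant
goes to the gene with the nearest 5′ end — `start` for +strand genes, the
last base of the half-open interval for −strand genes — with exact-distance
ties broken by gene_id. Coordinates are 0-based half-open internally (BED
native, GFF3 shifted on read), which keeps the distance arithmetic free of
off-by-one ambiguity. Gene-level 5′ ends are used, not canonical-transcript
TSSs; consequence terms arrive annotated in the input (no effect predictor
is run).

### Literature mining

Articles arrive pre-annotated with sentence-level target-disease mention
pairs (named-entity recognition is upstream). The filter pipeline is fixed
as (i) → (ii) → (iii):

1. only Research articles are mined;
2. mentions in Methods, References, Acknowledgement and Funding, Competing
   Interests, Author Contribution and Supplementary sections are discarded;
3. a pair appearing exactly once in the body ("once" counts sentences) and
   never in title or abstract is discarded.

The order matters and is tested: a Methods mention must not push a pair over
the once-only threshold. Surviving pairs score
`min(1, Σ w[section] over distinct locations)` with default weights title
1.0, abstract 0.8, Results 0.3, Discussion 0.2, Introduction 0.1, others
0.05 — stand-ins, config-overridable; unknown section names take the
"others" weight. Each surviving (article, target, disease) becomes a
standard europepmc evidence record whose payload score feeds the
pass-through scorer.

## Validation

Records are validated against a bundled draft-07 JSON schema
(`tdscore/data/evidence.schema.json`) enforced by a compact in-package
validator covering exactly the keyword subset the schema uses; all
violations for a record are reported at once, not just the first.
Identifier checks are syntactic (schema patterns) plus membership of the
disease term in the loaded ontology — deliberately offline and
reproducible, with no live database cross-referencing. Duplicate
evidence_ids follow a configurable policy (default first-wins with a logged
warning; strict mode records an error).

## Synthetic fixtures

The generators (`tdscore.fixtures`) emulate the *shape* of real inputs:
schema-valid evidence with payloads drawn from documented distributions
(p-values log-uniform down to each source's floor, phases and categories
uniform over their bins, pass-through scores uniform on [0, 1]), rooted
ontology trees of configurable depth/branching that embed the named asthma
chain, non-overlapping gene intervals along one contig, and article corpora
cycling through five kinds whose filter-survivor count has a closed form.
One integer seed drives a single numpy Generator stream; identical configs
give byte-identical files.

They do **not** emulate the empirical score distributions, evidence-volume
skew, ontology topology or mention statistics of the production databases.
Passing tests therefore demonstrate correctness of the scoring, filtering,
propagation and aggregation *rules* under controlled conditions — not
calibration of the resulting scores against any real platform release.

Default sizes (200 evidence records for pipeline fixtures, 10–12k for fuzz
batteries, 1000-vector oracle comparisons) were chosen to exercise every
code path with margin while keeping the whole suite in a few seconds.

## Known limitations

* The consequence table, source weights and section weights are documented
  stand-ins, not fitted or curated values.
* Propagation treats all subclass-of edges equally; no edge-type or
  relation-specific inference.
* The pass-through scorers trust upstream scores; no recalibration.
* `explain` reconstructs contributing evidence via the ontology closure; in
  no-propagation runs only directly annotated records are listed.
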