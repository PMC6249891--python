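# oncovis

A variant information system (VIS) for precision oncology: a relational core
model for minimum variant-level data (MVLD), a conflict-preserving two-step
pipeline that integrates heterogeneous variant-knowledgebase exports, HGVS
based variant identity resolution, harmonization of evidence levels across
published grading schemes, and request-time derivation of clinical relevance
tiers.

## The problem

Interpreting a tumor's mutational profile requires information that is
dispersed over many databases (ClinVar-, CIViC-, COSMIC-style sources and
others), each with its own identifiers, disease terminologies, evidence
scales and file layouts — and the sources frequently contradict one another.
`oncovis` materializes these sources into one embedded relational store
without suppressing that uncertainty: conflicting assertions coexist as
separate rows, every stored fact carries lineage links back to the
(source, release, record) it came from, and divergent values are shown side
by side for the clinician to judge.

## The model in brief

The central entity is the **cancer variant** `(v, c)` — one genomic variant
`v` in one cancer type `c` — because a drug effect, a biomarker class or a
clinical relevance tier is only defined for that pair. Variant identity is
the **canonical genomic key** `(assembly, contig, pos, ref, alt)` derived
from genomic-level HGVS descriptions (`NC_000012.11:g.25398284C>G`);
transcript- and protein-level spellings (`NM_033360.3:c.35G>C`,
`NP_203524.1:p.Gly12Ala`, ...) are aliases grouped under that key via
source-supplied cross-references. Drug-effect evidence is stored with both
its original source grading and a harmonized macro level `A > B > C > D > E`
(validated association down to inferential), with sublevels `1A…4B` assigned
only where the source scale is that precise. The clinical relevance tier is
never stored: it is a pure function of the current evidence state, evaluated
on every request (best macro A→Tier 1, C→Tier 2, D→Tier 3, E→Tier 4).

Integration is two-step: releases are first staged *verbatim* into
per-source table spaces (structure fingerprinting halts ingest on unnoticed
schema drift; release activation is an atomic swap and retired releases stay
queryable for reproducible decisions), then a small declarative mapping
document per source moves values into the core model, resolving genes,
diseases and drugs across identifier namespaces and synonym rings.

## Worked example

The package ships a generator for a deterministic single-record release (the
KRAS G12A / colorectal cancer / Panitumumab record) and three seeded
fictional source dialects. A complete session:

```sh
oncovis init --store vis.db
oncovis fixtures worked-example --out we
oncovis sources register --store vis.db --name paperdemo \
    --file genes=record_id,symbol,chromosome,entrez_id,ensembl_id,refseq_id,transcript_ensembl,transcript_refseq,protein_refseq,uniprot,genome_build,cytoband \
    ...   # one --file per logical file, as listed in we/manifest.json
oncovis ingest --store vis.db --source paperdemo --release v1 \
    genes=we/paperdemo/genes.tsv diseases=we/paperdemo/diseases.tsv \
    drugs=we/paperdemo/drugs.tsv variants=we/paperdemo/variants.tsv \
    clinical=we/paperdemo/clinical.tsv aliases=we/paperdemo/aliases.tsv \
    scores=we/paperdemo/scores.tsv
oncovis releases activate --store vis.db --source paperdemo --release v1
oncovis map --store vis.db --source paperdemo --spec we/paperdemo.mapping.yaml
oncovis report --store vis.db --hgvs "NC_000012.11:g.25398284C>G" \
    --cancer-type "colon cancer"
```

prints

```
Cancer variant CV000001 (Colorectal cancer)
  biomarker class: predictive
  clinical relevance (derived): Tier 2
  position [GRCh37.p13]: NC_000012.11:g.25398284C>G
  gene KRAS (Entrez 3845): missense
    transcript T0000001: NM_033360.3(KRAS):c.35G >C (p.Gly12Ala) [FATHMM 0.98468, SIFT 0.0, PolyPhen 0.97] -> concordant-deleterious
  sample S0000001: confirmed somatic, AF 1.647e-05, purity 0.763, TNM T2N1M1
  drug Panitumumab: resistant (evidence C/3A, source Proposed 3A)
```

Reading the output: the variant was queried by a disease *synonym* ("colon
cancer") and resolved to the primary concept; the three risk scores agree
after per-algorithm binarization (`concordant-deleterious`); the single drug
assertion carries evidence macro C, sublevel 3A, so the derived relevance is
Tier 2 — derived at request time, so inserting stronger evidence changes the
next report with no cache to invalidate. `--json` emits the same report
machine-readably with per-fact lineage links.

The same flow works from Python:

```python
from oncovis import VariantStore, synth, build_variant_report

store = VariantStore("vis.db"); store.initialize()
release = synth.generate_worked_example("we")
synth.integrate_release(store, release)
report = build_variant_report(store, "NC_000012.11:g.25398284C>G",
                              "Colorectal cancer")
print(report["clinical_relevance_level"])   # "Tier 2"
```

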