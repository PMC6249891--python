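# Methods

This note documents the data model, the integration procedure, the defaults
that matter, and the limits of what the shipped tests demonstrate.

## Core data model

The store is an embedded SQLite database whose schema mirrors an
MVLD-extended relational model. Entities fall into three blocks:

* **allele descriptive** — gene (HGNC symbol, chromosome, Entrez/Ensembl/
  RefSeq accessions), transcripts (an Ensembl transcript id is mandatory, as
  it is defined for every gene, while RefSeq ids exist only for cataloged
  transcripts), per-assembly gene positions, pathways;
* **allele interpretive** — variant (closed type vocabulary SNV/MNV/INS/DEL),
  per-assembly positions as verbatim HGVS strings, per-gene consequence,
  per-transcript protein change and domain, molecular risk scores;
* **somatic interpretive** — cancer type with synonym ring, the central
  cancer-variant join (unique per `(variant, cancer type)`, with a five-value
  biomarker-class vocabulary), samples/specimens, drugs, and drug-effect
  assertions with evidence levels.

Internal ids are eight characters: a kind prefix (`G`, `T`, `V`, `C`, `CV`,
`S`, `D`, `P`, and `F` for row-level fact uids) plus an uppercase base-36
counter, minted deterministically per store. Closed vocabularies are enforced
twice — as SQL `CHECK` constraints and at typed insertion — so raw writes are
caught by the integrity sweep.

**Lineage is mandatory.** Every row in every core table carries a fact uid,
and at least one lineage link `(source, release, source record id, optional
PMIDs)` must accompany each insertion. The integrity sweep reports
lineage-less facts, dangling references, duplicate cancer-variant pairs and
vocabulary violations.

**Merge semantics.** Inserting a record whose logical key already exists
merges instead of raising: missing fields are filled, present fields are
never overwritten, and the new lineage accumulates on the row. For
multi-assertion tables (drug effects, risk scores) a differing value tuple
coexists as a new row — conflicts are preserved, never averaged — while a
byte-identical assertion only adds lineage. The logical conflict keys are
fixed per table (effect: cancer variant + drug; risk score: gene + transcript
+ variant + algorithm), chosen from the model's cardinalities.

## Variant identity

HGVS strings are parsed for the six description levels (g, c, r, p, m, n)
over a deliberately small grammar: substitution, insertion, deletion and
delins, mirroring the model's four variant types. Anything else
(duplications, inversions, frameshift notation, ...) raises a distinct
"unsupported" error rather than being misread. Two pragmatic choices:

* dialect tolerance: whitespace around the substitution `>` is accepted on
  input (printed exports differ) and never emitted;
* the nomenclature reuses level letters for mitochondria, so descriptions
  against the mitochondrial reference (`NC_012920…`) are reclassified to
  level `m`; the ambiguity is recorded here rather than silently ignored.

Canonical identity is the genomic key `(assembly, contig accession,
position, ref, alt)`, derived from g-level descriptions only, since those
depend on the assembly alone. There is **no computational projection from
c. to g.** — that would require a transcript annotation dataset the model
does not carry; instead, transcript- and protein-level records must carry a
source-supplied cross-reference to a g-level description (sources provide
these, e.g. through shared variant accessions), and alias grouping partitions
records by genomic key, returning records without any cross-reference in an
explicit `unresolved` list. Coordinates are 1-based and fully closed, per
HGVS convention. Ref alleles are not validated against an actual reference
sequence (no FASTA handling).

## Staging and release management

Each source release is loaded verbatim — all values as text, no
transformation — into name-prefixed staging tables (`stg_<source>_<file>`)
that mirror the source's own column layout; prefixing keeps table spaces
portable across embedded stores without schema support. Before loading, each
file's structure is fingerprinted: the ordered column-name list plus a
coarse per-column value kind (`number` if every non-empty value is numeric,
`empty` if the column is entirely empty, `text` otherwise). The fingerprint
is independent of row order and count and identical for gzipped and plain
spellings. A fingerprint change relative to the active release halts the
ingest with a structure diff (added / removed / renamed-candidate /
reordered columns); a human must pass an explicit override to proceed —
automatic adaptation is deliberately not attempted, since unnoticed
restructuring is a classic source of silent conflicts. Release versions are
opaque strings ordered by ingest time. Activation is a single-transaction
swap (previous active → retired), so a reader sees a wholly-old or
wholly-new release, never a mixture; retired releases are retained
indefinitely and stay queryable, which is what makes a past clinical
decision reproducible against the exact reference state it used.

## Semantic mapping

Mapping documents are small declarative YAML files (source schemas are a few
dozen elements, and schema-level conflict resolution is a manual task), one
per source, validated completely before any data moves: unknown targets or
fields, uncovered mandatory fields, recode outputs outside a closed
vocabulary, and missing variant-identity rules are all load-time errors.

Instance-level resolution:

* **identifiers** — cross-reference namespaces per entity kind (gene:
  Entrez primary, then Ensembl, RefSeq; transcript: RefSeq primary, Ensembl,
  UniProt; disease: Disease Ontology primary, UMLS, HPO; drug: DrugBank
  primary, PharmGKB, FDA; pathway: KEGG primary, GO, PathwayCommons,
  Reactome). `(namespace, external id)` maps to at most one internal id per
  kind; a row whose cross-references disagree on identity is skipped and
  reported, not guessed.
* **terms** — disease mentions resolve case-insensitively against primary
  names and recorded synonyms; a surface form matching more than one concept
  returns an explicit ambiguity signal listing the candidates. Judgment is
  left to the expert, never auto-picked.
* **variants** — through the canonical genomic key as above; the key also
  deduplicates variants across sources.

Row-level failures are collected in a machine-readable load report (counts
of inserted / merged-as-conflict / deduplicated facts plus skipped rows with
reasons) and never abort a run. Re-applying the same release is idempotent:
identical assertions deduplicate via the value-tuple match and lineage
uniqueness.

## Evidence harmonization

The registry pins six published grading schemes to a shared macro ladder
A–E (validated association … inferential) with harmonized sublevels 1A–4B
(A: 1A–1C, B: 2A–2C, C: 3A, D: 3B, E: 4A–4B): CIViC's five letters, the
four MVLD working-group tiers, OncoKB's four narrative categories, the six
MD Anderson precision-therapy codes, and the ten levels of Andre et al.
Mapping a source level to its macro is exact (it is the row the level
occupies); a harmonized sublevel is assigned only when the source level
occupies exactly one sublevel row — refining a coarser level would require
per-assertion literature review by a clinician, so the system never invents
sublevels. OncoKB's cells carry no printed codes and are keyed by the macro
row they occupy; rows where a scheme has no cell are simply absent from that
scheme (no interpolation). Original `(scheme, code)` pairs are stored on
every effect row beside the harmonized values. The strength ordering
A > B > C > D > E follows the ladder's top-to-bottom arrangement; within a
macro, sublevel row order decides, and a defined sublevel is incomparable
with an undefined one.

## Risk scores and clinical relevance

Score sets keep every entry; concordance classification binarizes each score
by its algorithm's deleterious pole and threshold and reports
concordant-deleterious / concordant-benign / discordant / under-determined
(fewer than two distinct algorithms). Default thresholds — SIFT < 0.05
deleterious, PolyPhen > 0.85 damaging, FATHMM (0–1 scaled) > 0.5 — are
configuration, not biology: the published scales fix only the poles, and the
registry is open for re-registration with other cutoffs or new algorithms.

The clinical relevance tier is a pluggable pure function evaluated at
request time against the current store state; it is never cached or
persisted, because its inputs (approvals, evidence levels) change upstream
and a precomputed tier would need invalidation machinery and could silently
go stale. The default rule maps the best available macro to the four-tier
ladder printed alongside it (A→Tier 1, C→Tier 2, D→Tier 3, E→Tier 4). Macro
B carries no tier label of its own on that ladder; the default rule groups
it with the clinical-evidence block as **Tier 1** — a documented choice,
overridable by supplying another rule. With no drug-effect evidence the
default yields Tier 3 (variant of unknown clinical significance) and flags
the derivation as low-information. Every derivation returns a JSON
explanation listing the contributing effect rows, their original and
harmonized levels and their lineage.

## Synthetic sources

The generator fabricates three fictional dialects (gzipped multi-file TSV
with the disease terminology and MD Anderson codes; plain CSV with a
`cancer_entity` disease column, c-level HGVS plus genomic cross-references
and CIViC codes; gzipped single-table TSV with Andre codes) and injects,
under a seeded RNG, the hazards the pipeline must survive: cross-source
variant overlap (default 30 % of variants in ≥ 2 sources), contradictory
drug effects (default 20 % of overlapping pairs), synonym-only disease
mentions (default 30 % of mentions) and optional schema drift for a second
release. Defaults (25 genes, 250 variants, 8 cancer types, 12 drugs) yield
on the order of a thousand staged rows per run — large enough to exercise
identity and conflict logic, small enough that the full property suite over
ten seeds runs in seconds. A ground-truth manifest fully determines expected
pipeline outputs, and generation is byte-deterministic per seed (gzip
members are written with a pinned mtime).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic mutation spectra or allele frequencies
(positions are uniform within per-gene windows), real source row counts,
free-text curation noise, partially structured fields, or identifier errors
in the sources themselves. Accessions are syntactically valid but fictional;
the manifest marks the release as fictional.

The separate worked-example release is fully deterministic (no RNG) and
reproduces one canonical record end to end; its alias and predictor-score
tables are staged verbatim as source-specific extras (the staging layer
deliberately retains data the core model does not map).

## Numerical and degenerate-input choices

* Ratios (tumor purity, allele frequency) are validated to [0, 1]; floats
  are stored as SQLite REALs, compared exactly in tests where the inputs are
  exact decimal literals and with approximate comparison otherwise.
* Empty strings in source cells are treated as absent values.
* Name uniqueness (genes, diseases, drugs) is ASCII case-insensitive;
  source exports vary in casing and nothing more exotic is attempted.
* Best-evidence selection iterates in row order and keeps the incumbent on
  incomparable ties; since tiers depend only on the macro, tie-breaking
  cannot change a derived tier.
* An entity row whose cross-references resolve to two different internal
  ids is skipped with a report entry (no automatic identity merge).

## Known limitations

* Coding-region, single-variant scope: no non-coding variants, no
  multi-variant signatures, no HGVS extension for transcriptome
  aberrations (transcript-level consequences without a genomic cause are
  representable, but not first-class HGVS citizens).
* Cancer only; extending to other disease areas would rename the central
  join and add per-disease context tables, which is out of scope here.
* No live source adapters: ingestion starts from files on disk; fetching,
  scheduling and per-source ETL quirks are the operator's concern.
* Risk-score algorithms themselves (SIFT, PolyPhen, FATHMM) are not
  implemented — only the storage, concordance classification and display of
  their outputs.
* Term resolution is exact-match over names and synonyms (after case
  folding); no fuzzy matching or ontology traversal.
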