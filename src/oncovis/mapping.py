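"""Semantic integration: declarative mapping of staged source data to the core.

The second integration step (the first being verbatim staging) moves each
relevant element of a source's own schema into the core model. It splits into
schema-element mapping — a small, manually curated, declarative document per
source saying which source column feeds which target field, with value
recodes — and instance-level resolution: identifiers are reconciled through
the cross-reference namespaces (Entrez/Ensembl/RefSeq for genes, Disease
Ontology/UMLS/HPO for diseases, DrugBank/PharmGKB/FDA for drugs, ...),
disease mentions through names and synonyms, and variants through their
canonical genomic identity derived from HGVS descriptions.

Fact merging is conflict-preserving: a byte-identical assertion accumulates
lineage on the existing row; the same logical key with a different value
tuple (for example two sources reporting different drug effects for one
cancer variant) coexists as a new row. Nothing is overwritten or averaged.
Row-level failures (unparseable HGVS, unknown disease term, unmapped
vocabulary value) are collected in the load report and skip only their row —
a single bad record never aborts an integration run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import yaml

from . import hgvs as hgvs_mod
from . import staging
from .evidence import harmonize_level
from .schema import (TABLES, Lineage, ValidationError, VariantStore,
                     VocabularyError)

__all__ = [
    "NAMESPACES",
    "PRIMARY_NAMESPACE",
    "MappingSpec",
    "TableRule",
    "LoadReport",
    "MappingSpecError",
    "NotFoundError",
    "AmbiguousTermError",
    "load_mapping_spec",
    "resolve_identifier",
    "resolve_term",
    "apply_mapping",
    "merge_fact",
]

# cross-reference namespaces per entity kind; the first entry is the primary
# identifier source, recorded preferentially
NAMESPACES: Mapping[str, tuple[str, ...]] = {
    "gene": ("entrez_gene", "ensembl", "refseq"),
    "transcript": ("refseq", "ensembl", "uniprot"),
    "disease": ("disease_ontology", "umls", "hpo"),
    "drug": ("drugbank", "pharmgkb", "fda"),
    "pathway": ("kegg", "go", "pathwaycommons", "reactome"),
}
PRIMARY_NAMESPACE = {kind: spaces[0] for kind, spaces in NAMESPACES.items()}

#: entity kind backing each xref-carrying target table
_XREF_KIND = {"gene": "gene", "gene_transcript": "transcript",
              "cancer_type": "disease", "drug": "drug", "pathway": "pathway"}

#: order in which table rules are applied (referenced entities first)
_TARGET_ORDER = (
    "gene", "gene_transcript", "gene_position", "pathway", "gene_pathway",
    "cancer_type", "drug", "drug_mechanism", "variant", "gene_variant",
    "gene_variant_transcript", "cancer_variant", "sample_specimen",
    "cancer_variant_sample", "cancer_variant_drug_effect", "risk_score",
)

#: target fields the engine itself resolves (never required from the document)
_ENGINE_FIELDS = {
    "gene": {"gene_id"},
    "gene_transcript": {"transcript_id", "gene_id"},
    "gene_position": {"gene_id"},
    "pathway": {"pathway_id"},
    "gene_pathway": {"gene_id", "pathway_id"},
    "cancer_type": {"cancer_type_id"},
    "drug": {"drug_id"},
    "drug_mechanism": {"drug_id"},
    "variant": {"variant_id", "variant_type"},
    "gene_variant": {"gene_id", "variant_id"},
    "gene_variant_transcript": {"gene_id", "variant_id", "transcript_id"},
    "cancer_variant": {"cancer_variant_id", "variant_id", "cancer_type_id"},
    "sample_specimen": {"sample_id"},
    "cancer_variant_sample": {"cancer_variant_id", "sample_id"},
    "cancer_variant_drug_effect": {"cancer_variant_id", "drug_id",
                                   "evidence_level", "evidence_sublevel",
                                   "source_scheme", "source_level_code"},
    "risk_score": {"gene_id", "transcript_id", "variant_id", "algorithm",
                   "score"},
}

#: targets that must carry a variant-identity (HGVS) directive
_NEEDS_HGVS = {"variant", "gene_variant", "gene_variant_transcript",
               "cancer_variant", "cancer_variant_sample",
               "cancer_variant_drug_effect", "risk_score"}


class MappingSpecError(ValueError):
    """The mapping document is invalid; raised before any data moves."""


class NotFoundError(KeyError):
    """Identifier or term resolution found no matching entity."""


class AmbiguousTermError(ValueError):
    """A surface form matches more than one concept; carries the candidates."""

    def __init__(self, surface: str, candidates: Sequence[str]):
        self.surface = surface
        self.candidates = list(candidates)
        super().__init__(
            f"term {surface!r} is ambiguous between concepts {self.candidates}")


@dataclass(frozen=True)
class TableRule:
    target: str
    file: str
    fields: Mapping[str, Mapping[str, Any]]  # target field -> directive
    record_id: str | None = None  # source column naming the record id
    hgvs: Mapping[str, Any] | None = None
    gene: Mapping[str, Any] | None = None
    transcript: Mapping[str, Any] | None = None
    cancer: Mapping[str, Any] | None = None
    drug: Mapping[str, Any] | None = None
    sample: Mapping[str, Any] | None = None
    evidence: Mapping[str, Any] | None = None
    scores: Mapping[str, str] | None = None
    synonyms: Mapping[str, Any] | None = None
    xrefs: Mapping[str, str] | None = None  # namespace -> source column


@dataclass(frozen=True)
class MappingSpec:
    source_name: str
    rules: tuple[TableRule, ...]


@dataclass
class LoadReport:
    """Counts and skip reasons of one mapping run, JSON-serializable."""

    source_name: str
    release_version: str
    inserted: int = 0
    merged_as_conflict: int = 0
    deduplicated: int = 0
    skipped: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"source": self.source_name, "release": self.release_version,
                "inserted": self.inserted,
                "merged_as_conflict": self.merged_as_conflict,
                "deduplicated": self.deduplicated,
                "skipped": self.skipped}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# ---------------------------------------------------------------------------
# Spec loading and validation
# ---------------------------------------------------------------------------


def load_mapping_spec(document: str | Mapping) -> MappingSpec:
    """Parse and validate a mapping document (YAML text or mapping).

    Validation is complete before any data moves: unknown target tables or
    fields, recode outputs outside a closed vocabulary, uncovered mandatory
    fields and missing variant-identity rules all raise
    :class:`MappingSpecError` here.
    """
    doc = yaml.safe_load(document) if isinstance(document, str) else document
    if not isinstance(doc, Mapping) or "source" not in doc:
        raise MappingSpecError("mapping document must declare 'source'")
    raw_rules = doc.get("tables")
    if not raw_rules:
        raise MappingSpecError("mapping document declares no table rules")
    rules = []
    for raw in raw_rules:
        rules.append(_load_rule(raw))
    return MappingSpec(str(doc["source"]), tuple(rules))


def _load_rule(raw: Mapping) -> TableRule:
    target = raw.get("target")
    if target not in _ENGINE_FIELDS:
        raise MappingSpecError(
            f"unknown or non-mappable target table {target!r}; mappable: "
            f"{sorted(_ENGINE_FIELDS)}")
    if not raw.get("file"):
        raise MappingSpecError(f"rule for {target!r} names no source file")
    table = TABLES[target]
    fields = dict(raw.get("fields") or {})
    known = {c.name for c in table.columns}
    for fname, directive in fields.items():
        if fname not in known:
            raise MappingSpecError(
                f"rule for {target!r}: unknown target field {fname!r}")
        if not isinstance(directive, Mapping) or not (
                "column" in directive or "const" in directive):
            raise MappingSpecError(
                f"rule for {target!r}.{fname}: directive needs 'column' or "
                f"'const'")
        col = table.column(fname)
        if col.vocab is not None and "recode" in directive:
            bad = [v for v in directive["recode"].values()
                   if v not in col.vocab]
            if bad:
                raise MappingSpecError(
                    f"rule for {target!r}.{fname}: recode outputs {bad} not "
                    f"in vocabulary '{col.vocab_name}' {list(col.vocab)}")
    rule = TableRule(
        target=target, file=str(raw["file"]), fields=fields,
        record_id=raw.get("record_id"),
        hgvs=raw.get("hgvs"), gene=raw.get("gene"),
        transcript=raw.get("transcript"), cancer=raw.get("cancer"),
        drug=raw.get("drug"), sample=raw.get("sample"),
        evidence=raw.get("evidence"), scores=raw.get("scores"),
        synonyms=raw.get("synonyms"), xrefs=raw.get("xrefs"))
    _check_coverage(rule)
    return rule


def _check_coverage(rule: TableRule) -> None:
    table = TABLES[rule.target]
    engine = _ENGINE_FIELDS[rule.target]
    uncovered = []
    for c in table.columns:
        if not c.mandatory or c.name in engine or c.name == table.id_column:
            continue
        if c.name not in rule.fields:
            uncovered.append(c.name)
    if uncovered:
        raise MappingSpecError(
            f"rule for {rule.target!r}: mandatory core fields {uncovered} "
            f"are not covered by any column rule or constant")
    if rule.target in _NEEDS_HGVS and not rule.hgvs:
        raise MappingSpecError(
            f"rule for {rule.target!r}: missing variant identity rule "
            f"('hgvs' block naming the HGVS column)")
    if rule.target == "cancer_variant_drug_effect" and not rule.evidence:
        raise MappingSpecError(
            "rule for 'cancer_variant_drug_effect': missing 'evidence' block "
            "(scheme and level column)")
    if rule.target == "risk_score" and not rule.scores:
        raise MappingSpecError(
            "rule for 'risk_score': missing 'scores' block "
            "(algorithm -> column)")


# ---------------------------------------------------------------------------
# Instance-level resolution
# ---------------------------------------------------------------------------

_KIND_TABLE = {"gene": "gene", "transcript": "gene_transcript",
               "disease": "cancer_type", "drug": "drug", "pathway": "pathway"}
_KIND_ID_KIND = {"gene": "gene", "transcript": "transcript",
                 "disease": "cancer_type", "drug": "drug",
                 "pathway": "pathway"}


def resolve_identifier(store: VariantStore, entity_kind: str, namespace: str,
                       external_id: str, create_if_absent: bool = False,
                       lineage: Lineage | None = None) -> str:
    """Resolve an external accession to the internal id of its entity.

    ``namespace`` must be registered for the entity kind (the genomic-key
    namespace used for variants is handled by the variant pipeline, not
    here). With ``create_if_absent`` a new internal id is minted and the
    cross-reference recorded (lineage required); the caller is responsible
    for inserting the entity row itself under that id.
    """
    if entity_kind not in NAMESPACES:
        raise ValidationError(f"unknown entity kind {entity_kind!r}")
    if namespace not in NAMESPACES[entity_kind]:
        raise ValidationError(
            f"namespace {namespace!r} is not registered for entity kind "
            f"{entity_kind!r}; registered: {list(NAMESPACES[entity_kind])}")
    row = store.fetch_one("identifier_xref", entity_kind=entity_kind,
                          namespace=namespace, external_id=str(external_id))
    if row is not None:
        return row["internal_id"]
    if not create_if_absent:
        raise NotFoundError(
            f"no {entity_kind} known under {namespace}:{external_id}")
    if lineage is None:
        raise ValidationError(
            "creating an identifier cross-reference requires lineage")
    internal = store.mint_id(_KIND_ID_KIND[entity_kind])
    store.insert_fact("identifier_xref", {
        "entity_kind": entity_kind, "namespace": namespace,
        "external_id": str(external_id), "internal_id": internal}, lineage)
    return internal


def resolve_term(store: VariantStore, entity_kind: str,
                 surface_form: str) -> str:
    """Case-insensitive resolution of a name or synonym to a concept id.

    Sources typically mention a disease by any one of its synonyms without
    the concept id; this matches against primary names and recorded synonyms.
    More than one matching concept raises :class:`AmbiguousTermError` —
    ambiguity is surfaced, never silently picked.
    """
    surface = surface_form.strip()
    candidates: set[str] = set()
    if entity_kind == "disease":
        row = store.fetch_one("cancer_type", cancer_type_name=surface)
        if row:
            candidates.add(row["cancer_type_id"])
        for syn in store.fetch("cancer_type_synonym", surface_form=surface):
            candidates.add(syn["cancer_type_id"])
    elif entity_kind == "drug":
        row = store.fetch_one("drug", substance_name=surface)
        if row:
            candidates.add(row["drug_id"])
    elif entity_kind == "gene":
        row = store.fetch_one("gene", gene_name=surface)
        if row:
            candidates.add(row["gene_id"])
    else:
        raise ValidationError(
            f"term resolution is not defined for kind {entity_kind!r}")
    if not candidates:
        raise NotFoundError(f"no {entity_kind} matches term {surface!r}")
    if len(candidates) > 1:
        raise AmbiguousTermError(surface, sorted(candidates))
    return candidates.pop()


def merge_fact(store: VariantStore, table: str, record: Mapping[str, Any],
               lineage: Lineage) -> tuple[str, str]:
    """Conflict-preserving merge; thin alias of the store's merge primitive."""
    return store.merge_fact(table, record, lineage)


# ---------------------------------------------------------------------------
# Mapping engine
# ---------------------------------------------------------------------------


class _RowSkip(Exception):
    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def _eval_field(directive: Mapping[str, Any], row: Mapping[str, str],
                fname: str) -> Any:
    if "const" in directive:
        return directive["const"]
    col = directive["column"]
    if col not in row:
        raise _RowSkip(f"source column {col!r} absent")
    value: Any = row[col].strip() if isinstance(row[col], str) else row[col]
    if value == "":
        return None
    if "recode" in directive:
        table = directive["recode"]
        if value not in table:
            raise _RowSkip(
                f"{fname}: value {value!r} not covered by recode table")
        value = table[value]
    if directive.get("cast") == "float":
        try:
            value = float(value)
        except ValueError:
            raise _RowSkip(f"{fname}: {value!r} is not a number") from None
    if directive.get("lower"):
        value = value.lower()
    return value


class _Engine:
    def __init__(self, store: VariantStore, spec: MappingSpec,
                 release: staging.SourceRelease,
                 assembly_default: str = "GRCh37.p13"):
        self.store = store
        self.spec = spec
        self.release = release
        self.assembly_default = assembly_default
        self.report = LoadReport(spec.source_name, release.release_version)

    # -- generic helpers ---------------------------------------------------

    def _lineage(self, rule: TableRule, row: Mapping[str, str]) -> Lineage:
        if rule.record_id and row.get(rule.record_id, "").strip():
            rid = row[rule.record_id].strip()
        else:
            rid = f"{rule.file}:{row['_row']}"
        pmids: tuple[str, ...] = ()
        if "pmids" in row and str(row.get("pmids", "")).strip():
            pmids = tuple(p.strip() for p in str(row["pmids"]).split(";")
                          if p.strip())
        return Lineage(self.spec.source_name, self.release.release_version,
                       rid, pmids)

    def _count(self, outcome: str) -> None:
        if outcome == "inserted-new":
            self.report.inserted += 1
        elif outcome == "attached-conflict":
            self.report.merged_as_conflict += 1
        else:
            self.report.deduplicated += 1

    def _merge(self, table: str, record: dict, lineage: Lineage) -> str:
        ident, outcome = self.store.merge_fact(table, record, lineage)
        self._count(outcome)
        return ident

    def _fields(self, rule: TableRule, row: Mapping[str, str]) -> dict:
        out = {}
        for fname, directive in rule.fields.items():
            out[fname] = _eval_field(directive, row, fname)
        return out

    # -- entity resolution -------------------------------------------------

    def _upsert_entity(self, kind: str, record: dict,
                       xrefs: Sequence[tuple[str, str]],
                       lineage: Lineage) -> str:
        """Insert-or-merge an entity row, reconciling across namespaces."""
        table = _KIND_TABLE[kind]
        ids = set()
        for ns, ext in xrefs:
            try:
                ids.add(resolve_identifier(self.store, kind, ns, ext))
            except NotFoundError:
                pass
        if len(ids) > 1:
            raise _RowSkip(
                f"{kind}: cross-references disagree on identity {sorted(ids)}")
        id_col = TABLES[table].id_column
        if ids:
            record = dict(record)
            record[id_col] = ids.pop()
        internal = self._merge(table, record, lineage)
        for ns, ext in xrefs:
            try:
                existing = resolve_identifier(self.store, kind, ns, ext)
                if existing != internal:
                    raise _RowSkip(
                        f"{kind}: {ns}:{ext} already bound to {existing}")
            except NotFoundError:
                self.store.insert_fact("identifier_xref", {
                    "entity_kind": kind, "namespace": ns,
                    "external_id": str(ext), "internal_id": internal}, lineage)
        return internal

    def _collect_xrefs(self, rule: TableRule, kind: str, record: dict,
                       row: Mapping[str, str]) -> list[tuple[str, str]]:
        # accession fields of the entity row double as cross-references
        auto = {
            "gene": (("entrez_gene", "entrez_gene_id"),
                     ("ensembl", "ensembl_gene_id"),
                     ("refseq", "refseq_gene_id")),
            "transcript": (("refseq", "refseq_transcript_id"),
                           ("ensembl", "ensembl_transcript_id"),
                           ("uniprot", "uniprot_id")),
            "disease": (("umls", "umls_id"), ("hpo", "hpo_id")),
            "drug": (("drugbank", "drugbank_id"), ("pharmgkb", "pharmgkb_id"),
                     ("fda", "fda_id")),
            "pathway": (("kegg", "kegg_id"), ("reactome", "reactome_id"),
                        ("pathwaycommons", "pathwaycommons_id")),
        }[kind]
        xrefs = [(ns, str(record[f])) for ns, f in auto if record.get(f)]
        for ns, col in (rule.xrefs or {}).items():
            if ns not in NAMESPACES[kind]:
                raise _RowSkip(f"namespace {ns!r} not registered for {kind!r}")
            v = row.get(col, "").strip()
            if v:
                xrefs.append((ns, v))
        # primary namespace recorded preferentially
        order = {ns: i for i, ns in enumerate(NAMESPACES[kind])}
        xrefs.sort(key=lambda p: order.get(p[0], 99))
        seen = set()
        out = []
        for p in xrefs:
            if p not in seen:
                seen.add(p)
                out.append(p)
        return out

    def _resolve_gene(self, rule: TableRule, row: Mapping[str, str]) -> str:
        spec = rule.gene or {}
        col = spec.get("name_column")
        if not col:
            raise _RowSkip(f"{rule.target}: rule names no gene column")
        name = row.get(col, "").strip()
        if not name:
            raise _RowSkip("gene name missing in row")
        try:
            return resolve_term(self.store, "gene", name)
        except NotFoundError:
            raise _RowSkip(f"unknown gene {name!r}") from None

    def _resolve_transcript(self, rule: TableRule,
                            row: Mapping[str, str]) -> str:
        spec = rule.transcript or {}
        col = spec.get("ensembl_column")
        if not col:
            raise _RowSkip(f"{rule.target}: rule names no transcript column")
        acc = row.get(col, "").strip()
        if not acc:
            raise _RowSkip("transcript accession missing in row")
        try:
            return resolve_identifier(self.store, "transcript", "ensembl", acc)
        except NotFoundError:
            raise _RowSkip(f"unknown transcript {acc!r}") from None

    def _resolve_cancer(self, rule: TableRule, row: Mapping[str, str]) -> str:
        spec = rule.cancer or {}
        col = spec.get("term_column")
        if not col:
            raise _RowSkip(f"{rule.target}: rule names no cancer-type column")
        term = row.get(col, "").strip()
        if not term:
            raise _RowSkip("cancer type term missing in row")
        try:
            return resolve_term(self.store, "disease", term)
        except NotFoundError:
            raise _RowSkip(f"unknown cancer type term {term!r}") from None
        except AmbiguousTermError as exc:
            raise _RowSkip(str(exc)) from None

    def _resolve_drug(self, rule: TableRule, row: Mapping[str, str]) -> str:
        spec = rule.drug or {}
        col = spec.get("name_column")
        if not col:
            raise _RowSkip(f"{rule.target}: rule names no drug column")
        name = row.get(col, "").strip()
        if not name:
            raise _RowSkip("drug name missing in row")
        try:
            return resolve_term(self.store, "drug", name)
        except NotFoundError:
            raise _RowSkip(f"unknown drug {name!r}") from None

    def _genomic_key_string(self, rule: TableRule,
                            row: Mapping[str, str]) -> str:
        """Canonical g-level spelling identifying the row's variant."""
        spec = rule.hgvs
        col = spec.get("column")
        text = row.get(col, "").strip()
        if not text:
            raise _RowSkip("HGVS string missing in row")
        try:
            desc = hgvs_mod.parse_hgvs(text)
        except (hgvs_mod.HgvsParseError,
                hgvs_mod.UnsupportedHgvsError) as exc:
            raise _RowSkip(f"HGVS parse error: {exc}") from None
        if desc.level != "g":
            ref_col = spec.get("level_g_ref")
            gtext = row.get(ref_col, "").strip() if ref_col else ""
            if not gtext:
                raise _RowSkip(
                    f"non-genomic HGVS {text!r} without a g-level "
                    f"cross-reference")
            try:
                desc = hgvs_mod.parse_hgvs(gtext)
            except (hgvs_mod.HgvsParseError,
                    hgvs_mod.UnsupportedHgvsError) as exc:
                raise _RowSkip(f"HGVS parse error: {exc}") from None
            if desc.level != "g":
                raise _RowSkip(
                    f"cross-reference {gtext!r} is not a g-level description")
        return hgvs_mod.format_hgvs(desc)

    def _resolve_variant(self, rule: TableRule, row: Mapping[str, str],
                         create: bool, lineage: Lineage | None = None) -> str:
        key = self._genomic_key_string(rule, row)
        found = self.store.fetch_one("identifier_xref", entity_kind="variant",
                                     namespace="genomic_key", external_id=key)
        if found is not None:
            return found["internal_id"]
        if not create:
            raise _RowSkip(f"unknown variant {key!r}")
        desc = hgvs_mod.parse_hgvs(key)
        vtype = _infer_variant_type(desc)
        variant_id = self._merge("variant", {"variant_type": vtype}, lineage)
        self.store.insert_fact("identifier_xref", {
            "entity_kind": "variant", "namespace": "genomic_key",
            "external_id": key, "internal_id": variant_id}, lineage)
        assembly = (rule.hgvs.get("genome_version")
                    or self.assembly_default)
        self._merge("variant_position", {
            "variant_id": variant_id, "genome_version": assembly,
            "dna_sub_and_position": key}, lineage)
        return variant_id

    def _resolve_cancer_variant(self, rule: TableRule, row: Mapping[str, str],
                                lineage: Lineage,
                                biomarker_class: str | None = None) -> str:
        variant_id = self._resolve_variant(rule, row, create=False)
        cancer_id = self._resolve_cancer(rule, row)
        existing = self.store.fetch_one(
            "cancer_variant", variant_id=variant_id, cancer_type_id=cancer_id)
        if existing is not None:
            return existing["cancer_variant_id"]
        if biomarker_class is None:
            raise _RowSkip("cancer variant unknown and row carries no "
                           "biomarker class to create it")
        return self._merge("cancer_variant", {
            "variant_id": variant_id, "cancer_type_id": cancer_id,
            "biomarker_class": biomarker_class}, lineage)

    # -- per-target handlers ----------------------------------------------

    def apply_rule(self, rule: TableRule) -> None:
        rows = staging.staged_rows(self.store, self.spec.source_name,
                                   rule.file, self.release.release_version)
        handler = getattr(self, "_do_" + rule.target)
        for row in rows:
            lineage = self._lineage(rule, row)
            try:
                handler(rule, row, lineage)
            except _RowSkip as skip:
                self.report.skipped.append({
                    "target": rule.target, "file": rule.file,
                    "row": row["_row"], "reason": skip.reason})
            except (ValidationError, VocabularyError) as exc:
                self.report.skipped.append({
                    "target": rule.target, "file": rule.file,
                    "row": row["_row"], "reason": str(exc)})

    def _do_gene(self, rule, row, lineage):
        record = self._fields(rule, row)
        xrefs = self._collect_xrefs(rule, "gene", record, row)
        self._upsert_entity("gene", record, xrefs, lineage)

    def _do_gene_transcript(self, rule, row, lineage):
        record = self._fields(rule, row)
        record["gene_id"] = self._resolve_gene(rule, row)
        xrefs = self._collect_xrefs(rule, "transcript", record, row)
        self._upsert_entity("transcript", record, xrefs, lineage)

    def _do_gene_position(self, rule, row, lineage):
        record = self._fields(rule, row)
        record["gene_id"] = self._resolve_gene(rule, row)
        self._merge("gene_position", record, lineage)

    def _do_pathway(self, rule, row, lineage):
        record = self._fields(rule, row)
        xrefs = self._collect_xrefs(rule, "pathway", record, row)
        self._upsert_entity("pathway", record, xrefs, lineage)

    def _do_gene_pathway(self, rule, row, lineage):
        record = self._fields(rule, row)
        record["gene_id"] = self._resolve_gene(rule, row)
        name = record.pop("common_name", None)
        if name is None:
            raise _RowSkip("gene_pathway rule must map 'common_name'")
        found = self.store.fetch_one("pathway", common_name=name)
        if found is None:
            raise _RowSkip(f"unknown pathway {name!r}")
        record["pathway_id"] = found["pathway_id"]
        self._merge("gene_pathway", record, lineage)

    def _do_cancer_type(self, rule, row, lineage):
        record = self._fields(rule, row)
        xrefs = self._collect_xrefs(rule, "disease", record, row)
        concept = self._upsert_entity("disease", record, xrefs, lineage)
        if rule.synonyms:
            col = rule.synonyms.get("column")
            sep = rule.synonyms.get("separator", "|")
            tag = rule.synonyms.get("terminology")
            for form in (row.get(col, "") or "").split(sep):
                form = form.strip()
                if form:
                    self._merge("cancer_type_synonym", {
                        "cancer_type_id": concept, "surface_form": form,
                        "terminology": tag}, lineage)

    def _do_drug(self, rule, row, lineage):
        record = self._fields(rule, row)
        xrefs = self._collect_xrefs(rule, "drug", record, row)
        self._upsert_entity("drug", record, xrefs, lineage)

    def _do_drug_mechanism(self, rule, row, lineage):
        record = self._fields(rule, row)
        record["drug_id"] = self._resolve_drug(rule, row)
        self._merge("drug_mechanism", record, lineage)

    def _do_variant(self, rule, row, lineage):
        self._resolve_variant(rule, row, create=True, lineage=lineage)

    def _do_gene_variant(self, rule, row, lineage):
        record = self._fields(rule, row)
        record["gene_id"] = self._resolve_gene(rule, row)
        record["variant_id"] = self._resolve_variant(rule, row, create=False)
        self._merge("gene_variant", record, lineage)

    def _do_gene_variant_transcript(self, rule, row, lineage):
        record = self._fields(rule, row)
        record["gene_id"] = self._resolve_gene(rule, row)
        record["transcript_id"] = self._resolve_transcript(rule, row)
        record["variant_id"] = self._resolve_variant(rule, row, create=False)
        self._merge("gene_variant_transcript", record, lineage)

    def _do_cancer_variant(self, rule, row, lineage):
        record = self._fields(rule, row)
        self._resolve_cancer_variant(rule, row, lineage,
                                     record.get("biomarker_class"))

    def _do_sample_specimen(self, rule, row, lineage):
        record = self._fields(rule, row)
        code = None
        if rule.sample:
            code = row.get(rule.sample.get("code_column", ""), "").strip()
        sample_id = None
        if code:
            found = self.store.fetch_one("identifier_xref",
                                         entity_kind="sample",
                                         namespace="source_sample",
                                         external_id=code)
            if found:
                sample_id = found["internal_id"]
        record["sample_id"] = sample_id
        sample_id = self._merge("sample_specimen", record, lineage)
        if code and self.store.fetch_one(
                "identifier_xref", entity_kind="sample",
                namespace="source_sample", external_id=code) is None:
            self.store.insert_fact("identifier_xref", {
                "entity_kind": "sample", "namespace": "source_sample",
                "external_id": code, "internal_id": sample_id}, lineage)

    def _do_cancer_variant_sample(self, rule, row, lineage):
        record = self._fields(rule, row)
        record["cancer_variant_id"] = self._resolve_cancer_variant(
            rule, row, lineage)
        code = row.get((rule.sample or {}).get("code_column", ""), "").strip()
        if not code:
            raise _RowSkip("sample code missing in row")
        found = self.store.fetch_one("identifier_xref", entity_kind="sample",
                                     namespace="source_sample",
                                     external_id=code)
        if found is None:
            raise _RowSkip(f"unknown sample specimen {code!r}")
        record["sample_id"] = found["internal_id"]
        self._merge("cancer_variant_sample", record, lineage)

    def _do_cancer_variant_drug_effect(self, rule, row, lineage):
        record = self._fields(rule, row)
        cv = self._resolve_cancer_variant(rule, row, lineage)
        drug_id = self._resolve_drug(rule, row)
        self._merge("cancer_variant_drug", {
            "cancer_variant_id": cv, "drug_id": drug_id}, lineage)
        scheme = rule.evidence.get("scheme")
        level_col = rule.evidence.get("level_column")
        code = row.get(level_col, "").strip() if level_col else ""
        if not code:
            raise _RowSkip("evidence level missing in row")
        try:
            assignment = harmonize_level(scheme, code)
        except KeyError as exc:
            raise _RowSkip(str(exc)) from None
        record.update({
            "cancer_variant_id": cv, "drug_id": drug_id,
            "evidence_level": assignment.macro,
            "evidence_sublevel": assignment.sublevel,
            "source_scheme": scheme, "source_level_code": code})
        self._merge("cancer_variant_drug_effect", record, lineage)

    def _do_risk_score(self, rule, row, lineage):
        gene_id = self._resolve_gene(rule, row)
        transcript_id = self._resolve_transcript(rule, row)
        variant_id = self._resolve_variant(rule, row, create=False)
        for algo, col in rule.scores.items():
            raw = row.get(col, "").strip()
            if raw == "":
                continue
            try:
                score = float(raw)
            except ValueError:
                raise _RowSkip(f"{algo} score {raw!r} is not a number") \
                    from None
            self._merge("risk_score", {
                "gene_id": gene_id, "transcript_id": transcript_id,
                "variant_id": variant_id, "algorithm": algo,
                "score": score}, lineage)


def _infer_variant_type(d: hgvs_mod.HgvsDescriptor) -> str:
    if d.change_kind == "substitution":
        return "SNV" if len(d.ref_allele or "") == 1 else "MNV"
    if d.change_kind == "insertion":
        return "INS"
    if d.change_kind == "deletion":
        return "DEL"
    return "MNV"  # delins: multi-nucleotide replacement


def apply_mapping(store: VariantStore, spec: MappingSpec,
                  release_version: str | None = None,
                  assembly_default: str = "GRCh37.p13") -> LoadReport:
    """Run a validated mapping spec over one staged release.

    Uses the source's active release unless ``release_version`` names one
    explicitly. Entities are resolved or minted, variant identity goes
    through the genomic key, and every fact lands via the conflict-preserving
    merge with a lineage link naming (source, release, source record). The
    returned report counts inserted / merged-as-conflict / deduplicated facts
    and lists skipped rows with reasons; re-applying the same release inserts
    nothing new.
    """
    if release_version is None:
        rel = staging.active_release(store, spec.source_name)
        if rel is None:
            raise ValidationError(
                f"source {spec.source_name!r} has no active release")
    else:
        rows = [r for r in staging.list_releases(store, spec.source_name)
                if r.release_version == release_version]
        if not rows:
            raise ValidationError(
                f"source {spec.source_name!r} has no release "
                f"{release_version!r}")
        rel = rows[0]
    engine = _Engine(store, spec, rel, assembly_default)
    order = {t: i for i, t in enumerate(_TARGET_ORDER)}
    for rule in sorted(spec.rules, key=lambda r: order[r.target]):
        engine.apply_rule(rule)
    store.conn.commit()
    return engine.report
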