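"""Relational core data model for minimum variant-level data (MVLD) in oncology.

The central entity is the *cancer variant*: the join of one genomic variant and
one cancer type, carrier of the biomarker class and of the request-time derived
clinical relevance tier. Around it the model holds allele-descriptive context
(gene, transcript, position, pathway), allele-interpretive context (variant,
consequence per gene and per transcript, molecular risk scores) and somatic
interpretive context (cancer type, sample, drug, drug effect with evidence
level). Every stored fact carries at least one lineage link binding it to the
(source, release, source record) it was extracted from; conflicting assertions
coexist as separate rows and are never collapsed.

The store is an embedded SQLite database. DDL is emitted as a single SQL text
(:func:`emit_ddl`); typed access goes through :class:`VariantStore`, whose
``insert_fact`` enforces closed vocabularies, value ranges and mandatory
lineage, and merges duplicate logical keys instead of raising.
"""

from __future__ import annotations

import json
import re
import sqlite3
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = [
    "CHROMOSOMES",
    "VARIANT_TYPES",
    "GENE_VARIANT_CONSEQUENCES",
    "TRANSCRIPT_CONSEQUENCES",
    "TRANSCRIPT_ABERRATIONS",
    "BIOMARKER_CLASSES",
    "SOMATIC_CLASSIFICATIONS",
    "DRUG_EFFECTS",
    "MACRO_LEVELS",
    "SUBLEVELS",
    "ID_PREFIXES",
    "INTERNAL_ID_RE",
    "Lineage",
    "ValidationError",
    "VocabularyError",
    "UnknownKindError",
    "IntegrityReport",
    "VariantStore",
    "emit_ddl",
]

# ---------------------------------------------------------------------------
# Closed vocabularies (exact value sets of the core model)
# ---------------------------------------------------------------------------

CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

VARIANT_TYPES = ("SNV", "MNV", "INS", "DEL")

GENE_VARIANT_CONSEQUENCES = (
    "non-sense", "missense", "silent", "frame shift", "in-frame",
    "3UTR", "5UTR", "splice", "splice-region", "intronic",
    "upstream", "downstream",
)

TRANSCRIPT_CONSEQUENCES = (
    "expression", "amplification", "deletion", "fusion",
    "loss of function", "missense",
)
# transcript-level aberrations without a known genomic cause: these are the
# only consequences for which a gene_variant_transcript row may lack a variant
TRANSCRIPT_ABERRATIONS = (
    "expression", "amplification", "deletion", "fusion", "loss of function",
)

BIOMARKER_CLASSES = (
    "diagnostic", "prognostic", "predictive", "predisposing", "pharmacogenomic",
)

SOMATIC_CLASSIFICATIONS = ("confirmed somatic", "confirmed germline", "unknown")

DRUG_EFFECTS = (
    "resistant", "responsive", "non-responsive", "sensitive",
    "reduced sensitivity", "other",
)

PRIMARY_RELAPSE = ("primary", "relapse")

MACRO_LEVELS = ("A", "B", "C", "D", "E")
SUBLEVELS = ("1A", "1B", "1C", "2A", "2B", "2C", "3A", "3B", "4A", "4B")
MACRO_OF_SUBLEVEL = {
    "1A": "A", "1B": "A", "1C": "A",
    "2A": "B", "2B": "B", "2C": "B",
    "3A": "C", "3B": "D",
    "4A": "E", "4B": "E",
}

# ---------------------------------------------------------------------------
# Internal identifiers
# ---------------------------------------------------------------------------

#: kind prefix registry; ids are prefix + base-36 counter, 8 characters total
ID_PREFIXES = {
    "gene": "G",
    "transcript": "T",
    "variant": "V",
    "cancer_type": "C",
    "cancer_variant": "CV",
    "sample": "S",
    "drug": "D",
    "pathway": "P",
    "fact": "F",  # row-level uid used to bind lineage to non-entity facts
}

INTERNAL_ID_RE = re.compile(r"^[A-Z]{1,2}[A-Z0-9]{6,7}$")

_B36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _base36(n: int) -> str:
    if n == 0:
        return "0"
    digits = []
    while n:
        n, r = divmod(n, 36)
        digits.append(_B36[r])
    return "".join(reversed(digits))


class ValidationError(ValueError):
    """A record violates a mandatory-field, range or reference constraint."""


class VocabularyError(ValidationError):
    """A value falls outside a closed vocabulary; names the vocabulary."""


class UnknownKindError(KeyError):
    """An entity kind has no registered id prefix."""


@dataclass(frozen=True)
class Lineage:
    """Provenance of one stored fact: where it came from, exactly.

    ``pmids`` is an optional tuple of PubMed ids supporting the assertion.
    """

    source_name: str
    release_version: str
    source_record_id: str
    pmids: tuple[str, ...] = ()

    def key(self) -> tuple[str, str, str]:
        return (self.source_name, self.release_version, self.source_record_id)


# ---------------------------------------------------------------------------
# Table metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Column:
    name: str
    sql_type: str = "TEXT"
    mandatory: bool = False
    vocab: tuple[str, ...] | None = None
    vocab_name: str | None = None
    ratio01: bool = False
    references: str | None = None  # "table.column"
    nocase_unique: bool = False


@dataclass(frozen=True)
class Table:
    name: str
    columns: tuple[Column, ...]
    id_column: str | None = None  # column minted as an internal id
    id_kind: str | None = None
    logical_key: tuple[str, ...] = ()  # identity of a row for merge purposes
    multi_valued: bool = False  # conflicting value tuples coexist as rows
    check_sql: tuple[str, ...] = ()

    def column(self, name: str) -> Column:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def value_columns(self) -> tuple[str, ...]:
        skip = set(self.logical_key) | {self.id_column, "fact_uid"}
        return tuple(c.name for c in self.columns if c.name not in skip)


def _vc(name: str, vocab: tuple[str, ...], vocab_name: str, mandatory: bool = True) -> Column:
    return Column(name, mandatory=mandatory, vocab=vocab, vocab_name=vocab_name)


TABLES: dict[str, Table] = {}


def _register(table: Table) -> None:
    TABLES[table.name] = table


_register(Table(
    "gene",
    (
        Column("gene_id", mandatory=True),
        Column("gene_name", mandatory=True, nocase_unique=True),
        _vc("chromosome", CHROMOSOMES, "chromosome", mandatory=False),
        Column("entrez_gene_id"),
        Column("ensembl_gene_id"),
        Column("refseq_gene_id"),
    ),
    id_column="gene_id", id_kind="gene",
    logical_key=("gene_name",),
    check_sql=(
        "CHECK (entrez_gene_id IS NOT NULL OR ensembl_gene_id IS NOT NULL "
        "OR refseq_gene_id IS NOT NULL)",
    ),
))

_register(Table(
    "gene_transcript",
    (
        Column("transcript_id", mandatory=True),
        Column("gene_id", mandatory=True, references="gene.gene_id"),
        Column("ensembl_transcript_id", mandatory=True),
        Column("refseq_transcript_id"),
        Column("refseq_protein_id"),
        Column("uniprot_id"),
    ),
    id_column="transcript_id", id_kind="transcript",
    logical_key=("ensembl_transcript_id",),
))

_register(Table(
    "gene_position",
    (
        Column("gene_id", mandatory=True, references="gene.gene_id"),
        Column("genome_version", mandatory=True),
        Column("dna_position", mandatory=True),
    ),
    logical_key=("gene_id", "genome_version"),
))

_register(Table(
    "pathway",
    (
        Column("pathway_id", mandatory=True),
        Column("common_name", mandatory=True),
        Column("kegg_id"),
        Column("reactome_id"),
        Column("pathwaycommons_id"),
    ),
    id_column="pathway_id", id_kind="pathway",
    logical_key=("common_name",),
))

_register(Table(
    "gene_pathway",
    (
        Column("gene_id", mandatory=True, references="gene.gene_id"),
        Column("pathway_id", mandatory=True, references="pathway.pathway_id"),
    ),
    logical_key=("gene_id", "pathway_id"),
))

_register(Table(
    "variant",
    (
        Column("variant_id", mandatory=True),
        _vc("variant_type", VARIANT_TYPES, "variant type"),
    ),
    id_column="variant_id", id_kind="variant",
    logical_key=("variant_id",),
))

_register(Table(
    "variant_position",
    (
        Column("variant_id", mandatory=True, references="variant.variant_id"),
        Column("genome_version", mandatory=True),
        Column("dna_sub_and_position", mandatory=True),
    ),
    logical_key=("variant_id", "genome_version"),
))

_register(Table(
    "gene_variant",
    (
        Column("gene_id", mandatory=True, references="gene.gene_id"),
        Column("variant_id", mandatory=True, references="variant.variant_id"),
        _vc("variant_consequence", GENE_VARIANT_CONSEQUENCES, "variant consequence"),
    ),
    logical_key=("gene_id", "variant_id"),
))

_register(Table(
    "gene_variant_transcript",
    (
        Column("gene_id", mandatory=True, references="gene.gene_id"),
        Column("variant_id", references="variant.variant_id"),
        Column("transcript_id", mandatory=True,
               references="gene_transcript.transcript_id"),
        Column("protein_sub_and_position"),
        Column("protein_domain"),
        _vc("variant_consequence", TRANSCRIPT_CONSEQUENCES,
            "transcript variant consequence"),
    ),
    logical_key=("gene_id", "transcript_id", "variant_id"),
))

_register(Table(
    "cancer_type",
    (
        Column("cancer_type_id", mandatory=True),
        Column("cancer_type_name", mandatory=True, nocase_unique=True),
        Column("umls_id"),
        Column("hpo_id"),
    ),
    id_column="cancer_type_id", id_kind="cancer_type",
    logical_key=("cancer_type_name",),
))

_register(Table(
    "cancer_type_synonym",
    (
        Column("cancer_type_id", mandatory=True,
               references="cancer_type.cancer_type_id"),
        Column("surface_form", mandatory=True, nocase_unique=True),
        Column("terminology"),
    ),
    logical_key=("surface_form",),
))

_register(Table(
    "cancer_variant",
    (
        Column("cancer_variant_id", mandatory=True),
        Column("variant_id", mandatory=True, references="variant.variant_id"),
        Column("cancer_type_id", mandatory=True,
               references="cancer_type.cancer_type_id"),
        _vc("biomarker_class", BIOMARKER_CLASSES, "biomarker class"),
    ),
    id_column="cancer_variant_id", id_kind="cancer_variant",
    logical_key=("variant_id", "cancer_type_id"),
))

_register(Table(
    "sample_specimen",
    (
        Column("sample_id", mandatory=True),
        Column("tumor_purity", sql_type="REAL", ratio01=True),
        Column("tnm_status"),
        _vc("primary_or_relapse", PRIMARY_RELAPSE, "primary/relapse", mandatory=False),
    ),
    id_column="sample_id", id_kind="sample",
    logical_key=("sample_id",),
))

_register(Table(
    "cancer_variant_sample",
    (
        Column("cancer_variant_id", mandatory=True,
               references="cancer_variant.cancer_variant_id"),
        Column("sample_id", mandatory=True,
               references="sample_specimen.sample_id"),
        _vc("somatic_classification", SOMATIC_CLASSIFICATIONS,
            "somatic classification"),
        Column("allele_frequency", sql_type="REAL", ratio01=True),
    ),
    logical_key=("cancer_variant_id", "sample_id"),
))

_register(Table(
    "drug",
    (
        Column("drug_id", mandatory=True),
        Column("substance_name", mandatory=True, nocase_unique=True),
        Column("drugbank_id"),
        Column("pharmgkb_id"),
        Column("fda_id"),
    ),
    id_column="drug_id", id_kind="drug",
    logical_key=("substance_name",),
))

_register(Table(
    "drug_mechanism",
    (
        Column("drug_id", mandatory=True, references="drug.drug_id"),
        Column("mechanism", mandatory=True),
    ),
    logical_key=("drug_id", "mechanism"),
))

_register(Table(
    "cancer_variant_drug",
    (
        Column("cancer_variant_id", mandatory=True,
               references="cancer_variant.cancer_variant_id"),
        Column("drug_id", mandatory=True, references="drug.drug_id"),
    ),
    logical_key=("cancer_variant_id", "drug_id"),
))

_register(Table(
    "cancer_variant_drug_effect",
    (
        Column("cancer_variant_id", mandatory=True,
               references="cancer_variant.cancer_variant_id"),
        Column("drug_id", mandatory=True, references="drug.drug_id"),
        _vc("effect", DRUG_EFFECTS, "drug effect"),
        _vc("evidence_level", MACRO_LEVELS, "evidence macro level"),
        _vc("evidence_sublevel", SUBLEVELS, "evidence sublevel", mandatory=False),
        Column("source_scheme"),
        Column("source_level_code"),
    ),
    logical_key=("cancer_variant_id", "drug_id"),
    multi_valued=True,
))

_register(Table(
    "risk_score",
    (
        Column("gene_id", mandatory=True, references="gene.gene_id"),
        Column("transcript_id", mandatory=True,
               references="gene_transcript.transcript_id"),
        Column("variant_id", references="variant.variant_id"),
        Column("algorithm", mandatory=True),
        Column("score", sql_type="REAL", mandatory=True),
    ),
    logical_key=("gene_id", "transcript_id", "variant_id", "algorithm"),
    multi_valued=True,
))

_register(Table(
    "identifier_xref",
    (
        Column("entity_kind", mandatory=True),
        Column("namespace", mandatory=True),
        Column("external_id", mandatory=True),
        Column("internal_id", mandatory=True),
    ),
    logical_key=("entity_kind", "namespace", "external_id"),
))

#: tables whose rows require a lineage link (all core fact tables)
FACT_TABLES = tuple(TABLES)


# ---------------------------------------------------------------------------
# DDL emission
# ---------------------------------------------------------------------------

_META_DDL = """\
CREATE TABLE id_counter (
    kind TEXT PRIMARY KEY,
    next_value INTEGER NOT NULL DEFAULT 1
);
CREATE TABLE lineage (
    fact_table TEXT NOT NULL,
    fact_uid TEXT NOT NULL,
    source_name TEXT NOT NULL,
    release_version TEXT NOT NULL,
    source_record_id TEXT NOT NULL,
    pmids TEXT,
    UNIQUE (fact_table, fact_uid, source_name, release_version, source_record_id)
);
CREATE INDEX idx_lineage_fact ON lineage (fact_table, fact_uid);
"""


def _table_ddl(t: Table) -> str:
    lines: list[str] = []
    for c in t.columns:
        parts = [c.name, c.sql_type]
        if c.mandatory:
            parts.append("NOT NULL")
        if c.vocab is not None:
            quoted = ", ".join(f"'{v}'" for v in c.vocab)
            parts.append(f"CHECK ({c.name} IS NULL OR {c.name} IN ({quoted}))")
        if c.ratio01:
            parts.append(f"CHECK ({c.name} IS NULL OR "
                         f"({c.name} >= 0.0 AND {c.name} <= 1.0))")
        if c.nocase_unique:
            parts.append("COLLATE NOCASE UNIQUE")
        lines.append("    " + " ".join(parts))
    lines.append("    fact_uid TEXT NOT NULL UNIQUE")
    if t.id_column:
        lines.append(f"    , PRIMARY KEY ({t.id_column})")
    elif t.logical_key and not t.multi_valued:
        cols = ", ".join(t.logical_key)
        lines.append(f"    , UNIQUE ({cols})")
    for c in t.columns:
        if c.references:
            rt, rc = c.references.split(".")
            lines.append(f"    , FOREIGN KEY ({c.name}) REFERENCES {rt} ({rc})")
    for chk in t.check_sql:
        lines.append("    , " + chk)
    # column definitions need separating commas; constraint lines carry their own
    joined: list[str] = []
    for line in lines:
        if joined and not line.lstrip().startswith(","):
            joined[-1] += ","
        joined.append(line)
    return f"CREATE TABLE {t.name} (\n" + "\n".join(joined) + "\n);"


def emit_ddl() -> str:
    """Emit the complete schema as a single UTF-8 SQL text.

    The text creates one table per domain class plus the lineage and
    id-counter bookkeeping tables. Executing it twice on the same store
    raises unless ``VariantStore.initialize(if_exists="ignore")`` is used.
    """
    parts = ["-- oncovis core data model", "PRAGMA foreign_keys = ON;", _META_DDL]
    parts.extend(_table_ddl(t) for t in TABLES.values())
    return "\n\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# Integrity reporting
# ---------------------------------------------------------------------------


@dataclass
class IntegrityReport:
    """Findings of a store-wide consistency sweep; empty means consistent."""

    dangling_references: list[dict] = field(default_factory=list)
    missing_lineage: list[dict] = field(default_factory=list)
    duplicate_cancer_variants: list[dict] = field(default_factory=list)
    vocabulary_violations: list[dict] = field(default_factory=list)

    @property
    def findings(self) -> list[dict]:
        return (self.dangling_references + self.missing_lineage
                + self.duplicate_cancer_variants + self.vocabulary_violations)

    @property
    def is_empty(self) -> bool:
        return not self.findings

    def to_json(self) -> str:
        return json.dumps({
            "dangling_references": self.dangling_references,
            "missing_lineage": self.missing_lineage,
            "duplicate_cancer_variants": self.duplicate_cancer_variants,
            "vocabulary_violations": self.vocabulary_violations,
        }, indent=2)


# ---------------------------------------------------------------------------
# Store
# ---------------------------------------------------------------------------


class MergeOutcome:
    INSERTED_NEW = "inserted-new"
    ATTACHED_CONFLICT = "attached-conflict"
    DEDUPLICATED = "deduplicated"


class VariantStore:
    """Embedded relational store with typed, lineage-mandatory access.

    ``path`` may be ``":memory:"`` for an ephemeral store. Call
    :meth:`initialize` once to create the schema.
    """

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self.conn = sqlite3.connect(path)
        self.conn.row_factory = sqlite3.Row
        self.conn.execute("PRAGMA foreign_keys = ON")

    # -- lifecycle ---------------------------------------------------------

    def initialize(self, if_exists: str = "error") -> None:
        """Execute the DDL. ``if_exists``: 'error' (default) or 'ignore'."""
        have = self._existing_tables()
        if "gene" in have:
            if if_exists == "ignore":
                return
            raise RuntimeError("store already initialized")
        self.conn.executescript(emit_ddl())
        self.conn.commit()

    def _existing_tables(self) -> set[str]:
        rows = self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type = 'table'").fetchall()
        return {r["name"] for r in rows}

    def close(self) -> None:
        self.conn.close()

    # -- id minting --------------------------------------------------------

    def mint_id(self, entity_kind: str) -> str:
        """Mint the next internal id for a kind: prefix + padded base-36 counter.

        Deterministic per store: a fresh store always yields the same id
        sequence for the same insertion order.
        """
        try:
            prefix = ID_PREFIXES[entity_kind]
        except KeyError:
            raise UnknownKindError(
                f"unknown entity kind {entity_kind!r}; known: "
                f"{sorted(ID_PREFIXES)}") from None
        cur = self.conn.execute(
            "SELECT next_value FROM id_counter WHERE kind = ?", (entity_kind,))
        row = cur.fetchone()
        n = row["next_value"] if row else 1
        self.conn.execute(
            "INSERT INTO id_counter (kind, next_value) VALUES (?, ?) "
            "ON CONFLICT (kind) DO UPDATE SET next_value = ?",
            (entity_kind, n + 1, n + 1))
        body = _base36(n).rjust(8 - len(prefix), "0")
        ident = prefix + body
        if not INTERNAL_ID_RE.match(ident) or len(ident) != 8:
            raise ValidationError(f"minted id {ident!r} violates the id format")
        return ident

    # -- validation --------------------------------------------------------

    def _validate(self, table: Table, record: Mapping[str, Any]) -> dict[str, Any]:
        unknown = set(record) - {c.name for c in table.columns}
        if unknown:
            raise ValidationError(
                f"{table.name}: unknown fields {sorted(unknown)}")
        clean: dict[str, Any] = {}
        missing: list[str] = []
        for c in table.columns:
            v = record.get(c.name)
            if v == "":
                v = None
            if v is None:
                if c.mandatory and c.name != table.id_column:
                    missing.append(c.name)
                clean[c.name] = None
                continue
            if c.vocab is not None and v not in c.vocab:
                raise VocabularyError(
                    f"{table.name}.{c.name}: {v!r} not in closed vocabulary "
                    f"'{c.vocab_name}' {list(c.vocab)}")
            if c.ratio01:
                v = float(v)
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(
                        f"{table.name}.{c.name}: {v} outside [0, 1]")
            if c.sql_type == "REAL":
                v = float(v)
            clean[c.name] = v
        if missing:
            raise ValidationError(
                f"{table.name}: missing mandatory core fields {missing}")
        if table.name == "gene" and not any(
                clean.get(k) for k in
                ("entrez_gene_id", "ensembl_gene_id", "refseq_gene_id")):
            raise ValidationError(
                "gene: at least one external accession "
                "(entrez/ensembl/refseq) is required")
        if (table.name == "gene_variant_transcript"
                and clean.get("variant_id") is None
                and clean.get("variant_consequence") not in TRANSCRIPT_ABERRATIONS):
            raise ValidationError(
                "gene_variant_transcript: variant_id may be omitted only for "
                f"transcript-level aberrations {list(TRANSCRIPT_ABERRATIONS)}")
        return clean

    # -- insertion / merge -------------------------------------------------

    def insert_fact(self, table_name: str, record: Mapping[str, Any],
                    lineage: Lineage) -> str:
        """Validate and store one fact with its lineage; returns its id.

        Duplicate logical keys merge onto the existing row (missing fields are
        filled, present fields are never overwritten); for multi-valued tables
        a differing value tuple coexists as a new row. Raises
        :class:`ValidationError` / :class:`VocabularyError` on bad records and
        on a missing lineage.
        """
        ident, _ = self.merge_fact(table_name, record, lineage)
        return ident

    def merge_fact(self, table_name: str, record: Mapping[str, Any],
                   lineage: Lineage) -> tuple[str, str]:
        """As :meth:`insert_fact` but also reports the merge outcome.

        Returns ``(id, outcome)`` with outcome one of ``inserted-new``,
        ``attached-conflict``, ``deduplicated``.
        """
        if table_name not in TABLES:
            raise ValidationError(f"unknown fact table {table_name!r}")
        if lineage is None:
            raise ValidationError(f"{table_name}: lineage is mandatory")
        table = TABLES[table_name]
        clean = self._validate(table, record)

        existing = self._find_logical(table, clean)
        if existing is None:
            return self._insert_row(table, clean, lineage), MergeOutcome.INSERTED_NEW

        if table.multi_valued:
            match = self._find_value_match(table, clean)
            if match is not None:
                self._attach_lineage(table.name, match["fact_uid"], lineage)
                return match["fact_uid"], MergeOutcome.DEDUPLICATED
            return (self._insert_row(table, clean, lineage),
                    MergeOutcome.ATTACHED_CONFLICT)

        # single-valued: merge onto the existing row, fill missing fields only
        uid = existing["fact_uid"]
        updates = {}
        for name in table.value_columns:
            new = clean.get(name)
            if new is not None and existing[name] is None:
                updates[name] = new
        if updates:
            sets = ", ".join(f"{k} = ?" for k in updates)
            self.conn.execute(
                f"UPDATE {table.name} SET {sets} WHERE fact_uid = ?",
                (*updates.values(), uid))
        self._attach_lineage(table.name, uid, lineage)
        ident = existing[table.id_column] if table.id_column else uid
        return ident, MergeOutcome.DEDUPLICATED

    def _find_logical(self, table: Table, clean: Mapping[str, Any]):
        if not table.logical_key:
            return None
        conds, args = [], []
        for k in table.logical_key:
            v = clean.get(k)
            if v is None:
                conds.append(f"{k} IS NULL")
            else:
                col = table.column(k)
                op = f"{k} = ? COLLATE NOCASE" if col.nocase_unique else f"{k} = ?"
                conds.append(op)
                args.append(v)
        sql = f"SELECT * FROM {table.name} WHERE " + " AND ".join(conds)
        return self.conn.execute(sql, args).fetchone()

    def _find_value_match(self, table: Table, clean: Mapping[str, Any]):
        conds, args = [], []
        for c in table.columns:
            v = clean.get(c.name)
            if v is None:
                conds.append(f"{c.name} IS NULL")
            else:
                conds.append(f"{c.name} = ?")
                args.append(v)
        sql = f"SELECT * FROM {table.name} WHERE " + " AND ".join(conds)
        return self.conn.execute(sql, args).fetchone()

    def _insert_row(self, table: Table, clean: dict[str, Any],
                    lineage: Lineage) -> str:
        if table.id_column and clean.get(table.id_column) is None:
            clean[table.id_column] = self.mint_id(table.id_kind)
        uid = self.mint_id("fact")
        cols = list(clean) + ["fact_uid"]
        vals = list(clean.values()) + [uid]
        ph = ", ".join("?" for _ in cols)
        try:
            self.conn.execute(
                f"INSERT INTO {table.name} ({', '.join(cols)}) VALUES ({ph})",
                vals)
        except sqlite3.IntegrityError as exc:
            raise ValidationError(f"{table.name}: {exc}") from exc
        self._attach_lineage(table.name, uid, lineage)
        return clean[table.id_column] if table.id_column else uid

    def _attach_lineage(self, table_name: str, fact_uid: str,
                        lineage: Lineage) -> None:
        self.conn.execute(
            "INSERT OR IGNORE INTO lineage (fact_table, fact_uid, source_name,"
            " release_version, source_record_id, pmids) VALUES (?, ?, ?, ?, ?, ?)",
            (table_name, fact_uid, lineage.source_name, lineage.release_version,
             lineage.source_record_id,
             ",".join(lineage.pmids) if lineage.pmids else None))

    # -- querying ----------------------------------------------------------

    def fetch(self, table_name: str, **where: Any) -> list[sqlite3.Row]:
        table = TABLES[table_name]
        conds, args = [], []
        for k, v in where.items():
            table.column(k)  # validates the column name
            if v is None:
                conds.append(f"{k} IS NULL")
            else:
                conds.append(f"{k} = ?")
                args.append(v)
        sql = f"SELECT * FROM {table_name}"
        if conds:
            sql += " WHERE " + " AND ".join(conds)
        return self.conn.execute(sql, args).fetchall()

    def fetch_one(self, table_name: str, **where: Any) -> sqlite3.Row | None:
        rows = self.fetch(table_name, **where)
        return rows[0] if rows else None

    def lineage_of(self, table_name: str, fact_uid: str) -> list[dict]:
        rows = self.conn.execute(
            "SELECT * FROM lineage WHERE fact_table = ? AND fact_uid = ?",
            (table_name, fact_uid)).fetchall()
        return [dict(r) for r in rows]

    # -- integrity ---------------------------------------------------------

    def validate_integrity(self) -> IntegrityReport:
        """Sweep the whole store for dangling references, lineage-less facts,
        duplicate (variant, cancer type) pairs and vocabulary violations."""
        report = IntegrityReport()
        for row in self.conn.execute("PRAGMA foreign_key_check"):
            report.dangling_references.append({
                "table": row[0], "rowid": row[1], "references": row[2]})
        for table in TABLES.values():
            for c in table.columns:
                if not c.references:
                    continue
                rt, rc = c.references.split(".")
                sql = (f"SELECT t.fact_uid FROM {table.name} t "
                       f"LEFT JOIN {rt} r ON t.{c.name} = r.{rc} "
                       f"WHERE t.{c.name} IS NOT NULL AND r.{rc} IS NULL")
                for row in self.conn.execute(sql):
                    entry = {"table": table.name, "column": c.name,
                             "fact_uid": row["fact_uid"], "references": rt}
                    if entry not in report.dangling_references:
                        report.dangling_references.append(entry)
            sql = (f"SELECT t.fact_uid FROM {table.name} t LEFT JOIN lineage l "
                   f"ON l.fact_table = '{table.name}' AND l.fact_uid = t.fact_uid "
                   f"WHERE l.fact_uid IS NULL")
            for row in self.conn.execute(sql):
                report.missing_lineage.append(
                    {"table": table.name, "fact_uid": row["fact_uid"]})
            for c in table.columns:
                if c.vocab is None:
                    continue
                quoted = ", ".join(f"'{v}'" for v in c.vocab)
                sql = (f"SELECT fact_uid, {c.name} AS value FROM {table.name} "
                       f"WHERE {c.name} IS NOT NULL AND {c.name} NOT IN ({quoted})")
                for row in self.conn.execute(sql):
                    report.vocabulary_violations.append(
                        {"table": table.name, "column": c.name,
                         "fact_uid": row["fact_uid"], "value": row["value"]})
        sql = ("SELECT variant_id, cancer_type_id, COUNT(*) AS n "
               "FROM cancer_variant GROUP BY variant_id, cancer_type_id "
               "HAVING n > 1")
        for row in self.conn.execute(sql):
            report.duplicate_cancer_variants.append(
                {"variant_id": row["variant_id"],
                 "cancer_type_id": row["cancer_type_id"], "count": row["n"]})
        return report

    def lineage_less_fact_count(self) -> int:
        return len(self.validate_integrity().missing_lineage)
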