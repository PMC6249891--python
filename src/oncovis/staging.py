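"""Technical integration: versioned staging of source-database exports.

Sources publish their data as delimited flat files (CSV/TSV, often gzipped)
whose layout drifts from release to release. The staging layer isolates this
volatility from the semantic core: each release of each source is loaded
*verbatim* — every value as text, no transformation — into name-prefixed
staging tables (``stg_<source>_<file>``) that mirror the source's own column
layout. Value typing, recoding and identity resolution happen later, in the
mapping layer; staging stays byte-faithful so any past release can be
re-exported and a clinical decision reproduced against the exact reference
state it was taken on.

Before ingesting, the structure of every file is fingerprinted (ordered
column names plus coarse value kinds) and compared against the currently
active release. A structural difference halts the ingest unless an explicit
override is given — unnoticed restructuring is a classic source of silent
integration conflicts, so a human must acknowledge drift. Release activation
is an atomic swap: readers observe either the wholly-old or the wholly-new
release, never a mixture, and retired releases remain queryable.
"""

from __future__ import annotations

import csv
import gzip
import io
import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .schema import ValidationError, VariantStore

__all__ = [
    "Dialect",
    "SourceDescriptor",
    "StructureFingerprint",
    "StructureDiff",
    "SourceRelease",
    "StructureDriftError",
    "register_source",
    "fingerprint_structure",
    "fingerprint_file",
    "diff_structure",
    "ingest_release",
    "swap_active_release",
    "list_releases",
    "active_release",
    "staged_rows",
    "export_staged_file",
]


@dataclass(frozen=True)
class Dialect:
    """Flat-file conventions of one source."""

    delimiter: str = "\t"
    quoting: int = csv.QUOTE_MINIMAL
    compression: str | None = None  # None | "gzip"
    encoding: str = "utf-8"


@dataclass(frozen=True)
class SourceDescriptor:
    source_name: str
    dialect: Dialect
    expected_files: tuple[str, ...]
    declared_schema: Mapping[str, tuple[str, ...]]  # logical file -> columns


@dataclass(frozen=True)
class StructureFingerprint:
    """Ordered column names plus coarse per-column value kinds.

    Deterministic for a file's structure: independent of row order and of row
    count, and identical for gzip and plain spellings of the same content.
    """

    columns: tuple[str, ...]
    kinds: tuple[str, ...]  # per column: "number" | "text" | "empty"


@dataclass
class StructureDiff:
    added: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)
    renamed_candidates: list[tuple[str, str]] = field(default_factory=list)
    reordered: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not (self.added or self.removed or self.renamed_candidates
                    or self.reordered)

    def to_dict(self) -> dict:
        return {"added": self.added, "removed": self.removed,
                "renamed_candidates": [list(p) for p in self.renamed_candidates],
                "reordered": self.reordered}


@dataclass
class SourceRelease:
    source_name: str
    release_version: str
    ingested_at: str
    status: str  # staged | active | retired
    row_counts: dict[str, int]
    fingerprints: dict[str, StructureFingerprint]


class StructureDriftError(RuntimeError):
    """Structure differs from the active release; carries the per-file diffs."""

    def __init__(self, source: str, diffs: Mapping[str, StructureDiff]):
        self.diffs = dict(diffs)
        detail = {f: d.to_dict() for f, d in diffs.items()}
        super().__init__(
            f"structural drift for source {source!r}; re-run with the "
            f"structure-change override to accept: {json.dumps(detail)}")


_NAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")
_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _catalog_ddl(store: VariantStore) -> None:
    store.conn.executescript("""
        CREATE TABLE IF NOT EXISTS staging_source (
            source_name TEXT PRIMARY KEY,
            descriptor TEXT NOT NULL
        );
        CREATE TABLE IF NOT EXISTS staging_release (
            source_name TEXT NOT NULL REFERENCES staging_source (source_name),
            release_version TEXT NOT NULL,
            ingested_at TEXT NOT NULL,
            status TEXT NOT NULL CHECK (status IN ('staged','active','retired')),
            row_counts TEXT NOT NULL,
            fingerprints TEXT NOT NULL,
            PRIMARY KEY (source_name, release_version)
        );
    """)


def _stg_table(source: str, logical_file: str) -> str:
    return f"stg_{source}_{logical_file}"


# ---------------------------------------------------------------------------
# Source registration
# ---------------------------------------------------------------------------


def register_source(store: VariantStore, desc: SourceDescriptor) -> str:
    """Persist a source descriptor and reserve its staging namespace."""
    if not _NAME_RE.match(desc.source_name):
        raise ValidationError(
            f"source name {desc.source_name!r} must be an identifier")
    for f in desc.expected_files:
        cols = desc.declared_schema.get(f)
        if not cols:
            raise ValidationError(
                f"source {desc.source_name!r}: empty declared schema for "
                f"file {f!r}")
    _catalog_ddl(store)
    if store.conn.execute(
            "SELECT 1 FROM staging_source WHERE source_name = ?",
            (desc.source_name,)).fetchone():
        raise ValidationError(
            f"source {desc.source_name!r} is already registered")
    doc = json.dumps({
        "dialect": {"delimiter": desc.dialect.delimiter,
                    "quoting": desc.dialect.quoting,
                    "compression": desc.dialect.compression,
                    "encoding": desc.dialect.encoding},
        "expected_files": list(desc.expected_files),
        "declared_schema": {k: list(v) for k, v in desc.declared_schema.items()},
    })
    store.conn.execute(
        "INSERT INTO staging_source (source_name, descriptor) VALUES (?, ?)",
        (desc.source_name, doc))
    store.conn.commit()
    return desc.source_name


def get_source(store: VariantStore, source_name: str) -> SourceDescriptor:
    _catalog_ddl(store)
    row = store.conn.execute(
        "SELECT descriptor FROM staging_source WHERE source_name = ?",
        (source_name,)).fetchone()
    if row is None:
        raise KeyError(f"source {source_name!r} is not registered")
    doc = json.loads(row["descriptor"])
    return SourceDescriptor(
        source_name,
        Dialect(**doc["dialect"]),
        tuple(doc["expected_files"]),
        {k: tuple(v) for k, v in doc["declared_schema"].items()})


def list_sources(store: VariantStore) -> list[str]:
    _catalog_ddl(store)
    return [r["source_name"] for r in store.conn.execute(
        "SELECT source_name FROM staging_source ORDER BY source_name")]


# ---------------------------------------------------------------------------
# Fingerprinting
# ---------------------------------------------------------------------------


def _open_text(path: Path, dialect: Dialect):
    gz = dialect.compression == "gzip" or str(path).endswith(".gz")
    if gz:
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding=dialect.encoding)
    return open(path, "r", encoding=dialect.encoding)


def _read_table(path: Path, dialect: Dialect) -> tuple[list[str], list[list[str]]]:
    with _open_text(path, dialect) as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter,
                            quoting=dialect.quoting)
        rows = list(reader)
    if not rows:
        raise ValidationError(f"{path}: empty file (header row is mandatory)")
    header, body = rows[0], rows[1:]
    if not any(h.strip() for h in header):
        raise ValidationError(f"{path}: blank header row")
    return header, body


def _column_kind(values: Iterable[str]) -> str:
    saw_number = saw_text = False
    for v in values:
        v = v.strip()
        if not v:
            continue
        if _NUMBER_RE.match(v):
            saw_number = True
        else:
            saw_text = True
    if saw_text:
        return "text"
    if saw_number:
        return "number"
    return "empty"


def fingerprint_structure(header: Sequence[str],
                          rows: Iterable[Sequence[str]]) -> StructureFingerprint:
    """Fingerprint an in-memory table: column order + coarse value kinds."""
    cols = tuple(h.strip() for h in header)
    values: list[list[str]] = [[] for _ in cols]
    for row in rows:
        for i in range(len(cols)):
            values[i].append(row[i] if i < len(row) else "")
    return StructureFingerprint(cols, tuple(_column_kind(v) for v in values))


def fingerprint_file(path: str | Path,
                     dialect: Dialect | None = None) -> StructureFingerprint:
    """Fingerprint a delimited file (gzip transparent, row-order invariant)."""
    p = Path(path)
    d = dialect or Dialect()
    header, body = _read_table(p, d)
    return fingerprint_structure(header, body)


def diff_structure(old: StructureFingerprint,
                   new: StructureFingerprint) -> StructureDiff:
    """Structural change report between two fingerprints of one logical file.

    A column that disappears while a new name appears at the same position is
    reported once, as a renamed-candidate. The report is empty iff the
    ordered column lists are identical.
    """
    diff = StructureDiff()
    old_set, new_set = set(old.columns), set(new.columns)
    removed = [c for c in old.columns if c not in new_set]
    added = [c for c in new.columns if c not in old_set]
    for name in list(removed):
        pos = old.columns.index(name)
        if pos < len(new.columns) and new.columns[pos] in added:
            diff.renamed_candidates.append((name, new.columns[pos]))
            removed.remove(name)
            added.remove(new.columns[pos])
    diff.added = added
    diff.removed = removed
    shared = [c for c in old.columns if c in new_set]
    shared_new_order = [c for c in new.columns if c in old_set]
    if shared != shared_new_order:
        diff.reordered = [c for c, cn in zip(shared, shared_new_order) if c != cn]
    return diff


# ---------------------------------------------------------------------------
# Ingest
# ---------------------------------------------------------------------------


def _release_row(store: VariantStore, source: str, version: str):
    return store.conn.execute(
        "SELECT * FROM staging_release WHERE source_name = ? AND "
        "release_version = ?", (source, version)).fetchone()


def _to_release(row) -> SourceRelease:
    fps = {
        f: StructureFingerprint(tuple(v["columns"]), tuple(v["kinds"]))
        for f, v in json.loads(row["fingerprints"]).items()
    }
    return SourceRelease(row["source_name"], row["release_version"],
                         row["ingested_at"], row["status"],
                         json.loads(row["row_counts"]), fps)


def ingest_release(store: VariantStore, source_name: str,
                   files: Mapping[str, str | Path], version: str,
                   accept_structure_change: bool = False) -> SourceRelease:
    """Load one versioned file set verbatim into the source's staging tables.

    ``files`` maps logical file names to paths. The ingest refuses (a) a
    version already ingested, (b) an incomplete file set, (c) a header that
    contradicts the declared schema, and (d) — unless
    ``accept_structure_change`` — any structural drift from the currently
    active release, reporting the diff.
    """
    desc = get_source(store, source_name)
    if _release_row(store, source_name, version):
        raise ValidationError(
            f"release {version!r} of {source_name!r} was already ingested")
    missing = [f for f in desc.expected_files if f not in files]
    if missing:
        raise ValidationError(
            f"release {version!r} of {source_name!r}: missing files {missing}")

    tables: dict[str, tuple[list[str], list[list[str]]]] = {}
    fingerprints: dict[str, StructureFingerprint] = {}
    for logical in desc.expected_files:
        header, body = _read_table(Path(files[logical]), desc.dialect)
        header = [h.strip() for h in header]
        declared = list(desc.declared_schema[logical])
        fp = fingerprint_structure(header, body)
        fingerprints[logical] = fp
        if header != declared and not accept_structure_change:
            drift = diff_structure(
                StructureFingerprint(tuple(declared), ("text",) * len(declared)),
                fp)
            raise StructureDriftError(source_name, {logical: drift})
        tables[logical] = (header, body)

    active = active_release(store, source_name)
    if active is not None and not accept_structure_change:
        diffs = {}
        for logical, fp in fingerprints.items():
            old = active.fingerprints.get(logical)
            if old is not None:
                d = diff_structure(old, fp)
                if not d.is_empty:
                    diffs[logical] = d
        if diffs:
            raise StructureDriftError(source_name, diffs)

    row_counts: dict[str, int] = {}
    cur = store.conn
    for logical, (header, body) in tables.items():
        tname = _stg_table(source_name, logical)
        cols = ", ".join(f'"{c}" TEXT' for c in header)
        cur.execute(
            f'CREATE TABLE IF NOT EXISTS {tname} '
            f'(_release TEXT NOT NULL, _row INTEGER NOT NULL, {cols})')
        # a re-shaped file needs fresh columns; widen the table if drifted
        have = {r[1] for r in cur.execute(f"PRAGMA table_info({tname})")}
        for c in header:
            if c not in have:
                cur.execute(f'ALTER TABLE {tname} ADD COLUMN "{c}" TEXT')
        ph = ", ".join("?" for _ in header)
        quoted = ", ".join(f'"{c}"' for c in header)
        for i, row in enumerate(body, start=1):
            padded = list(row) + [""] * (len(header) - len(row))
            cur.execute(
                f'INSERT INTO {tname} (_release, _row, {quoted}) '
                f'VALUES (?, ?, {ph})',
                (version, i, *padded[:len(header)]))
        row_counts[logical] = len(body)

    now = datetime.now(timezone.utc).isoformat(timespec="seconds")
    cur.execute(
        "INSERT INTO staging_release (source_name, release_version, "
        "ingested_at, status, row_counts, fingerprints) VALUES (?, ?, ?, "
        "'staged', ?, ?)",
        (source_name, version, now, json.dumps(row_counts),
         json.dumps({f: {"columns": list(fp.columns), "kinds": list(fp.kinds)}
                     for f, fp in fingerprints.items()})))
    store.conn.commit()
    return _to_release(_release_row(store, source_name, version))


def swap_active_release(store: VariantStore, source_name: str,
                        version: str) -> str | None:
    """Atomically make ``version`` the active release; returns the previous.

    Runs in a single transaction: a concurrent reader sees either the old or
    the new active release, never a mixture. Swapping to the already-active
    version is a no-op.
    """
    row = _release_row(store, source_name, version)
    if row is None:
        raise KeyError(
            f"unknown release {version!r} for source {source_name!r}")
    if row["status"] == "active":
        return version
    prev = active_release(store, source_name)
    with store.conn:
        if prev is not None:
            store.conn.execute(
                "UPDATE staging_release SET status = 'retired' WHERE "
                "source_name = ? AND release_version = ?",
                (source_name, prev.release_version))
        store.conn.execute(
            "UPDATE staging_release SET status = 'active' WHERE "
            "source_name = ? AND release_version = ?", (source_name, version))
    return prev.release_version if prev else None


def list_releases(store: VariantStore,
                  source_name: str | None = None) -> list[SourceRelease]:
    _catalog_ddl(store)
    sql = "SELECT * FROM staging_release"
    args: tuple = ()
    if source_name:
        sql += " WHERE source_name = ?"
        args = (source_name,)
    sql += " ORDER BY ingested_at, release_version"
    return [_to_release(r) for r in store.conn.execute(sql, args)]


def active_release(store: VariantStore,
                   source_name: str) -> SourceRelease | None:
    _catalog_ddl(store)
    row = store.conn.execute(
        "SELECT * FROM staging_release WHERE source_name = ? AND "
        "status = 'active'", (source_name,)).fetchone()
    return _to_release(row) if row else None


def staged_rows(store: VariantStore, source_name: str, logical_file: str,
                version: str) -> list[dict[str, str]]:
    """All rows of one staged file of one release, as column->text dicts."""
    rel = _release_row(store, source_name, version)
    if rel is None:
        raise KeyError(
            f"unknown release {version!r} for source {source_name!r}")
    cols = json.loads(rel["fingerprints"])[logical_file]["columns"]
    tname = _stg_table(source_name, logical_file)
    quoted = ", ".join(f'"{c}"' for c in cols)
    rows = store.conn.execute(
        f'SELECT _row, {quoted} FROM {tname} WHERE _release = ? '
        f'ORDER BY _row', (version,)).fetchall()
    out = []
    for r in rows:
        d = {c: (r[c] if r[c] is not None else "") for c in cols}
        d["_row"] = r["_row"]
        out.append(d)
    return out


def export_staged_file(store: VariantStore, source_name: str,
                       logical_file: str, version: str) -> str:
    """Re-export a staged file as normalized TSV text (lossless staging check)."""
    rows = staged_rows(store, source_name, logical_file, version)
    rel = _release_row(store, source_name, version)
    cols = json.loads(rel["fingerprints"])[logical_file]["columns"]
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(cols)
    for r in rows:
        writer.writerow([r[c] for c in cols])
    return buf.getvalue()
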