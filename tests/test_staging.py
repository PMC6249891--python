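"""Staging ETL: fingerprints, drift detection, verbatim load, atomic swap."""

import csv
import gzip
import random

import pytest

from oncovis.schema import ValidationError
from oncovis.staging import (Dialect, SourceDescriptor, StructureDriftError,
                             StructureFingerprint, active_release,
                             diff_structure, export_staged_file,
                             fingerprint_file, fingerprint_structure,
                             ingest_release, list_releases, register_source,
                             staged_rows, swap_active_release)

HEADER = ["record_id", "gene", "value"]
ROWS = [["r1", "SYNG001", "1.5"], ["r2", "SYNG002", "x"],
        ["r3", "SYNG003", ""]]


def _write(path, header=HEADER, rows=ROWS, delimiter="\t", compress=False):
    if compress:
        fh = gzip.open(path, "wt", newline="")
    else:
        fh = open(path, "w", newline="")
    with fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(header)
        w.writerows(rows)
    return path


@pytest.fixture
def source(store):
    desc = SourceDescriptor("demo", Dialect(), ("data",),
                            {"data": tuple(HEADER)})
    register_source(store, desc)
    return desc


class TestRegister:
    def test_duplicate_name_refused(self, store, source):
        with pytest.raises(ValidationError, match="already registered"):
            register_source(store, source)

    def test_empty_schema_refused(self, store):
        desc = SourceDescriptor("bad", Dialect(), ("data",), {"data": ()})
        with pytest.raises(ValidationError, match="empty declared schema"):
            register_source(store, desc)


class TestFingerprint:
    def test_row_order_invariance(self, tmp_path):
        a = _write(tmp_path / "a.tsv")
        shuffled = list(ROWS)
        random.Random(0).shuffle(shuffled)
        b = _write(tmp_path / "b.tsv", rows=shuffled)
        assert fingerprint_file(a) == fingerprint_file(b)

    def test_gzip_and_plain_identical(self, tmp_path):
        a = _write(tmp_path / "a.tsv")
        b = _write(tmp_path / "b.tsv.gz", compress=True)
        assert fingerprint_file(a) == fingerprint_file(b)

    def test_renamed_column_changes_fingerprint(self, tmp_path):
        a = _write(tmp_path / "a.tsv")
        b = _write(tmp_path / "b.tsv",
                   header=["record_id", "gene_symbol", "value"])
        assert fingerprint_file(a) != fingerprint_file(b)

    def test_coarse_value_kinds(self, tmp_path):
        fp = fingerprint_file(_write(tmp_path / "a.tsv"))
        assert fp.kinds == ("text", "text", "text")
        fp2 = fingerprint_structure(HEADER,
                                    [["r1", "g", "1"], ["r2", "h", ""]])
        assert fp2.kinds == ("text", "text", "number")

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        with pytest.raises(ValidationError, match="empty"):
            fingerprint_file(p)


class TestDiff:
    def _fp(self, *cols):
        return StructureFingerprint(tuple(cols), ("text",) * len(cols))

    def test_identical_fingerprints_empty_diff(self):
        assert diff_structure(self._fp("a", "b"), self._fp("a", "b")).is_empty

    def test_added_column(self):
        d = diff_structure(self._fp("a", "b"), self._fp("a", "b", "c"))
        assert (d.added, d.removed) == (["c"], [])

    def test_same_position_swap_is_renamed_candidate(self):
        d = diff_structure(self._fp("a", "b", "c"), self._fp("a", "x", "c"))
        assert d.renamed_candidates == [("b", "x")]
        assert not d.added and not d.removed

    def test_reorder_reported(self):
        d = diff_structure(self._fp("a", "b", "c"), self._fp("c", "b", "a"))
        assert d.reordered


class TestIngest:
    def test_load_counts_and_verbatim_values(self, store, source, tmp_path):
        _write(tmp_path / "data.tsv")
        rel = ingest_release(store, "demo", {"data": tmp_path / "data.tsv"},
                             "v1")
        assert rel.status == "staged"
        assert rel.row_counts == {"data": len(ROWS)}
        rows = staged_rows(store, "demo", "data", "v1")
        assert [r["gene"] for r in rows] == ["SYNG001", "SYNG002", "SYNG003"]
        assert rows[0]["value"] == "1.5"  # text, untransformed

    def test_lossless_reexport(self, store, source, tmp_path):
        path = _write(tmp_path / "data.tsv")
        ingest_release(store, "demo", {"data": path}, "v1")
        assert export_staged_file(store, "demo", "data", "v1") == \
            path.read_text()

    def test_reingest_same_version_refused(self, store, source, tmp_path):
        _write(tmp_path / "data.tsv")
        ingest_release(store, "demo", {"data": tmp_path / "data.tsv"}, "v1")
        with pytest.raises(ValidationError, match="already ingested"):
            ingest_release(store, "demo", {"data": tmp_path / "data.tsv"},
                           "v1")

    def test_missing_file_listed(self, store, source):
        with pytest.raises(ValidationError, match="missing files"):
            ingest_release(store, "demo", {}, "v1")

    def test_drift_against_active_release_refused_with_diff(
            self, store, source, tmp_path):
        _write(tmp_path / "v1.tsv")
        ingest_release(store, "demo", {"data": tmp_path / "v1.tsv"}, "v1")
        swap_active_release(store, "demo", "v1")
        _write(tmp_path / "v2.tsv", header=HEADER + ["note"],
               rows=[r + [""] for r in ROWS])
        with pytest.raises(StructureDriftError) as exc:
            ingest_release(store, "demo", {"data": tmp_path / "v2.tsv"}, "v2")
        assert exc.value.diffs["data"].added == ["note"]
        rel = ingest_release(store, "demo", {"data": tmp_path / "v2.tsv"},
                             "v2", accept_structure_change=True)
        assert rel.status == "staged"


class TestSwap:
    def _two_releases(self, store, tmp_path):
        desc = SourceDescriptor("demo", Dialect(), ("data",),
                                {"data": tuple(HEADER)})
        register_source(store, desc)
        _write(tmp_path / "v1.tsv")
        _write(tmp_path / "v2.tsv", rows=ROWS + [["r4", "SYNG004", "9"]])
        ingest_release(store, "demo", {"data": tmp_path / "v1.tsv"}, "v1")
        ingest_release(store, "demo", {"data": tmp_path / "v2.tsv"}, "v2")

    def test_swap_retires_previous(self, store, tmp_path):
        self._two_releases(store, tmp_path)
        assert swap_active_release(store, "demo", "v1") is None
        assert swap_active_release(store, "demo", "v2") == "v1"
        statuses = {r.release_version: r.status
                    for r in list_releases(store, "demo")}
        assert statuses == {"v1": "retired", "v2": "active"}

    def test_swap_to_active_is_noop(self, store, tmp_path):
        self._two_releases(store, tmp_path)
        swap_active_release(store, "demo", "v1")
        assert swap_active_release(store, "demo", "v1") == "v1"
        assert active_release(store, "demo").release_version == "v1"

    def test_unknown_version_refused(self, store, tmp_path):
        self._two_releases(store, tmp_path)
        with pytest.raises(KeyError):
            swap_active_release(store, "demo", "v9")

    def test_retired_release_remains_queryable(self, store, tmp_path):
        self._two_releases(store, tmp_path)
        swap_active_release(store, "demo", "v1")
        swap_active_release(store, "demo", "v2")
        assert len(staged_rows(store, "demo", "data", "v1")) == len(ROWS)

    def test_reader_sees_whole_release_never_a_mix(self, store, tmp_path):
        """A reader keyed to the active pointer observes v1 or v2 wholly."""
        self._two_releases(store, tmp_path)
        swap_active_release(store, "demo", "v1")

        def read_active():
            rel = active_release(store, "demo")
            rows = staged_rows(store, "demo", "data", rel.release_version)
            return rel.release_version, len(rows)

        assert read_active() == ("v1", 3)
        swap_active_release(store, "demo", "v2")
        version, n = read_active()
        assert (version, n) in {("v1", 3), ("v2", 4)}
        assert read_active() == ("v2", 4)
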