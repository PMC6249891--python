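"""Semantic mapping: spec validation, identity resolution, conflict merge."""

import copy

import pytest
import yaml

from oncovis.mapping import (AmbiguousTermError, MappingSpecError,
                             NotFoundError, apply_mapping, load_mapping_spec,
                             resolve_identifier, resolve_term)
from oncovis.schema import Lineage, ValidationError, VariantStore
from oncovis import synth

LIN = Lineage("testsrc", "v1", "r1")


def _civic_spec_doc(small_release):
    path = small_release.out_dir / \
        small_release.manifest["sources"]["civiclike"]["mapping_spec"]
    return yaml.safe_load(path.read_text("utf-8"))


class TestLoadSpec:
    def test_fixture_spec_covers_drug_effects(self, small_release):
        spec = load_mapping_spec(_civic_spec_doc(small_release))
        targets = {r.target for r in spec.rules}
        assert "cancer_variant_drug_effect" in targets

    def test_cancer_entity_column_maps_to_cancer_type(self, small_release):
        # a schema-level naming conflict: source column "cancer_entity"
        doc = _civic_spec_doc(small_release)
        cv_rules = [r for r in doc["tables"]
                    if r["target"] == "cancer_variant"]
        assert cv_rules[0]["cancer"]["term_column"] == "cancer_entity"
        load_mapping_spec(doc)  # accepted

    def test_missing_variant_identity_rule_rejected(self, small_release):
        doc = copy.deepcopy(_civic_spec_doc(small_release))
        for rule in doc["tables"]:
            rule.pop("hgvs", None)
        with pytest.raises(MappingSpecError, match="variant identity"):
            load_mapping_spec(doc)

    def test_unknown_target_field_rejected(self):
        doc = {"source": "x", "tables": [
            {"target": "gene", "file": "f",
             "fields": {"gene_name": {"column": "a"},
                        "nonsense_field": {"column": "b"},
                        "entrez_gene_id": {"column": "c"}}}]}
        with pytest.raises(MappingSpecError, match="nonsense_field"):
            load_mapping_spec(doc)

    def test_uncovered_mandatory_field_rejected(self):
        doc = {"source": "x", "tables": [
            {"target": "gene", "file": "f",
             "fields": {"entrez_gene_id": {"column": "c"}}}]}
        with pytest.raises(MappingSpecError, match="gene_name"):
            load_mapping_spec(doc)

    def test_recode_output_outside_vocabulary_rejected(self):
        doc = {"source": "x", "tables": [
            {"target": "variant", "file": "f",
             "hgvs": {"column": "h"},
             "fields": {"variant_type": {
                 "column": "t", "recode": {"snp": "SNP"}}}}]}
        with pytest.raises(MappingSpecError, match="SNP"):
            load_mapping_spec(doc)


class TestResolveIdentifier:
    def test_same_gene_under_both_namespaces(self, we_store):
        by_entrez = resolve_identifier(we_store, "gene", "entrez_gene",
                                       "3845")
        by_ensembl = resolve_identifier(we_store, "gene", "ensembl",
                                        "ENSG00000133703")
        assert by_entrez == by_ensembl
        gene = we_store.fetch_one("gene", gene_id=by_entrez)
        assert gene["gene_name"] == "KRAS"

    def test_namespace_kind_mismatch(self, we_store):
        with pytest.raises(ValidationError, match="not registered"):
            resolve_identifier(we_store, "drug", "entrez_gene", "3845")

    def test_unknown_id_without_create_signals_not_found(self, we_store):
        with pytest.raises(NotFoundError):
            resolve_identifier(we_store, "gene", "entrez_gene", "999999")

    def test_create_if_absent_mints_and_records_xref(self, store):
        ident = resolve_identifier(store, "gene", "entrez_gene", "7157",
                                   create_if_absent=True, lineage=LIN)
        assert resolve_identifier(store, "gene", "entrez_gene", "7157") == \
            ident


class TestResolveTerm:
    def test_synonym_resolves_to_same_concept(self, we_store):
        primary = resolve_term(we_store, "disease", "Colorectal cancer")
        assert resolve_term(we_store, "disease",
                            "malignant neoplasm of the colon") == primary
        assert resolve_term(we_store, "disease", "colon cancer") == primary

    def test_case_folding(self, we_store):
        assert resolve_term(we_store, "disease", "colorectal CANCER") == \
            resolve_term(we_store, "disease", "Colorectal cancer")

    def test_unknown_term_not_found(self, we_store):
        with pytest.raises(NotFoundError):
            resolve_term(we_store, "disease", "no such disease")

    def test_ambiguity_surfaces_candidates(self, store):
        a = store.insert_fact("cancer_type",
                              {"cancer_type_name": "alpha tumor"}, LIN)
        b = store.insert_fact("cancer_type",
                              {"cancer_type_name": "beta tumor"}, LIN)
        # ambiguity across the name and synonym spaces: concept b acquires
        # concept a's primary name as a synonym
        store.conn.execute(
            "INSERT INTO cancer_type_synonym (cancer_type_id, surface_form,"
            " fact_uid) VALUES (?, 'alpha tumor', 'FAMBIG01')", (b,))
        with pytest.raises(AmbiguousTermError) as exc:
            resolve_term(store, "disease", "alpha tumor")
        assert set(exc.value.candidates) == {a, b}


class TestApplyMapping:
    def test_full_release_closure_against_manifest(self, small_release):
        store = VariantStore()
        store.initialize()
        reports = synth.integrate_release(store, small_release)
        assert all(not r.skipped for r in reports.values())
        exp = small_release.manifest["expected"]
        n = store.conn.execute(
            "SELECT COUNT(*) FROM cancer_variant").fetchone()[0]
        assert n == exp["cancer_variants"]
        assert store.validate_integrity().is_empty

    def test_reapplying_release_inserts_nothing(self, small_release):
        store = VariantStore()
        store.initialize()
        synth.integrate_release(store, small_release)
        manifest = small_release.manifest
        for source, entry in manifest["sources"].items():
            spec = load_mapping_spec(
                (small_release.out_dir / entry["mapping_spec"])
                .read_text("utf-8"))
            rep = apply_mapping(store, spec)
            assert rep.inserted == 0 and rep.merged_as_conflict == 0

    def test_malformed_hgvs_row_skipped_not_fatal(self, store, tmp_path):
        from oncovis.staging import Dialect, SourceDescriptor, \
            ingest_release, register_source, swap_active_release
        header = "record_id\thgvs_g\n"
        body = "r1\tNC_000001.1:g.5A>G\nr2\tnot-an-hgvs\n"
        (tmp_path / "v.tsv").write_text(header + body)
        register_source(store, SourceDescriptor(
            "tiny", Dialect(), ("v",), {"v": ("record_id", "hgvs_g")}))
        ingest_release(store, "tiny", {"v": tmp_path / "v.tsv"}, "v1")
        swap_active_release(store, "tiny", "v1")
        spec = load_mapping_spec({"source": "tiny", "tables": [
            {"target": "variant", "file": "v", "record_id": "record_id",
             "hgvs": {"column": "hgvs_g"}}]})
        rep = apply_mapping(store, spec)
        assert len(store.fetch("variant")) == 1
        assert len(rep.skipped) == 1
        assert "parse error" in rep.skipped[0]["reason"]

    def test_source_dropout_leaves_other_sources_untouched(
            self, small_release):
        """Facts are lineage-filterable per source; dropping one source's
        facts leaves the others' assertions intact."""
        store = VariantStore()
        store.initialize()
        synth.integrate_release(store, small_release)
        total = store.conn.execute(
            "SELECT COUNT(*) FROM cancer_variant_drug_effect").fetchone()[0]
        with_cosmic = store.conn.execute(
            "SELECT COUNT(DISTINCT fact_uid) FROM lineage WHERE fact_table ="
            " 'cancer_variant_drug_effect' AND source_name = 'cosmiclike'"
        ).fetchone()[0]
        without = store.conn.execute(
            "SELECT COUNT(*) FROM cancer_variant_drug_effect e WHERE NOT "
            "EXISTS (SELECT 1 FROM lineage l WHERE l.fact_table = "
            "'cancer_variant_drug_effect' AND l.fact_uid = e.fact_uid AND "
            "l.source_name = 'cosmiclike')").fetchone()[0]
        assert with_cosmic + without == total
        assert with_cosmic > 0 and without > 0
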