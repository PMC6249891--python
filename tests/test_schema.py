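"""Core data model: id minting, DDL, typed insertion, integrity sweep."""

import pytest

from oncovis.schema import (ID_PREFIXES, INTERNAL_ID_RE, TABLES, Lineage,
                            UnknownKindError, ValidationError, VariantStore,
                            VocabularyError, emit_ddl)

LIN = Lineage("testsrc", "v1", "rec1")


def _gene(**over):
    rec = {"gene_name": "KRAS", "chromosome": "12",
           "entrez_gene_id": "3845", "ensembl_gene_id": "ENSG00000133703"}
    rec.update(over)
    return rec


class TestMintId:
    @pytest.mark.parametrize("kind,prefix", sorted(ID_PREFIXES.items()))
    def test_format_and_prefix(self, store, kind, prefix):
        ident = store.mint_id(kind)
        assert ident.startswith(prefix)
        assert len(ident) == 8
        assert INTERNAL_ID_RE.match(ident)

    def test_successive_ids_distinct(self, store):
        ids = {store.mint_id("gene") for _ in range(50)}
        assert len(ids) == 50

    def test_cancer_variant_prefix_is_cv(self, store):
        assert store.mint_id("cancer_variant").startswith("CV")

    def test_unknown_kind_names_the_kind(self, store):
        with pytest.raises(UnknownKindError, match="nonsense"):
            store.mint_id("nonsense")

    def test_deterministic_across_fresh_stores(self):
        a, b = VariantStore(), VariantStore()
        a.initialize(), b.initialize()
        assert [a.mint_id("gene") for _ in range(5)] == \
               [b.mint_id("gene") for _ in range(5)]


class TestDdl:
    def test_one_table_per_domain_class(self):
        ddl = emit_ddl()
        for name in TABLES:
            assert f"CREATE TABLE {name} " in ddl

    def test_double_initialize_errors_unless_flagged(self, store):
        with pytest.raises(RuntimeError):
            store.initialize()
        store.initialize(if_exists="ignore")  # no-op

    def test_fresh_store_passes_integrity(self, store):
        assert store.validate_integrity().is_empty


class TestInsertFact:
    def test_gene_round_trip(self, store):
        gid = store.insert_fact("gene", _gene(), LIN)
        row = store.fetch_one("gene", gene_name="KRAS")
        assert row["gene_id"] == gid
        assert row["entrez_gene_id"] == "3845"
        assert row["chromosome"] == "12"

    def test_vocabulary_violation_names_the_vocabulary(self, store):
        with pytest.raises(VocabularyError, match="variant type"):
            store.insert_fact("variant", {"variant_type": "SNP"}, LIN)

    def test_ratio_range_enforced(self, store):
        sid = store.insert_fact("sample_specimen", {"tumor_purity": 0.5}, LIN)
        gid = store.insert_fact("gene", _gene(), LIN)
        vid = store.insert_fact("variant", {"variant_type": "SNV"}, LIN)
        cid = store.insert_fact("cancer_type",
                                {"cancer_type_name": "testoma"}, LIN)
        cvid = store.insert_fact("cancer_variant", {
            "variant_id": vid, "cancer_type_id": cid,
            "biomarker_class": "predictive"}, LIN)
        with pytest.raises(ValidationError, match=r"outside \[0, 1\]"):
            store.insert_fact("cancer_variant_sample", {
                "cancer_variant_id": cvid, "sample_id": sid,
                "somatic_classification": "unknown",
                "allele_frequency": 1.5}, LIN)

    def test_missing_mandatory_fields_listed(self, store):
        with pytest.raises(ValidationError, match="gene_name"):
            store.insert_fact("gene", {"entrez_gene_id": "1"}, LIN)

    def test_gene_requires_an_accession(self, store):
        with pytest.raises(ValidationError, match="accession"):
            store.insert_fact("gene", {"gene_name": "X", "chromosome": "1"},
                              LIN)

    def test_lineage_is_mandatory(self, store):
        with pytest.raises(ValidationError, match="lineage"):
            store.insert_fact("gene", _gene(), None)

    def test_transcript_aberration_may_lack_variant(self, store):
        gid = store.insert_fact("gene", _gene(), LIN)
        tid = store.insert_fact("gene_transcript", {
            "gene_id": gid, "ensembl_transcript_id": "ENST00000000001"}, LIN)
        store.insert_fact("gene_variant_transcript", {
            "gene_id": gid, "transcript_id": tid,
            "variant_consequence": "expression"}, LIN)
        with pytest.raises(ValidationError, match="aberration"):
            store.insert_fact("gene_variant_transcript", {
                "gene_id": gid, "transcript_id": tid,
                "variant_consequence": "missense"}, LIN)


class TestMerge:
    def test_duplicate_cancer_variant_merges_not_raises(self, store):
        vid = store.insert_fact("variant", {"variant_type": "SNV"}, LIN)
        cid = store.insert_fact("cancer_type",
                                {"cancer_type_name": "testoma"}, LIN)
        rec = {"variant_id": vid, "cancer_type_id": cid,
               "biomarker_class": "predictive"}
        first = store.insert_fact("cancer_variant", rec, LIN)
        second = store.insert_fact("cancer_variant", rec,
                                   Lineage("other", "v2", "r9"))
        assert first == second
        assert len(store.fetch("cancer_variant")) == 1
        row = store.fetch_one("cancer_variant")
        # both provenances retained on the single row
        assert len(store.lineage_of("cancer_variant", row["fact_uid"])) == 2

    def test_conflicting_effects_coexist(self, store):
        vid = store.insert_fact("variant", {"variant_type": "SNV"}, LIN)
        cid = store.insert_fact("cancer_type",
                                {"cancer_type_name": "testoma"}, LIN)
        cvid = store.insert_fact("cancer_variant", {
            "variant_id": vid, "cancer_type_id": cid,
            "biomarker_class": "predictive"}, LIN)
        did = store.insert_fact("drug", {"substance_name": "drugX"}, LIN)
        base = {"cancer_variant_id": cvid, "drug_id": did,
                "evidence_level": "C"}
        store.insert_fact("cancer_variant_drug_effect",
                          {**base, "effect": "sensitive"}, LIN)
        _, outcome = store.merge_fact(
            "cancer_variant_drug_effect", {**base, "effect": "resistant"},
            Lineage("src2", "v1", "r2"))
        assert outcome == "attached-conflict"
        assert len(store.fetch("cancer_variant_drug_effect")) == 2

    def test_identical_assertion_accumulates_lineage(self, store):
        gid1 = store.insert_fact("gene", _gene(), LIN)
        gid2, outcome = store.merge_fact("gene", _gene(),
                                         Lineage("testsrc", "v2", "rec1"))
        assert gid1 == gid2 and outcome == "deduplicated"
        row = store.fetch_one("gene", gene_name="KRAS")
        assert len(store.lineage_of("gene", row["fact_uid"])) == 2

    def test_name_merge_is_case_insensitive(self, store):
        store.insert_fact("drug", {"substance_name": "Panitumumab"}, LIN)
        _, outcome = store.merge_fact(
            "drug", {"substance_name": "panitumumab"}, LIN)
        assert outcome == "deduplicated"
        assert len(store.fetch("drug")) == 1


class TestIntegrity:
    def test_raw_insert_without_lineage_is_flagged(self, store):
        store.conn.execute(
            "INSERT INTO variant (variant_id, variant_type, fact_uid) "
            "VALUES ('V0000001', 'SNV', 'F0000099')")
        report = store.validate_integrity()
        assert report.missing_lineage == [
            {"table": "variant", "fact_uid": "F0000099"}]

    def test_dangling_reference_reported(self, store):
        gid = store.insert_fact("gene", _gene(), LIN)
        vid = store.insert_fact("variant", {"variant_type": "SNV"}, LIN)
        store.insert_fact("gene_variant", {
            "gene_id": gid, "variant_id": vid,
            "variant_consequence": "missense"}, LIN)
        store.conn.commit()  # a pragma change is ignored mid-transaction
        store.conn.execute("PRAGMA foreign_keys = OFF")
        store.conn.execute("DELETE FROM gene")
        store.conn.execute("DELETE FROM lineage WHERE fact_table = 'gene'")
        report = store.validate_integrity()
        assert any(f["table"] == "gene_variant"
                   for f in report.dangling_references)
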