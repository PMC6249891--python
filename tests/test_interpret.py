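"""Risk-score concordance and request-time clinical relevance."""

import itertools

import pytest

from oncovis.interpret import (DEFAULT_MACRO_TIER, RiskScoreAlgorithm,
                               classify_concordance, derive_clinical_relevance,
                               record_risk_scores)
from oncovis.schema import Lineage, MACRO_LEVELS, ValidationError

LIN = Lineage("testsrc", "v1", "r1")


@pytest.fixture
def gvt(store):
    gid = store.insert_fact("gene", {
        "gene_name": "KRAS", "entrez_gene_id": "3845"}, LIN)
    tid = store.insert_fact("gene_transcript", {
        "gene_id": gid, "ensembl_transcript_id": "ENST00000256078"}, LIN)
    vid = store.insert_fact("variant", {"variant_type": "SNV"}, LIN)
    return gid, tid, vid


class TestRecordScores:
    def test_multi_algorithm_set_not_flagged(self, store, gvt):
        gid, tid, vid = gvt
        out = record_risk_scores(store, gid, tid, vid,
                                 [("FATHMM", 0.98468), ("SIFT", 0),
                                  ("PolyPhen", 0.97)], LIN)
        assert not out.under_determined
        assert len(store.fetch("risk_score")) == 3

    def test_single_algorithm_flagged_under_determined(self, store, gvt):
        gid, tid, vid = gvt
        out = record_risk_scores(store, gid, tid, vid, [("SIFT", 0.2)], LIN)
        assert out.under_determined

    def test_out_of_scale_score_rejected(self, store, gvt):
        gid, tid, vid = gvt
        with pytest.raises(ValidationError, match="scale"):
            record_risk_scores(store, gid, tid, vid, [("SIFT", 1.2)], LIN)

    def test_unknown_algorithm_rejected_until_registered(self, store, gvt):
        gid, tid, vid = gvt
        with pytest.raises(ValidationError, match="not registered"):
            record_risk_scores(store, gid, tid, vid, [("CADD", 12.0)], LIN)
        registry = {"CADD": RiskScoreAlgorithm("CADD", 0, 99, "high", 20),
                    "SIFT": RiskScoreAlgorithm("SIFT", 0, 1, "low", 0.05)}
        out = record_risk_scores(store, gid, tid, vid, [("CADD", 12.0)],
                                 LIN, registry=registry)
        assert out.entries == [("CADD", 12.0)]


class TestConcordance:
    # predictor disagreement fixture: (entries, expected class)
    CASES = [
        ([("SIFT", 0.85), ("PolyPhen", 0.012)], "concordant-benign"),
        ([("SIFT", 0.36), ("PolyPhen", 1.0)], "discordant"),
        ([("SIFT", 0.0), ("PolyPhen", 0.97), ("FATHMM", 0.98468)],
         "concordant-deleterious"),
        ([("SIFT", 0.5)], "under-determined"),
        ([], "under-determined"),
    ]

    @pytest.mark.parametrize("entries,expected", CASES)
    def test_classification(self, entries, expected):
        assert classify_concordance(entries) == expected

    @pytest.mark.parametrize("entries,expected",
                             [c for c in CASES if len(c[0]) > 1])
    def test_invariant_under_reordering(self, entries, expected):
        for perm in itertools.permutations(entries):
            assert classify_concordance(list(perm)) == expected


@pytest.fixture
def cancer_variant(store):
    vid = store.insert_fact("variant", {"variant_type": "SNV"}, LIN)
    cid = store.insert_fact("cancer_type",
                            {"cancer_type_name": "testoma"}, LIN)
    cvid = store.insert_fact("cancer_variant", {
        "variant_id": vid, "cancer_type_id": cid,
        "biomarker_class": "predictive"}, LIN)
    did = store.insert_fact("drug", {"substance_name": "drugX"}, LIN)
    return cvid, did


def _effect(store, cvid, did, macro, sublevel=None, effect="sensitive",
            record="r1"):
    store.insert_fact("cancer_variant_drug_effect", {
        "cancer_variant_id": cvid, "drug_id": did, "effect": effect,
        "evidence_level": macro, "evidence_sublevel": sublevel,
        "source_scheme": "Proposed",
        "source_level_code": sublevel or macro},
        Lineage("testsrc", "v1", record))


class TestRelevance:
    def test_macro_c_gives_tier_2(self, store, cancer_variant):
        cvid, did = cancer_variant
        _effect(store, cvid, did, "C", "3A")
        tier, explanation = derive_clinical_relevance(store, cvid)
        assert tier == "Tier 2"
        assert explanation["best_evidence"] == {"macro": "C",
                                                "sublevel": "3A"}
        assert explanation["contributing_effects"][0]["lineage"]

    def test_no_cache_reflects_new_evidence_immediately(self, store,
                                                        cancer_variant):
        cvid, did = cancer_variant
        _effect(store, cvid, did, "C", "3A")
        assert derive_clinical_relevance(store, cvid)[0] == "Tier 2"
        _effect(store, cvid, did, "A", "1A", effect="resistant", record="r2")
        assert derive_clinical_relevance(store, cvid)[0] == "Tier 1"

    def test_only_inferential_evidence_gives_tier_4(self, store,
                                                    cancer_variant):
        cvid, did = cancer_variant
        _effect(store, cvid, did, "E")
        assert derive_clinical_relevance(store, cvid)[0] == "Tier 4"

    def test_no_evidence_flagged_low_information(self, store, cancer_variant):
        cvid, _ = cancer_variant
        tier, explanation = derive_clinical_relevance(store, cvid)
        assert explanation["low_information"]
        assert tier == "Tier 3"

    @pytest.mark.parametrize("macro", MACRO_LEVELS)
    def test_default_rule_matches_macro_tier_ladder(self, store, macro):
        vid = store.insert_fact("variant", {"variant_type": "SNV"}, LIN)
        cid = store.insert_fact("cancer_type",
                                {"cancer_type_name": f"t-{macro}"}, LIN)
        cvid = store.insert_fact("cancer_variant", {
            "variant_id": vid, "cancer_type_id": cid,
            "biomarker_class": "predictive"}, LIN)
        did = store.insert_fact("drug",
                                {"substance_name": f"d-{macro}"}, LIN)
        _effect(store, cvid, did, macro)
        assert derive_clinical_relevance(store, cvid)[0] == \
            DEFAULT_MACRO_TIER[macro]

    def test_unknown_cancer_variant_raises(self, store):
        with pytest.raises(KeyError):
            derive_clinical_relevance(store, "CV999999")
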