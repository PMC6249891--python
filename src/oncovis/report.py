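"""Assembly of the integrated per-cancer-variant report.

One report is the core MVLD view for a single (variant, cancer type) pair:
gene and transcript context, positions per assembly, consequences, molecular
risk scores with their concordance classification, drug effects with both the
original source evidence codes and the harmonized macro/sublevel, and the
request-time derived clinical relevance tier. Conflicting values appear side
by side — the report never collapses divergent assertions — and every fact
carries its lineage links so any displayed value can be followed back to a
(source, release, record) triple in staging.
"""

from __future__ import annotations

import json
from typing import Any

from . import hgvs as hgvs_mod
from .interpret import (RelevanceRule, classify_concordance,
                        default_relevance_rule, derive_clinical_relevance)
from .mapping import NotFoundError, resolve_term
from .schema import VariantStore

__all__ = ["build_variant_report", "report_to_text"]


def _with_lineage(store: VariantStore, table: str, row) -> dict:
    d = {k: row[k] for k in row.keys() if k != "fact_uid"}
    d["lineage"] = store.lineage_of(table, row["fact_uid"])
    return d


def find_variant(store: VariantStore, hgvs_text: str) -> str:
    """Resolve a g-level HGVS string to the internal variant id."""
    desc = hgvs_mod.parse_hgvs(hgvs_text)
    if desc.level != "g":
        raise NotFoundError(
            f"{hgvs_text!r} is not a genomic (g.) description; variant "
            "lookup requires the canonical genomic spelling")
    key = hgvs_mod.format_hgvs(desc)
    row = store.fetch_one("identifier_xref", entity_kind="variant",
                          namespace="genomic_key", external_id=key)
    if row is None:
        raise NotFoundError(f"no variant known under {key!r}")
    return row["internal_id"]


def build_variant_report(store: VariantStore, hgvs_text: str,
                         cancer_term: str,
                         rule: RelevanceRule = default_relevance_rule,
                         ) -> dict[str, Any]:
    """Build the full JSON-serializable report for one cancer variant."""
    variant_id = find_variant(store, hgvs_text)
    cancer_type_id = resolve_term(store, "disease", cancer_term)
    cv = store.fetch_one("cancer_variant", variant_id=variant_id,
                         cancer_type_id=cancer_type_id)
    if cv is None:
        raise NotFoundError(
            f"variant {hgvs_text!r} has no recorded association with "
            f"cancer type {cancer_term!r}")

    variant = store.fetch_one("variant", variant_id=variant_id)
    cancer = store.fetch_one("cancer_type", cancer_type_id=cancer_type_id)
    positions = [_with_lineage(store, "variant_position", r)
                 for r in store.fetch("variant_position",
                                      variant_id=variant_id)]
    gene_rows = store.fetch("gene_variant", variant_id=variant_id)
    genes = []
    for gv in gene_rows:
        gene = store.fetch_one("gene", gene_id=gv["gene_id"])
        entry = _with_lineage(store, "gene_variant", gv)
        entry["gene"] = _with_lineage(store, "gene", gene)
        transcripts = []
        for gvt in store.fetch("gene_variant_transcript",
                               gene_id=gv["gene_id"], variant_id=variant_id):
            t = _with_lineage(store, "gene_variant_transcript", gvt)
            tr = store.fetch_one("gene_transcript",
                                 transcript_id=gvt["transcript_id"])
            if tr is not None:
                t["transcript"] = _with_lineage(store, "gene_transcript", tr)
            scores = store.fetch("risk_score", gene_id=gv["gene_id"],
                                 transcript_id=gvt["transcript_id"],
                                 variant_id=variant_id)
            t["risk_scores"] = [_with_lineage(store, "risk_score", s)
                                for s in scores]
            t["risk_concordance"] = classify_concordance(
                [(s["algorithm"], s["score"]) for s in scores
                 if s["algorithm"] in ("SIFT", "PolyPhen", "FATHMM")]
                or [(s["algorithm"], s["score"]) for s in scores])
            transcripts.append(t)
        entry["transcripts"] = transcripts
        genes.append(entry)

    samples = []
    for cvs in store.fetch("cancer_variant_sample",
                           cancer_variant_id=cv["cancer_variant_id"]):
        s = _with_lineage(store, "cancer_variant_sample", cvs)
        spec = store.fetch_one("sample_specimen", sample_id=cvs["sample_id"])
        if spec is not None:
            s["specimen"] = _with_lineage(store, "sample_specimen", spec)
        samples.append(s)

    drug_effects = []
    for eff in store.fetch("cancer_variant_drug_effect",
                           cancer_variant_id=cv["cancer_variant_id"]):
        e = _with_lineage(store, "cancer_variant_drug_effect", eff)
        drug = store.fetch_one("drug", drug_id=eff["drug_id"])
        if drug is not None:
            e["drug"] = _with_lineage(store, "drug", drug)
        drug_effects.append(e)

    tier, explanation = derive_clinical_relevance(
        store, cv["cancer_variant_id"], rule)

    return {
        "cancer_variant": _with_lineage(store, "cancer_variant", cv),
        "variant": _with_lineage(store, "variant", variant),
        "cancer_type": _with_lineage(store, "cancer_type", cancer),
        "positions": positions,
        "genes": genes,
        "samples": samples,
        "drug_effects": drug_effects,
        "clinical_relevance_level": tier,
        "relevance_explanation": explanation,
    }


def report_to_text(report: dict[str, Any]) -> str:
    """Human-readable rendering of a report (conflicts shown side by side)."""
    lines = []
    cv = report["cancer_variant"]
    lines.append(f"Cancer variant {cv['cancer_variant_id']} "
                 f"({report['cancer_type']['cancer_type_name']})")
    lines.append(f"  biomarker class: {cv['biomarker_class']}")
    lines.append(
        f"  clinical relevance (derived): {report['clinical_relevance_level']}")
    for p in report["positions"]:
        lines.append(f"  position [{p['genome_version']}]: "
                     f"{p['dna_sub_and_position']}")
    for g in report["genes"]:
        lines.append(f"  gene {g['gene']['gene_name']} "
                     f"(Entrez {g['gene']['entrez_gene_id']}): "
                     f"{g['variant_consequence']}")
        for t in g["transcripts"]:
            scores = ", ".join(f"{s['algorithm']} {s['score']}"
                               for s in t["risk_scores"])
            lines.append(f"    transcript {t['transcript_id']}: "
                         f"{t.get('protein_sub_and_position') or ''}"
                         f" [{scores}] -> {t['risk_concordance']}")
    for s in report["samples"]:
        spec = s.get("specimen") or {}
        lines.append(f"  sample {s['sample_id']}: "
                     f"{s['somatic_classification']}, "
                     f"AF {s['allele_frequency']}, "
                     f"purity {spec.get('tumor_purity')}, "
                     f"TNM {spec.get('tnm_status')}")
    for e in report["drug_effects"]:
        drug = e.get("drug") or {}
        lines.append(f"  drug {drug.get('substance_name')}: {e['effect']} "
                     f"(evidence {e['evidence_level']}"
                     f"{'/' + e['evidence_sublevel'] if e['evidence_sublevel'] else ''}"
                     f", source {e['source_scheme']} {e['source_level_code']})")
    return "\n".join(lines)


def report_round_trip(report: dict[str, Any]) -> dict[str, Any]:
    """parse(emit(report)); reports are plain JSON and must round-trip."""
    return json.loads(json.dumps(report))
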