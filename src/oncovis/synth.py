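"""Seeded generator of fictional source-database releases.

Real variant knowledgebases cannot be redistributed, and their heterogeneity
— not their content — is what the integration pipeline has to survive. This
module therefore fabricates three source dialects that emulate the shapes of
widely used exports:

* ``clinvarlike`` — gzipped TSV, multi-file, carries the disease terminology
  (primary names plus synonyms) and grades drug assertions on the MD Anderson
  six-code scale;
* ``civiclike`` — plain CSV, names the disease column ``cancer_entity``,
  reports variants at coding-DNA (c.) level with a genomic cross-reference
  column, and grades on the CIViC five-letter scale;
* ``cosmiclike`` — gzipped TSV, single wide mutation table, grades on the
  ten-code scale of Andre et al.

Content is entirely fictional but syntactically valid (NC_/NM_/ENSG/ENST/DB
accession shapes); every file header carries a ``# fictional`` marker comment
in the manifest rather than in the data. The generator also injects, under
seeded control, the integration hazards the pipeline must handle: variants
shared between sources, contradictory drug effects, synonym-only disease
mentions and release-to-release schema drift. A ground-truth manifest fully
determines the expected pipeline outputs (row counts, entity counts, alias
groups, conflict list), so tests can assert pipeline closure exactly.

Variant positions are drawn uniformly within a per-gene window; no attempt
is made at realistic mutation spectra — identity and conflict logic is what
is under test, not population genetics.

A separate, fully deterministic worked-example release reproduces the
canonical KRAS G12A / colorectal cancer / Panitumumab record end to end,
including the alias table of transcript-level respellings and the predictor
disagreement score rows.
"""

from __future__ import annotations

import csv
import gzip
import io
import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import mapping as mapping_mod
from . import staging
from .schema import (BIOMARKER_CLASSES, DRUG_EFFECTS,
                     GENE_VARIANT_CONSEQUENCES, VariantStore)

__all__ = [
    "GeneratorConfig",
    "GeneratedRelease",
    "generate_worked_example",
    "generate_source_release",
    "generate_drifted_release",
    "integrate_release",
    "WORKED_EXAMPLE_SOURCE",
]

WORKED_EXAMPLE_SOURCE = "paperdemo"

_SCHEME_CODES = {
    "CIViC": ("A", "B", "C", "D", "E"),
    "MDAnderson": ("1A", "1B", "2A", "2B", "3A", "3B"),
    "Andre": ("1A", "1B", "1C", "2A", "2B", "2C", "3A", "3B", "4A", "4B"),
}
_SOURCE_SCHEME = {"clinvarlike": "MDAnderson", "civiclike": "CIViC",
                  "cosmiclike": "Andre"}
_SOURCES = ("clinvarlike", "civiclike", "cosmiclike")

_EFFECT_DIALECT = {e.capitalize(): e for e in DRUG_EFFECTS}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of one synthetic release.

    Defaults give each run on the order of a thousand staged rows spread
    over the three dialects, with realistic shares of cross-source overlap,
    contradiction and synonym-only disease mentions.
    """

    seed: int = 42
    n_genes: int = 25
    n_variants: int = 250
    n_cancer_types: int = 8
    n_drugs: int = 12
    overlap_fraction: float = 0.3
    conflict_rate: float = 0.2
    synonym_rate: float = 0.3

    def validate(self) -> None:
        for name in ("overlap_fraction", "conflict_rate", "synonym_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_genes", "n_variants", "n_cancer_types", "n_drugs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class GeneratedRelease:
    out_dir: Path
    manifest: dict

    @property
    def version(self) -> str:
        return self.manifest["version"]


# ---------------------------------------------------------------------------
# File rendering helpers
# ---------------------------------------------------------------------------


def _write_delim(path: Path, header: Sequence[str],
                 rows: Sequence[Sequence[Any]], delimiter: str,
                 compress: bool) -> None:
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(header)
    for row in rows:
        writer.writerow(row)
    data = buf.getvalue().encode("utf-8")
    path.parent.mkdir(parents=True, exist_ok=True)
    if compress:
        # mtime pinned so regeneration is byte-identical
        with open(path, "wb") as fh:
            with gzip.GzipFile(filename="", mode="wb", fileobj=fh,
                               mtime=0) as gz:
                gz.write(data)
    else:
        path.write_bytes(data)


def _contig(chromosome: str) -> str:
    n = {"X": 23, "Y": 24}.get(chromosome) or int(chromosome)
    return f"NC_{n:06d}.11"


# ---------------------------------------------------------------------------
# Worked example
# ---------------------------------------------------------------------------

# the alias table of transcript/protein-level respellings of one genomic
# change, with the isoform each spelling lives on (None: the genomic row)
WORKED_EXAMPLE_G = "NC_000012.11:g.25398284C>G"
WORKED_EXAMPLE_ALIASES: tuple[tuple[str, str | None], ...] = (
    ("NC_000012.11:g.25398284C>G", None),
    ("ENST00000256078.4:c.35G >C", "KRAS-004"),
    ("NM_033360.3:c.35G >C", "KRAS-004"),
    ("ENSP00000256078.4:p.Gly12Ala", "KRAS-004"),
    ("NP_203524.1:p.Gly12Ala", "KRAS-004"),
    ("ENST00000311936.3:c.35G >C", "KRAS-001"),
    ("NM_004985.4:c.35G >C", "KRAS-001"),
    ("ENSP00000308495.3:p.Gly12Ala", "KRAS-001"),
    ("NP_004976.2:p.Gly12Ala", "KRAS-001"),
    ("ENST00000556131.1:c.35G >C", "KRAS-002"),
    ("ENSP00000451856.1:p.Gly12Ala", "KRAS-002"),
    ("ENST00000557334.1:c.35G >C", "KRAS-003"),
    ("ENSP00000452512.1:p.Gly12Ala", "KRAS-003"),
)

# predictor disagreement rows: (rsid, SIFT, PolyPhen, clinical evidence)
WORKED_EXAMPLE_SCORES: tuple[tuple[str, str, str, str], ...] = (
    ("rs1048943590", "0.36", "1", "Pathogenic"),
    ("rs121913529", "0", "1", "Pathogenic"),
    ("rs1137282", "0.85", "0.012", "Benign"),
)

_WE_SYNONYMS = "|".join((
    "colon cancer",
    "adenocarcinoma of the colon",
    "cancer of the colon",
    "carcinoma of colon",
    "malignant tumor of the colon",
    "malignant neoplasm of the colon",
))


def _worked_example_tables() -> dict[str, tuple[list[str], list[list[str]]]]:
    genes = (
        ["record_id", "symbol", "chromosome", "entrez_id", "ensembl_id",
         "refseq_id", "transcript_ensembl", "transcript_refseq",
         "protein_refseq", "uniprot", "genome_build", "cytoband"],
        [["GEN00001", "KRAS", "12", "3845", "ENSG00000133703", "NG_007524",
          "ENST00000256078", "NM_033360", "NP_203524", "P01116",
          "GRCh37.p13", "12p12.1"]],
    )
    diseases = (
        ["record_id", "name", "umls", "hpo", "synonyms"],
        [["DIS00001", "Colorectal cancer", "C1527249", "HP:0003003",
          _WE_SYNONYMS]],
    )
    drugs = (
        ["record_id", "substance", "drugbank", "pharmgkb", "fda", "mechanism"],
        [["DRG00001", "Panitumumab", "DB01269", "PA162373091", "125147",
          "Binds to the epidermal growth factor receptor (EGFR) on both "
          "normal and tumor cells"]],
    )
    variants = (
        ["record_id", "symbol", "hgvs_g", "hgvs_c", "protein_hgvs",
         "protein_domain", "consequence", "transcript_consequence",
         "transcript_ensembl", "genome_build", "fathmm", "sift", "polyphen"],
        [["VAR00001", "KRAS", WORKED_EXAMPLE_G, "NM_033360.3:c.35G >C",
          "NM_033360.3(KRAS):c.35G >C (p.Gly12Ala)",
          "Small GTP-binding protein domain", "missense", "missense",
          "ENST00000256078", "GRCh37.p13", "0.98468", "0", "0.97"]],
    )
    clinical = (
        ["record_id", "hgvs_g", "disease", "biomarker", "drug", "effect",
         "evidence_level", "sample_code", "tumor_purity", "tnm",
         "primary_or_relapse", "somatic_classification", "allele_frequency"],
        [["CLN00001", WORKED_EXAMPLE_G, "Colorectal cancer", "predictive",
          "Panitumumab", "Resistance or non-response", "3A", "SXBQW0A7",
          "0.763", "T2N1M1", "primary", "somatic", "0.00001647"]],
    )
    aliases = (
        ["record_id", "hgvs", "hgvs_g", "transcript_name"],
        [[f"ALS{i + 1:05d}", text,
          "" if transcript is None else WORKED_EXAMPLE_G,
          transcript or ""]
         for i, (text, transcript) in enumerate(WORKED_EXAMPLE_ALIASES)],
    )
    scores = (
        ["rsid", "sift", "polyphen", "clinical_evidence"],
        [list(r) for r in WORKED_EXAMPLE_SCORES],
    )
    return {"genes": genes, "diseases": diseases, "drugs": drugs,
            "variants": variants, "clinical": clinical, "aliases": aliases,
            "scores": scores}


_WE_EFFECT_RECODE = {
    "Resistance or non-response": "resistant",
    **_EFFECT_DIALECT,
}

_WE_MAPPING = {
    "source": WORKED_EXAMPLE_SOURCE,
    "tables": [
        {"target": "gene", "file": "genes", "record_id": "record_id",
         "fields": {
             "gene_name": {"column": "symbol"},
             "chromosome": {"column": "chromosome"},
             "entrez_gene_id": {"column": "entrez_id"},
             "ensembl_gene_id": {"column": "ensembl_id"},
             "refseq_gene_id": {"column": "refseq_id"}}},
        {"target": "gene_transcript", "file": "genes",
         "record_id": "record_id", "gene": {"name_column": "symbol"},
         "fields": {
             "ensembl_transcript_id": {"column": "transcript_ensembl"},
             "refseq_transcript_id": {"column": "transcript_refseq"},
             "refseq_protein_id": {"column": "protein_refseq"},
             "uniprot_id": {"column": "uniprot"}}},
        {"target": "gene_position", "file": "genes",
         "record_id": "record_id", "gene": {"name_column": "symbol"},
         "fields": {
             "genome_version": {"column": "genome_build"},
             "dna_position": {"column": "cytoband"}}},
        {"target": "cancer_type", "file": "diseases",
         "record_id": "record_id",
         "synonyms": {"column": "synonyms", "separator": "|",
                      "terminology": "ICD-10"},
         "fields": {
             "cancer_type_name": {"column": "name"},
             "umls_id": {"column": "umls"},
             "hpo_id": {"column": "hpo"}}},
        {"target": "drug", "file": "drugs", "record_id": "record_id",
         "fields": {
             "substance_name": {"column": "substance"},
             "drugbank_id": {"column": "drugbank"},
             "pharmgkb_id": {"column": "pharmgkb"},
             "fda_id": {"column": "fda"}}},
        {"target": "drug_mechanism", "file": "drugs",
         "record_id": "record_id", "drug": {"name_column": "substance"},
         "fields": {"mechanism": {"column": "mechanism"}}},
        {"target": "variant", "file": "variants", "record_id": "record_id",
         "hgvs": {"column": "hgvs_g", "genome_version": "GRCh37.p13"}},
        {"target": "gene_variant", "file": "variants",
         "record_id": "record_id", "gene": {"name_column": "symbol"},
         "hgvs": {"column": "hgvs_g"},
         "fields": {"variant_consequence": {"column": "consequence"}}},
        {"target": "gene_variant_transcript", "file": "variants",
         "record_id": "record_id", "gene": {"name_column": "symbol"},
         "transcript": {"ensembl_column": "transcript_ensembl"},
         "hgvs": {"column": "hgvs_g"},
         "fields": {
             "protein_sub_and_position": {"column": "protein_hgvs"},
             "protein_domain": {"column": "protein_domain"},
             "variant_consequence": {"column": "transcript_consequence"}}},
        {"target": "risk_score", "file": "variants",
         "record_id": "record_id", "gene": {"name_column": "symbol"},
         "transcript": {"ensembl_column": "transcript_ensembl"},
         "hgvs": {"column": "hgvs_g"},
         "scores": {"FATHMM": "fathmm", "SIFT": "sift",
                    "PolyPhen": "polyphen"}},
        {"target": "cancer_variant", "file": "clinical",
         "record_id": "record_id", "hgvs": {"column": "hgvs_g"},
         "cancer": {"term_column": "disease"},
         "fields": {"biomarker_class": {"column": "biomarker"}}},
        {"target": "sample_specimen", "file": "clinical",
         "record_id": "record_id", "sample": {"code_column": "sample_code"},
         "fields": {
             "tumor_purity": {"column": "tumor_purity", "cast": "float"},
             "tnm_status": {"column": "tnm"},
             "primary_or_relapse": {"column": "primary_or_relapse"}}},
        {"target": "cancer_variant_sample", "file": "clinical",
         "record_id": "record_id", "hgvs": {"column": "hgvs_g"},
         "cancer": {"term_column": "disease"},
         "sample": {"code_column": "sample_code"},
         "fields": {
             "somatic_classification": {
                 "column": "somatic_classification",
                 "recode": {"somatic": "confirmed somatic",
                            "germline": "confirmed germline",
                            "unknown": "unknown"}},
             "allele_frequency": {"column": "allele_frequency",
                                  "cast": "float"}}},
        {"target": "cancer_variant_drug_effect", "file": "clinical",
         "record_id": "record_id", "hgvs": {"column": "hgvs_g"},
         "cancer": {"term_column": "disease"},
         "drug": {"name_column": "drug"},
         "evidence": {"scheme": "Proposed", "level_column": "evidence_level"},
         "fields": {"effect": {"column": "effect",
                               "recode": _WE_EFFECT_RECODE}}},
    ],
}


def generate_worked_example(out_dir: str | Path) -> GeneratedRelease:
    """Emit the canonical single-record release; regeneration is byte-identical.

    The release carries one gene (KRAS), one disease concept with its synonym
    ring, one drug (Panitumumab), one genomic variant with its transcript- and
    protein-level alias spellings, one clinical assertion (predictive
    biomarker, drug effect at evidence 3A) and the predictor disagreement
    score table. Ingesting and mapping it reproduces every core field of the
    canonical record.
    """
    out = Path(out_dir)
    tables = _worked_example_tables()
    files: dict[str, str] = {}
    row_counts: dict[str, int] = {}
    for logical, (header, rows) in tables.items():
        fname = f"{WORKED_EXAMPLE_SOURCE}/{logical}.tsv"
        _write_delim(out / fname, header, rows, "\t", compress=False)
        files[logical] = fname
        row_counts[logical] = len(rows)
    spec_name = f"{WORKED_EXAMPLE_SOURCE}.mapping.yaml"
    (out / spec_name).write_text(yaml.safe_dump(_WE_MAPPING, sort_keys=False),
                                 encoding="utf-8")
    manifest = {
        "kind": "worked-example",
        "version": "v1",
        "fictional": False,
        "apply_order": [WORKED_EXAMPLE_SOURCE],
        "sources": {
            WORKED_EXAMPLE_SOURCE: {
                "dialect": {"delimiter": "\t", "compression": None},
                "files": files,
                "row_counts": row_counts,
                "mapping_spec": spec_name,
                "declared_schema": {
                    logical: list(header)
                    for logical, (header, _) in tables.items()},
            },
        },
        "expected": {
            "gene_name": "KRAS",
            "entrez_gene_id": "3845",
            "ensembl_gene_id": "ENSG00000133703",
            "hgvs_g": WORKED_EXAMPLE_G,
            "genomic_position": 25398284,
            "allele_frequency": 0.00001647,
            "tumor_purity": 0.763,
            "tnm_status": "T2N1M1",
            "biomarker_class": "predictive",
            "evidence_level": "C",
            "evidence_sublevel": "3A",
            "clinical_relevance": "Tier 2",
            "risk_scores": {"FATHMM": 0.98468, "SIFT": 0.0, "PolyPhen": 0.97},
            "sample_code": "SXBQW0A7",
            "drug": "Panitumumab",
            "drugbank_id": "DB01269",
            "alias_count": len(WORKED_EXAMPLE_ALIASES),
            "alias_groups": 1,
            "transcript_isoforms": 4,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                       encoding="utf-8")
    return GeneratedRelease(out, manifest)


# ---------------------------------------------------------------------------
# Seeded three-dialect releases
# ---------------------------------------------------------------------------


@dataclass
class _Universe:
    genes: list[dict]
    cancer_types: list[dict]
    drugs: list[dict]
    variants: list[dict]


def _build_universe(config: GeneratorConfig) -> _Universe:
    rng = random.Random(config.seed)
    genes = []
    for i in range(config.n_genes):
        chrom = rng.choice([str(c) for c in range(1, 23)] + ["X", "Y"])
        genes.append({
            "symbol": f"SYNG{i + 1:03d}",
            "chromosome": chrom,
            "contig": _contig(chrom),
            "start": 1_000_000 + i * 200_000,
            "entrez": str(9_900_000 + i),
            "ensembl": f"ENSG{99_000_000_000 + i}",
            "refseq": f"NG_9{i:05d}",
            "transcript": f"ENST{99_000_000_000 + i}.1",
            "isoform": f"SYNG{i + 1:03d}-001",
        })
    cancer_types = []
    for i in range(config.n_cancer_types):
        cancer_types.append({
            "name": f"synthetic neoplasm type {i + 1}",
            "synonyms": [f"neoplasm of synthetic organ {i + 1}",
                         f"malignant synthetic tumor {i + 1}"],
            "umls": f"C99{i:05d}",
        })
    drugs = [{"name": f"synthemab-{i + 1:02d}", "drugbank": f"DB9{i:04d}"}
             for i in range(config.n_drugs)]

    n = config.n_variants
    n_overlap = round(config.overlap_fraction * n)
    if n_overlap > n:
        raise ValueError("overlap exceeds the number of variants")
    overlap_idx = set(rng.sample(range(n), n_overlap))
    conflict_idx = set(rng.sample(sorted(overlap_idx),
                                  round(config.conflict_rate * n_overlap)))
    variants = []
    seen_keys: set[tuple] = set()
    for vi in range(n):
        gene = rng.choice(genes)
        while True:
            pos = gene["start"] + rng.randrange(1, 100_000)
            ref = rng.choice("ACGT")
            alt = rng.choice([b for b in "ACGT" if b != ref])
            if (gene["contig"], pos, ref, alt) not in seen_keys:
                seen_keys.add((gene["contig"], pos, ref, alt))
                break
        home = _SOURCES[vi % 3]
        carriers = [home]
        if vi in overlap_idx:
            carriers.append(rng.choice([s for s in _SOURCES if s != home]))
        ct = rng.choice(cancer_types)
        drug = rng.choice(drugs)
        if vi in conflict_idx:
            effects = rng.sample(DRUG_EFFECTS, len(carriers))
        else:
            effects = [rng.choice(DRUG_EFFECTS)] * len(carriers)
        codes = {s: rng.choice(_SCHEME_CODES[_SOURCE_SCHEME[s]])
                 for s in carriers}
        variants.append({
            "index": vi,
            "gene": gene,
            "pos": pos, "ref": ref, "alt": alt,
            "hgvs_g": f"{gene['contig']}:g.{pos}{ref}>{alt}",
            "hgvs_c": f"{gene['transcript']}:c."
                      f"{pos - gene['start']}{ref}>{alt}",
            "consequence": rng.choice(GENE_VARIANT_CONSEQUENCES),
            "biomarker": rng.choice(BIOMARKER_CLASSES),
            "cancer_type": ct,
            "drug": drug,
            "carriers": carriers,
            "effects": dict(zip(carriers, effects)),
            "codes": codes,
            "conflict": vi in conflict_idx,
        })
    return _Universe(genes, cancer_types, drugs, variants)


def _term_for(rng: random.Random, ct: dict, synonym_rate: float,
              usage: list, source: str, record_id: str) -> str:
    if rng.random() < synonym_rate:
        surface = rng.choice(ct["synonyms"])
        usage.append({"source": source, "record_id": record_id,
                      "cancer_type": ct["name"], "surface": surface})
        return surface
    return ct["name"]


def _render_source(universe: _Universe, source: str, config: GeneratorConfig,
                   synonym_usage: list
                   ) -> dict[str, tuple[list[str], list[list[str]]]]:
    # per-source derived rng so a drifted regeneration reproduces content
    rng = random.Random(config.seed * 1000003 + _SOURCES.index(source))
    mine = [v for v in universe.variants if source in v["carriers"]]
    genes = sorted({id(v["gene"]): v["gene"] for v in mine}.values(),
                   key=lambda g: g["symbol"])
    scheme = _SOURCE_SCHEME[source]
    if source == "clinvarlike":
        diseases = (["record_id", "name", "umls", "synonyms"],
                    [[f"CTD{i + 1:05d}", ct["name"], ct["umls"],
                      "|".join(ct["synonyms"])]
                     for i, ct in enumerate(universe.cancer_types)])
        vs_rows, as_rows = [], []
        for j, v in enumerate(mine):
            rid = f"RCV{v['index'] + 1:06d}"
            vs_rows.append([rid, v["gene"]["symbol"], v["gene"]["entrez"],
                            "GRCh37.p13", v["hgvs_g"], v["consequence"],
                            v["biomarker"], v["cancer_type"]["name"]])
            as_rows.append([f"SCV{v['index'] + 1:06d}", v["hgvs_g"],
                            v["cancer_type"]["name"], v["drug"]["name"],
                            v["effects"][source].capitalize(),
                            v["codes"][source]])
        return {
            "diseases": diseases,
            "variant_summary": (
                ["record_id", "gene_symbol", "entrez_id", "assembly",
                 "hgvs_g", "consequence", "biomarker", "disease_name"],
                vs_rows),
            "assertions": (
                ["record_id", "hgvs_g", "disease_name", "drug_name",
                 "response", "evidence_code"], as_rows),
        }
    if source == "civiclike":
        gene_rows = [[f"CGN{i + 1:05d}", g["symbol"], g["entrez"],
                      g["ensembl"], g["chromosome"]]
                     for i, g in enumerate(genes)]
        ev_rows = []
        for v in mine:
            rid = f"EID{v['index'] + 1:05d}"
            term = _term_for(rng, v["cancer_type"], config.synonym_rate,
                             synonym_usage, source, rid)
            ev_rows.append([rid, v["gene"]["symbol"], v["gene"]["entrez"],
                            v["hgvs_c"], v["hgvs_g"], term, v["biomarker"],
                            v["consequence"], v["drug"]["name"],
                            v["drug"]["drugbank"],
                            v["effects"][source].capitalize(),
                            v["codes"][source], ""])
        return {
            "genes": (["record_id", "symbol", "entrez_id", "ensembl_id",
                       "chromosome"], gene_rows),
            "evidence": (
                ["record_id", "gene", "entrez_id", "variant_hgvs", "hgvs_g",
                 "cancer_entity", "biomarker", "consequence", "drug",
                 "drugbank_id", "effect", "evidence_level", "pmids"],
                ev_rows),
        }
    # cosmiclike
    rows = []
    for v in mine:
        rid = f"COSM{v['index'] + 1:06d}"
        term = _term_for(rng, v["cancer_type"], config.synonym_rate,
                         synonym_usage, source, rid)
        rows.append([rid, v["gene"]["symbol"], v["gene"]["entrez"],
                     v["gene"]["chromosome"], v["hgvs_g"], v["consequence"],
                     term, v["biomarker"], v["drug"]["name"],
                     v["effects"][source].capitalize(), v["codes"][source]])
    return {
        "mutations": (
            ["record_id", "gene_name", "entrez", "chromosome", "hgvs_g",
             "consequence", "site", "biomarker", "drug", "effect_class",
             "andre_level"], rows),
    }


def _mapping_spec_for(source: str) -> dict:
    effect_recode = dict(_EFFECT_DIALECT)
    if source == "clinvarlike":
        return {"source": source, "tables": [
            {"target": "cancer_type", "file": "diseases",
             "record_id": "record_id",
             "synonyms": {"column": "synonyms", "separator": "|",
                          "terminology": "synthetic"},
             "fields": {"cancer_type_name": {"column": "name"},
                        "umls_id": {"column": "umls"}}},
            {"target": "gene", "file": "variant_summary",
             "record_id": "record_id",
             "fields": {"gene_name": {"column": "gene_symbol"},
                        "entrez_gene_id": {"column": "entrez_id"}}},
            {"target": "variant", "file": "variant_summary",
             "record_id": "record_id",
             "hgvs": {"column": "hgvs_g", "genome_version": "GRCh37.p13"}},
            {"target": "gene_variant", "file": "variant_summary",
             "record_id": "record_id",
             "gene": {"name_column": "gene_symbol"},
             "hgvs": {"column": "hgvs_g"},
             "fields": {"variant_consequence": {"column": "consequence"}}},
            {"target": "cancer_variant", "file": "variant_summary",
             "record_id": "record_id", "hgvs": {"column": "hgvs_g"},
             "cancer": {"term_column": "disease_name"},
             "fields": {"biomarker_class": {"column": "biomarker"}}},
            {"target": "drug", "file": "assertions",
             "record_id": "record_id",
             "fields": {"substance_name": {"column": "drug_name"}}},
            {"target": "cancer_variant_drug_effect", "file": "assertions",
             "record_id": "record_id", "hgvs": {"column": "hgvs_g"},
             "cancer": {"term_column": "disease_name"},
             "drug": {"name_column": "drug_name"},
             "evidence": {"scheme": "MDAnderson",
                          "level_column": "evidence_code"},
             "fields": {"effect": {"column": "response",
                                   "recode": effect_recode}}},
        ]}
    if source == "civiclike":
        return {"source": source, "tables": [
            {"target": "gene", "file": "genes", "record_id": "record_id",
             "fields": {"gene_name": {"column": "symbol"},
                        "chromosome": {"column": "chromosome"},
                        "entrez_gene_id": {"column": "entrez_id"},
                        "ensembl_gene_id": {"column": "ensembl_id"}}},
            {"target": "variant", "file": "evidence",
             "record_id": "record_id",
             "hgvs": {"column": "variant_hgvs", "level_g_ref": "hgvs_g",
                      "genome_version": "GRCh37.p13"}},
            {"target": "gene_variant", "file": "evidence",
             "record_id": "record_id", "gene": {"name_column": "gene"},
             "hgvs": {"column": "variant_hgvs", "level_g_ref": "hgvs_g"},
             "fields": {"variant_consequence": {"column": "consequence"}}},
            # the source's own "cancer_entity" column feeds the model's
            # cancer-type concept (a classic schema-level naming conflict)
            {"target": "cancer_variant", "file": "evidence",
             "record_id": "record_id",
             "hgvs": {"column": "variant_hgvs", "level_g_ref": "hgvs_g"},
             "cancer": {"term_column": "cancer_entity"},
             "fields": {"biomarker_class": {"column": "biomarker"}}},
            {"target": "drug", "file": "evidence", "record_id": "record_id",
             "fields": {"substance_name": {"column": "drug"},
                        "drugbank_id": {"column": "drugbank_id"}}},
            {"target": "cancer_variant_drug_effect", "file": "evidence",
             "record_id": "record_id",
             "hgvs": {"column": "variant_hgvs", "level_g_ref": "hgvs_g"},
             "cancer": {"term_column": "cancer_entity"},
             "drug": {"name_column": "drug"},
             "evidence": {"scheme": "CIViC",
                          "level_column": "evidence_level"},
             "fields": {"effect": {"column": "effect",
                                   "recode": effect_recode}}},
        ]}
    return {"source": source, "tables": [
        {"target": "gene", "file": "mutations", "record_id": "record_id",
         "fields": {"gene_name": {"column": "gene_name"},
                    "chromosome": {"column": "chromosome"},
                    "entrez_gene_id": {"column": "entrez"}}},
        {"target": "variant", "file": "mutations", "record_id": "record_id",
         "hgvs": {"column": "hgvs_g", "genome_version": "GRCh37.p13"}},
        {"target": "gene_variant", "file": "mutations",
         "record_id": "record_id", "gene": {"name_column": "gene_name"},
         "hgvs": {"column": "hgvs_g"},
         "fields": {"variant_consequence": {"column": "consequence"}}},
        {"target": "cancer_variant", "file": "mutations",
         "record_id": "record_id", "hgvs": {"column": "hgvs_g"},
         "cancer": {"term_column": "site"},
         "fields": {"biomarker_class": {"column": "biomarker"}}},
        {"target": "drug", "file": "mutations", "record_id": "record_id",
         "fields": {"substance_name": {"column": "drug"}}},
        {"target": "cancer_variant_drug_effect", "file": "mutations",
         "record_id": "record_id", "hgvs": {"column": "hgvs_g"},
         "cancer": {"term_column": "site"},
         "drug": {"name_column": "drug"},
         "evidence": {"scheme": "Andre", "level_column": "andre_level"},
         "fields": {"effect": {"column": "effect_class",
                               "recode": effect_recode}}},
    ]}


_DIALECTS = {
    "clinvarlike": {"delimiter": "\t", "compression": "gzip"},
    "civiclike": {"delimiter": ",", "compression": None},
    "cosmiclike": {"delimiter": "\t", "compression": "gzip"},
}


def _expected_counts(universe: _Universe) -> dict:
    effect_tuples = set()
    conflicts = []
    for v in universe.variants:
        tuples = {
            (v["hgvs_g"], v["drug"]["name"], v["effects"][s],
             _SOURCE_SCHEME[s], v["codes"][s])
            for s in v["carriers"]
        }
        effect_tuples |= tuples
        if len(set(v["effects"].values())) > 1:
            conflicts.append({
                "hgvs_g": v["hgvs_g"],
                "cancer_type": v["cancer_type"]["name"],
                "drug": v["drug"]["name"],
                "effects": {s: v["effects"][s] for s in v["carriers"]},
            })
    genes_used = {v["gene"]["symbol"] for v in universe.variants}
    civic = [v for v in universe.variants if "civiclike" in v["carriers"]]
    return {
        "genes": len(genes_used),
        "cancer_types": len(universe.cancer_types),
        "variants": len({v["hgvs_g"] for v in universe.variants}),
        "cancer_variants": len({(v["hgvs_g"], v["cancer_type"]["name"])
                                for v in universe.variants}),
        "effect_rows": len(effect_tuples),
        "conflicts": conflicts,
        "alias_groups": len({v["hgvs_g"] for v in civic}),
    }


def _write_release(universe: _Universe, config: GeneratorConfig,
                   out_dir: Path, version: str,
                   drift: Mapping[str, Any] | None = None,
                   ) -> GeneratedRelease:
    out = Path(out_dir)
    synonym_usage: list[dict] = []
    sources_manifest: dict[str, dict] = {}
    expected_diff = None
    for source in _SOURCES:
        tables = _render_source(universe, source, config, synonym_usage)
        if drift and drift.get("source") == source:
            expected_diff = _apply_drift(tables, drift)
        d = _DIALECTS[source]
        files, row_counts, declared = {}, {}, {}
        for logical, (header, rows) in tables.items():
            ext = ".csv" if d["delimiter"] == "," else ".tsv"
            if d["compression"] == "gzip":
                ext += ".gz"
            fname = f"{source}/{logical}{ext}"
            _write_delim(out / fname, header, rows, d["delimiter"],
                         compress=d["compression"] == "gzip")
            files[logical] = fname
            row_counts[logical] = len(rows)
            declared[logical] = list(header)
        spec = _mapping_spec_for(source)
        spec_name = f"{source}.mapping.yaml"
        (out / spec_name).write_text(yaml.safe_dump(spec, sort_keys=False),
                                     encoding="utf-8")
        sources_manifest[source] = {
            "dialect": d, "files": files, "row_counts": row_counts,
            "mapping_spec": spec_name, "declared_schema": declared,
            "scheme": _SOURCE_SCHEME[source],
        }
    manifest = {
        "kind": "synthetic",
        "version": version,
        "fictional": True,
        "config": {
            "seed": config.seed, "n_genes": config.n_genes,
            "n_variants": config.n_variants,
            "n_cancer_types": config.n_cancer_types,
            "n_drugs": config.n_drugs,
            "overlap_fraction": config.overlap_fraction,
            "conflict_rate": config.conflict_rate,
            "synonym_rate": config.synonym_rate,
        },
        "apply_order": list(_SOURCES),
        "sources": sources_manifest,
        "expected": {**_expected_counts(universe),
                     "synonym_usage": synonym_usage},
    }
    if drift:
        manifest["drift"] = dict(drift)
        manifest["expected_diff"] = expected_diff
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                       encoding="utf-8")
    return GeneratedRelease(out, manifest)


def generate_source_release(config: GeneratorConfig,
                            out_dir: str | Path) -> GeneratedRelease:
    """Emit one three-dialect release plus its ground-truth manifest."""
    config.validate()
    universe = _build_universe(config)
    return _write_release(universe, config, Path(out_dir), "v1")


_DRIFT_OPS = ("add-column", "rename-column", "reorder", "remove-column")


def _apply_drift(tables: dict, drift: Mapping[str, Any]) -> dict:
    op = drift.get("op")
    logical = drift.get("file")
    if op not in _DRIFT_OPS:
        raise ValueError(f"unknown drift op {op!r}; known: {_DRIFT_OPS}")
    if logical not in tables:
        raise ValueError(f"drift names unknown file {logical!r}")
    header, rows = tables[logical]
    header = list(header)
    if op == "add-column":
        name = drift.get("column", "extra_annotation")
        header.append(name)
        rows = [list(r) + [""] for r in rows]
        expected = {"added": [name], "removed": [],
                    "renamed_candidates": [], "reordered": []}
    elif op == "remove-column":
        name = drift.get("column", header[-1])
        idx = header.index(name)
        header.pop(idx)
        rows = [[c for i, c in enumerate(r) if i != idx] for r in rows]
        expected = {"added": [], "removed": [name],
                    "renamed_candidates": [], "reordered": []}
    elif op == "rename-column":
        name = drift.get("column", header[-1])
        new = drift.get("new_name", name + "_renamed")
        idx = header.index(name)
        header[idx] = new
        rows = [list(r) for r in rows]
        expected = {"added": [], "removed": [],
                    "renamed_candidates": [[name, new]], "reordered": []}
    else:  # reorder: move the first column to the end
        header = header[1:] + header[:1]
        rows = [list(r[1:]) + [r[0]] for r in rows]
        expected = {"added": [], "removed": [], "renamed_candidates": [],
                    "reordered": "nonempty"}
    tables[logical] = (header, rows)
    return expected


def generate_drifted_release(manifest: Mapping[str, Any],
                             drift: Mapping[str, Any],
                             out_dir: str | Path) -> GeneratedRelease:
    """Regenerate the release of ``manifest`` with one structural drift.

    ``drift`` names a source, a logical file and an operation among
    ``add-column``, ``rename-column``, ``reorder``, ``remove-column``. The
    data content is identical to the prior release (same seed), only the
    named file's structure changes; the new manifest records the expected
    structure-diff output.
    """
    cfg = GeneratorConfig(**manifest["config"])
    universe = _build_universe(cfg)
    version = "v" + str(int(manifest["version"].lstrip("v")) + 1)
    return _write_release(universe, cfg, Path(out_dir), version, drift)


# ---------------------------------------------------------------------------
# Pipeline orchestration over a generated directory
# ---------------------------------------------------------------------------


def integrate_release(store: VariantStore, release: GeneratedRelease,
                      accept_structure_change: bool = False,
                      ) -> dict[str, mapping_mod.LoadReport]:
    """Register, ingest, activate and map every source of one release.

    Returns the per-source load reports. Sources are applied in the
    manifest's order (the terminology-carrying source first, so synonym-only
    disease mentions in later sources resolve).
    """
    manifest = release.manifest
    reports: dict[str, mapping_mod.LoadReport] = {}
    for source in manifest["apply_order"]:
        entry = manifest["sources"][source]
        d = entry["dialect"]
        desc = staging.SourceDescriptor(
            source,
            staging.Dialect(delimiter=d["delimiter"],
                            compression=d.get("compression")),
            tuple(entry["files"]),
            {k: tuple(v) for k, v in entry["declared_schema"].items()})
        if source not in staging.list_sources(store):
            staging.register_source(store, desc)
        files = {logical: release.out_dir / fname
                 for logical, fname in entry["files"].items()}
        staging.ingest_release(store, source, files, manifest["version"],
                               accept_structure_change=accept_structure_change)
        staging.swap_active_release(store, source, manifest["version"])
        spec = mapping_mod.load_mapping_spec(
            (release.out_dir / entry["mapping_spec"]).read_text("utf-8"))
        reports[source] = mapping_mod.apply_mapping(store, spec)
    return reports
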