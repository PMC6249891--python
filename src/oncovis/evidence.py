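"""Registry of published evidence-level schemes and their harmonization.

Variant–drug–cancer associations are annotated with strength-of-evidence
levels, but every knowledgebase grades on its own scale: CIViC uses five
letter levels, the MVLD working group (Ritter et al.) four tiers, OncoKB four
narrative categories, the MD Anderson precision-therapy scale six codes, and
Andre et al. ten. All of them agree at the macro level — a shared ladder from
validated human-medicine associations (A) down to purely inferential ones (E)
— while differing in the depth of their sub-leveling.

The registry pins each source level to the macro row it occupies on that
shared ladder, so mapping any (scheme, level) to a macro letter is exact and
total. A *sublevel* on the harmonized 1A–4B scale is assigned only when the
source level occupies exactly one sublevel row; where a source level spans
several sublevels the system leaves the sublevel undefined rather than
inventing precision that would require clinical literature review.

Macro strength ordering is A > B > C > D > E (top of the ladder strongest).
Within a macro, two assignments compare by sublevel row order; a defined
sublevel is incomparable with an undefined one.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

from .schema import MACRO_LEVELS, MACRO_OF_SUBLEVEL, SUBLEVELS

__all__ = [
    "EvidenceScheme",
    "SchemeLevel",
    "EvidenceLevelAssignment",
    "UnknownLevelError",
    "load_scheme_registry",
    "harmonize_level",
    "compare_evidence",
    "MACRO_SPAN",
    "MACRO_TIER_LABEL",
]

#: sublevel rows contained in each macro row of the harmonized scale
MACRO_SPAN: Mapping[str, tuple[str, ...]] = MappingProxyType({
    "A": ("1A", "1B", "1C"),
    "B": ("2A", "2B", "2C"),
    "C": ("3A",),
    "D": ("3B",),
    "E": ("4A", "4B"),
})

#: tier labels printed on the macro rows; macro B carries no tier of its own
#: (the four-tier scale groups it with the clinical-evidence block, see the
#: interpretation module's default relevance rule)
MACRO_TIER_LABEL: Mapping[str, str | None] = MappingProxyType({
    "A": "Tier 1", "B": None, "C": "Tier 2", "D": "Tier 3", "E": "Tier 4",
})


class UnknownLevelError(KeyError):
    """Unknown scheme or level code; lists the valid codes."""


@dataclass(frozen=True)
class SchemeLevel:
    code: str
    macro: str
    sublevels: tuple[str, ...]  # sublevel rows this source level occupies
    description: str


@dataclass(frozen=True)
class EvidenceScheme:
    scheme_name: str
    levels: tuple[SchemeLevel, ...]

    def level(self, code: str) -> SchemeLevel:
        for lv in self.levels:
            if lv.code == code:
                return lv
        raise UnknownLevelError(
            f"scheme {self.scheme_name!r} has no level {code!r}; valid: "
            f"{[lv.code for lv in self.levels]}")


@dataclass(frozen=True)
class EvidenceLevelAssignment:
    """A source (scheme, level) pair with its harmonized macro and sublevel."""

    scheme_name: str
    source_level_code: str
    macro: str
    sublevel: str | None
    mapping_basis: str  # "table-row" | "undefined"


def _lv(code: str, span: tuple[str, ...], description: str) -> SchemeLevel:
    macros = {MACRO_OF_SUBLEVEL[s] for s in span}
    assert len(macros) == 1, span
    return SchemeLevel(code, macros.pop(), span, description)


_CIVIC = (
    _lv("A", MACRO_SPAN["A"], "Validated association - proven/consensus "
        "association in human medicine"),
    _lv("B", MACRO_SPAN["B"], "Clinical evidence - clinical trial or other "
        "primary patient data supports association"),
    _lv("C", MACRO_SPAN["C"], "Case study - individual case reports from "
        "clinical journals"),
    _lv("D", MACRO_SPAN["D"], "Preclinical evidence - in vivo or in vitro "
        "models support association"),
    _lv("E", MACRO_SPAN["E"], "Inferential association - indirect evidence"),
)

_RITTER = (
    _lv("Tier 1", MACRO_SPAN["A"], "Validated association"),
    _lv("Tier 2", MACRO_SPAN["C"], "Case study"),
    _lv("Tier 3", MACRO_SPAN["D"], "Preclinical evidence"),
    _lv("Tier 4", MACRO_SPAN["E"], "Inferential association"),
)

# OncoKB prints no level codes on the comparison ladder; its four cells are
# keyed by the macro row they occupy.
_ONCOKB = (
    _lv("A", MACRO_SPAN["A"], "Alteration has matching FDA approved or NCCN "
        "recommended therapy"),
    _lv("C", MACRO_SPAN["C"], "Alteration has matching therapy based on "
        "evidence from clinical trials, case reports, or exceptional "
        "responders"),
    _lv("D", MACRO_SPAN["D"], "Alteration predicts for response or resistance "
        "to therapy based on evidence from pre-clinical data (in vitro or "
        "in vivo models)"),
    _lv("E", MACRO_SPAN["E"], "Alteration is a putative oncogenic driver "
        "based on functional activation of a pathway"),
)

_MDANDERSON = (
    _lv("1A", ("1A",), "FDA-approved biomarker and drug in this indication"),
    _lv("1B", ("1B",), "An adequately-powered, prospective study with "
        "biomarker selection/stratification, or a meta-analysis/overview "
        "demonstrates a biomarker predicts tumor response to a drug or that "
        "the drug is clinically effective in a biomarker-selected cohort in "
        "the same tumor type"),
    _lv("2A", ("2A",), "Standard-of-care biomarker and drug in this "
        "indication but not FDA-approved"),
    _lv("2B", ("2B",), "FDA-approved biomarker and drug in another "
        "indication, but not FDA or NCCN compendium-listed for this "
        "indication"),
    _lv("3A", ("3A",), "Clinical evidence links biomarker to drug response "
        "in this indication but neither biomarker or drug are FDA-approved "
        "or NCCN compendium-listed"),
    _lv("3B", ("3B",), "Clinical evidence links biomarker to drug response "
        "in another indication but neither biomarker or drug are "
        "FDA-approved or NCCN compendium-listed"),
)

_ANDRE = (
    _lv("1A", ("1A",), "Molecular alteration validated in several robust "
        "early phase trials or at least one phase III randomized trial; "
        "alteration validated in the disease under consideration, targeted "
        "therapies shown to be ineffective in patients lacking the genomic "
        "alteration"),
    _lv("1B", ("1B",), "Molecular alteration validated in several robust "
        "early phase trials or at least one phase III randomized trial; no "
        "evidence that the therapy does not work in the absence of the "
        "molecular alteration"),
    _lv("1C", ("1C",), "Molecular alteration validated in several robust "
        "early phase trials or at least one phase III randomized trial; "
        "level I molecular alteration, but not in the disease under "
        "consideration"),
    _lv("2A", ("2A",), "Efficacy of targeting molecular alteration suggested "
        "in single and underpowered phase I/II trials; alteration validated "
        "in the disease under consideration, targeted therapies shown to be "
        "ineffective in patients lacking the genomic alteration"),
    _lv("2B", ("2B",), "Efficacy of targeting molecular alteration suggested "
        "in single and underpowered phase I/II trials; no evidence that the "
        "therapy does not work in the absence of the molecular alteration"),
    _lv("2C", ("2C",), "Efficacy of targeting molecular alteration suggested "
        "in single and underpowered phase I/II trials; level I molecular "
        "alteration, but not in the disease under consideration, or "
        "anecdotal evidence of response in single patient case reports"),
    _lv("3A", ("3A",), "Target suggested by preclinical studies; preclinical "
        "studies include human samples, cell lines and animal models"),
    _lv("3B", ("3B",), "Target suggested by preclinical studies; preclinical "
        "studies that lack either cell lines or animal models"),
    _lv("4A", ("4A",), "Target predicted but lack of clinical or preclinical "
        "data; genomic alteration is a known cancer-related gene"),
    _lv("4B", ("4B",), "Target predicted but lack of clinical or preclinical "
        "data; genomic alteration is not known as cancer-related gene"),
)

_PROPOSED = (
    _lv("1A", ("1A",), "Drug is FDA-approved for the same tumor type "
        "harboring a specific biomarker"),
    _lv("1B", ("1B",), "An adequately-powered, prospective study with "
        "biomarker selection/stratification, or a meta-analysis/overview "
        "demonstrates a biomarker predicts tumor response to a drug or that "
        "the drug is clinically effective in a biomarker-selected cohort in "
        "the same tumor type"),
    _lv("1C", ("1C",), "Validated molecular alteration, but not in the "
        "disease under consideration"),
    _lv("2A", ("2A",), "Large-scale retrospective study demonstrates a "
        "biomarker is associated with tumor response to the drug in the same "
        "tumor type"),
    _lv("2B", ("2B",), "Clinical data (analogue 1A-2A) that the biomarker "
        "predicts tumor response to drug in a different tumor type"),
    _lv("2C", ("2C",), "Single unusual responder (or case study) shows a "
        "biomarker is associated with response to drug, supported by "
        "scientific rationale"),
    _lv("3A", ("3A",), "Preclinical data (in vitro or in vivo models and "
        "functional genomics) demonstrates that a biomarker predicts "
        "response of cells to drug treatment in the same tumor type"),
    _lv("3B", ("3B",), "Preclinical data (in vitro or in vivo models and "
        "functional genomics) demonstrates that a biomarker predicts "
        "response of cells to drug treatment in a different tumor type"),
    _lv("4A", ("4A",), "Inferential association between biomarker and "
        "treatment response"),
    _lv("4B", ("4B",), "Inferential association; genomic alteration is not "
        "known as cancer-related"),
)

_REGISTRY: Mapping[str, EvidenceScheme] = MappingProxyType({
    "CIViC": EvidenceScheme("CIViC", _CIVIC),
    "Ritter": EvidenceScheme("Ritter", _RITTER),
    "OncoKB": EvidenceScheme("OncoKB", _ONCOKB),
    "MDAnderson": EvidenceScheme("MDAnderson", _MDANDERSON),
    "Andre": EvidenceScheme("Andre", _ANDRE),
    "Proposed": EvidenceScheme("Proposed", _PROPOSED),
})


def load_scheme_registry() -> Mapping[str, EvidenceScheme]:
    """The immutable scheme registry, keyed by scheme name."""
    return _REGISTRY


def harmonize_level(scheme_name: str, level_code: str) -> EvidenceLevelAssignment:
    """Map a source (scheme, level) onto the harmonized (macro, sublevel).

    The macro letter is always assigned; the sublevel only when the source
    level occupies exactly one sublevel row, else it stays undefined.
    """
    try:
        scheme = _REGISTRY[scheme_name]
    except KeyError:
        raise UnknownLevelError(
            f"unknown scheme {scheme_name!r}; valid: {sorted(_REGISTRY)}"
        ) from None
    lv = scheme.level(level_code)
    if len(lv.sublevels) == 1:
        return EvidenceLevelAssignment(scheme_name, level_code, lv.macro,
                                       lv.sublevels[0], "table-row")
    return EvidenceLevelAssignment(scheme_name, level_code, lv.macro,
                                   None, "undefined")


def compare_evidence(a: EvidenceLevelAssignment,
                     b: EvidenceLevelAssignment) -> str:
    """Compare two harmonized assignments by strength.

    Returns ``"stronger"`` / ``"weaker"`` (a relative to b), ``"equal"``, or
    ``"incomparable"`` when equal macros differ only in an undefined sublevel.
    """
    ia, ib = MACRO_LEVELS.index(a.macro), MACRO_LEVELS.index(b.macro)
    if ia < ib:
        return "stronger"
    if ia > ib:
        return "weaker"
    if a.sublevel == b.sublevel:
        return "equal"
    if a.sublevel is None or b.sublevel is None:
        return "incomparable"
    return ("stronger" if SUBLEVELS.index(a.sublevel) < SUBLEVELS.index(b.sublevel)
            else "weaker")
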