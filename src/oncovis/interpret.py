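"""Molecular risk scores and request-time clinical relevance.

Risk scores from in-silico impact predictors (SIFT, PolyPhen, FATHMM, ...)
frequently disagree, so the store keeps *every* assessment and this module
only classifies their concordance — it never averages or discards scores.
Each algorithm is registered with its scale, the pole at which it calls a
variant deleterious, and a configurable binarization threshold:

* SIFT: scale [0, 1], 0 = deleterious, 1 = tolerated; deleterious when
  score < 0.05 (the algorithm's conventional cutoff).
* PolyPhen: scale [0, 1], 0 = benign, 1 = probably damaging; damaging when
  score > 0.85 (the "probably damaging" cutoff).
* FATHMM (0–1 scaled variant): damaging when score > 0.5.

The thresholds are configuration, not biology: the scales only define the
poles, and users may re-register an algorithm with their preferred cutoff.

The clinical relevance tier of a cancer variant is never stored. It is a pure
function evaluated against the current store state on every request, because
its inputs (drug approvals, evidence levels) change upstream and a cached
tier would silently go stale. The default rule follows the four-tier
AMP-style ladder printed beside the macro evidence levels: best macro A →
Tier 1, C → Tier 2, D → Tier 3, E → Tier 4. Macro B carries no tier label of
its own on that ladder; the default rule groups it with the clinical-evidence
block as Tier 1. With no drug-effect evidence at all the default rule yields
Tier 3 (variant of unknown clinical significance) and flags the derivation
as low-information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .evidence import EvidenceLevelAssignment, compare_evidence
from .schema import Lineage, ValidationError, VariantStore

__all__ = [
    "RiskScoreAlgorithm",
    "RiskScoreSet",
    "RelevanceRule",
    "DEFAULT_ALGORITHMS",
    "register_algorithm",
    "record_risk_scores",
    "classify_concordance",
    "default_relevance_rule",
    "derive_clinical_relevance",
]


@dataclass(frozen=True)
class RiskScoreAlgorithm:
    """An impact predictor's scale and deleterious-call configuration."""

    name: str
    scale_min: float
    scale_max: float
    deleterious_pole: str  # "low" | "high"
    deleterious_threshold: float

    def in_scale(self, score: float) -> bool:
        return self.scale_min <= score <= self.scale_max

    def is_deleterious(self, score: float) -> bool:
        if self.deleterious_pole == "low":
            return score < self.deleterious_threshold
        return score > self.deleterious_threshold


DEFAULT_ALGORITHMS: dict[str, RiskScoreAlgorithm] = {
    "SIFT": RiskScoreAlgorithm("SIFT", 0.0, 1.0, "low", 0.05),
    "PolyPhen": RiskScoreAlgorithm("PolyPhen", 0.0, 1.0, "high", 0.85),
    "FATHMM": RiskScoreAlgorithm("FATHMM", 0.0, 1.0, "high", 0.5),
}


def register_algorithm(algorithm: RiskScoreAlgorithm,
                       registry: dict[str, RiskScoreAlgorithm] | None = None,
                       ) -> None:
    """Add (or replace) an algorithm in the open registry."""
    (DEFAULT_ALGORITHMS if registry is None else registry)[algorithm.name] = \
        algorithm


@dataclass
class RiskScoreSet:
    """All retained score entries for one gene-variant-transcript context."""

    gene_id: str
    transcript_id: str
    variant_id: str | None
    entries: list[tuple[str, float]] = field(default_factory=list)
    under_determined: bool = False  # fewer than two independent algorithms


def record_risk_scores(store: VariantStore, gene_id: str, transcript_id: str,
                       variant_id: str | None,
                       entries: Sequence[tuple[str, float]],
                       lineage: Lineage,
                       registry: Mapping[str, RiskScoreAlgorithm] | None = None,
                       ) -> RiskScoreSet:
    """Store score entries with lineage, flagging under-determined sets.

    Each entry is ``(algorithm_name, score)``; unknown algorithms and
    out-of-scale scores are rejected. A warning flag is set when fewer than
    two distinct algorithms contributed, since a single predictor is not an
    independent assessment.
    """
    reg = DEFAULT_ALGORITHMS if registry is None else registry
    for name, score in entries:
        if name not in reg:
            raise ValidationError(
                f"risk score algorithm {name!r} is not registered; known: "
                f"{sorted(reg)}")
        algo = reg[name]
        if not algo.in_scale(float(score)):
            raise ValidationError(
                f"{name} score {score} outside scale "
                f"[{algo.scale_min}, {algo.scale_max}]")
    out = RiskScoreSet(gene_id, transcript_id, variant_id)
    for name, score in entries:
        store.insert_fact("risk_score", {
            "gene_id": gene_id, "transcript_id": transcript_id,
            "variant_id": variant_id, "algorithm": name,
            "score": float(score)}, lineage)
        out.entries.append((name, float(score)))
    out.under_determined = len({n for n, _ in out.entries}) < 2
    return out


def classify_concordance(entries: Iterable[tuple[str, float]] | RiskScoreSet,
                         registry: Mapping[str, RiskScoreAlgorithm] | None = None,
                         ) -> str:
    """Classify a score set's agreement after per-algorithm binarization.

    Returns one of ``concordant-deleterious``, ``concordant-benign``,
    ``discordant``, ``under-determined``. Raw scores are untouched — the
    classification is display metadata beside them, never a replacement.
    Order of entries is irrelevant.
    """
    reg = DEFAULT_ALGORITHMS if registry is None else registry
    if isinstance(entries, RiskScoreSet):
        entries = entries.entries
    calls: dict[str, bool] = {}
    for name, score in entries:
        calls[name] = reg[name].is_deleterious(float(score))
    if len(calls) < 2:
        return "under-determined"
    votes = set(calls.values())
    if votes == {True}:
        return "concordant-deleterious"
    if votes == {False}:
        return "concordant-benign"
    return "discordant"


# ---------------------------------------------------------------------------
# Clinical relevance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelevanceRule:
    """A pure, total mapping from evidence context to a clinical tier.

    ``function`` receives ``(biomarker_class, best_assignment_or_None)`` and
    must return one of "Tier 1" .. "Tier 4". Rules never mutate the store.
    """

    name: str
    function: Callable[[str, EvidenceLevelAssignment | None], str]
    version: str = "1"


#: best macro letter -> tier of the default rule; macro B is grouped with
#: Tier 1 (clinical-evidence block), documented prominently above.
DEFAULT_MACRO_TIER = {
    "A": "Tier 1", "B": "Tier 1", "C": "Tier 2", "D": "Tier 3", "E": "Tier 4",
}


def _default_rule_fn(biomarker_class: str,
                     best: EvidenceLevelAssignment | None) -> str:
    if best is None:
        return "Tier 3"
    return DEFAULT_MACRO_TIER[best.macro]


default_relevance_rule = RelevanceRule("macro-ladder-default", _default_rule_fn)

RULES: dict[str, RelevanceRule] = {
    default_relevance_rule.name: default_relevance_rule,
}


def _best_assignment(assignments: Sequence[EvidenceLevelAssignment],
                     ) -> EvidenceLevelAssignment | None:
    best = None
    for a in assignments:
        if best is None or compare_evidence(a, best) == "stronger":
            best = a
    return best


def derive_clinical_relevance(store: VariantStore, cancer_variant_id: str,
                              rule: RelevanceRule = default_relevance_rule,
                              ) -> tuple[str, dict]:
    """Derive the tier for one cancer variant from the current store state.

    Never cached: every call re-reads the effect rows, so an evidence change
    is reflected on the next request with no invalidation step. Returns
    ``(tier, explanation)`` where the explanation lists every contributing
    effect row with its original and harmonized levels.
    """
    cv = store.fetch_one("cancer_variant", cancer_variant_id=cancer_variant_id)
    if cv is None:
        raise KeyError(f"unknown cancer variant {cancer_variant_id!r}")
    rows = store.fetch("cancer_variant_drug_effect",
                       cancer_variant_id=cancer_variant_id)
    assignments: list[EvidenceLevelAssignment] = []
    contributing: list[dict] = []
    for row in rows:
        a = EvidenceLevelAssignment(
            row["source_scheme"] or "Proposed",
            row["source_level_code"] or row["evidence_level"],
            row["evidence_level"], row["evidence_sublevel"],
            "table-row" if row["evidence_sublevel"] else "undefined")
        assignments.append(a)
        contributing.append({
            "drug_id": row["drug_id"],
            "effect": row["effect"],
            "evidence_level": row["evidence_level"],
            "evidence_sublevel": row["evidence_sublevel"],
            "source_scheme": row["source_scheme"],
            "source_level_code": row["source_level_code"],
            "lineage": store.lineage_of("cancer_variant_drug_effect",
                                        row["fact_uid"]),
        })
    best = _best_assignment(assignments)
    tier = rule.function(cv["biomarker_class"], best)
    explanation = {
        "rule": rule.name,
        "rule_version": rule.version,
        "cancer_variant_id": cancer_variant_id,
        "biomarker_class": cv["biomarker_class"],
        "best_evidence": None if best is None else {
            "macro": best.macro, "sublevel": best.sublevel},
        "low_information": best is None,
        "contributing_effects": contributing,
        "tier": tier,
    }
    return tier, explanation
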