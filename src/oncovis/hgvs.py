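"""HGVS string parsing, canonical genomic identity, and alias grouping.

Source databases name the same sequence change at different levels — genomic
(g.), coding DNA (c.), RNA (r.), protein (p.), mitochondrial (m.) or
non-coding (n.) — and against different reference sequences, so even a
complete HGVS string is ambiguous across overlapping genes and transcript
isoforms. The genomic-level description is the only one that depends solely on
the assembly, so variant identity here is the *genomic key*
(assembly, contig accession, position, ref, alt); transcript- and
protein-level spellings are treated as aliases and grouped under that key via
the cross-references the sources themselves supply. No computational
projection from c. to g. is attempted: that would require a transcript
annotation dataset, and source-supplied cross-references to a single
authoritative genomic description are both sufficient and safer.

Supported change kinds mirror the core model's variant types: substitution
(SNV/MNV), insertion, deletion and deletion-insertion. Other HGVS constructs
(duplication, inversion, frameshift, repeats, ...) raise
:class:`UnsupportedHgvsError` rather than being silently misread.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "HgvsDescriptor",
    "GenomicKey",
    "AliasGroup",
    "AliasRecord",
    "HgvsParseError",
    "UnsupportedHgvsError",
    "CrossReferenceConflictError",
    "parse_hgvs",
    "format_hgvs",
    "canonical_key",
    "group_aliases",
]

LEVELS = ("g", "c", "r", "p", "m", "n")

#: mitochondrial reference accession; descriptions against it are level "m"
#: even where a source writes another level letter (the nomenclature reuses
#: letters ambiguously for mitochondria)
MITO_ACCESSION_PREFIX = "NC_012920"

AMINO3 = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    "Ter",
)

_UNSUPPORTED_KEYWORDS = ("dup", "inv", "con", "ext", "fs", "=")


class HgvsParseError(ValueError):
    """Unparseable HGVS string; carries the offset of the first bad character."""

    def __init__(self, text: str, offset: int, reason: str):
        self.text = text
        self.offset = offset
        self.reason = reason
        super().__init__(f"cannot parse {text!r} at position {offset}: {reason}")


class UnsupportedHgvsError(ValueError):
    """Syntactically recognizable HGVS construct outside the supported subset."""


class CrossReferenceConflictError(ValueError):
    """One alias record points at two different genomic identities."""

    def __init__(self, record, candidates):
        self.record = record
        self.candidates = candidates
        super().__init__(
            f"conflicting genomic cross-references for {record!r}: {candidates}")


@dataclass(frozen=True)
class HgvsDescriptor:
    """One parsed HGVS description.

    ``position`` is the (1-based, fully closed) start coordinate;
    ``end_position`` is set for ranged changes (insertion anchors, multi-base
    deletions). ``raw`` preserves the input byte-exactly and does not take
    part in equality, so a descriptor parsed from a dialect spelling with
    stray whitespace compares equal to its canonical respelling.
    """

    accession: str
    level: str
    position: int
    ref_allele: str | None
    alt_allele: str | None
    change_kind: str  # substitution | insertion | deletion | delins
    end_position: int | None = None
    raw: str = field(default="", compare=False)


@dataclass(frozen=True)
class GenomicKey:
    """Canonical variant identity: assembly-scoped genomic coordinates."""

    genome_version: str
    contig_accession: str
    position: int
    ref_allele: str
    alt_allele: str


@dataclass
class AliasGroup:
    """All spellings of one genomic change, with the isoforms they live on."""

    key: GenomicKey
    aliases: list[HgvsDescriptor] = field(default_factory=list)
    transcripts: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class AliasRecord:
    """One source-supplied naming of a variant plus its genomic cross-reference.

    ``genomic_ref`` is the g-level HGVS string (or ``None``) the source links
    this spelling to; g-level records reference themselves implicitly.
    ``transcript`` is the isoform name the source associates with the spelling.
    """

    descriptor: HgvsDescriptor
    genomic_ref: str | None = None
    transcript: str | None = None
    source_record_id: str | None = None


_ACCESSION_RE = re.compile(r"[A-Za-z][A-Za-z0-9_.\-]*")
_NUC_RE = re.compile(r"[ACGTUacgtu]+")
_POS_RE = re.compile(r"\d+")


def parse_hgvs(text: str) -> HgvsDescriptor:
    """Parse an HGVS string into a descriptor.

    Whitespace around the substitution ``>`` is tolerated on input (source
    dialects print both ``C>G`` and ``C >G``) but never re-emitted. Errors
    report the offset of the first offending character; recognized but
    unsupported constructs raise :class:`UnsupportedHgvsError` instead.
    """
    if not text or not text.strip():
        raise HgvsParseError(text or "", 0, "empty string")
    raw = text
    colon = text.find(":")
    if colon < 0:
        raise HgvsParseError(raw, len(text), "missing ':' separator")
    accession = text[:colon].strip()
    m = _ACCESSION_RE.fullmatch(accession)
    if not m:
        raise HgvsParseError(raw, 0, "invalid reference accession")
    rest = text[colon + 1:]
    if len(rest) < 2 or rest[1] != ".":
        raise HgvsParseError(raw, colon + 2, "expected level letter and '.'")
    level = rest[0]
    if level not in LEVELS:
        raise HgvsParseError(raw, colon + 1,
                             f"level {level!r} not one of {LEVELS}")
    change = rest[2:].strip()
    offset0 = colon + 3
    if not change:
        raise HgvsParseError(raw, offset0, "empty change description")

    if _is_unsupported(change.lower()):
        raise UnsupportedHgvsError(
            f"{raw!r}: construct not in the supported subset "
            "(substitution, insertion, deletion, delins)")

    if level == "p":
        desc = _parse_protein_change(raw, accession, change, offset0)
    else:
        desc = _parse_nucleotide_change(raw, accession, level, change, offset0)
    if desc.accession.startswith(MITO_ACCESSION_PREFIX) and desc.level != "m":
        desc = HgvsDescriptor(desc.accession, "m", desc.position,
                              desc.ref_allele, desc.alt_allele,
                              desc.change_kind, desc.end_position, raw)
    return desc


def _is_unsupported(low: str) -> bool:
    if "delins" in low:
        return False
    return any(kw in low for kw in _UNSUPPORTED_KEYWORDS)


def _parse_pos_span(raw: str, change: str, offset0: int) -> tuple[int, int | None, str]:
    m = _POS_RE.match(change)
    if not m:
        raise HgvsParseError(raw, offset0, "expected a position integer")
    start = int(m.group())
    rest = change[m.end():]
    end = None
    if rest.startswith("_"):
        m2 = _POS_RE.match(rest[1:])
        if not m2:
            raise HgvsParseError(raw, offset0 + m.end() + 1,
                                 "expected an end position after '_'")
        end = int(m2.group())
        rest = rest[1 + m2.end():]
    if start < 1 or (end is not None and end < start):
        raise HgvsParseError(raw, offset0, "positions must be >= 1 and ordered")
    return start, end, rest


def _parse_nucleotide_change(raw: str, accession: str, level: str,
                             change: str, offset0: int) -> HgvsDescriptor:
    start, end, rest = _parse_pos_span(raw, change, offset0)
    tail = rest.strip()
    low = tail.lower()
    if low.startswith("delins"):
        seq = tail[6:].strip()
        if not _NUC_RE.fullmatch(seq):
            raise HgvsParseError(raw, offset0 + len(change) - len(seq),
                                 "delins requires an inserted sequence")
        return HgvsDescriptor(accession, level, start, None, seq.upper(),
                              "delins", end, raw)
    if low.startswith("del"):
        seq = tail[3:].strip() or None
        if seq is not None and not _NUC_RE.fullmatch(seq):
            raise HgvsParseError(raw, offset0 + len(change) - len(seq),
                                 "invalid deleted sequence")
        return HgvsDescriptor(accession, level, start,
                              seq.upper() if seq else None, None,
                              "deletion", end, raw)
    if low.startswith("ins"):
        if end is None or end != start + 1:
            raise HgvsParseError(
                raw, offset0, "insertion requires a flanking range start_end")
        seq = tail[3:].strip()
        if not _NUC_RE.fullmatch(seq):
            raise HgvsParseError(raw, offset0 + len(change) - len(seq),
                                 "insertion requires an inserted sequence")
        return HgvsDescriptor(accession, level, start, None, seq.upper(),
                              "insertion", end, raw)
    # substitution: ref '>' alt, optional spaces around '>' (dialect tolerance)
    m = re.fullmatch(
        r"([ACGTUacgtu]+)\s*>\s*([ACGTUacgtu]+)", tail)
    if not m:
        raise HgvsParseError(raw, offset0 + len(change) - len(tail),
                             "expected substitution 'REF>ALT'")
    ref, alt = m.group(1).upper(), m.group(2).upper()
    if len(ref) != len(alt):
        raise HgvsParseError(raw, offset0,
                             "substitution requires equal-length alleles")
    if end is not None:
        raise HgvsParseError(raw, offset0,
                             "substitution takes a single start position")
    return HgvsDescriptor(accession, level, start, ref, alt,
                          "substitution", None, raw)


_AA_ALT = "|".join(AMINO3)
_PROTEIN_SUB_RE = re.compile(rf"({_AA_ALT})(\d+)({_AA_ALT})")


def _parse_protein_change(raw: str, accession: str, change: str,
                          offset0: int) -> HgvsDescriptor:
    m = _PROTEIN_SUB_RE.fullmatch(change.strip())
    if not m:
        raise HgvsParseError(
            raw, offset0,
            "expected a protein substitution like 'Gly12Ala'")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if pos < 1:
        raise HgvsParseError(raw, offset0, "protein position must be >= 1")
    return HgvsDescriptor(accession, "p", pos, ref, alt,
                          "substitution", None, raw)


def format_hgvs(d: HgvsDescriptor) -> str:
    """Canonical spelling of a descriptor; ``parse_hgvs(format_hgvs(d)) == d``."""
    if d.level == "p":
        return f"{d.accession}:p.{d.ref_allele}{d.position}{d.alt_allele}"
    span = str(d.position) if d.end_position is None \
        else f"{d.position}_{d.end_position}"
    if d.change_kind == "substitution":
        return f"{d.accession}:{d.level}.{span}{d.ref_allele}>{d.alt_allele}"
    if d.change_kind == "insertion":
        return f"{d.accession}:{d.level}.{span}ins{d.alt_allele}"
    if d.change_kind == "deletion":
        return f"{d.accession}:{d.level}.{span}del{d.ref_allele or ''}"
    if d.change_kind == "delins":
        return f"{d.accession}:{d.level}.{span}delins{d.alt_allele}"
    raise ValueError(f"unknown change kind {d.change_kind!r}")


def canonical_key(d: HgvsDescriptor, assembly: str) -> GenomicKey:
    """Project a genomic-level descriptor onto its canonical identity.

    Only g-level descriptions qualify: they depend on the assembly alone,
    which is why they are preferred over transcript- or protein-scoped ones.
    """
    if d.level != "g":
        raise ValueError(
            f"canonical identity requires a genomic (g.) description, got "
            f"level {d.level!r}; resolve via an alias cross-reference instead")
    return GenomicKey(assembly, d.accession, d.position,
                      d.ref_allele or "", d.alt_allele or "")


def group_aliases(records: Iterable[AliasRecord], assembly: str = "GRCh37.p13",
                  ) -> tuple[list[AliasGroup], list[AliasRecord]]:
    """Partition alias records into one group per distinct genomic key.

    Every record lands in exactly one group, or in the returned ``unresolved``
    list when it carries no genomic cross-reference — records are never
    silently dropped. A g-level record that *also* carries a cross-reference
    to a different genomic change raises
    :class:`CrossReferenceConflictError`.
    """
    groups: dict[GenomicKey, AliasGroup] = {}
    unresolved: list[AliasRecord] = []
    for rec in records:
        candidates: list[GenomicKey] = []
        if rec.descriptor.level == "g":
            candidates.append(canonical_key(rec.descriptor, assembly))
        if rec.genomic_ref is not None:
            candidates.append(canonical_key(parse_hgvs(rec.genomic_ref),
                                            assembly))
        uniq = sorted(set(candidates),
                      key=lambda k: (k.contig_accession, k.position,
                                     k.ref_allele, k.alt_allele))
        if len(uniq) > 1:
            raise CrossReferenceConflictError(rec, uniq)
        if not uniq:
            unresolved.append(rec)
            continue
        key = uniq[0]
        group = groups.setdefault(key, AliasGroup(key))
        group.aliases.append(rec.descriptor)
        if rec.transcript:
            group.transcripts.add(rec.transcript)
    return list(groups.values()), unresolved
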