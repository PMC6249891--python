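"""HGVS parsing, canonical genomic identity and alias grouping."""

import re

import pytest
from hypothesis import given, strategies as st

from oncovis.hgvs import (AliasRecord, CrossReferenceConflictError,
                          GenomicKey, HgvsDescriptor, HgvsParseError,
                          UnsupportedHgvsError, canonical_key, format_hgvs,
                          group_aliases, parse_hgvs)
from oncovis.synth import WORKED_EXAMPLE_ALIASES, WORKED_EXAMPLE_G


class TestParse:
    def test_genomic_substitution(self):
        d = parse_hgvs("NC_000012.11:g.25398284C>G")
        assert (d.accession, d.level, d.position) == \
            ("NC_000012.11", "g", 25398284)
        assert (d.ref_allele, d.alt_allele) == ("C", "G")
        assert d.change_kind == "substitution"

    def test_coding_substitution_with_space_dialect(self):
        # some exports print a space before '>'
        d = parse_hgvs("NM_033360.3:c.35G >C")
        assert (d.accession, d.level, d.position) == ("NM_033360.3", "c", 35)
        assert (d.ref_allele, d.alt_allele) == ("G", "C")

    def test_protein_substitution(self):
        d = parse_hgvs("NP_203524.1:p.Gly12Ala")
        assert (d.level, d.position, d.ref_allele, d.alt_allele) == \
            ("p", 12, "Gly", "Ala")

    def test_insertion_with_flanking_range(self):
        d = parse_hgvs("NC_000001.1:g.100_101insA")
        assert d.change_kind == "insertion"
        assert (d.position, d.end_position, d.alt_allele) == (100, 101, "A")

    def test_deletion_range(self):
        d = parse_hgvs("NC_000001.1:g.100_102del")
        assert d.change_kind == "deletion"
        assert (d.position, d.end_position) == (100, 102)

    def test_delins(self):
        d = parse_hgvs("NC_000001.1:g.100_101delinsTT")
        assert d.change_kind == "delins"
        assert d.alt_allele == "TT"

    def test_mitochondrial_accession_forces_level_m(self):
        d = parse_hgvs("NC_012920.1:g.100A>G")
        assert d.level == "m"

    @pytest.mark.parametrize("bad", ["not-an-hgvs", "", "NM_1:z.5A>G",
                                     "NM_1:c.0A>G", "NM_1:c.5AA>G"])
    def test_parse_errors_carry_offset(self, bad):
        with pytest.raises(HgvsParseError) as exc:
            parse_hgvs(bad)
        assert exc.value.offset >= 0

    @pytest.mark.parametrize("text", [
        "NC_000001.1:g.100dupA", "NC_000001.1:g.100_200inv",
        "NP_000001.1:p.Gly12fs"])
    def test_unsupported_constructs_are_distinct_errors(self, text):
        with pytest.raises(UnsupportedHgvsError):
            parse_hgvs(text)


# independent decomposition of simple substitution strings, used as a
# reference oracle: a bare regex with no shared code with the parser
_ORACLE_SUB = re.compile(
    r"^(?P<acc>[A-Za-z][\w.]*):(?P<level>[a-z])\.(?P<pos>\d+)"
    r"(?P<ref>[A-Z]+)\s*>\s*(?P<alt>[A-Z]+)$")
_ORACLE_PROT = re.compile(
    r"^(?P<acc>[A-Za-z][\w.]*):p\.(?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)"
    r"(?P<alt>[A-Z][a-z]{2})$")


@pytest.mark.parametrize("text", [t for t, _ in WORKED_EXAMPLE_ALIASES])
def test_oracle_equivalence_on_alias_fixture(text):
    d = parse_hgvs(text)
    m = _ORACLE_PROT.match(text) or _ORACLE_SUB.match(text)
    assert m is not None, text
    g = m.groupdict()
    assert d.accession == g["acc"]
    assert d.position == int(g["pos"])
    assert d.ref_allele == g["ref"]
    assert d.alt_allele == g["alt"]
    if "level" in g:
        assert d.level == g["level"]


class TestFormat:
    def test_canonical_spelling_has_no_whitespace(self):
        d = parse_hgvs("NM_033360.3:c.35G >C")
        assert format_hgvs(d) == "NM_033360.3:c.35G>C"

    def test_worked_example_round_trip(self):
        d = parse_hgvs(WORKED_EXAMPLE_G)
        assert format_hgvs(d) == WORKED_EXAMPLE_G

    @pytest.mark.parametrize("text", [t for t, _ in WORKED_EXAMPLE_ALIASES])
    def test_parse_format_parse_identity_on_fixture(self, text):
        d = parse_hgvs(text)
        assert parse_hgvs(format_hgvs(d)) == d


_nuc = st.text("ACGT", min_size=1, max_size=3)
# the mitochondrial contig is excluded: the parser reclassifies it to level m
_acc = st.from_regex(r"N[CM]_[0-9]{6}\.[0-9]", fullmatch=True).filter(
    lambda a: not a.startswith("NC_012920"))
_pos = st.integers(min_value=1, max_value=10**8)


@st.composite
def descriptors(draw):
    kind = draw(st.sampled_from(
        ["substitution", "insertion", "deletion", "delins"]))
    acc = draw(_acc)
    level = draw(st.sampled_from(["g", "c", "n"]))
    pos = draw(_pos)
    if kind == "substitution":
        ref = draw(_nuc)
        alt = draw(st.text("ACGT", min_size=len(ref), max_size=len(ref)))
        return HgvsDescriptor(acc, level, pos, ref, alt, "substitution")
    if kind == "insertion":
        return HgvsDescriptor(acc, level, pos, None, draw(_nuc),
                              "insertion", pos + 1)
    delta = draw(st.integers(0, 5))
    end = pos + delta if delta else None
    if kind == "deletion":
        return HgvsDescriptor(acc, level, pos,
                              draw(_nuc) if end is None else None, None,
                              "deletion", end)
    return HgvsDescriptor(acc, level, pos, None, draw(_nuc), "delins", end)


@given(descriptors())
def test_format_parse_identity_property(d):
    """parse . format is the identity on the supported grammar subset."""
    assert parse_hgvs(format_hgvs(d)) == d


class TestCanonicalKey:
    def test_projects_genomic_descriptor(self):
        d = parse_hgvs(WORKED_EXAMPLE_G)
        key = canonical_key(d, "GRCh37.p13")
        assert key == GenomicKey("GRCh37.p13", "NC_000012.11", 25398284,
                                 "C", "G")

    def test_non_genomic_level_refused(self):
        with pytest.raises(ValueError, match="g\\."):
            canonical_key(parse_hgvs("NM_033360.3:c.35G>C"), "GRCh37.p13")

    def test_deterministic(self):
        d = parse_hgvs(WORKED_EXAMPLE_G)
        assert canonical_key(d, "X") == canonical_key(d, "X")


def _alias_records():
    return [AliasRecord(parse_hgvs(text),
                        None if transcript is None else WORKED_EXAMPLE_G,
                        transcript)
            for text, transcript in WORKED_EXAMPLE_ALIASES]


class TestGroupAliases:
    def test_alias_table_forms_one_group_four_isoforms(self):
        groups, unresolved = group_aliases(_alias_records())
        assert len(groups) == 1 and not unresolved
        assert len(groups[0].aliases) == len(WORKED_EXAMPLE_ALIASES)
        assert groups[0].transcripts == \
            {"KRAS-001", "KRAS-002", "KRAS-003", "KRAS-004"}

    def test_empty_input(self):
        assert group_aliases([]) == ([], [])

    def test_keys_differing_in_alt_split_groups(self):
        a = AliasRecord(parse_hgvs("NC_000001.1:g.5A>G"))
        b = AliasRecord(parse_hgvs("NC_000001.1:g.5A>T"))
        groups, _ = group_aliases([a, b])
        assert len(groups) == 2

    def test_record_without_cross_reference_goes_to_unresolved(self):
        rec = AliasRecord(parse_hgvs("NM_033360.3:c.35G>C"))
        groups, unresolved = group_aliases([rec])
        assert not groups and unresolved == [rec]

    def test_conflicting_cross_reference_raises_with_candidates(self):
        rec = AliasRecord(parse_hgvs("NC_000001.1:g.5A>G"),
                          "NC_000001.1:g.5A>T")
        with pytest.raises(CrossReferenceConflictError) as exc:
            group_aliases([rec])
        assert len(exc.value.candidates) == 2

    def test_grouping_is_a_partition(self):
        records = _alias_records() + [
            AliasRecord(parse_hgvs("NC_000001.1:g.5A>G")),
            AliasRecord(parse_hgvs("NM_000001.1:c.9A>G")),  # no cross-ref
        ]
        groups, unresolved = group_aliases(records)
        placed = sum(len(g.aliases) for g in groups) + len(unresolved)
        assert placed == len(records)
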