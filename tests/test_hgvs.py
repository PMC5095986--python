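"""Grammar-level HGVS parsing, serialization round-trips, and the
variant-type length rule checked against a brute-force oracle."""

import itertools

import pytest
from hypothesis import given, strategies as st

from mvld.hgvs import (
    HgvsParse,
    HgvsSyntaxError,
    Position,
    UnsupportedHgvsError,
    VariantTypeUndefined,
    check_dna_hgvs,
    check_protein_hgvs,
    infer_variant_type,
    parse_hgvs,
)


class TestDnaGrammar:
    def test_single_base_substitution(self):
        p = check_dna_hgvs("c.76A>T")
        assert (p.molecule, p.edit_kind) == ("c", "substitution")
        assert p.start == Position(76) and p.ref_allele == "A" and p.alt_allele == "T"

    def test_delins_with_range(self):
        p = check_dna_hgvs("c.76_78delinsTT")
        assert p.edit_kind == "delins"
        assert (p.start.value, p.end.value, p.alt_allele) == (76, 78, "TT")

    def test_intronic_offset_position(self):
        p = check_dna_hgvs("c.88+2T>G")
        assert p.start == Position(88, offset=2)

    @pytest.mark.parametrize("text", ["c.-14G>A", "c.*46T>A", "n.76A>T", "g.140753336A>T"])
    def test_utr_noncoding_and_genomic_forms(self, text):
        assert check_dna_hgvs(text).serialize() == text

    @pytest.mark.parametrize(
        "bad",
        [
            "76A>T",  # no molecule prefix
            "c.76A>",  # truncated edit
            "c..76A>T",  # malformed position
            "c.78_76del",  # end precedes start
            "c.76_78A>T",  # substitution over a range
            "c.76ins",  # insertion without sequence
            "c.76insA",  # insertion without flanking range
            "c.76_79insA",  # non-adjacent flanks
            "g.76+1A>T",  # intronic offset on a genomic molecule
            "p.V600E",  # protein given to the DNA checker
            "",
        ],
    )
    def test_malformed_dna_is_rejected(self, bad):
        with pytest.raises(HgvsSyntaxError):
            check_dna_hgvs(bad)

    @pytest.mark.parametrize("exotic", ["c.[76A>T];[77G>A]", "c.76A>T/77G>A", "c.76="])
    def test_exotic_constructs_get_a_distinct_error(self, exotic):
        with pytest.raises(UnsupportedHgvsError):
            check_dna_hgvs(exotic)


class TestProteinGrammar:
    def test_one_letter_substitution(self):
        p = check_protein_hgvs("p.V600E")
        assert (p.molecule, p.edit_kind) == ("p", "substitution")
        assert (p.start.value, p.ref_allele, p.alt_allele) == (600, "V", "E")

    def test_three_letter_equals_one_letter(self):
        assert check_protein_hgvs("p.Val600Glu") == check_protein_hgvs("p.V600E")

    def test_nonsense_silent_and_predicted_forms(self):
        assert check_protein_hgvs("p.R100*").alt_allele == "*"
        assert check_protein_hgvs("p.Arg100Ter").alt_allele == "*"
        assert check_protein_hgvs("p.V600=").alt_allele == "="
        assert check_protein_hgvs("p.(V600E)").predicted is True

    def test_frameshift_and_extension(self):
        fs = check_protein_hgvs("p.Val600Glyfs*12")
        assert (fs.edit_kind, fs.alt_allele, fs.terminus) == ("frameshift", "G", 12)
        assert check_protein_hgvs("p.V600fs").terminus is None
        ext = check_protein_hgvs("p.M1ext-5")
        assert (ext.edit_kind, ext.terminus) == ("extension", -5)

    @pytest.mark.parametrize("bad", ["V600E", "p.600VE", "p.Xyz600Glu", "p.V600", ""])
    def test_malformed_protein_is_rejected(self, bad):
        with pytest.raises(HgvsSyntaxError):
            check_protein_hgvs(bad)


# --------------------------------------------------------------------------
# round-trip: serialize(parse(s)) is canonical; parse(serialize(p)) == p

_CANONICAL = [
    "c.76A>T",
    "c.88+2T>G",
    "c.88-1G>A",
    "c.-14G>A",
    "c.*46T>A",
    "n.211del",
    "g.123456del",
    "c.76_78del",
    "c.76_78delAAT",
    "c.76dup",
    "c.76_78dupGGG",
    "c.76_77insG",
    "c.76_78delinsTT",
    "c.76delAinsGG",
    "p.V600E",
    "p.R100*",
    "p.V600=",
    "p.(V600E)",
    "p.V600fs",
    "p.V600Gfs*12",
    "p.M1ext-5",
    "p.K601del",
    "p.K601_L603del",
]


@pytest.mark.parametrize("text", _CANONICAL)
def test_roundtrip_on_canonical_forms(text):
    p = parse_hgvs(text)
    assert p.serialize() == text
    assert parse_hgvs(p.serialize()) == p


@pytest.mark.parametrize(
    "variant,canonical",
    [("p.Val600Glu", "p.V600E"), ("p.Arg100Ter", "p.R100*"), ("p.(Val600Glu)", "p.(V600E)")],
)
def test_noncanonical_inputs_serialize_to_canonical(variant, canonical):
    assert parse_hgvs(variant).serialize() == canonical


@given(st.text(max_size=30))
def test_parsing_is_total(text):
    """Arbitrary text either parses or raises the structured error; no crashes."""
    for checker in (check_dna_hgvs, check_protein_hgvs):
        try:
            result = checker(text)
        except HgvsSyntaxError:
            continue
        assert isinstance(result, HgvsParse)


@given(
    st.sampled_from("cn"),
    st.integers(1, 9999),
    st.sampled_from("ACGT"),
    st.sampled_from("ACGT"),
    st.integers(-10, 10),
)
def test_substitution_roundtrip_property(mol, pos, ref, alt, offset):
    off = f"{offset:+d}" if offset else ""
    text = f"{mol}.{pos}{off}{ref}>{alt}"
    p = check_dna_hgvs(text)
    assert p.serialize() == text and check_dna_hgvs(p.serialize()) == p


# --------------------------------------------------------------------------
# variant-type inference vs. the brute-force length-rule oracle


def length_rule(ref: str, alt: str) -> str:
    """Independent oracle: SNV for 1↔1, MNV for any other replacement,
    INS when nothing is removed, DEL when nothing is added."""
    if not ref:
        return "INS"
    if not alt:
        return "DEL"
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    return "MNV"


def _alleles(max_len: int):
    for n in range(max_len + 1):
        for combo in itertools.product("ACGT", repeat=n):
            yield "".join(combo)


def _to_hgvs(ref: str, alt: str, pos: int = 10) -> str:
    if ref and alt and len(ref) == 1 and len(alt) == 1:
        return f"c.{pos}{ref}>{alt}"
    if not ref:
        return f"c.{pos}_{pos + 1}ins{alt}"
    end = pos + len(ref) - 1
    span = f"{pos}" if len(ref) == 1 else f"{pos}_{end}"
    if not alt:
        return f"c.{span}del{ref}"
    return f"c.{span}del{ref}ins{alt}"


def test_variant_type_matches_length_oracle_exhaustively():
    checked = 0
    for ref in _alleles(3):
        for alt in _alleles(3):
            if not ref and not alt:
                continue
            got = infer_variant_type(check_dna_hgvs(_to_hgvs(ref, alt)))
            assert got == length_rule(ref, alt), (ref, alt)
            checked += 1
    assert checked == 85 * 85 - 1


@pytest.mark.parametrize(
    "text,expected",
    [
        ("c.76A>T", "SNV"),
        ("c.76_78delinsTT", "MNV"),
        ("c.76delinsT", "SNV"),  # single-base replacement in delins clothing
        ("c.76_77insG", "INS"),
        ("c.76dup", "INS"),  # a duplication adds bases
        ("c.76del", "DEL"),
    ],
)
def test_variant_type_examples(text, expected):
    assert infer_variant_type(check_dna_hgvs(text)) == expected


def test_variant_type_undefined_for_protein():
    with pytest.raises(VariantTypeUndefined):
        infer_variant_type(check_protein_hgvs("p.V600E"))
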