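"""Syntax-level validation of HGVS variant descriptions.

MVLD requires the DNA and protein change fields to be written in HGVS
nomenclature.  This module checks that requirement at the *grammar* level: a
string is parsed into a structured :class:`HgvsParse` or rejected with a
:class:`HgvsSyntaxError` naming the offending span.  No reference sequence,
transcript model or genome is ever consulted — whether ``c.76A>T`` really has
an ``A`` at position 76 is out of scope; whether it is well-formed HGVS is not.

Supported constructs
--------------------
DNA (``g.``, ``c.``, ``n.``): single-base substitution, deletion, duplication,
insertion and deletion-insertion, with 5'/3' UTR markers (``-``/``*``) and
intronic offsets (``88+2``) on coding/noncoding molecules.  Protein (``p.``):
substitutions in one- or three-letter code (including nonsense ``*`` and
silent ``=``), frameshifts, simple deletions and terminal extensions, with
the parenthesized "predicted" form.  Everything is normalized to one-letter
amino-acid code internally.

Deliberately *unsupported* HGVS (alleles in cis/trans, mosaicism, repeats,
uncertain positions) is rejected with a distinct "unsupported HGVS construct"
message rather than a generic parse failure.

Coordinates follow the HGVS convention: 1-based, fully closed intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Position",
    "HgvsParse",
    "HgvsSyntaxError",
    "UnsupportedHgvsError",
    "VariantTypeUndefined",
    "check_dna_hgvs",
    "check_protein_hgvs",
    "parse_hgvs",
    "infer_variant_type",
]


class HgvsSyntaxError(ValueError):
    """A string is not grammar-conforming HGVS; ``span`` is the offending part."""

    def __init__(self, message: str, span: str = ""):
        self.span = span
        super().__init__(f"{message}: {span!r}" if span else message)


class UnsupportedHgvsError(HgvsSyntaxError):
    """Grammatical HGVS outside the supported subset (alleles, repeats, ...)."""


class VariantTypeUndefined(ValueError):
    """Variant type (SNV/MNV/INS/DEL) is defined on DNA descriptions only."""


# one- and three-letter amino-acid codes; Ter/* is the stop codon
_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
_AA1 = set("ARNDCQEGHILKMFPSTWYV*")

_POS_RE = re.compile(r"^([-*]?)(\d+)([+-]\d+)?$")
_DNA_SPLIT_RE = re.compile(r"^([gcn])\.(.+)$")
_BASES = "ACGTN"

# characters that mark HGVS constructs outside the supported subset
_UNSUPPORTED_CHARS = set("[];,^/?(){}")


@dataclass(frozen=True, order=False)
class Position:
    """An HGVS sequence position.

    ``prefix`` is ``""`` (CDS/plain), ``"-"`` (5' UTR / upstream of the coding
    start) or ``"*"`` (3' UTR, downstream of the stop); ``offset`` is the
    intronic offset (``+2`` in ``88+2``), zero when absent.
    """

    value: int
    offset: int = 0
    prefix: str = ""

    def __post_init__(self) -> None:
        if self.value < 1:
            raise HgvsSyntaxError("position must be >= 1", str(self.value))
        if self.prefix not in ("", "-", "*"):
            raise HgvsSyntaxError("bad position prefix", self.prefix)

    @property
    def is_plain(self) -> bool:
        """True for an unadorned integer coordinate."""
        return self.offset == 0 and self.prefix == ""

    def __str__(self) -> str:
        s = f"{self.prefix}{self.value}"
        if self.offset:
            s += f"{self.offset:+d}"
        return s


def _parse_position(text: str) -> Position:
    m = _POS_RE.match(text)
    if not m:
        raise HgvsSyntaxError("malformed position", text)
    prefix, value, offset = m.groups()
    return Position(value=int(value), offset=int(offset) if offset else 0, prefix=prefix)


@dataclass(frozen=True)
class HgvsParse:
    """Structured result of the syntactic analysis of one HGVS description.

    ``ref_allele``/``alt_allele`` hold nucleotides for DNA parses and
    one-letter amino acids for protein parses (``end_ref`` carries the residue
    at the end of a protein range).  ``terminus`` records the new-stop
    distance of frameshifts (``fs*12``) and extensions (``ext*17`` /
    ``ext-5``); ``predicted`` marks the parenthesized protein form
    ``p.(V600E)``.
    """

    molecule: str  # "g" | "c" | "n" | "p"
    edit_kind: str  # substitution|deletion|duplication|insertion|delins|frameshift|extension
    start: Position
    end: Position | None = None
    ref_allele: str | None = None
    alt_allele: str | None = None
    end_ref: str | None = None
    terminus: int | None = None
    predicted: bool = field(default=False, compare=True)

    def __post_init__(self) -> None:
        if self.molecule == "g" and (not self.start.is_plain or (self.end and not self.end.is_plain)):
            raise HgvsSyntaxError(
                "genomic (g.) positions are plain integers; UTR/intronic markers "
                "apply to coding/noncoding molecules only",
                str(self.start),
            )
        if self.end is not None and self.start.is_plain and self.end.is_plain:
            if self.end.value < self.start.value:
                raise HgvsSyntaxError(
                    "end position precedes start", f"{self.start}_{self.end}"
                )

    # -- rendering -------------------------------------------------------

    def _span(self) -> str:
        if self.molecule == "p":
            s = f"{self.ref_allele}{self.start}"
            if self.end is not None:
                s += f"_{self.end_ref}{self.end}"
            return s
        s = str(self.start)
        if self.end is not None:
            s += f"_{self.end}"
        return s

    def serialize(self) -> str:
        """Render the canonical string form (one-letter protein code)."""
        if self.molecule == "p":
            body = self._serialize_protein()
            return f"p.({body})" if self.predicted else f"p.{body}"
        span = self._span()
        k = self.edit_kind
        if k == "substitution":
            return f"{self.molecule}.{span}{self.ref_allele}>{self.alt_allele}"
        if k == "deletion":
            return f"{self.molecule}.{span}del{self.ref_allele or ''}"
        if k == "duplication":
            return f"{self.molecule}.{span}dup{self.ref_allele or ''}"
        if k == "insertion":
            return f"{self.molecule}.{span}ins{self.alt_allele}"
        if k == "delins":
            mid = f"del{self.ref_allele}ins" if self.ref_allele else "delins"
            return f"{self.molecule}.{span}{mid}{self.alt_allele}"
        raise AssertionError(f"unrenderable edit kind {k!r}")

    def _serialize_protein(self) -> str:
        span = self._span()
        k = self.edit_kind
        if k == "substitution":
            return f"{span}{self.alt_allele}"
        if k == "deletion":
            return f"{span}del"
        if k == "frameshift":
            s = f"{span}{self.alt_allele or ''}fs"
            if self.terminus is not None:
                s += f"*{self.terminus}"
            return s
        if k == "extension":
            s = f"{span}{self.alt_allele or ''}ext"
            if self.terminus is not None:
                s += str(self.terminus) if self.terminus < 0 else f"*{self.terminus}"
            return s
        raise AssertionError(f"unrenderable protein edit kind {k!r}")


def _reject_unsupported(body: str, original: str) -> None:
    found = sorted(_UNSUPPORTED_CHARS & set(body))
    if found:
        raise UnsupportedHgvsError(
            "unsupported HGVS construct (alleles/mosaic/uncertain/repeat notation "
            "is outside the supported subset)",
            original,
        )


def check_dna_hgvs(text: str) -> HgvsParse:
    """Validate a DNA-level (``g.``/``c.``/``n.``) HGVS description.

    Returns the structured parse; raises :class:`HgvsSyntaxError` (or its
    :class:`UnsupportedHgvsError` subclass) otherwise.  Syntax only — no
    sequence is consulted.
    """
    if not isinstance(text, str) or not text.strip():
        raise HgvsSyntaxError("empty HGVS description", text if isinstance(text, str) else repr(text))
    s = text.strip()
    if s.startswith("p."):
        raise HgvsSyntaxError("protein (p.) description given where DNA expected", s)
    m = _DNA_SPLIT_RE.match(s)
    if not m:
        raise HgvsSyntaxError(
            "missing or unknown molecule prefix (expected g., c. or n.)", s
        )
    molecule, body = m.groups()
    _reject_unsupported(body, s)
    if "=" in body:
        raise UnsupportedHgvsError("unsupported HGVS construct (identity assertion)", s)

    m = re.match(r"^([-*]?\d+(?:[+-]\d+)?)(?:_([-*]?\d+(?:[+-]\d+)?))?(.*)$", body)
    if not m or not m.group(3):
        raise HgvsSyntaxError("malformed position or missing edit", body)
    start = _parse_position(m.group(1))
    end = _parse_position(m.group(2)) if m.group(2) else None
    edit = m.group(3)

    if molecule == "g" and (not start.is_plain or (end and not end.is_plain)):
        raise HgvsSyntaxError("genomic (g.) positions are plain integers", body)

    sub = re.match(rf"^([{_BASES}])>([{_BASES}])$", edit)
    if sub:
        if end is not None:
            raise HgvsSyntaxError(
                "substitution applies to a single position, not a range", body
            )
        return HgvsParse(molecule, "substitution", start, None, sub.group(1), sub.group(2))

    m = re.match(rf"^del([{_BASES}]*)ins([{_BASES}]+)$", edit)
    if m:
        return HgvsParse(molecule, "delins", start, end, m.group(1) or None, m.group(2))
    m = re.match(rf"^del([{_BASES}]*)$", edit)
    if m:
        return HgvsParse(molecule, "deletion", start, end, m.group(1) or None, None)
    m = re.match(rf"^dup([{_BASES}]*)$", edit)
    if m:
        return HgvsParse(molecule, "duplication", start, end, m.group(1) or None, None)
    m = re.match(rf"^ins([{_BASES}]+)$", edit)
    if m:
        if end is None:
            raise HgvsSyntaxError(
                "insertion requires a two-position flanking range (e.g. 76_77ins)", body
            )
        if (
            start.is_plain
            and end.is_plain
            and end.value != start.value + 1
        ):
            raise HgvsSyntaxError(
                "insertion flanks must be adjacent positions", body
            )
        return HgvsParse(molecule, "insertion", start, end, None, m.group(1))
    if re.match(r"^(inv|con|fs|ext)", edit):
        raise UnsupportedHgvsError("unsupported HGVS construct", s)
    raise HgvsSyntaxError("malformed edit", edit)


def _parse_aa(token: str, context: str) -> str:
    """Amino-acid token (one- or three-letter, Ter/*) to one-letter code."""
    if token in _AA3_TO_1:
        return _AA3_TO_1[token]
    if token in _AA1:
        return token
    raise HgvsSyntaxError("unknown amino-acid code", f"{token} in {context}")


_AA_TOKEN = r"(?:Ter|[A-Z][a-z]{2}|[A-Z*])"


def check_protein_hgvs(text: str) -> HgvsParse:
    """Validate a protein-level (``p.``) HGVS description.

    Accepts one- and three-letter code (normalized to one-letter), nonsense
    (``*``/``Ter``), silent (``=``), frameshift, simple deletion, terminal
    extension and the parenthesized predicted form ``p.(V600E)``.
    """
    if not isinstance(text, str) or not text.strip():
        raise HgvsSyntaxError("empty HGVS description", text if isinstance(text, str) else repr(text))
    s = text.strip()
    if not s.startswith("p."):
        raise HgvsSyntaxError("missing protein molecule prefix (expected p.)", s)
    body = s[2:]
    predicted = False
    if body.startswith("(") and body.endswith(")"):
        predicted = True
        body = body[1:-1]
    _reject_unsupported(body, s)

    # frameshift: p.V600fs, p.Val600Glyfs*12, p.V600GfsTer12
    m = re.match(
        rf"^({_AA_TOKEN})(\d+)({_AA_TOKEN})?fs(?:(?:\*|Ter)(\d+))?$", body
    )
    if m:
        ref = _parse_aa(m.group(1), body)
        alt = _parse_aa(m.group(3), body) if m.group(3) else None
        return HgvsParse(
            "p", "frameshift", Position(int(m.group(2))),
            ref_allele=ref, alt_allele=alt,
            terminus=int(m.group(4)) if m.group(4) else None,
            predicted=predicted,
        )

    # extension: p.M1ext-5 (N-terminal), p.*110Qext*17 (C-terminal)
    m = re.match(
        rf"^({_AA_TOKEN})(\d+)({_AA_TOKEN})?ext(?:(-\d+)|(?:\*|Ter)(\d+))?$", body
    )
    if m:
        ref = _parse_aa(m.group(1), body)
        alt = _parse_aa(m.group(3), body) if m.group(3) else None
        terminus = int(m.group(4)) if m.group(4) else (int(m.group(5)) if m.group(5) else None)
        return HgvsParse(
            "p", "extension", Position(int(m.group(2))),
            ref_allele=ref, alt_allele=alt, terminus=terminus, predicted=predicted,
        )

    # deletion: p.K601del, p.K601_L603del
    m = re.match(rf"^({_AA_TOKEN})(\d+)(?:_({_AA_TOKEN})(\d+))?del$", body)
    if m:
        ref = _parse_aa(m.group(1), body)
        end_ref = _parse_aa(m.group(3), body) if m.group(3) else None
        return HgvsParse(
            "p", "deletion", Position(int(m.group(2))),
            end=Position(int(m.group(4))) if m.group(4) else None,
            ref_allele=ref, end_ref=end_ref, predicted=predicted,
        )

    # substitution: p.V600E, p.Val600Glu, p.R100*, p.V600=
    m = re.match(rf"^({_AA_TOKEN})(\d+)({_AA_TOKEN}|=)$", body)
    if m:
        ref = _parse_aa(m.group(1), body)
        alt = "=" if m.group(3) == "=" else _parse_aa(m.group(3), body)
        return HgvsParse(
            "p", "substitution", Position(int(m.group(2))),
            ref_allele=ref, alt_allele=alt, predicted=predicted,
        )

    raise HgvsSyntaxError("malformed protein description", body)


def parse_hgvs(text: str) -> HgvsParse:
    """Dispatch on the molecule prefix: ``p.`` → protein, else DNA."""
    if isinstance(text, str) and text.strip().startswith("p."):
        return check_protein_hgvs(text)
    return check_dna_hgvs(text)


def infer_variant_type(parse: HgvsParse) -> str:
    """Derive the MVLD Variant Type (SNV/MNV/INS/DEL) from a DNA parse.

    The classification follows the length rule: a one-base-for-one-base
    substitution is an SNV; any equal- or unequal-length replacement beyond
    that (including deletion-insertion, the "deletion plus substitution"
    complex case) is an MNV; events that only add sequence (insertion,
    duplication) are INS; events that only remove sequence are DEL.
    """
    if parse.molecule == "p":
        raise VariantTypeUndefined(
            "variant type is defined on DNA descriptions; got a protein parse"
        )
    k = parse.edit_kind
    if k == "substitution":
        return "SNV"
    if k in ("insertion", "duplication"):
        return "INS"
    if k == "deletion":
        return "DEL"
    if k == "delins":
        ref_len: int | None
        if parse.ref_allele:
            ref_len = len(parse.ref_allele)
        elif parse.end is None:
            ref_len = 1
        elif parse.start.is_plain and parse.end.is_plain:
            ref_len = parse.end.value - parse.start.value + 1
        else:
            ref_len = None  # span not computable from offset positions
        alt_len = len(parse.alt_allele or "")
        if ref_len == 1 and alt_len == 1:
            return "SNV"
        return "MNV"
    raise VariantTypeUndefined(f"no variant type for edit kind {k!r}")
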