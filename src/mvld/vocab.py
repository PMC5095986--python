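"""Controlled vocabularies for the enumerated MVLD fields.

The Minimal Variant Level Data (MVLD) standard fixes short controlled term
lists for five of its fields.  The lists below are the canonical, ordered
vocabularies; :func:`vocabulary` returns them and :func:`normalize_term` maps
free-form input (case/whitespace variants and declared synonyms) onto the
canonical spelling.

The canonical capitalization is deliberately uneven — interpretive terms are
capitalized ("Diagnostic", "Missense") while the drug-effect terms are
lowercase ("sensitive", "reduced sensitivity") — because that is how the
standard prints them; we preserve it exactly so that exported tables are
comparable across curation groups.
"""

from __future__ import annotations

import difflib
import re
from types import MappingProxyType

__all__ = [
    "VOCABULARIES",
    "SYNONYMS",
    "EFFECT_BASE_TERMS",
    "NONCODING_CONSEQUENCES",
    "CHROMOSOMES",
    "GENOME_BUILD_RE",
    "TRANSCRIPT_RE",
    "PROTEIN_ID_RE",
    "NCT_RE",
    "CANDL_TIER_LABELS",
    "UnknownFieldError",
    "UnknownTermError",
    "vocabulary",
    "normalize_term",
    "normalize_chromosome",
]

#: Canonical term lists, in the order the standard presents them.
VOCABULARIES: MappingProxyType[str, tuple[str, ...]] = MappingProxyType(
    {
        "somatic_classification": (
            "Confirmed somatic",
            "Confirmed germline",
            "Unknown",
        ),
        "variant_type": ("SNV", "MNV", "INS", "DEL"),
        "variant_consequence": (
            "Nonsense",
            "Missense",
            "Silent",
            "Frame shift",
            "In-frame",
            "3UTR",
            "5UTR",
            "Splice",
            "Splice-region",
            "Intronic",
            "Upstream",
            "Downstream",
        ),
        "biomarker_class": ("Diagnostic", "Prognostic", "Predictive"),
        "effect": (
            "resistant",
            "responsive",
            "not-responsive",
            "sensitive",
            "reduced sensitivity",
            "other",
        ),
    }
)

#: The five substantive effect descriptors; "other" is the free-text escape.
EFFECT_BASE_TERMS: tuple[str, ...] = VOCABULARIES["effect"][:-1]

#: Consequences for which a protein-level description is not expected, so a
#: DNA-only record satisfies the substitution-and-position guidance.
NONCODING_CONSEQUENCES: frozenset[str] = frozenset(
    {"3UTR", "5UTR", "Splice", "Splice-region", "Intronic", "Upstream", "Downstream"}
)

# Declared synonyms, keyed by (field, folded spelling).  Sequence Ontology
# spells the UTR terms with a prime mark; curation tables vary further.
SYNONYMS: MappingProxyType[str, MappingProxyType[str, str]] = MappingProxyType(
    {
        "variant_consequence": MappingProxyType(
            {
                "3'utr": "3UTR",
                "5'utr": "5UTR",
                "three_prime_utr": "3UTR",
                "five_prime_utr": "5UTR",
                "three_prime_utr_variant": "3UTR",
                "five_prime_utr_variant": "5UTR",
                "stop_gained": "Nonsense",
                "missense_variant": "Missense",
                "synonymous_variant": "Silent",
                "frameshift": "Frame shift",
                "frameshift_variant": "Frame shift",
                "inframe": "In-frame",
                "in frame": "In-frame",
                "splice_region": "Splice-region",
                "splice region": "Splice-region",
                "intron_variant": "Intronic",
                "intron": "Intronic",
            }
        ),
        "effect": MappingProxyType(
            {
                "not responsive": "not-responsive",
                "non-responsive": "not-responsive",
                "reduced-sensitivity": "reduced sensitivity",
                "reduced_sensitivity": "reduced sensitivity",
            }
        ),
        "variant_type": MappingProxyType(
            {
                "single nucleotide variant": "SNV",
                "multi-nucleotide variant": "MNV",
                "insertion": "INS",
                "deletion": "DEL",
            }
        ),
    }
)

#: Chromosomes admitted by the allele descriptive block ("chr" prefixes are
#: stripped on input; see :func:`normalize_chromosome`).
CHROMOSOMES: frozenset[str] = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "MT"])

#: GRCh37/GRCh38 with an optional patch suffix such as ".p13".
GENOME_BUILD_RE = re.compile(r"^GRCh3[78](\.p\d+)?$")

#: RefSeq transcript accessions, optional version suffix.
TRANSCRIPT_RE = re.compile(r"^N[MR]_\d+(\.\d+)?$")

#: RefSeq protein accessions.
PROTEIN_ID_RE = re.compile(r"^NP_\d+(\.\d+)?$")

#: ClinicalTrials.gov registry identifiers.
NCT_RE = re.compile(r"^NCT\d{8}$")

#: Level labels of the built-in CanDL evidence scheme (see :mod:`mvld.tiering`).
CANDL_TIER_LABELS: tuple[str, ...] = ("Tier 1", "Tier 2", "Tier 3", "Tier 4")


class UnknownFieldError(KeyError):
    """Raised when a field name does not denote an enumerated MVLD field."""

    def __init__(self, field_name: str):
        self.field_name = field_name
        super().__init__(
            f"no such enumerated field: {field_name!r} "
            f"(enumerated fields: {', '.join(sorted(VOCABULARIES))})"
        )


class UnknownTermError(ValueError):
    """Raised when a raw term cannot be mapped onto a canonical vocabulary term.

    Carries the nearest canonical candidates in :attr:`suggestions`.
    """

    def __init__(self, field_name: str, raw: str, suggestions: tuple[str, ...]):
        self.field_name = field_name
        self.raw = raw
        self.suggestions = suggestions
        hint = f"; nearest: {', '.join(suggestions)}" if suggestions else ""
        super().__init__(f"unknown term for field {field_name!r}: {raw!r}{hint}")


def vocabulary(field_name: str) -> tuple[str, ...]:
    """Return the canonical ordered term list for an enumerated field."""
    try:
        return VOCABULARIES[field_name]
    except KeyError:
        raise UnknownFieldError(field_name) from None


def normalize_term(field_name: str, raw: str) -> str:
    """Map ``raw`` onto the canonical spelling of a vocabulary term.

    Matching is whitespace-trimmed and case-insensitive; declared synonyms
    (e.g. ``3'UTR`` for ``3UTR``) are accepted.  Canonical terms map to
    themselves, so normalization is idempotent.

    Raises
    ------
    UnknownFieldError
        If ``field_name`` is not an enumerated field.
    UnknownTermError
        If no canonical term matches; the error carries nearest candidates.
    """
    terms = vocabulary(field_name)
    folded = raw.strip().casefold()
    for term in terms:
        if term.casefold() == folded:
            return term
    synonyms = SYNONYMS.get(field_name, {})
    if folded in synonyms:
        return synonyms[folded]
    suggestions = tuple(
        difflib.get_close_matches(folded, [t.casefold() for t in terms], n=3, cutoff=0.5)
    )
    # report suggestions in canonical spelling
    canon = {t.casefold(): t for t in terms}
    raise UnknownTermError(field_name, raw, tuple(canon[s] for s in suggestions))


def normalize_chromosome(raw: str) -> str:
    """Canonicalize a chromosome label: strip any ``chr`` prefix, upper-case
    the sex/mitochondrial letters, and map ``M`` to ``MT``."""
    name = raw.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    name = name.upper()
    if name == "M":
        name = "MT"
    return name
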