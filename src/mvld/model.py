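"""Typed data model for Minimal Variant Level Data (MVLD) records.

An :class:`MVLDRecord` is one variant-level assertion — one variant in one
cancer type, with one biomarker class and (for predictive assertions) one
therapeutic context — composed of the standard's three field blocks:

* :class:`AlleleDescriptor` — where the allele is (build, gene, chromosome,
  position, RefSeq transcript/protein identifiers);
* :class:`AlleleInterpretation` — what the allele is (somatic status, HGVS
  descriptions, variant type and molecular consequence, literature support);
* :class:`CancerInterpretation` — what the allele means clinically (cancer
  type from an ontology, biomarker class, therapeutic context and effect,
  level and sub-level of evidence).

Construction is *checked*: the checked constructors reject invariant-violating
field combinations outright (an ``effect`` of ``"other"`` without free text,
a CanDL level outside Tier 1–4, an interpretation with neither a DNA nor a
protein HGVS description, ...).  Missing values (``None`` / empty lists) are
permitted at construction — whether a field is *required* is the business of
:mod:`mvld.validation`, which reports findings instead of raising.

Ingestion paths that must be able to represent broken upstream data (the file
readers, the violation injector in :mod:`mvld.fixtures`) use the documented
escape hatch :meth:`MvldBase.build_unchecked`, which bypasses the checks so the
validator can report on the result.
"""

from __future__ import annotations

from typing import Any, Literal, Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from . import vocab
from .vocab import (
    CANDL_TIER_LABELS,
    CHROMOSOMES,
    GENOME_BUILD_RE,
    NCT_RE,
    PROTEIN_ID_RE,
    TRANSCRIPT_RE,
    normalize_chromosome,
    normalize_term,
)

__all__ = [
    "evolve",
    "MvldBase",
    "OntologyTerm",
    "Effect",
    "LevelOfEvidence",
    "ExpertOpinion",
    "EvidenceAssertion",
    "AlleleDescriptor",
    "AlleleInterpretation",
    "CancerInterpretation",
    "MVLDRecord",
]

MVLD_VERSION = "1.0"


class MvldBase(BaseModel):
    """Frozen base model; equality is field-wise."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    @classmethod
    def build_unchecked(cls, **fields: Any):
        """Construct without running validators (defaults still applied).

        For ingestion of non-conformant upstream data that the validator must
        be able to inspect; never use for data you author in memory.
        """
        clean: dict[str, Any] = {}
        for name, info in cls.model_fields.items():
            if name in fields:
                value = fields.pop(name)
            elif info.is_required():
                value = None
            else:
                value = info.get_default(call_default_factory=True)
            # keep tuple-typed fields hashable/consistent with checked builds
            if isinstance(value, list):
                value = tuple(value)
            clean[name] = value
        if fields:
            raise TypeError(f"unknown fields for {cls.__name__}: {sorted(fields)}")
        return cls.model_construct(**clean)


def evolve(obj: "MvldBase", **changes: Any) -> "MvldBase":
    """Copy a frozen model with some fields replaced, without re-validating.

    Deliberately unchecked: it is the tool the ingestion and fixture layers
    use to materialize states the checked constructors would refuse.
    """
    data = {name: getattr(obj, name) for name in type(obj).model_fields}
    data.update(changes)
    return type(obj).build_unchecked(**data)


class OntologyTerm(MvldBase):
    """A cancer-type term drawn from NCI Thesaurus, Oncotree or a local list.

    Oncotree codes are the short initialisms the ontology is known for
    (``RGNT`` = rosette-forming glioneuronal tumor); NCIt codes are the
    ``C``-prefixed thesaurus identifiers.
    """

    source: Literal["NCIt", "Oncotree", "local"]
    code: str
    label: str = ""

    @field_validator("code")
    @classmethod
    def _code_nonempty(cls, v: str) -> str:
        if not v or not v.strip():
            raise ValueError("ontology code must be non-empty")
        return v.strip()

    @model_validator(mode="after")
    def _oncotree_initialism(self) -> "OntologyTerm":
        if self.source == "Oncotree" and not self.code.isupper():
            raise ValueError(
                f"Oncotree codes are upper-case initialisms (e.g. RGNT); got {self.code!r}"
            )
        return self


class Effect(MvldBase):
    """Direction of the variant–drug relationship in the therapeutic context.

    ``free_text`` is the escape description and is non-empty exactly when the
    term is ``"other"``.
    """

    term: str
    free_text: str = ""

    @field_validator("term")
    @classmethod
    def _canonical_term(cls, v: str) -> str:
        return normalize_term("effect", v)

    @model_validator(mode="after")
    def _free_text_iff_other(self) -> "Effect":
        if self.term == "other" and not self.free_text.strip():
            raise ValueError('effect "other" requires a free-text description')
        if self.term != "other" and self.free_text.strip():
            raise ValueError('effect free text is only allowed with term "other"')
        return self


class LevelOfEvidence(MvldBase):
    """A level from a pluggable evidence-scoring scheme.

    Any well-described interpretive framework may be named via
    ``schema_name``; the CanDL four-tier scheme is built in and its labels
    are checked.  Foreign labels are stored verbatim and never re-tiered.
    """

    schema_name: str
    level_label: str

    @model_validator(mode="after")
    def _candl_labels(self) -> "LevelOfEvidence":
        if self.schema_name == "CanDL" and self.level_label not in CANDL_TIER_LABELS:
            raise ValueError(
                f"CanDL levels are {', '.join(CANDL_TIER_LABELS)}; got {self.level_label!r}"
            )
        return self


class ExpertOpinion(MvldBase):
    """Name, date and academic/medical affiliation of a cited expert."""

    name: str
    date: str
    affiliation: str

    @model_validator(mode="after")
    def _all_parts(self) -> "ExpertOpinion":
        if not (self.name.strip() and self.date.strip() and self.affiliation.strip()):
            raise ValueError("expert opinion requires name, date and affiliation")
        return self


class EvidenceAssertion(MvldBase):
    """One sub-level evidence item supporting the level-of-evidence claim.

    ``category`` is the 1–6 sub-level: (1) prospective trials/studies,
    (2) retrospective trials/studies and metadata analysis, (3) expert
    opinion, (4) case reports, (5) published preclinical data, (6) inferential
    data or publications / in-silico predictions.  Citation requirements per
    category are checked by :func:`mvld.validation.check_evidence_citations`.
    """

    category: int
    trial_ids: tuple[str, ...] = ()
    pmids: tuple[int, ...] = ()
    expert: Optional[ExpertOpinion] = None
    tools: tuple[str, ...] = ()
    note: str = ""

    @field_validator("category")
    @classmethod
    def _category_range(cls, v: int) -> int:
        if not 1 <= v <= 6:
            raise ValueError(f"evidence sub-level category must be 1..6, got {v}")
        return v

    @field_validator("trial_ids")
    @classmethod
    def _nct_pattern(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        for t in v:
            if not NCT_RE.match(t):
                raise ValueError(f"clinical-trial id must match NCT + 8 digits, got {t!r}")
        return v

    @field_validator("pmids")
    @classmethod
    def _positive_pmids(cls, v: tuple[int, ...]) -> tuple[int, ...]:
        for p in v:
            if p <= 0:
                raise ValueError(f"PMIDs are positive integers, got {p}")
        return v


class AlleleDescriptor(MvldBase):
    """Allele descriptive block: where the variant lives.

    ``genome_build`` is GRCh37/GRCh38 with an optional patch suffix, so the
    actual reference version used for calling can be recorded (``GRCh38.p7``).
    Chromosomes are stored without any ``chr`` prefix; positions are 1-based
    per HGVS convention.  Transcripts and protein identifiers are RefSeq
    accessions (``NM_``/``NR_``, ``NP_``).
    """

    genome_build: Optional[str] = None
    gene_symbol: Optional[str] = None
    chromosome: Optional[str] = None
    genomic_position: Optional[int] = None
    transcripts: tuple[str, ...] = ()
    protein_id: Optional[str] = None

    @field_validator("genome_build")
    @classmethod
    def _build_format(cls, v: Optional[str]) -> Optional[str]:
        if v is None:
            return v
        v = v.strip()
        if not GENOME_BUILD_RE.match(v):
            raise ValueError(
                f"genome build must be GRCh37/GRCh38 (optionally with .pN patch), got {v!r}"
            )
        return v

    @field_validator("chromosome")
    @classmethod
    def _chromosome_set(cls, v: Optional[str]) -> Optional[str]:
        if v is None:
            return v
        name = normalize_chromosome(v)
        if name not in CHROMOSOMES:
            raise ValueError(f"chromosome must be 1-22, X, Y or MT, got {v!r}")
        return name

    @field_validator("genomic_position")
    @classmethod
    def _position_positive(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v < 1:
            raise ValueError(f"genomic position is 1-based and must be >= 1, got {v}")
        return v

    @field_validator("transcripts")
    @classmethod
    def _refseq_transcripts(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        for t in v:
            if not TRANSCRIPT_RE.match(t):
                raise ValueError(f"transcripts must be RefSeq NM_/NR_ accessions, got {t!r}")
        return v

    @field_validator("protein_id")
    @classmethod
    def _refseq_protein(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and not PROTEIN_ID_RE.match(v):
            raise ValueError(f"protein id must be a RefSeq NP_ accession, got {v!r}")
        return v


class AlleleInterpretation(MvldBase):
    """Allele interpretive block: what the variant is.

    At least one of ``dna_hgvs``/``protein_hgvs`` must be present (a
    noncoding variant may carry the DNA description only).  The enumerated
    fields accept any spelling :func:`mvld.vocab.normalize_term` recognizes
    and store the canonical form.  HGVS strings are stored as given; their
    grammar is checked by the validator, not the constructor, so a record
    with a malformed description can still be loaded and reported on.
    """

    somatic_classification: Optional[str] = None
    dna_hgvs: Optional[str] = None
    protein_hgvs: Optional[str] = None
    variant_type: Optional[str] = None
    variant_consequence: Optional[str] = None
    pmids: tuple[int, ...] = ()

    @field_validator("somatic_classification")
    @classmethod
    def _canonical_class(cls, v: Optional[str]) -> Optional[str]:
        return None if v is None else normalize_term("somatic_classification", v)

    @field_validator("variant_type")
    @classmethod
    def _canonical_type(cls, v: Optional[str]) -> Optional[str]:
        return None if v is None else normalize_term("variant_type", v)

    @field_validator("variant_consequence")
    @classmethod
    def _canonical_consequence(cls, v: Optional[str]) -> Optional[str]:
        return None if v is None else normalize_term("variant_consequence", v)

    @field_validator("pmids")
    @classmethod
    def _positive_pmids(cls, v: tuple[int, ...]) -> tuple[int, ...]:
        for p in v:
            if p <= 0:
                raise ValueError(f"PMIDs are positive integers, got {p}")
        return v

    @model_validator(mode="after")
    def _at_least_one_hgvs(self) -> "AlleleInterpretation":
        if self.dna_hgvs is None and self.protein_hgvs is None:
            raise ValueError(
                "at least one of the DNA and protein HGVS descriptions is required"
            )
        return self


class CancerInterpretation(MvldBase):
    """Cancer interpretive block: what the variant means clinically.

    The effect of a variant is only meaningful relative to a therapy, so an
    ``effect`` may be recorded only when ``therapeutic_context`` names at
    least one drug.
    """

    cancer_type: Optional[OntologyTerm] = None
    biomarker_class: Optional[str] = None
    therapeutic_context: tuple[str, ...] = ()
    effect: Optional[Effect] = None
    level_of_evidence: Optional[LevelOfEvidence] = None
    sub_level: tuple[EvidenceAssertion, ...] = ()

    @field_validator("biomarker_class")
    @classmethod
    def _canonical_class(cls, v: Optional[str]) -> Optional[str]:
        return None if v is None else normalize_term("biomarker_class", v)

    @model_validator(mode="after")
    def _effect_needs_context(self) -> "CancerInterpretation":
        if self.effect is not None and not self.therapeutic_context:
            raise ValueError(
                "an effect is asserted relative to a therapeutic context; "
                "supply at least one drug"
            )
        return self


class MVLDRecord(MvldBase):
    """One complete variant-level assertion.

    ``extensions`` is a free key→text map carrying columns outside the
    standard; it is round-tripped byte-identically and never validated.
    """

    descriptor: AlleleDescriptor
    interpretation: AlleleInterpretation
    cancer: CancerInterpretation
    extensions: dict[str, str] = {}

    @model_validator(mode="after")
    def _transcripts_unless_genomic(self) -> "MVLDRecord":
        # a transcript anchors c./n. coordinates; only purely genomic (g.)
        # descriptions can do without one
        if not self.descriptor.transcripts:
            dna = self.interpretation.dna_hgvs
            if not (dna and dna.strip().startswith("g.")):
                raise ValueError(
                    "transcripts may be empty only when the DNA description is genomic (g.)"
                )
        return self

    def is_noncoding(self) -> bool:
        """True when the record describes a change outside coding sequence,
        so a DNA-only description satisfies the HGVS guidance."""
        cons = self.interpretation.variant_consequence
        if cons in vocab.NONCODING_CONSEQUENCES:
            return True
        dna = self.interpretation.dna_hgvs
        return bool(dna and dna.strip()[:2] in ("n.", "g."))
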