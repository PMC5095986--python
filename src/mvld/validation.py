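"""Rule engine for MVLD conformance checking.

:func:`validate_record` applies the standard's required / conditional /
vocabulary / HGVS logic to one record and returns a :class:`ValidationReport`
of ordered findings — problems are reported, never raised, so a whole corpus
can be checked in one pass.  Rule identifiers are frozen strings from
:data:`RULES`; the registry is also rendered as a table in the package docs
so external manifests (e.g. fixture injection manifests) can reference rules
stably.

Two validation profiles exist.  ``submission`` is the baseline: it errors on
everything the standard requires and warns about the strongly-suggested items
(both DNA *and* protein HGVS descriptions, supporting PMIDs), which are
optional in this iteration of the standard.  ``strict`` upgrades those
suggestions to errors.  For every record, the strict error set is a superset
of the submission error set.

Cross-field sanity checks (:func:`check_consistency`) are warnings only:
legacy curated data may legitimately disagree with what the HGVS string
implies, and the standard does not mandate agreement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Literal

from . import vocab
from .hgvs import HgvsSyntaxError, check_dna_hgvs, check_protein_hgvs, infer_variant_type
from .model import EvidenceAssertion, MVLDRecord

__all__ = [
    "RULES",
    "REQUIRED_FIELD_RULES",
    "INJECTABLE_RULES",
    "ValidationFinding",
    "ValidationReport",
    "validate_record",
    "validate_records",
    "check_consistency",
    "check_evidence_citations",
    "known_gene_symbols",
]

Profile = Literal["submission", "strict"]

#: Frozen rule registry: rule id -> (default severity, summary).
RULES: MappingProxyType[str, tuple[str, str]] = MappingProxyType(
    {
        "REQ.GENOME_BUILD": ("error", "Genome Build is required (GRCh37/GRCh38)"),
        "REQ.GENE_NAME": ("error", "Gene Name (HUGO-approved symbol) is required"),
        "REQ.CHROMOSOME": ("error", "Chromosome is required"),
        "REQ.DNA_POSITION": ("error", "DNA Position (1-based genomic coordinate) is required"),
        "REQ.TRANSCRIPT": (
            "error",
            "A RefSeq transcript is required unless the DNA description is genomic (g.)",
        ),
        "REQ.SOMATIC_CLASS": ("error", "Somatic Classification is required"),
        "REQ.VARIANT_TYPE": ("error", "Variant Type is required"),
        "REQ.CONSEQUENCE": ("error", "Variant Consequence is required"),
        "REQ.CANCER_TYPE": ("error", "Cancer Type (ontology term) is required"),
        "REQ.BIOMARKER_CLASS": ("error", "Biomarker Class is required"),
        "REQ.EVIDENCE_LEVEL": ("error", "Level of Evidence is required"),
        "COND.HGVS_PRESENT": (
            "error",
            "At least one of the DNA and protein HGVS descriptions is required",
        ),
        "COND.EFFECT_CONTEXT": (
            "error",
            "Effect is dependent upon Therapeutic Context; name at least one drug",
        ),
        "COND.EFFECT_OTHER_TEXT": (
            "error",
            'Effect free text is required iff the term is "other"',
        ),
        "COND.CANDL_LABEL": ("error", "CanDL levels are Tier 1 through Tier 4"),
        "VOC.GENOME_BUILD": ("error", "Genome Build must be GRCh37/GRCh38 (+ optional patch)"),
        "VOC.CHROMOSOME": ("error", "Chromosome must be 1-22, X, Y or MT"),
        "VOC.POSITION": ("error", "DNA Position must be a positive 1-based integer"),
        "VOC.TRANSCRIPT": ("error", "Transcripts must be RefSeq NM_/NR_ accessions"),
        "VOC.PROTEIN_ID": ("error", "Protein id must be a RefSeq NP_ accession"),
        "VOC.SOMATIC_CLASS": ("error", "Somatic Classification outside the controlled vocabulary"),
        "VOC.VARIANT_TYPE": ("error", "Variant Type outside the controlled vocabulary"),
        "VOC.CONSEQUENCE": ("error", "Variant Consequence outside the controlled vocabulary"),
        "VOC.BIOMARKER_CLASS": ("error", "Biomarker Class outside the controlled vocabulary"),
        "VOC.EFFECT": ("error", "Effect term outside the controlled vocabulary"),
        "VOC.PMID": ("error", "PMIDs must be positive integers"),
        "HGVS.DNA": ("error", "DNA description is not grammar-conforming HGVS"),
        "HGVS.PROTEIN": ("error", "Protein description is not grammar-conforming HGVS"),
        "SUGG.HGVS_BOTH": (
            "warning",
            "Both DNA and protein HGVS descriptions are strongly suggested for coding variants",
        ),
        "SUGG.PMIDS": ("warning", "Supporting PMIDs are strongly suggested"),
        "SUGG.PROTEIN_ID": (
            "warning",
            "A RefSeq protein id is suggested when a protein HGVS description is given",
        ),
        "WARN.GENE_UNKNOWN": (
            "warning",
            "Gene symbol not found in the packaged HUGO symbol subset",
        ),
        "EVID.TRIAL_REQUIRED": (
            "error",
            "Trial-based evidence (sub-level 1/2) must cite an NCT id or PMID",
        ),
        "EVID.EXPERT_REQUIRED": (
            "error",
            "Expert opinion (sub-level 3) must cite name, date and affiliation",
        ),
        "EVID.PMID_REQUIRED": (
            "error",
            "Case reports and preclinical data (sub-level 4/5) must cite at least one PMID",
        ),
        "EVID.CITATION_REQUIRED": (
            "error",
            "Inferential evidence (sub-level 6) must cite a PMID or the programs used",
        ),
        "EVID.NCT_FORMAT": ("error", "Clinical-trial ids must match NCT + 8 digits"),
        "EVID.CATEGORY_RANGE": ("error", "Evidence sub-level category must be 1..6"),
        "CONS.TYPE_MISMATCH": (
            "warning",
            "Declared Variant Type disagrees with the type inferred from the DNA HGVS",
        ),
        "CONS.FRAMESHIFT_SNV": (
            "warning",
            "Frame shift consequence is inconsistent with an equal-length substitution",
        ),
        "CONS.INTRONIC_PROTEIN": (
            "warning",
            "Intronic consequence is inconsistent with a protein-level change",
        ),
        "IO.UNKNOWN_COLUMN": ("warning", "Unknown column preserved into extensions"),
        "IO.ROW_SKIPPED": ("error", "Row could not be structured as an MVLD record"),
    }
)

#: The rules exercised by the required-field completeness loop, with the
#: record field path each one guards.
REQUIRED_FIELD_RULES: MappingProxyType[str, str] = MappingProxyType(
    {
        "REQ.GENOME_BUILD": "descriptor.genome_build",
        "REQ.GENE_NAME": "descriptor.gene_symbol",
        "REQ.CHROMOSOME": "descriptor.chromosome",
        "REQ.DNA_POSITION": "descriptor.genomic_position",
        "REQ.TRANSCRIPT": "descriptor.transcripts",
        "REQ.SOMATIC_CLASS": "interpretation.somatic_classification",
        "REQ.VARIANT_TYPE": "interpretation.variant_type",
        "REQ.CONSEQUENCE": "interpretation.variant_consequence",
        "REQ.CANCER_TYPE": "cancer.cancer_type",
        "REQ.BIOMARKER_CLASS": "cancer.biomarker_class",
        "REQ.EVIDENCE_LEVEL": "cancer.level_of_evidence",
    }
)

#: Rules the fixture generator knows how to inject deliberately.
INJECTABLE_RULES: tuple[str, ...] = tuple(REQUIRED_FIELD_RULES) + (
    "COND.HGVS_PRESENT",
    "COND.EFFECT_CONTEXT",
    "COND.EFFECT_OTHER_TEXT",
    "VOC.SOMATIC_CLASS",
    "VOC.VARIANT_TYPE",
    "VOC.CONSEQUENCE",
    "VOC.BIOMARKER_CLASS",
    "VOC.EFFECT",
    "HGVS.DNA",
    "HGVS.PROTEIN",
    "EVID.TRIAL_REQUIRED",
    "EVID.EXPERT_REQUIRED",
    "EVID.PMID_REQUIRED",
    "EVID.CITATION_REQUIRED",
    "EVID.NCT_FORMAT",
)


@dataclass(frozen=True)
class ValidationFinding:
    """One problem found in a record.

    ``rule_id`` is a frozen code from :data:`RULES`; ``field_path`` is the
    dotted path of the offending field within the record; ``record_index``
    is set when the finding belongs to a corpus-level report.
    """

    severity: str  # "error" | "warning"
    rule_id: str
    field_path: str
    message: str
    record_index: int | None = None

    def as_dict(self) -> dict:
        d = {
            "severity": self.severity,
            "rule_id": self.rule_id,
            "field_path": self.field_path,
            "message": self.message,
        }
        if self.record_index is not None:
            d["record_index"] = self.record_index
        return d


@dataclass(frozen=True)
class ValidationReport:
    """Ordered findings plus severity tallies; empty findings ⇔ conformant."""

    findings: tuple[ValidationFinding, ...] = ()

    @property
    def error_count(self) -> int:
        return sum(1 for f in self.findings if f.severity == "error")

    @property
    def warning_count(self) -> int:
        return sum(1 for f in self.findings if f.severity == "warning")

    @property
    def ok(self) -> bool:
        return self.error_count == 0

    def errors(self) -> tuple[ValidationFinding, ...]:
        return tuple(f for f in self.findings if f.severity == "error")

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(
            {
                "error_count": self.error_count,
                "warning_count": self.warning_count,
                "findings": [f.as_dict() for f in self.findings],
            },
            indent=indent,
        )

    def to_text(self) -> str:
        if not self.findings:
            return "conformant: 0 errors, 0 warnings\n"
        lines = [
            f"{f.severity.upper():7s} {f.rule_id:22s} "
            + (f"records[{f.record_index}]." if f.record_index is not None else "")
            + f"{f.field_path}: {f.message}"
            for f in self.findings
        ]
        lines.append(f"{self.error_count} error(s), {self.warning_count} warning(s)")
        return "\n".join(lines) + "\n"

    def __add__(self, other: "ValidationReport") -> "ValidationReport":
        return ValidationReport(self.findings + other.findings)


_GENE_SYMBOLS: frozenset[str] | None = None


def known_gene_symbols() -> frozenset[str]:
    """The packaged subset of HUGO-approved symbols (for the unknown-symbol
    warning; this is not a live HGNC check)."""
    global _GENE_SYMBOLS
    if _GENE_SYMBOLS is None:
        from .interop import _load_gene_table

        _GENE_SYMBOLS = frozenset(_load_gene_table())
    return _GENE_SYMBOLS


def _finding(rule_id: str, field_path: str, detail: str = "", severity: str | None = None) -> ValidationFinding:
    default_sev, summary = RULES[rule_id]
    msg = summary if not detail else f"{summary} ({detail})"
    return ValidationFinding(severity or default_sev, rule_id, field_path, msg)


def _missing(value) -> bool:
    return value is None or value == "" or value == ()


def validate_record(record: MVLDRecord, profile: Profile = "submission") -> ValidationReport:
    """Check one record against the MVLD required/conditional/vocabulary/HGVS
    rules and the per-category evidence citation rules.

    All problems are findings; this function never raises on record content.
    Under ``strict`` the strongly-suggested items (both HGVS forms, PMIDs)
    are errors instead of warnings.
    """
    out: list[ValidationFinding] = []
    d, i, c = record.descriptor, record.interpretation, record.cancer
    upgrade = "error" if profile == "strict" else None

    # --- required fields, in block order -------------------------------
    if _missing(d.genome_build):
        out.append(_finding("REQ.GENOME_BUILD", "descriptor.genome_build"))
    if _missing(d.gene_symbol):
        out.append(_finding("REQ.GENE_NAME", "descriptor.gene_symbol"))
    if _missing(d.chromosome):
        out.append(_finding("REQ.CHROMOSOME", "descriptor.chromosome"))
    if _missing(d.genomic_position):
        out.append(_finding("REQ.DNA_POSITION", "descriptor.genomic_position"))
    genomic_dna = bool(i.dna_hgvs and str(i.dna_hgvs).strip().startswith("g."))
    if _missing(d.transcripts) and not genomic_dna:
        out.append(_finding("REQ.TRANSCRIPT", "descriptor.transcripts"))
    if _missing(i.somatic_classification):
        out.append(_finding("REQ.SOMATIC_CLASS", "interpretation.somatic_classification"))
    if _missing(i.variant_type):
        out.append(_finding("REQ.VARIANT_TYPE", "interpretation.variant_type"))
    if _missing(i.variant_consequence):
        out.append(_finding("REQ.CONSEQUENCE", "interpretation.variant_consequence"))
    if _missing(c.cancer_type):
        out.append(_finding("REQ.CANCER_TYPE", "cancer.cancer_type"))
    if _missing(c.biomarker_class):
        out.append(_finding("REQ.BIOMARKER_CLASS", "cancer.biomarker_class"))
    if _missing(c.level_of_evidence):
        out.append(_finding("REQ.EVIDENCE_LEVEL", "cancer.level_of_evidence"))

    # --- conditional rules ---------------------------------------------
    if _missing(i.dna_hgvs) and _missing(i.protein_hgvs):
        out.append(_finding("COND.HGVS_PRESENT", "interpretation.dna_hgvs"))
    if c.effect is not None and _missing(c.therapeutic_context):
        out.append(_finding("COND.EFFECT_CONTEXT", "cancer.therapeutic_context"))
    if c.effect is not None:
        term = getattr(c.effect, "term", None)
        text = (getattr(c.effect, "free_text", "") or "").strip()
        if term == "other" and not text:
            out.append(
                _finding("COND.EFFECT_OTHER_TEXT", "cancer.effect.free_text",
                         'term is "other" but no description given')
            )
        elif term not in (None, "other") and text:
            out.append(
                _finding("COND.EFFECT_OTHER_TEXT", "cancer.effect.free_text",
                         f"free text given with term {term!r}")
            )
    loe = c.level_of_evidence
    if loe is not None and getattr(loe, "schema_name", None) == "CanDL":
        if loe.level_label not in vocab.CANDL_TIER_LABELS:
            out.append(
                _finding("COND.CANDL_LABEL", "cancer.level_of_evidence.level_label",
                         repr(loe.level_label))
            )

    # "strongly suggested in this iteration" items
    if not record.is_noncoding():
        if _missing(i.protein_hgvs) and not _missing(i.dna_hgvs):
            out.append(
                _finding("SUGG.HGVS_BOTH", "interpretation.protein_hgvs", severity=upgrade)
            )
        elif _missing(i.dna_hgvs) and not _missing(i.protein_hgvs):
            out.append(
                _finding("SUGG.HGVS_BOTH", "interpretation.dna_hgvs", severity=upgrade)
            )
    if _missing(i.pmids):
        out.append(_finding("SUGG.PMIDS", "interpretation.pmids", severity=upgrade))
    if not _missing(i.protein_hgvs) and _missing(d.protein_id):
        out.append(_finding("SUGG.PROTEIN_ID", "descriptor.protein_id"))

    # --- vocabulary / format rules -------------------------------------
    out.extend(_vocabulary_findings(record))

    # --- HGVS grammar ---------------------------------------------------
    if not _missing(i.dna_hgvs):
        try:
            check_dna_hgvs(i.dna_hgvs)
        except HgvsSyntaxError as exc:
            out.append(_finding("HGVS.DNA", "interpretation.dna_hgvs", str(exc)))
    if not _missing(i.protein_hgvs):
        try:
            check_protein_hgvs(i.protein_hgvs)
        except HgvsSyntaxError as exc:
            out.append(_finding("HGVS.PROTEIN", "interpretation.protein_hgvs", str(exc)))

    # --- gene symbol against the packaged subset ------------------------
    if not _missing(d.gene_symbol) and d.gene_symbol not in known_gene_symbols():
        out.append(
            _finding("WARN.GENE_UNKNOWN", "descriptor.gene_symbol", repr(d.gene_symbol))
        )

    # --- sub-level evidence citations -----------------------------------
    for idx, assertion in enumerate(c.sub_level):
        for f in check_evidence_citations(assertion):
            out.append(
                ValidationFinding(
                    f.severity, f.rule_id, f"cancer.sub_level[{idx}].{f.field_path}", f.message
                )
            )

    return ValidationReport(tuple(out))


def _vocabulary_findings(record: MVLDRecord) -> list[ValidationFinding]:
    out: list[ValidationFinding] = []
    d, i, c = record.descriptor, record.interpretation, record.cancer

    if not _missing(d.genome_build) and not vocab.GENOME_BUILD_RE.match(str(d.genome_build)):
        out.append(_finding("VOC.GENOME_BUILD", "descriptor.genome_build", repr(d.genome_build)))
    if not _missing(d.chromosome) and str(d.chromosome) not in vocab.CHROMOSOMES:
        out.append(_finding("VOC.CHROMOSOME", "descriptor.chromosome", repr(d.chromosome)))
    if d.genomic_position is not None and (
        not isinstance(d.genomic_position, int) or d.genomic_position < 1
    ):
        out.append(_finding("VOC.POSITION", "descriptor.genomic_position", repr(d.genomic_position)))
    for t in d.transcripts or ():
        if not vocab.TRANSCRIPT_RE.match(str(t)):
            out.append(_finding("VOC.TRANSCRIPT", "descriptor.transcripts", repr(t)))
    if not _missing(d.protein_id) and not vocab.PROTEIN_ID_RE.match(str(d.protein_id)):
        out.append(_finding("VOC.PROTEIN_ID", "descriptor.protein_id", repr(d.protein_id)))

    enum_checks = [
        ("VOC.SOMATIC_CLASS", "interpretation.somatic_classification",
         "somatic_classification", i.somatic_classification),
        ("VOC.VARIANT_TYPE", "interpretation.variant_type", "variant_type", i.variant_type),
        ("VOC.CONSEQUENCE", "interpretation.variant_consequence",
         "variant_consequence", i.variant_consequence),
        ("VOC.BIOMARKER_CLASS", "cancer.biomarker_class", "biomarker_class", c.biomarker_class),
    ]
    for rule, path, fieldname, value in enum_checks:
        if not _missing(value) and value not in vocab.VOCABULARIES[fieldname]:
            out.append(_finding(rule, path, repr(value)))
    if c.effect is not None:
        term = getattr(c.effect, "term", None)
        if not _missing(term) and term not in vocab.VOCABULARIES["effect"]:
            out.append(_finding("VOC.EFFECT", "cancer.effect.term", repr(term)))
    for p in i.pmids or ():
        if not isinstance(p, int) or p <= 0:
            out.append(_finding("VOC.PMID", "interpretation.pmids", repr(p)))
    return out


def check_consistency(record: MVLDRecord) -> list[ValidationFinding]:
    """Cross-field sanity checks; warnings only.

    A declared Variant Type should agree with what the DNA HGVS implies; a
    Frame shift consequence cannot come from an equal-length substitution; an
    Intronic consequence should not coexist with a protein change.
    """
    out: list[ValidationFinding] = []
    i = record.interpretation

    inferred: str | None = None
    if i.dna_hgvs:
        try:
            inferred = infer_variant_type(check_dna_hgvs(i.dna_hgvs))
        except (HgvsSyntaxError, ValueError):
            inferred = None

    if inferred and i.variant_type and i.variant_type != inferred:
        out.append(
            _finding(
                "CONS.TYPE_MISMATCH",
                "interpretation.variant_type",
                f"declared {i.variant_type}, HGVS implies {inferred}",
            )
        )
    if i.variant_consequence == "Frame shift" and inferred == "SNV":
        out.append(
            _finding("CONS.FRAMESHIFT_SNV", "interpretation.variant_consequence")
        )
    if i.variant_consequence == "Intronic" and not _missing(i.protein_hgvs):
        out.append(
            _finding("CONS.INTRONIC_PROTEIN", "interpretation.variant_consequence")
        )
    return out


def check_evidence_citations(assertion: EvidenceAssertion) -> list[ValidationFinding]:
    """Citation requirements per evidence sub-level.

    Trials/retrospective studies (1, 2) need an NCT id or PMID; expert
    opinion (3) needs the expert's name, date and affiliation; case reports
    and preclinical data (4, 5) always cite at least the PMID; inferential
    data (6) cites a PMID or, for in-silico predictions, the programs used.
    """
    out: list[ValidationFinding] = []
    cat = assertion.category
    if not isinstance(cat, int) or not 1 <= cat <= 6:
        out.append(_finding("EVID.CATEGORY_RANGE", "category", repr(cat)))
        return out
    for t in assertion.trial_ids or ():
        if not vocab.NCT_RE.match(str(t)):
            out.append(_finding("EVID.NCT_FORMAT", "trial_ids", repr(t)))
    if cat in (1, 2) and not (assertion.trial_ids or assertion.pmids):
        out.append(_finding("EVID.TRIAL_REQUIRED", "trial_ids"))
    elif cat == 3:
        e = assertion.expert
        if e is None or not (
            str(getattr(e, "name", "") or "").strip()
            and str(getattr(e, "date", "") or "").strip()
            and str(getattr(e, "affiliation", "") or "").strip()
        ):
            out.append(_finding("EVID.EXPERT_REQUIRED", "expert"))
    elif cat in (4, 5) and not assertion.pmids:
        out.append(_finding("EVID.PMID_REQUIRED", "pmids"))
    elif cat == 6 and not (assertion.pmids or assertion.tools):
        out.append(_finding("EVID.CITATION_REQUIRED", "pmids"))
    return out


def validate_records(
    records: Iterable[MVLDRecord], profile: Profile = "submission"
) -> ValidationReport:
    """Validate a corpus; findings carry their record index."""
    out: list[ValidationFinding] = []
    for idx, record in enumerate(records):
        for f in validate_record(record, profile).findings:
            out.append(
                ValidationFinding(f.severity, f.rule_id, f.field_path, f.message, idx)
            )
    return ValidationReport(tuple(out))
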