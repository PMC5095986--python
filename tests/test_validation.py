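"""Required/conditional/vocabulary/HGVS rule logic and report behavior."""

import pytest

from mvld.model import (
    AlleleDescriptor,
    AlleleInterpretation,
    CancerInterpretation,
    Effect,
    EvidenceAssertion,
    ExpertOpinion,
    LevelOfEvidence,
    OntologyTerm,
    evolve,
)
from mvld.validation import (
    REQUIRED_FIELD_RULES,
    RULES,
    check_consistency,
    check_evidence_citations,
    validate_record,
)
from tests.conftest import make_record


def rule_ids(findings):
    return [f.rule_id for f in findings]


def test_conformant_record_yields_empty_report(record):
    report = validate_record(record, "strict")
    assert report.findings == ()
    assert report.ok and report.error_count == 0 and report.warning_count == 0


def _null_path(record, path):
    block_name, field = path.split(".", 1)
    empty = () if field == "transcripts" else None
    block = evolve(getattr(record, block_name), **{field: empty})
    return evolve(record, **{block_name: block})


def test_deleting_each_required_field_yields_exactly_that_error(record):
    """Completeness: every required field is guarded by exactly one REQ rule."""
    for rule, path in REQUIRED_FIELD_RULES.items():
        report = validate_record(_null_path(record, path), "submission")
        assert rule_ids(report.errors()) == [rule], path
        assert report.errors()[0].field_path == path


def test_adding_optional_fields_never_creates_required_errors():
    minimal = make_record(
        cancer=CancerInterpretation(
            cancer_type=OntologyTerm(source="Oncotree", code="MEL", label="Melanoma"),
            biomarker_class="Predictive",
            level_of_evidence=LevelOfEvidence(schema_name="CanDL", level_label="Tier 2"),
        )
    )
    base_req = {f.rule_id for f in validate_record(minimal).findings if f.rule_id.startswith("REQ.")}
    assert base_req == set()
    enriched = evolve(
        minimal,
        cancer=evolve(
            minimal.cancer,
            therapeutic_context=("vemurafenib", "dabrafenib"),
            effect=Effect(term="responsive"),
            sub_level=(EvidenceAssertion(category=4, pmids=(123456,)),),
        ),
        extensions={"site_notes": "reviewed"},
    )
    assert not any(f.rule_id.startswith("REQ.") for f in validate_record(enriched).findings)


def test_noncoding_dna_only_record_is_not_asked_for_protein():
    r = make_record(
        interpretation=AlleleInterpretation(
            somatic_classification="Confirmed somatic",
            dna_hgvs="c.88+2T>G",
            variant_type="SNV",
            variant_consequence="Splice",
            pmids=(123456,),
        ),
        descriptor=AlleleDescriptor(
            genome_build="GRCh38",
            gene_symbol="BRAF",
            chromosome="7",
            genomic_position=140753336,
            transcripts=("NM_004333.4",),
        ),
    )
    report = validate_record(r, "strict")
    assert "SUGG.HGVS_BOTH" not in rule_ids(report.findings)
    assert report.ok


def test_effect_without_context_is_a_conditional_error(record):
    broken = evolve(
        record,
        cancer=evolve(record.cancer, therapeutic_context=()),
    )
    report = validate_record(broken)
    assert "COND.EFFECT_CONTEXT" in rule_ids(report.errors())


def test_effect_other_free_text_pairing(record):
    broken = evolve(
        record,
        cancer=evolve(record.cancer, effect=Effect.build_unchecked(term="other", free_text="")),
    )
    assert "COND.EFFECT_OTHER_TEXT" in rule_ids(validate_record(broken).errors())


def test_unknown_classification_is_conformant(record):
    r = evolve(
        record,
        interpretation=evolve(record.interpretation, somatic_classification="Unknown"),
    )
    assert validate_record(r, "strict").ok


def test_vocabulary_rules_fire_on_unchecked_data(record):
    r = evolve(
        record,
        interpretation=evolve(record.interpretation, variant_type="INDEL"),
    )
    assert "VOC.VARIANT_TYPE" in rule_ids(validate_record(r).errors())


def test_malformed_hgvs_becomes_a_finding_not_an_exception(record):
    r = evolve(
        record,
        interpretation=evolve(record.interpretation, dna_hgvs="76A>T", protein_hgvs="V600E"),
    )
    ids = rule_ids(validate_record(r).errors())
    assert "HGVS.DNA" in ids and "HGVS.PROTEIN" in ids


def test_unknown_gene_symbol_is_a_warning_not_an_error(record):
    r = evolve(record, descriptor=evolve(record.descriptor, gene_symbol="NOTAGENE1"))
    report = validate_record(r)
    assert "WARN.GENE_UNKNOWN" in rule_ids(report.findings)
    assert report.ok


def test_strict_upgrades_suggestions_to_errors(record):
    r = evolve(
        record,
        interpretation=evolve(record.interpretation, protein_hgvs=None, pmids=()),
    )
    submission = validate_record(r, "submission")
    strict = validate_record(r, "strict")
    assert {f.rule_id for f in submission.findings if f.severity == "warning"} >= {
        "SUGG.HGVS_BOTH",
        "SUGG.PMIDS",
    }
    assert submission.ok and not strict.ok


def test_profile_ordering_property(record):
    candidates = [
        record,
        evolve(record, interpretation=evolve(record.interpretation, protein_hgvs=None, pmids=())),
        evolve(record, descriptor=evolve(record.descriptor, gene_symbol=None)),
        evolve(record, cancer=evolve(record.cancer, level_of_evidence=None)),
    ]
    for r in candidates:
        sub = {(f.rule_id, f.field_path) for f in validate_record(r, "submission").errors()}
        strict = {(f.rule_id, f.field_path) for f in validate_record(r, "strict").errors()}
        assert strict >= sub


def test_reports_are_deterministic(record):
    a = validate_record(record.model_copy(deep=True))
    b = validate_record(record)
    assert a.to_json() == b.to_json()
    assert a.to_text() == b.to_text()


def test_report_counts_match_findings(record):
    broken = evolve(record, descriptor=evolve(record.descriptor, gene_symbol=None))
    report = validate_record(broken)
    assert report.error_count == sum(1 for f in report.findings if f.severity == "error")
    assert report.warning_count == len(report.findings) - report.error_count


def test_all_finding_rule_ids_are_registered(record):
    broken = evolve(
        record,
        descriptor=evolve(record.descriptor, gene_symbol=None, genome_build=None),
        interpretation=evolve(record.interpretation, dna_hgvs="76A>T"),
    )
    for f in validate_record(broken, "strict").findings:
        assert f.rule_id in RULES


class TestConsistency:
    def test_type_mismatch_is_flagged(self, record):
        r = evolve(record, interpretation=evolve(record.interpretation, variant_type="DEL"))
        findings = check_consistency(r)
        assert rule_ids(findings) == ["CONS.TYPE_MISMATCH"]
        assert all(f.severity == "warning" for f in findings)

    def test_consistent_pair_is_silent(self, record):
        assert check_consistency(record) == []

    def test_intronic_with_protein_change(self, record):
        r = evolve(
            record,
            interpretation=evolve(record.interpretation, variant_consequence="Intronic"),
        )
        assert "CONS.INTRONIC_PROTEIN" in rule_ids(check_consistency(r))

    def test_frameshift_with_equal_length_substitution(self, record):
        r = evolve(
            record,
            interpretation=evolve(record.interpretation, variant_consequence="Frame shift"),
        )
        assert "CONS.FRAMESHIFT_SNV" in rule_ids(check_consistency(r))


class TestEvidenceCitations:
    @pytest.mark.parametrize(
        "assertion,expected",
        [
            (EvidenceAssertion(category=1, trial_ids=("NCT01234567",)), []),
            (EvidenceAssertion.build_unchecked(category=1), ["EVID.TRIAL_REQUIRED"]),
            (EvidenceAssertion(category=2, pmids=(123,)), []),
            (
                EvidenceAssertion(
                    category=3,
                    expert=ExpertOpinion(name="A", date="2016-01-01", affiliation="X"),
                ),
                [],
            ),
            (EvidenceAssertion.build_unchecked(category=3), ["EVID.EXPERT_REQUIRED"]),
            (EvidenceAssertion.build_unchecked(category=4), ["EVID.PMID_REQUIRED"]),
            (EvidenceAssertion(category=5, pmids=(9,)), []),
            (EvidenceAssertion.build_unchecked(category=5), ["EVID.PMID_REQUIRED"]),
            (EvidenceAssertion(category=6, tools=("PolyPhen",)), []),
            (EvidenceAssertion.build_unchecked(category=6), ["EVID.CITATION_REQUIRED"]),
            (
                EvidenceAssertion.build_unchecked(category=1, trial_ids=("NCT123",)),
                ["EVID.NCT_FORMAT"],
            ),
        ],
    )
    def test_per_category_requirements(self, assertion, expected):
        assert rule_ids(check_evidence_citations(assertion)) == expected
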