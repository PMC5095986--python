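import pytest
from hypothesis import HealthCheck, settings

from mvld.model import (
    AlleleDescriptor,
    AlleleInterpretation,
    CancerInterpretation,
    Effect,
    EvidenceAssertion,
    LevelOfEvidence,
    MVLDRecord,
    OntologyTerm,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=75, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_record(**overrides) -> MVLDRecord:
    """A fully conformant predictive assertion (BRAF V600E in melanoma,
    sensitive to vemurafenib, CanDL Tier 1) with selective overrides per block."""
    parts = dict(
        descriptor=AlleleDescriptor(
            genome_build="GRCh38",
            gene_symbol="BRAF",
            chromosome="7",
            genomic_position=140753336,
            transcripts=("NM_004333.4",),
            protein_id="NP_004324.2",
        ),
        interpretation=AlleleInterpretation(
            somatic_classification="Confirmed somatic",
            dna_hgvs="c.1799T>A",
            protein_hgvs="p.V600E",
            variant_type="SNV",
            variant_consequence="Missense",
            pmids=(12068308,),
        ),
        cancer=CancerInterpretation(
            cancer_type=OntologyTerm(source="Oncotree", code="MEL", label="Melanoma"),
            biomarker_class="Predictive",
            therapeutic_context=("vemurafenib",),
            effect=Effect(term="sensitive"),
            level_of_evidence=LevelOfEvidence(schema_name="CanDL", level_label="Tier 1"),
            sub_level=(EvidenceAssertion(category=1, trial_ids=("NCT01006980",)),),
        ),
    )
    parts.update(overrides)
    return MVLDRecord(**parts)


@pytest.fixture
def record() -> MVLDRecord:
    return make_record()
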