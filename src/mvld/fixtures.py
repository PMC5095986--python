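"""Seeded generator of MVLD test corpora with controllable rule violations.

:func:`generate_records` produces deterministic corpora of conformant
records — gene symbols and RefSeq identifiers from the packaged gene table,
grammar-conforming HGVS edits across all four variant types, consequences,
cancer terms from the packaged ontology subset, biomarker classes, effects
and evidence assertions across all six sub-level categories — and, on
request, injects specific validation-rule violations, logging each one in a
:class:`FixtureManifest` so a validator run over the corpus can be scored
for exact recovery.

Record *i* of a corpus is generated from a sub-stream keyed by
``(seed, i)``, so the first ``k`` records of an ``n``-record corpus are the
same for every ``n >= k``.  Injected HGVS violations come from a fixed
catalogue of malformed strings so error text is stable for snapshot tests.

The generator emulates the shape of curated variant tables, not tumor
biology: draws are uniform over the valid spaces, with no mutational
spectrum, hotspot structure or drug–gene plausibility.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from typing import Callable, Mapping

from .hgvs import check_dna_hgvs, infer_variant_type
from .interop import gene_entries, oncotree_entries
from .model import (
    AlleleDescriptor,
    AlleleInterpretation,
    CancerInterpretation,
    Effect,
    EvidenceAssertion,
    ExpertOpinion,
    LevelOfEvidence,
    MVLDRecord,
    OntologyTerm,
    evolve,
)
from .tiering import NoTierableEvidence, TierFlags, assign_tier
from .validation import INJECTABLE_RULES
from .vocab import VOCABULARIES

__all__ = ["FixtureManifest", "InjectedViolation", "generate_records", "MALFORMED_DNA", "MALFORMED_PROTEIN"]

_BASES = "ACGT"
_AA = "ARNDCQEGHILKMFPSTWYV"

_DRUGS = (
    "vemurafenib", "dabrafenib", "trametinib", "imatinib", "erlotinib",
    "gefitinib", "osimertinib", "crizotinib", "olaparib", "cetuximab",
    "panitumumab", "sunitinib", "vandetanib", "everolimus", "palbociclib",
)
_TOOLS = ("PolyPhen-2", "SIFT", "MutationTaster", "CADD")
_EXPERTS = (
    ("A. Curator", "2016-05-12", "Example Cancer Center"),
    ("B. Reviewer", "2016-03-02", "University Molecular Tumor Board"),
    ("C. Pathologist", "2015-11-20", "Reference Sequencing Laboratory"),
)

#: Fixed catalogue of malformed DNA descriptions for deterministic injection.
MALFORMED_DNA: tuple[str, ...] = (
    "76A>T",            # no molecule prefix
    "c.76A>",           # missing alternate base
    "c.78_76del",       # end precedes start
    "c..76A>T",         # malformed position
    "c.76_78A>T",       # substitution over a range
)

#: Fixed catalogue of malformed protein descriptions.
MALFORMED_PROTEIN: tuple[str, ...] = (
    "V600E",            # no p. prefix
    "p.600VE",          # position before residues
    "p.Xyz600Glu",      # unknown amino-acid code
    "p.V600",           # missing alternate residue
)


@dataclass(frozen=True)
class InjectedViolation:
    index: int
    rule_id: str
    field_path: str


@dataclass(frozen=True)
class FixtureManifest:
    """What was injected where: ``(record index, rule id, field path)``."""

    seed: int
    n: int
    injected: tuple[InjectedViolation, ...] = ()

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "n": self.n,
                "injected": [
                    {"index": v.index, "rule_id": v.rule_id, "field_path": v.field_path}
                    for v in self.injected
                ],
            },
            indent=indent,
        )

    @classmethod
    def from_json(cls, text: str) -> "FixtureManifest":
        obj = json.loads(text)
        return cls(
            seed=obj["seed"],
            n=obj["n"],
            injected=tuple(
                InjectedViolation(v["index"], v["rule_id"], v["field_path"])
                for v in obj["injected"]
            ),
        )


def _record_rng(seed: int, i: int) -> random.Random:
    # sub-stream keyed by (seed, i): corpora are stable prefixes under n changes
    return random.Random(((seed & 0x7FFFFFFF) * 1_000_003 + i * 7_919 + 17) % (2**31))


def _pick_base(rng: random.Random, not_base: str | None = None) -> str:
    choices = [b for b in _BASES if b != not_base]
    return rng.choice(choices)


def _dna_edit(rng: random.Random, kind: str, pos: str, pos_end_plain: int | None = None) -> str:
    """Render one coding-relative edit at a (possibly offset/UTR) position."""
    if kind == "sub":
        ref = _pick_base(rng)
        return f"c.{pos}{ref}>{_pick_base(rng, ref)}"
    if kind == "del":
        if pos_end_plain is None:
            return f"c.{pos}del"
        return f"c.{pos}_{pos_end_plain}del"
    if kind == "ins":
        seq = "".join(_pick_base(rng) for _ in range(rng.randint(1, 3)))
        assert pos_end_plain is not None
        return f"c.{pos}_{pos_end_plain}ins{seq}"
    if kind == "delins":
        assert pos_end_plain is not None
        seq = "".join(_pick_base(rng) for _ in range(rng.randint(2, 4)))
        return f"c.{pos}_{pos_end_plain}delins{seq}"
    raise AssertionError(kind)


def _interpretive_edit(rng: random.Random, consequence: str) -> tuple[str, str | None]:
    """(dna_hgvs, protein_hgvs) consistent with the drawn consequence."""
    cds = rng.randint(100, 5000)
    k = rng.randint(10, 800)
    a1, a2 = rng.choice(_AA), rng.choice(_AA)
    while a2 == a1:
        a2 = rng.choice(_AA)

    if consequence == "Missense":
        return _dna_edit(rng, "sub", str(cds)), f"p.{a1}{k}{a2}"
    if consequence == "Nonsense":
        return _dna_edit(rng, "sub", str(cds)), f"p.{a1}{k}*"
    if consequence == "Silent":
        return _dna_edit(rng, "sub", str(cds)), f"p.{a1}{k}="
    if consequence == "Frame shift":
        length = rng.choice([1, 2])
        if rng.random() < 0.5:
            dna = _dna_edit(rng, "del", str(cds), cds + length - 1 if length > 1 else None)
        else:
            seq = "".join(_pick_base(rng) for _ in range(length))
            dna = f"c.{cds}_{cds + 1}ins{seq}"
        protein = f"p.{a1}{k}fs" if rng.random() < 0.5 else f"p.{a1}{k}{a2}fs*{rng.randint(2, 40)}"
        return dna, protein
    if consequence == "In-frame":
        choice = rng.random()
        if choice < 0.4:
            dna = f"c.{cds}_{cds + 2}del"
        elif choice < 0.7:
            seq = "".join(_pick_base(rng) for _ in range(3))
            dna = f"c.{cds}_{cds + 1}ins{seq}"
        else:
            seq = "".join(_pick_base(rng) for _ in range(3))
            dna = f"c.{cds}_{cds + 2}delins{seq}"
        return dna, f"p.{a1}{k}del"

    # noncoding consequences: DNA description only
    kind = rng.choice(["sub", "sub", "del", "ins", "delins"])
    if consequence == "5UTR":
        pos = f"-{rng.randint(1, 200)}"
    elif consequence == "3UTR":
        pos = f"*{rng.randint(1, 500)}"
    elif consequence == "Upstream":
        pos = f"-{rng.randint(1000, 5000)}"
    elif consequence == "Downstream":
        pos = f"*{rng.randint(1000, 5000)}"
    elif consequence == "Splice":
        pos = f"{cds}{rng.choice(['+', '-'])}{rng.randint(1, 2)}"
    elif consequence == "Splice-region":
        pos = f"{cds}{rng.choice(['+', '-'])}{rng.randint(3, 8)}"
    else:  # Intronic
        pos = f"{cds}{rng.choice(['+', '-'])}{rng.randint(20, 5000)}"
    if kind in ("ins", "delins", "del") and not pos.lstrip("-*").isdigit():
        kind = "sub"  # offset positions keep single-base edits for simplicity
    if kind == "sub":
        return _dna_edit(rng, "sub", pos), None
    if pos.startswith(("-", "*")):
        # UTR-anchored multi-base edits: keep within the same anchor system
        return _dna_edit(rng, "sub", pos), None
    base = int(pos)
    if kind == "del":
        return _dna_edit(rng, "del", pos, base + rng.randint(1, 3)), None
    if kind == "ins":
        return _dna_edit(rng, "ins", pos, base + 1), None
    return _dna_edit(rng, "delins", pos, base + rng.randint(1, 3)), None


def _evidence_assertion(rng: random.Random, category: int) -> EvidenceAssertion:
    pmid = lambda: rng.randint(10_000_000, 34_999_999)  # noqa: E731
    nct = lambda: f"NCT{rng.randint(0, 99_999_999):08d}"  # noqa: E731
    if category in (1, 2):
        return EvidenceAssertion(
            category=category,
            trial_ids=(nct(),),
            pmids=(pmid(),) if rng.random() < 0.5 else (),
        )
    if category == 3:
        name, date, affiliation = rng.choice(_EXPERTS)
        return EvidenceAssertion(
            category=3, expert=ExpertOpinion(name=name, date=date, affiliation=affiliation)
        )
    if category in (4, 5):
        return EvidenceAssertion(category=category, pmids=(pmid(),))
    if rng.random() < 0.5:
        return EvidenceAssertion(category=6, tools=(rng.choice(_TOOLS),))
    return EvidenceAssertion(category=6, pmids=(pmid(),))


def _clean_record(seed: int, i: int) -> MVLDRecord:
    rng = _record_rng(seed, i)
    gene = rng.choice(gene_entries())
    consequence = rng.choice(VOCABULARIES["variant_consequence"])
    dna, protein = _interpretive_edit(rng, consequence)
    variant_type = infer_variant_type(check_dna_hgvs(dna))

    descriptor = AlleleDescriptor(
        genome_build=rng.choice(["GRCh37", "GRCh38", "GRCh38.p7", "GRCh37.p13"]),
        gene_symbol=gene["symbol"],
        chromosome=gene["chromosome"],
        genomic_position=rng.randint(10_000, 150_000_000),
        transcripts=(gene["transcript"],),
        protein_id=gene["protein"] if protein is not None else None,
    )
    interpretation = AlleleInterpretation(
        somatic_classification=rng.choice(VOCABULARIES["somatic_classification"]),
        dna_hgvs=dna,
        protein_hgvs=protein,
        variant_type=variant_type,
        variant_consequence=consequence,
        pmids=tuple(rng.randint(10_000_000, 34_999_999) for _ in range(rng.randint(1, 3))),
    )

    onco = rng.choice(oncotree_entries())
    if rng.random() < 0.8:
        cancer_type = OntologyTerm(source="Oncotree", code=onco["oncotree_code"], label=onco["label"])
    else:
        cancer_type = OntologyTerm(source="NCIt", code=onco["ncit_code"], label=onco["label"])

    context: tuple[str, ...] = ()
    effect = None
    if rng.random() < 0.85:
        context = tuple(rng.sample(_DRUGS, rng.randint(1, 2)))
        if rng.random() < 0.8:
            term = rng.choice(VOCABULARIES["effect"])
            effect = Effect(
                term=term,
                free_text="variant–drug relationship outside the base vocabulary"
                if term == "other"
                else "",
            )

    evidence = tuple(
        _evidence_assertion(rng, rng.randint(1, 6)) for _ in range(rng.randint(1, 3))
    )
    flags = TierFlags(
        fda_approved=rng.random() < 0.25,
        nccn_recommended=rng.random() < 0.15,
        pathway_driver=rng.random() < 0.30,
    )
    try:
        tier = assign_tier(evidence, flags)
    except NoTierableEvidence:
        tier = assign_tier(evidence, TierFlags(pathway_driver=True))
    cancer = CancerInterpretation(
        cancer_type=cancer_type,
        biomarker_class=rng.choice(VOCABULARIES["biomarker_class"]),
        therapeutic_context=context,
        effect=effect,
        level_of_evidence=LevelOfEvidence(schema_name="CanDL", level_label=tier.level_label),
        sub_level=evidence,
    )
    return MVLDRecord(descriptor=descriptor, interpretation=interpretation, cancer=cancer)


# ---------------------------------------------------------------------------
# violation injection

Injector = Callable[[MVLDRecord, random.Random], tuple[MVLDRecord, str]]


def _null_field(block: str, field: str, empty=None) -> Injector:
    def inject(record: MVLDRecord, rng: random.Random) -> tuple[MVLDRecord, str]:
        new_block = evolve(getattr(record, block), **{field: empty})
        return evolve(record, **{block: new_block}), f"{block}.{field}"

    return inject


def _with_effect_no_context(record: MVLDRecord, rng: random.Random) -> tuple[MVLDRecord, str]:
    effect = record.cancer.effect or Effect(term="sensitive")
    if effect.term == "other" and not effect.free_text:
        effect = Effect(term="sensitive")
    cancer = evolve(record.cancer, effect=effect, therapeutic_context=())
    return evolve(record, cancer=cancer), "cancer.therapeutic_context"


def _with_other_no_text(record: MVLDRecord, rng: random.Random) -> tuple[MVLDRecord, str]:
    cancer = evolve(
        record.cancer,
        effect=Effect.build_unchecked(term="other", free_text=""),
        therapeutic_context=record.cancer.therapeutic_context or ("imatinib",),
    )
    return evolve(record, cancer=cancer), "cancer.effect.free_text"


def _bogus_term(block: str, field: str, value: str, path: str | None = None) -> Injector:
    def inject(record: MVLDRecord, rng: random.Random) -> tuple[MVLDRecord, str]:
        new_block = evolve(getattr(record, block), **{field: value})
        return evolve(record, **{block: new_block}), path or f"{block}.{field}"

    return inject


def _bogus_effect(record: MVLDRecord, rng: random.Random) -> tuple[MVLDRecord, str]:
    cancer = evolve(
        record.cancer,
        effect=Effect.build_unchecked(term="refractory", free_text=""),
        therapeutic_context=record.cancer.therapeutic_context or ("imatinib",),
    )
    return evolve(record, cancer=cancer), "cancer.effect.term"


def _malformed_dna(record: MVLDRecord, rng: random.Random) -> tuple[MVLDRecord, str]:
    bad = rng.choice(MALFORMED_DNA)
    interp = evolve(record.interpretation, dna_hgvs=bad)
    return evolve(record, interpretation=interp), "interpretation.dna_hgvs"


def _malformed_protein(record: MVLDRecord, rng: random.Random) -> tuple[MVLDRecord, str]:
    bad = rng.choice(MALFORMED_PROTEIN)
    interp = evolve(record.interpretation, protein_hgvs=bad)
    return evolve(record, interpretation=interp), "interpretation.protein_hgvs"


def _no_hgvs(record: MVLDRecord, rng: random.Random) -> tuple[MVLDRecord, str]:
    interp = evolve(record.interpretation, dna_hgvs=None, protein_hgvs=None)
    return evolve(record, interpretation=interp), "interpretation.dna_hgvs"


def _bad_evidence(category: int, path_field: str, **fields) -> Injector:
    def inject(record: MVLDRecord, rng: random.Random) -> tuple[MVLDRecord, str]:
        bad = EvidenceAssertion.build_unchecked(category=category, **fields)
        cancer = evolve(record.cancer, sub_level=(bad,))
        return evolve(record, cancer=cancer), f"cancer.sub_level[0].{path_field}"

    return inject


INJECTORS: Mapping[str, Injector] = {
    "REQ.GENOME_BUILD": _null_field("descriptor", "genome_build"),
    "REQ.GENE_NAME": _null_field("descriptor", "gene_symbol"),
    "REQ.CHROMOSOME": _null_field("descriptor", "chromosome"),
    "REQ.DNA_POSITION": _null_field("descriptor", "genomic_position"),
    "REQ.TRANSCRIPT": _null_field("descriptor", "transcripts", empty=()),
    "REQ.SOMATIC_CLASS": _null_field("interpretation", "somatic_classification"),
    "REQ.VARIANT_TYPE": _null_field("interpretation", "variant_type"),
    "REQ.CONSEQUENCE": _null_field("interpretation", "variant_consequence"),
    "REQ.CANCER_TYPE": _null_field("cancer", "cancer_type"),
    "REQ.BIOMARKER_CLASS": _null_field("cancer", "biomarker_class"),
    "REQ.EVIDENCE_LEVEL": _null_field("cancer", "level_of_evidence"),
    "COND.HGVS_PRESENT": _no_hgvs,
    "COND.EFFECT_CONTEXT": _with_effect_no_context,
    "COND.EFFECT_OTHER_TEXT": _with_other_no_text,
    "VOC.SOMATIC_CLASS": _bogus_term("interpretation", "somatic_classification", "Somatic"),
    "VOC.VARIANT_TYPE": _bogus_term("interpretation", "variant_type", "INDEL"),
    "VOC.CONSEQUENCE": _bogus_term("interpretation", "variant_consequence", "Nonsynonymous"),
    "VOC.BIOMARKER_CLASS": _bogus_term("cancer", "biomarker_class", "Theranostic"),
    "VOC.EFFECT": _bogus_effect,
    "HGVS.DNA": _malformed_dna,
    "HGVS.PROTEIN": _malformed_protein,
    "EVID.TRIAL_REQUIRED": _bad_evidence(1, "trial_ids"),
    "EVID.EXPERT_REQUIRED": _bad_evidence(3, "expert"),
    "EVID.PMID_REQUIRED": _bad_evidence(4, "pmids"),
    "EVID.CITATION_REQUIRED": _bad_evidence(6, "pmids"),
    "EVID.NCT_FORMAT": _bad_evidence(1, "trial_ids", trial_ids=("NCT123",)),
}

assert set(INJECTORS) == set(INJECTABLE_RULES)


def generate_records(
    n: int,
    seed: int,
    error_spec: Mapping[str, int] | None = None,
) -> tuple[list[MVLDRecord], FixtureManifest]:
    """Generate ``n`` records from ``seed``; inject the requested violations.

    ``error_spec`` maps rule ids (from the injectable subset of the
    validation registry) to the number of records that should violate that
    rule; each injection lands on a distinct record, so the total must not
    exceed ``n``.  With an empty spec every record validates cleanly under
    the strict profile.  Output is deterministic for fixed
    ``(n, seed, error_spec)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    error_spec = dict(error_spec or {})
    unknown = sorted(set(error_spec) - set(INJECTORS))
    if unknown:
        raise ValueError(f"unknown or non-injectable rule ids: {unknown}")
    if any(count < 0 for count in error_spec.values()):
        raise ValueError("violation counts must be >= 0")
    total = sum(error_spec.values())
    if total > n:
        raise ValueError(f"requested {total} violations for {n} records")

    assign_rng = random.Random(((seed & 0x7FFFFFFF) * 2_654_435 + 12_345) % (2**31))
    targets = sorted(assign_rng.sample(range(n), total))
    schedule = {
        idx: rule
        for idx, rule in zip(
            targets,
            [rule for rule in sorted(error_spec) for _ in range(error_spec[rule])],
        )
    }

    records: list[MVLDRecord] = []
    injected: list[InjectedViolation] = []
    for i in range(n):
        record = _clean_record(seed, i)
        if i in schedule:
            rule = schedule[i]
            record, path = INJECTORS[rule](record, _record_rng(seed ^ 0x5A5A5A, i))
            injected.append(InjectedViolation(index=i, rule_id=rule, field_path=path))
        records.append(record)
    return records, FixtureManifest(seed=seed, n=n, injected=tuple(injected))
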