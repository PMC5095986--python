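"""CanDL tier assignment vs. a brute-force oracle, and sub-level categories."""

import itertools

import pytest

from mvld.model import EvidenceAssertion, ExpertOpinion
from mvld.tiering import (
    SUBLEVEL_LABELS,
    TIER_SENTENCES,
    NoTierableEvidence,
    TierFlags,
    TierResult,
    UncategorizableEvidence,
    assign_tier,
    categorize_sublevel,
)


def oracle_tier(fda, nccn, pathway, categories):
    """Independent minimum-applicable-tier oracle."""
    applicable = []
    if fda or nccn:
        applicable.append(1)
    if categories & {1, 2, 4}:
        applicable.append(2)
    if 5 in categories:
        applicable.append(3)
    if pathway or 6 in categories:
        applicable.append(4)
    return min(applicable) if applicable else None


def _assertion(category: int) -> EvidenceAssertion:
    if category in (1, 2):
        return EvidenceAssertion(category=category, trial_ids=("NCT00000001",))
    if category == 3:
        return EvidenceAssertion(
            category=3, expert=ExpertOpinion(name="A", date="2016-01-01", affiliation="X")
        )
    if category == 6:
        return EvidenceAssertion(category=6, tools=("SIFT",))
    return EvidenceAssertion(category=category, pmids=(1234567,))


def test_examples_from_the_scheme():
    assert assign_tier([], TierFlags(fda_approved=True)).tier == 1
    assert assign_tier([_assertion(5)]).tier == 3
    assert assign_tier([_assertion(4), _assertion(6)]).tier == 2
    assert assign_tier([], TierFlags(pathway_driver=True)).tier == 4


def test_matches_brute_force_oracle_on_all_combinations():
    """Exhaustive over 2^3 flag settings x 2^6 category-presence sets."""
    for fda, nccn, pathway in itertools.product([False, True], repeat=3):
        for mask in itertools.product([False, True], repeat=6):
            categories = {c for c, present in zip(range(1, 7), mask) if present}
            evidence = [_assertion(c) for c in sorted(categories)]
            flags = TierFlags(fda, nccn, pathway)
            expected = oracle_tier(fda, nccn, pathway, categories)
            if expected is None:
                with pytest.raises(NoTierableEvidence):
                    assign_tier(evidence, flags)
            else:
                assert assign_tier(evidence, flags).tier == expected


def test_monotone_under_evidence_addition():
    """More evidence or more flags never weakens (raises) the tier number."""
    base_sets = [[], [_assertion(5)], [_assertion(6)], [_assertion(3)]]
    for base in base_sets:
        for flags in (TierFlags(), TierFlags(pathway_driver=True), TierFlags(fda_approved=True)):
            try:
                before = assign_tier(base, flags).tier
            except NoTierableEvidence:
                before = 5  # weaker than any tier
            for extra in range(1, 7):
                try:
                    after = assign_tier(base + [_assertion(extra)], flags).tier
                except NoTierableEvidence:
                    after = 5
                assert after <= before


def test_sentence_always_matches_tier():
    for tier, sentence in TIER_SENTENCES.items():
        assert f"Alteration" in sentence
        with pytest.raises(ValueError):
            TierResult("CanDL", tier, TIER_SENTENCES[1 if tier != 1 else 2])
    result = assign_tier([_assertion(5)])
    assert result.sentence == TIER_SENTENCES[result.tier]
    assert result.level_label == "Tier 3"


def test_supporting_lists_only_matching_evidence():
    result = assign_tier([_assertion(4), _assertion(5), _assertion(6)])
    assert result.tier == 2
    assert [a.category for a in result.supporting] == [4]


def test_expert_opinion_alone_is_not_tierable():
    with pytest.raises(NoTierableEvidence):
        assign_tier([_assertion(3)])
    with pytest.raises(NoTierableEvidence):
        assign_tier([])


class TestSublevel:
    def test_six_categories_exist(self):
        assert sorted(SUBLEVEL_LABELS) == [1, 2, 3, 4, 5, 6]

    def test_trial_citation_prospective_vs_retrospective(self):
        a = EvidenceAssertion(category=1, trial_ids=("NCT00000001",))
        assert categorize_sublevel(a, prospective=True) == 1
        assert categorize_sublevel(a, retrospective=True) == 2
        assert categorize_sublevel(a) == 2

    def test_expert_and_tools_take_precedence(self):
        assert categorize_sublevel(_assertion(3)) == 3
        assert categorize_sublevel(_assertion(6)) == 6

    def test_pmid_with_kind_hint(self):
        a = EvidenceAssertion(category=4, pmids=(1,))
        assert categorize_sublevel(a, kind_hint="case_report") == 4
        assert categorize_sublevel(a, kind_hint="preclinical") == 5
        assert categorize_sublevel(a, kind_hint="inferential") == 6
        with pytest.raises(UncategorizableEvidence):
            categorize_sublevel(a)

    def test_empty_item_is_uncategorizable(self):
        with pytest.raises(UncategorizableEvidence):
            categorize_sublevel(EvidenceAssertion.build_unchecked(category=4))
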