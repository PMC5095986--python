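"""Assign a CanDL level of evidence from evidence assertions and flags.

The strongest (numerically smallest) applicable tier wins: an FDA-approved
therapy gives Tier 1 regardless of the literature; preclinical-only support
gives Tier 3; a pathway-driver rationale alone gives Tier 4.  Each result
carries the scheme's fixed structured sentence.
"""

from mvld import EvidenceAssertion, TierFlags, assign_tier, categorize_sublevel

preclinical = EvidenceAssertion(category=5, pmids=(26619011,))
trial = EvidenceAssertion(category=1, trial_ids=("NCT01006980",))

for label, evidence, flags in [
    ("FDA-approved therapy", [], TierFlags(fda_approved=True)),
    ("clinical trial", [trial], TierFlags()),
    ("preclinical only", [preclinical], TierFlags()),
    ("pathway driver", [], TierFlags(pathway_driver=True)),
]:
    result = assign_tier(evidence, flags)
    print(f"{label:22s} Tier {result.tier}: {result.sentence}")

# sub-level categorization of a single evidence item
print("trial citation, prospective ->", categorize_sublevel(trial, prospective=True))
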