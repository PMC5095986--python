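"""CanDL level-of-evidence tiering and sub-level categorization.

The Cancer Driver Log (CanDL) scheme stratifies the clinical evidence behind
a somatic variant assertion into four tiers, each carried by a fixed
structured sentence (strongest first):

1. matching FDA-approved or NCCN-recommended therapy;
2. matching therapy supported by clinical trials, case reports or
   exceptional responders;
3. response/resistance prediction supported by preclinical (in vitro /
   in vivo) data;
4. putative oncogenic driver based on functional pathway activation.

:func:`assign_tier` returns the strongest (numerically smallest) tier whose
predicate is met by the supplied evidence assertions and regulatory flags,
together with the verbatim sentence and the assertions/flags that support it.
:func:`categorize_sublevel` places a single evidence item into the 1–6
sub-level scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Optional, Sequence

from .model import EvidenceAssertion

__all__ = [
    "TIER_SENTENCES",
    "SUBLEVEL_LABELS",
    "TierFlags",
    "TierResult",
    "NoTierableEvidence",
    "UncategorizableEvidence",
    "assign_tier",
    "categorize_sublevel",
]

#: The four structured tier sentences, verbatim; single source of truth.
TIER_SENTENCES: MappingProxyType[int, str] = MappingProxyType(
    {
        1: "Alteration has matching FDA approved or NCCN recommended therapy",
        2: (
            "Alteration has matching therapy based on evidence from clinical "
            "trials, case reports, or exceptional responders"
        ),
        3: (
            "Alteration predicts for response or resistance to therapy based on "
            "evidence from pre-clinical data (in vitro or in vivo models)"
        ),
        4: (
            "Alteration is a putative oncogenic driver based on functional "
            "activation of a pathway"
        ),
    }
)

#: The six sub-level-of-evidence categories.
SUBLEVEL_LABELS: MappingProxyType[int, str] = MappingProxyType(
    {
        1: "prospective trials/studies",
        2: "retrospective trials/studies and metadata analysis",
        3: "expert opinion",
        4: "case reports",
        5: "published preclinical data",
        6: "inferential data or publications",
    }
)

# which sub-level categories feed which tier (tier 1 is flag-driven)
_TIER_CATEGORIES: MappingProxyType[int, frozenset[int]] = MappingProxyType(
    {
        2: frozenset({1, 2, 4}),  # trials (pro/retrospective), case reports
        3: frozenset({5}),  # preclinical publications
        4: frozenset({6}),  # inferential / in-silico
    }
)


class NoTierableEvidence(ValueError):
    """No supplied assertion or flag satisfies any tier predicate."""


class UncategorizableEvidence(ValueError):
    """An evidence item carries nothing that places it in a sub-level."""


@dataclass(frozen=True)
class TierFlags:
    """Regulatory / biological context flags supplied by the caller.

    FDA/NCCN status is not computable from drug names, so it is asserted
    explicitly; ``pathway_driver`` asserts functional pathway activation.
    """

    fda_approved: bool = False
    nccn_recommended: bool = False
    pathway_driver: bool = False


@dataclass(frozen=True)
class TierResult:
    """A CanDL tier assignment with its justification.

    ``sentence`` is always the fixed sentence of ``tier``; ``supporting``
    lists the evidence assertions, and ``supporting_flags`` the flag names,
    that match the returned tier.
    """

    schema_name: str
    tier: int
    sentence: str
    supporting: tuple[EvidenceAssertion, ...] = ()
    supporting_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tier not in TIER_SENTENCES:
            raise ValueError(f"tier must be 1..4, got {self.tier}")
        if self.sentence != TIER_SENTENCES[self.tier]:
            raise ValueError(f"sentence does not match tier {self.tier}")

    @property
    def level_label(self) -> str:
        return f"Tier {self.tier}"


def assign_tier(
    evidence: Sequence[EvidenceAssertion] | Iterable[EvidenceAssertion] = (),
    flags: TierFlags | None = None,
) -> TierResult:
    """Assign the strongest applicable CanDL tier.

    Tier predicates, strongest first: FDA-approved or NCCN-recommended
    therapy → 1; any trial, retrospective-study or case-report assertion
    (sub-level 1, 2 or 4) → 2; any preclinical assertion (sub-level 5) → 3;
    a pathway-driver flag or inferential assertion (sub-level 6) → 4.
    Adding evidence or enabling flags can only strengthen (never raise the
    number of) the result.

    Raises :class:`NoTierableEvidence` when nothing matches — including the
    case of expert-opinion-only evidence (sub-level 3), which CanDL does not
    tier on its own.
    """
    flags = flags or TierFlags()
    evidence = tuple(evidence)

    if flags.fda_approved or flags.nccn_recommended:
        names = tuple(
            n for n, on in (
                ("fda_approved", flags.fda_approved),
                ("nccn_recommended", flags.nccn_recommended),
            ) if on
        )
        return TierResult("CanDL", 1, TIER_SENTENCES[1], supporting_flags=names)

    for tier in (2, 3):
        matching = tuple(a for a in evidence if a.category in _TIER_CATEGORIES[tier])
        if matching:
            return TierResult("CanDL", tier, TIER_SENTENCES[tier], supporting=matching)

    tier4 = tuple(a for a in evidence if a.category in _TIER_CATEGORIES[4])
    if flags.pathway_driver or tier4:
        return TierResult(
            "CanDL",
            4,
            TIER_SENTENCES[4],
            supporting=tier4,
            supporting_flags=("pathway_driver",) if flags.pathway_driver else (),
        )

    raise NoTierableEvidence(
        "no tierable evidence: no flag set and no assertion of sub-level 1, 2, 4, 5 or 6"
    )


def categorize_sublevel(
    assertion: EvidenceAssertion,
    *,
    prospective: bool = False,
    retrospective: bool = False,
    kind_hint: Optional[str] = None,
) -> int:
    """Place one evidence item into the six-category sub-level scheme.

    Precedence: a cited expert → 3 (expert opinion); named in-silico programs
    → 6; a clinical-trial identifier → 1 if ``prospective`` else 2
    (``retrospective`` documents intent but 2 is also the default for trial
    citations); otherwise the literature kind must be declared via
    ``kind_hint``: ``"case_report"`` → 4, ``"preclinical"`` → 5,
    ``"inferential"`` → 6.
    """
    if assertion.expert is not None:
        return 3
    if assertion.tools:
        return 6
    if assertion.trial_ids:
        if prospective and retrospective:
            raise ValueError("a trial citation is prospective or retrospective, not both")
        return 1 if prospective else 2
    if assertion.pmids:
        hints = {"case_report": 4, "preclinical": 5, "inferential": 6}
        if kind_hint in hints:
            return hints[kind_hint]
        raise UncategorizableEvidence(
            "a bare PMID needs a kind hint: case_report, preclinical or inferential"
        )
    raise UncategorizableEvidence(
        "uncategorizable evidence item: no trial id, PMID, expert or program cited"
    )
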