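"""Blood–liver variant concordance per proband.

Comparing the prioritized variant set called from constitutional (blood) DNA
with the set called from liver tissue tests whether candidate variants are
germline or arose somatically during organogenesis. "Identical" demands
genotype-level identity (same key *and* same zygosity), not mere site
overlap; probands with no surviving variant in either tissue are
"undetected", a distinct state from concordant-with-content.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

from .model import VariantKey, Zygosity

#: One tissue's prioritized calls for a proband: key -> proband zygosity.
TissueCalls = Mapping[VariantKey, Zygosity]


class ConcordanceStatus(enum.Enum):
    IDENTICAL = "identical"
    DISCORDANT = "discordant"
    UNDETECTED = "undetected"


@dataclass(frozen=True)
class ConcordanceResult:
    proband_id: str
    status: ConcordanceStatus
    shared: frozenset[tuple[VariantKey, Zygosity]]
    blood_only: frozenset[tuple[VariantKey, Zygosity]]
    liver_only: frozenset[tuple[VariantKey, Zygosity]]


def compare_tissues(
    proband_id: str, blood: TissueCalls, liver: TissueCalls
) -> ConcordanceResult:
    """Partition the union of two tissues' calls into shared / blood-only /
    liver-only and assign a concordance status.

    A site called in both tissues with different zygosity contributes to
    both exclusive sets (genotype identity is required for sharing).
    """
    b = frozenset(blood.items())
    l = frozenset(liver.items())
    shared = b & l
    blood_only = b - l
    liver_only = l - b
    if not b and not l:
        status = ConcordanceStatus.UNDETECTED
    elif blood_only or liver_only:
        status = ConcordanceStatus.DISCORDANT
    else:
        status = ConcordanceStatus.IDENTICAL
    return ConcordanceResult(proband_id, status, shared, blood_only, liver_only)


@dataclass
class ConcordanceSummary:
    n_identical: int = 0
    n_undetected: int = 0
    n_discordant: int = 0
    n_somatic_variants: int = 0  # total liver-only calls = putative somatic


def summarize_concordance(results: Iterable[ConcordanceResult]) -> ConcordanceSummary:
    """Cohort counts over paired probands; liver-only calls are the putative
    somatic variant count."""
    s = ConcordanceSummary()
    for r in results:
        if r.status is ConcordanceStatus.IDENTICAL:
            s.n_identical += 1
        elif r.status is ConcordanceStatus.UNDETECTED:
            s.n_undetected += 1
        else:
            s.n_discordant += 1
        s.n_somatic_variants += len(r.liver_only)
    return s
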