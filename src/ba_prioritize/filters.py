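"""Rarity, consequence and deleteriousness filtering of classified variants.

The cascade keeps a variant only if it (a) received a non-none inheritance
mode, (b) has a protein-relevant consequence, (c) is rare — minor allele
frequency strictly below the threshold in the configured combination of
population databases — and (d) is predicted deleterious (CADD Phred strictly
above the threshold; >10 marks the 10% most deleterious substitutions
genome-wide).

The multi-database rarity rule is deliberately configurable: published
candidate tables sometimes retain variants at or above the nominal threshold
in one database while being rare in the others, which an ``all``-databases
rule would reject. ``any`` (the default) keeps a variant rare in at least one
database; ``majority`` needs more than half; ``all`` needs every database.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .inheritance import classify_inheritance
from .model import (
    DEFAULT_MAF_DATABASES,
    GRCH38_X_PAR,
    AnnotatedVariant,
    InheritanceCall,
    Mode,
    TrioRecord,
    VariantKey,
)


class MafPolicy(enum.Enum):
    ALL = "all"          # rare in every database
    MAJORITY = "majority"  # rare in more than half
    ANY = "any"          # rare in at least one


class MissingCaddAction(enum.Enum):
    FAIL = "fail"
    ERROR = "error"


@dataclass(frozen=True)
class FilterConfig:
    maf_max: float = 0.01
    maf_policy: MafPolicy = MafPolicy.ANY
    cadd_min: float = 10.0
    allowed_consequences: frozenset[str] = frozenset({"missense", "stopgain", "splice"})
    maf_databases: tuple[str, ...] = DEFAULT_MAF_DATABASES
    missing_cadd: MissingCaddAction = MissingCaddAction.FAIL

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_max < 1.0):
            raise ValueError(f"maf_max must be in (0,1), got {self.maf_max}")
        if self.cadd_min < 0:
            raise ValueError(f"cadd_min must be >= 0, got {self.cadd_min}")


@dataclass(frozen=True)
class RarityVerdict:
    passed: bool
    per_database: Mapping[str, bool]  # database -> rare here?


def filter_rarity(v: AnnotatedVariant, cfg: FilterConfig) -> RarityVerdict:
    """Strict per-database MAF < threshold, combined per the policy.

    A database absent from the variant's MAF map counts as frequency 0
    (unobserved allele), which trivially passes.
    """
    unknown = set(v.maf) - set(cfg.maf_databases)
    if unknown:
        raise ValueError(f"{v.key}: MAF databases not in config: {sorted(unknown)}")
    per_db = {db: v.maf.get(db, 0.0) < cfg.maf_max for db in cfg.maf_databases}
    n_pass = sum(per_db.values())
    n = len(per_db)
    if cfg.maf_policy is MafPolicy.ALL:
        overall = n_pass == n
    elif cfg.maf_policy is MafPolicy.MAJORITY:
        overall = n_pass * 2 > n
    else:
        overall = n_pass >= 1
    return RarityVerdict(overall, per_db)


def filter_deleteriousness(v: AnnotatedVariant, cfg: FilterConfig) -> bool:
    """Strict CADD Phred > threshold; a boundary score fails."""
    if v.cadd_phred is None:
        if cfg.missing_cadd is MissingCaddAction.ERROR:
            raise ValueError(f"{v.key}: CADD score missing")
        return False
    return v.cadd_phred > cfg.cadd_min


class Reason(enum.Enum):
    """Enumerated audit vocabulary for why a variant was kept or dropped."""

    PASS = "PASS"
    MOI_NONE = "MOI_NONE"
    FAIL_CONSEQUENCE = "FAIL_CONSEQUENCE"
    FAIL_MAF = "FAIL_MAF"
    FAIL_CADD = "FAIL_CADD"
    NO_ANNOTATION = "NO_ANNOTATION"


@dataclass(frozen=True)
class AuditRow:
    """All verdicts for one (proband, variant) pair, for audit trails."""

    record: TrioRecord
    annotation: Optional[AnnotatedVariant]
    inheritance: Optional[InheritanceCall]
    rarity: Optional[RarityVerdict]
    cadd_pass: Optional[bool]
    consequence_pass: Optional[bool]
    surviving: bool
    reasons: tuple[Reason, ...]


@dataclass
class PrioritizationReport:
    rows: list[AuditRow] = field(default_factory=list)

    @property
    def survivors(self) -> list[AuditRow]:
        return [r for r in self.rows if r.surviving]

    def surviving_genes(self) -> set[str]:
        return {r.annotation.gene for r in self.survivors if r.annotation}


def run_prioritization(
    records: Iterable[TrioRecord],
    annotations: Mapping[VariantKey, AnnotatedVariant],
    cfg: FilterConfig = FilterConfig(),
    par_intervals=GRCH38_X_PAR,
) -> PrioritizationReport:
    """Classify and filter every trio record; keep the full audit trail.

    A variant survives iff its consequence is allowed, it is rare and
    deleterious under ``cfg``, and it received a non-none inheritance mode.
    Records without an annotation are excluded (reason ``NO_ANNOTATION``)
    rather than silently dropped.
    """
    report = PrioritizationReport()
    for rec in records:
        ann = annotations.get(rec.key)
        reasons: list[Reason] = []
        if ann is None:
            report.rows.append(
                AuditRow(rec, None, None, None, None, None, False, (Reason.NO_ANNOTATION,))
            )
            continue
        inh = classify_inheritance(rec, par_intervals)
        rarity = filter_rarity(ann, cfg)
        cadd_ok = filter_deleteriousness(ann, cfg)
        cons_ok = ann.consequence in cfg.allowed_consequences
        if inh.mode is Mode.NONE:
            reasons.append(Reason.MOI_NONE)
        if not cons_ok:
            reasons.append(Reason.FAIL_CONSEQUENCE)
        if not rarity.passed:
            reasons.append(Reason.FAIL_MAF)
        if not cadd_ok:
            reasons.append(Reason.FAIL_CADD)
        surviving = not reasons
        report.rows.append(
            AuditRow(
                rec, ann, inh, rarity, cadd_ok, cons_ok, surviving,
                tuple(reasons) if reasons else (Reason.PASS,),
            )
        )
    return report
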