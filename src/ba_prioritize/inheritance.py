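"""Trio inheritance-mode classification.

Each proband's variant is assigned exactly one of three disease-relevant
modes — de novo, autosomal homozygous-recessive, or X-linked — or ``none``.
The rules operate on zygosity classes and are applied in a fixed priority
order (de novo > homozygous-recessive > X-linked), making the categories
mutually exclusive per variant:

1. **de novo** — the proband carries the alternate allele, at least one
   parent is genotyped, and every genotyped parent carries zero alternate
   copies. With one parent ungenotyped the call is only *putative*.
2. **homozygous recessive** — autosomal (or pseudoautosomal) site, proband
   homozygous alternate, each parent a heterozygous carrier (exactly one
   alternate copy). One missing parent with the other HET gives a putative
   call.
3. **X-linked** — non-PAR chrX site, proband carries the alternate
   (hemizygous for males; HET or HOM_ALT for females) and the mother is a
   carrier. For males the father's X is never transmitted and is not
   consulted; a female HOM_ALT call additionally needs the father observed
   to be confirmed rather than putative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .model import (
    GRCH38_X_PAR,
    AnnotatedVariant,
    InheritanceCall,
    Mode,
    Sex,
    Tier,
    TrioRecord,
    VariantKey,
    Zygosity,
    is_non_par_x,
)


class GenotypeInconsistency(ValueError):
    """A genotype impossible for the sample's sex/chromosome context."""


def _validate(record: TrioRecord, x_nonpar: bool) -> None:
    if record.proband is Zygosity.MISSING:
        raise ValueError(f"{record.key}: proband genotype missing; cannot classify")
    if record.mother.is_hemi:
        raise GenotypeInconsistency(f"{record.key}: hemizygous maternal genotype")
    if record.proband.is_hemi:
        if record.proband_sex is not Sex.MALE:
            raise GenotypeInconsistency(
                f"{record.key}: hemizygous genotype in female proband"
            )
        if not x_nonpar:
            raise GenotypeInconsistency(
                f"{record.key}: hemizygous proband genotype outside non-PAR chrX"
            )
    if record.father.is_hemi and not x_nonpar:
        raise GenotypeInconsistency(
            f"{record.key}: hemizygous paternal genotype outside non-PAR chrX"
        )


def classify_inheritance(
    record: TrioRecord, par_intervals=GRCH38_X_PAR
) -> InheritanceCall:
    """Assign the inheritance mode of one variant in one proband.

    Raises
    ------
    GenotypeInconsistency
        For hemizygous calls on autosomes or in female probands.
    ValueError
        If the proband genotype is MISSING.
    """
    x_nonpar = is_non_par_x(record.key, par_intervals)
    _validate(record, x_nonpar)

    def call(mode: Mode, tier: Tier, why: str) -> InheritanceCall:
        return InheritanceCall(record.key, record.proband_id, mode, tier, why)

    if not record.proband.carries_alt:
        return call(Mode.NONE, Tier.CONFIRMED, "proband_no_alt")

    mother, father = record.mother, record.father
    n_missing = sum(z is Zygosity.MISSING for z in (mother, father))

    # rule 1: de novo — all genotyped parents alt-free, >=1 genotyped
    if n_missing < 2 and all(
        z.is_ref for z in (mother, father) if z is not Zygosity.MISSING
    ):
        tier = Tier.CONFIRMED if n_missing == 0 else Tier.PUTATIVE
        return call(Mode.DE_NOVO, tier, "absent_from_genotyped_parents")

    # rule 2: autosomal homozygous recessive — HET x HET carriers
    if not x_nonpar and record.proband is Zygosity.HOM_ALT:
        if mother is Zygosity.HET and father is Zygosity.HET:
            return call(
                Mode.HOMOZYGOUS_RECESSIVE, Tier.CONFIRMED, "biparental_het_carriers"
            )
        if n_missing == 1 and (mother is Zygosity.HET or father is Zygosity.HET):
            return call(
                Mode.HOMOZYGOUS_RECESSIVE, Tier.PUTATIVE, "one_het_carrier_one_missing"
            )

    # rule 3: X-linked — maternally carried alt on non-PAR chrX
    if x_nonpar:
        proband_x_ok = (
            record.proband is Zygosity.HEMI_ALT
            if record.proband_sex is Sex.MALE
            else record.proband in (Zygosity.HET, Zygosity.HOM_ALT)
        )
        mother_carrier = mother in (Zygosity.HET, Zygosity.HOM_ALT)
        if proband_x_ok and mother_carrier:
            needs_father = (
                record.proband_sex is Sex.FEMALE
                and record.proband is Zygosity.HOM_ALT
            )
            tier = (
                Tier.PUTATIVE
                if needs_father and father is Zygosity.MISSING
                else Tier.CONFIRMED
            )
            return call(Mode.X_LINKED, tier, "maternal_carrier_x")

    return call(Mode.NONE, Tier.CONFIRMED, "no_mode_pattern")


@dataclass
class ModeSummary:
    """Cohort-level breakdown of classified (non-none) variants."""

    counts: dict[Mode, int] = field(default_factory=dict)
    percentages: dict[Mode, int] = field(default_factory=dict)
    genes: dict[Mode, int] = field(default_factory=dict)
    probands: dict[Mode, int] = field(default_factory=dict)
    total: int = 0


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


_REAL_MODES = (Mode.X_LINKED, Mode.DE_NOVO, Mode.HOMOZYGOUS_RECESSIVE)


def summarize_modes(
    calls: Iterable[InheritanceCall],
    annotations: Optional[Mapping[VariantKey, AnnotatedVariant]] = None,
) -> ModeSummary:
    """Count variants, distinct genes and distinct probands per mode.

    Percentages are of the classified (non-none) total, rounded half-up to
    integers; input is deduplicated per (proband, key).
    """
    seen: set[tuple[str, VariantKey]] = set()
    s = ModeSummary(
        counts={m: 0 for m in _REAL_MODES},
        percentages={m: 0 for m in _REAL_MODES},
        genes={m: 0 for m in _REAL_MODES},
        probands={m: 0 for m in _REAL_MODES},
    )
    gene_sets: dict[Mode, set[str]] = {m: set() for m in _REAL_MODES}
    proband_sets: dict[Mode, set[str]] = {m: set() for m in _REAL_MODES}
    for c in calls:
        if (c.proband_id, c.key) in seen:
            continue
        seen.add((c.proband_id, c.key))
        if c.mode is Mode.NONE:
            continue
        s.counts[c.mode] += 1
        s.total += 1
        proband_sets[c.mode].add(c.proband_id)
        if annotations is not None and c.key in annotations:
            gene_sets[c.mode].add(annotations[c.key].gene)
    for m in _REAL_MODES:
        s.genes[m] = len(gene_sets[m])
        s.probands[m] = len(proband_sets[m])
        s.percentages[m] = (
            _round_half_up(100.0 * s.counts[m] / s.total) if s.total else 0
        )
    return s
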