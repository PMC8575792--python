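"""Domain types for trio-based variant prioritization.

The pipeline operates on abstract genotype *zygosity classes* rather than
literal allele strings: published trio tables frequently print alleles on
inconsistent strands, while the inheritance logic only needs to know how many
alternate alleles each family member carries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Zygosity(enum.Enum):
    """Abstract genotype call for one sample at one site.

    HEMI_* is reserved for hemizygous contexts (males on non-PAR chrX or
    chrY); MISSING covers uncalled genotypes and absent family members.
    """

    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    HEMI_REF = "HEMI_REF"
    HEMI_ALT = "HEMI_ALT"
    MISSING = "MISSING"

    @property
    def carries_alt(self) -> bool:
        return self in (Zygosity.HET, Zygosity.HOM_ALT, Zygosity.HEMI_ALT)

    @property
    def is_hemi(self) -> bool:
        return self in (Zygosity.HEMI_REF, Zygosity.HEMI_ALT)

    @property
    def is_ref(self) -> bool:
        """True for an observed genotype with zero alternate alleles."""
        return self in (Zygosity.HOM_REF, Zygosity.HEMI_REF)


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Mode(enum.Enum):
    """Inheritance mode assigned to a proband's variant."""

    DE_NOVO = "de_novo"
    HOMOZYGOUS_RECESSIVE = "homozygous_recessive"
    X_LINKED = "x_linked"
    NONE = "none"


class Tier(enum.Enum):
    CONFIRMED = "confirmed"
    PUTATIVE = "putative"


@dataclass(frozen=True, order=True)
class VariantKey:
    """chrom/pos/ref/alt identity of a single decomposed variant call.

    This is the join key across callers, tissues and annotation tables, so
    keys must be normalized (one alt per key, 'chr'-prefixed chromosome,
    shared ref/alt context trimmed) before any comparison.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r}")
        if not self.chrom.startswith("chr"):
            raise ValueError(f"chrom must be 'chr'-prefixed, got {self.chrom!r}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def normalize_chrom(chrom: str) -> str:
    """Map a chromosome label to the 'chr'-prefixed dialect ('X' -> 'chrX')."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "MT":
        c = "M"
    return "chr" + c


def trim_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Build a VariantKey with shared ref/alt context trimmed.

    Trims the common suffix, then the common prefix (advancing pos), keeping
    at least one base on each side. This makes representation differences
    between callers (padded alleles) join correctly; full indel
    left-alignment would additionally need the reference sequence.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(normalize_chrom(chrom), pos, ref, alt)


#: GRCh38 pseudoautosomal intervals on chrX (1-based, inclusive). Inside
#: these, chrX genotypes behave autosomally.
GRCH38_X_PAR: tuple[tuple[int, int], ...] = ((10_001, 2_781_479), (155_701_383, 156_030_895))


def is_non_par_x(key: VariantKey, par_intervals=GRCH38_X_PAR) -> bool:
    if key.chrom != "chrX":
        return False
    return not any(lo <= key.pos <= hi for lo, hi in par_intervals)


@dataclass(frozen=True)
class TrioRecord:
    """One variant's genotype calls across a proband's family."""

    key: VariantKey
    proband: Zygosity
    mother: Zygosity
    father: Zygosity
    proband_sex: Sex
    proband_id: str
    sib: Optional[Zygosity] = None


@dataclass(frozen=True)
class AnnotatedVariant:
    """Functional and population-frequency annotation for one variant.

    ``maf`` maps database name -> allele frequency; a database absent from
    the map means the allele was unobserved there (frequency 0 downstream).
    """

    key: VariantKey
    gene: str
    transcript_change: str
    consequence: str  # missense | stopgain | splice | synonymous | other
    maf: dict[str, float]
    cadd_phred: Optional[float]
    predictor_fields: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for db, f in self.maf.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"MAF for {db} out of [0,1]: {f}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"CADD Phred must be >= 0, got {self.cadd_phred}")


CONSEQUENCES = ("missense", "stopgain", "splice", "synonymous", "other")

#: Default MAF database labels: Kinh Vietnamese, GnomAD East Asian, 1000 Genomes.
DEFAULT_MAF_DATABASES = ("KHV", "GnomAD_EAS", "1KG")


@dataclass(frozen=True)
class CallSet:
    """The set of variant keys emitted by one variant caller."""

    caller: str
    keys: frozenset[VariantKey]


@dataclass(frozen=True)
class InheritanceCall:
    """The inheritance mode assigned to one variant in one proband."""

    key: VariantKey
    proband_id: str
    mode: Mode
    tier: Tier
    rationale: str
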