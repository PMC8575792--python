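"""Synthetic trio-cohort generator with a known truth manifest.

The pipeline is a deterministic cascade, so the generator's job is pattern
coverage, not quantitative effect sizes: it plants variants whose trio
genotype patterns realize each inheritance mode, surrounds them with decoy
variants that each violate exactly one filter, and optionally corrupts the
per-caller call sets and adds liver-only (somatic) plants. Every planted
variant is recorded in a truth manifest so that recovery, precision and
mode-confusion can be scored exactly.

Cohort-shape defaults mirror a family-based exome study of ~40 families
with affected children: a 56% male proband fraction, one in eight families
lacking the father (child–mother duos), and liver tissue available for
just under half of the probands.

Coordinates live on a miniature three-contig genome (two autosomes plus a
chrX with declared pseudoautosomal ends) so that emitted VCFs stay tiny
while PAR semantics remain testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import write_annotation_table, write_gmt
from .model import (
    AnnotatedVariant,
    CallSet,
    Sex,
    TrioRecord,
    VariantKey,
    Zygosity,
)

#: miniature genome: contig -> length. chrX keeps the real PAR1 boundary so
#: that hemizygosity semantics match the default pseudoautosomal intervals.
SIM_CONTIGS = {"chr1": 1_000_000, "chr2": 1_000_000, "chrX": 4_000_000}
#: declared pseudoautosomal interval of the miniature chrX (= PAR1)
SIM_X_PAR = ((10_001, 2_781_479),)
_X_NONPAR = (2_781_480, 4_000_000)

DECOY_TYPES = ("decoy_common", "decoy_benign", "decoy_synonymous", "decoy_inherited")
PLANT_MODES = ("de_novo", "homozygous_recessive", "x_linked")


@dataclass(frozen=True)
class SimConfig:
    n_families: int = 40
    sex_ratio: float = 0.56  # male proband fraction
    plants_per_family: dict[str, int] = field(
        default_factory=lambda: {"de_novo": 1, "homozygous_recessive": 1, "x_linked": 1}
    )
    n_background_variants: int = 12  # decoys per family
    rare_maf_beta: tuple[float, float] = (0.5, 200.0)
    common_maf_beta: tuple[float, float] = (2.0, 5.0)
    cadd_range: tuple[float, float] = (0.0, 40.0)
    planted_cadd_floor: float = 15.0
    missing_parent_prob: float = 0.125  # child-mother duos
    caller_labels: tuple[str, ...] = ("caller_a", "caller_b", "caller_c")
    caller_miss_rate: float = 0.0
    caller_false_rate: float = 0.0
    liver_pair_prob: float = 0.44
    somatic_plant_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "sex_ratio": self.sex_ratio,
            "missing_parent_prob": self.missing_parent_prob,
            "caller_miss_rate": self.caller_miss_rate,
            "caller_false_rate": self.caller_false_rate,
            "liver_pair_prob": self.liver_pair_prob,
            "somatic_plant_rate": self.somatic_plant_rate,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.n_families < 0 or self.n_background_variants < 0:
            raise ValueError("counts must be >= 0")
        unknown = set(self.plants_per_family) - set(PLANT_MODES)
        if unknown:
            raise ValueError(f"unknown plant modes: {sorted(unknown)}")
        if any(c < 0 for c in self.plants_per_family.values()):
            raise ValueError("plant counts must be >= 0")
        if self.somatic_plant_rate > 0 and self.liver_pair_prob == 0:
            raise ValueError(
                "somatic plants requested but liver_pair_prob is 0: no liver samples"
            )
        if not self.caller_labels:
            raise ValueError("need at least one caller label")


@dataclass(frozen=True)
class SimVariant:
    key: VariantKey
    truth: str  # planted mode, decoy type, or "somatic"
    proband: Zygosity
    mother: Zygosity
    father: Zygosity
    liver_proband: Optional[Zygosity]  # None = absent from liver
    in_blood: bool
    annotation: AnnotatedVariant
    detected_by: dict[str, bool]


@dataclass(frozen=True)
class SimFamily:
    family_id: str
    proband_id: str
    mother_id: str
    father_id: Optional[str]  # None for child-mother duos
    proband_sex: Sex
    has_liver: bool
    variants: tuple[SimVariant, ...]


@dataclass
class SimulatedCohort:
    """In-memory cohort plus writers for the on-disk formats."""

    cfg: SimConfig
    families: list[SimFamily]
    #: caller -> spurious keys emitted by that caller only (no annotation,
    #: no family genotypes); rate-controlled by caller_false_rate
    false_keys: dict[str, frozenset[VariantKey]] = field(default_factory=dict)

    # -- views consumed by the pipeline ------------------------------------

    def trio_records(self, tissue: str = "blood") -> list[TrioRecord]:
        recs = []
        for fam in self.families:
            for v in fam.variants:
                if tissue == "blood":
                    if not v.in_blood:
                        continue
                    proband = v.proband
                else:
                    if v.liver_proband is None:
                        continue
                    proband = v.liver_proband
                recs.append(
                    TrioRecord(
                        key=v.key,
                        proband=proband,
                        mother=v.mother,
                        father=v.father,
                        proband_sex=fam.proband_sex,
                        proband_id=fam.proband_id,
                    )
                )
        return recs

    def annotations(self) -> dict[VariantKey, AnnotatedVariant]:
        return {v.key: v.annotation for fam in self.families for v in fam.variants}

    def callsets(self) -> list[CallSet]:
        per_caller: dict[str, set[VariantKey]] = {c: set() for c in self.cfg.caller_labels}
        for fam in self.families:
            for v in fam.variants:
                if not v.in_blood:
                    continue
                for c, hit in v.detected_by.items():
                    if hit:
                        per_caller[c].add(v.key)
        for c, extra in self.false_keys.items():
            per_caller[c].update(extra)
        return [CallSet(c, frozenset(keys)) for c, keys in per_caller.items()]

    def manifest(self) -> list[dict]:
        rows = []
        for fam in self.families:
            for v in fam.variants:
                rows.append(
                    {
                        "family": fam.family_id,
                        "proband": fam.proband_id,
                        "key": str(v.key),
                        "truth": v.truth,
                        "tissues": (["blood"] if v.in_blood else [])
                        + (["liver"] if v.liver_proband is not None else []),
                        "detected_by": {c: bool(h) for c, h in v.detected_by.items()},
                    }
                )
        return rows

    def planted(self) -> list[tuple[SimFamily, SimVariant]]:
        return [
            (fam, v)
            for fam in self.families
            for v in fam.variants
            if v.truth in PLANT_MODES
        ]

    # -- file emission -----------------------------------------------------

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self._write_ped(outdir / "cohort.ped")
        for fam in self.families:
            self._write_vcf(fam, outdir / f"{fam.family_id}.vcf", tissue="blood")
            if fam.has_liver:
                self._write_vcf(fam, outdir / f"{fam.family_id}.liver.vcf", tissue="liver")
        write_annotation_table(self.annotations().values(), outdir / "annotations.tsv")
        for cs in self.callsets():
            with open(outdir / f"callset.{cs.caller}.tsv", "w") as fh:
                for k in sorted(cs.keys):
                    fh.write(f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\n")
        with open(outdir / "manifest.jsonl", "w") as fh:
            for row in self.manifest():
                fh.write(json.dumps(row, sort_keys=True) + "\n")
        self._write_toy_gmt(outdir / "toy_genesets.gmt")

    def _write_ped(self, path: Path) -> None:
        with open(path, "w") as fh:
            for fam in self.families:
                sex = "1" if fam.proband_sex is Sex.MALE else "2"
                father = fam.father_id or "0"
                fh.write(
                    f"{fam.family_id} {fam.proband_id} {father} {fam.mother_id} {sex} 2\n"
                )
                fh.write(f"{fam.family_id} {fam.mother_id} 0 0 2 1\n")
                if fam.father_id:
                    fh.write(f"{fam.family_id} {fam.father_id} 0 0 1 1\n")

    def _write_vcf(self, fam: SimFamily, path: Path, tissue: str) -> None:
        gt = {
            Zygosity.HOM_REF: "0/0",
            Zygosity.HET: "0/1",
            Zygosity.HOM_ALT: "1/1",
            Zygosity.HEMI_REF: "0",
            Zygosity.HEMI_ALT: "1",
            Zygosity.MISSING: "./.",
        }
        samples = [fam.proband_id, fam.mother_id] + (
            [fam.father_id] if fam.father_id else []
        )
        lines = ["##fileformat=VCFv4.2"]
        lines += [f"##contig=<ID={c},length={l}>" for c, l in SIM_CONTIGS.items()]
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
        order = {c: i for i, c in enumerate(SIM_CONTIGS)}
        variants = sorted(fam.variants, key=lambda v: (order[v.key.chrom], v.key.pos))
        for v in variants:
            if tissue == "blood":
                if not v.in_blood:
                    continue
                proband = v.proband
            else:
                if v.liver_proband is None:
                    continue
                proband = v.liver_proband
            calls = {fam.proband_id: proband, fam.mother_id: v.mother}
            if fam.father_id:
                calls[fam.father_id] = v.father
            lines.append(
                "\t".join(
                    [
                        v.key.chrom, str(v.key.pos), ".", v.key.ref, v.key.alt,
                        ".", "PASS", ".", "GT",
                    ]
                    + [gt[calls[s]] for s in samples]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def _write_toy_gmt(self, path: Path) -> None:
        genes = sorted({v.annotation.gene for fam in self.families for v in fam.variants})
        half = genes[: max(1, len(genes) // 2)] or ["GENE_NONE"]
        write_gmt(
            {
                "TOY_PLANTED_GENES": ("planted and decoy genes, first half", half),
                "TOY_ALL_GENES": ("every simulated gene", genes or ["GENE_NONE"]),
            },
            path,
        )


# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


class _PositionPool:
    """Draws unused (contig, pos) pairs deterministically."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def draw(self, chrom: str, lo: int, hi: int) -> int:
        while True:
            pos = int(self.rng.integers(lo, hi + 1))
            if (chrom, pos) not in self.used:
                self.used.add((chrom, pos))
                return pos


def _alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.integers(0, 4))
    j = (i + 1 + int(rng.integers(0, 3))) % 4
    return _BASES[i], _BASES[j]


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate a cohort of trio/duo families with planted variants.

    Deterministic: the same config (including seed) yields an identical
    cohort, and :meth:`SimulatedCohort.write` emits byte-identical files.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pool = _PositionPool(rng)
    families: list[SimFamily] = []
    gene_counter = 0

    def next_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"GENE{gene_counter:05d}"

    def rare_maf() -> dict[str, float]:
        a, b = cfg.rare_maf_beta
        return {
            db: float(min(rng.beta(a, b), 0.009))
            for db in ("KHV", "GnomAD_EAS", "1KG")
        }

    def common_maf() -> dict[str, float]:
        a, b = cfg.common_maf_beta
        return {
            db: float(max(rng.beta(a, b), 0.02))
            for db in ("KHV", "GnomAD_EAS", "1KG")
        }

    def deleterious_cadd() -> float:
        return float(rng.uniform(cfg.planted_cadd_floor, cfg.cadd_range[1]))

    def benign_cadd() -> float:
        return float(rng.uniform(cfg.cadd_range[0], 10.0))

    def detection() -> dict[str, bool]:
        return {
            c: bool(rng.random() >= cfg.caller_miss_rate) for c in cfg.caller_labels
        }

    for i in range(cfg.n_families):
        fid = f"F{i + 1:03d}"
        proband_id, mother_id = f"{fid}_P", f"{fid}_M"
        is_duo = bool(rng.random() < cfg.missing_parent_prob)
        father_id = None if is_duo else f"{fid}_F"
        sex = Sex.MALE if rng.random() < cfg.sex_ratio else Sex.FEMALE
        has_liver = bool(rng.random() < cfg.liver_pair_prob)
        variants: list[SimVariant] = []

        def add(key, truth, proband, mother, father, ann, in_blood=True, liver_only=False):
            liver = None
            if has_liver:
                liver = proband if in_blood else None
            if liver_only:
                liver = proband
                in_blood = False
            variants.append(
                SimVariant(
                    key=key,
                    truth=truth,
                    proband=proband,
                    mother=mother,
                    father=Zygosity.MISSING if father_id is None else father,
                    liver_proband=liver,
                    in_blood=in_blood,
                    annotation=ann,
                    detected_by=detection() if in_blood else {c: False for c in cfg.caller_labels},
                )
            )

        def annotation(key, consequence, maf, cadd) -> AnnotatedVariant:
            gene = next_gene()
            return AnnotatedVariant(
                key=key,
                gene=gene,
                transcript_change=f"{gene}:c.{key.pos % 997 + 1}{key.ref}>{key.alt}",
                consequence=consequence,
                maf=maf,
                cadd_phred=cadd,
            )

        def autosomal_key() -> VariantKey:
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            pos = pool.draw(chrom, 1, SIM_CONTIGS[chrom])
            ref, alt = _alleles(rng)
            return VariantKey(chrom, pos, ref, alt)

        def x_nonpar_key() -> VariantKey:
            pos = pool.draw("chrX", *_X_NONPAR)
            ref, alt = _alleles(rng)
            return VariantKey("chrX", pos, ref, alt)

        def planted_consequence() -> str:
            r = rng.random()
            return "missense" if r < 0.8 else ("stopgain" if r < 0.95 else "splice")

        # planted mode variants
        for _ in range(cfg.plants_per_family.get("de_novo", 0)):
            key = autosomal_key()
            add(
                key, "de_novo", Zygosity.HET, Zygosity.HOM_REF, Zygosity.HOM_REF,
                annotation(key, planted_consequence(), rare_maf(), deleterious_cadd()),
            )
        for _ in range(cfg.plants_per_family.get("homozygous_recessive", 0)):
            key = autosomal_key()
            add(
                key, "homozygous_recessive", Zygosity.HOM_ALT, Zygosity.HET, Zygosity.HET,
                annotation(key, planted_consequence(), rare_maf(), deleterious_cadd()),
            )
        for _ in range(cfg.plants_per_family.get("x_linked", 0)):
            key = x_nonpar_key()
            proband = Zygosity.HEMI_ALT if sex is Sex.MALE else Zygosity.HET
            father = Zygosity.HEMI_REF
            add(
                key, "x_linked", proband, Zygosity.HET, father,
                annotation(key, planted_consequence(), rare_maf(), deleterious_cadd()),
            )

        # background decoys, each violating exactly one filter
        for j in range(cfg.n_background_variants):
            dtype = DECOY_TYPES[j % len(DECOY_TYPES)]
            key = autosomal_key()
            if dtype == "decoy_common":
                ann = annotation(key, planted_consequence(), common_maf(), deleterious_cadd())
                add(key, dtype, Zygosity.HET, Zygosity.HOM_REF, Zygosity.HOM_REF, ann)
            elif dtype == "decoy_benign":
                ann = annotation(key, planted_consequence(), rare_maf(), benign_cadd())
                add(key, dtype, Zygosity.HET, Zygosity.HOM_REF, Zygosity.HOM_REF, ann)
            elif dtype == "decoy_synonymous":
                ann = annotation(key, "synonymous", rare_maf(), deleterious_cadd())
                add(key, dtype, Zygosity.HET, Zygosity.HOM_REF, Zygosity.HOM_REF, ann)
            else:  # inherited: rare + deleterious but no disease-mode pattern
                ann = annotation(key, planted_consequence(), rare_maf(), deleterious_cadd())
                add(key, dtype, Zygosity.HET, Zygosity.HET, Zygosity.HOM_REF, ann)

        # liver-only (somatic) plants
        if has_liver and rng.random() < cfg.somatic_plant_rate:
            key = autosomal_key()
            ann = annotation(key, planted_consequence(), rare_maf(), deleterious_cadd())
            add(
                key, "somatic", Zygosity.HET, Zygosity.HOM_REF, Zygosity.HOM_REF, ann,
                liver_only=True,
            )

        families.append(
            SimFamily(
                family_id=fid,
                proband_id=proband_id,
                mother_id=mother_id,
                father_id=father_id,
                proband_sex=sex,
                has_liver=has_liver,
                variants=tuple(variants),
            )
        )

    n_true = sum(v.in_blood for fam in families for v in fam.variants)
    false_keys: dict[str, frozenset[VariantKey]] = {}
    for c in cfg.caller_labels:
        n_false = int(round(cfg.caller_false_rate * n_true))
        extra = set()
        for _ in range(n_false):
            chrom = ("chr1", "chr2", "chrX")[int(rng.integers(0, 3))]
            pos = pool.draw(chrom, 1, SIM_CONTIGS[chrom])
            ref, alt = _alleles(rng)
            extra.add(VariantKey(chrom, pos, ref, alt))
        false_keys[c] = frozenset(extra)
    return SimulatedCohort(cfg=cfg, families=families, false_keys=false_keys)
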