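"""Readers and writers for the standard formats the pipeline touches.

VCF parsing goes through pysam; PED and the annotation table are simple
tabular dialects handled with the standard library / pandas. All variant
identities are normalized to decomposed, context-trimmed :class:`VariantKey`
values so that joins across callers, tissues and annotations are
representation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .model import (
    CONSEQUENCES,
    GRCH38_X_PAR,
    AnnotatedVariant,
    CallSet,
    Sex,
    VariantKey,
    Zygosity,
    normalize_chrom,
    trim_key,
)


class VcfError(ValueError):
    pass


class PedError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


def _is_hemizygous_context(chrom: str, pos: int, sex: Optional[Sex], par_intervals) -> bool:
    if sex is not Sex.MALE:
        return False
    if chrom == "chrY":
        return True
    if chrom != "chrX":
        return False
    return not any(lo <= pos <= hi for lo, hi in par_intervals)


def _zygosity_from_dosage(
    n_alt: int, ploidy: int, chrom: str, pos: int, sex: Optional[Sex], par_intervals
) -> Zygosity:
    hemi = _is_hemizygous_context(chrom, pos, sex, par_intervals)
    if hemi:
        # male non-PAR chrX / chrY: haploid- or diploid-coded alike collapse
        # to a single-copy call
        return Zygosity.HEMI_ALT if n_alt >= 1 else Zygosity.HEMI_REF
    if ploidy == 1:
        raise VcfError(
            f"haploid genotype at {chrom}:{pos} outside a hemizygous context"
        )
    if n_alt == 0:
        return Zygosity.HOM_REF
    if n_alt == 1:
        return Zygosity.HET
    return Zygosity.HOM_ALT


def read_vcf(
    path: str | Path,
    sample_names: Optional[Sequence[str]] = None,
    sample_sexes: Optional[dict[str, Sex]] = None,
    par_intervals=GRCH38_X_PAR,
) -> list[tuple[VariantKey, dict[str, Zygosity]]]:
    """Read a multi-sample VCF into decomposed per-alt genotype calls.

    Multi-allelic records are split into one :class:`VariantKey` per
    alternate allele; each sample's zygosity for a key counts only that
    alt's copies, so total alt dosage per sample per site is preserved
    across decomposition. Male genotypes on non-PAR chrX (or chrY) are
    mapped to HEMI_* whether coded haploid ("1") or diploid ("1/1").

    Parameters
    ----------
    sample_names
        Restrict to these samples (all must be present in the header).
    sample_sexes
        Sample -> Sex map, needed for hemizygous calling; samples absent
        from the map are treated as non-hemizygous everywhere.
    """
    sample_sexes = sample_sexes or {}
    out: list[tuple[VariantKey, dict[str, Zygosity]]] = []
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = list(vcf.header.samples)
        if sample_names is None:
            samples = header_samples
        else:
            missing = [s for s in sample_names if s not in header_samples]
            if missing:
                raise VcfError(f"samples absent from VCF header: {missing}")
            samples = list(sample_names)
        for rec in vcf:
            if rec.alts is None:
                continue
            chrom = normalize_chrom(rec.chrom)
            for alt_index, alt in enumerate(rec.alts, start=1):
                if alt is None or alt in (".", "<NON_REF>", "*"):
                    continue
                try:
                    key = trim_key(rec.chrom, rec.pos, rec.ref, alt)
                except ValueError as e:
                    raise VcfError(
                        f"malformed record at {rec.chrom}:{rec.pos}: {e}"
                    ) from e
                calls: dict[str, Zygosity] = {}
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt) or len(gt) == 0:
                        calls[s] = Zygosity.MISSING
                        continue
                    n_alt = sum(1 for a in gt if a == alt_index)
                    calls[s] = _zygosity_from_dosage(
                        n_alt, len(gt), chrom, rec.pos,
                        sample_sexes.get(s), par_intervals,
                    )
                out.append((key, calls))
    return out


# ---------------------------------------------------------------------------
# PED

@dataclass(frozen=True)
class PedIndividual:
    family_id: str
    iid: str
    father_id: Optional[str]  # None when coded "0"
    mother_id: Optional[str]
    sex: Optional[Sex]  # None when coded "0" (unknown)
    affected: bool


@dataclass
class Pedigree:
    """Family graph from a 6-column PED file."""

    individuals: dict[str, PedIndividual] = field(default_factory=dict)

    @property
    def families(self) -> dict[str, list[PedIndividual]]:
        fams: dict[str, list[PedIndividual]] = {}
        for ind in self.individuals.values():
            fams.setdefault(ind.family_id, []).append(ind)
        return fams

    def probands(self) -> list[PedIndividual]:
        """Affected individuals with at least one recorded parent."""
        return [
            i for i in self.individuals.values()
            if i.affected and (i.father_id or i.mother_id)
        ]

    def affected_sibs(self, proband_id: str) -> list[PedIndividual]:
        p = self.individuals[proband_id]
        return [
            i for i in self.individuals.values()
            if i.iid != p.iid and i.affected
            and i.father_id == p.father_id and i.mother_id == p.mother_id
            and (i.father_id or i.mother_id)
        ]

    def sex_map(self) -> dict[str, Sex]:
        return {i.iid: i.sex for i in self.individuals.values() if i.sex is not None}


_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE, "0": None}


def read_ped(path: str | Path) -> Pedigree:
    """Parse a whitespace-delimited 6-column PED file.

    Columns: family, individual, father, mother, sex (1=male, 2=female,
    0=unknown), phenotype (2=affected). Parent ids must either be "0"
    (absent) or appear in the file; cyclic parentage is rejected.
    """
    ped = Pedigree()
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedError(f"line {lineno}: expected 6 columns, got {len(fields)}")
        fid, iid, father, mother, sex_code, pheno = fields[:6]
        if sex_code not in _PED_SEX:
            raise PedError(f"line {lineno}: invalid sex code {sex_code!r}")
        if iid in ped.individuals:
            raise PedError(f"line {lineno}: duplicate individual id {iid!r}")
        ped.individuals[iid] = PedIndividual(
            family_id=fid,
            iid=iid,
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
            sex=_PED_SEX[sex_code],
            affected=(pheno == "2"),
        )
    for ind in ped.individuals.values():
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None and pid not in ped.individuals:
                raise PedError(f"{ind.iid}: parent {pid!r} not present in pedigree")
    _check_acyclic(ped)
    return ped


def _check_acyclic(ped: Pedigree) -> None:
    for start in ped.individuals:
        seen = {start}
        frontier = [start]
        while frontier:
            iid = frontier.pop()
            ind = ped.individuals[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    continue
                if pid in seen:
                    raise PedError(f"cyclic parentage involving {pid!r}")
                seen.add(pid)
                frontier.append(pid)


# ---------------------------------------------------------------------------
# Annotation table

#: canonical column order of the annotation TSV
ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "transcript_change", "consequence",
    "maf_khv", "maf_gnomad_eas", "maf_1kg", "cadd_phred",
]

_MAF_COLUMN_TO_DB = {
    "maf_khv": "KHV",
    "maf_gnomad_eas": "GnomAD_EAS",
    "maf_1kg": "1KG",
}
_DB_TO_MAF_COLUMN = {v: k for k, v in _MAF_COLUMN_TO_DB.items()}


def read_annotation_table(path: str | Path) -> dict[VariantKey, AnnotatedVariant]:
    """Read the per-variant annotation TSV into a key -> annotation map.

    Empty MAF cells mean the allele was unobserved in that database (the
    database is omitted from the map; downstream filters treat it as
    frequency 0). Extra columns are carried through as opaque
    ``predictor_fields`` strings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"annotation table missing columns: {missing}")
    extra_cols = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    out: dict[VariantKey, AnnotatedVariant] = {}
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            key = trim_key(d["chrom"], int(d["pos"]), d["ref"], d["alt"])
        except ValueError as e:
            raise AnnotationError(f"bad variant key in row {d}: {e}") from e
        if key in out:
            raise AnnotationError(f"duplicate annotation for {key}")
        maf: dict[str, float] = {}
        for col, db in _MAF_COLUMN_TO_DB.items():
            cell = d[col].strip()
            if cell == "":
                continue
            try:
                maf[db] = float(cell)
            except ValueError as e:
                raise AnnotationError(f"non-numeric MAF {cell!r} for {key}") from e
        cadd_cell = d["cadd_phred"].strip()
        if cadd_cell == "":
            cadd = None
        else:
            try:
                cadd = float(cadd_cell)
            except ValueError as e:
                raise AnnotationError(f"non-numeric CADD {cadd_cell!r} for {key}") from e
        cons = d["consequence"].strip()
        if cons not in CONSEQUENCES:
            raise AnnotationError(f"unknown consequence {cons!r} for {key}")
        out[key] = AnnotatedVariant(
            key=key,
            gene=d["gene"],
            transcript_change=d["transcript_change"],
            consequence=cons,
            maf=maf,
            cadd_phred=cadd,
            predictor_fields={c: d[c] for c in extra_cols if d[c] != ""},
        )
    return out


def write_annotation_table(
    annotations: Iterable[AnnotatedVariant], path: str | Path
) -> None:
    """Write annotations as a TSV that round-trips through
    :func:`read_annotation_table` exactly."""
    anns = list(annotations)
    extra_cols = sorted({c for a in anns for c in a.predictor_fields})
    rows = []
    for a in anns:
        row = {
            "chrom": a.key.chrom,
            "pos": a.key.pos,
            "ref": a.key.ref,
            "alt": a.key.alt,
            "gene": a.gene,
            "transcript_change": a.transcript_change,
            "consequence": a.consequence,
            "cadd_phred": "" if a.cadd_phred is None else repr(a.cadd_phred),
        }
        for db, col in _DB_TO_MAF_COLUMN.items():
            row[col] = repr(a.maf[db]) if db in a.maf else ""
        for c in extra_cols:
            row[c] = a.predictor_fields.get(c, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS + extra_cols)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file into {set_name: (description, member genes)}.

    Gene symbols are uppercased; duplicate members collapse.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise AnnotationError(f"GMT line {lineno}: need name, description, >=1 gene")
        name, desc = fields[0], fields[1]
        genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
        if not genes:
            raise AnnotationError(f"GMT line {lineno}: gene set {name!r} is empty")
        sets[name] = (desc, genes)
    return sets


def write_gmt(sets: dict[str, tuple[str, Iterable[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in sets.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Multi-caller consensus

def consensus_intersect(
    callsets: Sequence[CallSet], min_callers: Optional[int] = None
) -> frozenset[VariantKey]:
    """Keys supported by at least ``min_callers`` of the given call sets.

    The default (``min_callers=None``) is the strict intersection of all
    call sets — the conservative policy for suppressing caller-specific
    false positives.
    """
    if not callsets:
        raise ValueError("need at least one call set")
    if min_callers is None:
        min_callers = len(callsets)
    if not (1 <= min_callers <= len(callsets)):
        raise ValueError(
            f"min_callers must be in [1, {len(callsets)}], got {min_callers}"
        )
    counts: dict[VariantKey, int] = {}
    for cs in callsets:
        for k in cs.keys:
            counts[k] = counts.get(k, 0) + 1
    return frozenset(k for k, c in counts.items() if c >= min_callers)
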