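"""Packaged reference tables from the published candidate-variant study.

Three small TSVs transcribe the study's printed tables:

* ``table2`` — 28 prioritized variants with trio zygosity classes, three
  population MAFs and CADD Phred scores. Printed allele letters are
  strand-inconsistent with the stated DNA changes, so genotypes are encoded
  as zygosity classes (inferred from the printed trio genotypes and mode)
  and ref/alt letters serve only as join keys.
* ``table3`` — 18 probands with paired blood/liver calls; 8 with identical
  variants in both tissues, 10 with none detected in either. The published
  table legibly prints 17 rows against a stated total of 18 liver pairs;
  the remaining undetected proband is included under the synthetic
  placeholder id ``BA0XX``.
* ``table4`` — 10 human-phenotype gene-set overlap rows (K, k, p, q and
  overlap genes as printed).

Files are integrity-checked by SHA-256 before parsing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

from .model import (
    AnnotatedVariant,
    Sex,
    TrioRecord,
    VariantKey,
    Zygosity,
)

FIXTURE_SHA256 = {
    "table2.tsv": "62049fedfbf6662e0c32a6d58b3eedc1b266032bacad5aaaae3d413be7710a3f",
    "table3.tsv": "a4a3cee45ae68169988ac892586776d8ed328fb9c4115d6ca5f124b9afd24be8",
    "table4.tsv": "240439721f9c7f6981602b04d7c12b69a2b1e44a404a90899843e7736bdcaaf3",
}


class FixtureError(RuntimeError):
    pass


def _fixture_bytes(filename: str) -> bytes:
    data = resources.files("ba_prioritize.data").joinpath(filename).read_bytes()
    expected = FIXTURE_SHA256.get(filename)
    got = hashlib.sha256(data).hexdigest()
    if expected is not None and got != expected:
        raise FixtureError(
            f"packaged fixture {filename} is corrupted (sha256 {got}, expected {expected})"
        )
    return data


def _read_tsv(filename: str) -> pd.DataFrame:
    import io as _io

    return pd.read_csv(
        _io.BytesIO(_fixture_bytes(filename)), sep="\t", dtype=str, keep_default_na=False
    )


_SEX = {"M": Sex.MALE, "F": Sex.FEMALE}


def _load_table2() -> list[tuple[TrioRecord, AnnotatedVariant]]:
    df = _read_tsv("table2.tsv")
    out = []
    for r in df.itertuples(index=False):
        key = VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
        rec = TrioRecord(
            key=key,
            proband=Zygosity[r.gt_proband],
            mother=Zygosity[r.gt_mother],
            father=Zygosity[r.gt_father],
            sib=Zygosity[r.gt_sib] if r.gt_sib else None,
            proband_sex=_SEX[r.proband_sex],
            proband_id=r.proband,
        )
        maf = {}
        for db, col in (("KHV", r.maf_khv), ("GnomAD_EAS", r.maf_gnomad_eas), ("1KG", r.maf_1kg)):
            maf[db] = float(col)
        ann = AnnotatedVariant(
            key=key,
            gene=r.gene,
            transcript_change=r.transcript_change,
            consequence=r.consequence,
            maf=maf,
            cadd_phred=float(r.cadd_phred),
        )
        out.append((rec, ann))
    return out


@dataclass(frozen=True)
class TissuePair:
    """One liver-sampled proband's prioritized calls in both tissues."""

    proband_id: str
    sex: Optional[Sex]
    blood: dict[VariantKey, Zygosity]
    liver: dict[VariantKey, Zygosity]
    genes: dict[VariantKey, str]


def _load_table3() -> list[TissuePair]:
    df = _read_tsv("table3.tsv")
    pairs: dict[str, dict] = {}
    order: list[str] = []
    for r in df.itertuples(index=False):
        pid = r.proband
        if pid not in pairs:
            pairs[pid] = {
                "sex": _SEX.get(r.proband_sex),
                "calls": {},
                "genes": {},
            }
            order.append(pid)
        if r.chrom:
            key = VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
            pairs[pid]["calls"][key] = Zygosity[r.gt_proband]
            pairs[pid]["genes"][key] = r.gene
    # the published comparison found tissue-identical calls throughout
    return [
        TissuePair(
            proband_id=pid,
            sex=d["sex"],
            blood=dict(d["calls"]),
            liver=dict(d["calls"]),
            genes=dict(d["genes"]),
        )
        for pid, d in ((p, pairs[p]) for p in order)
    ]


@dataclass(frozen=True)
class OverlapRowSkeleton:
    """One published gene-set overlap row (values as printed)."""

    set_name: str
    description: str
    K: int
    k: int
    ratio: float
    p: float
    q: float
    overlap_genes: tuple[str, ...]


def _load_table4() -> list[OverlapRowSkeleton]:
    df = _read_tsv("table4.tsv")
    return [
        OverlapRowSkeleton(
            set_name=r.set_name,
            description=r.description,
            K=int(r.K),
            k=int(r.k),
            ratio=float(r.ratio),
            p=float(r.p),
            q=float(r.q),
            overlap_genes=tuple(r.overlap_genes.split(",")),
        )
        for r in df.itertuples(index=False)
    ]


def load_reference_fixture(name: str):
    """Load one of the packaged study tables.

    Parameters
    ----------
    name
        ``"table2"`` -> list of (TrioRecord, AnnotatedVariant);
        ``"table3"`` -> list of :class:`TissuePair`;
        ``"table4"`` -> list of :class:`OverlapRowSkeleton`.
    """
    loaders = {"table2": _load_table2, "table3": _load_table3, "table4": _load_table4}
    if name not in loaders:
        raise ValueError(f"unknown fixture {name!r}; expected one of {sorted(loaders)}")
    return loaders[name]()


def candidate_genes() -> list[str]:
    """The distinct gene symbols of the prioritized variant table."""
    seen: list[str] = []
    for _, ann in _load_table2():
        if ann.gene not in seen:
            seen.append(ann.gene)
    return seen
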