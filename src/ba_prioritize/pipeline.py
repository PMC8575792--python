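"""End-to-end orchestration: consensus -> classify -> filter -> concordance
-> enrichment, with a full audit trail and summary artifacts."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .concordance import ConcordanceResult, ConcordanceSummary, summarize_concordance
from .enrichment import EnrichmentConfig, EnrichmentRow, compute_overlaps
from .filters import FilterConfig, PrioritizationReport, run_prioritization
from .inheritance import ModeSummary, summarize_modes
from .io import Pedigree, consensus_intersect, read_vcf
from .model import (
    GRCH38_X_PAR,
    AnnotatedVariant,
    CallSet,
    Mode,
    TrioRecord,
    VariantKey,
    Zygosity,
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineReport:
    prioritization: PrioritizationReport
    mode_summary: ModeSummary
    concordance: Optional[ConcordanceSummary] = None
    concordance_results: list[ConcordanceResult] = field(default_factory=list)
    enrichment: list[EnrichmentRow] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def _config_hash(cfg: FilterConfig, min_callers: Optional[int]) -> str:
    payload = json.dumps(
        {
            "maf_max": cfg.maf_max,
            "maf_policy": cfg.maf_policy.value,
            "cadd_min": cfg.cadd_min,
            "allowed_consequences": sorted(cfg.allowed_consequences),
            "maf_databases": list(cfg.maf_databases),
            "min_callers": min_callers,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    records: Sequence[TrioRecord],
    annotations: Mapping[VariantKey, AnnotatedVariant],
    filter_cfg: FilterConfig = FilterConfig(),
    callsets: Optional[Sequence[CallSet]] = None,
    min_callers: Optional[int] = None,
    liver_records: Optional[Sequence[TrioRecord]] = None,
    query_genes_for_enrichment: bool = False,
    gene_sets=None,
    enrichment_cfg: EnrichmentConfig = EnrichmentConfig(),
    par_intervals=GRCH38_X_PAR,
) -> PipelineReport:
    """Run the full prioritization cascade over in-memory inputs.

    ``callsets`` (when given) gates records to the multi-caller consensus
    before classification. ``liver_records`` triggers the per-proband
    tissue-concordance stage; ``gene_sets`` triggers enrichment of the
    surviving genes.
    """
    try:
        if callsets:
            consensus = consensus_intersect(callsets, min_callers)
            records = [r for r in records if r.key in consensus]
            if liver_records is not None:
                liver_records = [r for r in liver_records if r.key in consensus]
    except ValueError as e:
        raise StageError("consensus", str(e)) from e

    try:
        report = run_prioritization(records, annotations, filter_cfg, par_intervals)
    except ValueError as e:
        raise StageError("classify_filter", str(e)) from e

    summary = summarize_modes(
        [r.inheritance for r in report.survivors if r.inheritance], annotations
    )

    out = PipelineReport(
        prioritization=report,
        mode_summary=summary,
        metadata={
            "version": __version__,
            "config_hash": _config_hash(filter_cfg, min_callers),
            "n_input_records": len(records),
            "n_survivors": len(report.survivors),
        },
    )

    if liver_records is not None:
        try:
            liver_report = run_prioritization(
                liver_records, annotations, filter_cfg, par_intervals
            )
            out.concordance_results = pair_and_compare(report, liver_report)
            out.concordance = summarize_concordance(out.concordance_results)
        except ValueError as e:
            raise StageError("concordance", str(e)) from e

    if gene_sets is not None:
        try:
            genes = sorted(report.surviving_genes())
            out.enrichment = (
                compute_overlaps(genes, gene_sets, enrichment_cfg) if genes else []
            )
        except ValueError as e:
            raise StageError("enrichment", str(e)) from e
    return out


def pair_and_compare(
    blood_report: PrioritizationReport, liver_report: PrioritizationReport
) -> list[ConcordanceResult]:
    """Compare surviving blood vs liver calls for every liver-assayed proband."""
    from .concordance import compare_tissues

    def by_proband(rep: PrioritizationReport) -> dict[str, dict[VariantKey, Zygosity]]:
        d: dict[str, dict[VariantKey, Zygosity]] = {}
        for row in rep.rows:
            d.setdefault(row.record.proband_id, {})
        for row in rep.survivors:
            d[row.record.proband_id][row.record.key] = row.record.proband
        return d

    blood = by_proband(blood_report)
    liver = by_proband(liver_report)
    results = []
    for pid in sorted(liver):  # only probands with a liver assay are paired
        results.append(compare_tissues(pid, blood.get(pid, {}), liver[pid]))
    return results


# ---------------------------------------------------------------------------
# building trio records from files

def trio_records_from_vcf(
    vcf_path: str | Path,
    pedigree: Pedigree,
    par_intervals=GRCH38_X_PAR,
    proband_override: Optional[dict[str, str]] = None,
) -> list[TrioRecord]:
    """Join one family VCF against the pedigree into per-proband trio records.

    Absent family members (duo families, samples missing from the VCF)
    contribute MISSING genotypes. ``proband_override`` maps a VCF sample
    name to the pedigree proband it stands in for (used for liver-tissue
    samples carrying their own sample id).
    """
    sexes = pedigree.sex_map()
    calls = read_vcf(vcf_path, sample_sexes=sexes, par_intervals=par_intervals)
    import pysam

    with pysam.VariantFile(str(vcf_path)) as vf:
        vcf_samples = set(vf.header.samples)
    records: list[TrioRecord] = []
    override = proband_override or {}
    for proband in pedigree.probands():
        sample_for_proband = proband.iid
        for alias, pid in override.items():
            if pid == proband.iid and alias in vcf_samples:
                sample_for_proband = alias
        if sample_for_proband not in vcf_samples:
            continue
        if proband.sex is None:
            raise StageError("input", f"proband {proband.iid} has unknown sex in PED")
        for key, sample_calls in calls:
            pz = sample_calls.get(sample_for_proband, Zygosity.MISSING)
            if not pz.carries_alt:  # classification needs an alt-carrying proband
                continue
            records.append(
                TrioRecord(
                    key=key,
                    proband=pz,
                    mother=sample_calls.get(proband.mother_id, Zygosity.MISSING)
                    if proband.mother_id
                    else Zygosity.MISSING,
                    father=sample_calls.get(proband.father_id, Zygosity.MISSING)
                    if proband.father_id
                    else Zygosity.MISSING,
                    proband_sex=proband.sex,
                    proband_id=proband.iid,
                )
            )
    return records


# ---------------------------------------------------------------------------
# rendering

_MODE_LABELS = {
    Mode.X_LINKED: "X-linked",
    Mode.DE_NOVO: "De novo",
    Mode.HOMOZYGOUS_RECESSIVE: "Homozygous recessive",
}
_MODE_COLORS = {
    Mode.X_LINKED: "white",
    Mode.DE_NOVO: "0.6",
    Mode.HOMOZYGOUS_RECESSIVE: "0.85",
}


def render_mode_chart(summary: ModeSummary, path: str | Path) -> dict[str, int]:
    """Render the inheritance-mode breakdown as a pie chart (PNG).

    The integer percentages are embedded in the PNG text metadata under the
    key ``mode_percentages`` so they can be re-extracted losslessly.
    Returns {mode label: percentage}.
    """
    if summary.total <= 0:
        raise ValueError("cannot render a mode chart for an empty summary")
    modes = [m for m in _MODE_LABELS if summary.counts.get(m, 0) > 0]
    counts = [summary.counts[m] for m in modes]
    labels = [
        f"{_MODE_LABELS[m]} ({summary.counts[m]}, {summary.percentages[m]}%)"
        for m in modes
    ]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.pie(
        counts,
        labels=labels,
        colors=[_MODE_COLORS[m] for m in modes],
        wedgeprops={"edgecolor": "black"},
        startangle=90,
    )
    ax.set_title("Mode of inheritance of prioritized variants")
    percentages = {_MODE_LABELS[m]: summary.percentages[m] for m in modes}
    fig.savefig(
        path, metadata={"mode_percentages": json.dumps(percentages, sort_keys=True)}
    )
    plt.close(fig)
    return percentages


# ---------------------------------------------------------------------------
# tabular report output

def audit_rows_table(report: PrioritizationReport) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for r in report.rows:
        rows.append(
            {
                "proband": r.record.proband_id,
                "chrom": r.record.key.chrom,
                "pos": r.record.key.pos,
                "ref": r.record.key.ref,
                "alt": r.record.key.alt,
                "gene": r.annotation.gene if r.annotation else "",
                "consequence": r.annotation.consequence if r.annotation else "",
                "moi": r.inheritance.mode.value if r.inheritance else "",
                "tier": r.inheritance.tier.value if r.inheritance else "",
                "rationale": r.inheritance.rationale if r.inheritance else "",
                "cadd_phred": r.annotation.cadd_phred if r.annotation else "",
                "surviving": r.surviving,
                "reasons": ";".join(x.value for x in r.reasons),
            }
        )
    return pd.DataFrame(rows)


def enrichment_table(rows: Iterable[EnrichmentRow]) -> "pd.DataFrame":
    import pandas as pd
    from .enrichment import round_sig

    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "K": r.K,
                "description": r.description,
                "k": r.k,
                "k/K": r.ratio,
                "p": round_sig(r.p),
                "q": round_sig(r.q),
                "significant": r.significant,
                "overlap_genes": ",".join(r.overlap_genes),
            }
            for r in rows
        ]
    )
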