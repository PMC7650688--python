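"""End-to-end orchestration: QC → annotate → prioritize → classify →
inheritance → cohort summary.

Thin glue over the stage modules; every stage keeps its own config object
so a run is fully described by (inputs, PipelineConfig).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .acmg import EvidenceConfig, classify_record
from .annotate import AnnotationSnapshots, annotate_all
from .cnv import CnvConfig, DepthMatrix, call_cnvs, normalize_depth
from .family import (Pedigree, detect_biallelic, detect_cooccurrence,
                     read_ped, segregation_check)
from .panel import PanelDefinition, RECESSIVE_GENES, default_panel
from .prioritize import PrioritizerConfig, prioritize
from .qc import QcConfig, SampleQcReport, compute_sample_qc
from .report import CohortSummary, PatientRecord, summarize
from .variants import VariantRecord, read_vcf, vcf_sample_list


@dataclass
class PipelineConfig:
    qc: QcConfig = field(default_factory=QcConfig)
    prioritizer: PrioritizerConfig = field(default_factory=PrioritizerConfig)
    evidence: EvidenceConfig = field(default_factory=EvidenceConfig)
    cnv: CnvConfig = field(default_factory=CnvConfig)


@dataclass
class PipelineResult:
    qc_reports: list[SampleQcReport]
    records: list[VariantRecord]
    candidates: list[VariantRecord]
    traces: list
    cnv_calls: list
    findings: list
    patients: list[PatientRecord]
    summary: CohortSummary

    @property
    def passing_samples(self) -> set[str]:
        return {r.sample_id for r in self.qc_reports if r.passed}


def expand_depths(depths: DepthMatrix, sample: str) -> list[float]:
    """Per-base depth vector for one sample, expanding per-target means."""
    col = depths.samples.index(sample)
    out: list[float] = []
    for ti, t in enumerate(depths.targets):
        out.extend([float(depths.mean_depth[ti, col])] * (t.end - t.start))
    return out


def populate_pedigree_genotypes(pedigrees: dict[str, Pedigree],
                                records: Sequence[VariantRecord],
                                vcf_samples: Sequence[str]) -> None:
    """Fill pedigree genotype maps from VCF-derived records.

    For every variant carried by a family member, each family member
    present in the VCF gets an explicit allele count (0 when no record —
    a called reference genotype, not a missing one).
    """
    sample_set = set(vcf_samples)
    carried: dict[str, set] = {}
    for r in records:
        carried.setdefault(r.sample_id, set()).add(r.key)
    by_ind = {(r.sample_id, r.key): r for r in records}
    for ped in pedigrees.values():
        keys = set()
        for iid in ped.members:
            keys |= carried.get(iid, set())
        for iid in ped.members:
            if iid not in sample_set:
                continue
            for key in keys:
                rec = by_ind.get((iid, key))
                count = 0 if rec is None else (2 if rec.zygosity == "hom" else 1)
                ped.set_genotype(iid, key, count)


def run_pipeline(
    vcf_path: str | Path,
    depths: DepthMatrix | str | Path,
    snapshots: AnnotationSnapshots | str | Path,
    panel: Optional[PanelDefinition] = None,
    pedigrees: Optional[dict[str, Pedigree] | str | Path] = None,
    etiologies: Optional[dict[str, str]] = None,
    cohort_samples: Optional[Sequence[str]] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run every stage over a cohort VCF + depth matrix + snapshots."""
    config = config or PipelineConfig()
    panel = panel or default_panel()
    if not isinstance(depths, DepthMatrix):
        depths = DepthMatrix.from_tsv(depths)
    if not isinstance(snapshots, AnnotationSnapshots):
        snapshots = AnnotationSnapshots.load(snapshots)
    if pedigrees is not None and not isinstance(pedigrees, dict):
        pedigrees = read_ped(pedigrees)

    records = read_vcf(vcf_path, panel)
    if pedigrees:
        populate_pedigree_genotypes(pedigrees, records,
                                    vcf_sample_list(vcf_path))
    per_sample: dict[str, list[VariantRecord]] = {}
    for r in records:
        per_sample.setdefault(r.sample_id, []).append(r)

    if cohort_samples is None:
        cohort_samples = depths.samples
    lengths = [t.end - t.start for t in depths.targets]
    qc_reports = []
    for s in cohort_samples:
        recs = per_sample.get(s, [])
        known = [snapshots.known_sites.get(r.key) is not None for r in recs]
        col = depths.samples.index(s)
        qc_reports.append(compute_sample_qc(
            s, depths.mean_depth[:, col], recs, known, config=config.qc,
            weights=lengths))
    passing = {r.sample_id for r in qc_reports if r.passed}

    analysis_records = [r for r in records if r.sample_id in passing]
    annotate_all(analysis_records, snapshots)
    candidates, traces = prioritize(analysis_records, panel, config.prioritizer)
    for rec in candidates:
        classify_record(rec, panel, config=config.evidence)

    ratios = normalize_depth(depths)
    cnv_calls = [c for c in call_cnvs(ratios, config.cnv)
                 if c.sample_id in passing]

    cohort_cands = [r for r in candidates if r.sample_id in passing]
    findings = detect_cooccurrence(cohort_cands, cnv_calls)
    ped_members: set[str] = set()
    for ped in (pedigrees or {}).values():
        ped_members |= set(ped.members)
    for gene in sorted(RECESSIVE_GENES):
        for ped in (pedigrees or {}).values():
            findings.extend(detect_biallelic(
                [r for r in cohort_cands if r.sample_id in ped.members],
                ped, gene))
        findings.extend(detect_biallelic(
            [r for r in cohort_cands if r.sample_id not in ped_members],
            None, gene))

    if pedigrees:
        by_patient_ped = {
            iid: ped for ped in pedigrees.values() for iid in ped.members
        }
        for f in findings:
            ped = by_patient_ped.get(f.patient_id)
            if ped is not None and f.segregation == "untested":
                segregation_check(f, ped)

    patients = []
    cands_by_sample: dict[str, list[VariantRecord]] = {}
    for r in cohort_cands:
        cands_by_sample.setdefault(r.sample_id, []).append(r)
    cnvs_by_sample: dict[str, list] = {}
    for c in cnv_calls:
        cnvs_by_sample.setdefault(c.sample_id, []).append(c)
    findings_by_sample: dict[str, list] = {}
    for f in findings:
        findings_by_sample.setdefault(f.patient_id, []).append(f)
    for s in sorted(passing):
        patients.append(PatientRecord(
            patient_id=s,
            etiology=(etiologies or {}).get(s, "other"),
            variants=cands_by_sample.get(s, []),
            cnvs=cnvs_by_sample.get(s, []),
            findings=findings_by_sample.get(s, []),
        ))
    summary = summarize(patients, qc_reports)
    return PipelineResult(
        qc_reports=qc_reports, records=records, candidates=candidates,
        traces=traces, cnv_calls=cnv_calls, findings=findings,
        patients=patients, summary=summary,
    )


def run_fixture_pipeline(config: Optional[PipelineConfig] = None):
    """Annotate, prioritize, classify and analyze the bundled fixture.

    The fixture has no sequencing-level data (no VCF/depths), so QC is
    skipped and the stage chain starts at annotation.
    """
    from .paper_tables import fixture_snapshots, load_paper_fixture

    config = config or PipelineConfig()
    fixture = load_paper_fixture()
    snaps = fixture_snapshots(fixture)
    annotate_all(fixture.records, snaps)
    candidates, traces = prioritize(fixture.records, fixture.panel,
                                    config.prioritizer)
    for rec in candidates:
        classify_record(rec, fixture.panel, config=config.evidence)
    findings = detect_cooccurrence(candidates, fixture.cnvs)
    for gene in sorted(RECESSIVE_GENES):
        for ped in fixture.pedigrees.values():
            findings.extend(detect_biallelic(
                [r for r in candidates if r.sample_id in ped.members],
                ped, gene))
        findings.extend(detect_biallelic(
            [r for r in candidates
             if not any(r.sample_id in ped.members
                        for ped in fixture.pedigrees.values())],
            None, gene))
    findings_by_sample: dict[str, list] = {}
    for f in findings:
        findings_by_sample.setdefault(f.patient_id, []).append(f)
    for p in fixture.patients:
        p.findings = findings_by_sample.get(p.patient_id, [])
    summary = summarize(fixture.patients)
    return fixture, candidates, traces, findings, summary
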