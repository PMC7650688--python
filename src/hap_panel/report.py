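"""Cohort-level aggregation: eligibility, per-gene/per-etiology tallies,
classification breakdowns, and the summary tables behind a cohort figure.

Percentages are always reported next to their raw fraction: patient-level
and variant-level denominators differ, and printing both disambiguates
(e.g. carriers among analyzed patients vs classes among variants).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cnv import CnvCall
from .family import DIGENIC, InheritanceFinding
from .qc import SampleQcReport
from .variants import VariantRecord

ETIOLOGIES = ("IPAH", "HPAH", "PVOD", "CHD", "CTD", "HHT", "other")
CANDIDATE_CLASSES = ("P", "LP", "VUS")

MPAP_MIN = 25.0   # mmHg at rest
PAWP_MAX = 15.0   # mmHg
PVR_MIN = 3.0     # Wood units (exclusive)


class ReportError(ValueError):
    pass


@dataclass
class Hemodynamics:
    mpap: Optional[float] = None
    pawp: Optional[float] = None
    pvr: Optional[float] = None

    def __post_init__(self):
        for name in ("mpap", "pawp", "pvr"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ReportError(f"{name}={v} must be positive")


def check_precapillary_ph(h: Hemodynamics) -> Optional[bool]:
    """Hemodynamic precapillary-PH triad: mPAP ≥ 25, PAWP ≤ 15, PVR > 3 WU.

    Returns None (undetermined) when any value is missing — distinct from
    a definite False.
    """
    if h.mpap is None or h.pawp is None or h.pvr is None:
        return None
    return h.mpap >= MPAP_MIN and h.pawp <= PAWP_MAX and h.pvr > PVR_MIN


@dataclass
class PatientRecord:
    patient_id: str
    etiology: str
    subtype: Optional[str] = None  # e.g. CREST under CTD
    hemodynamics: Optional[Hemodynamics] = None
    variants: list[VariantRecord] = field(default_factory=list)
    cnvs: list[CnvCall] = field(default_factory=list)
    findings: list[InheritanceFinding] = field(default_factory=list)

    def __post_init__(self):
        if self.etiology not in ETIOLOGIES:
            raise ReportError(f"{self.patient_id}: unknown etiology "
                              f"{self.etiology!r}")

    def candidate_variants(self) -> list[VariantRecord]:
        return [v for v in self.variants
                if (v.acmg_class or v.printed_class) in CANDIDATE_CLASSES]


@dataclass
class CohortSummary:
    n_sequenced: int = 0
    n_failed_qc: int = 0
    n_carriers: int = 0
    n_candidate_variants: int = 0
    per_class: Counter = field(default_factory=Counter)
    per_gene: Counter = field(default_factory=Counter)
    per_gene_plp: Counter = field(default_factory=Counter)
    per_gene_vus: Counter = field(default_factory=Counter)
    per_etiology_variants: Counter = field(default_factory=Counter)
    per_etiology_patients: Counter = field(default_factory=Counter)
    per_gene_etiology: Counter = field(default_factory=Counter)
    digenic_count: int = 0
    n_cnv_carriers: int = 0

    @property
    def n_analyzed(self) -> int:
        return self.n_sequenced - self.n_failed_qc

    @property
    def carrier_fraction(self) -> Optional[float]:
        return self.n_carriers / self.n_analyzed if self.n_analyzed else None


def summarize(patients: Sequence[PatientRecord],
              qc: Iterable[SampleQcReport] = ()) -> CohortSummary:
    """Deterministic cohort tallies over classified patients.

    Candidate variants are those classified P/LP/VUS; carriers are
    patients with at least one candidate (small variant or CNV call).
    """
    ids = [p.patient_id for p in patients]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ReportError(f"duplicate patient ids: {dupes}")
    qc = list(qc)
    s = CohortSummary()
    s.n_sequenced = len(qc) if qc else len(patients)
    s.n_failed_qc = sum(1 for r in qc if not r.passed)
    for p in sorted(patients, key=lambda p: p.patient_id):
        cands = p.candidate_variants()
        if cands or p.cnvs:
            s.n_carriers += 1
        if p.cnvs:
            s.n_cnv_carriers += 1
        s.per_etiology_patients[p.etiology] += bool(cands or p.cnvs)
        for v in cands:
            cls = v.acmg_class or v.printed_class
            s.n_candidate_variants += 1
            s.per_class[cls] += 1
            gene = v.gene or "?"
            s.per_gene[gene] += 1
            if cls in ("P", "LP"):
                s.per_gene_plp[gene] += 1
            elif cls == "VUS":
                s.per_gene_vus[gene] += 1
            s.per_etiology_variants[p.etiology] += 1
            s.per_gene_etiology[(gene, p.etiology)] += 1
        s.digenic_count += sum(1 for f in p.findings if f.kind == DIGENIC)
    return s


def per_gene_table(summary: CohortSummary) -> pd.DataFrame:
    """Genes sorted descending by P/LP count, then VUS, then name."""
    genes = sorted(
        summary.per_gene,
        key=lambda g: (-summary.per_gene_plp.get(g, 0),
                       -summary.per_gene_vus.get(g, 0), g),
    )
    return pd.DataFrame([
        {
            "gene": g,
            "p_lp": summary.per_gene_plp.get(g, 0),
            "vus": summary.per_gene_vus.get(g, 0),
            "total": summary.per_gene[g],
        }
        for g in genes
    ], columns=["gene", "p_lp", "vus", "total"])


def cohort_fractions_table(summary: CohortSummary) -> pd.DataFrame:
    """Cohort-level fractions with explicit numerators and denominators."""
    n_seq = summary.n_sequenced
    n_an = summary.n_analyzed
    rows = []

    def add(label, num, den):
        rows.append({
            "quantity": label, "numerator": num, "denominator": den,
            "fraction": round(num / den, 4) if den else "",
        })

    add("qc_failed_of_sequenced", summary.n_failed_qc, n_seq)
    add("carriers_of_analyzed", summary.n_carriers, n_an)
    nv = summary.n_candidate_variants
    for cls in CANDIDATE_CLASSES:
        add(f"{cls.lower()}_of_candidate_variants", summary.per_class.get(cls, 0), nv)
    add("negative_of_analyzed", max(n_an - summary.n_carriers, 0), n_an)
    add("digenic_of_analyzed", summary.digenic_count, n_an)
    return pd.DataFrame(rows, columns=["quantity", "numerator", "denominator",
                                       "fraction"])


def render_figure2_tables(summary: CohortSummary
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(cohort-level fractions, per-gene P-LP/VUS bar table)."""
    return cohort_fractions_table(summary), per_gene_table(summary)
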