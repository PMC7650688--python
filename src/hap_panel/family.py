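"""Inheritance-pattern detection: digenic co-occurrence, biallelic events
in recessive genes, and pedigree segregation checks.

Compound-heterozygote calls follow trio phase logic: two heterozygous
variants in one gene are in trans only when the parental genotypes force
one variant through each parent. Unaffected carriers never falsify
segregation — reduced penetrance is the norm for dominant PAH genes — but
a child allele absent from both genotyped parents does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .cnv import CnvCall
from .variants import VariantRecord

CANDIDATE_CLASSES = frozenset({"P", "LP", "VUS"})

DIGENIC = "digenic_candidate"
BIALLELIC_HOM = "biallelic_hom"
COMPOUND_HET = "compound_het"
SINGLE_HET = "single_het"

CONSISTENT, INCONSISTENT, UNTESTED = "consistent", "inconsistent", "untested"


class PedigreeError(ValueError):
    pass


@dataclass(frozen=True)
class Individual:
    iid: str
    father: Optional[str]
    mother: Optional[str]
    sex: str = "unknown"       # male | female | unknown
    affected: bool = False


@dataclass
class Pedigree:
    family_id: str
    members: dict[str, Individual] = field(default_factory=dict)
    # (individual, variant key) -> alt allele count 0/1/2
    genotypes: dict[tuple[str, tuple], int] = field(default_factory=dict)

    def add(self, ind: Individual) -> None:
        self.members[ind.iid] = ind

    def validate(self) -> None:
        for ind in self.members.values():
            for p in (ind.father, ind.mother):
                if p is not None and p not in self.members:
                    raise PedigreeError(
                        f"{self.family_id}: parent {p} of {ind.iid} unknown")
        for iid in self.members:
            seen = set()
            stack = [iid]
            while stack:
                cur = stack.pop()
                ind = self.members[cur]
                for p in (ind.father, ind.mother):
                    if p is None:
                        continue
                    if p == iid:
                        raise PedigreeError(f"{iid} is its own ancestor")
                    if p not in seen:
                        seen.add(p)
                        stack.append(p)

    def set_genotype(self, iid: str, key: tuple, alt_count: int) -> None:
        if alt_count not in (0, 1, 2):
            raise PedigreeError(f"bad allele count {alt_count}")
        self.genotypes[(iid, key)] = alt_count

    def genotype(self, iid: str, key: tuple) -> Optional[int]:
        return self.genotypes.get((iid, key))

    def parents_of(self, iid: str) -> tuple[Optional[str], Optional[str]]:
        ind = self.members.get(iid)
        if ind is None:
            return None, None
        return ind.father, ind.mother


_SEX = {"1": "male", "2": "female"}


def read_ped(path: str | Path) -> dict[str, Pedigree]:
    """Parse a PED file into one Pedigree per family.

    Columns: family, individual, father, mother, sex (1/2/0), phenotype
    (2=affected). '0' parent entries denote founders.
    """
    peds: dict[str, Pedigree] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 6:
                raise PedigreeError(f"{path}:{ln}: expected 6 columns")
            fam, iid, father, mother, sex, pheno = f[:6]
            ped = peds.setdefault(fam, Pedigree(family_id=fam))
            ped.add(Individual(
                iid=iid,
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
                sex=_SEX.get(sex, "unknown"),
                affected=(pheno == "2"),
            ))
    for ped in peds.values():
        ped.validate()
    return peds


@dataclass
class InheritanceFinding:
    patient_id: str
    kind: str
    variants: list = field(default_factory=list)  # VariantRecords / CnvCalls
    genes: list[str] = field(default_factory=list)
    segregation: str = UNTESTED
    notes: list[str] = field(default_factory=list)


def _record_class(r: VariantRecord) -> Optional[str]:
    return r.acmg_class or r.printed_class


def detect_cooccurrence(candidates: Sequence[VariantRecord],
                        cnvs: Sequence[CnvCall] = ()) -> list[InheritanceFinding]:
    """One digenic_candidate finding per patient with candidate variants
    (small variants or CNV calls) in two or more distinct genes."""
    per_patient: dict[str, dict[str, list]] = {}
    for r in candidates:
        if _record_class(r) not in CANDIDATE_CLASSES or r.gene is None:
            continue
        per_patient.setdefault(r.sample_id, {}).setdefault(r.gene, []).append(r)
    for c in cnvs:
        per_patient.setdefault(c.sample_id, {}).setdefault(c.gene, []).append(c)
    findings = []
    for patient in sorted(per_patient):
        genes = per_patient[patient]
        if len(genes) < 2:
            continue
        ordered = sorted(genes)
        findings.append(InheritanceFinding(
            patient_id=patient,
            kind=DIGENIC,
            variants=[v for g in ordered for v in genes[g]],
            genes=ordered,
        ))
    return findings


def phase_compound_het(child_keys: tuple[tuple, tuple],
                       father_gt: Optional[int], mother_gt: Optional[int],
                       father_gt2: Optional[int], mother_gt2: Optional[int]
                       ) -> tuple[str, str]:
    """Phase two heterozygous child variants from parental genotypes.

    Returns (kind, segregation): compound_het/consistent when transmission
    forces trans; single_het/consistent when both variants must come from
    one parent (cis); compound_het/untested when parents are missing or
    both phases remain possible; compound_het/inconsistent when no
    Mendelian transmission explains the child.
    """
    if father_gt is None and mother_gt is None and \
            father_gt2 is None and mother_gt2 is None:
        return COMPOUND_HET, UNTESTED

    def transmissible(gt: Optional[int]) -> set[int]:
        if gt is None:
            return {0, 1}
        return {0: {0}, 1: {0, 1}, 2: {1}}[gt]

    trans = cis = any_valid = False
    for f1 in transmissible(father_gt):
        for f2 in transmissible(father_gt2):
            for m1 in transmissible(mother_gt):
                for m2 in transmissible(mother_gt2):
                    if f1 + m1 != 1 or f2 + m2 != 1:
                        continue  # child is het at both sites
                    any_valid = True
                    if (f1, f2) in ((1, 0), (0, 1)):
                        trans = True
                    if (f1, f2) in ((1, 1), (0, 0)):
                        cis = True
    if not any_valid:
        return COMPOUND_HET, INCONSISTENT
    if trans and not cis:
        return COMPOUND_HET, CONSISTENT
    if cis and not trans:
        return SINGLE_HET, CONSISTENT
    return COMPOUND_HET, UNTESTED


def detect_biallelic(candidates: Sequence[VariantRecord],
                     pedigree: Optional[Pedigree] = None,
                     gene: str = "EIF2AK4") -> list[InheritanceFinding]:
    """Biallelic findings in a recessive gene (default: the PVOD gene)."""
    per_patient: dict[str, list[VariantRecord]] = {}
    for r in candidates:
        if r.gene == gene and _record_class(r) in CANDIDATE_CLASSES | {None}:
            per_patient.setdefault(r.sample_id, []).append(r)
    findings = []
    for patient in sorted(per_patient):
        recs = per_patient[patient]
        homs = [r for r in recs if r.zygosity == "hom"]
        hets = [r for r in recs if r.zygosity == "het"]
        for r in homs:
            f = InheritanceFinding(patient_id=patient, kind=BIALLELIC_HOM,
                                   variants=[r], genes=[gene])
            if pedigree is not None:
                f = segregation_check(f, pedigree)
            findings.append(f)
        if len(hets) >= 2:
            v1, v2 = hets[0], hets[1]
            if len(hets) > 2:
                pass  # first pair considered; others are extra hets
            father_gt = mother_gt = father_gt2 = mother_gt2 = None
            if pedigree is not None:
                father, mother = pedigree.parents_of(patient)
                if father is not None:
                    father_gt = pedigree.genotype(father, v1.key)
                    father_gt2 = pedigree.genotype(father, v2.key)
                if mother is not None:
                    mother_gt = pedigree.genotype(mother, v1.key)
                    mother_gt2 = pedigree.genotype(mother, v2.key)
            kind, seg = phase_compound_het(
                (v1.key, v2.key), father_gt, mother_gt, father_gt2, mother_gt2)
            f = InheritanceFinding(
                patient_id=patient, kind=kind, variants=[v1, v2], genes=[gene],
                segregation=seg,
            )
            if kind == SINGLE_HET:
                f.notes.append("both variants in cis (one parental haplotype)")
            findings.append(f)
    return findings


def segregation_check(finding: InheritanceFinding,
                      ped: Pedigree) -> InheritanceFinding:
    """Mendelian-compatibility check of a finding against a pedigree.

    Consistent when every genotyped relative's carrier pattern admits a
    Mendelian transmission; unaffected carriers are noted as reduced
    penetrance, never as inconsistency.
    """
    keys = [v.key for v in finding.variants if isinstance(v, VariantRecord)]
    tested = False
    consistent = True
    for key in keys:
        for (iid, k), gt in ped.genotypes.items():
            if k != key or iid == finding.patient_id:
                continue
            tested = True
            ind = ped.members.get(iid)
            if ind is not None and gt > 0 and not ind.affected:
                note = f"unaffected carrier {iid} (reduced penetrance)"
                if note not in finding.notes:
                    finding.notes.append(note)
        child_gt = ped.genotype(finding.patient_id, key)
        if child_gt is None:
            continue
        father, mother = ped.parents_of(finding.patient_id)
        f_gt = ped.genotype(father, key) if father else None
        m_gt = ped.genotype(mother, key) if mother else None
        if f_gt is None and m_gt is None:
            continue
        tested = True

        def transmissible(gt):
            if gt is None:
                return {0, 1}
            return {0: {0}, 1: {0, 1}, 2: {1}}[gt]

        ok = any(
            a + b == child_gt
            for a in transmissible(f_gt) for b in transmissible(m_gt)
        )
        if not ok:
            consistent = False
    if not tested:
        finding.segregation = UNTESTED
    else:
        finding.segregation = CONSISTENT if consistent else INCONSISTENT
    return finding


def findings_table(findings: Iterable[InheritanceFinding]):
    import pandas as pd

    return pd.DataFrame([
        {
            "patient_id": f.patient_id,
            "kind": f.kind,
            "genes": ",".join(f.genes),
            "n_variants": len(f.variants),
            "segregation": f.segregation,
            "notes": "; ".join(f.notes),
        }
        for f in findings
    ])
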