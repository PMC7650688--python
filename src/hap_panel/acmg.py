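"""ACMG/AMP evidence-code algebra and the 2015 combining rules.

Evidence codes are combined into the 5-tier verdict (Pathogenic, Likely
pathogenic, VUS, Likely benign, Benign) by the published criteria-combining
table; any co-occurrence of a pathogenic-tier and a benign-tier rule is the
guideline's "conflicting evidence" outcome and yields VUS. A sixth value,
``N/A``, is reserved for copy-number calls, which never pass through this
engine.

``default_evidence`` maps the annotation bundle onto codes with explicit,
configurable thresholds so every classification is auditable per variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .annotate import AnnotationBundle, predictor_consensus
from .panel import PanelDefinition
from .variants import VariantRecord

PATHOGENIC, LIKELY_PATHOGENIC, VUS = "P", "LP", "VUS"
LIKELY_BENIGN, BENIGN, NOT_APPLICABLE = "LB", "B", "N/A"
CLASSIFICATIONS = (PATHOGENIC, LIKELY_PATHOGENIC, VUS, LIKELY_BENIGN,
                   BENIGN, NOT_APPLICABLE)

LONG_NAMES = {
    "P": "Pathogenic", "LP": "Likely pathogenic", "VUS": "VUS",
    "LB": "Likely benign", "B": "Benign", "N/A": "Not applicable",
}

PATHOGENIC_CODES = (
    "PVS1",
    "PS1", "PS2", "PS3", "PS4",
    "PM1", "PM2", "PM3", "PM4", "PM5", "PM6",
    "PP1", "PP2", "PP3", "PP4", "PP5",
)
BENIGN_CODES = ("BA1", "BS1", "BS2", "BS3", "BS4",
                "BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7")
ALL_CODES = PATHOGENIC_CODES + BENIGN_CODES

_DEFAULT_STRENGTH = {
    "PVS": "very_strong", "PS": "strong", "PM": "moderate", "PP": "supporting",
    "BA": "stand_alone", "BS": "strong", "BP": "supporting",
}
STRENGTHS = ("stand_alone", "very_strong", "strong", "moderate", "supporting")


class EvidenceError(ValueError):
    pass


def code_strength(code: str) -> str:
    for prefix, strength in _DEFAULT_STRENGTH.items():
        if code.startswith(prefix) and code in ALL_CODES:
            return strength
    raise EvidenceError(f"unknown evidence code {code!r}")


@dataclass
class EvidenceSet:
    codes: frozenset[str] = frozenset()
    strength_overrides: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.codes = frozenset(self.codes)
        for c in self.codes:
            code_strength(c)  # validates
        for c, s in self.strength_overrides.items():
            if c not in self.codes:
                raise EvidenceError(f"override for absent code {c!r}")
            if s not in STRENGTHS:
                raise EvidenceError(f"unknown strength {s!r}")

    def strength_of(self, code: str) -> str:
        return self.strength_overrides.get(code, code_strength(code))

    def counts(self) -> dict[str, int]:
        """Counts per effective strength, split by pathogenic/benign side."""
        n = {"pvs": 0, "ps": 0, "pm": 0, "pp": 0, "ba": 0, "bs": 0, "bp": 0}
        for c in self.codes:
            s = self.strength_of(c)
            if c in PATHOGENIC_CODES:
                n[{"very_strong": "pvs", "strong": "ps", "moderate": "pm",
                   "supporting": "pp", "stand_alone": "pvs"}[s]] += 1
            else:
                n[{"stand_alone": "ba", "very_strong": "bs", "strong": "bs",
                   "moderate": "bs", "supporting": "bp"}[s]] += 1
        return n


def combine_evidence(ev: EvidenceSet | Iterable[str]) -> str:
    """Apply the criteria-combining table to an evidence set."""
    if not isinstance(ev, EvidenceSet):
        ev = EvidenceSet(frozenset(ev))
    # contradictory evidence: codes on both sides default the verdict to
    # uncertain significance regardless of the combining rules
    if ev.codes & set(PATHOGENIC_CODES) and ev.codes & set(BENIGN_CODES):
        return VUS
    n = ev.counts()
    pvs, ps, pm, pp = n["pvs"], n["ps"], n["pm"], n["pp"]
    ba, bs, bp = n["ba"], n["bs"], n["bp"]

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or pvs >= 2
        or ps >= 2
        or (ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm >= 1)
        or (ps >= 1 and (pm >= 1 or pp >= 2))
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    if pathogenic:
        return PATHOGENIC
    if likely_pathogenic:
        return LIKELY_PATHOGENIC
    if benign:
        return BENIGN
    if likely_benign:
        return LIKELY_BENIGN
    return VUS


LOF_CONSEQUENCES = frozenset({"stop_gained", "frameshift", "splice_canonical"})


@dataclass
class EvidenceConfig:
    """Thresholds for the default annotation→code mapping."""

    pm2_max_af: float = 1e-4        # absent-or-rarer-than counts as PM2
    ba1_min_af: float = 0.05
    bs1_min_af: float = 1e-3
    pp3_min_consensus: float = 0.5
    bp4_max_consensus: float = 0.2
    min_predictors: int = 3


def default_evidence(record: VariantRecord, panel: PanelDefinition,
                     cohort_context: Optional[dict] = None,
                     config: Optional[EvidenceConfig] = None) -> EvidenceSet:
    """Deterministic evidence assignment from a record's annotations.

    PVS1 fires for truncating consequences in established loss-of-function
    genes; PM2 for variants absent from (or extremely rare in) population
    snapshots; PP3/BP4 from in-silico predictor consensus; PP5/BP6 from
    prior clinical assertions; BA1/BS1 from high population frequency; PP1
    when segregation support is supplied through ``cohort_context``.
    """
    if record.annotations is None:
        raise EvidenceError(f"record {record.key} is not annotated")
    bundle: AnnotationBundle = record.annotations
    config = config or EvidenceConfig()
    codes: set[str] = set()

    tier = None
    if record.gene is not None and record.gene in panel.gene_symbols:
        tier = panel.gene_info(record.gene).evidence_tier
    if bundle.consequence in LOF_CONSEQUENCES and tier == "established":
        codes.add("PVS1")

    af = bundle.popmax_af
    if af is None or af < config.pm2_max_af:
        codes.add("PM2")
    if af is not None and af > config.ba1_min_af:
        codes.add("BA1")
    if af is not None and af > config.bs1_min_af:
        codes.add("BS1")

    consensus = predictor_consensus(bundle)
    if consensus is not None and bundle.predictor_total >= config.min_predictors:
        if consensus >= config.pp3_min_consensus:
            codes.add("PP3")
        elif consensus <= config.bp4_max_consensus:
            codes.add("BP4")

    if bundle.clinical_assertion == "pathogenic_reported":
        codes.add("PP5")
    elif bundle.clinical_assertion == "benign_reported":
        codes.add("BP6")

    if cohort_context and cohort_context.get("segregation_support"):
        codes.add("PP1")

    return EvidenceSet(frozenset(codes))


def classify_record(record: VariantRecord, panel: PanelDefinition,
                    cohort_context: Optional[dict] = None,
                    config: Optional[EvidenceConfig] = None
                    ) -> tuple[EvidenceSet, str]:
    """Assign evidence, combine it, and stamp the record's ACMG class."""
    ev = default_evidence(record, panel, cohort_context, config)
    verdict = combine_evidence(ev)
    record.acmg_class = verdict
    return ev, verdict


def audit_table(rows: Iterable[tuple[VariantRecord, EvidenceSet, str]]):
    """Evidence audit: one row per variant with codes and verdict."""
    import pandas as pd

    return pd.DataFrame([
        {
            "variant": r.variant_string,
            "sample_id": r.sample_id,
            "codes": ",".join(sorted(ev.codes)),
            "class": verdict,
        }
        for r, ev, verdict in rows
    ])
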