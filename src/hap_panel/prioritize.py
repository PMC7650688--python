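"""Variant prioritization cascade: quality → frequency → panel → consequence.

Each record passes through the stages in order and receives a full trace.
Quality failures never drop a variant: they mark it for orthogonal (Sanger)
confirmation if it survives the remaining filters. Population-frequency and
consequence drops can be rescued by a prior pathogenic clinical assertion,
so known founder variants are never lost to a rarity cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .panel import PanelDefinition
from .variants import VariantRecord

CANDIDATE = "candidate"
CANDIDATE_NEEDS_CONFIRMATION = "candidate_needs_confirmation"
DROPPED = "dropped"

DROP_CONSEQUENCES = frozenset({"synonymous", "intronic"})


class PrioritizeError(ValueError):
    pass


@dataclass
class PrioritizerConfig:
    min_depth: int = 10
    min_genotype_quality: float = 30.0
    max_af: float = 1e-3


@dataclass
class FilterTrace:
    key: tuple
    stage_results: list[tuple[str, bool, str]] = field(default_factory=list)
    final: Optional[str] = None

    def add(self, stage: str, keep: bool, reason: str) -> bool:
        self.stage_results.append((stage, keep, reason))
        return keep


def prioritize(records: Iterable[VariantRecord],
               panel: PanelDefinition,
               config: Optional[PrioritizerConfig] = None
               ) -> tuple[list[VariantRecord], list[FilterTrace]]:
    """Run the filter cascade; returns (candidates, one trace per record)."""
    config = config or PrioritizerConfig()
    candidates: list[VariantRecord] = []
    traces: list[FilterTrace] = []
    for rec in records:
        if rec.annotations is None:
            raise PrioritizeError(f"record {rec.key} is not annotated")
        bundle = rec.annotations
        trace = FilterTrace(key=rec.key)
        traces.append(trace)

        low_quality = False
        quality_bits = []
        if rec.depth is not None and rec.depth < config.min_depth:
            low_quality = True
            quality_bits.append(f"DP {rec.depth} < {config.min_depth}")
        if rec.quality is not None and rec.quality < config.min_genotype_quality:
            low_quality = True
            quality_bits.append(f"GQ {rec.quality:g} < {config.min_genotype_quality:g}")
        trace.add("quality", True,
                  "flagged for confirmation: " + "; ".join(quality_bits)
                  if low_quality else "passes quality thresholds")

        rescued = bundle.clinical_assertion == "pathogenic_reported"
        af = bundle.popmax_af
        if af is not None and af > config.max_af and not rescued:
            trace.add("frequency", False,
                      f"popmax AF {af:g} > {config.max_af:g}")
            trace.final = DROPPED
            continue
        trace.add("frequency", True,
                  f"popmax AF {af:g} rescued by prior pathogenic assertion"
                  if (af is not None and af > config.max_af)
                  else (f"popmax AF {af:g} <= {config.max_af:g}"
                        if af is not None else "not observed in controls"))

        if rec.gene is None or rec.gene not in panel.gene_symbols or rec.off_target:
            trace.add("gene", False, f"off-panel ({rec.gene or 'no gene'})")
            trace.final = DROPPED
            continue
        trace.add("gene", True, f"on-panel gene {rec.gene}")

        csq = bundle.consequence
        if csq in DROP_CONSEQUENCES and not rescued:
            trace.add("consequence", False, f"non-candidate consequence {csq}")
            trace.final = DROPPED
            continue
        trace.add("consequence", True,
                  f"consequence {csq or 'unknown'} retained"
                  + (" (rescued)" if csq in DROP_CONSEQUENCES else ""))

        trace.final = CANDIDATE_NEEDS_CONFIRMATION if low_quality else CANDIDATE
        candidates.append(rec)
    return candidates, traces


def explain(trace: FilterTrace) -> str:
    """Deterministic one-line-per-stage rendering of a trace."""
    if not trace.stage_results:
        raise PrioritizeError("trace has no stages")
    lines = [f"variant {trace.key[0]}:{trace.key[1]} {trace.key[2]}>{trace.key[3]}"]
    for stage, keep, reason in trace.stage_results:
        lines.append(f"  [{stage}] {'keep' if keep else 'drop'}: {reason}")
    lines.append(f"  final: {trace.final}")
    return "\n".join(lines)


def trace_table(traces: Iterable[FilterTrace]):
    import pandas as pd

    rows = []
    for t in traces:
        for stage, keep, reason in t.stage_results:
            rows.append({
                "chrom": t.key[0], "pos": t.key[1], "ref": t.key[2],
                "alt": t.key[3], "stage": stage,
                "decision": "keep" if keep else "drop", "reason": reason,
                "final": t.final,
            })
    return pd.DataFrame(rows)
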