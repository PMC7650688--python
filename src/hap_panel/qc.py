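"""Per-sample sequencing QC: coverage, capture, Ti/Tv, and the analysis gate.

Metrics follow standard capture-panel QC practice: fraction of target bases
at >=20x (the gating rule), capture efficiency (on-target fraction),
uniformity (bases within 0.2-2x of the sample mean), and transition /
transversion ratios stratified by known vs novel sites (coding Ti/Tv is
typically ~3.2 for known and ~2.9 for novel sites on a well-behaved run).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .variants import VariantRecord

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class QcConfig:
    min_fraction_at_20x: float = 0.95
    depth_threshold: int = 20
    min_on_target: float = 0.70
    titv_known_band: tuple[float, float] = (2.0, 4.5)
    # Ti/Tv is an unstable estimate on few variants; the band only gates
    # samples with at least this many known-site SNVs.
    titv_min_snvs: int = 50


@dataclass
class SampleQcReport:
    sample_id: str
    total_reads: Optional[int] = None
    on_target_fraction: Optional[float] = None
    fraction_at_20x: Optional[float] = None
    uniformity: Optional[float] = None
    titv_known: Optional[float] = None
    titv_novel: Optional[float] = None
    n_snvs_known: Optional[int] = None  # None = count unknown
    n_snvs_novel: Optional[int] = None
    known_fraction: Optional[float] = None
    het_hom_ratio: Optional[float] = None
    duplicate_fraction: Optional[float] = None  # library complexity; never gates
    error_rate: Optional[float] = None          # raw mismatch rate; never gates
    passed: bool = True
    failure_reasons: list[str] = field(default_factory=list)

    def __post_init__(self):
        for name in ("on_target_fraction", "fraction_at_20x", "uniformity",
                     "known_fraction", "duplicate_fraction", "error_rate"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.sample_id}: {name}={v} outside [0,1]")


def coverage_fraction(depths: Sequence[float], threshold: int = 20,
                      weights: Optional[Sequence[float]] = None) -> float:
    """Fraction of target positions covered at >= threshold (inclusive).

    ``depths`` may be per-base values, or per-target means with target
    lengths passed as ``weights``.
    """
    arr = np.asarray(depths, dtype=float)
    if arr.size == 0:
        raise ValueError("empty target set")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return float(np.average(arr >= threshold, weights=weights))


def uniformity_fraction(depths: Sequence[float], low: float = 0.2,
                        high: float = 2.0,
                        weights: Optional[Sequence[float]] = None) -> float:
    """Fraction of target bases within [low, high] x the sample mean depth."""
    arr = np.asarray(depths, dtype=float)
    if arr.size == 0:
        raise ValueError("empty target set")
    mean = np.average(arr, weights=weights)
    if mean == 0:
        return 0.0
    return float(np.average((arr >= low * mean) & (arr <= high * mean),
                            weights=weights))


def _is_snv(r: VariantRecord) -> bool:
    return len(r.ref) == 1 and len(r.alt) == 1


def titv_counts(records: Iterable[VariantRecord],
                known_flags: Iterable[bool]) -> dict[bool, list[int]]:
    """stratum (known?) -> [transitions, transversions] over SNVs only."""
    counts = {True: [0, 0], False: [0, 0]}
    for rec, known in zip(records, known_flags, strict=True):
        if not _is_snv(rec):
            continue
        ti = (rec.ref.upper(), rec.alt.upper()) in TRANSITIONS
        counts[bool(known)][0 if ti else 1] += 1
    return counts


def titv_ratio(records: Iterable[VariantRecord],
               known_flags: Iterable[bool]) -> tuple[Optional[float], Optional[float]]:
    """(Ti/Tv known, Ti/Tv novel) over SNVs; None where Tv count is zero."""
    counts = titv_counts(records, known_flags)

    def ratio(ti: int, tv: int) -> Optional[float]:
        return ti / tv if tv else None

    return ratio(*counts[True]), ratio(*counts[False])


def compute_sample_qc(
    sample_id: str,
    depths: Sequence[float],
    records: Sequence[VariantRecord] = (),
    known_flags: Optional[Sequence[bool]] = None,
    total_reads: Optional[int] = None,
    on_target_fraction: Optional[float] = None,
    duplicate_fraction: Optional[float] = None,
    error_rate: Optional[float] = None,
    config: Optional[QcConfig] = None,
    weights: Optional[Sequence[float]] = None,
) -> SampleQcReport:
    """Assemble a sample's QC report from depth and variant summaries."""
    config = config or QcConfig()
    if known_flags is None:
        known_flags = [False] * len(records)
    counts = titv_counts(records, known_flags)
    tk = counts[True][0] / counts[True][1] if counts[True][1] else None
    tn = counts[False][0] / counts[False][1] if counts[False][1] else None
    n = len(records)
    hets = sum(1 for r in records if r.zygosity == "het")
    homs = sum(1 for r in records if r.zygosity == "hom")
    report = SampleQcReport(
        sample_id=sample_id,
        total_reads=total_reads,
        on_target_fraction=on_target_fraction,
        fraction_at_20x=coverage_fraction(depths, config.depth_threshold,
                                          weights=weights),
        uniformity=uniformity_fraction(depths, weights=weights),
        titv_known=tk,
        titv_novel=tn,
        n_snvs_known=sum(counts[True]),
        n_snvs_novel=sum(counts[False]),
        known_fraction=(sum(map(bool, known_flags)) / n) if n else None,
        het_hom_ratio=(hets / homs) if homs else None,
        duplicate_fraction=duplicate_fraction,
        error_rate=error_rate,
    )
    return qc_gate(report, config)


def qc_gate(report: SampleQcReport,
            config: Optional[QcConfig] = None) -> SampleQcReport:
    """Fill passed/failure_reasons; a sample fails on any breached rule."""
    config = config or QcConfig()
    reasons: list[str] = []
    if report.fraction_at_20x is not None and \
            report.fraction_at_20x < config.min_fraction_at_20x:
        reasons.append(
            f"coverage: {report.fraction_at_20x:.3f} of target bases at "
            f">={config.depth_threshold}x (requires "
            f">={config.min_fraction_at_20x:.2f})"
        )
    if report.on_target_fraction is not None and \
            report.on_target_fraction < config.min_on_target:
        reasons.append(
            f"capture efficiency: on-target {report.on_target_fraction:.3f} "
            f"< {config.min_on_target:.2f}"
        )
    if report.titv_known is not None and \
            (report.n_snvs_known is None
             or report.n_snvs_known >= config.titv_min_snvs):
        lo, hi = config.titv_known_band
        if not lo <= report.titv_known <= hi:
            reasons.append(
                f"titv: known-site Ti/Tv {report.titv_known:.2f} outside "
                f"[{lo}, {hi}]"
            )
    report.failure_reasons = reasons
    report.passed = not reasons
    return report


def qc_table(reports: Iterable[SampleQcReport]):
    import pandas as pd

    rows = []
    for r in reports:
        rows.append({
            "sample_id": r.sample_id,
            "total_reads": r.total_reads,
            "on_target_fraction": r.on_target_fraction,
            "fraction_at_20x": r.fraction_at_20x,
            "uniformity": r.uniformity,
            "titv_known": r.titv_known,
            "titv_novel": r.titv_novel,
            "known_fraction": r.known_fraction,
            "het_hom_ratio": r.het_hom_ratio,
            "passed": r.passed,
            "failure_reasons": "; ".join(r.failure_reasons),
        })
    return pd.DataFrame(rows)
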