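"""Cross-sample read-depth CNV detection on capture-panel targets.

Two-stage median normalization (library size, then per-target bias) turns
the depth matrix into ratios that sit near 1 for diploid targets; calls
require both a ratio excursion and a robust z-score against the
across-sample distribution for the target, and adjacent called targets of
one gene in one sample merge into a single event. Single-exon events —
e.g. an exon duplication invisible to small-variant calling — are the
design target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .panel import TargetRegion

MIN_REFERENCE_SAMPLES = 8


class DepthError(ValueError):
    pass


@dataclass
class DepthMatrix:
    """Mean per-target depth, targets × samples."""

    targets: list[TargetRegion]
    samples: list[str]
    mean_depth: np.ndarray

    def __post_init__(self):
        self.mean_depth = np.asarray(self.mean_depth, dtype=float)
        if self.mean_depth.shape != (len(self.targets), len(self.samples)):
            raise DepthError(
                f"depth matrix shape {self.mean_depth.shape} != "
                f"({len(self.targets)}, {len(self.samples)})")
        if (self.mean_depth < 0).any():
            raise DepthError("negative depths")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.mean_depth, columns=self.samples)
        meta = pd.DataFrame({
            "chrom": [t.chrom for t in self.targets],
            "start": [t.start for t in self.targets],
            "end": [t.end for t in self.targets],
            "gene": [t.gene for t in self.targets],
            "label": [t.label for t in self.targets],
        })
        pd.concat([meta, df], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DepthMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        meta_cols = ["chrom", "start", "end", "gene", "label"]
        missing = [c for c in meta_cols if c not in df.columns]
        if missing:
            raise DepthError(f"{path}: missing columns {missing}")
        samples = [c for c in df.columns if c not in meta_cols]
        targets = [
            TargetRegion(r.chrom, int(r.start), int(r.end), r.gene, r.label)
            for r in df[meta_cols].itertuples(index=False)
        ]
        return cls(targets, samples, df[samples].to_numpy(dtype=float))


@dataclass
class RatioMatrix:
    targets: list[TargetRegion]
    samples: list[str]
    ratios: np.ndarray
    low_confidence: bool = False


@dataclass
class CnvCall:
    sample_id: str
    gene: str
    labels: list[str]
    kind: str  # gain | loss
    ratio: float
    zscore: float
    classification: str = "N/A"
    low_confidence: bool = False

    def __post_init__(self):
        if self.kind == "gain" and self.ratio <= 1:
            raise ValueError("gain requires ratio > 1")
        if self.kind == "loss" and self.ratio >= 1:
            raise ValueError("loss requires ratio < 1")


@dataclass
class CnvConfig:
    min_ratio_gain: float = 1.35
    max_ratio_loss: float = 0.65
    min_abs_zscore: float = 2.5


def normalize_depth(m: DepthMatrix) -> RatioMatrix:
    """Library-size then target-bias median normalization.

    Samples with zero median target depth are excluded with a warning;
    fewer than 2 usable samples is an error. Ratios are ≈1 for diploid
    cells regardless of per-sample sequencing yield.
    """
    medians = np.median(m.mean_depth, axis=0)
    usable = medians > 0
    if not usable.all():
        dropped = [s for s, u in zip(m.samples, usable) if not u]
        warnings.warn(f"excluding samples with zero median depth: {dropped}")
    if usable.sum() < 2:
        raise DepthError("fewer than 2 usable samples for normalization")
    depth = m.mean_depth[:, usable]
    samples = [s for s, u in zip(m.samples, usable) if u]
    lib_normed = depth / np.median(depth, axis=0, keepdims=True)
    target_med = np.median(lib_normed, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(target_med > 0, lib_normed / target_med, np.nan)
    return RatioMatrix(
        targets=m.targets, samples=samples, ratios=ratios,
        low_confidence=len(samples) < MIN_REFERENCE_SAMPLES,
    )


def call_cnvs(rm: RatioMatrix, config: Optional[CnvConfig] = None) -> list[CnvCall]:
    """Dual ratio/z-score thresholding with per-gene merging of adjacency."""
    config = config or CnvConfig()
    ratios = rm.ratios
    n_targets, n_samples = ratios.shape
    if rm.low_confidence:
        warnings.warn(
            f"only {n_samples} reference samples (<{MIN_REFERENCE_SAMPLES}); "
            "calls marked low confidence")

    center = np.nanmedian(ratios, axis=1, keepdims=True)
    mad = np.nanmedian(np.abs(ratios - center), axis=1, keepdims=True)
    scale = 1.4826 * mad
    fallback = np.nanstd(ratios, axis=1, keepdims=True)
    scale = np.where(scale > 0, scale, fallback)
    degenerate = (scale <= 0) | ~np.isfinite(scale)
    if degenerate.any():
        bad = [rm.targets[i].label for i in np.flatnonzero(degenerate[:, 0])]
        warnings.warn(f"zero-variance targets skipped: {bad}")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (ratios - center) / scale

    calls: list[CnvCall] = []
    for si, sample in enumerate(rm.samples):
        flagged: list[tuple[int, str]] = []
        for ti in range(n_targets):
            if degenerate[ti, 0] or not np.isfinite(ratios[ti, si]):
                continue
            r, zz = ratios[ti, si], z[ti, si]
            if r >= config.min_ratio_gain and abs(zz) >= config.min_abs_zscore:
                flagged.append((ti, "gain"))
            elif r <= config.max_ratio_loss and abs(zz) >= config.min_abs_zscore:
                flagged.append((ti, "loss"))
        # merge runs of adjacent flagged targets within one gene and kind
        runs: list[list[tuple[int, str]]] = []
        for ti, kind in flagged:
            if (runs and runs[-1][-1][1] == kind
                    and runs[-1][-1][0] == ti - 1
                    and rm.targets[ti].gene == rm.targets[runs[-1][-1][0]].gene):
                runs[-1].append((ti, kind))
            else:
                runs.append([(ti, kind)])
        for run in runs:
            idxs = [ti for ti, _ in run]
            kind = run[0][1]
            zz = z[idxs, si]
            calls.append(CnvCall(
                sample_id=sample,
                gene=rm.targets[idxs[0]].gene,
                labels=[rm.targets[ti].label for ti in idxs],
                kind=kind,
                ratio=float(np.mean(ratios[idxs, si])),
                zscore=float(zz[np.argmax(np.abs(zz))]),
                low_confidence=rm.low_confidence,
            ))
    return calls


def calls_table(calls: list[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "sample_id": c.sample_id, "gene": c.gene,
            "targets": ",".join(c.labels), "kind": c.kind,
            "ratio": round(c.ratio, 4), "zscore": round(c.zscore, 3),
            "classification": c.classification,
            "low_confidence": c.low_confidence,
        }
        for c in calls
    ], columns=["sample_id", "gene", "targets", "kind", "ratio", "zscore",
                "classification", "low_confidence"])
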