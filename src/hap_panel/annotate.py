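"""Offline variant annotation: frequency/predictor/clinical snapshots and
consequence calling on the toy transcript models.

Annotation is snapshot-based by design: the lookup tables are plain TSVs
(emulating gnomAD-like population frequencies, dbNSFP-like predictor tallies
and ClinVar-like assertions) loaded once, so annotation is pure and
reproducible with no live queries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import transcripts as _tx
from .variants import VariantRecord

CONSEQUENCES = (
    "missense", "stop_gained", "frameshift", "splice_canonical",
    "splice_region", "inframe_indel", "synonymous", "intronic", "other",
)

CLINICAL_ASSERTIONS = ("pathogenic_reported", "benign_reported",
                       "conflicting", "none")

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SPLICE_CANONICAL_WINDOW = 2
SPLICE_REGION_WINDOW = 8
EXONIC_SPLICE_BASES = 3


class SnapshotError(ValueError):
    pass


class ConsequenceError(ValueError):
    pass


@dataclass
class AnnotationBundle:
    dbsnp_id: Optional[str] = None
    af_sources: dict[str, float] = field(default_factory=dict)
    predictor_deleterious: int = 0
    predictor_total: int = 0
    cadd_like: Optional[float] = None
    clinical_assertion: str = "none"
    consequence: Optional[str] = None

    def __post_init__(self):
        if self.predictor_deleterious > self.predictor_total:
            raise ValueError("predictor_deleterious exceeds predictor_total")
        if self.clinical_assertion not in CLINICAL_ASSERTIONS:
            raise ValueError(f"bad clinical assertion {self.clinical_assertion!r}")
        for src, af in self.af_sources.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"{src}: allele frequency {af} outside [0,1]")

    @property
    def popmax_af(self) -> Optional[float]:
        """Maximum frequency over sources; None means never observed."""
        return max(self.af_sources.values()) if self.af_sources else None

    @property
    def known(self) -> bool:
        return self.dbsnp_id is not None


def predictor_consensus(bundle: AnnotationBundle) -> Optional[float]:
    """Fraction of available in-silico predictors voting deleterious."""
    if bundle.predictor_total == 0:
        return None
    return bundle.predictor_deleterious / bundle.predictor_total


_SNAPSHOT_SCHEMAS = {
    "frequencies": ["chrom", "pos", "ref", "alt", "source", "af"],
    "predictors": ["chrom", "pos", "ref", "alt", "deleterious", "total", "cadd"],
    "clinical": ["chrom", "pos", "ref", "alt", "assertion"],
    "known_sites": ["chrom", "pos", "ref", "alt", "dbsnp_id"],
}

Key = tuple[str, int, str, str]


@dataclass
class AnnotationSnapshots:
    """In-memory annotation tables keyed by normalized (chrom,pos,ref,alt)."""

    frequencies: dict[Key, dict[str, float]] = field(default_factory=dict)
    predictors: dict[Key, tuple[int, int, Optional[float]]] = field(default_factory=dict)
    clinical: dict[Key, str] = field(default_factory=dict)
    known_sites: dict[Key, str] = field(default_factory=dict)

    @staticmethod
    def _check_schema(df: pd.DataFrame, name: str, path) -> None:
        need = _SNAPSHOT_SCHEMAS[name]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise SnapshotError(f"{path}: {name} snapshot missing columns {missing}")

    @classmethod
    def load(cls, directory: str | Path) -> "AnnotationSnapshots":
        directory = Path(directory)
        self = cls()
        for name in _SNAPSHOT_SCHEMAS:
            path = directory / f"{name}.tsv"
            if not path.exists():
                continue
            df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
            cls._check_schema(df, name, path)
            for row in df.itertuples(index=False):
                key = (row.chrom, int(row.pos), row.ref, row.alt)
                if name == "frequencies":
                    self.frequencies.setdefault(key, {})[row.source] = float(row.af)
                elif name == "predictors":
                    cadd = float(row.cadd) if pd.notna(row.cadd) else None
                    self.predictors[key] = (int(row.deleterious), int(row.total), cadd)
                elif name == "clinical":
                    if row.assertion not in CLINICAL_ASSERTIONS:
                        raise SnapshotError(
                            f"{path}: bad assertion {row.assertion!r}")
                    self.clinical[key] = row.assertion
                else:
                    self.known_sites[key] = str(row.dbsnp_id)
        return self

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        freq_rows = [
            {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
             "source": s, "af": af}
            for k, srcs in sorted(self.frequencies.items())
            for s, af in sorted(srcs.items())
        ]
        pd.DataFrame(freq_rows, columns=_SNAPSHOT_SCHEMAS["frequencies"]).to_csv(
            directory / "frequencies.tsv", sep="\t", index=False)
        pred_rows = [
            {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
             "deleterious": d, "total": t, "cadd": c if c is not None else ""}
            for k, (d, t, c) in sorted(self.predictors.items())
        ]
        pd.DataFrame(pred_rows, columns=_SNAPSHOT_SCHEMAS["predictors"]).to_csv(
            directory / "predictors.tsv", sep="\t", index=False)
        clin_rows = [
            {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "assertion": a}
            for k, a in sorted(self.clinical.items())
        ]
        pd.DataFrame(clin_rows, columns=_SNAPSHOT_SCHEMAS["clinical"]).to_csv(
            directory / "clinical.tsv", sep="\t", index=False)
        known_rows = [
            {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "dbsnp_id": d}
            for k, d in sorted(self.known_sites.items())
        ]
        pd.DataFrame(known_rows, columns=_SNAPSHOT_SCHEMAS["known_sites"]).to_csv(
            directory / "known_sites.tsv", sep="\t", index=False)


def consequence_call(record: VariantRecord,
                     model: Optional[_tx.ToyTranscript] = None,
                     reference: Optional[str] = None) -> str:
    """Predicted functional effect of a variant on a toy transcript.

    Precedence: stop_gained > frameshift > splice_canonical > splice_region
    > codon comparison. A variant is splice_canonical only when it lies
    entirely within the ±1/±2 intron positions; anything else touching the
    ±3..±8 window (or the last 3 exonic bases of a non-terminal exon) is
    splice_region.
    """
    if model is None:
        models = _tx.transcript_models()
        if record.gene is None or record.gene not in models:
            raise ConsequenceError(
                f"{record.key}: no transcript model for gene {record.gene!r}")
        model = models[record.gene]
    if reference is None:
        reference = _tx.reference_sequence()

    ref, alt, pos0 = record.ref, record.alt, record.pos - 1
    # reduce to the changed bases (VCF records carry a shared anchor base)
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos0 = ref[1:], alt[1:], pos0 + 1
    if len(ref) > 1 or len(alt) > 1:
        if ref[0] == alt[0]:
            ref, alt, pos0 = ref[1:], alt[1:], pos0 + 1

    if len(ref) == len(alt) == 1:
        affected = [pos0]
    elif ref:  # deletion / delins: the removed reference bases
        affected = list(range(pos0, pos0 + len(ref)))
    else:      # pure insertion: classify by the flanking bases
        affected = [pos0 - 1, pos0]

    try:
        mapped = [model.genomic_to_cdna(g) for g in affected]
    except ValueError as exc:
        raise ConsequenceError(str(exc)) from exc
    offsets = [off for _, off in mapped]

    indel_len = abs(len(ref) - len(alt))
    exonic = all(off == 0 for off in offsets)

    if not exonic:
        intronic_offsets = [off for off in offsets if off != 0]
        if all(off != 0 for off in offsets) and \
                all(abs(o) <= SPLICE_CANONICAL_WINDOW for o in intronic_offsets):
            return "splice_canonical"
        if any(abs(o) <= SPLICE_REGION_WINDOW for o in intronic_offsets) or \
                any(off == 0 for off in offsets):
            return "splice_region"
        return "intronic"

    cds = model.cds_sequence(reference)

    if len(ref) == len(alt) == 1:
        cpos = mapped[0][0]
        ci = (cpos - 1) // 3
        codon = cds[ci * 3:ci * 3 + 3]
        if len(codon) < 3:
            return "other"
        within = (cpos - 1) % 3
        if codon[within].upper() != ref.upper():
            raise ConsequenceError(
                f"{record.key}: reference/codon disagreement at c.{cpos}")
        new_codon = codon[:within] + alt + codon[within + 1:]
        aa_ref = CODON_TABLE[codon.upper()]
        aa_alt = CODON_TABLE[new_codon.upper()]
        if aa_alt == "*" and aa_ref != "*":
            return "stop_gained"
        # exonic splice region: last 3 bases of a non-terminal exon
        ei = model.exon_containing_cdna(cpos)
        if ei < len(model.exons) - 1:
            exon_end_g = model.exons[ei][1]
            if exon_end_g - EXONIC_SPLICE_BASES <= pos0 < exon_end_g:
                return "splice_region"
        if aa_ref == aa_alt:
            return "synonymous"
        if aa_ref == "*" or aa_alt == "*":
            return "other"
        return "missense"

    # exonic indel
    if indel_len % 3 != 0:
        return "frameshift"
    return "inframe_indel" if indel_len else "other"


def annotate(record: VariantRecord, snapshots: AnnotationSnapshots,
             call_consequence: bool = True) -> VariantRecord:
    """Attach an :class:`AnnotationBundle` to a record (pure given inputs)."""
    key = record.key
    d, t, cadd = snapshots.predictors.get(key, (0, 0, None))
    consequence = None
    if call_consequence and record.gene is not None:
        try:
            consequence = consequence_call(record)
        except ConsequenceError:
            consequence = None
    record.annotations = AnnotationBundle(
        dbsnp_id=snapshots.known_sites.get(key),
        af_sources=dict(snapshots.frequencies.get(key, {})),
        predictor_deleterious=d,
        predictor_total=t,
        cadd_like=cadd,
        clinical_assertion=snapshots.clinical.get(key, "none"),
        consequence=consequence,
    )
    return record


def annotate_all(records, snapshots: AnnotationSnapshots,
                 call_consequence: bool = True):
    return [annotate(r, snapshots, call_consequence) for r in records]
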