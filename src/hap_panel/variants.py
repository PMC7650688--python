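"""Small-variant handling: HGVS-style cDNA descriptors, VCF input, reports.

The parser covers the descriptor subset that appears in clinical panel
reports (substitution, deletion, duplication, insertion, delins, with
intronic ±offsets and ranges) — enough to round-trip every variant string
in the bundled fixture tables. It is deliberately not a full HGVS grammar.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam

from . import transcripts as _tx
from .panel import PanelDefinition


class HgvsParseError(ValueError):
    pass


class VcfError(ValueError):
    pass


_POS_RE = re.compile(r"^(\d+)([+-]\d+)?$")
_CHANGE_RE = re.compile(
    r"^(?P<sub>(?P<ref>[ACGT])>(?P<alt>[ACGT]))$"
    r"|^(?P<delins>delins(?P<delins_seq>[ACGT]+))$"
    r"|^(?P<del>del(?P<del_seq>[ACGT]*))$"
    r"|^(?P<dup>dup(?P<dup_seq>[ACGT]*))$"
    r"|^(?P<ins>ins(?P<ins_seq>[ACGT]+))$"
)


@dataclass(frozen=True, order=True)
class CdnaPos:
    """A cDNA coordinate: position N with optional intronic offset ±k."""

    pos: int
    offset: int = 0

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.pos)
        return f"{self.pos}{self.offset:+d}"

    @classmethod
    def parse(cls, text: str) -> "CdnaPos":
        m = _POS_RE.match(text)
        if not m:
            raise HgvsParseError(f"bad cDNA position {text!r}")
        return cls(int(m.group(1)), int(m.group(2) or 0))


@dataclass(frozen=True)
class HgvsDescription:
    transcript: str
    start: CdnaPos
    end: Optional[CdnaPos]  # None for single-position descriptors
    kind: str               # substitution|deletion|duplication|insertion|delins
    ref: str = ""
    alt: str = ""
    protein: Optional[str] = None
    gene: Optional[str] = None

    KINDS = ("substitution", "deletion", "duplication", "insertion", "delins")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise HgvsParseError(f"unknown kind {self.kind!r}")
        if self.kind == "substitution" and not (len(self.ref) == len(self.alt) == 1):
            raise HgvsParseError("substitution requires single ref and alt bases")
        if self.kind in ("insertion", "delins") and not self.alt:
            raise HgvsParseError(f"{self.kind} requires an inserted sequence")

    @property
    def cdna(self) -> str:
        span = str(self.start) if self.end is None else f"{self.start}_{self.end}"
        if self.kind == "substitution":
            change = f"{self.ref}>{self.alt}"
        elif self.kind == "deletion":
            change = f"del{self.ref}"
        elif self.kind == "duplication":
            change = f"dup{self.ref}"
        elif self.kind == "insertion":
            change = f"ins{self.alt}"
        else:
            change = f"delins{self.alt}"
        return f"c.{span}{change}"

    def format(self) -> str:
        """Canonical string; parsing it reproduces this description."""
        out = f"{self.transcript}:{self.cdna}"
        if self.protein:
            out += f":{self.protein}"
        return out

    __str__ = format


_PROTEIN_RE = re.compile(r"^p\.\(?[A-Za-z0-9*?=_]+\)?$")


def parse_hgvs(text: str) -> HgvsDescription:
    """Parse a transcript-anchored HGVS-style variant string.

    Accepts the layouts seen in clinical tables: an optional leading gene
    symbol, a versioned or unversioned NM_ accession optionally followed by
    ``(GENE)``, optional ``exonNN`` tokens, a ``c.`` descriptor and an
    optional trailing ``p.`` effect. Raises :class:`HgvsParseError` naming
    the offending token otherwise.
    """
    if not text or not text.strip():
        raise HgvsParseError("empty variant string")
    tokens = [t.strip() for t in text.strip().split(":") if t.strip()]
    transcript = gene = protein = None
    cdna_tok = None
    for tok in tokens:
        if tok.startswith("NM_"):
            m = re.match(r"^(NM_\d+(?:\.\d+)?)(?:\((\w+)\))?$", tok)
            if not m:
                raise HgvsParseError(f"bad transcript token {tok!r}")
            transcript = m.group(1)
            gene = gene or m.group(2)
        elif tok.startswith("c."):
            cdna_tok = tok
        elif tok.startswith("p."):
            if not _PROTEIN_RE.match(tok):
                raise HgvsParseError(f"bad protein token {tok!r}")
            protein = tok
        elif re.match(r"^exon\d+$", tok, flags=re.IGNORECASE):
            continue
        elif re.match(r"^\w+$", tok) and transcript is None and cdna_tok is None:
            gene = tok  # leading gene symbol
        else:
            raise HgvsParseError(f"unrecognized token {tok!r}")
    if cdna_tok is None:
        raise HgvsParseError(f"no c. descriptor in {text!r}")
    if transcript is None:
        raise HgvsParseError(f"missing transcript prefix in {text!r}")

    body = cdna_tok[2:]
    m = re.match(r"^(\d+[+-]?\d*)(?:_(\d+[+-]?\d*))?(.*)$", body)
    if not m or not m.group(3):
        raise HgvsParseError(f"bad cDNA descriptor {cdna_tok!r}")
    start = CdnaPos.parse(m.group(1))
    end = CdnaPos.parse(m.group(2)) if m.group(2) else None
    cm = _CHANGE_RE.match(m.group(3))
    if not cm:
        raise HgvsParseError(f"bad change token {m.group(3)!r} in {cdna_tok!r}")
    if cm.group("sub"):
        kind, ref, alt = "substitution", cm.group("ref"), cm.group("alt")
    elif cm.group("delins"):
        kind, ref, alt = "delins", "", cm.group("delins_seq")
    elif cm.group("del"):
        kind, ref, alt = "deletion", cm.group("del_seq"), ""
    elif cm.group("dup"):
        kind, ref, alt = "duplication", cm.group("dup_seq"), ""
    else:
        kind, ref, alt = "insertion", "", cm.group("ins_seq")
    if kind == "substitution" and end is not None:
        raise HgvsParseError(f"substitution cannot span a range: {cdna_tok!r}")
    return HgvsDescription(
        transcript=transcript, start=start, end=end, kind=kind,
        ref=ref, alt=alt, protein=protein, gene=gene,
    )


ZYGOSITIES = ("het", "hom", "hemi")


@dataclass
class VariantRecord:
    """One observed alternate allele in one sample, VCF-style coordinates."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_id: str
    gene: Optional[str] = None
    hgvs: Optional[HgvsDescription] = None
    zygosity: str = "het"
    quality: Optional[float] = None  # genotype quality
    depth: Optional[int] = None
    etiology: Optional[str] = None
    off_target: bool = False
    annotations: Optional[object] = None  # AnnotationBundle, filled later
    acmg_class: Optional[str] = None      # filled by the classifier
    printed_class: Optional[str] = None   # class as printed in a source table

    def __post_init__(self):
        if self.ref == self.alt:
            raise VcfError(f"{self.key}: ref equals alt")
        if self.zygosity not in ZYGOSITIES:
            raise VcfError(f"bad zygosity {self.zygosity!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_string(self) -> str:
        if self.hgvs is not None:
            s = self.hgvs.format()
            return f"{self.gene}:{s}" if self.gene else s
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


def normalize_variant(chrom: str, pos: int, ref: str, alt: str,
                      seq: str) -> tuple[int, str, str]:
    """Left-align and trim an allele pair against a reference sequence.

    ``pos`` is 1-based; ``seq`` is the full reference for ``chrom``. The
    algorithm shifts the representation left until it can shift no further,
    then trims the shared prefix — the parsimonious VCF normal form.
    """
    if ref == alt:
        raise VcfError("ref equals alt")
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise VcfError(f"cannot left-extend at {chrom}:1")
                base = seq[pos - 2]
                ref, alt = base + ref, base + alt
                pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def vcf_sample_list(path: str | Path) -> list[str]:
    with pysam.VariantFile(str(path)) as vcf:
        return list(vcf.header.samples)


def read_vcf(path: str | Path, panel: PanelDefinition,
             reference: Optional[dict[str, str]] = None) -> list[VariantRecord]:
    """Read a multi-sample VCF into one record per sample × alt allele.

    Multi-allelic sites are decomposed; indels are left-aligned against the
    reference (the packaged synthetic contig by default); records outside
    panel targets are flagged ``off_target``. Sites whose REF disagrees
    with the reference raise :class:`VcfError` naming the site.
    """
    if reference is None:
        reference = {_tx.CONTIG: _tx.reference_sequence()}
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        if "GT" not in vcf.header.formats:
            raise VcfError(f"{path}: no GT FORMAT field in header")
        for rec in vcf:
            seq = reference.get(rec.chrom)
            if seq is not None:
                have = seq[rec.start:rec.start + len(rec.ref)].upper()
                if have != rec.ref.upper():
                    raise VcfError(
                        f"reference mismatch at {rec.chrom}:{rec.pos} "
                        f"(VCF ref {rec.ref!r}, reference {have!r})"
                    )
            alts = rec.alts or ()
            for sample, call in rec.samples.items():
                gt = call.get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                called = [a for a in gt if a not in (None, 0)]
                for ai in sorted(set(called)):
                    alt = alts[ai - 1]
                    if alt in (None, "*", "<NON_REF>"):
                        continue
                    zyg = "hom" if called.count(ai) >= 2 else "het"
                    pos, ref, alt_n = rec.pos, rec.ref, alt
                    if seq is not None and (len(ref) > 1 or len(alt_n) > 1):
                        pos, ref, alt_n = normalize_variant(
                            rec.chrom, pos, ref, alt_n, seq)
                    gene = panel.gene_at(rec.chrom, pos)
                    dp = call.get("DP")
                    gq = call.get("GQ")
                    records.append(VariantRecord(
                        chrom=rec.chrom, pos=pos, ref=ref, alt=alt_n,
                        sample_id=sample, gene=gene,
                        zygosity=zyg,
                        quality=float(gq) if gq is not None else None,
                        depth=int(dp) if dp is not None else None,
                        off_target=gene is None,
                    ))
    return records


REPORT_COLUMNS = ["Patient ID", "PAH Etiology", "Variant", "GT",
                  "ACMG Classification"]

_GT_LABEL = {"het": "Het", "hom": "Hom", "hemi": "Hemi"}


def report_table(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Patient/variant report mirroring the layout of clinical panel tables."""
    rows = []
    for r in records:
        rows.append({
            "Patient ID": r.sample_id,
            "PAH Etiology": r.etiology or "",
            "Variant": r.variant_string,
            "GT": _GT_LABEL[r.zygosity],
            "ACMG Classification": r.acmg_class or r.printed_class or "",
            "_gene": r.gene or "",
            "_cdna": r.hgvs.start.pos if r.hgvs else r.pos,
        })
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS + ["_gene", "_cdna"])
    df = df.sort_values(["Patient ID", "_gene", "_cdna"], kind="mergesort")
    return df[REPORT_COLUMNS].reset_index(drop=True)


def write_report_table(records: Iterable[VariantRecord],
                       path: str | Path) -> pd.DataFrame:
    df = report_table(records)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_report_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
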