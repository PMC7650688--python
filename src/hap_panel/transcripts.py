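"""Synthetic reference and toy transcript models for the 21 panel genes.

The paper-derived fixtures describe variants only in transcript (c.) space;
no genomic coordinates or capture BED were published. This module builds a
deterministic synthetic reference contig (``panel_ref``) that lays out one
toy transcript per panel gene: coding exons separated by short introns with
canonical GT..AG splice sites, CDS lengths large enough to contain every
printed c. position, and codons at fixture positions patched so that the
printed reference alleles and protein effects hold on the toy sequence.

Coordinates follow the two standard conventions: genomic intervals are
0-based half-open, cDNA/HGVS positions are 1-based. Conversion happens only
through :class:`ToyTranscript`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

CONTIG = "panel_ref"

#: All 21 HAP v1.2 panel genes with the transcript accession used for each
#: (versions as printed where the tables print one).
TRANSCRIPT_IDS: dict[str, str] = {
    "ABCC8": "NM_000352.4",
    "ACVRL1": "NM_000020.3",
    "BMPR1B": "NM_001203.3",
    "BMPR2": "NM_001204.6",
    "CAV1": "NM_001753.5",
    "CBLN2": "NM_182511.3",
    "CPS1": "NM_001122633.2",
    "EIF2AK4": "NM_001013703.3",
    "ENG": "NM_001114753.3",
    "GDF2": "NM_016204.4",
    "KCNA5": "NM_002234.4",
    "KCNK3": "NM_002246.3",
    "MMACHC": "NM_015506.3",
    "NOTCH3": "NM_000435.2",
    "SARS2": "NM_017827.3",
    "SMAD1": "NM_005900.2",
    "SMAD4": "NM_005359.6",
    "SMAD5": "NM_001001420.2",
    "SMAD9": "NM_005905.6",
    "TBX4": "NM_018488.3",
    "TOPBP1": "NM_007027.4",
}

#: Toy CDS length per gene (multiple of 3, includes the stop codon). Sized
#: from the real protein lengths so every fixture c. position fits.
CDS_LENGTHS: dict[str, int] = {
    "ABCC8": 4746,
    "ACVRL1": 1512,
    "BMPR1B": 1509,
    "BMPR2": 3114,
    "CAV1": 537,
    "CBLN2": 660,
    "CPS1": 4503,
    "EIF2AK4": 4896,
    "ENG": 1977,
    "GDF2": 1290,
    "KCNA5": 1842,
    "KCNK3": 1185,
    "MMACHC": 849,
    "NOTCH3": 6966,
    "SARS2": 1557,
    "SMAD1": 1398,
    "SMAD4": 1659,
    "SMAD5": 1398,
    "SMAD9": 1404,
    "TBX4": 1641,
    "TOPBP1": 4569,
}

# cDNA positions after which an intron must fall, so that the fixture's
# intronic descriptors (c.77-5.., c.579+5, c.2694+1) sit at real junctions.
REQUIRED_EXON_ENDS: dict[str, tuple[int, ...]] = {
    "ABCC8": (579, 2694),
    "BMPR2": (76,),
}

# (gene, 1-based codon index, codon) — reference codons forced so printed
# ref alleles / protein effects are consistent with the toy CDS.
CODON_PATCHES: tuple[tuple[str, int, str], ...] = (
    ("NOTCH3", 61, "CGG"),     # c.181C>T  p.(Arg61Trp)
    ("NOTCH3", 655, "AAT"),    # c.1964A>G p.(Asn655Ser)
    ("NOTCH3", 1735, "GAA"),   # c.5203G>A p.(Glu1735Lys)
    ("NOTCH3", 2033, "CCT"),   # c.6097C>G p.(Pro2033Ala)
    ("NOTCH3", 2178, "CCA"),   # c.6532C>T p.(Pro2178Ser)
    ("ABCC8", 477, "GTG"),     # c.1429G>A p.(Val477Met)
    ("ABCC8", 548, "ACG"),     # c.1643C>T p.(Thr548Met)
    ("ABCC8", 808, "CAA"),     # c.2422C>A p.(Gln808Lys)
    ("ABCC8", 1080, "GTT"),    # c.3238G>A p.(Val1080Ile)
    ("ABCC8", 1132, "GAT"),    # c.3394G>A p.(Asp1132Asn)
    ("ABCC8", 1326, "GAA"),    # c.3976G>A p.(Glu1326Lys)
    ("SARS2", 46, "GAG"),      # c.136G>A  p.(Glu46Lys)
    ("TBX4", 340, "CGA"),      # c.1018C>T p.(Arg340*)
    ("TBX4", 371, "CCA"),      # c.1112dupC p.(Pro372Serfs*14)
    ("SMAD1", 246, "ATG"),     # c.738G>C  p.(Met246Ile)
    ("SMAD5", 255, "ATC"),     # c.763A>G  p.(Ile255Val)
    ("CPS1", 346, "GCT"),      # c.1036G>A p.(Ala346Thr)
    ("CPS1", 1016, "ACG"),     # c.3047C>T p.(Thr1016Met)
    ("CPS1", 1418, "CCT"),     # c.4252C>T p.(Pro1418Ser)
    ("GDF2", 214, "TGG"),      # c.642G>A  p.(Trp214*)
    ("BMPR2", 892, "GAA"),     # c.2674delG p.(Glu892Asnfs*4)
    ("CBLN2", 88, "TCC"),      # c.263C>T  p.(Ser88Phe)
    ("EIF2AK4", 1115, "CCG"),  # c.3344C>T p.(Pro1115Leu)
    ("EIF2AK4", 1256, "CGA"),  # c.3766C>T p.(Arg1256*)
)

# (gene, anchor cdna position, intron offset of first patched base, bases)
INTRON_PATCHES: tuple[tuple[str, int, int, str], ...] = (
    ("BMPR2", 77, -5, "TTTA"),  # c.77-5_77-2delTTTA
    ("ABCC8", 579, 5, "G"),     # c.579+5G>A
)

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]

INTRON_LEN = 300
EXON_TARGET_LEN = 160
FLANK_LEN = 1000


@dataclass(frozen=True)
class ToyTranscript:
    """A plus-strand coding transcript on the synthetic contig.

    The transcript has no UTRs: cDNA position c.1 is the first base of the
    first exon and the CDS (stop codon included) spans all exons.
    """

    gene: str
    tx_id: str
    exons: tuple[tuple[int, int], ...]  # genomic, 0-based half-open
    cds_len: int
    # cumulative cdna position at exon starts, 1-based (derived)
    _exon_cdna_starts: tuple[int, ...] = field(default=(), repr=False)

    def __post_init__(self):
        starts, c = [], 1
        for s, e in self.exons:
            starts.append(c)
            c += e - s
        object.__setattr__(self, "_exon_cdna_starts", tuple(starts))

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exon_containing_cdna(self, pos: int) -> int:
        """0-based exon index whose cDNA range contains ``pos`` (1-based)."""
        if not 1 <= pos <= self.cds_len:
            raise ValueError(f"{self.gene}: c.{pos} outside CDS 1..{self.cds_len}")
        idx = int(np.searchsorted(self._exon_cdna_starts, pos, side="right")) - 1
        return idx

    def cdna_to_genomic(self, pos: int, offset: int = 0) -> int:
        """Map c.pos(+/-offset) to a 0-based genomic coordinate."""
        i = self.exon_containing_cdna(pos)
        g = self.exons[i][0] + (pos - self._exon_cdna_starts[i])
        if offset:
            # +k runs into the downstream intron, -k into the upstream one
            exon_s, exon_e = self.exons[i]
            gpos = g + offset
            if offset > 0 and g != exon_e - 1:
                raise ValueError(
                    f"{self.gene}: c.{pos}+{offset} but c.{pos} is not an exon end"
                )
            if offset < 0 and g != exon_s:
                raise ValueError(
                    f"{self.gene}: c.{pos}{offset} but c.{pos} is not an exon start"
                )
            return gpos
        return g

    def genomic_to_cdna(self, gpos: int) -> tuple[int, int]:
        """Map a genomic coordinate to (cdna position, intron offset).

        Offset 0 for exonic positions; otherwise the HGVS-style nearest-edge
        offset (positive after an exon end, negative before an exon start).
        Raises ValueError outside the transcript span.
        """
        lo, hi = self.span
        if not lo <= gpos < hi:
            raise ValueError(f"{self.gene}: position {gpos} outside transcript")
        for i, (s, e) in enumerate(self.exons):
            if s <= gpos < e:
                return self._exon_cdna_starts[i] + (gpos - s), 0
            if gpos < s:  # in intron between exon i-1 and i
                prev_e = self.exons[i - 1][1]
                d_prev = gpos - prev_e + 1          # +1 at first intron base
                d_next = gpos - s                   # negative
                if d_prev <= -d_next:
                    return self._exon_cdna_starts[i] - 1, d_prev
                return self._exon_cdna_starts[i], d_next
        raise AssertionError("unreachable")

    def cds_sequence(self, ref: str) -> str:
        return "".join(ref[s:e] for s, e in self.exons)


def _split_exons(cds_len: int, required_ends: tuple[int, ...]) -> list[int]:
    """cDNA end positions (1-based, inclusive) of successive exons."""
    ends: list[int] = []
    required = sorted(required_ends)
    cur = 0
    while cur < cds_len:
        nxt = cur + EXON_TARGET_LEN
        for b in required:
            if cur < b <= cur + int(EXON_TARGET_LEN * 1.5):
                nxt = b
                break
        nxt = min(nxt, cds_len)
        if cds_len - nxt < 30:  # avoid a trailing sliver exon
            nxt = cds_len
        ends.append(nxt)
        cur = nxt
    return ends


def _gene_rng(gene: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(gene.encode()) & 0x7FFFFFFF)


def _random_cds(gene: str) -> list[str]:
    rng = _gene_rng(gene)
    n_codons = CDS_LENGTHS[gene] // 3
    codons = ["ATG"]
    picks = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
    codons += [_NONSTOP_CODONS[i] for i in picks]
    codons.append("TAA")
    for g, idx, codon in CODON_PATCHES:
        if g == gene:
            codons[idx - 1] = codon
    return codons


@lru_cache(maxsize=1)
def build_reference() -> tuple[str, dict[str, ToyTranscript]]:
    """Build the synthetic contig and all 21 toy transcripts (cached).

    Deterministic: every random draw is seeded from the gene symbol, so the
    reference is identical across processes and runs.
    """
    pieces: list[str] = []
    transcripts: dict[str, ToyTranscript] = {}
    cursor = 0
    for gene in sorted(CDS_LENGTHS):
        rng = _gene_rng(gene)
        cds = "".join(_random_cds(gene))
        ends = _split_exons(CDS_LENGTHS[gene], REQUIRED_EXON_ENDS.get(gene, ()))

        flank = "".join(_BASES[i] for i in rng.integers(0, 4, size=FLANK_LEN))
        pieces.append(flank)
        cursor += FLANK_LEN

        exons: list[tuple[int, int]] = []
        prev = 0
        for k, end in enumerate(ends):
            exon_seq = cds[prev:end]
            exons.append((cursor, cursor + len(exon_seq)))
            pieces.append(exon_seq)
            cursor += len(exon_seq)
            if k < len(ends) - 1:
                mid = "".join(
                    _BASES[i] for i in rng.integers(0, 4, size=INTRON_LEN - 4)
                )
                intron = "GT" + mid + "AG"
                # apply intron patches anchored at this junction
                for g, anchor, off, bases in INTRON_PATCHES:
                    if g == gene and anchor in (end, end + 1):
                        if off > 0 and anchor == end:
                            i0 = off - 1
                            intron = intron[:i0] + bases + intron[i0 + len(bases):]
                        elif off < 0 and anchor == end + 1:
                            i0 = INTRON_LEN + off
                            intron = intron[:i0] + bases + intron[i0 + len(bases):]
                pieces.append(intron)
                cursor += INTRON_LEN
            prev = end

        pieces.append(
            "".join(_BASES[i] for i in rng.integers(0, 4, size=FLANK_LEN))
        )
        cursor += FLANK_LEN
        transcripts[gene] = ToyTranscript(
            gene=gene,
            tx_id=TRANSCRIPT_IDS[gene],
            exons=tuple(exons),
            cds_len=CDS_LENGTHS[gene],
        )
    return "".join(pieces), transcripts


def reference_sequence() -> str:
    return build_reference()[0]


def transcript_models() -> dict[str, ToyTranscript]:
    return build_reference()[1]
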