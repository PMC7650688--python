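"""The HAP v1.2 gene panel: gene list, target regions, membership queries.

The bundled default panel carries the 21 genes of the capture design with
target regions derived from the toy transcript models (full coding exons
padded by 25 bp). BED intervals are 0-based half-open; position queries are
1-based (VCF convention) and converted only here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from intervaltree import IntervalTree

from . import transcripts as _tx

#: Genes related to PAH with a higher level of evidence (intersected with
#: the panel); the remaining panel genes are carried as candidates.
ESTABLISHED_GENES = frozenset(
    {"BMPR2", "EIF2AK4", "TBX4", "GDF2", "ACVRL1", "SMAD9", "ENG", "KCNK3", "CAV1"}
)

#: Genes with autosomal-recessive disease mechanism on this panel (PVOD).
RECESSIVE_GENES = frozenset({"EIF2AK4"})

TARGET_PAD = 25


class PanelError(ValueError):
    """Malformed or inconsistent panel definition."""


@dataclass(frozen=True)
class PanelGene:
    symbol: str
    transcript: str
    evidence_tier: str = "candidate"   # established | candidate
    inheritance_hint: str = "AD"       # AD | AR | either

    def __post_init__(self):
        if not self.transcript.startswith("NM_"):
            raise PanelError(
                f"{self.symbol}: transcript {self.transcript!r} does not match NM_*"
            )
        if self.evidence_tier not in ("established", "candidate"):
            raise PanelError(f"bad evidence tier {self.evidence_tier!r}")
        if self.inheritance_hint not in ("AD", "AR", "either"):
            raise PanelError(f"bad inheritance hint {self.inheritance_hint!r}")


@dataclass(frozen=True)
class TargetRegion:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    gene: str
    label: str

    def __post_init__(self):
        if self.start >= self.end:
            raise PanelError(f"{self.label}: start {self.start} >= end {self.end}")

    def contains(self, chrom: str, pos1: int) -> bool:
        """Whether a 1-based position lies in this 0-based half-open region."""
        return chrom == self.chrom and self.start < pos1 <= self.end


@dataclass
class PanelDefinition:
    name: str
    genes: list[PanelGene]
    regions: list[TargetRegion]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        symbols = [g.symbol for g in self.genes]
        if len(symbols) != len(set(symbols)):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise PanelError(f"duplicate gene symbols: {dupes}")
        known = set(symbols)
        for r in self.regions:
            if r.gene not in known:
                raise PanelError(
                    f"region {r.label} names gene {r.gene!r} absent from gene list"
                )
        self.regions = sorted(self.regions, key=lambda r: (r.chrom, r.start))
        per_gene: dict[str, list[TargetRegion]] = {}
        for r in self.regions:
            per_gene.setdefault(r.gene, []).append(r)
        for gene, regs in per_gene.items():
            for a, b in zip(regs, regs[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise PanelError(f"overlapping targets within {gene}: {a.label}/{b.label}")
        for r in self.regions:
            self._trees.setdefault(r.chrom, IntervalTree())[r.start:r.end] = r

    @property
    def gene_symbols(self) -> set[str]:
        return {g.symbol for g in self.genes}

    def gene_info(self, symbol: str) -> PanelGene:
        for g in self.genes:
            if g.symbol == symbol:
                return g
        raise KeyError(symbol)

    def gene_at(self, chrom: str, pos: int) -> str | None:
        """Gene whose target contains the 1-based position, or None."""
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = tree[pos - 1]
        return next(iter(hits)).data.gene if hits else None

    def regions_for(self, gene: str) -> list[TargetRegion]:
        return [r for r in self.regions if r.gene == gene]


def load_panel(genes_file: str | Path, bed_file: str | Path,
               name: str = "custom") -> PanelDefinition:
    """Load a panel from a gene-metadata TSV and a BED of targets.

    The TSV needs columns symbol/transcript and optional evidence_tier,
    inheritance_hint; the BED needs chrom/start/end plus a 4th column
    ``GENE`` or ``GENE_label``.
    """
    genes_file, bed_file = Path(genes_file), Path(bed_file)
    genes: list[PanelGene] = []
    with open(genes_file) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for c in ("symbol", "transcript"):
            if c not in idx:
                raise PanelError(f"{genes_file}: missing column {c!r}")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            genes.append(PanelGene(
                symbol=f[idx["symbol"]],
                transcript=f[idx["transcript"]],
                evidence_tier=f[idx["evidence_tier"]] if "evidence_tier" in idx else "candidate",
                inheritance_hint=f[idx["inheritance_hint"]] if "inheritance_hint" in idx else "AD",
            ))
    regions: list[TargetRegion] = []
    with open(bed_file) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise PanelError(f"{bed_file}:{ln}: expected >=4 columns, got {len(f)}")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise PanelError(f"{bed_file}:{ln}: non-integer coordinate") from exc
            label = f[3]
            gene = label.split("_")[0]
            regions.append(TargetRegion(f[0], start, end, gene, label))
    return PanelDefinition(name=name, genes=genes, regions=regions)


def write_panel(panel: PanelDefinition, genes_file: str | Path,
                bed_file: str | Path) -> None:
    with open(genes_file, "w") as fh:
        fh.write("symbol\ttranscript\tevidence_tier\tinheritance_hint\n")
        for g in panel.genes:
            fh.write(f"{g.symbol}\t{g.transcript}\t{g.evidence_tier}\t{g.inheritance_hint}\n")
    with open(bed_file, "w") as fh:
        for r in panel.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


def default_panel() -> PanelDefinition:
    """The bundled HAP v1.2 panel: 21 genes, exon±25bp targets on panel_ref."""
    genes = []
    with resources.files("hap_panel.data").joinpath("panel_genes.tsv").open() as fh:
        next(fh)
        for line in fh:
            sym, tx, tier, hint = line.rstrip("\n").split("\t")
            genes.append(PanelGene(sym, tx, tier, hint))
    regions = []
    for gene, model in _tx.transcript_models().items():
        for k, (s, e) in enumerate(model.exons, start=1):
            regions.append(TargetRegion(
                _tx.CONTIG, s - TARGET_PAD, e + TARGET_PAD, gene, f"{gene}_ex{k}"
            ))
    return PanelDefinition(name="HAP v1.2", genes=genes, regions=regions)
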