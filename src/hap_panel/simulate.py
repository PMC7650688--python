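"""Synthetic cohorts with planted truth for every pipeline stage.

The generator emulates the shape of a national-registry panel cohort:
~300 samples of which ~11% fail the coverage gate, ~30% carry a reportable
variant, a handful of two-gene (digenic) carriers, biallelic cases in the
recessive PVOD gene (one founder-missense homozygote plus compound-
heterozygous trios), one single-exon duplication, and a background of
common/known and rare/novel coding SNVs drawn with the coding Ti/Tv odds
of a well-behaved capture run (3.2 known / 2.9 novel).

Everything is reproducible from (config, seed): outputs are plain text
(VCF, depth TSV, PED, snapshot TSVs, truth JSON).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import transcripts as _tx
from .annotate import CODON_TABLE, AnnotationSnapshots
from .panel import PanelDefinition, default_panel
from .paper_tables import hgvs_to_vcf
from .variants import VariantRecord, normalize_variant, parse_hgvs

TRANSITIONS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
TRANSVERSIONS = [("A", "C"), ("A", "T"), ("C", "A"), ("C", "G"),
                 ("G", "C"), ("G", "T"), ("T", "A"), ("T", "G")]

#: Founder missense variant planted for the homozygous PVOD case.
FOUNDER_VARIANT = "NM_001013703.3:c.3344C>T:p.(Pro1115Leu)"

PATHOGENIC_GENE_WEIGHTS = {
    "BMPR2": 0.45, "EIF2AK4": 0.15, "TBX4": 0.12, "ACVRL1": 0.12,
    "GDF2": 0.06, "ENG": 0.05, "KCNK3": 0.03, "CAV1": 0.02,
}
VUS_GENE_WEIGHTS = {
    "NOTCH3": 0.30, "ABCC8": 0.25, "CPS1": 0.12, "SMAD1": 0.07,
    "SMAD5": 0.06, "SARS2": 0.06, "KCNA5": 0.05, "TOPBP1": 0.05,
    "CBLN2": 0.04,
}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_samples: int = 300
    seed: int = 0
    qc_fail_fraction: float = 0.11
    carrier_fraction: float = 0.30
    pathogenic_fraction: float = 0.55   # of carriers; the rest are VUS-like
    per_gene_rate: Optional[dict] = None
    digenic_pairs: int = 5
    biallelic_cases: int = 3            # 1 founder homozygote + trios
    planted_cnvs: list = field(
        default_factory=lambda: [("BMPR2", "BMPR2_ex2", 1.5)])
    depth_mean: float = 300.0
    depth_dispersion: float = 2.0       # per-base negative-binomial size
    fail_target_fraction: float = 0.12  # targets depressed in QC-fail samples
    fail_depth_mean: float = 8.0
    titv_known_odds: float = 3.2
    titv_novel_odds: float = 2.9
    n_background_known: int = 40
    n_background_novel: int = 30

    def validate(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if self.n_samples < 1:
            raise SimulationError("n_samples must be positive")
        for name in ("qc_fail_fraction", "carrier_fraction",
                     "pathogenic_fraction", "fail_target_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0,1]")
        if self.digenic_pairs + self.biallelic_cases > self.n_samples:
            raise SimulationError("more planted cases than samples")


@dataclass
class TruthSet:
    planted_variants: list = field(default_factory=list)
    digenic: list = field(default_factory=list)
    biallelic: list = field(default_factory=list)
    cnvs: list = field(default_factory=list)
    qc_fail_samples: list = field(default_factory=list)
    cohort_samples: list = field(default_factory=list)
    parent_samples: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------- variants

def _derive_rng(rng: np.random.Generator) -> np.random.Generator:
    return np.random.default_rng(int(rng.integers(0, 2**31 - 1)))


def _weighted_gene(rng: np.random.Generator, weights: dict) -> str:
    genes = sorted(weights)
    p = np.array([weights[g] for g in genes], dtype=float)
    return genes[rng.choice(len(genes), p=p / p.sum())]


def _cds_positions(model: _tx.ToyTranscript, margin: int = 10):
    """cDNA positions safely interior to exons (codon edges respected)."""
    spans = []
    c = 1
    for s, e in model.exons:
        n = e - s
        lo, hi = c + margin, c + n - 1 - margin
        if hi > lo:
            spans.append((lo, hi))
        c += n
    return spans


def _random_interior_pos(rng, model, used: set, margin: int = 10) -> int:
    spans = _cds_positions(model, margin)
    for _ in range(200):
        lo, hi = spans[rng.integers(0, len(spans))]
        pos = int(rng.integers(lo, hi + 1))
        if 3 < pos < model.cds_len - 3 and pos not in used:
            used.add(pos)
            return pos
    raise SimulationError("could not find a free CDS position")


def _codon_context(model, cds, cpos):
    ci = (cpos - 1) // 3
    return ci, (cpos - 1) % 3, cds[ci * 3:ci * 3 + 3]


def _make_snv(rng, gene, model, cds, used, want: str) -> tuple[int, str, str]:
    """Find (cdna_pos, ref, alt) producing the wanted consequence."""
    for _ in range(500):
        cpos = _random_interior_pos(rng, model, used)
        _, within, codon = _codon_context(model, cds, cpos)
        ref = codon[within]
        alts = [b for b in "ACGT" if b != ref]
        rng.shuffle(alts)
        for alt in alts:
            new = codon[:within] + alt + codon[within + 1:]
            aa_ref, aa_alt = CODON_TABLE[codon], CODON_TABLE[new]
            if aa_ref == "*":
                break
            if want == "stop_gained" and aa_alt == "*":
                return cpos, ref, alt
            if want == "missense" and aa_alt not in ("*", aa_ref):
                return cpos, ref, alt
            if want == "synonymous" and aa_alt == aa_ref:
                return cpos, ref, alt
        used.discard(cpos)
    raise SimulationError(f"no {want} SNV found in {gene}")


def _make_titv_snv(rng, gene, model, cds, used, transition: bool):
    """A coding synonymous SNV of the requested Ti/Tv type."""
    pairs = TRANSITIONS if transition else TRANSVERSIONS
    for _ in range(2000):
        cpos = _random_interior_pos(rng, model, used)
        _, within, codon = _codon_context(model, cds, cpos)
        ref = codon[within]
        cands = [alt for r, alt in pairs if r == ref]
        rng.shuffle(cands)
        for alt in cands:
            new = codon[:within] + alt + codon[within + 1:]
            if CODON_TABLE[codon] != "*" and CODON_TABLE[new] == CODON_TABLE[codon]:
                return cpos, ref, alt
        used.discard(cpos)
    raise SimulationError("no synonymous SNV of requested type found")


@dataclass
class _Site:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    genotypes: dict  # sample -> alt allele count (1 or 2)

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


def write_vcf(path: str | Path, sites: Sequence[_Site], samples: Sequence[str],
              depth: int = 300, gq: int = 99) -> None:
    ref_len = len(_tx.reference_sequence())
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={_tx.CONTIG},length={ref_len}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for site in sorted(sites, key=lambda s: s.pos):
        gts = []
        for s in samples:
            n = site.genotypes.get(s, 0)
            gt = {0: "0/0", 1: "0/1", 2: "1/1"}[n]
            gts.append(f"{gt}:{gq}:{depth}")
        lines.append(
            f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\t"
            "GT:GQ:DP\t" + "\t".join(gts))
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------ depths

def simulate_depth_matrix(
    panel: PanelDefinition,
    samples: Sequence[str],
    rng: np.random.Generator,
    mean: float = 300.0,
    dispersion: float = 2.0,
    fail_samples: Sequence[str] = (),
    fail_target_fraction: float = 0.12,
    fail_depth_mean: float = 8.0,
    cnv_plants: Sequence[tuple[str, str, float]] = (),
):
    """Negative-binomial per-target depth with planted QC failures and CNVs.

    Per cell, total reads over the target are drawn NB (sum of per-base
    NB(mean, size=dispersion)) and divided by target length, on top of
    lognormal sample (library size) and target (capture bias) factors.
    """
    from .cnv import DepthMatrix

    targets = panel.regions
    n_t, n_s = len(targets), len(samples)
    sf = rng.lognormal(0.0, 0.15, size=n_s)
    tf = rng.lognormal(0.0, 0.20, size=n_t)
    lengths = np.array([t.end - t.start for t in targets])
    mu = mean * np.outer(tf, sf)

    fail_idx = {samples.index(s) for s in fail_samples}
    fail_targets: dict[int, np.ndarray] = {}
    for si in fail_idx:
        k = max(1, int(round(fail_target_fraction * n_t)))
        chosen = rng.choice(n_t, size=k, replace=False)
        fail_targets[si] = chosen
        mu[chosen, si] *= fail_depth_mean / mean

    label_to_idx = {t.label: i for i, t in enumerate(targets)}
    for sample, label, ratio in cnv_plants:
        mu[label_to_idx[label], samples.index(sample)] *= ratio

    n_param = lengths[:, None] * dispersion
    p_param = n_param / (n_param + lengths[:, None] * mu)
    counts = rng.negative_binomial(n_param, p_param)
    depth = counts / lengths[:, None]
    return DepthMatrix(list(targets), list(samples), depth)


def simulate_cnv_cohort(seed: int, n_samples: int = 24,
                        ratio: float = 1.5,
                        panel: Optional[PanelDefinition] = None):
    """One cohort with a single-target CNV planted in one sample.

    Returns (DepthMatrix, (sample, gene, label, kind)) for benchmarking the
    caller's sensitivity/false-positive behaviour.
    """
    panel = panel or default_panel()
    rng = np.random.default_rng(seed)
    samples = [f"C{j:03d}" for j in range(n_samples)]
    ti = int(rng.integers(0, len(panel.regions)))
    target = panel.regions[ti]
    sample = samples[int(rng.integers(0, n_samples))]
    dm = simulate_depth_matrix(
        panel, samples, rng, cnv_plants=[(sample, target.label, ratio)])
    kind = "gain" if ratio > 1 else "loss"
    return dm, (sample, target.gene, target.label, kind)


# ------------------------------------------------------------------- titv

def simulate_titv_records(n: int, odds: float, rng: np.random.Generator
                          ) -> list[VariantRecord]:
    """n coding SNV records with P(transition) = odds/(1+odds)."""
    records = []
    is_ti = rng.random(n) < odds / (1.0 + odds)
    ti_idx = rng.integers(0, len(TRANSITIONS), size=n)
    tv_idx = rng.integers(0, len(TRANSVERSIONS), size=n)
    for i in range(n):
        ref, alt = (TRANSITIONS[ti_idx[i]] if is_ti[i]
                    else TRANSVERSIONS[tv_idx[i]])
        records.append(VariantRecord(
            chrom=_tx.CONTIG, pos=i + 1, ref=ref, alt=alt, sample_id="SIM"))
    return records


# --------------------------------------------------------------- generate

@dataclass
class GeneratedCohort:
    outdir: Path
    vcf: Path
    depths_tsv: Path
    ped: Path
    snapshot_dir: Path
    truth: TruthSet
    etiologies: dict


def generate(config: SimulationConfig, outdir: str | Path) -> GeneratedCohort:
    """Write a full synthetic cohort (VCF, depths, PED, snapshots, truth)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    panel = default_panel()
    models = _tx.transcript_models()
    ref_seq = _tx.reference_sequence()
    cds_cache = {g: m.cds_sequence(ref_seq) for g, m in models.items()}
    used_pos: dict[str, set] = {g: set() for g in models}

    cohort = [f"S{j:04d}" for j in range(1, config.n_samples + 1)]
    truth = TruthSet(cohort_samples=list(cohort))

    n_fail = int(np.floor(config.n_samples * config.qc_fail_fraction))
    fail = sorted(rng.choice(cohort, size=n_fail, replace=False).tolist())
    truth.qc_fail_samples = fail
    passing = [s for s in cohort if s not in set(fail)]

    sites: list[_Site] = []
    snaps = AnnotationSnapshots()

    def plant(sample: str, gene: str, want: str, zyg: int = 1) -> _Site:
        model, cds = models[gene], cds_cache[gene]
        if want == "frameshift":
            cpos = _random_interior_pos(rng, model, used_pos[gene])
            g0 = model.cdna_to_genomic(cpos)
            pos, ref, alt = normalize_variant(
                _tx.CONTIG, g0, ref_seq[g0 - 1:g0 + 1], ref_seq[g0 - 1], ref_seq)
        else:
            cpos, r, a = _make_snv(rng, gene, model, cds, used_pos[gene], want)
            pos, ref, alt = model.cdna_to_genomic(cpos) + 1, r, a
        site = _Site(_tx.CONTIG, pos, ref, alt, gene, {sample: zyg})
        sites.append(site)
        if want == "missense":
            snaps.predictors[site.key] = (4, 10, 22.0)
        return site

    # --- carriers (single planted variant each)
    n_carriers = int(round(config.carrier_fraction * config.n_samples))
    special = config.digenic_pairs + config.biallelic_cases
    carriers = list(rng.choice(passing, size=min(n_carriers, len(passing)),
                               replace=False))
    if special > len(carriers):
        raise SimulationError(
            f"{special} digenic+biallelic cases exceed {len(carriers)} carriers")
    reserved = carriers[:special]
    plain = carriers[special:]
    n_path = int(round(config.pathogenic_fraction * len(plain)))
    for i, sample in enumerate(plain):
        if i < n_path:
            gene = _weighted_gene(rng, config.per_gene_rate
                                  or PATHOGENIC_GENE_WEIGHTS)
            want = "stop_gained" if rng.random() < 0.5 else "frameshift"
            site = plant(sample, gene, want)
            truth.planted_variants.append({
                "sample": sample, "gene": gene, "key": list(site.key),
                "intended_class": "P"})
        else:
            gene = _weighted_gene(rng, VUS_GENE_WEIGHTS)
            site = plant(sample, gene, "missense")
            truth.planted_variants.append({
                "sample": sample, "gene": gene, "key": list(site.key),
                "intended_class": "VUS"})

    # --- digenic pairs: pathogenic + second-gene VUS in one patient
    digenic_samples = reserved[:config.digenic_pairs]
    for sample in digenic_samples:
        g1 = _weighted_gene(rng, PATHOGENIC_GENE_WEIGHTS)
        s1 = plant(sample, g1, "stop_gained")
        g2 = g1
        while g2 == g1:
            g2 = _weighted_gene(rng, VUS_GENE_WEIGHTS)
        s2 = plant(sample, g2, "missense")
        truth.planted_variants.append({
            "sample": sample, "gene": g1, "key": list(s1.key),
            "intended_class": "P"})
        truth.planted_variants.append({
            "sample": sample, "gene": g2, "key": list(s2.key),
            "intended_class": "VUS"})
        truth.digenic.append({"sample": sample, "genes": sorted([g1, g2])})

    # --- biallelic PVOD cases
    biallelic_samples = reserved[config.digenic_pairs:special]
    ped_lines: list[str] = []
    for i, sample in enumerate(biallelic_samples):
        if i == 0:
            desc = parse_hgvs(FOUNDER_VARIANT)
            chrom, pos, ref, alt = hgvs_to_vcf(desc, "EIF2AK4")
            site = _Site(chrom, pos, ref, alt, "EIF2AK4", {sample: 2})
            sites.append(site)
            snaps.predictors[site.key] = (4, 10, 23.0)
            truth.biallelic.append({"sample": sample, "kind": "biallelic_hom"})
            ped_lines.append(f"FAM{i:02d} {sample} 0 0 0 2")
        else:
            fa, mo = f"F_{sample}", f"M_{sample}"
            truth.parent_samples += [fa, mo]
            s1 = plant(sample, "EIF2AK4", "stop_gained")
            s2 = plant(sample, "EIF2AK4", "stop_gained")
            s1.genotypes[fa] = 1
            s2.genotypes[mo] = 1
            truth.biallelic.append({"sample": sample, "kind": "compound_het"})
            ped_lines += [
                f"FAM{i:02d} {fa} 0 0 1 1",
                f"FAM{i:02d} {mo} 0 0 2 1",
                f"FAM{i:02d} {sample} {fa} {mo} 0 2",
            ]

    # --- background: common/known and rare/novel synonymous coding SNVs
    gene_list = sorted(models)
    p_ti_known = config.titv_known_odds / (1 + config.titv_known_odds)
    p_ti_novel = config.titv_novel_odds / (1 + config.titv_novel_odds)
    all_samples = cohort + truth.parent_samples
    for j in range(config.n_background_known):
        gene = gene_list[int(rng.integers(0, len(gene_list)))]
        cpos, ref, alt = _make_titv_snv(
            rng, gene, models[gene], cds_cache[gene], used_pos[gene],
            transition=bool(rng.random() < p_ti_known))
        pos = models[gene].cdna_to_genomic(cpos) + 1
        af = float(rng.uniform(0.05, 0.30))
        gts = {}
        draws = rng.binomial(2, af, size=len(cohort))
        for s, n in zip(cohort, draws):
            if n:
                gts[s] = int(n)
        site = _Site(_tx.CONTIG, pos, ref, alt, gene, gts)
        sites.append(site)
        snaps.known_sites[site.key] = f"rs{900000 + j}"
        snaps.frequencies.setdefault(site.key, {})["gnomad_exomes_like"] = af
        if rng.random() < 0.3:
            snaps.clinical[site.key] = "benign_reported"
    for j in range(config.n_background_novel):
        gene = gene_list[int(rng.integers(0, len(gene_list)))]
        cpos, ref, alt = _make_titv_snv(
            rng, gene, models[gene], cds_cache[gene], used_pos[gene],
            transition=bool(rng.random() < p_ti_novel))
        pos = models[gene].cdna_to_genomic(cpos) + 1
        k = int(rng.integers(1, 4))
        gts = {s: 1 for s in rng.choice(cohort, size=k, replace=False)}
        sites.append(_Site(_tx.CONTIG, pos, ref, alt, gene, gts))

    # --- CNV plants (QC-passing samples)
    cnv_assignments = []
    for gene, label, ratio in config.planted_cnvs:
        sample = passing[int(rng.integers(0, len(passing)))]
        cnv_assignments.append((sample, label, ratio))
        truth.cnvs.append({"sample": sample, "gene": gene, "label": label,
                           "ratio": ratio,
                           "kind": "gain" if ratio > 1 else "loss"})

    # --- outputs
    vcf_path = outdir / "cohort.vcf"
    write_vcf(vcf_path, sites, all_samples, depth=int(config.depth_mean))
    depths = simulate_depth_matrix(
        panel, all_samples, rng,
        mean=config.depth_mean, dispersion=config.depth_dispersion,
        fail_samples=fail,
        fail_target_fraction=config.fail_target_fraction,
        fail_depth_mean=config.fail_depth_mean,
        cnv_plants=cnv_assignments,
    )
    depths_path = outdir / "depths.tsv"
    depths.to_tsv(depths_path)
    ped_path = outdir / "families.ped"
    ped_path.write_text("\n".join(ped_lines) + "\n" if ped_lines else "")
    snap_dir = outdir / "snapshots"
    snaps.write(snap_dir)
    truth.to_json(outdir / "truth.json")

    etiologies = {s: "IPAH" for s in cohort}
    for b in truth.biallelic:
        etiologies[b["sample"]] = "PVOD"
    return GeneratedCohort(
        outdir=outdir, vcf=vcf_path, depths_tsv=depths_path, ped=ped_path,
        snapshot_dir=snap_dir, truth=truth, etiologies=etiologies,
    )


# --------------------------------------------------------------- recovery

def evaluate_recovery(result, truth: TruthSet) -> dict:
    """Planted-truth recovery of a pipeline run (QC-passing samples only)."""
    passing = result.passing_samples
    by_key = {}
    for r in result.candidates:
        by_key[(r.sample_id, r.key)] = r

    path_total = path_hit = 0
    for pv in truth.planted_variants:
        if pv["intended_class"] != "P" or pv["sample"] not in passing:
            continue
        path_total += 1
        rec = by_key.get((pv["sample"], tuple(pv["key"])))
        if rec is not None and rec.acmg_class in ("P", "LP"):
            path_hit += 1

    digenic_found = {f.patient_id for f in result.findings
                     if f.kind == "digenic_candidate"}
    dig_total = dig_hit = 0
    for d in truth.digenic:
        if d["sample"] not in passing:
            continue
        dig_total += 1
        if d["sample"] in digenic_found:
            dig_hit += 1

    qc_failed = {r.sample_id for r in result.qc_reports if not r.passed}
    return {
        "pathogenic_total": path_total,
        "pathogenic_recovered": path_hit,
        "pathogenic_recovery": path_hit / path_total if path_total else None,
        "digenic_total": dig_total,
        "digenic_recovered": dig_hit,
        "digenic_recovery": dig_hit / dig_total if dig_total else None,
        "qc_failed_observed": len(qc_failed),
        "qc_failed_intended": len(truth.qc_fail_samples),
        "qc_fail_agreement": set(truth.qc_fail_samples) == qc_failed,
    }
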