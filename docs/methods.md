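# Methods

This note documents the models, conventions and design choices behind
hap-panel: what each stage assumes, which knobs matter, what the
synthetic data do and do not emulate, and where the known limitations
are.

## Coordinates and reference

Genomic intervals are 0-based half-open (BED convention); VCF and query
positions are 1-based. Conversion happens only at module boundaries
(`panel`, `variants`), never inside stage logic.

No public capture design or patient-level coordinates exist for the
panel, so the package carries a deterministic synthetic reference
(`panel_ref`, ~180 kb): one toy plus-strand transcript per gene, coding
exons of ~160 bp separated by 300 bp introns with canonical GT..AG
dinucleotides, CDS lengths matching the real protein sizes so every
cDNA position referenced by the bundled tables exists. Codons at fixture
positions are patched so that the printed reference alleles and protein
effects hold on the toy sequence (e.g. codon 340 of *TBX4* is CGA so
c.1018C>T creates the printed p.(Arg340\*) stop), and exon boundaries are
forced where the tables name intronic positions (c.77−5, c.579+5,
c.2694+1). The reference is rebuilt identically in every process from
per-gene seeds; nothing binary is stored.

Consequence of this design: the pipeline's logic is exercised on real
coordinates arithmetic (splice offsets, codon frames, left-alignment in
homopolymers), but the genomic positions themselves are synthetic, and
nothing here can be lifted onto a real genome build.

## Variant representation

The HGVS-style parser covers the descriptor subset that appears in
clinical panel tables — substitutions, deletions, duplications,
insertions and delins, with intronic ±offsets and position ranges, and
tolerant of the layout quirks those tables actually contain (unversioned
accessions, `exonNN` tokens, parenthesized gene names, spaces after
colons). It is deliberately not a full HGVS grammar (no inversions,
mosaicism, or uncertain breakpoints). Protein descriptors are carried as
validated opaque strings; only the consequence caller recomputes effects,
and only on the toy transcripts.

VCF input is decomposed to one record per sample × alternate allele and
left-aligned by shift-until-fixed-point against the reference; the test
suite checks this against an exhaustive-search normal form. All
annotation lookups key on the normalized `(chrom, pos, ref, alt)`.

## Sample QC

Metrics: fraction of target bases at ≥20× (the gate, threshold 0.95),
capture efficiency (on-target fraction, default floor 0.70), uniformity
(bases within 0.2–2× of the sample mean), known/novel Ti/Tv, known-site
fraction and het/hom ratio. Library complexity (duplicate fraction) and
raw error rate are accepted and reported but never gate — no published
rule exists for them. The Ti/Tv band ([2.0, 4.5] for known sites) only
gates samples with ≥50 known-site SNVs: the ratio is an unstable
estimate below that, and a small panel yields few variants per sample.
Coverage accepts either per-base depth vectors or per-target means
weighted by target length; the two agree exactly when depth is constant
within a target, which is also how the simulator generates data.

## Annotation and consequence

Annotation is snapshot-based: plain TSV tables for population
frequencies (per source; popmax is the maximum, absence means "never
observed"), predictor tallies (deleterious / total, CADD-like score),
clinical assertions and known-site IDs. There are no live queries, so
annotation is pure and reproducible. Conflicting clinical assertions are
exposed as `conflicting`, not resolved.

Consequence precedence: stop_gained > frameshift > splice_canonical >
splice_region > codon comparison. A variant is splice_canonical only
when it lies entirely within the ±1/±2 intron positions; anything
touching ±3..±8 (or the last 3 exonic bases of a non-terminal exon) is
splice_region. This matters for the fixture's intronic deletion spanning
−5..−2, which is called splice_region — the conservative choice, since a
four-base intronic deletion reaching −2 plausibly but not certainly
disrupts the acceptor.

## Prioritization

Stage order: quality → frequency → panel gene → consequence. Quality
failures (DP < 10 or GQ < 30) never drop a variant; a surviving
low-quality variant is `candidate_needs_confirmation` (i.e. requires
Sanger confirmation). The frequency filter (popmax > 10⁻³ drops) and the
consequence filter (synonymous and deep-intronic drop) are both rescued
by a prior pathogenic clinical assertion, so known founder variants
cannot be lost to population drift or annotation edge cases. The
specific thresholds are reconstructions of common practice — the
original filter figure does not legibly state them — and all are
configuration, logged in each variant's filter trace.

## ACMG engine

`combine_evidence` implements the 2015 criteria-combining table over
effective strengths (overrides allowed, e.g. PVS1 demoted to strong).
Contradictory evidence — any pathogenic-side code together with any
benign-side code — defaults to VUS before the combining rules run. The
engine is verified exhaustively against an independently transcribed
enumeration oracle on all evidence subsets of size ≤ 4 (24,158 sets).

`default_evidence` maps annotations to codes deterministically:

| code | rule | default |
|------|------|---------|
| PVS1 | truncating consequence in an established LOF gene | — |
| PM2 | popmax absent or < `pm2_max_af` | 10⁻⁴ |
| PP3 / BP4 | predictor consensus ≥ 0.5 / ≤ 0.2, ≥3 predictors | — |
| PP5 / BP6 | prior clinical assertion | — |
| BA1 / BS1 | popmax > 0.05 / > 10⁻³ | — |
| PP1 | segregation support supplied | — |

`pm2_max_af` is 10⁻⁴ rather than the stricter 10⁻⁵ some labs use: the
panel's exemplar nonsense variant sits at popmax 2.81×10⁻⁵ and is
"extremely low frequency" by the source's own reading; both values are
defensible and the threshold is plain configuration. "Established" vs
"candidate" gene tiers follow the higher-evidence gene list intersected
with the panel (9 of 21 genes).

The classifications printed in the source tables were backed by the
authors' review of clinical databases; the fixture snapshot therefore
asserts `pathogenic_reported` for the rows printed P. With it, truncating
variants in established genes combine PVS1+PM2+PP5 → Pathogenic, which
reproduces every P-printed truncating row. Four rows do not reproduce
and are asserted as the expected mismatch set in the tests: the intronic
−5..−2 deletion (printed P, called splice_region → VUS), one missense
printed LP (defaults give VUS; no automatic rule yields LP for it), the
*GDF2* nonsense printed VUS in its table but called pathogenic in the
running text (the engine sides with the text: LP), and the founder
missense printed P on functional/founder evidence the engine cannot see.
Copy-number calls never enter the engine; they carry class `N/A`.

## CNV caller

The published pipeline used an in-house depth-ratio tool whose algorithm
is not described; the caller here is a standard panel-CNV design with
declared semantics. Normalization divides each cell by its sample's
median target depth (library size), then by the target's across-sample
median (capture bias), so diploid cells sit at ratio ≈ 1. Per target,
z-scores use median and 1.4826·MAD (robust to the event itself inflating
the scale); calls need ratio ≥ 1.35 (gain) or ≤ 0.65 (loss) *and*
|z| ≥ 2.5; adjacent called targets of one gene merge per sample. With
fewer than 8 reference samples, calls are emitted but marked
low-confidence. Whole-cohort background is used rather than a matched
reference subset. A consequence of median-based library-size correction:
an event spanning the majority of all targets of the panel would be
absorbed as library size — irrelevant at single-gene scale on a 21-gene
design, but a real limit for tiny panels.

## Inheritance

Digenic candidacy: candidate variants (P/LP/VUS — the VUS tier is
included because published digenic families pair a P with a VUS) in ≥2
distinct genes in one patient; depth-level CNV calls count as candidates
in their gene. Compound-heterozygote phasing enumerates parental
transmissions: trans only when every consistent transmission splits the
two variants across the parents; both-from-one-parent is cis
(`single_het`); both phases possible is `untested`; no consistent
transmission is `inconsistent`. Verified exhaustively against an
independent enumeration over all trio genotype combinations.
Segregation checks are Mendelian-compatibility only; unaffected carriers
generate a reduced-penetrance note, never an inconsistency, reflecting
the ~20% penetrance of the major PAH gene.

## Synthetic cohorts

The generator emulates the cohort shape of a national-registry panel
study: 300 samples, QC-failure fraction 0.11 (intended failures =
⌊n·fraction⌋ = 33), carrier fraction 0.30 of which 55% carry a planted
truncating variant in an established gene (classifying P by
construction) and the rest a rare missense with a deliberately mixed
predictor vote (4/10 — classifying VUS by construction, mirroring the
study's VUS burden without asserting its exact value), 5 digenic pairs,
3 biallelic PVOD cases (one homozygote for the founder missense
c.3344C>T, plus compound-het trios whose parents are extra VCF samples
each carrying one allele), and one single-exon duplication at ratio 1.5.

Depth: per-target read counts are negative-binomial (the sum over the
target length of per-base NB with mean 300 and size 2), on lognormal
sample (σ=0.15) and target (σ=0.20) factors; mean per-target depth has
CV ≈ 6%, a realistic value for a small capture design. QC failures are
planted by depressing 12% of a sample's targets to mean depth 8, which
puts the sample's ≥20× fraction far below the 0.95 gate with negligible
chance of crossing back. Background variation: common known synonymous
SNVs (AF 0.05–0.30, dropped by the frequency filter) and rare novel
synonymous SNVs (dropped by the consequence filter), drawn with
transition odds 3.2 (known) and 2.9 (novel).

What the simulation does *not* emulate: read-level artifacts (mapping
error, strand bias, duplicates), allele-fraction noise in genotypes,
population structure, relatedness outside the planted trios, and any
realistic site-frequency spectrum. Passing the recovery tests therefore
shows the interpretation logic is correct, not that the pipeline is
robust to raw-sequencing pathology.

## Numerical and edge-case conventions

Ti/Tv with zero transversions is undefined (`None`), not infinity.
Ratios and fractions always travel with numerator and denominator
because patient-level and variant-level denominators differ. Degenerate
zero-variance CNV targets are skipped with a warning; samples with zero
median depth are excluded from normalization with a warning; fewer than
two usable samples is an error. Empty target sets, empty cohorts and
header-only tables are defined results, not crashes. The digenic count
for the fixture is reported as the raw fraction (5 of the analyzed
patients) rather than any rounded percentage.

## Problem sizes used by the checks

The acceptance script runs the fixture pipeline (26 patients, 32
records), the exhaustive ACMG comparison (24,158 subsets), Ti/Tv at
n = 10,000 per stratum, 50 simulated 24-sample CNV cohorts, the full
256-combination trio phase enumeration, and one 300-sample end-to-end
cohort — a few seconds in total on one core.
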