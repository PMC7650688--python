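# hap-panel

Interpretation pipeline for a customized 21-gene massively parallel
sequencing panel used in the molecular diagnosis of pulmonary arterial
hypertension (PAH). The package is aimed at people who analyze targeted
capture panels in a clinical-genetics setting and want every step of the
interpretation — sample QC, annotation, variant prioritization, ACMG
classification, read-depth CNV calling, inheritance-pattern detection and
cohort reporting — as auditable, configurable, offline-testable code.

## What it implements

The panel (HAP v1.2) covers 21 genes implicated in PAH: *ABCC8*, *ACVRL1*,
*BMPR1B*, *BMPR2*, *CAV1*, *CBLN2*, *CPS1*, *EIF2AK4*, *ENG*, *GDF2*,
*KCNA5*, *KCNK3*, *MMACHC*, *NOTCH3*, *SARS2*, *SMAD1*, *SMAD4*, *SMAD5*,
*SMAD9*, *TBX4* and *TOPBP1*. The pipeline stages are:

- **Sample QC** — coverage distribution (gate: ≥95% of target bases at
  ≥20×), capture efficiency, uniformity, and coding Ti/Tv stratified by
  known/novel sites (typical values ≈3.2 and ≈2.9).
- **Annotation** — offline snapshot tables emulating population
  frequencies (popmax = max over sources; absence means "not observed"),
  in-silico predictor tallies, and clinical-database assertions, plus
  consequence calling on bundled transcript models.
- **Prioritization** — quality (DP ≥ 10, GQ ≥ 30; failures are flagged for
  orthogonal confirmation, never silently dropped) → population frequency
  (popmax ≤ 10⁻³, with rescue by prior pathogenic assertions) → panel
  membership → consequence, with a per-variant filter trace.
- **ACMG classification** — the evidence codes (PVS1, PS1–4, PM1–6, PP1–5,
  BA1, BS1–4, BP1–7) combined by the published criteria-combining rules
  into Pathogenic / Likely pathogenic / VUS / Likely benign / Benign;
  contradictory evidence defaults to VUS; every threshold of the default
  annotation→code mapping is explicit configuration.
- **CNV calling** — cross-sample read-depth analysis on capture targets:
  two-stage median normalization (library size, then per-target bias),
  robust z-scores, dual ratio/z thresholds (gain ≥ 1.35, loss ≤ 0.65,
  |z| ≥ 2.5), adjacent targets merged per gene. Calls carry the
  classification `N/A` — they bypass the small-variant ACMG engine.
- **Inheritance** — digenic co-occurrence (candidate variants in ≥2 genes
  in one patient), biallelic events in the recessive PVOD gene *EIF2AK4*
  (homozygous founder variant and compound heterozygotes phased through
  trio genotypes), and pedigree segregation checks in which unaffected
  carriers are noted as reduced penetrance, never as inconsistency.
- **Cohort reporting** — per-gene / per-etiology / per-class tallies with
  raw fractions next to every percentage, and the hemodynamic
  precapillary-PH eligibility triad (mPAP ≥ 25 mmHg, PAWP ≤ 15 mmHg,
  PVR > 3 WU).

Because no patient-level sequence data are public, the package bundles
two kinds of inputs: (a) a fixture transcribing the published variant
tables (digenic families, *ABCC8* carriers, associated-PAH forms, and the
*EIF2AK4* biallelic cases) projected onto a deterministic synthetic
reference, and (b) a synthetic-cohort generator that plants truth
(pathogenic variants, digenic pairs, biallelic trios, a single-exon
duplication, QC failures) at the cohort shape of the study (~300 samples,
~11% QC failures, ~30% carriers).

## Worked example

Running the full pipeline over the bundled table fixture:

```python
from hap_panel.pipeline import run_fixture_pipeline
from hap_panel.report import render_figure2_tables

fixture, candidates, traces, findings, summary = run_fixture_pipeline()
digenic = [f for f in findings if f.kind == "digenic_candidate"]
print(f"digenic families: {len(digenic)} "
      f"({', '.join(f.patient_id for f in digenic)})")
print(f"ABCC8 variants: {summary.per_gene['ABCC8']} "
      f"({summary.per_gene_etiology[('ABCC8', 'IPAH')]} in IPAH)")
_, per_gene = render_figure2_tables(summary)
print(per_gene.head(5).to_string(index=False))
```

prints

```
digenic families: 5 (HTP070, HTP081, HTP466, HTP474, HTP611)
ABCC8 variants: 9 (7 in IPAH)
   gene  p_lp  vus  total
EIF2AK4     4    1      5
  BMPR2     2    1      3
   TBX4     2    0      2
   GDF2     1    0      1
  ABCC8     0    9      9
```

i.e. five unrelated patients carry candidate variants in two genes (one
of them a *BMPR2* exon-2 duplication found by the CNV caller rather than
the small-variant path), nine *ABCC8* variants of which seven are in
idiopathic PAH, and a per-gene tally in which truncating variants in the
established genes classify P/LP while the missense burden (*ABCC8*,
*NOTCH3*) stays VUS.

The same stages run from the shell:

```sh
hap simulate --seed 7 --n-samples 300 --out simdir/
hap report --vcf simdir/cohort.vcf --depths simdir/depths.tsv \
           --snapshots simdir/snapshots --ped simdir/families.ped --out summary/
hap variants parse "NM_018488.3:c.1018C>T:p.(Arg340*)"
```

## Layout

```
src/hap_panel/
  panel.py         gene list, target regions, membership queries
  transcripts.py   synthetic reference + toy transcript models
  variants.py      HGVS-subset parser, VCF input, normalization, reports
  qc.py            coverage/Ti/Tv metrics and the sample gate
  annotate.py      snapshot annotation + consequence calling
  prioritize.py    the filter cascade with per-variant traces
  acmg.py          evidence algebra and combining rules
  cnv.py           depth normalization and CNV calling
  family.py        pedigrees, digenic/biallelic detection, segregation
  report.py        cohort summaries and eligibility checks
  simulate.py      synthetic cohorts with planted truth
  paper_tables.py  the transcribed worked-example tables
  pipeline.py      end-to-end orchestration
  cli.py           the `hap` command
docs/methods.md    models, assumptions, parameter choices, limitations
```
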