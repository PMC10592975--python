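# snordtarget

Downstream inference for orphan C/D-box snoRNA target studies:
consensus differential expression across isogenic deletion models and
enrichment of predicted snoRNA targeting on the resulting gene list.

## The problem

The Prader-Willi locus at chr15q11-q13 contains two tandem arrays of
*orphan* C/D box snoRNAs — 30 copies of SNORD116 (groups I, II, III)
and 48 copies of SNORD115 — whose loss is central to Prader-Willi
syndrome, yet whose RNA targets are unknown. A rigorous way to look
for those targets is to engineer isogenic deletions (smDEL: the
SNORD116 cluster alone; lgDEL: SNRPN promoter through SNORD116) in two
genetic backgrounds (H9, CT2), derive neurons, and ask which genes are
*consistently* dysregulated — then test whether that consensus list is
preferentially targeted by sliding-window RNA–RNA interaction
predictions for SNORD116.

This package implements every statistical step of that downstream
analysis as a tested, reusable library with a synthetic-data generator
that plants known structure, so each stage can be validated end to end
without sequencing data:

- **`consensus`** — low-count filtering, shared-DEG calling across
  backgrounds (padj < 0.05 with concordant direction), the
  three-design consensus, cross-model intersection (the "shared gene
  list"), and pseudocount locus log2 fold changes.
- **`resampling`** — permutation nulls for k-way gene-list overlaps:
  observed `|∩ lists|` vs redraws of the same sizes from the universe,
  fold = observed / mean(null), add-one empirical
  p = (1 + #{null ≥ obs}) / (n_perm + 1).
- **`ora`** — hypergeometric over-representation with BH adjustment and
  foldEnrichment = GeneRatio / BgRatio.
- **`interactions`** — consolidation of sliding-window predictions into
  binding events: runs of ≥ w consecutive windows (1-nt co-linear steps
  on both molecules, antiparallel duplex) all scoring ≥ t, default
  t = 0.98, w = 3; per-copy and per-group event counts.
- **`enrichment`** — control gene lists rejection-sampled until
  indistinguishable from the target list (two-sided Wilcoxon rank-sum
  p > 0.05 on merged-exonic length, GC, neuron CPM), then enrichment of
  the mean / median / sum of per-gene event counts against that matched
  null; SNORD116-vs-SNORD115 family contrast.
- **`coverage`** — per-base feature composition (5'UTR / 3'UTR / CDS /
  other exon / intron / splice-junction ± 2 nt) of a gene set over
  TSL 1–3 basic transcripts, vs per-event composition of binding events.
- **`position`** — binding-event centers relative to snoRNA copy length
  and to the C / D' / C' / D boxes and the ASE2 antisense element.
- **`simulate`** — generators for all inputs (GTF, counts + sample
  sheet, DESeq2-style result tables, snoGloBe-style window tables) with
  planted DEGs, a configurable targeting-enrichment fold, 5'UTR
  placement bias and group-III ASE2 bias, plus a deterministic model of
  the PWS locus.

## Worked example

The `analysis/` scripts run the whole study on synthetic data
(seed-deterministic, ~1 minute total):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_consensus_degs.py
python analysis/03_filter_windows.py
python analysis/04_targeting_enrichment.py
python analysis/05_feature_coverage.py
python analysis/06_sno_positions.py
python analysis/07_ora.py
```

Selected output (seeds as committed):

```
lgDEL: shared up 70, down 70
cross-model shared genes: 80 (planted: 80, recovered exactly: True)
cross-model overlap fold 8.2, p = 0.0001

20977 windows -> 3333 merged binding events

group-III targeting mean: observed 0.23, fold 2.32, p = 0.0099
group-III targeting sum:  observed 18.00, fold 2.32, p = 0.0099
77/80 shared genes have >= 1 predicted event

      utr5          0.3889               0.0135           28.8612   # event vs background fraction

group III: ase2 0.82, C 0.02, C' 0.01, D/D' 0.00, other 0.14  (n=219)
SNORD115:  ase2 0.23, C 0.05, C' 0.11, D/D' 0.06, other 0.55  (n=2042)
```

Reading this: the consensus machinery recovers the 80 planted
cross-model genes exactly, and their overlap across models is 8-fold
above the permutation null. The generator plants a 2.5-fold
targeting-enrichment on those genes; the matched-null analysis recovers
fold ≈ 2.3 with empirical p ≈ 0.01. The planted 5'UTR placement bias
appears as a ~29× utr5 enrichment ratio, and group-III snoRNA-side
event centers concentrate in ASE2 (82%) while the SNORD115 control
family sits near the uniform expectation (~23% for an element covering
~a fifth of the copy).

The same operations are exposed as a CLI
(`snordtarget simulate|consensus|overlap-test|ora|filter-windows|enrich|coverage|position|run-all`);
`snordtarget run-all --seed 0 --outdir out/` runs every stage and
writes a manifest with SHA-256 hashes of all outputs (byte-identical
across runs with the same config).

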