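# Methods

This note documents the statistical procedures, the synthetic-data
model behind the test suite, and the numerical and design choices made
where the underlying analysis convention was genuinely open.

## Consensus differential expression

Inputs are DESeq2-style per-contrast result tables (gene, baseMean,
log2FoldChange, pvalue, BH-adjusted padj); the package consumes these
tables and never refits count models. Three operations build the
consensus:

1. **Shared DEGs across backgrounds.** A gene is shared-up for a
   deletion model when padj < α (default 0.05) with log2FC > 0 in
   *both* genetic backgrounds; shared-down analogously. Genes
   significant everywhere but with discordant signs are excluded from
   both sets — direction consistency is required because a gene that
   flips sign between isogenic pairs is not a reproducible
   deletion effect. Tables with different gene universes are
   intersected first (recorded in the result's provenance).
2. **Three-design consensus.** Genes with padj < α in all three
   model formulations fit per comparison (a per-pair
   background-condition design, a pooled condition design, and a
   background × condition interaction design).
3. **Cross-model intersection.** The consensus sets of the two
   deletion models are intersected to give the shared gene list. The
   upstream study applies an additional, not fully specified filter
   between the three-design consensus and the intersected lists; the
   pipeline therefore exposes both stages explicitly and labels
   outputs by stage rather than guessing the missing filter.

Low-count filtering retains genes whose mean count across all samples
is ≥ `min_mean` (1 by default; a total-count cutoff of 39 in a
39-sample design is the identical rule). Locus fold changes are
log2((mean_A + c)/(mean_B + c)) with pseudocount c = 1 so genes inside
an engineered deletion (zero counts in one group) remain finite;
counts are CPM-normalized per sample first. CPM is used rather than
median-of-ratios: the fitting machinery that owns size-factor
estimation is upstream of this package, and CPM preserves the
qualitative contract (depth-invariance) the fold changes need.

## Permutation overlap test

For k gene lists within a universe of size N, the observed statistic
is |∩ lists|. Each of `n_perm` (default 10,000) permutations redraws
all k lists jointly, uniformly without replacement at the original
sizes, and records the intersection size. Fold = observed / mean(null)
(fold 0 when the null mean is 0), and the empirical p uses the add-one
rule p = (1 + #{null ≥ obs}) / (n_perm + 1), which is never 0 and can
reach 1. The joint redraw is the default because one enrichment value
is reported per intersection; a pairwise mode (minimum pairwise
overlap) is available behind a flag. For k = 2 the null mean has the
closed form s1·s2/N, which the tests verify by exhaustive enumeration
on universes ≤ 14.

## Over-representation analysis

One-sided (upper-tail) hypergeometric p per term, BH across terms,
foldEnrichment = GeneRatio/BgRatio = (k/n)/(K/N), results ordered by
padj then descending foldEnrichment. Zero-overlap terms are reported
with p = 1 and fold 0; terms with < 2 in-universe genes are skipped as
degenerate. Term databases are supplied by the user (two-column TSV or
GMT); no ontology content ships with the package.

## Window merging

Sliding-window interaction predictions score an L-nt snoRNA window
against an L-nt target window; L is read from the input, never
hard-coded (the generator's default L = 13 follows the prediction
tool's convention — the window geometry is a documented default, not a
reported fact). A binding event is a maximal run of ≥ w windows, all
scoring ≥ t, whose target starts advance by exactly 1 nt and whose
snoRNA starts step 1 nt in the duplex-consistent direction: the
snoRNA:target duplex is antiparallel, so on a `+`-strand target the
snoRNA coordinate decreases as the genomic target coordinate
increases, and increases on a `-`-strand target. A target-only mode
ignores the snoRNA side for inputs that do not carry it. Event spans
run from first window start to last start + L on both molecules; with
the merge flag, events of the same copy overlapping on the target are
unioned (idempotent). Event scores are summarized as both min and mean
since neither summary is canonical. Defaults t = 0.98, w = 3 mirror
the upstream prediction-filter settings.

## Covariate-matched targeting enrichment

Per-gene covariates are merged-exonic length (nt), GC fraction of the
merged-exonic sequence, and mean neuron CPM — operationalizations
chosen because they are the simplest quantities consistent with
"length, GC content, and expression". Control lists are drawn
uniformly without replacement from universe ∖ target (targets are
excluded so a control cannot trivially match by containing the
targets) and accepted iff all three two-sided Wilcoxon rank-sum tests
against the target list give p > α_match (0.05; "not significantly
different" quantified as the conventional level). Sampling stops at
`n_lists` accepted lists (default 100) or fails loudly after
`max_tries` with the most-rejecting covariate named. Accepted lists
are re-testable post hoc; no between-list disjointness screen is
applied. Enrichment of the mean, median and sum of per-gene event
counts on the target list is scored against the same statistic on each
control list with fold = observed/mean(null) and the add-one p. The
median can sit at 0 when per-gene counts are sparse (its fold is then
0 with p = 1); the sum and mean are the informative statistics at low
event rates.

## Feature coverage

Transcripts are restricted to support level 1–3 with the basic tag
(TSL "NA" counts as missing and is excluded). Background composition
assigns every base under the union of a gene's filtered transcripts a
single category with priority junction > 5'UTR > 3'UTR > CDS >
other-exon > intron, where a junction is the ±J nt neighborhood of
each splice site (J = 2 by default; the junction
operationalization is a declared parameter since no standard width
exists). GENCODE-style side-agnostic UTR records are split into 5'/3'
relative to the CDS span and strand. Events receive one category each
by the same priority over the bases they overlap, so an event touching
an exon-intron boundary is junctional. The two compositions
deliberately use different denominators (bases vs events), as in
coverage-donut figures; consequently the event distribution does not
converge numerically to the background distribution even without
placement bias, and the tests check bias recovery (ratio direction)
rather than distributional equality.

## snoRNA positions

The center of an event's snoRNA-side span (left-of-middle for
even-length spans — a documented tie-break) is divided by copy length
to give a relative position in [0, 1]; box intervals are scaled the
same way, and per-group histograms use a fixed 0.01 bin width. Region
fractions count centers in ASE2, C, C', D/D' (pooled) and elsewhere,
in copy coordinates, summing to 1 exactly; an empty event set is an
error rather than silent zeros. ASE2 is modeled as the 15 nt
immediately 5' of the D' box: antisense elements abut their box on
the 5' side by C/D-box architecture, and 15 nt is a typical guide
length (configurable; no standard width exists). A motif scanner
(C: RUGAUGA near the 5' end; D/D': CUGA; C': one-mismatch RUGAUGA)
proposes boxes for user-supplied copies; curated fixture boxes always
take precedence.

## The locus model

`build_locus_fixture()` returns a deterministic synthetic model of the
imprinted snoRNA cluster: 30 SNORD116 copies (groups I = copies 1–9,
II = 10–24, III = 25–30), 48 SNORD115 copies, the flanking genes
(MKRN3, MAGEL2, NDN, SNURF, SNRPN, IPW, UBE3A) in their real relative
order, and smDEL / lgDEL deletion intervals (smDEL covers exactly the
SNORD116 array; lgDEL extends from the SNRPN promoter region through
the array). Coordinates live on a pseudo-chromosome and copy sequences
are generated with the canonical box motifs planted (and spurious
motif matches scrubbed), so the fixture exercises every coordinate
path without any genome download; it is explicitly *not* hg38 and the
sequences are not the real snoRNA sequences.

## The synthetic cohort

The generator emulates the study's structure at desk scale; all
outputs are pure functions of the config seed (independent named RNG
streams per artifact).

- **Annotation**: 2000 genes by default on pseudo-chromosomes, 1–3
  transcripts each (first transcript always TSL 1–3 + basic so every
  gene survives the confidence filter), 70% coding with CDS/UTR
  records, both strands; per-gene GC drawn from a Beta(8, 10)
  (mean ≈ 0.44, a realistic transcriptome-wide spread).
- **Counts**: negative binomial with log-normal baseline means
  (median ≈ 200) and log-normal gene-wise dispersions (median 0.05,
  typical for isogenic cell-line RNA-seq); design = {H9, CT2} ×
  {WT, smDEL, lgDEL} × {ESC, neuron} × 3 replicates. Planted DEGs
  multiply the neuron-lineage mean by 2^±2 in the affected cells:
  shared genes (both backgrounds, both models — the cross-model truth,
  40 up + 40 down by default), model-specific genes (60 per model),
  and background-specific genes (30, one background only). The
  planted-set sizes echo the scale of the study's consensus lists
  while keeping every null estimate well-sampled at 2000 genes.
- **DE tables**: synthesized directly from the planted truth ("oracle
  mode"): affected genes get p ≈ 1e-8·U with the planted sign, null
  genes uniform p, BH within each table. Genes affected in one
  background are significant only in that background's table and the
  combined background-condition table (diluted elsewhere). Count-model
  fitting is deliberately bypassed — it is upstream of this package —
  which is what makes exact truth-recovery assertions possible.
- **Windows**: stray sub-threshold windows (score U[0.5, 0.98)) at
  0.05 per copy-gene pair, plus planted events — runs of 3 + Poisson(1)
  consecutive windows scoring U[0.98, 1] — at 0.02 events per
  copy-gene pair, multiplied by the targeting-enrichment fold (default
  2.5, the effect size the pipeline is designed to detect) on the
  target set. Event placement is 5'UTR-biased with odds weight 3 and,
  for group-III copies, ASE2-centered with odds weight 4 on the
  snoRNA side.

What the generator does *not* emulate: real GC/length/expression
correlations with targeting (covariates are independent of event
placement, so matched-null calibration is tested under the easiest
matching regime), DESeq2's shrinkage and dispersion estimation, hg38
gene structure, alternative-promoter complexity, and read-level noise.
Passing tests therefore demonstrate correctness of the downstream
statistics under their stated assumptions, not robustness of the
upstream DE fitting.

## Numerical choices and problem sizes

- Internal coordinates 0-based half-open everywhere; GTF converted at
  the boundary (1-based closed on disk), BED written natively.
  Feature assignment uses the target gene's own strand (events carry
  it); antisense overlap is out of scope.
- Every stochastic stage takes an explicit seed; the pipeline derives
  per-stage seeds from one master seed via named streams, and
  `run_all` output (including its SHA-256 manifest) is byte-identical
  across runs.
- Calibration suites use 500 replicates (overlap test; universe 1000,
  lists of 150, 499 permutations) and 200 replicates (targeting
  enrichment; 400 genes, 25 targets, 99 matched lists). List and
  universe sizes were set so the integer-valued statistics are fine-
  grained enough that the deterministic add-one p's inherent
  conservatism does not mask nominal behavior; with very small
  intersections the discrete tail makes any permutation test
  under-reject.
- Enumeration oracles cap at universes ≤ 15 (ORA) and ≤ 14 (overlap
  expectation) where exhaustive iteration is fast and exact.

## Known limitations

- Oracle-mode DE tables cannot surface pathologies of count-model
  fitting (outlier replicates, dispersion shrinkage artifacts).
- The matched-null machinery tests marginal similarity only; three
  Wilcoxon screens do not enforce joint covariate similarity.
- Event-level vs base-level denominators make feature-coverage ratios
  scale-dependent (long events inflate junction hits); ratios are
  comparable across analyses run with the same L and J only.
- The fixture locus is synthetic; analyses of real data must supply a
  real GTF and real snoRNA windows, and group/copy naming must follow
  the `SNORD116-<n>` / `SNORD115-<n>` convention to map onto the
  locus model.
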