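"""Synthetic cohort generator with planted, recoverable structure.

Emulates the four inputs of the analysis at desk scale:

1. a GENCODE-style annotation of protein-coding and noncoding genes on
   pseudo-chromosomes, with transcript support levels and "basic" tags;
2. negative-binomial count matrices for an isogenic two-background
   (H9, CT2) design with WT / smDEL / lgDEL conditions in ESC and
   neuron lineages, with planted shared, model-specific and
   background-specific differentially expressed genes;
3. DESeq2-style differential-expression result tables synthesized
   directly from the planted truth ("oracle mode" — the count model fit
   itself is upstream of this pipeline);
4. snoGloBe-style sliding-window interaction predictions with a
   configurable targeting-enrichment fold on a chosen gene set, a 5'UTR
   placement bias, and an ASE2 bias of group-III snoRNA-side windows.

Every generator is a pure function of its config seed; the planted
truth tables are sufficient to score each downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .annotation import Annotation
from .locus import LocusModel

BACKGROUNDS = ("H9", "CT2")
CONDITIONS = ("WT", "smDEL", "lgDEL")
LINEAGES = ("ESC", "neuron")
DESIGNS = ("background_condition", "condition", "interaction")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Sizes and rates are chosen to mirror the structure of an isogenic
    two-background deletion study at desk scale; ``seed`` fully
    determines every generated artifact.
    """

    n_genes: int = 2000
    n_replicates: int = 3  # per (background, condition, lineage) cell
    nb_dispersion: float = 0.05  # median gene-wise dispersion
    planted_shared_up: int = 40  # DE in both backgrounds and both models
    planted_shared_down: int = 40
    planted_model_specific: int = 60  # per model, shared across backgrounds
    planted_background_specific: int = 30  # one background only (per model)
    lfc_magnitude: float = 2.0
    coding_fraction: float = 0.7
    # interaction-window generator
    targeting_enrichment_fold: float = 2.5
    base_event_rate: float = 0.02  # expected events per (copy, gene)
    background_window_rate: float = 0.05  # stray sub-threshold windows
    utr5_bias_weight: float = 3.0
    ase2_bias_weight: float = 4.0
    window_length: int = 13  # L, snoGloBe-style sliding window (nt)
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = (
            self.n_genes,
            self.planted_shared_up,
            self.planted_shared_down,
            self.planted_model_specific,
            self.planted_background_specific,
        )
        if any(s < 0 for s in sizes) or self.n_genes < 1:
            raise ValueError("gene-set sizes must be non-negative, n_genes >= 1")
        if self.targeting_enrichment_fold < 0:
            raise ValueError("targeting_enrichment_fold must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per design cell")
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent, named RNG stream derived from a master seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(sum(map(ord, stream)),))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def gen_annotation(config: SimConfig) -> tuple[Annotation, dict[str, str]]:
    """Generate a synthetic annotation and merged-exonic gene sequences.

    Each gene gets 1-3 transcripts on a pseudo-chromosome; the first
    transcript is always TSL 1-3 with the basic tag so every gene
    survives the confidence filter, extra transcripts draw TSL from
    {1..5, NA} and the basic tag at random. Coding genes carry CDS and
    UTR records (GENCODE side-agnostic UTR features). Returns the
    annotation and a dict gene_id -> merged-exonic sequence with
    gene-specific GC content.
    """
    rng = _stream_rng(config.seed, "annotation")
    rows: list[dict] = []
    sequences: dict[str, str] = {}
    bases = np.array(list("ACGT"))

    genes_per_chrom = 500
    pos = 1000
    chrom_i = 1
    for gi in range(config.n_genes):
        if gi > 0 and gi % genes_per_chrom == 0:
            chrom_i += 1
            pos = 1000
        chrom = f"chrSIM{chrom_i}"
        gene_id = f"GSIM{gi + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        coding = rng.random() < config.coding_fraction
        biotype = "protein_coding" if coding else "lncRNA"

        n_exons = int(rng.integers(1, 9))
        exon_lens = rng.integers(80, 301, size=n_exons)
        intron_lens = rng.integers(100, 1001, size=max(n_exons - 1, 0))
        exons: list[tuple[int, int]] = []
        cur = pos
        for k in range(n_exons):
            exons.append((cur, cur + int(exon_lens[k])))
            cur += int(exon_lens[k])
            if k < n_exons - 1:
                cur += int(intron_lens[k])
        gene_start, gene_end = exons[0][0], exons[-1][1]

        def add(feature, s, e, tid=None, tsl=np.nan, basic=False):
            rows.append(
                dict(
                    chrom=chrom,
                    feature=feature,
                    start=s,
                    end=e,
                    strand=strand,
                    gene_id=gene_id,
                    transcript_id=tid,
                    gene_biotype=biotype,
                    tsl=tsl,
                    basic=basic,
                )
            )

        add("gene", gene_start, gene_end)

        # CDS geometry shared by transcripts that keep the terminal exons
        u5 = int(rng.integers(20, min(80, exon_lens[0])))
        u3 = int(rng.integers(20, min(80, exon_lens[-1])))
        left_off, right_off = (u5, u3) if strand == "+" else (u3, u5)
        cds_lo = exons[0][0] + left_off
        cds_hi = exons[-1][1] - right_off

        n_tx = int(rng.integers(1, 4))
        for t in range(n_tx):
            tid = f"{gene_id}.t{t + 1}"
            if t == 0:
                tsl, basic = float(rng.integers(1, 4)), True
                tx_exons = exons
            else:
                tsl = float(rng.integers(1, 6)) if rng.random() < 0.8 else np.nan
                basic = bool(rng.random() < 0.5)
                keep = [True] * n_exons
                for k in range(1, n_exons - 1):  # drop internal exons only
                    keep[k] = bool(rng.random() < 0.7)
                tx_exons = [e for e, kp in zip(exons, keep) if kp]
            add("transcript", tx_exons[0][0], tx_exons[-1][1], tid, tsl, basic)
            for s, e in tx_exons:
                add("exon", s, e, tid, tsl, basic)
            if coding:
                for s, e in tx_exons:
                    cs, ce = max(s, cds_lo), min(e, cds_hi)
                    if cs < ce:
                        add("CDS", cs, ce, tid, tsl, basic)
                    if s < min(e, cds_lo):
                        add("UTR", s, min(e, cds_lo), tid, tsl, basic)
                    if max(s, cds_hi) < e:
                        add("UTR", max(s, cds_hi), e, tid, tsl, basic)

        gc = float(rng.beta(8, 10))  # gene-specific GC around 0.44
        exonic_len = sum(e - s for s, e in exons)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        sequences[gene_id] = "".join(rng.choice(bases, size=exonic_len, p=p))

        pos = gene_end + int(rng.integers(2000, 8001))

    return Annotation(pd.DataFrame(rows)), sequences


# ---------------------------------------------------------------------------
# Counts and planted truth
# ---------------------------------------------------------------------------

def _sample_name(bg: str, cond: str, lin: str, rep: int) -> str:
    return f"{bg}_{cond}_{lin}_r{rep + 1}"


def sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = [
        dict(sample=_sample_name(bg, cond, lin, r), background=bg,
             condition=cond, lineage=lin)
        for bg in BACKGROUNDS
        for cond in CONDITIONS
        for lin in LINEAGES
        for r in range(config.n_replicates)
    ]
    return pd.DataFrame(rows)


def plant_truth(annotation: Annotation, config: SimConfig) -> pd.DataFrame:
    """Assign planted DEG roles to disjoint gene sets.

    Scopes: ``shared`` genes are perturbed in both backgrounds and both
    deletion models (the cross-model consensus truth); ``<model>_only``
    genes in both backgrounds of one model; ``H9_only`` / ``CT2_only``
    genes in a single background (lgDEL and smDEL respectively).
    Columns: gene_id, contrast (smDEL|lgDEL), scope, direction, log2fc.
    """
    rng = _stream_rng(config.seed, "truth")
    genes = np.array(annotation.gene_ids)
    n_needed = (
        config.planted_shared_up
        + config.planted_shared_down
        + 2 * config.planted_model_specific
        + 2 * config.planted_background_specific
    )
    if n_needed > len(genes):
        raise ValueError("not enough genes for the requested planted sets")
    chosen = rng.choice(genes, size=n_needed, replace=False)
    it = iter(chosen)

    def take(n):
        return [next(it) for _ in range(n)]

    rows: list[dict] = []
    lfc = config.lfc_magnitude

    def emit(gene, contrast, scope, direction):
        rows.append(
            dict(gene_id=gene, contrast=contrast, scope=scope,
                 direction=direction, log2fc=lfc if direction == "up" else -lfc)
        )

    for g in take(config.planted_shared_up):
        for m in ("smDEL", "lgDEL"):
            emit(g, m, "shared", "up")
    for g in take(config.planted_shared_down):
        for m in ("smDEL", "lgDEL"):
            emit(g, m, "shared", "down")
    for m in ("lgDEL", "smDEL"):
        for i, g in enumerate(take(config.planted_model_specific)):
            emit(g, m, f"{m}_only", "up" if i % 2 == 0 else "down")
    for bg, m in (("H9", "lgDEL"), ("CT2", "smDEL")):
        for i, g in enumerate(take(config.planted_background_specific)):
            emit(g, m, f"{bg}_only", "up" if i % 2 == 0 else "down")
    return pd.DataFrame(rows, columns=["gene_id", "contrast", "scope", "direction", "log2fc"])


def _affected(truth: pd.DataFrame, contrast: str, background: str) -> pd.DataFrame:
    """Truth rows active for one (deletion model, background) cell."""
    t = truth[truth["contrast"] == contrast]
    scopes = {"shared", f"{contrast}_only", f"{background}_only"}
    return t[t["scope"].isin(scopes)]


def gen_counts(
    annotation: Annotation, config: SimConfig, truth: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix for the full design.

    Planted genes have their neuron-lineage mean shifted by
    ``2**log2fc`` in the affected (background, deletion) cells.
    Returns (counts genes x samples, sample sheet, truth table).
    """
    if truth is None:
        truth = plant_truth(annotation, config)
    rng = _stream_rng(config.seed, "counts")
    genes = annotation.gene_ids
    n = len(genes)
    sheet = sample_sheet(config)

    base_mean = np.exp(rng.normal(np.log(200), 1.0, size=n))
    dispersion = np.exp(rng.normal(np.log(config.nb_dispersion), 0.3, size=n))
    gene_index = {g: i for i, g in enumerate(genes)}

    cols = {}
    for _, s in sheet.iterrows():
        mu = base_mean.copy()
        if s.condition in ("smDEL", "lgDEL") and s.lineage == "neuron":
            for _, row in _affected(truth, s.condition, s.background).iterrows():
                mu[gene_index[row.gene_id]] *= 2.0 ** row.log2fc
        # NB with mean mu and dispersion a: var = mu + a mu^2
        r = 1.0 / dispersion
        p = r / (r + mu)
        cols[s["sample"]] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    return counts, sheet, truth


# ---------------------------------------------------------------------------
# Differential-expression tables (oracle mode)
# ---------------------------------------------------------------------------

def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def _synth_table(
    genes: list[str], sig: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """One DESeq2-style result table; ``sig`` rows get tiny p, correct sign."""
    n = len(genes)
    p = rng.uniform(0, 1, size=n)
    lfc = rng.normal(0, 0.1, size=n)
    base = np.exp(rng.normal(np.log(200), 1.0, size=n))
    idx = {g: i for i, g in enumerate(genes)}
    for _, row in sig.iterrows():
        i = idx[row.gene_id]
        p[i] = 1e-8 * rng.uniform(0.01, 1)
        lfc[i] = row.log2fc + rng.normal(0, 0.05)
    return pd.DataFrame(
        dict(gene_id=genes, baseMean=base, log2FoldChange=lfc, pvalue=p, padj=_bh(p))
    )


def gen_de_tables(
    truth: pd.DataFrame, config: SimConfig, genes: list[str]
) -> dict[str, dict[str, pd.DataFrame]]:
    """Synthesize DE result tables from the planted truth (oracle mode).

    For each deletion model: per-background tables (the
    Background_Condition contrast of that isogenic pair) and three
    combined-design tables (background_condition, condition,
    interaction). Planted genes receive padj << 0.05 with the planted
    sign in every table they affect; null genes draw uniform p. Genes
    perturbed in only one background are significant only in that
    background's table and in the combined background_condition table
    (their effect is diluted in the other designs).
    """
    rng = _stream_rng(config.seed, "de_tables")
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for model in ("smDEL", "lgDEL"):
        tables: dict[str, pd.DataFrame] = {}
        for bg in BACKGROUNDS:
            tables[bg] = _synth_table(genes, _affected(truth, model, bg), rng)
        t = truth[truth["contrast"] == model]
        both_bg = t[t["scope"].isin({"shared", f"{model}_only"})]
        any_bg = t
        for design in DESIGNS:
            sig = both_bg if design != "background_condition" else any_bg
            tables[design] = _synth_table(genes, sig, rng)
        out[model] = tables
    return out


# ---------------------------------------------------------------------------
# Interaction windows
# ---------------------------------------------------------------------------

def gen_windows(
    locus: LocusModel,
    annotation: Annotation,
    target_set: set[str],
    config: SimConfig,
) -> pd.DataFrame:
    """snoGloBe-style sliding-window prediction table with planted events.

    Background: stray sub-threshold windows (score < 0.98) uniformly on
    gene bodies. Planted events: runs of >= 3 consecutive windows with
    score >= 0.98, at rate ``base_event_rate`` per (copy, gene), times
    ``targeting_enrichment_fold`` for genes in ``target_set``. Event
    placement is biased to annotated 5'UTRs with ``utr5_bias_weight``
    (odds weight) and, on the snoRNA side of group-III SNORD116 copies,
    to the ASE2 element with ``ase2_bias_weight``.
    """
    unknown = target_set - set(annotation.gene_ids)
    if unknown:
        raise ValueError(f"target genes absent from annotation: {sorted(unknown)[:5]}")
    rng = _stream_rng(config.seed, "windows")
    L = config.window_length
    genes = annotation.genes[["gene_id", "chrom", "start", "end", "strand"]]
    utr_df = annotation.utrs_by_side()
    utr5_by_gene: dict[str, list[tuple[int, int]]] = {}
    if not utr_df.empty:
        for g, sub in utr_df[utr_df["side"] == "utr5"].groupby("gene_id"):
            utr5_by_gene[g] = [
                (int(s), int(e)) for s, e in zip(sub["start"], sub["end"]) if e - s >= L
            ]

    p_utr5 = config.utr5_bias_weight / (config.utr5_bias_weight + 1.0)
    p_ase2 = config.ase2_bias_weight / (config.ase2_bias_weight + 1.0)

    rows: list[tuple] = []

    def add_window(copy, sno_start, grow, chrom, tstart, strand, score):
        rows.append(
            (
                copy.copy_id,
                sno_start,
                sno_start + L,
                grow,
                chrom,
                tstart,
                tstart + L,
                strand,
                round(score, 4),
            )
        )

    gene_rows = list(genes.itertuples(index=False))
    for copy in locus.copies:
        max_sno = copy.length - L
        # stray background windows
        n_noise = rng.poisson(config.background_window_rate * len(gene_rows))
        for _ in range(n_noise):
            g = gene_rows[int(rng.integers(len(gene_rows)))]
            tstart = int(rng.integers(g.start, max(g.end - L, g.start) + 1))
            add_window(
                copy,
                int(rng.integers(0, max_sno + 1)),
                g.gene_id,
                g.chrom,
                tstart,
                g.strand,
                float(rng.uniform(0.5, 0.9799)),
            )
        # planted events
        for g in gene_rows:
            rate = config.base_event_rate * (
                config.targeting_enrichment_fold if g.gene_id in target_set else 1.0
            )
            for _ in range(rng.poisson(rate)):
                run = 3 + int(rng.poisson(1.0))
                span = run - 1 + L
                # target-side anchor
                ivs = utr5_by_gene.get(g.gene_id, [])
                if ivs and rng.random() < p_utr5:
                    s, e = ivs[int(rng.integers(len(ivs)))]
                    lo, hi = s, max(e - span, s)
                else:
                    lo, hi = g.start, max(g.end - span, g.start)
                t0 = int(rng.integers(lo, hi + 1))
                # snoRNA-side anchor (center in ASE2 for biased group III)
                if (
                    copy.family == "SNORD116"
                    and copy.group == "III"
                    and rng.random() < p_ase2
                ):
                    center = rng.uniform(copy.ase2.start, copy.ase2.end)
                    s0 = int(round(center - span / 2))
                else:
                    s0 = int(rng.integers(0, max(copy.length - span, 1)))
                s0 = min(max(s0, 0), max(copy.length - span, 0))
                # duplex-consistent stepping: antiparallel on + strand
                for k in range(run):
                    if g.strand == "+":
                        sno_start = s0 + (run - 1) - k
                    else:
                        sno_start = s0 + k
                    add_window(
                        copy,
                        sno_start,
                        g.gene_id,
                        g.chrom,
                        t0 + k,
                        g.strand,
                        float(rng.uniform(0.98, 1.0)),
                    )

    from .io import WINDOW_COLUMNS

    df = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    return df.sort_values(WINDOW_COLUMNS[:7]).reset_index(drop=True)


def gen_expression_covariate(
    counts: pd.DataFrame, sheet: pd.DataFrame
) -> pd.Series:
    """Mean CPM over neuron samples — the expression covariate."""
    neuron = sheet.loc[sheet["lineage"] == "neuron", "sample"]
    sub = counts[list(neuron)]
    cpm = sub / sub.sum(axis=0) * 1e6
    return cpm.mean(axis=1)
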