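"""Covariate-matched control lists and targeting-enrichment statistics.

Whether predicted snoRNA binding is enriched on a dysregulated gene
list cannot be judged against arbitrary random genes: longer, more
GC-rich or more highly expressed genes accumulate more predicted
windows. The null here is therefore built from random gene lists
accepted only when they are statistically indistinguishable from the
target list (two-sided Wilcoxon rank-sum p > alpha on each of
merged-exonic length, GC fraction and mean neuron expression — the
study used 100 such lists). Enrichment of the mean / median / sum of
per-gene predicted-event counts is then scored against that matched
null with an add-one empirical p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, ranksums

from .annotation import Annotation
from .interactions import events_per_copy
from .locus import LocusModel
from .resampling import EnrichmentResult, empirical_result

COVARIATES = ("length", "gc", "expression")


def compute_covariates(
    annotation: Annotation,
    sequences: dict[str, str],
    expression: pd.Series,
) -> pd.DataFrame:
    """Per-gene matching covariates: length, gc, expression.

    length = merged-exonic span (nt); gc = GC fraction of the
    merged-exonic sequence; expression = the supplied per-gene mean
    normalized expression (neuron CPM in this pipeline). Genes without
    a sequence are excluded.
    """
    rows = []
    for gene in annotation.gene_ids:
        seq = sequences.get(gene)
        if seq is None:
            continue
        length = annotation.merged_exonic_length(gene)
        if length <= 0:
            continue
        up = seq.upper()
        gc = (up.count("G") + up.count("C")) / len(up) if up else 0.0
        rows.append(
            dict(gene_id=gene, length=length, gc=gc,
                 expression=float(expression.get(gene, 0.0)))
        )
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class MatchedNull:
    """Accepted covariate-matched control gene lists."""

    lists: list[list[str]]
    acceptance_pvalues: pd.DataFrame  # one row per list, one col per covariate
    seed: int
    alpha_match: float
    n_tried: int = 0

    @property
    def n_lists(self) -> int:
        return len(self.lists)


def _screen(
    candidate: pd.DataFrame, target: pd.DataFrame, alpha: float
) -> tuple[bool, dict[str, float]]:
    ps = {}
    for cov in COVARIATES:
        ps[cov] = float(ranksums(candidate[cov], target[cov]).pvalue)
    return all(p > alpha for p in ps.values()), ps


def sample_matched_lists(
    target: list[str],
    universe: list[str],
    covariates: pd.DataFrame,
    n_lists: int = 100,
    alpha_match: float = 0.05,
    max_tries: int = 100_000,
    seed: int = 0,
) -> MatchedNull:
    """Rejection-sample control lists matched to ``target`` covariates.

    Draws |target| genes uniformly without replacement from
    ``universe \\ target`` and accepts a draw when every covariate's
    two-sided Wilcoxon rank-sum p exceeds ``alpha_match``. Raises after
    ``max_tries`` draws with a diagnostic of the most discriminating
    covariate.
    """
    target = list(dict.fromkeys(target))
    pool = sorted(set(universe) - set(target))
    if len(pool) < len(target):
        raise ValueError("universe (minus target) smaller than target list")
    missing = [g for g in target if g not in covariates.index]
    if missing:
        raise ValueError(f"target genes without covariates: {missing[:5]}")
    pool = [g for g in pool if g in covariates.index]

    rng = np.random.default_rng(seed)
    tcov = covariates.loc[target]
    pool_arr = np.array(pool)
    accepted: list[list[str]] = []
    pvals: list[dict[str, float]] = []
    reject_counts = {c: 0 for c in COVARIATES}
    tries = 0
    while len(accepted) < n_lists:
        if tries >= max_tries:
            worst = max(reject_counts, key=reject_counts.get)
            raise RuntimeError(
                f"matched-list sampling failed after {max_tries} tries "
                f"({len(accepted)}/{n_lists} accepted); most discriminating "
                f"covariate: {worst} ({reject_counts[worst]} rejections)"
            )
        tries += 1
        draw = list(pool_arr[rng.choice(len(pool_arr), size=len(target), replace=False)])
        ok, ps = _screen(covariates.loc[draw], tcov, alpha_match)
        if ok:
            accepted.append(draw)
            pvals.append(ps)
        else:
            for c, p in ps.items():
                if p <= alpha_match:
                    reject_counts[c] += 1
    return MatchedNull(
        lists=accepted,
        acceptance_pvalues=pd.DataFrame(pvals),
        seed=seed,
        alpha_match=alpha_match,
        n_tried=tries,
    )


def per_gene_event_counts(events: pd.DataFrame, genes: list[str],
                          sno_ids: set[str] | None = None) -> pd.Series:
    """Predicted-event count per gene (0 for untargeted genes).

    ``sno_ids`` restricts events to a subset of snoRNA copies (e.g.
    the group-III SNORD116 copies).
    """
    sub = events
    if sno_ids is not None and not events.empty:
        sub = events[events["sno_id"].isin(sno_ids)]
    counts = sub.groupby("target_gene").size() if not sub.empty else pd.Series(dtype=int)
    return pd.Series([int(counts.get(g, 0)) for g in genes], index=genes, name="n_events")


_STATS = {
    "mean": np.mean,
    "median": np.median,
    "sum": np.sum,
}


def targeting_enrichment(
    events: pd.DataFrame,
    target: list[str],
    null: MatchedNull,
    sno_ids: set[str] | None = None,
    statistics: tuple[str, ...] = ("mean", "median", "sum"),
) -> dict[str, EnrichmentResult]:
    """Enrichment of per-gene event counts on ``target`` vs matched lists.

    For each statistic in {mean, median, sum}, the observed value over
    the target list is compared with the same statistic over each
    matched control list; fold = observed / null mean, p is the add-one
    empirical tail probability.
    """
    if null.n_lists < 1:
        raise ValueError("empty matched null")
    target_counts = per_gene_event_counts(events, target, sno_ids).to_numpy()
    null_counts = [
        per_gene_event_counts(events, lst, sno_ids).to_numpy() for lst in null.lists
    ]
    out: dict[str, EnrichmentResult] = {}
    for name in statistics:
        fn = _STATS[name]
        observed = float(fn(target_counts))
        null_vals = np.array([float(fn(c)) for c in null_counts])
        out[name] = empirical_result(observed, null_vals, seed=null.seed,
                                     statistic=f"targeting_{name}")
    return out


@dataclass
class FamilyContrast:
    per_copy: pd.DataFrame
    per_group: pd.DataFrame
    family_p: float  # SNORD116 vs SNORD115 per-copy counts, rank-sum
    group3_vs_115_p: float
    snord116_mean: float
    snord115_mean: float
    group3_mean: float = field(default=np.nan)


def family_contrast(events: pd.DataFrame, locus: LocusModel) -> FamilyContrast:
    """Compare per-copy predicted targeting between snoRNA families.

    SNORD115 — the other orphan array in the locus — serves as the
    within-locus control family. Reports two-sided Mann-Whitney tests
    of per-copy event counts, SNORD116 vs SNORD115 and group-III-only
    vs SNORD115.
    """
    per_copy, per_group = events_per_copy(events, locus)
    c116 = per_copy.loc[per_copy["family"] == "SNORD116", "n_events"].to_numpy()
    c115 = per_copy.loc[per_copy["family"] == "SNORD115", "n_events"].to_numpy()
    c3 = per_copy.loc[
        (per_copy["family"] == "SNORD116") & (per_copy["group"] == "III"), "n_events"
    ].to_numpy()

    def _mwu(a, b) -> float:
        if a.size == 0 or b.size == 0 or (np.ptp(np.concatenate([a, b])) == 0):
            return 1.0
        return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)

    return FamilyContrast(
        per_copy=per_copy,
        per_group=per_group,
        family_p=_mwu(c116, c115),
        group3_vs_115_p=_mwu(c3, c115),
        snord116_mean=float(c116.mean()),
        snord115_mean=float(c115.mean()),
        group3_mean=float(c3.mean()),
    )
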