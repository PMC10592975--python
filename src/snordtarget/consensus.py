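"""Consensus differential-expression calling across isogenic pairs.

The study design compares each engineered deletion line (smDEL, lgDEL)
to its isogenic wild-type control in two genetic backgrounds (H9, CT2).
A gene is a *shared* DEG for a deletion model when it is significant
(BH-adjusted p < alpha) with a consistent fold-change direction in both
backgrounds; a *triple-design consensus* gene is significant in all
three DESeq2-style designs for that comparison; and the cross-model
gene set is the intersection of the two models' consensus sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ConsensusSet:
    """Direction-stratified shared DEGs with provenance."""

    up: set[str]
    down: set[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both shared-up and shared-down")

    @property
    def all(self) -> set[str]:
        return self.up | self.down

    @property
    def total(self) -> int:
        return len(self.up) + len(self.down)


def _check_de_table(table: pd.DataFrame, label: str) -> None:
    for col in ("gene_id", "log2FoldChange", "padj"):
        if col not in table.columns:
            raise ValueError(f"DE table {label!r} missing column {col!r}")


def filter_low_counts(counts: pd.DataFrame, min_mean: float) -> list[str]:
    """Genes whose mean count across all samples is >= ``min_mean``.

    With ``min_mean = 1`` this removes unexpressed genes; in a 39-sample
    design a total-count threshold of 39 is the same rule (one count per
    sample on average).
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    keep = counts.mean(axis=1) >= min_mean
    return list(counts.index[keep])


def call_shared_degs(
    tables: dict[str, pd.DataFrame], alpha: float = 0.05,
    require_direction: bool = True,
) -> ConsensusSet:
    """Shared DEGs across genetic backgrounds, stratified by direction.

    ``tables`` maps background label -> DE result table. A gene is
    shared-up when padj < alpha and log2FoldChange > 0 in every
    background (shared-down likewise with negative fold change).
    Significant genes with discordant directions are excluded from both
    sets when ``require_direction`` (the default); otherwise genes
    significant everywhere are assigned by their first table's sign.
    """
    if len(tables) < 2:
        raise ValueError("need at least two backgrounds to call shared DEGs")
    universes = []
    for label, t in tables.items():
        _check_de_table(t, label)
        universes.append(set(t["gene_id"]))
    common = set.intersection(*universes)

    up_sets, down_sets, sig_sets = [], [], []
    for t in tables.values():
        t = t[t["gene_id"].isin(common)]
        sig = t[t["padj"].notna() & (t["padj"] < alpha)]
        sig_sets.append(set(sig["gene_id"]))
        up_sets.append(set(sig.loc[sig["log2FoldChange"] > 0, "gene_id"]))
        down_sets.append(set(sig.loc[sig["log2FoldChange"] < 0, "gene_id"]))
    if require_direction:
        up = set.intersection(*up_sets)
        down = set.intersection(*down_sets)
    else:
        everywhere = set.intersection(*sig_sets)
        first_up = up_sets[0]
        up = everywhere & first_up
        down = everywhere - first_up
    return ConsensusSet(
        up=up,
        down=down,
        provenance=dict(
            backgrounds=sorted(tables), alpha=alpha,
            require_direction=require_direction, universe_size=len(common),
        ),
    )


def triple_design_consensus(
    tables: dict[str, pd.DataFrame], alpha: float = 0.05
) -> set[str]:
    """Genes significant (padj < alpha) in all three analysis designs.

    ``tables`` must contain the keys background_condition, condition and
    interaction — the three model formulations fit for one deletion
    comparison.
    """
    needed = {"background_condition", "condition", "interaction"}
    if not needed <= set(tables):
        raise ValueError(f"need all three design tables; missing {needed - set(tables)}")
    sig = []
    for design in sorted(needed):
        t = tables[design]
        _check_de_table(t, design)
        sig.append(set(t.loc[t["padj"].notna() & (t["padj"] < alpha), "gene_id"]))
    return set.intersection(*sig)


def cross_model_shared(lgdel_set: set[str], smdel_set: set[str]) -> set[str]:
    """Genes dysregulated in both deletion models (the 42-gene analog)."""
    return set(lgdel_set) & set(smdel_set)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million, per sample (library-size normalization)."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero total counts")
    return counts / totals * 1e6


def locus_log2fc(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 1.0,
    normalize: bool = True,
) -> pd.Series:
    """Per-gene log2((mean_A + c) / (mean_B + c)) with pseudocount c.

    The pseudocount keeps fold changes finite for genes with zero counts
    in one group — e.g. genes inside an engineered deletion. Counts are
    CPM-normalized per sample first unless ``normalize=False``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if set(group_a) & set(group_b):
        raise ValueError("sample groups overlap")
    missing = (set(group_a) | set(group_b)) - set(counts.columns)
    if missing:
        raise ValueError(f"unknown samples: {sorted(missing)}")
    mat = cpm(counts) if normalize else counts
    mean_a = mat[group_a].mean(axis=1)
    mean_b = mat[group_b].mean(axis=1)
    return np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
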