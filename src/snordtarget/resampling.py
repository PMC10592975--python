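"""Permutation nulls for k-way gene-list overlaps.

The observed statistic is the size of the intersection of k gene lists;
the null redraws all k lists (sizes fixed) uniformly without
replacement from the analysis universe and records the intersection
size. Significance is the add-one empirical p-value
``(1 + #{null >= observed}) / (n_perm + 1)`` and effect size is the
fold of the observed intersection over the null mean.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass
class EnrichmentResult:
    """Observed statistic vs a resampling null."""

    observed: float
    null_mean: float
    null_median: float
    fold: float
    p_empirical: float
    n_perm: int
    seed: int | None = None
    statistic: str = "intersection_size"

    def to_dict(self) -> dict:
        return asdict(self)


def empirical_result(
    observed: float,
    null: np.ndarray,
    seed: int | None = None,
    statistic: str = "statistic",
) -> EnrichmentResult:
    """Summarize an observed value against a null sample (add-one p).

    Convention: a null with mean 0 and observed 0 reports fold 0 and
    p = 1 (nothing to detect).
    """
    null = np.asarray(null, dtype=float)
    if null.size < 1:
        raise ValueError("empty null distribution")
    mean = float(null.mean())
    fold = float(observed / mean) if mean > 0 else 0.0
    p = float((1 + int((null >= observed).sum())) / (null.size + 1))
    return EnrichmentResult(
        observed=float(observed),
        null_mean=mean,
        null_median=float(np.median(null)),
        fold=fold,
        p_empirical=p,
        n_perm=int(null.size),
        seed=seed,
        statistic=statistic,
    )


def _null_intersections(
    sizes: list[int], n_universe: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Intersection sizes of k independent uniform draws, vectorized."""
    out = np.empty(n_perm, dtype=np.int64)
    hit = np.empty(n_universe, dtype=np.int64)
    for i in range(n_perm):
        hit[:] = 0
        for s in sizes:
            hit[rng.choice(n_universe, size=s, replace=False)] += 1
        out[i] = int((hit == len(sizes)).sum())
    return out


def _pairwise_null(
    sizes: list[int], n_universe: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Minimum over all pairwise intersections per permutation."""
    k = len(sizes)
    out = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        draws = [set(rng.choice(n_universe, size=s, replace=False).tolist()) for s in sizes]
        out[i] = min(len(draws[a] & draws[b]) for a in range(k) for b in range(a + 1, k))
    return out


def overlap_permutation_test(
    lists: list[set[str]],
    universe: set[str],
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "joint",
) -> EnrichmentResult:
    """Permutation test for the overlap of k gene lists.

    ``mode="joint"`` (default) redraws all k lists simultaneously and
    scores the k-way intersection; ``mode="pairwise"`` scores the
    minimum pairwise intersection instead.
    """
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    lists = [set(l) for l in lists]
    universe = set(universe)
    for i, l in enumerate(lists):
        extra = l - universe
        if extra:
            raise ValueError(f"list {i} has genes outside the universe: {sorted(extra)[:5]}")
    observed = len(set.intersection(*lists))
    rng = np.random.default_rng(seed)
    sizes = [len(l) for l in lists]
    if mode == "joint":
        null = _null_intersections(sizes, len(universe), n_perm, rng)
    elif mode == "pairwise":
        null = _pairwise_null(sizes, len(universe), n_perm, rng)
    else:
        raise ValueError(f"unknown mode: {mode}")
    return empirical_result(observed, null, seed=seed, statistic=f"{mode}_overlap")


def expected_pairwise_overlap(s1: int, s2: int, n_universe: int) -> float:
    """Exact E[|A ∩ B|] for independent uniform draws: s1*s2/N."""
    return s1 * s2 / n_universe
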