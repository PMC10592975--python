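"""Consolidation of sliding-window interaction predictions into events.

Prediction tools score every L-nt snoRNA window against every L-nt
target window as the pair slides 1 nt at a time. A *binding event* is a
run of at least ``w`` consecutive windows all scoring at least ``t``
(the study setting: ``-t 0.98 -w 3``). "Consecutive" requires co-linear
1-nt steps on both molecules in the duplex-consistent direction: the
duplex is antiparallel, so on a ``+``-strand target the snoRNA start
decreases by 1 as the genomic target start increases by 1, and
increases on a ``-``-strand target. A target-only mode ignores the
snoRNA side.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .locus import LocusModel

EVENT_COLUMNS = [
    "sno_id",
    "target_gene",
    "target_chrom",
    "strand",
    "sno_start",
    "sno_end",
    "target_start",
    "target_end",
    "n_windows",
    "min_score",
    "mean_score",
    "sno_center",
    "target_center",
]


def _window_length(windows: pd.DataFrame) -> int:
    widths = set(windows["sno_window_end"] - windows["sno_window_start"]) | set(
        windows["target_window_end"] - windows["target_window_start"]
    )
    if len(widths) != 1:
        raise ValueError(f"inconsistent window widths: {sorted(widths)}")
    return int(widths.pop())


def _sno_step(strand: str) -> int:
    return -1 if strand == "+" else 1


def merge_consecutive(
    windows: pd.DataFrame,
    t: float = 0.98,
    w: int = 3,
    merge_overlaps: bool = True,
    target_only: bool = False,
) -> pd.DataFrame:
    """Merge runs of >= ``w`` consecutive windows scoring >= ``t``.

    Windows are grouped by (sno_id, target_gene, strand); within a
    group a run is a maximal chain in which the target start advances
    by exactly 1 nt per window and (unless ``target_only``) the snoRNA
    start steps 1 nt in the duplex-consistent direction. Each run of
    length >= w becomes one event spanning first start to last start +
    L on both molecules. With ``merge_overlaps``, events of the same
    snoRNA copy overlapping on the target are unioned.
    """
    if not 0 <= t <= 1:
        raise ValueError("score threshold t must be in [0, 1]")
    if w < 1:
        raise ValueError("minimum run length w must be >= 1")
    if windows.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    L = _window_length(windows)

    passing = windows[windows["score"] >= t]
    events: list[dict] = []
    for (sno_id, gene, chrom, strand), grp in passing.groupby(
        ["sno_id", "target_gene", "target_chrom", "strand"], sort=True
    ):
        step = 0 if target_only else _sno_step(strand)
        pairs = sorted(
            zip(grp["target_window_start"].astype(int),
                grp["sno_window_start"].astype(int),
                grp["score"].astype(float))
        )
        index = {(tg, sn): sc for tg, sn, sc in pairs}
        if target_only:
            # collapse duplicate sno positions: chain on target start only
            by_target: dict[int, list[tuple[int, float]]] = {}
            for tg, sn, sc in pairs:
                by_target.setdefault(tg, []).append((sn, sc))
            starts = sorted(by_target)
            run: list[tuple[int, int, float]] = []
            for tg in starts + [None]:
                if run and (tg is None or tg != run[-1][0] + 1):
                    if len(run) >= w:
                        events.append(_run_to_event(run, L, sno_id, gene, chrom, strand))
                    run = []
                if tg is not None:
                    sn, sc = min(by_target[tg])
                    run.append((tg, sn, sc))
        else:
            for tg, sn, sc in pairs:
                if (tg - 1, sn - step) in index:
                    continue  # not a run start
                run = [(tg, sn, sc)]
                nt, ns = tg + 1, sn + step
                while (nt, ns) in index:
                    run.append((nt, ns, index[(nt, ns)]))
                    nt, ns = nt + 1, ns + step
                if len(run) >= w:
                    events.append(_run_to_event(run, L, sno_id, gene, chrom, strand))

    out = pd.DataFrame(events, columns=EVENT_COLUMNS)
    if merge_overlaps and not out.empty:
        out = merge_events(out)
    return out.sort_values(EVENT_COLUMNS[:8]).reset_index(drop=True)


def _run_to_event(
    run: list[tuple[int, int, float]], L: int, sno_id, gene, chrom, strand
) -> dict:
    tstarts = [r[0] for r in run]
    sstarts = [r[1] for r in run]
    scores = [r[2] for r in run]
    t0, t1 = min(tstarts), max(tstarts) + L
    s0, s1 = min(sstarts), max(sstarts) + L
    return dict(
        sno_id=sno_id,
        target_gene=gene,
        target_chrom=chrom,
        strand=strand,
        sno_start=s0,
        sno_end=s1,
        target_start=t0,
        target_end=t1,
        n_windows=len(run),
        min_score=float(min(scores)),
        mean_score=float(np.mean(scores)),
        sno_center=(s0 + s1) // 2,
        target_center=(t0 + t1) // 2,
    )


def merge_events(events: pd.DataFrame) -> pd.DataFrame:
    """Union events of the same snoRNA copy that overlap on the target.

    Idempotent: applying it to its own output changes nothing. Spans
    are unioned, supporting-window counts summed, min_score is the min
    and mean_score the window-weighted mean of the merged parts.
    """
    merged: list[dict] = []
    for _, grp in events.groupby(["sno_id", "target_gene", "target_chrom", "strand"],
                                 sort=True):
        grp = grp.sort_values(["target_start", "target_end"])
        cur: dict | None = None
        for r in grp.to_dict("records"):
            if cur is not None and r["target_start"] < cur["target_end"]:
                cur["target_end"] = max(cur["target_end"], r["target_end"])
                cur["sno_start"] = min(cur["sno_start"], r["sno_start"])
                cur["sno_end"] = max(cur["sno_end"], r["sno_end"])
                total = cur["n_windows"] + r["n_windows"]
                cur["mean_score"] = (
                    cur["mean_score"] * cur["n_windows"]
                    + r["mean_score"] * r["n_windows"]
                ) / total
                cur["n_windows"] = total
                cur["min_score"] = min(cur["min_score"], r["min_score"])
            else:
                if cur is not None:
                    merged.append(cur)
                cur = dict(r)
        if cur is not None:
            merged.append(cur)
    out = pd.DataFrame(merged, columns=EVENT_COLUMNS)
    out["sno_center"] = (out["sno_start"] + out["sno_end"]) // 2
    out["target_center"] = (out["target_start"] + out["target_end"]) // 2
    return out.sort_values(EVENT_COLUMNS[:8]).reset_index(drop=True)


def events_per_copy(
    events: pd.DataFrame, locus: LocusModel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Event counts per snoRNA copy and mean counts per group.

    Copies with no events count zero. Returns (per-copy table with
    columns copy_id, family, group, n_events; per-group summary with
    family, group, n_copies, mean_events). SNORD115 copies form their
    own single "NA" group.
    """
    known = set(locus.copy_ids)
    unknown = set(events["sno_id"]) - known if not events.empty else set()
    if unknown:
        raise ValueError(f"events reference unknown snoRNA copies: {sorted(unknown)[:5]}")
    counts = events.groupby("sno_id").size() if not events.empty else pd.Series(dtype=int)
    per_copy = pd.DataFrame(
        dict(
            copy_id=[c.copy_id for c in locus.copies],
            family=[c.family for c in locus.copies],
            group=[c.group for c in locus.copies],
            n_events=[int(counts.get(c.copy_id, 0)) for c in locus.copies],
        )
    )
    per_group = (
        per_copy.groupby(["family", "group"], sort=True)
        .agg(n_copies=("copy_id", "size"), mean_events=("n_events", "mean"))
        .reset_index()
    )
    return per_copy, per_group
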