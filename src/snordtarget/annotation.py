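"""In-memory gene annotation with GENCODE-style transcript metadata.

The container is a flat feature table (one row per gene / transcript /
exon / CDS / UTR record) in 0-based half-open coordinates, carrying the
two GENCODE transcript-confidence attributes the pipeline filters on:
transcript_support_level (TSL) and the "basic" tag. UTR records are
stored side-agnostic (as in GENCODE GTF) and split into 5' and 3' parts
relative to the CDS on demand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FEATURE_KINDS = ("gene", "transcript", "exon", "CDS", "UTR")

_REQUIRED = [
    "chrom",
    "feature",
    "start",
    "end",
    "strand",
    "gene_id",
    "transcript_id",
    "gene_biotype",
    "tsl",
    "basic",
]


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 0-based half-open intervals, sorted and coalesced."""
    if not intervals:
        return []
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class Annotation:
    """Feature table wrapper; ``df`` holds one row per annotation record."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        bad = set(self.df["feature"]) - set(FEATURE_KINDS)
        if bad:
            raise ValueError(f"unknown feature kinds: {sorted(bad)}")
        self.df = self.df.sort_values(
            ["chrom", "gene_id", "transcript_id", "start", "feature"],
            na_position="first",
        ).reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> pd.DataFrame:
        return self.df[self.df["feature"] == "gene"]

    @property
    def gene_ids(self) -> list[str]:
        return self.genes["gene_id"].tolist()

    @property
    def transcripts(self) -> pd.DataFrame:
        return self.df[self.df["feature"] == "transcript"]

    def features(self, kind: str, transcript_ids=None) -> pd.DataFrame:
        sub = self.df[self.df["feature"] == kind]
        if transcript_ids is not None:
            sub = sub[sub["transcript_id"].isin(set(transcript_ids))]
        return sub

    def gene_span(self, gene_id: str) -> tuple[str, int, int, str]:
        row = self.genes[self.genes["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(f"unknown gene: {gene_id}")
        r = row.iloc[0]
        return r["chrom"], int(r["start"]), int(r["end"]), r["strand"]

    # -- derived geometry ------------------------------------------------
    def merged_exons(self, gene_id: str, transcript_ids=None) -> list[tuple[int, int]]:
        ex = self.features("exon", transcript_ids)
        ex = ex[ex["gene_id"] == gene_id]
        return merge_intervals(list(zip(ex["start"].astype(int), ex["end"].astype(int))))

    def merged_exonic_length(self, gene_id: str) -> int:
        return sum(e - s for s, e in self.merged_exons(gene_id))

    def utrs_by_side(self, transcript_ids=None) -> pd.DataFrame:
        """Split UTR records into 5' and 3' parts relative to the CDS.

        A UTR record strictly upstream (in transcript orientation) of the
        transcript's CDS span is 5'; downstream is 3'. Transcripts without
        CDS contribute no rows. Adds a ``side`` column in {utr5, utr3}.
        """
        utr = self.features("UTR", transcript_ids)
        cds = self.features("CDS", transcript_ids)
        if utr.empty or cds.empty:
            return utr.assign(side=pd.Series(dtype=object)).iloc[0:0]
        cds_span = cds.groupby("transcript_id").agg(
            cds_start=("start", "min"), cds_end=("end", "max")
        )
        out = utr.merge(cds_span, left_on="transcript_id", right_index=True, how="inner")
        upstream = out["end"] <= out["cds_start"]
        plus = out["strand"] == "+"
        out["side"] = np.where(upstream == plus, "utr5", "utr3")
        return out.drop(columns=["cds_start", "cds_end"])
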