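"""Readers and writers for the pipeline's on-disk formats.

Conventions:

* internal coordinates are 0-based half-open everywhere; GTF is
  converted at the boundary (1-based closed on disk), BED is written
  natively 0-based half-open;
* every TSV/BED the pipeline writes starts with ``#`` comment lines
  declaring its coordinate convention and column schema; readers skip
  ``#`` lines.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr

from .annotation import Annotation

WINDOW_COLUMNS = [
    "sno_id",
    "sno_window_start",
    "sno_window_end",
    "target_gene",
    "target_chrom",
    "target_window_start",
    "target_window_end",
    "strand",
    "score",
]

DE_COLUMNS = ["gene_id", "baseMean", "log2FoldChange", "pvalue", "padj"]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _fmt_attrs(row: pd.Series) -> str:
    parts = [f'gene_id "{row.gene_id}"']
    if isinstance(row.gene_biotype, str):
        parts.append(f'gene_biotype "{row.gene_biotype}"')
    if isinstance(row.transcript_id, str) and row.transcript_id:
        parts.append(f'transcript_id "{row.transcript_id}"')
        tsl = "NA" if pd.isna(row.tsl) else str(int(row.tsl))
        parts.append(f'transcript_support_level "{tsl}"')
        if row.basic:
            parts.append('tag "basic"')
    return "; ".join(parts) + ";"


def write_gtf(ann: Annotation, path: str | Path) -> None:
    """Write GENCODE-dialect GTF (1-based closed coordinates on disk)."""
    lines = ["##format: gtf", "##coordinates: 1-based closed"]
    for _, row in ann.df.iterrows():
        lines.append(
            "\t".join(
                [
                    row.chrom,
                    "snordtarget",
                    row.feature,
                    str(int(row.start) + 1),
                    str(int(row.end)),
                    ".",
                    row.strand,
                    ".",
                    _fmt_attrs(row),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path: str | Path) -> Annotation:
    """Read a GENCODE-dialect GTF into an :class:`Annotation`.

    Coordinates are converted to internal 0-based half-open; the
    ``transcript_support_level`` and ``tag "basic"`` attributes are
    parsed into ``tsl`` (float, NaN when missing/NA) and ``basic``
    (bool) columns.
    """
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
        try:
            int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc

    df = pr.read_gtf(str(path)).df
    out = pd.DataFrame(
        {
            "chrom": df["Chromosome"].astype(str),
            "feature": df["Feature"].astype(str),
            "start": df["Start"].astype(int),
            "end": df["End"].astype(int),
            "strand": df["Strand"].astype(str),
            "gene_id": df["gene_id"].astype(str),
            "transcript_id": df.get("transcript_id", pd.Series(index=df.index)),
            "gene_biotype": df.get("gene_biotype", pd.Series(index=df.index)),
        }
    )
    tsl_raw = df.get("transcript_support_level", pd.Series(index=df.index))
    out["tsl"] = pd.to_numeric(tsl_raw, errors="coerce")
    tag = df.get("tag", pd.Series(index=df.index)).fillna("")
    out["basic"] = tag.str.contains("basic")
    return Annotation(out)


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = None,
              index: bool = False) -> None:
    header = "# coordinates: 0-based half-open\n"
    if comment:
        header += f"# {comment}\n"
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index)
    Path(path).write_text(header + buf.getvalue())


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Count matrix TSV: gene rows (index), sample columns."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table {path} missing columns: {missing}")
    return df


def read_windows(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = [c for c in WINDOW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"window table {path} missing columns: {missing}")
    return df


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + ("\n" if genes else ""))


def read_gene_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


# ---------------------------------------------------------------------------
# FASTA (merged-exonic gene sequences for covariate computation)
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = []
        elif name is not None:
            seqs[name].append(line.strip())
    return {k: "".join(v) for k, v in seqs.items()}


# ---------------------------------------------------------------------------
# Term maps (over-representation analysis)
# ---------------------------------------------------------------------------

def read_term_tsv(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (term, gene) -> term -> gene set."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["term", "gene"])
    return {t: set(g["gene"]) for t, g in df.groupby("term")}


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        terms[fields[0]] = set(f for f in fields[2:] if f)
    return terms


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    """Write merged binding events as BED6.

    Expects columns target_chrom, target_start, target_end, sno_id,
    min_score, strand; score is ``round(1000 * min_score)``.
    """
    lines = ["# coordinates: 0-based half-open (BED)"]
    for _, r in df.iterrows():
        lines.append(
            "\t".join(
                [
                    str(r.target_chrom),
                    str(int(r.target_start)),
                    str(int(r.target_end)),
                    str(r.sno_id),
                    str(int(round(1000 * r.min_score))),
                    str(r.strand),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
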