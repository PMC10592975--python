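"""Generate the synthetic study inputs with planted structure.

Writes the annotation, gene sequences, count matrix, sample sheet,
DESeq2-style result tables, interaction windows and the planted-truth
table under results/data/. All later analysis steps read from there.
"""

from pathlib import Path

import snordtarget as st
from snordtarget import io as sio

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = st.SimConfig(seed=SEED)  # defaults: 2000 genes, fold 2.5 planted
    locus = st.build_locus_fixture()
    ann, seqs = st.gen_annotation(cfg)
    counts, sheet, truth = st.gen_counts(ann, cfg)
    tables = st.gen_de_tables(truth, cfg, ann.gene_ids)
    planted = set(truth.loc[truth["scope"] == "shared", "gene_id"])
    windows = st.gen_windows(locus, ann, planted, cfg)

    sio.write_gtf(ann, OUT / "annotation.gtf")
    sio.write_fasta(seqs, OUT / "gene_sequences.fa")
    sio.write_tsv(counts, OUT / "counts.tsv", index=True)
    sio.write_tsv(sheet, OUT / "sample_sheet.tsv")
    sio.write_tsv(truth, OUT / "truth.tsv")
    sio.write_tsv(windows, OUT / "windows.tsv")
    for model, tset in tables.items():
        for label, t in tset.items():
            sio.write_tsv(t, OUT / f"de_{model}_{label}.tsv")

    print(f"simulated {cfg.n_genes} genes, {counts.shape[1]} samples")
    print(f"planted shared (cross-model) genes: {len(planted)}")
    print(f"interaction windows: {len(windows)}")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
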