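"""Over-representation analysis of the shared gene list.

Runs the hypergeometric ORA against a synthetic term map containing one
term seeded with the planted genes plus random terms; the planted term
should rank first with foldEnrichment >> 1.
"""

from pathlib import Path

import snordtarget as st
from snordtarget import io as sio
from snordtarget.pipeline import _synthetic_terms

BASE = Path(__file__).resolve().parents[1] / "results"
DATA, OUT = BASE / "data", BASE / "tables"
SEED = 31


def main() -> None:
    counts = sio.read_counts(DATA / "counts.tsv")
    target = sio.read_gene_list(OUT / "cross_model_shared.txt")
    universe = set(st.filter_low_counts(counts, min_mean=1))
    query = set(target) & universe
    terms = _synthetic_terms(sorted(universe), query, SEED)
    table = st.hypergeom_ora(query, universe, terms)
    sio.write_tsv(table, OUT / "ora.tsv")
    top = table.iloc[0]
    print(f"{len(table)} terms tested; top: {top['term']} "
          f"(padj {top['padj']:.2g}, foldEnrichment {top['foldEnrichment']:.2f})")


if __name__ == "__main__":
    main()
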