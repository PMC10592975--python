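import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import snordtarget as st

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def locus():
    return st.build_locus_fixture()


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully structured synthetic cohort (shared across tests)."""
    cfg = st.SimConfig(
        n_genes=300,
        seed=42,
        planted_shared_up=20,
        planted_shared_down=20,
        planted_model_specific=30,
        planted_background_specific=15,
    )
    ann, seqs = st.gen_annotation(cfg)
    counts, sheet, truth = st.gen_counts(ann, cfg)
    tables = st.gen_de_tables(truth, cfg, ann.gene_ids)
    return dict(cfg=cfg, ann=ann, seqs=seqs, counts=counts, sheet=sheet,
                truth=truth, tables=tables)


@pytest.fixture(scope="session")
def small_windows(locus, small_sim):
    cfg = small_sim["cfg"]
    truth = small_sim["truth"]
    planted = set(truth.loc[truth["scope"] == "shared", "gene_id"])
    windows = st.gen_windows(locus, small_sim["ann"], planted, cfg)
    return dict(windows=windows, planted=planted)


def make_de_table(genes, sig_up=(), sig_down=(), seed=0):
    """Minimal DESeq2-style table: listed genes significant, rest null."""
    rng = np.random.default_rng(seed)
    sig_up, sig_down = set(sig_up), set(sig_down)
    rows = []
    for g in genes:
        if g in sig_up or g in sig_down:
            p = 1e-10
            lfc = 2.0 if g in sig_up else -2.0
        else:
            p = rng.uniform(0.2, 1.0)
            lfc = rng.normal(0, 0.05)
        rows.append(dict(gene_id=g, baseMean=100.0, log2FoldChange=lfc, pvalue=p))
    df = pd.DataFrame(rows)
    from statsmodels.stats.multitest import multipletests

    df["padj"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    return df
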