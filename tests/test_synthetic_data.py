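"""Generator contracts: determinism, planted structure, schema validity."""

import numpy as np
import pandas as pd
import pytest

import snordtarget as st
from snordtarget import io as sio
from snordtarget.simulate import gen_expression_covariate, sample_sheet


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        st.SimConfig(n_genes=0)
    with pytest.raises(ValueError):
        st.SimConfig(planted_shared_up=-1)
    with pytest.raises(ValueError):
        st.SimConfig(targeting_enrichment_fold=-0.1)
    with pytest.raises(ValueError):
        st.SimConfig(n_replicates=1)


def test_annotation_structure(small_sim):
    ann = small_sim["ann"]
    genes = ann.genes
    assert set(genes["strand"]) == {"+", "-"}
    # noncoding genes carry no CDS/UTR records
    nc = set(genes.loc[genes["gene_biotype"] != "protein_coding", "gene_id"])
    cds = ann.features("CDS")
    utr = ann.features("UTR")
    assert not (set(cds["gene_id"]) & nc)
    assert not (set(utr["gene_id"]) & nc)
    # every transcript's exons lie within its gene bounds and are non-empty
    gene_bounds = genes.set_index("gene_id")[["start", "end"]]
    ex = ann.features("exon")
    assert len(ex) > 0
    for tid, sub in ex.groupby("transcript_id"):
        gid = sub["gene_id"].iloc[0]
        assert len(sub) >= 1
        assert sub["start"].min() >= gene_bounds.loc[gid, "start"]
        assert sub["end"].max() <= gene_bounds.loc[gid, "end"]


def test_single_noncoding_gene_degenerate():
    cfg = st.SimConfig(n_genes=1, coding_fraction=0.0, planted_shared_up=0,
                       planted_shared_down=0, planted_model_specific=0,
                       planted_background_specific=0, seed=3)
    ann, seqs = st.gen_annotation(cfg)
    assert len(ann.gene_ids) == 1
    assert ann.features("CDS").empty and ann.features("UTR").empty
    gene = ann.gene_ids[0]
    assert len(seqs[gene]) == ann.merged_exonic_length(gene)


def test_annotation_gtf_deterministic(tmp_path):
    cfg = st.SimConfig(n_genes=40, seed=9, planted_shared_up=2,
                       planted_shared_down=2, planted_model_specific=2,
                       planted_background_specific=2)
    paths = []
    for tag in ("a", "b"):
        ann, _ = st.gen_annotation(cfg)
        p = tmp_path / f"{tag}.gtf"
        sio.write_gtf(ann, p)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_planted_mean_shift_matches_lfc():
    """Planted genes' NB mean ratio across conditions approaches 2**lfc."""
    cfg = st.SimConfig(n_genes=60, n_replicates=50, seed=21, lfc_magnitude=2.0,
                       planted_shared_up=10, planted_shared_down=10,
                       planted_model_specific=5, planted_background_specific=5)
    ann, _ = st.gen_annotation(cfg)
    counts, sheet, truth = st.gen_counts(ann, cfg)
    up = truth[(truth["scope"] == "shared") & (truth["direction"] == "up")
               & (truth["contrast"] == "lgDEL")]["gene_id"].unique()
    del_samples = sheet[(sheet["condition"] == "lgDEL") & (sheet["lineage"] == "neuron")]["sample"]
    wt_samples = sheet[(sheet["condition"] == "WT") & (sheet["lineage"] == "neuron")]["sample"]
    ratio = counts.loc[up, list(del_samples)].mean(axis=1) / counts.loc[
        up, list(wt_samples)].mean(axis=1)
    assert np.allclose(np.log2(ratio), cfg.lfc_magnitude, atol=0.35)


def test_null_config_has_empty_truth():
    cfg = st.SimConfig(n_genes=50, seed=5, planted_shared_up=0,
                       planted_shared_down=0, planted_model_specific=0,
                       planted_background_specific=0)
    ann, _ = st.gen_annotation(cfg)
    _, _, truth = st.gen_counts(ann, cfg)
    assert truth.empty


def test_truth_table_sizes(small_sim):
    truth, cfg = small_sim["truth"], small_sim["cfg"]
    shared_up = truth[(truth["scope"] == "shared") & (truth["direction"] == "up")]
    assert shared_up["gene_id"].nunique() == cfg.planted_shared_up
    # shared genes are planted in both models
    assert set(shared_up["contrast"]) == {"smDEL", "lgDEL"}


def test_de_tables_oracle_contract(small_sim):
    tables, truth = small_sim["tables"], small_sim["truth"]
    for model in ("smDEL", "lgDEL"):
        t = truth[truth["contrast"] == model]
        both_bg = t[t["scope"].isin({"shared", f"{model}_only"})]
        for design in ("background_condition", "condition", "interaction"):
            tab = tables[model][design].set_index("gene_id")
            for _, row in both_bg.iterrows():
                assert tab.loc[row.gene_id, "padj"] < 0.05
                assert np.sign(tab.loc[row.gene_id, "log2FoldChange"]) == (
                    1 if row.direction == "up" else -1
                )


def test_de_tables_null_bh_behavior():
    """With nothing planted, BH on uniform p yields (almost) no calls."""
    cfg = st.SimConfig(n_genes=400, seed=8, planted_shared_up=0,
                       planted_shared_down=0, planted_model_specific=0,
                       planted_background_specific=0)
    ann, _ = st.gen_annotation(cfg)
    _, _, truth = st.gen_counts(ann, cfg)
    tables = st.gen_de_tables(truth, cfg, ann.gene_ids)
    frac = (tables["lgDEL"]["H9"]["padj"] < 0.05).mean()
    assert frac < 0.01


def test_windows_schema_and_scores(small_windows, small_sim):
    w = small_windows["windows"]
    assert list(w.columns) == sio.WINDOW_COLUMNS
    assert w["score"].between(0, 1).all()
    L = small_sim["cfg"].window_length
    assert ((w["sno_window_end"] - w["sno_window_start"]) == L).all()
    assert ((w["target_window_end"] - w["target_window_start"]) == L).all()


def test_windows_deterministic(locus, small_sim):
    cfg, ann = small_sim["cfg"], small_sim["ann"]
    truth = small_sim["truth"]
    planted = set(truth.loc[truth["scope"] == "shared", "gene_id"])
    w1 = st.gen_windows(locus, ann, planted, cfg)
    w2 = st.gen_windows(locus, ann, planted, cfg)
    pd.testing.assert_frame_equal(w1, w2)


def test_windows_unknown_target_rejected(locus, small_sim):
    with pytest.raises(ValueError, match="absent"):
        st.gen_windows(locus, small_sim["ann"], {"NOT_A_GENE"}, small_sim["cfg"])


def test_ase2_bias_limit(locus, small_sim):
    """With overwhelming ASE2 weight, all group-III event centers land in ASE2."""
    cfg = st.SimConfig(n_genes=80, seed=13, ase2_bias_weight=1e9,
                       planted_shared_up=5, planted_shared_down=5,
                       planted_model_specific=5, planted_background_specific=5)
    ann, _ = st.gen_annotation(cfg)
    w = st.gen_windows(locus, ann, set(), cfg)
    ev = st.merge_consecutive(w)
    prof = st.relative_centers(ev, locus)
    g3 = prof.events[prof.events["group"] == "III"]
    assert len(g3) > 0
    for _, e in g3.iterrows():
        copy = locus.get_copy(e["sno_id"])
        # center within ASE2 up to the half-window discretization
        assert copy.ase2.start - 2 <= e["center"] <= copy.ase2.end + 1


def test_expression_covariate_is_neuron_cpm(small_sim):
    counts, sheet = small_sim["counts"], small_sim["sheet"]
    expr = gen_expression_covariate(counts, sheet)
    neuron = sheet.loc[sheet["lineage"] == "neuron", "sample"]
    manual = (counts[list(neuron)] / counts[list(neuron)].sum(axis=0) * 1e6).mean(axis=1)
    pd.testing.assert_series_equal(expr, manual)


def test_sample_sheet_design(small_sim):
    sheet = sample_sheet(small_sim["cfg"])
    cells = sheet.groupby(["background", "condition", "lineage"]).size()
    assert (cells == small_sim["cfg"].n_replicates).all()
    assert len(cells) == 2 * 3 * 2
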