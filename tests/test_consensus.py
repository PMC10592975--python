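"""Shared-DEG calling, design consensus and locus fold changes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst

import snordtarget as st
from tests.conftest import make_de_table

GENES = [f"g{i}" for i in range(60)]


# -- low-count filter ----------------------------------------------------

def test_filter_low_counts_arithmetic():
    counts = pd.DataFrame(
        {"s1": [0, 3, 0, 39], "s2": [1, 1, 0, 39]},
        index=["low", "kept", "zero", "high"],
    )
    kept = st.filter_low_counts(counts, min_mean=1)
    assert kept == ["kept", "high"]  # mean 0.5 removed, mean 2 kept


def test_filter_total39_equals_one_per_sample():
    """In a 39-sample design, mean >= 1 is the same as total >= 39."""
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.integers(0, 4, size=(50, 39)),
                          index=[f"g{i}" for i in range(50)])
    by_mean = set(st.filter_low_counts(counts, min_mean=1))
    by_total = set(counts.index[counts.sum(axis=1) >= 39])
    assert by_mean == by_total


def test_filter_rejects_empty_and_negative():
    with pytest.raises(ValueError):
        st.filter_low_counts(pd.DataFrame(), 1)
    with pytest.raises(ValueError):
        st.filter_low_counts(pd.DataFrame({"s": [-1]}, index=["g"]), 1)


# -- shared DEGs across backgrounds --------------------------------------

@pytest.mark.parametrize(
    "padj_h9,padj_ct2,lfc_h9,lfc_ct2,in_up,in_down",
    [
        (0.01, 0.01, 2.0, 1.0, True, False),  # concordant up
        (0.01, 0.01, -2.0, -1.0, False, True),  # concordant down
        (0.01, 0.20, 2.0, 2.0, False, False),  # significant in one only
        (0.01, 0.01, 2.0, -2.0, False, False),  # discordant: excluded from both
        (0.20, 0.20, 2.0, 2.0, False, False),
        (0.01, 0.01, -2.0, 2.0, False, False),
    ],
)
def test_shared_deg_sign_patterns(padj_h9, padj_ct2, lfc_h9, lfc_ct2, in_up, in_down):
    def table(padj, lfc):
        return pd.DataFrame(
            dict(gene_id=["x", "null"], baseMean=[10, 10],
                 log2FoldChange=[lfc, 0.0], pvalue=[padj, 0.9], padj=[padj, 0.9])
        )

    cs = st.call_shared_degs({"H9": table(padj_h9, lfc_h9),
                              "CT2": table(padj_ct2, lfc_ct2)})
    assert ("x" in cs.up) == in_up
    assert ("x" in cs.down) == in_down


def test_shared_degs_disjoint_and_universe_intersection():
    t1 = make_de_table(GENES, sig_up=GENES[:10], sig_down=GENES[10:20], seed=1)
    t2 = make_de_table(GENES[:40], sig_up=GENES[:10], sig_down=GENES[10:20], seed=2)
    cs = st.call_shared_degs({"H9": t1, "CT2": t2})
    assert not (cs.up & cs.down)
    assert cs.up == set(GENES[:10]) and cs.down == set(GENES[10:20])
    assert cs.provenance["universe_size"] == 40


def test_shared_degs_missing_column_rejected():
    bad = pd.DataFrame(dict(gene_id=["a"], log2FoldChange=[1.0]))
    with pytest.raises(ValueError, match="padj"):
        st.call_shared_degs({"H9": bad, "CT2": bad})


@given(alpha_pair=hst.tuples(hst.floats(0.001, 0.2), hst.floats(0.001, 0.2)))
def test_consensus_monotone_in_alpha(alpha_pair):
    """Shrinking alpha never grows the consensus sets."""
    lo, hi = min(alpha_pair), max(alpha_pair)
    t1 = make_de_table(GENES, sig_up=GENES[:15], sig_down=GENES[20:30], seed=3)
    t2 = make_de_table(GENES, sig_up=GENES[5:20], sig_down=GENES[20:35], seed=4)
    cs_lo = st.call_shared_degs({"H9": t1, "CT2": t2}, alpha=lo)
    cs_hi = st.call_shared_degs({"H9": t1, "CT2": t2}, alpha=hi)
    assert cs_lo.up <= cs_hi.up and cs_lo.down <= cs_hi.down


# -- triple-design consensus and cross-model intersection ----------------

def test_triple_design_requires_all_three():
    t = make_de_table(GENES, sig_up=GENES[:5])
    with pytest.raises(ValueError):
        st.triple_design_consensus({"background_condition": t, "condition": t})


def test_triple_design_consensus_logic():
    a = make_de_table(GENES, sig_up=GENES[:10], seed=5)
    b = make_de_table(GENES, sig_up=GENES[5:15], seed=6)
    c = make_de_table(GENES, sig_up=GENES[8:20], seed=7)
    got = st.triple_design_consensus(
        {"background_condition": a, "condition": b, "interaction": c}
    )
    assert got == set(GENES[8:10])  # significant in all three only
    disjoint = st.triple_design_consensus(
        {"background_condition": a, "condition": make_de_table(GENES, sig_up=GENES[30:40], seed=8),
         "interaction": c}
    )
    assert disjoint == set()


def test_triple_design_recovers_planted_truth(small_sim):
    tables, truth = small_sim["tables"], small_sim["truth"]
    for model in ("smDEL", "lgDEL"):
        designs = {k: tables[model][k]
                   for k in ("background_condition", "condition", "interaction")}
        got = st.triple_design_consensus(designs)
        t = truth[truth["contrast"] == model]
        expected = set(t.loc[t["scope"].isin({"shared", f"{model}_only"}), "gene_id"])
        assert got == expected


def test_cross_model_shared_is_intersection(small_sim):
    tables, truth = small_sim["tables"], small_sim["truth"]
    sets = {}
    for model in ("smDEL", "lgDEL"):
        designs = {k: tables[model][k]
                   for k in ("background_condition", "condition", "interaction")}
        sets[model] = st.triple_design_consensus(designs)
    got = st.cross_model_shared(sets["lgDEL"], sets["smDEL"])
    assert got == set(truth.loc[truth["scope"] == "shared", "gene_id"])
    assert st.cross_model_shared(sets["lgDEL"], sets["lgDEL"]) == sets["lgDEL"]
    assert st.cross_model_shared(sets["lgDEL"], set()) == set()


# -- oracle-mode recovery ------------------------------------------------

def test_shared_degs_perfect_on_oracle_tables(small_sim):
    """Sensitivity and specificity are 1.0 against the planted truth."""
    tables, truth = small_sim["tables"], small_sim["truth"]
    for model in ("smDEL", "lgDEL"):
        cs = st.call_shared_degs({k: tables[model][k] for k in ("H9", "CT2")})
        t = truth[truth["contrast"] == model]
        expected = t[t["scope"].isin({"shared", f"{model}_only"})]
        exp_up = set(expected.loc[expected["direction"] == "up", "gene_id"])
        exp_down = set(expected.loc[expected["direction"] == "down", "gene_id"])
        assert cs.up == exp_up
        assert cs.down == exp_down


# -- locus pseudocount fold changes --------------------------------------

def test_locus_log2fc_arithmetic():
    counts = pd.DataFrame(
        {"a1": [0, 3, 0], "a2": [0, 3, 0], "b1": [0, 1, 63], "b2": [0, 1, 63]},
        index=["both_zero", "three_vs_one", "deleted"],
    )
    lfc = st.locus_log2fc(counts, ["a1", "a2"], ["b1", "b2"],
                          pseudocount=1, normalize=False)
    assert lfc["both_zero"] == 0.0
    assert lfc["three_vs_one"] == pytest.approx(1.0)
    assert lfc["deleted"] == pytest.approx(-6.0)  # log2(1/64)


def test_locus_log2fc_input_validation():
    counts = pd.DataFrame({"a": [1], "b": [2]}, index=["g"])
    with pytest.raises(ValueError, match="overlap"):
        st.locus_log2fc(counts, ["a"], ["a"])
    with pytest.raises(ValueError, match="pseudocount"):
        st.locus_log2fc(counts, ["a"], ["b"], pseudocount=0)


def test_locus_log2fc_cpm_normalization_removes_depth_effect():
    rng = np.random.default_rng(1)
    base = rng.integers(50, 150, size=20)
    counts = pd.DataFrame(
        {"a1": base, "a2": base, "b1": base * 5, "b2": base * 5},
        index=[f"g{i}" for i in range(20)],
    )  # group B is the same library sequenced 5x deeper
    lfc = st.locus_log2fc(counts, ["a1", "a2"], ["b1", "b2"], pseudocount=1)
    assert np.allclose(lfc, 0.0, atol=1e-9)
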