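"""Covariate matching and targeting-enrichment statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ranksums

import snordtarget as st
from snordtarget.annotation import Annotation
from snordtarget.enrichment import per_gene_event_counts


def iid_covariates(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        dict(
            length=rng.lognormal(7, 0.5, n),
            gc=rng.beta(8, 10, n),
            expression=rng.lognormal(3, 1, n),
        ),
        index=[f"g{i}" for i in range(n)],
    )


def event_frame(gene_counts: dict[str, int], sno_id="SNORD116-25"):
    rows = [dict(sno_id=sno_id, target_gene=g)
            for g, k in gene_counts.items() for _ in range(k)]
    return pd.DataFrame(rows, columns=["sno_id", "target_gene"])


# -- covariates ----------------------------------------------------------

def test_compute_covariates_interval_arithmetic():
    df = pd.DataFrame(
        [
            dict(chrom="c", feature="gene", start=0, end=150, strand="+",
                 gene_id="g", transcript_id=None, gene_biotype="lncRNA",
                 tsl=np.nan, basic=False),
            dict(chrom="c", feature="transcript", start=0, end=150, strand="+",
                 gene_id="g", transcript_id="t", gene_biotype="lncRNA",
                 tsl=1.0, basic=True),
            dict(chrom="c", feature="exon", start=0, end=50, strand="+",
                 gene_id="g", transcript_id="t", gene_biotype="lncRNA",
                 tsl=1.0, basic=True),
            dict(chrom="c", feature="exon", start=100, end=150, strand="+",
                 gene_id="g", transcript_id="t", gene_biotype="lncRNA",
                 tsl=1.0, basic=True),
        ]
    )
    ann = Annotation(df)
    cov = st.compute_covariates(ann, {"g": "G" * 50 + "C" * 50}, pd.Series(dtype=float))
    assert cov.loc["g", "length"] == 100  # merged exons [0,50) + [100,150)
    assert cov.loc["g", "gc"] == 1.0
    assert cov.loc["g", "expression"] == 0.0


def test_compute_covariates_skips_missing_sequence(small_sim):
    ann, seqs = small_sim["ann"], dict(small_sim["seqs"])
    dropped = ann.gene_ids[0]
    del seqs[dropped]
    cov = st.compute_covariates(ann, seqs, pd.Series(dtype=float))
    assert dropped not in cov.index
    assert len(cov) == len(ann.gene_ids) - 1
    assert cov["gc"].between(0, 1).all()
    assert (cov["length"] > 0).all()


# -- matched-list sampling -----------------------------------------------

def test_matched_lists_pass_screens_post_hoc():
    cov = iid_covariates(300, seed=1)
    target = list(cov.index[:30])
    mn = st.sample_matched_lists(target, list(cov.index), cov, n_lists=25, seed=2)
    assert mn.n_lists == 25
    tcov = cov.loc[target]
    for lst in mn.lists:
        assert len(lst) == len(target)
        assert not set(lst) & set(target)  # controls exclude the target genes
        for c in ("length", "gc", "expression"):
            assert ranksums(cov.loc[lst, c], tcov[c]).pvalue > mn.alpha_match
    # acceptance rate near the null expectation (<= ~15% rejected per screen)
    assert mn.n_tried < 25 * 3


def test_matched_sampling_fails_on_shifted_universe():
    cov = iid_covariates(200, seed=3)
    target = list(cov.index[:20])
    cov.loc[~cov.index.isin(target), "length"] *= 10  # universe 10x longer
    with pytest.raises(RuntimeError, match="length"):
        st.sample_matched_lists(target, list(cov.index), cov, n_lists=5,
                                max_tries=200, seed=4)


def test_matched_sampling_universe_too_small():
    cov = iid_covariates(10)
    with pytest.raises(ValueError, match="smaller"):
        st.sample_matched_lists(list(cov.index), list(cov.index), cov, n_lists=1)


# -- targeting enrichment ------------------------------------------------

def test_per_gene_counts_with_restriction():
    ev = pd.concat([
        event_frame({"a": 2, "b": 1}, sno_id="SNORD116-25"),
        event_frame({"a": 1}, sno_id="SNORD115-3"),
    ])
    all_counts = per_gene_event_counts(ev, ["a", "b", "c"])
    assert list(all_counts) == [3, 1, 0]
    g3 = per_gene_event_counts(ev, ["a", "b", "c"], sno_ids={"SNORD116-25"})
    assert list(g3) == [2, 1, 0]


def test_planted_fold_recovered_and_null_flat():
    rng = np.random.default_rng(5)
    cov = iid_covariates(400, seed=6)
    genes = list(cov.index)
    target = genes[:40]
    lam = 1.0
    fold = 2.5
    counts = {
        g: int(rng.poisson(lam * (fold if g in set(target) else 1.0))) for g in genes
    }
    ev = event_frame(counts)
    mn = st.sample_matched_lists(target, genes, cov, n_lists=60, seed=7)
    res = st.targeting_enrichment(ev, target, mn)
    assert set(res) == {"mean", "median", "sum"}
    assert res["sum"].fold == pytest.approx(fold, rel=0.2)
    assert res["sum"].p_empirical <= 0.05
    # same events, un-enriched list: fold ~ 1
    other = genes[60:100]
    res0 = st.targeting_enrichment(ev, other, mn)
    assert res0["sum"].fold == pytest.approx(1.0, abs=0.5)  # ~3 sigma at n=40


def test_zero_events_convention():
    cov = iid_covariates(100, seed=8)
    genes = list(cov.index)
    mn = st.sample_matched_lists(genes[:10], genes, cov, n_lists=10, seed=9)
    res = st.targeting_enrichment(event_frame({}), genes[:10], mn)
    assert res["sum"].fold == 0.0 and res["sum"].p_empirical == 1.0


def test_fold_invariant_to_relabeling():
    rng = np.random.default_rng(10)
    cov = iid_covariates(200, seed=11)
    genes = list(cov.index)
    target = genes[:20]
    ev = event_frame({g: int(rng.poisson(1.0)) for g in genes})
    mn = st.sample_matched_lists(target, genes, cov, n_lists=30, seed=12)
    res = st.targeting_enrichment(ev, target, mn)
    mapping = {g: f"RENAMED_{g}" for g in genes}
    cov2 = cov.rename(index=mapping)
    ev2 = ev.assign(target_gene=ev["target_gene"].map(mapping))
    mn2 = st.sample_matched_lists([mapping[g] for g in target],
                                  [mapping[g] for g in genes], cov2,
                                  n_lists=30, seed=12)
    res2 = st.targeting_enrichment(ev2, [mapping[g] for g in target], mn2)
    assert res["sum"].fold == pytest.approx(res2["sum"].fold)


def test_empty_null_rejected():
    mn = st.MatchedNull(lists=[], acceptance_pvalues=pd.DataFrame(),
                        seed=0, alpha_match=0.05)
    with pytest.raises(ValueError, match="empty"):
        st.targeting_enrichment(event_frame({"a": 1}), ["a"], mn)


# -- family contrast -----------------------------------------------------

def test_family_contrast_group3_planting(locus):
    rng = np.random.default_rng(13)
    rows = []
    for c in locus.group("III"):
        for _ in range(int(rng.poisson(5))):
            rows.append(dict(sno_id=c.copy_id, target_gene="G1"))
    for c in locus.family("SNORD115")[:10]:
        rows.append(dict(sno_id=c.copy_id, target_gene="G2"))
    ev = pd.DataFrame(rows)
    fc = st.family_contrast(ev, locus)
    assert fc.group3_mean > fc.snord115_mean
    assert fc.group3_vs_115_p < 0.05
    assert len(fc.per_copy) == 78


def test_family_contrast_type_one_error(locus):
    """Equal planted rates: the rank-sum comparison rejects at ~nominal rate."""
    rejections = 0
    n_rep = 40
    for rep in range(n_rep):
        rng = np.random.default_rng(1000 + rep)
        rows = [
            dict(sno_id=c.copy_id, target_gene="G")
            for c in locus.copies
            for _ in range(int(rng.poisson(2.0)))
        ]
        fc = st.family_contrast(pd.DataFrame(rows), locus)
        rejections += fc.family_p < 0.05
    assert rejections <= 6  # ~2 expected at the 5% level over 40 replicates
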