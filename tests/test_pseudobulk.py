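"""Resampled pseudobulking, the NB Wald engine (with an independent
reference implementation as oracle), signature construction and Wilcoxon
markers."""

import itertools
import zlib

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from homingtrack import (
    PseudobulkConfig,
    PseudobulkTable,
    build_signature,
    nb_wald_dge,
    normalize_rna,
    rank_markers_wilcoxon,
    resample_pseudobulk,
)
from homingtrack.pseudobulk import filter_markers, size_factors_median_of_ratios
from .conftest import make_cells


def _paired_cells(counts_by_sample, cluster="T09"):
    rows, samples, donors, groups, clusters = [], [], [], [], []
    for sample, counts in counts_by_sample.items():
        donor, group = sample.rsplit("_", 1)
        for row in counts:
            rows.append(row)
            samples.append(sample)
            donors.append(donor)
            groups.append(group)
            clusters.append(cluster)
    return make_cells(np.array(rows), samples, donors, groups, clusters)


def test_resample_single_cell_sample():
    """With one available cell, the pseudobulk is n_fixed x its counts."""
    data = {
        "d1_treated": [[1, 2, 3]],
        "d1_untreated": [[2, 0, 1], [4, 1, 0]],
    }
    cells = _paired_cells(data)
    tab = resample_pseudobulk(cells, PseudobulkConfig(cluster="T09", n_fixed=10, seed=0))
    assert tab.counts["d1_treated"].tolist() == [10, 20, 30]


def test_resample_deterministic_and_hand_traced():
    data = {
        "d1_treated": [[1, 0, 0], [0, 1, 0], [0, 0, 1]],
        "d1_untreated": [[5, 5, 5]],
    }
    cells = _paired_cells(data)
    cfg = PseudobulkConfig(cluster="T09", n_fixed=7, seed=11)
    tab1 = resample_pseudobulk(cells, cfg)
    tab2 = resample_pseudobulk(cells, cfg)
    pd.testing.assert_frame_equal(tab1.counts, tab2.counts)
    # replay the documented per-sample stream: rng keyed by (seed, crc32(sample))
    rng = np.random.default_rng([11, zlib.crc32(b"d1_treated")])
    draws = rng.integers(0, 3, size=7)
    expected = np.zeros(3, int)
    for d in draws:
        expected[d] += 1  # cell i has a single UMI of gene i
    assert tab1.counts["d1_treated"].tolist() == expected.tolist()


def test_resample_keyed_streams_stable_under_new_samples():
    """Adding a sample does not change any other sample's pseudobulk."""
    data = {
        "d1_treated": [[1, 2, 0], [0, 1, 1]],
        "d1_untreated": [[3, 0, 1], [1, 1, 1]],
    }
    cells_a = _paired_cells(data)
    data2 = dict(data)
    data2["d2_treated"] = [[9, 9, 9]]
    data2["d2_untreated"] = [[1, 0, 0]]
    cells_b = _paired_cells(data2)
    cfg = PseudobulkConfig(cluster="T09", n_fixed=13, seed=5)
    a = resample_pseudobulk(cells_a, cfg)
    b = resample_pseudobulk(cells_b, cfg)
    pd.testing.assert_series_equal(a.counts["d1_treated"], b.counts["d1_treated"])


def test_resample_empty_sample_error():
    data = {"d1_treated": [[1, 2, 3]], "d1_untreated": [[1, 1, 1]]}
    cells = _paired_cells(data)
    with pytest.raises(ValueError, match="d1_untreated"):
        resample_pseudobulk(cells, PseudobulkConfig(cluster="OTHER", n_fixed=5))
    # only one sample lacks cells of the cluster
    mixed = make_cells(
        np.ones((3, 2)),
        ["d1_treated", "d1_untreated", "d1_untreated"],
        ["d1"] * 3, ["treated", "untreated", "untreated"],
        ["T09", "T09", "C01"],
    )
    resample_pseudobulk(mixed, PseudobulkConfig(cluster="T09", n_fixed=3))  # fine
    with pytest.raises(ValueError, match="d1_treated"):
        resample_pseudobulk(mixed, PseudobulkConfig(cluster="C01", n_fixed=3))


def test_size_factors_hand_computed():
    counts = pd.DataFrame(
        {"s1": [10, 100, 20], "s2": [20, 200, 40], "s3": [5, 50, 10], "s4": [10, 100, 20]},
        index=["g1", "g2", "g3"],
    )
    sf = size_factors_median_of_ratios(counts)
    # every gene gives the same ratio per column, so the median equals it
    mat = counts.to_numpy(float)
    geo = np.exp(np.log(mat).mean(axis=1))
    expected = np.median(mat / geo[:, None], axis=0)
    np.testing.assert_allclose(sf.to_numpy(), expected, rtol=1e-12)
    # exact scalar column multiples are recovered (up to normalization)
    ratio = sf["s2"] / sf["s1"]
    assert ratio == pytest.approx(2.0)
    assert sf["s3"] / sf["s1"] == pytest.approx(0.5)


def _planted_table(seed=0, n_genes=150, n_de=20, lfc=1.0, n_donors=6):
    """Small pseudobulk table with NB noise and planted group effects."""
    rng = np.random.default_rng(seed)
    base = rng.gamma(2.0, 50.0, n_genes)
    samples, donor, group = [], [], []
    cols = {}
    de = np.zeros(n_genes)
    de[:n_de // 2] = lfc
    de[n_de // 2:n_de] = -lfc
    for d in range(n_donors):
        dsize = np.exp(rng.normal(0, 0.2))
        donor_eff = np.exp(rng.normal(0, 0.1, n_genes))
        for g, gname in ((0, "untreated"), (1, "treated")):
            mu = base * donor_eff * dsize * (2.0 ** (de * g))
            y = rng.poisson(rng.gamma(1 / 0.05, mu * 0.05))
            s = f"d{d}_{gname}"
            cols[s] = y
            samples.append(s)
            donor.append(f"d{d}")
            group.append(gname)
    counts = pd.DataFrame(cols, index=[f"g{i:03d}" for i in range(n_genes)])
    design = pd.DataFrame({"donor": donor, "group": group}, index=pd.Index(samples, name="sample"))
    truth = {f"g{i:03d}" for i in range(n_de)}
    return PseudobulkTable(counts, design), truth


def test_nb_wald_recovers_planted_genes():
    tab, truth = _planted_table(seed=3)
    res = nb_wald_dge(tab)
    hits = set(res.index[res["padj"] <= 0.1])
    sens = len(hits & truth) / len(truth)
    fdr = len(hits - truth) / max(len(hits), 1)
    assert sens >= 0.8
    # this toy plants gene-specific donor interactions the donor factor
    # cannot absorb, so the Wald test runs somewhat liberal here
    assert fdr <= 0.3
    # signs of planted effects
    up = [g for g in truth if res.loc[g, "log2fc"] > 0]
    assert 8 <= len(up) <= 12  # 10 planted up


def test_nb_wald_agrees_with_reference_engine():
    """Independent cross-check: log2 fold changes track an established
    NB Wald implementation on the same table."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    tab, truth = _planted_table(seed=9, n_genes=120)
    res = nb_wald_dge(tab)
    meta = tab.design.copy()
    dds = DeseqDataSet(
        counts=tab.counts.T, metadata=meta, design="~donor + group", quiet=True
    )
    dds.deseq2()
    st = DeseqStats(dds, contrast=["group", "treated", "untreated"], quiet=True)
    st.summary()
    ref = st.results_df
    common = res.index.intersection(ref.index)
    r = np.corrcoef(res.loc[common, "log2fc"], ref.loc[common, "log2FoldChange"])[0, 1]
    assert r > 0.95
    ours = set(res.index[res["padj"] <= 0.1])
    theirs = set(ref.index[ref["padj"] <= 0.1])
    jac = len(ours & theirs) / max(len(ours | theirs), 1)
    assert jac >= 0.6


def test_nb_wald_design_errors_and_zero_genes():
    tab, _ = _planted_table(seed=1, n_genes=40)
    # all-zero gene excluded but reported
    counts = tab.counts.copy()
    counts.loc["gzero"] = 0
    res = nb_wald_dge(PseudobulkTable(counts, tab.design))
    assert "gzero" not in res.index
    assert res.attrs["excluded_genes"] == ["gzero"]
    # incomplete blocks rejected
    bad_design = tab.design.copy()
    bad_design.loc[bad_design.index[0], "donor"] = "dX"
    with pytest.raises(ValueError, match="block|rank"):
        nb_wald_dge(PseudobulkTable(tab.counts, bad_design))


def test_build_signature_rules():
    dge = pd.DataFrame(
        {
            "log2fc": [1.0, -0.5, 0.2, -0.1, 0.0, 2.0],
            "p": [0.001, 0.04, 0.5, 0.6, 0.001, 0.2],
            "padj": [0.09, 0.30, 0.9, 0.95, 0.02, 0.04],
        },
        index=["up_padj", "down_p", "null1", "null2", "zero_fc", "up_padj2"],
    )
    sig = build_signature(dge)
    assert "up_padj" in sig.positive      # padj 0.09 <= 0.1
    assert "down_p" in sig.negative       # p 0.04 <= 0.05 despite padj 0.3
    assert "null1" not in sig.genes and "null2" not in sig.genes
    assert "zero_fc" not in sig.genes     # zero log2fc excluded
    # empty side -> error
    only_up = dge.drop(["down_p"])
    with pytest.raises(ValueError, match="side empty"):
        build_signature(only_up)


def test_signature_size_under_uniform_null():
    """With uniform p-values and no small padj, the p <= 0.05 rule admits
    about 5% of genes."""
    rng = np.random.default_rng(0)
    n = 4000
    p = rng.uniform(size=n)
    from statsmodels.stats.multitest import multipletests

    padj = multipletests(p, method="fdr_bh")[1]
    dge = pd.DataFrame({"log2fc": rng.normal(size=n), "p": p, "padj": padj},
                       index=[f"g{i}" for i in range(n)])
    sig = build_signature(dge)
    n_sig = len(sig.positive) + len(sig.negative)
    # binomial 4-sigma band around 0.05 * n (padj <= 0.1 adds none under this null)
    assert abs(n_sig - 0.05 * n) < 4 * np.sqrt(n * 0.05 * 0.95) + (padj <= 0.1).sum()


def _marker_cells(t_vals, r_vals):
    vals = np.concatenate([t_vals, r_vals])[:, None].astype(float)
    n_t, n_r = len(t_vals), len(r_vals)
    cells = make_cells(
        np.hstack([vals, np.ones_like(vals)]),
        ["s"] * (n_t + n_r), ["d"] * (n_t + n_r), ["g"] * (n_t + n_r),
        ["T"] * n_t + ["R"] * n_r,
    )
    return cells


def test_wilcoxon_constant_gene_p1():
    cells = _marker_cells([3, 3, 3], [3, 3, 3])
    norm_vals = cells.counts.toarray().astype(float)
    from homingtrack.containers import NormalizedMatrix

    norm = NormalizedMatrix(norm_vals, cells.genes, cells.cell_ids, "log-CPM")
    res = rank_markers_wilcoxon(norm, cells, "T")
    assert (res["p"] == 1.0).all()


def test_wilcoxon_matches_exact_enumeration():
    """Complete separation, 6 vs 6: p equals the exact permutation value."""
    t_vals = [10, 11, 12, 13, 14, 15]
    r_vals = [1, 2, 3, 4, 5, 6]
    cells = _marker_cells(t_vals, r_vals)
    from homingtrack.containers import NormalizedMatrix

    norm = NormalizedMatrix(cells.counts.toarray().astype(float), cells.genes,
                            cells.cell_ids, "log-CPM")
    res = rank_markers_wilcoxon(norm, cells, "T")
    # brute-force enumeration of the rank-sum null over all 12C6 splits
    pooled = np.array(t_vals + r_vals, float)
    ranks = stats.rankdata(pooled)
    obs = ranks[:6].sum()
    null = [sum(c) for c in itertools.combinations(ranks, 6)]
    mean = np.mean(null)
    p_exact = np.mean([abs(s - mean) >= abs(obs - mean) - 1e-9 for s in null])
    assert res["p"].iloc[0] == pytest.approx(p_exact, rel=1e-9)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_wilcoxon_exact_agreement_random_small_groups(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = 5, 7
    t_vals = rng.normal(12, 1, n1)
    r_vals = rng.normal(10, 1, n2)
    cells = _marker_cells(t_vals, r_vals)
    from homingtrack.containers import NormalizedMatrix

    norm = NormalizedMatrix(cells.counts.toarray().astype(float), cells.genes,
                            cells.cell_ids, "log-CPM")
    res = rank_markers_wilcoxon(norm, cells, "T")
    ref = stats.mannwhitneyu(t_vals, r_vals, alternative="two-sided", method="exact")
    assert res["p"].iloc[0] == pytest.approx(ref.pvalue, rel=1e-12)


def test_marker_logfc_and_filter(effect_cohort):
    """Planted up-genes in the homing cluster pass the padj/logFC marker
    filter against the other clusters for treated samples."""
    _, (cells, _, truth) = effect_cohort
    treated = cells.subset_cells((cells.obs["group"] == "treated").to_numpy())
    norm = normalize_rna(treated)
    res = rank_markers_wilcoxon(norm, treated, truth.homing_cluster_id)
    picked = filter_markers(res, padj_max=0.1, logfc_min=0.3)
    up = set(truth.de_genes_up)
    # planted 2-fold genes are strong markers of the treated homing cluster
    assert len(up & set(picked.index)) / len(up) >= 0.5
    assert (picked["logfc"] > 0.3).all()
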