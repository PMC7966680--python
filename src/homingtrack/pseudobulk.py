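"""Fixed-n resampled pseudobulking and negative-binomial differential
expression.

Per-sample cell matrices for one cluster are first resampled with
replacement to a fixed cell number (default 1,558) before gene-wise
aggregation, so that differential-expression gene counts do not depend on
how many cells each sample happened to contribute. The aggregated table
is then tested gene-by-gene with a negative-binomial generalized linear
model (log link, blocking factor + group design) and a Wald test on the
group coefficient.

The NB engine follows the standard bulk RNA-seq recipe: median-of-ratios
size factors, per-gene method-of-moments dispersions estimated on GLM
residuals (rescaled by n/(n-p) so they are not biased low at
cohort-scale sample numbers) and shrunk toward a fitted mean-dispersion
trend, a normal-quantile Wald test, and BH adjustment across tested
genes. No outlier refitting or independent filtering is performed.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .containers import CellDataset, NormalizedMatrix, PseudobulkTable, SignatureSet

__all__ = [
    "PseudobulkConfig",
    "resample_pseudobulk",
    "size_factors_median_of_ratios",
    "nb_wald_dge",
    "build_signature",
    "rank_markers_wilcoxon",
]


@dataclass
class PseudobulkConfig:
    """Resampling setup: which cluster, how many cells to draw with
    replacement per sample, and the design factors carried along."""

    cluster: str
    n_fixed: int = 1558
    seed: int = 0
    blocking_factor: str = "donor"
    group_factor: str = "group"

    def __post_init__(self) -> None:
        if self.n_fixed <= 0:
            raise ValueError("n_fixed must be > 0")


def _sample_stream(seed: int, sample: str) -> np.random.Generator:
    # one stream per sample keyed by content, so adding/removing a sample
    # leaves the draws of all other samples untouched
    return np.random.default_rng([int(seed), zlib.crc32(str(sample).encode())])


def resample_pseudobulk(cells: CellDataset, cfg: PseudobulkConfig) -> PseudobulkTable:
    """Fixed-n with-replacement resampling, then gene-wise summation.

    Every sample must contribute at least one cell of the target cluster.
    """
    in_cluster = cells.obs["cluster"] == cfg.cluster
    sub = cells.subset_cells(in_cluster.to_numpy())
    all_samples = cells.obs.drop_duplicates("sample")
    have = set(sub.obs["sample"])
    empty = [s for s in all_samples["sample"] if s not in have]
    if empty:
        raise ValueError(
            f"samples with no cells in cluster {cfg.cluster!r}: {empty}"
        )
    cols = {}
    for sample, idx in sub.obs.groupby("sample", sort=False).indices.items():
        rng = _sample_stream(cfg.seed, sample)
        draw = rng.integers(0, len(idx), size=cfg.n_fixed)
        chosen = idx[draw]
        counts = np.asarray(sub.counts[chosen].sum(axis=0)).ravel()
        cols[sample] = counts
    counts = pd.DataFrame(cols, index=sub.genes)
    design = (
        sub.obs.drop_duplicates("sample")
        .set_index("sample")[[cfg.blocking_factor, cfg.group_factor]]
        .loc[counts.columns]
    )
    return PseudobulkTable(counts, design)


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with all-positive counts."""
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene has positive counts in every sample; cannot estimate size factors")
    logmat = np.log(mat[allpos])
    loggeo = logmat.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logmat - loggeo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _design_matrix(design: pd.DataFrame, blocking: str, group: str,
                   group_treated: str | None) -> tuple[np.ndarray, list[str], str]:
    levels = sorted(design[group].unique())
    if len(levels) != 2:
        raise ValueError(f"group factor must have exactly 2 levels, got {levels}")
    if group_treated is None:
        group_treated = "treated" if "treated" in levels else levels[-1]
    block_dummies = pd.get_dummies(design[blocking], drop_first=True, dtype=float)
    X = np.column_stack(
        [np.ones(len(design))]
        + [block_dummies[c].to_numpy() for c in block_dummies.columns]
        + [(design[group] == group_treated).to_numpy(dtype=float)]
    )
    names = ["intercept"] + [f"{blocking}:{c}" for c in block_dummies.columns] + [f"{group}:{group_treated}"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (incomplete blocks?)")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("not enough samples for the design (no residual degrees of freedom)")
    return X, names, group_treated


def _fit_nb_glm(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float,
                max_iter: int = 50, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """IRLS fit of an NB GLM with log link and known dispersion ``alpha``.

    Returns (beta, covariance of beta). Working weights are
    ``mu / (1 + alpha * mu)`` (canonical NB2 Fisher information).
    """
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean() / np.exp(offset).mean(), 1e-8))
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * w
        A = XtW @ X
        b = XtW @ z
        try:
            new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq(A, b, rcond=None)[0]
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    eta = np.clip(X @ beta + offset, -30, 30)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    A = (X.T * w) @ X
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(A)
    return beta, cov


def _dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Fit the parametric trend ``alpha(mu) = a0 + a1/mu`` by least squares
    on informative genes and evaluate it at every gene's mean."""
    ok = (alpha > 1e-6) & (mu > 0)
    if ok.sum() < 10:
        return np.full_like(mu, max(np.median(alpha[mu > 0]) if (mu > 0).any() else 1e-6, 1e-6))
    A = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(A, alpha[ok], rcond=None)
    a0, a1 = np.maximum(coef, 0.0)
    if a0 == 0 and a1 == 0:
        a0 = max(np.median(alpha[ok]), 1e-6)
    return a0 + a1 / np.maximum(mu, 1e-8)


def nb_wald_dge(
    tab: PseudobulkTable,
    *,
    group_treated: str | None = None,
    min_dispersion: float = 1e-8,
    max_dispersion: float = 10.0,
) -> pd.DataFrame:
    """Negative-binomial Wald differential expression on a pseudobulk table.

    Returns one row per tested gene: ``baseMean`` (mean of size-factor
    normalized counts), ``log2fc`` and its standard error for the group
    coefficient, the Wald ``stat``, ``p`` and BH-adjusted ``padj``.
    All-zero genes are excluded and listed in ``result.attrs["excluded_genes"]``.
    """
    counts = tab.counts
    design = tab.design
    blocking, group = design.columns[0], design.columns[1]
    X, names, group_treated = _design_matrix(design, blocking, group, group_treated)
    per_block = design.groupby(blocking)[group].nunique()
    if (per_block < 2).any():
        raise ValueError(
            f"incomplete blocks (levels of {blocking!r} missing a group): "
            f"{per_block[per_block < 2].index.tolist()}"
        )

    sf = size_factors_median_of_ratios(counts)
    offset = np.log(sf.to_numpy())
    mat = counts.to_numpy(dtype=float)
    nonzero = mat.sum(axis=1) > 0
    excluded = counts.index[~nonzero].tolist()
    mat = mat[nonzero]
    gene_names = counts.index[nonzero]

    q = mat / sf.to_numpy()[None, :]
    base_mean = q.mean(axis=1)
    n, p = X.shape
    df_resid = n - p

    # Pass 1: Poisson fit (alpha ~ 0) to get design-adjusted fitted means,
    # then method-of-moments dispersion from Pearson-type residuals.
    alpha_mom = np.empty(len(mat))
    mus = np.empty_like(mat)
    # residual variance is deflated by the fitted design; rescale by
    # n/(n-p) so the moment estimator is not biased low at small n
    infl = n / df_resid
    for i, y in enumerate(mat):
        beta, _ = _fit_nb_glm(y, X, offset, alpha=1e-8)
        mu = np.exp(np.clip(X @ beta + offset, -30, 30))
        mus[i] = mu
        num = (infl * (y - mu) ** 2 - mu).sum()
        den = (mu ** 2).sum()
        alpha_mom[i] = num / den if den > 0 else min_dispersion
    alpha_gene = np.clip(alpha_mom, min_dispersion, max_dispersion)
    trend = np.clip(_dispersion_trend(base_mean, alpha_gene), min_dispersion, max_dispersion)
    # shrink on the log scale halfway toward the trend
    alpha_final = np.exp(0.5 * np.log(alpha_gene) + 0.5 * np.log(trend))
    alpha_final = np.clip(alpha_final, min_dispersion, max_dispersion)

    coef_idx = len(names) - 1
    log2fc = np.empty(len(mat))
    se = np.empty(len(mat))
    for i, y in enumerate(mat):
        beta, cov = _fit_nb_glm(y, X, offset, alpha=float(alpha_final[i]))
        log2fc[i] = beta[coef_idx] / np.log(2.0)
        se[i] = np.sqrt(max(cov[coef_idx, coef_idx], 0.0)) / np.log(2.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / se, np.nan)
    pvals = 2.0 * stats.norm.sf(np.abs(stat))
    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "p": pvals,
            "dispersion": alpha_final,
        },
        index=gene_names,
    )
    tested = out["p"].notna()
    out["padj"] = np.nan
    if tested.any():
        out.loc[tested, "padj"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out.attrs["excluded_genes"] = excluded
    out.attrs["size_factors"] = sf.to_dict()
    out.attrs["design_columns"] = names
    out.attrs["group_treated"] = group_treated
    out.attrs["df_resid"] = df_resid
    return out


def build_signature(
    dge: pd.DataFrame, padj_max: float = 0.1, p_max: float = 0.05, name: str = "signature"
) -> SignatureSet:
    """Split differential genes into a bidirectional signature.

    A gene enters the signature when ``padj <= padj_max`` or (for gene-set
    use) its unadjusted ``p <= p_max``; the side is the sign of ``log2fc``
    and exact-zero fold changes are excluded. Raises if either side comes
    out empty, because the AUC ratio is undefined then.
    """
    sel = dge[(dge["padj"] <= padj_max) | (dge["p"] <= p_max)]
    pos = sel.index[sel["log2fc"] > 0].tolist()
    neg = sel.index[sel["log2fc"] < 0].tolist()
    if not pos or not neg:
        raise ValueError(
            f"signature side empty (n_up={len(pos)}, n_down={len(neg)}); "
            "AUC ratio would be undefined"
        )
    return SignatureSet(name=name, positive=pos, negative=neg)


def _wilcoxon_gene(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)


def rank_markers_wilcoxon(
    norm: NormalizedMatrix,
    cells: CellDataset,
    target_cluster: str,
    reference=None,
) -> pd.DataFrame:
    """Cluster marker genes by two-sided Wilcoxon rank-sum test.

    ``reference`` is a set of cluster labels (default: all other clusters).
    Small untied groups use the exact rank-sum distribution; otherwise the
    normal approximation with tie correction applies. ``logfc`` is the
    natural-log ratio of (mean de-logged expression + 1) between target and
    reference, the legacy single-cell convention under which a marker
    filter like ``logfc > 0.3`` is meaningful.
    """
    labels = cells.obs["cluster"]
    t_mask = (labels == target_cluster).to_numpy()
    if reference is None:
        r_mask = ~t_mask
    else:
        r_mask = labels.isin(set(reference)).to_numpy() & ~t_mask
    if not t_mask.any() or not r_mask.any():
        raise ValueError("target or reference cluster has no cells")

    vals = norm.values
    dense_t = vals[t_mask].toarray() if sparse.issparse(vals) else np.asarray(vals)[t_mask]
    dense_r = vals[r_mask].toarray() if sparse.issparse(vals) else np.asarray(vals)[r_mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pvals = np.array([
            _wilcoxon_gene(dense_t[:, j], dense_r[:, j]) for j in range(dense_t.shape[1])
        ])
    mean_t = np.expm1(dense_t).mean(axis=0)
    mean_r = np.expm1(dense_r).mean(axis=0)
    logfc = np.log(mean_t + 1.0) - np.log(mean_r + 1.0)
    out = pd.DataFrame({"logfc": logfc, "p": pvals}, index=norm.var_names)
    out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def filter_markers(markers: pd.DataFrame, padj_max: float = 0.1, logfc_min: float = 0.3) -> pd.DataFrame:
    """The downstream marker filter: significant (``padj <= padj_max``) and
    ``logfc > logfc_min``."""
    return markers[(markers["padj"] <= padj_max) & (markers["logfc"] > logfc_min)]
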