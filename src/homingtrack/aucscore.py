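"""Rank-recovery AUC scoring of bidirectional gene signatures.

For one expression profile (a cell, a pseudobulk or a spatial spot) genes
are ranked by decreasing expression, ties broken uniformly at random with
a per-unit seeded stream. The recovery curve of a gene set counts how
many set members appear within the top ``r`` ranks for ``r = 1..k`` with
``k = ceil(top_frac * n_genes)``; the AUC is the area under that curve
normalized by the ideal curve in which set genes occupy the very top
ranks, so it lies in [0, 1]. The enrichment statistic for a signature is
the ratio ``AUC(positive set) / AUC(negative set)``: a profile that
expresses the up-genes highly and the down-genes weakly scores high. The
negative-set AUC is floored at ``eps`` to keep the ratio finite; floored
ratios are flagged as capped.

Group comparisons average the per-cell ratio over a fixed-size draw of
cells per sample (default 150, samples with fewer are excluded) and
t-test across samples, with matched-size random signatures as a negative
control.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .containers import CellDataset, SignatureSet

__all__ = [
    "CompareConfig",
    "rank_genes",
    "recovery_auc",
    "score_profiles",
    "random_control_signature",
    "compare_enrichment",
    "pseudobulk_enrichment",
    "adjust_tests",
]

DEFAULT_TOP_FRAC = 0.05
EPS_NEG_AUC = 1e-6


@dataclass
class CompareConfig:
    """Setup for the per-sample subsampled group comparison."""

    n_cells_per_sample: int = 150
    paired: bool = False
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_sample <= 0:
            raise ValueError("n_cells_per_sample must be > 0")


def _unit_stream(seed: int, unit) -> np.random.Generator:
    return np.random.default_rng([int(seed), zlib.crc32(str(unit).encode())])


def rank_genes(values, seed: int = 0) -> np.ndarray:
    """Ranks (1 = highest expression) per profile, random tie-break.

    ``values`` is one profile (1-D) or a units x genes matrix (dense or
    sparse). Ties — notably the zero block — are permuted uniformly at
    random using a stream keyed by ``(seed, profile content)``: scoring a
    unit depends on nothing but its own expression vector and the seed,
    so identical profiles rank identically wherever they appear (a spot
    and a pseudobulk with the same counts score bit-identically) while
    different profiles get independent tie-break streams.
    """
    one_d = np.ndim(values) == 1 and not sparse.issparse(values)
    if one_d:
        mat = np.asarray(values, dtype=float)[None, :]
    else:
        mat = values.toarray() if sparse.issparse(values) else np.asarray(values, dtype=float)
    mat = np.ascontiguousarray(mat, dtype=np.float64)
    n_units, n_genes = mat.shape
    ranks = np.empty((n_units, n_genes), dtype=np.int64)
    arange = np.arange(1, n_genes + 1)
    for i in range(n_units):
        row = mat[i]
        tiebreak = np.random.default_rng(
            [int(seed), zlib.crc32(row.tobytes())]
        ).random(n_genes)
        order = np.lexsort((tiebreak, -row))
        ranks[i, order] = arange
    return ranks[0] if one_d else ranks


def _top_k(n_genes: int, top_frac: float) -> int:
    # epsilon guards the ceil against float artifacts (0.7 * 10 -> 7.0000000000000009)
    k = math.ceil(top_frac * n_genes - 1e-9)
    if k < 1:
        raise ValueError("top_frac too small: top-rank window is empty")
    return min(k, n_genes)


def recovery_auc(ranks: np.ndarray, set_idx, top_frac: float = DEFAULT_TOP_FRAC) -> np.ndarray | float:
    """Normalized recovery-curve AUC of one gene set.

    ``ranks`` is a rank vector (or units x genes matrix) from
    :func:`rank_genes`; ``set_idx`` are column indices of the set genes.
    The ideal curve places the set genes at ranks 1, 2, ...; the AUC is the
    ratio of curve areas, 1 iff all reachable set genes occupy the top
    ranks and 0 iff none falls within the top-``k`` window.
    """
    set_idx = np.asarray(set_idx, dtype=int)
    if set_idx.size == 0:
        raise ValueError("empty gene set")
    one_d = ranks.ndim == 1
    r = ranks[None, :] if one_d else ranks
    n_genes = r.shape[1]
    k = _top_k(n_genes, top_frac)
    m = min(set_idx.size, k)
    ideal = m * (m + 1) // 2 + m * (k - m)
    sr = r[:, set_idx]
    contrib = np.where(sr <= k, k - sr + 1, 0)
    auc = contrib.sum(axis=1) / ideal
    return float(auc[0]) if one_d else auc


def _signature_indices(genes: pd.Index, sig: SignatureSet) -> tuple[np.ndarray, np.ndarray]:
    pos = genes.get_indexer(pd.Index(sig.positive))
    neg = genes.get_indexer(pd.Index(sig.negative))
    n_miss = int((pos < 0).sum() + (neg < 0).sum())
    if n_miss:
        warnings.warn(
            f"signature {sig.name!r}: {n_miss} gene(s) absent from the universe were dropped",
            stacklevel=3,
        )
    pos, neg = pos[pos >= 0], neg[neg >= 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            f"signature {sig.name!r}: a side has no genes left in the universe"
        )
    return pos, neg


def score_profiles(
    values,
    genes: pd.Index,
    sig: SignatureSet,
    *,
    top_frac: float = DEFAULT_TOP_FRAC,
    seed: int = 0,
    ids=None,
    eps: float = EPS_NEG_AUC,
) -> pd.DataFrame:
    """AUC-ratio enrichment of one signature across profiles.

    Returns a frame indexed by unit id with ``auc_pos``, ``auc_neg``,
    ``auc_ratio`` and a ``capped`` flag marking ratios floored at
    ``auc_neg = eps``.
    """
    genes = pd.Index(genes)
    pos_idx, neg_idx = _signature_indices(genes, sig)
    ranks = rank_genes(values, seed=seed)
    if ranks.ndim == 1:
        ranks = ranks[None, :]
        if ids is None:
            ids = [0]
    auc_pos = np.atleast_1d(recovery_auc(ranks, pos_idx, top_frac))
    auc_neg = np.atleast_1d(recovery_auc(ranks, neg_idx, top_frac))
    capped = auc_neg < eps
    ratio = auc_pos / np.maximum(auc_neg, eps)
    index = pd.Index(list(ids) if ids is not None else range(len(auc_pos)), name="unit")
    out = pd.DataFrame(
        {"auc_pos": auc_pos, "auc_neg": auc_neg, "auc_ratio": ratio, "capped": capped},
        index=index,
    )
    out.attrs["top_frac"] = top_frac
    out.attrs["seed"] = seed
    out.attrs["signature"] = sig.name
    return out


def random_control_signature(sig: SignatureSet, universe, seed: int = 0) -> SignatureSet:
    """Matched-size random control: uniform draws (without replacement)
    from the universe excluding the signature's own genes."""
    universe = pd.Index(universe)
    pool = universe.difference(pd.Index(sorted(sig.genes))).to_numpy()
    n_pos, n_neg = len(sig.positive), len(sig.negative)
    if len(pool) < n_pos + n_neg:
        raise ValueError("universe too small for a matched-size random control")
    rng = np.random.default_rng([int(seed), zlib.crc32(sig.name.encode())])
    drawn = rng.choice(pool, size=n_pos + n_neg, replace=False)
    return SignatureSet(
        name=f"{sig.name}_random_control",
        positive=list(drawn[:n_pos]),
        negative=list(drawn[n_pos:]),
    )


def compare_enrichment(
    scores: pd.DataFrame,
    cells: CellDataset,
    cluster: str,
    cfg: CompareConfig,
    *,
    group_treated: str = "treated",
    group_control: str = "untreated",
) -> tuple[pd.DataFrame, dict]:
    """Group comparison of per-sample mean AUC ratios in one cluster.

    From each sample, ``n_cells_per_sample`` cluster cells are drawn
    without replacement (samples with fewer cells are excluded) and their
    AUC ratios averaged; sample means are compared with a two-tailed
    t-test, paired across donors or unpaired per the config.
    """
    obs = cells.obs
    in_cluster = obs[obs["cluster"] == cluster]
    per_sample_rows = []
    for sample, sub in in_cluster.groupby("sample", sort=False):
        if len(sub) < cfg.n_cells_per_sample:
            continue
        rng = _unit_stream(cfg.seed, f"compare:{sample}")
        chosen = rng.choice(sub.index.to_numpy(), size=cfg.n_cells_per_sample, replace=False)
        mean_ratio = float(scores.loc[chosen, "auc_ratio"].mean())
        info = sub.iloc[0]
        per_sample_rows.append((sample, info["donor"], info["group"], len(sub), mean_ratio))
    per_sample = pd.DataFrame(
        per_sample_rows, columns=["sample", "donor", "group", "n_cells", "mean_ratio"]
    )
    a = per_sample[per_sample["group"] == group_treated]
    b = per_sample[per_sample["group"] == group_control]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"fewer than 2 samples per group after the {cfg.n_cells_per_sample}-cell "
            f"exclusion rule (treated={len(a)}, control={len(b)})"
        )
    if cfg.paired:
        da = a.set_index("donor")["mean_ratio"].sort_index()
        db = b.set_index("donor")["mean_ratio"].sort_index()
        common = da.index.intersection(db.index)
        if len(common) < 2:
            raise ValueError("fewer than 2 complete donor pairs")
        t, p = stats.ttest_rel(da[common], db[common])
        n_pairs = int(len(common))
    else:
        t, p = stats.ttest_ind(a["mean_ratio"], b["mean_ratio"])
        n_pairs = None
    result = {
        "t": float(t),
        "p": float(p),
        "mean_treated": float(a["mean_ratio"].mean()),
        "mean_control": float(b["mean_ratio"].mean()),
        "n_treated": int(len(a)),
        "n_control": int(len(b)),
        "n_pairs": n_pairs,
        "paired": cfg.paired,
    }
    return per_sample, result


def adjust_tests(results: list[dict]) -> list[dict]:
    """BH adjustment across a family of comparison results (adds ``padj``)."""
    ps = [r["p"] for r in results]
    padj = multipletests(ps, method="fdr_bh")[1] if results else []
    out = []
    for r, q in zip(results, padj):
        r = dict(r)
        r["padj"] = float(q)
        out.append(r)
    return out


def pseudobulk_enrichment(
    cells: CellDataset,
    sig: SignatureSet,
    *,
    min_cells: int = 20,
    min_samples: int = 3,
    top_frac: float = DEFAULT_TOP_FRAC,
    seed: int = 0,
    eps: float = EPS_NEG_AUC,
) -> pd.DataFrame:
    """Signature enrichment of per-(sample, cluster) pseudobulk profiles.

    Counts are summed per sample-cluster combination; combinations with
    fewer than ``min_cells`` cells and clusters left with fewer than
    ``min_samples`` samples are excluded.
    """
    obs = cells.obs
    groups = obs.groupby(["sample", "cluster"], sort=False).indices
    kept = {key: idx for key, idx in groups.items() if len(idx) >= min_cells}
    per_cluster: dict[str, int] = {}
    for (_, c) in kept:
        per_cluster[c] = per_cluster.get(c, 0) + 1
    kept = {k: v for k, v in kept.items() if per_cluster[k[1]] >= min_samples}
    if not kept:
        raise ValueError("all sample-cluster combinations excluded by the 20-cell/3-sample rules")

    keys = list(kept)
    profiles = np.vstack([
        np.asarray(cells.counts[idx].sum(axis=0)).ravel() for idx in kept.values()
    ])
    ids = [f"{s}|{c}" for s, c in keys]
    scored = score_profiles(
        profiles, cells.genes, sig, top_frac=top_frac, seed=seed, ids=ids, eps=eps
    )
    meta = pd.DataFrame(keys, columns=["sample", "cluster"])
    meta["n_cells"] = [len(idx) for idx in kept.values()]
    out = pd.concat([meta, scored.reset_index(drop=True)], axis=1)
    out.attrs.update(scored.attrs)
    return out
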