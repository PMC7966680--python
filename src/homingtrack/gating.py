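"""Surface-marker gating and paired frequency-shift testing.

Cells are called double-positive (VLA-4+, i.e. ITGA4+/ITGB1+) when both
CLR-normalized marker values exceed their thresholds; thresholds can be
set manually or derived automatically as the midpoint between the two
component means of a 1-D two-component Gaussian mixture per marker.
Per-cluster double-positive frequencies are then compared between paired
treated/untreated samples with one-sample t-tests on the per-donor
frequency differences, BH-adjusted across clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CellDataset, NormalizedMatrix

__all__ = [
    "GateDefinition",
    "GatingError",
    "gate_double_positive",
    "frequency_table",
    "paired_frequency_shift",
    "gene_mean_group_test",
]


class GatingError(ValueError):
    pass


@dataclass
class GateDefinition:
    """A 2-D rectangular gate on CLR-scale marker values; thresholds may be
    floats or the string ``"auto"``."""

    marker_x: str = "ITGA4"
    marker_y: str = "ITGB1"
    threshold_x: float | str = "auto"
    threshold_y: float | str = "auto"


def auto_threshold(
    values: np.ndarray, min_separation: float = 0.5, seed: int = 0, max_fit: int = 20_000
) -> float:
    """Midpoint between the two component means of a 1-D two-component
    Gaussian mixture fit. Raises :class:`GatingError` when the components
    are closer than ``min_separation`` (effectively unimodal data).
    Fitting uses at most ``max_fit`` values (seeded subsample) — the
    threshold is a two-parameter summary, so this loses nothing."""
    from sklearn.mixture import GaussianMixture

    x = np.asarray(values, dtype=float)
    if x.size > max_fit:
        x = np.random.default_rng(seed).choice(x, size=max_fit, replace=False)
    x = x.reshape(-1, 1)
    gm = GaussianMixture(n_components=2, n_init=3, random_state=seed).fit(x)
    m = np.sort(gm.means_.ravel())
    if m[1] - m[0] < min_separation:
        raise GatingError(
            f"mixture means separated by only {m[1]-m[0]:.3f} (< {min_separation}); "
            "data look unimodal - supply a manual threshold"
        )
    return float(m.mean())


def gate_double_positive(
    adt_clr: NormalizedMatrix, gate: GateDefinition, *, min_separation: float = 0.5
) -> pd.Series:
    """Per-cell double-positive flag: value above threshold on both markers."""
    if adt_clr.method != "CLR":
        raise GatingError("gating expects CLR-normalized ADT values")
    flags = np.ones(len(adt_clr.obs_names), dtype=bool)
    thresholds = {}
    for marker, th in ((gate.marker_x, gate.threshold_x), (gate.marker_y, gate.threshold_y)):
        if marker not in adt_clr.var_names:
            raise GatingError(f"marker {marker!r} not in ADT panel")
        v = adt_clr.column(marker)
        t = auto_threshold(v, min_separation) if th == "auto" else float(th)
        thresholds[marker] = t
        flags &= v > t
    out = pd.Series(flags, index=adt_clr.obs_names, name="double_positive")
    out.attrs["thresholds"] = thresholds
    return out


def _pairing(tab: pd.DataFrame) -> None:
    """Validate that every donor has exactly one sample per group."""
    per_donor = tab.drop_duplicates("sample").groupby("donor")["group"].agg(["count", "nunique"])
    bad = per_donor[(per_donor["count"] != 2) | (per_donor["nunique"] != 2)]
    if len(bad):
        raise ValueError(f"donors without a complete treated/untreated pair: {bad.index.tolist()}")


def frequency_table(
    cells: CellDataset, flags: pd.Series, min_cells: int = 20, *, paired: bool = True
) -> pd.DataFrame:
    """Double-positive frequency per (sample, cluster).

    Combinations with fewer than ``min_cells`` cells are excluded together
    with the same cluster's row of the paired sample (same donor, other
    group), so every retained cluster keeps complete pairs.
    """
    if not flags.index.equals(cells.cell_ids):
        flags = flags.reindex(cells.cell_ids)
        if flags.isna().any():
            raise ValueError("gate flags missing for some cells")
    meta = cells.obs.copy()
    meta["dp"] = flags.to_numpy(dtype=bool)

    sample_info = meta.drop_duplicates("sample")[["sample", "donor", "group"]]
    if paired:
        _pairing(meta)

    # full sample x cluster grid: combinations with zero cells also count
    # as "< min_cells" and drag their paired rows out with them.
    clusters = meta["cluster"].unique()
    grid = pd.MultiIndex.from_product(
        [sample_info["sample"], clusters], names=["sample", "cluster"]
    )
    g = meta.groupby(["sample", "cluster"], sort=False).agg(
        n_cells=("dp", "size"), n_dp=("dp", "sum")
    )
    g = g.reindex(grid, fill_value=0).reset_index()
    g = g.merge(sample_info, on="sample")

    low = g["n_cells"] < min_cells
    if paired:
        bad_keys = set(zip(g.loc[low, "donor"], g.loc[low, "cluster"]))
        drop = [
            (d, c) in bad_keys for d, c in zip(g["donor"], g["cluster"])
        ]
        g = g[~np.asarray(drop)]
    else:
        g = g[~low]
    g = g.copy()
    g["freq"] = g["n_dp"] / g["n_cells"]
    return g[["sample", "donor", "group", "cluster", "n_cells", "n_dp", "freq"]].reset_index(drop=True)


def paired_frequency_shift(
    tab: pd.DataFrame,
    min_samples: int = 5,
    *,
    group_treated: str = "treated",
    group_control: str = "untreated",
) -> pd.DataFrame:
    """Per-cluster paired t-test on treated-minus-untreated frequencies.

    Clusters with fewer than ``min_samples`` complete donor pairs are
    excluded. Degenerate clusters (all deltas identical) are reported with
    NaN statistics and a warning instead of a sham p-value. BH adjustment
    runs across the tested clusters.
    """
    groups = set(tab["group"].unique())
    if not {group_treated, group_control} <= groups:
        raise ValueError(f"groups {group_treated!r}/{group_control!r} not found in table (has {sorted(groups)})")
    wide = tab.pivot_table(index=["donor", "cluster"], columns="group", values="freq")
    wide = wide.dropna(subset=[group_treated, group_control])
    wide["delta"] = wide[group_treated] - wide[group_control]

    rows = []
    for cluster, sub in wide.groupby(level="cluster", sort=False):
        deltas = sub["delta"].to_numpy()
        if len(deltas) < max(min_samples, 2):
            continue
        if np.ptp(deltas) == 0:
            warnings.warn(
                f"cluster {cluster}: all frequency deltas identical; t-test degenerate",
                stacklevel=2,
            )
            t = p = np.nan
        else:
            t, p = stats.ttest_1samp(deltas, 0.0)
        rows.append((cluster, len(deltas), float(deltas.mean()), t, p))
    out = pd.DataFrame(rows, columns=["cluster", "n_pairs", "mean_delta", "t", "p"])
    out["padj"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "padj"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


def gene_mean_group_test(
    norm: NormalizedMatrix,
    cells: CellDataset,
    genes,
    *,
    paired: bool = False,
    group_treated: str = "treated",
    group_control: str = "untreated",
) -> pd.DataFrame:
    """Direct test of differential expression on per-sample mean values.

    For each requested gene, the normalized expression is averaged per
    sample and compared between groups with a two-tailed t-test (paired
    across donors or unpaired), BH-adjusted over the tested genes.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in norm.var_names]
    if missing:
        raise ValueError(f"genes absent from normalized matrix: {missing}")
    obs = cells.obs
    rows = []
    for gene in genes:
        v = pd.Series(norm.column(gene), index=norm.obs_names)
        per_sample = v.groupby(obs["sample"]).mean()
        info = obs.drop_duplicates("sample").set_index("sample")
        a = per_sample[info["group"] == group_treated]
        b = per_sample[info["group"] == group_control]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 samples per group")
        if paired:
            da = a.rename(index=info["donor"].to_dict()).sort_index()
            db = b.rename(index=info["donor"].to_dict()).sort_index()
            common = da.index.intersection(db.index)
            t, p = stats.ttest_rel(da[common], db[common])
        else:
            t, p = stats.ttest_ind(a, b)
        rows.append((gene, float(a.mean()), float(b.mean()), float(t), float(p)))
    out = pd.DataFrame(rows, columns=["gene", "mean_treated", "mean_control", "t", "p"])
    out["padj"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else np.nan
    return out
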