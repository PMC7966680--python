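"""Synthetic multimodal cohorts and spatial sections with known ground truth.

The generator emulates the structure of a paired multi-donor CITE-seq
cohort: each donor contributes a treated and an untreated PBMC sample,
cells fall into transcriptionally distinct clusters, and one designated
"homing" cluster carries two planted, condition-dependent effects:

* a bidirectional expression signature — a set of genes whose means are
  multiplied by ``2**signature_log2fc`` (up genes) or ``2**-signature_log2fc``
  (down genes) in treated samples, and
* a shift in the fraction of cells double-positive for the two gating
  surface markers (ITGA4/ITGB1, the VLA-4 integrin subunits).

Counts are negative binomial with a mean/dispersion parameterization
(``var = mu + mu**2 * dispersion``), sampled as a gamma-Poisson mixture.
Per-cell library-size factors are log-normal, and a configurable fraction
of "damaged" cells over-expresses the mitochondrial genes, so the QC
filters downstream have realistic work to do.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import ADTMatrix, CellDataset, SignatureSet, SpotDataset

__all__ = [
    "CohortSimConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_spots",
    "make_section_profiles",
    "sample_nb",
    "write_fixture",
]


def sample_nb(mean, dispersion: float, size, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial counts with ``var = mu + mu^2 * dispersion``.

    Sampled as Poisson(Gamma(shape=1/dispersion, scale=mu*dispersion));
    ``dispersion == 0`` degenerates to Poisson.
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _stream(seed: int, *keys: str) -> np.random.Generator:
    """Independent RNG stream keyed by seed plus string labels (stable
    across platforms; adding one labelled stream never perturbs others)."""
    return np.random.default_rng([int(seed)] + [zlib.crc32(k.encode()) for k in keys])


@dataclass
class CohortSimConfig:
    """Study conditions for the synthetic cohort.

    ``cells_per_sample_range`` is the (min, max) of the uniform draw of
    cell numbers per (sample, cluster) combination. ``dp_freq_base`` is the
    double-positive fraction in every cluster; treated samples add
    ``dp_freq_shift`` in the homing cluster only.
    """

    n_donors: int = 8
    paired: bool = True
    n_clusters: int = 12
    cells_per_sample_range: tuple[int, int] = (400, 600)
    n_genes: int = 500
    n_adt: int = 6
    homing_cluster_id: str = "T09"
    n_signature_genes_up: int = 50
    n_signature_genes_down: int = 50
    signature_log2fc: float = 1.0
    dp_freq_base: float = 0.3
    dp_freq_shift: float = 0.2
    nb_mean_shape: float = 0.6
    nb_dispersion: float = 0.3
    seed: int = 0
    # secondary realism knobs
    mean_umi_per_cell: float = 2500.0
    cluster_lfc_sigma: float = 0.4
    size_factor_sigma: float = 0.3
    n_mito_genes: int = 10
    mito_base_share: float = 0.08
    damaged_frac: float = 0.05
    damaged_mito_frac: float = 0.35
    adt_pos_mean: float = 600.0
    adt_neg_mean: float = 30.0
    adt_dispersion: float = 0.25
    groups: tuple[str, str] = ("untreated", "treated")

    def __post_init__(self) -> None:
        counts = {
            "n_donors": self.n_donors,
            "n_clusters": self.n_clusters,
            "n_genes": self.n_genes,
            "n_adt": self.n_adt,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.cells_per_sample_range
        if not (0 < lo <= hi):
            raise ValueError("cells_per_sample_range must satisfy 0 < min <= max")
        if self.n_signature_genes_up + self.n_signature_genes_down > self.n_genes:
            raise ValueError("signature genes exceed the gene universe")
        if not (0.0 <= self.dp_freq_base <= 1.0):
            raise ValueError("dp_freq_base must be in [0, 1]")
        if not (0.0 <= self.dp_freq_base + self.dp_freq_shift <= 1.0):
            raise ValueError("dp_freq_base + dp_freq_shift must be in [0, 1]")
        if self.n_adt < 2:
            raise ValueError("need at least the two gating markers")
        if self.n_mito_genes >= self.n_genes:
            raise ValueError("n_mito_genes must be < n_genes")
        if not (0 <= self.damaged_frac < 1):
            raise ValueError("damaged_frac must be in [0, 1)")

    @property
    def cluster_ids(self) -> list[str]:
        others = [f"C{i:02d}" for i in range(1, self.n_clusters)]
        return [self.homing_cluster_id] + others


@dataclass
class GroundTruth:
    """Planted truth of a simulated cohort or section set."""

    de_genes_up: list[str] = field(default_factory=list)
    de_genes_down: list[str] = field(default_factory=list)
    homing_cluster_id: str | None = None
    dp_expected: pd.DataFrame | None = None  # per (sample, cluster): expected DP fraction
    dp_truth: pd.Series | None = None  # per cell: planted double-positive flag
    infiltrate_fraction: pd.Series | None = None  # per spot

    def __post_init__(self) -> None:
        if set(self.de_genes_up) & set(self.de_genes_down):
            raise ValueError("up/down truth gene lists must be disjoint")

    def to_dict(self) -> dict:
        d: dict = {
            "de_genes_up": list(self.de_genes_up),
            "de_genes_down": list(self.de_genes_down),
            "homing_cluster_id": self.homing_cluster_id,
        }
        if self.dp_expected is not None:
            d["dp_expected"] = self.dp_expected.reset_index().to_dict(orient="list")
        if self.dp_truth is not None:
            d["dp_truth"] = {"cell": self.dp_truth.index.tolist(),
                             "dp": self.dp_truth.astype(int).tolist()}
        if self.infiltrate_fraction is not None:
            d["infiltrate_fraction"] = {"spot": self.infiltrate_fraction.index.tolist(),
                                        "f": self.infiltrate_fraction.tolist()}
        return d


def _gene_names(cfg: CohortSimConfig) -> pd.Index:
    n_reg = cfg.n_genes - cfg.n_mito_genes
    names = [f"G{i:04d}" for i in range(n_reg)]
    names += [f"MT-{i:02d}" for i in range(cfg.n_mito_genes)]
    return pd.Index(names)


def _sample_table(cfg: CohortSimConfig) -> pd.DataFrame:
    donors = [f"D{i:02d}" for i in range(cfg.n_donors)]
    rows = []
    if cfg.paired:
        for d in donors:
            for g in cfg.groups:
                rows.append((f"{d}_{g}", d, g))
    else:
        half = cfg.n_donors // 2
        for i, d in enumerate(donors):
            g = cfg.groups[0] if i < half else cfg.groups[1]
            rows.append((f"{d}_{g}", d, g))
    return pd.DataFrame(rows, columns=["sample", "donor", "group"]).set_index("sample")


def simulate_cohort(cfg: CohortSimConfig) -> tuple[CellDataset, ADTMatrix, GroundTruth]:
    """Simulate a paired multi-donor cohort with a planted homing cluster.

    Returns the RNA counts, the surface-marker counts and the planted
    ground truth. Identical configs (including seed) give identical output.
    """
    genes = _gene_names(cfg)
    n_genes = cfg.n_genes
    rng_global = _stream(cfg.seed, "cohort")

    # Base gene weights: gamma-distributed, mitochondrial genes pinned to a
    # fixed share of the library so the mito filter has a stable baseline.
    w = rng_global.gamma(cfg.nb_mean_shape, 1.0, size=n_genes)
    is_mito = np.asarray(genes.str.startswith("MT-"))
    if is_mito.any():
        w_m = w[is_mito] / w[is_mito].sum() * cfg.mito_base_share
        w_r = w[~is_mito] / w[~is_mito].sum() * (1.0 - cfg.mito_base_share)
        w[is_mito] = w_m
        w[~is_mito] = w_r
    else:
        w = w / w.sum()
    base_mu = w * cfg.mean_umi_per_cell

    # Planted signature genes: drawn from the better-expressed non-mito
    # genes (detected signatures are, by construction, detectable genes).
    eligible = np.flatnonzero(~is_mito & (base_mu >= np.quantile(base_mu[~is_mito], 0.3)))
    n_sig = cfg.n_signature_genes_up + cfg.n_signature_genes_down
    if len(eligible) < n_sig:
        raise ValueError("not enough well-expressed genes for the requested signature size")
    sig_idx = rng_global.choice(eligible, size=n_sig, replace=False)
    up_idx = np.sort(sig_idx[: cfg.n_signature_genes_up])
    down_idx = np.sort(sig_idx[cfg.n_signature_genes_up :])

    # Per-cluster expression profiles, drawn once and shared across samples.
    clusters = cfg.cluster_ids
    cluster_mu = {}
    for c in clusters:
        lfc = _stream(cfg.seed, "cluster-profile", c).normal(0.0, cfg.cluster_lfc_sigma, size=n_genes)
        cluster_mu[c] = base_mu * np.exp2(lfc)

    effect = cfg.signature_log2fc != 0
    samples = _sample_table(cfg)
    treated_group = cfg.groups[1]

    counts_blocks: list[sparse.csr_matrix] = []
    obs_rows = []
    adt_blocks = []
    dp_expected_rows = []
    markers = ["ITGA4", "ITGB1"] + [f"ADT{i:02d}" for i in range(2, cfg.n_adt)]
    marker_pos_rate = _stream(cfg.seed, "adt-panel").uniform(0.15, 0.6, size=cfg.n_adt - 2)

    lo, hi = cfg.cells_per_sample_range
    ids_all: list[str] = []
    dp_all: list[np.ndarray] = []
    for sample, row in samples.iterrows():
        treated = row["group"] == treated_group
        rng = _stream(cfg.seed, "sample", str(sample))
        sample_blocks = []
        for c in clusters:
            n_cells = int(rng.integers(lo, hi + 1))
            mu = cluster_mu[c].copy()
            homing = c == cfg.homing_cluster_id
            if homing and treated and effect:
                mu[up_idx] *= 2.0 ** cfg.signature_log2fc
                mu[down_idx] *= 2.0 ** (-cfg.signature_log2fc)
            size_factors = np.exp(rng.normal(0.0, cfg.size_factor_sigma, size=n_cells))
            damaged = rng.random(n_cells) < cfg.damaged_frac
            mu_cells = size_factors[:, None] * mu[None, :]
            if damaged.any() and is_mito.any():
                # boost mito means so damaged cells hit ~damaged_mito_frac
                share = mu[is_mito].sum() / mu.sum()
                t = cfg.damaged_mito_frac
                k = t * (1 - share) / (share * (1 - t))
                mu_cells[np.ix_(damaged, is_mito)] *= k
            sample_blocks.append(
                sample_nb(mu_cells, cfg.nb_dispersion, mu_cells.shape, rng).astype(np.int32)
            )

            # surface markers
            p_dp = cfg.dp_freq_base + (cfg.dp_freq_shift if homing and treated else 0.0)
            dp = rng.random(n_cells) < p_dp
            gate_state = np.zeros((n_cells, 2), dtype=bool)
            gate_state[dp] = True
            non_dp = ~dp
            combo = rng.choice(3, size=int(non_dp.sum()), p=[0.6, 0.2, 0.2])
            gate_state[np.flatnonzero(non_dp)[combo == 1], 0] = True
            gate_state[np.flatnonzero(non_dp)[combo == 2], 1] = True
            other_pos = rng.random((n_cells, cfg.n_adt - 2)) < marker_pos_rate[None, :]
            pos = np.concatenate([gate_state, other_pos], axis=1)
            adt_mu = np.where(pos, cfg.adt_pos_mean, cfg.adt_neg_mean)
            adt_blocks.append(sample_nb(adt_mu, cfg.adt_dispersion, adt_mu.shape, rng).astype(np.int32))

            ids_all.extend(f"{sample}:{c}:c{i:04d}" for i in range(n_cells))
            dp_all.append(dp)
            obs_rows.append((sample, row["donor"], row["group"], c, n_cells))
            dp_expected_rows.append((sample, c, p_dp))
        counts_blocks.append(sparse.csr_matrix(np.concatenate(sample_blocks, axis=0)))

    obs = pd.DataFrame(
        {
            "sample": np.repeat([r[0] for r in obs_rows], [r[4] for r in obs_rows]),
            "donor": np.repeat([r[1] for r in obs_rows], [r[4] for r in obs_rows]),
            "group": np.repeat([r[2] for r in obs_rows], [r[4] for r in obs_rows]),
            "cluster": np.repeat([r[3] for r in obs_rows], [r[4] for r in obs_rows]),
        },
        index=pd.Index(ids_all, name="cell"),
    )
    cells = CellDataset(sparse.vstack(counts_blocks, format="csr"), genes, obs)
    adt = ADTMatrix(sparse.csr_matrix(np.concatenate(adt_blocks, axis=0)), pd.Index(markers), obs.index)
    truth = GroundTruth(
        de_genes_up=genes[up_idx].tolist() if effect else [],
        de_genes_down=genes[down_idx].tolist() if effect else [],
        homing_cluster_id=cfg.homing_cluster_id,
        dp_expected=pd.DataFrame(dp_expected_rows, columns=["sample", "cluster", "dp_freq"]).set_index(["sample", "cluster"]),
        dp_truth=pd.Series(np.concatenate(dp_all), index=obs.index),
    )
    return cells, adt, truth


def simulate_spots(
    n_spots: int,
    infiltrate_spots,
    infiltrate_fraction: float,
    t09_profile: pd.Series,
    background_profile: pd.Series,
    seed: int,
    *,
    dispersion: float = 0.3,
    section: str = "S1",
    condition: str = "disease",
) -> tuple[SpotDataset, GroundTruth]:
    """Simulate one spatial section as a grid of NB-sampled spots.

    Each spot's expected expression is ``(1-f)*background + f*t09`` with
    ``f = infiltrate_fraction`` for the designated infiltrate spots and 0
    otherwise. ``infiltrate_spots`` is either a count (spots chosen at
    random) or an explicit list of spot indices.
    """
    if not t09_profile.index.equals(background_profile.index):
        raise ValueError("t09 and background profiles must share the same gene universe")
    if not (0.0 <= infiltrate_fraction <= 1.0):
        raise ValueError("infiltrate_fraction must be in [0, 1]")
    rng = _stream(seed, "spots", section)
    if np.isscalar(infiltrate_spots):
        k = int(infiltrate_spots)
        if k > n_spots:
            raise ValueError("more infiltrate spots than spots")
        chosen = rng.choice(n_spots, size=k, replace=False)
    else:
        chosen = np.asarray(infiltrate_spots, dtype=int)
        if chosen.size and (chosen.min() < 0 or chosen.max() >= n_spots):
            raise ValueError("infiltrate spot index out of range")
    f = np.zeros(n_spots)
    f[chosen] = infiltrate_fraction

    bg = background_profile.to_numpy(dtype=float)
    t09 = t09_profile.to_numpy(dtype=float)
    mu = (1.0 - f)[:, None] * bg[None, :] + f[:, None] * t09[None, :]
    counts = sample_nb(mu, dispersion, mu.shape, rng)

    side = math.ceil(math.sqrt(n_spots))
    xs = np.arange(n_spots) % side
    ys = np.arange(n_spots) // side
    ids = [f"{section}:{x}x{y}" for x, y in zip(xs, ys)]
    obs = pd.DataFrame(
        {"section": section, "x": xs, "y": ys, "condition": condition},
        index=pd.Index(ids, name="spot"),
    )
    spots = SpotDataset(sparse.csr_matrix(counts), t09_profile.index, obs)
    truth = GroundTruth(infiltrate_fraction=pd.Series(f, index=obs.index))
    return spots, truth


def make_section_profiles(
    genes,
    seed: int,
    *,
    n_pos: int = 100,
    n_neg: int = 100,
    marker_log2fc: float = 4.0,
    depth: float = 5000.0,
) -> tuple[pd.Series, pd.Series, SignatureSet]:
    """Build a brain-background profile, an immune (homing-cell) profile and
    the signature distinguishing them.

    Positive signature genes are ``2**marker_log2fc``-fold higher in the
    immune profile than in background, negative genes the reverse —
    emulating cell-type marker contrasts, which are strong by nature.
    Both profiles are expected-count vectors summing to ``depth``.
    """
    genes = pd.Index(genes)
    rng = _stream(seed, "section-profiles")
    if n_pos + n_neg > len(genes):
        raise ValueError("signature larger than gene universe")
    w_bg = rng.gamma(0.6, 1.0, size=len(genes)) + 1e-9
    w_im = rng.gamma(0.6, 1.0, size=len(genes)) + 1e-9
    sig_idx = rng.choice(len(genes), size=n_pos + n_neg, replace=False)
    pos_idx, neg_idx = sig_idx[:n_pos], sig_idx[n_pos:]
    w_im[pos_idx] = w_bg[pos_idx] * 2.0 ** marker_log2fc
    w_im[neg_idx] = w_bg[neg_idx] * 2.0 ** (-marker_log2fc)
    background = pd.Series(w_bg / w_bg.sum() * depth, index=genes)
    t09 = pd.Series(w_im / w_im.sum() * depth, index=genes)
    sig = SignatureSet(
        name="t09_markers",
        positive=genes[np.sort(pos_idx)].tolist(),
        negative=genes[np.sort(neg_idx)].tolist(),
    )
    return background, t09, sig


def write_fixture(dataset, directory, *, adt: ADTMatrix | None = None,
                  truth: GroundTruth | None = None) -> None:
    """Write a dataset (plus optional ADT matrix and ground truth) as a
    plain-text fixture directory that round-trips through the readers."""
    from . import io as htio

    if dataset.counts.shape[0] == 0 or dataset.counts.shape[1] == 0:
        raise ValueError("refusing to write an empty dataset")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    htio.write_counts(dataset, directory)
    if adt is not None:
        htio.write_adt(adt, directory)
    if truth is not None:
        (directory / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))


def config_to_dict(cfg: CohortSimConfig) -> dict:
    d = asdict(cfg)
    d["cells_per_sample_range"] = list(d["cells_per_sample_range"])
    d["groups"] = list(d["groups"])
    return d
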