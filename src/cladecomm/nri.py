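"""Node-by-node net relatedness index (NRI) with subtree-restricted nulls.

For every internal tree node, the species pool is restricted to the tips
descending from that node that occur in at least one plot.  Within each plot
holding >= 2 pool species, the observed mean pairwise patristic distance
(MPD) is compared against null communities of identical richness drawn from
the pool without replacement, with selection probabilities proportional to
each species' occurrence frequency (richness held exactly, prevalence in
expectation).  NRI is the negative standardized effect size:

    nri = -(mpd_obs - mean(mpd_null)) / sd(mpd_null)

so positive values indicate phylogenetic clustering and negative values
overdispersion.  Per-node averages over plots are classified with a fixed
band: clustered if mean > 0.5, overdispersed if mean < -0.5, random in
between (band edges inclusive in "random").

Weighted sampling without replacement uses the Gumbel-top-k trick, which is
distributionally identical to successive draws proportional to weight.
Every (node, plot) pair gets its own RNG substream derived from the global
seed, so results are reproducible regardless of evaluation order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .communities import CommunityMatrix
from .trees import DatedTree, PhyloDistanceMatrix, cophenetic

__all__ = [
    "NRIRecord",
    "CLASS_CLUSTERED",
    "CLASS_OVERDISPERSED",
    "CLASS_RANDOM",
    "CLASS_NOT_ESTIMABLE",
    "mpd",
    "nri_community",
    "classify_node",
    "node_nri_scan",
]

CLASS_CLUSTERED = "clustered"
CLASS_OVERDISPERSED = "overdispersed"
CLASS_RANDOM = "random"
CLASS_NOT_ESTIMABLE = "not_estimable"

#: half-width of the "random" classification band around 0
DEFAULT_NRI_BAND = 0.5


@dataclass(frozen=True)
class NRIRecord:
    node_id: int
    plot_id: str
    n_species: int          # pool species present in the plot
    mpd_obs: float
    mpd_null_mean: float
    mpd_null_sd: float
    nri: float              # NaN when the null SD degenerates


def mpd(species, dist: PhyloDistanceMatrix) -> float:
    """Mean patristic distance over all unordered pairs of ``species``."""
    species = list(species)
    if len(species) < 2:
        raise ValueError("MPD requires at least 2 species")
    sub = dist.submatrix(species).values
    k = len(species)
    return float(sub.sum() / (k * (k - 1)))


def _mpd_from_indices(d: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """MPD for each row of ``idx`` (n_draws, k) against distance matrix ``d``."""
    k = idx.shape[1]
    sub = d[idx[:, :, None], idx[:, None, :]]
    return sub.sum(axis=(1, 2)) / (k * (k - 1))


def _weighted_subsets(
    rng: np.random.Generator, m: int, k: int, log_w: np.ndarray, n: int
) -> np.ndarray:
    """Draw ``n`` size-``k`` subsets of range(m), weighted without replacement."""
    if k == m:
        return np.tile(np.arange(m), (n, 1))
    keys = rng.gumbel(size=(n, m)) + log_w
    return np.argpartition(keys, m - k, axis=1)[:, m - k:]


def _null_mpd(
    d_pool: np.ndarray,
    k: int,
    weights: np.ndarray,
    n_null: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte-Carlo null MPD mean and sample SD for richness ``k``."""
    m = d_pool.shape[0]
    log_w = np.log(weights)
    idx = _weighted_subsets(rng, m, k, log_w, n_null)
    vals = _mpd_from_indices(d_pool, idx)
    return float(vals.mean()), float(vals.std(ddof=1))


def nri_community(
    plot_species,
    pool,
    dist: PhyloDistanceMatrix,
    prevalence: dict[str, int],
    n_null: int = 999,
    seed=None,
    plot_id: str = "",
    node_id: int = -1,
) -> NRIRecord:
    """NRI of one community against richness-preserving draws from a pool."""
    pool = list(pool)
    plot_species = set(plot_species)
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    if len(pool) < 3:
        raise ValueError("species pool must have >= 3 species")
    if not plot_species <= set(pool):
        raise ValueError("community is not a subset of the pool")
    if len(plot_species) < 2:
        raise ValueError("community must contain >= 2 pool species")
    d_pool = dist.submatrix(pool).values
    pool_index = {s: i for i, s in enumerate(pool)}
    obs_idx = np.array(sorted(pool_index[s] for s in plot_species))
    weights = np.array([prevalence[s] for s in pool], dtype=float)
    if (weights <= 0).any():
        raise ValueError("prevalence weights must be positive")
    k = len(obs_idx)
    mpd_obs = float(_mpd_from_indices(d_pool, obs_idx[None, :])[0])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null_mean, null_sd = _null_mpd(d_pool, k, weights, n_null, rng)
    if null_sd > 0 and k < len(pool):
        nri = -(mpd_obs - null_mean) / null_sd
    else:
        nri = math.nan
    return NRIRecord(node_id, plot_id, k, mpd_obs, null_mean, null_sd, nri)


def classify_node(mean_nri: float, band: float = DEFAULT_NRI_BAND) -> str:
    """Fixed-band classification of a node's average NRI."""
    if mean_nri is None or math.isnan(mean_nri):
        return CLASS_NOT_ESTIMABLE
    if mean_nri > band:
        return CLASS_CLUSTERED
    if mean_nri < -band:
        return CLASS_OVERDISPERSED
    return CLASS_RANDOM


def _substream(seed, node_id: int, plot_idx: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=0 if seed is None else seed, spawn_key=(node_id, plot_idx)
    )
    return np.random.default_rng(ss)


def node_nri_scan(
    tree: DatedTree,
    cm: CommunityMatrix,
    n_null: int = 999,
    seed: int | None = None,
    node_ids=None,
    band: float = DEFAULT_NRI_BAND,
    dist: PhyloDistanceMatrix | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node NRI over all plots, averaged and classified.

    Returns ``(node_table, records)``:

    * ``node_table`` — one row per internal node: node age, pool richness,
      number of contributing communities, mean/SD of NRI, mean community
      size, and the band classification.
    * ``records`` — one row per (node, plot) evaluation.

    ``node_ids`` restricts the scan to a subset of internal nodes (the full
    enumeration is the default).  A precomputed ``dist`` over the analysis
    species may be supplied to avoid recomputation.
    """
    shared = [s for s in cm.species if s in set(tree.tip_labels)]
    dropped = len(cm.species) - len(shared)
    if not shared:
        raise ValueError("no overlap between tree tips and community species")
    if dropped:
        warnings.warn(f"{dropped} matrix species absent from the tree; dropped")
    cm = cm.subset_species(shared)
    pres = cm.presence
    counts = pres.sum(axis=0)
    occurring = [s for s in shared if counts[s] > 0]
    prevalence = {s: int(counts[s]) for s in occurring}
    if dist is None:
        dist = cophenetic(tree, occurring)
    else:
        missing = set(occurring) - set(dist.labels)
        if missing:
            raise KeyError(f"distance matrix lacks species: {sorted(missing)[:5]}")
        dist = dist.submatrix(occurring)
    didx = dist.index
    pres_arr = pres.loc[:, occurring].to_numpy(dtype=bool)
    col_of = {s: j for j, s in enumerate(occurring)}
    plot_ids = list(cm.cover.index)

    scan_nodes = tree.node_ids if node_ids is None else tuple(node_ids)
    rec_rows: list[NRIRecord] = []
    node_rows = []
    for nid in scan_nodes:
        clade = tree.subtree_tips(nid)
        pool = [s for s in occurring if s in clade]
        age = tree.node_age(nid)
        richness = len(pool)
        if richness < 3:
            node_rows.append(
                (nid, age, richness, 0, math.nan, math.nan, math.nan,
                 CLASS_NOT_ESTIMABLE)
            )
            continue
        pool_cols = np.array([col_of[s] for s in pool])
        d_order = [didx[s] for s in pool]
        d_pool = dist.values[np.ix_(d_order, d_order)]
        weights = np.array([prevalence[s] for s in pool], dtype=float)
        log_w = np.log(weights)
        sub = pres_arr[:, pool_cols]
        ks = sub.sum(axis=1)
        nris = []
        sizes = []
        m = richness
        for pi in np.flatnonzero(ks >= 2):
            obs_idx = np.flatnonzero(sub[pi])
            k = len(obs_idx)
            mpd_obs = float(_mpd_from_indices(d_pool, obs_idx[None, :])[0])
            rng = _substream(seed, nid, int(pi))
            idx = _weighted_subsets(rng, m, k, log_w, n_null)
            vals = _mpd_from_indices(d_pool, idx)
            null_mean = float(vals.mean())
            null_sd = float(vals.std(ddof=1))
            if null_sd > 0 and k < m:
                nri_val = -(mpd_obs - null_mean) / null_sd
                nris.append(nri_val)
                sizes.append(k)
            else:
                nri_val = math.nan
            rec_rows.append(
                NRIRecord(nid, plot_ids[pi], k, mpd_obs, null_mean,
                          null_sd, nri_val)
            )
        if nris:
            arr = np.asarray(nris)
            mean_nri = float(arr.mean())
            sd_nri = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            node_rows.append(
                (nid, age, richness, len(arr), mean_nri, sd_nri,
                 float(np.mean(sizes)), classify_node(mean_nri, band))
            )
        else:
            node_rows.append(
                (nid, age, richness, 0, math.nan, math.nan, math.nan,
                 CLASS_NOT_ESTIMABLE)
            )

    node_table = pd.DataFrame(
        node_rows,
        columns=["node_id", "node_age", "clade_richness", "n_communities",
                 "mean_nri", "sd_nri", "mean_community_size",
                 "classification"],
    )
    records = pd.DataFrame(
        [(r.node_id, r.plot_id, r.n_species, r.mpd_obs, r.mpd_null_mean,
          r.mpd_null_sd, r.nri) for r in rec_rows],
        columns=["node_id", "plot_id", "n_species", "mpd_obs",
                 "mpd_null_mean", "mpd_null_sd", "nri"],
    )
    return node_table, records
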