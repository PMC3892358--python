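"""Pairwise species co-occurrence and the global phylogeny-vs-co-occurrence test.

The co-occurrence index of a species pair is the number of plots shared by
both species divided by the occurrence count of the rarer species, ranging
from 0 (never together) to 1 (the rarer species never occurs without the
other).  The global test correlates these indices with patristic distances
over all species pairs (Spearman) and builds the null by permuting species
labels on the distance matrix, which preserves the occupancy structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .communities import CommunityMatrix
from .trees import PhyloDistanceMatrix

__all__ = [
    "CooccurrenceMatrix",
    "GlobalTestResult",
    "cooccurrence_index",
    "cooccurrence_matrix",
    "global_phylo_cooccurrence_test",
    "pair_table",
]


@dataclass(frozen=True)
class CooccurrenceMatrix:
    species: tuple[str, ...]
    values: np.ndarray          # symmetric, in [0, 1], diagonal 1
    occurrences: np.ndarray     # N_i per species

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    def value(self, s1: str, s2: str) -> float:
        idx = self.index
        return float(self.values[idx[s1], idx[s2]])


@dataclass(frozen=True)
class GlobalTestResult:
    rho: float
    p_value: float
    n_pairs: int
    n_randomizations: int
    stratum: str
    seed: int | None


def cooccurrence_index(cm: CommunityMatrix, s1: str, s2: str) -> float:
    """Shared-plot count over the rarer species' occurrence count."""
    pres = cm.presence
    for s in (s1, s2):
        if s not in pres.columns:
            raise KeyError(f"unknown species: {s!r}")
    n1 = int(pres[s1].sum())
    n2 = int(pres[s2].sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("co-occurrence undefined for species with no occurrences")
    both = int((pres[s1] & pres[s2]).sum())
    return both / min(n1, n2)


def cooccurrence_matrix(cm: CommunityMatrix) -> CooccurrenceMatrix:
    """All-pairs co-occurrence indices (species with zero occurrences dropped)."""
    pres = cm.presence
    counts = pres.sum(axis=0)
    if (counts == 0).any():
        warnings.warn(
            f"dropping {int((counts == 0).sum())} species with no occurrences"
        )
        pres = pres.loc[:, counts > 0]
        counts = counts[counts > 0]
    if pres.shape[1] < 2:
        raise ValueError("need at least 2 species with occurrences")
    p = pres.to_numpy(dtype=np.int64)
    joint = p.T @ p
    n = counts.to_numpy(dtype=np.int64)
    c = joint / np.minimum.outer(n, n)
    return CooccurrenceMatrix(tuple(pres.columns), c, n)


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def global_phylo_cooccurrence_test(
    cm: CommunityMatrix,
    dist: PhyloDistanceMatrix,
    n_rand: int = 9999,
    seed: int | None = None,
    stratum_species=None,
    stratum: str = "all",
) -> GlobalTestResult:
    """Permutation test of Spearman's rho between co-occurrence and distance.

    The observed statistic correlates the upper triangles of the
    co-occurrence and patristic distance matrices over the common species
    (optionally restricted to ``stratum_species``).  Null replicates permute
    the species labels of the distance matrix; the two-sided p-value uses the
    add-one rule, so it is never exactly zero.
    """
    if n_rand < 99:
        raise ValueError("n_rand must be >= 99")
    co = cooccurrence_matrix(cm)
    common = [s for s in co.species if s in set(dist.labels)]
    if stratum_species is not None:
        chosen = set(stratum_species)
        common = [s for s in common if s in chosen]
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 species in stratum {stratum!r}, got {len(common)}"
        )
    idx = co.index
    order = [idx[s] for s in common]
    c_mat = co.values[np.ix_(order, order)]
    d_mat = dist.submatrix(common).values

    c_rank = stats.rankdata(_upper(c_mat))
    d_vec = _upper(d_mat)
    rho_obs = _pearson(c_rank, stats.rankdata(d_vec))

    rng = np.random.default_rng(seed)
    m = len(common)
    exceed = 0
    for _ in range(n_rand):
        perm = rng.permutation(m)
        d_perm = _upper(d_mat[np.ix_(perm, perm)])
        rho = _pearson(c_rank, stats.rankdata(d_perm))
        if abs(rho) >= abs(rho_obs):
            exceed += 1
    p = (1 + exceed) / (1 + n_rand)
    n_pairs = m * (m - 1) // 2
    return GlobalTestResult(float(rho_obs), float(p), n_pairs, n_rand,
                            stratum, seed)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return 0.0
    return float((x * y).sum() / denom)


def pair_table(cm: CommunityMatrix, dist: PhyloDistanceMatrix) -> pd.DataFrame:
    """Long-format table of all species pairs: counts, index, distance."""
    co = cooccurrence_matrix(cm)
    pres = cm.presence
    dset = set(dist.labels)
    rows = []
    species = [s for s in co.species if s in dset]
    for i, s1 in enumerate(species):
        for s2 in species[i + 1:]:
            n1 = int(pres[s1].sum())
            n2 = int(pres[s2].sum())
            both = int((pres[s1] & pres[s2]).sum())
            rows.append(
                (s1, s2, n1, n2, both, co.value(s1, s2), dist.distance(s1, s2))
            )
    return pd.DataFrame(
        rows, columns=["s1", "s2", "N1", "N2", "N_both", "C", "phylo_dist"]
    )
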