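"""Synthetic dated trees and elevation-structured community matrices.

Communities are assembled on an elevation grid from a known process so the
whole pipeline can be exercised and calibrated without field data:

* *filtering* — species are drawn with weight
  ``exp(-filter_strength * ((trait - elevation) / scale)^2)`` where the
  trait is a Brownian "optimum elevation", producing clustering wherever
  the trait is phylogenetically conserved;
* *competition* — species are added sequentially, down-weighting candidates
  close to an already-selected species by ``exp(-strength / d_min)``,
  producing overdispersion;
* *neutral* — both strengths zero; uniform sampling.

Covers are decoupled from the assembly process (log-normal, rescaled to
percent) since all core statistics are presence-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .communities import CommunityMatrix, PlotMetadata
from .trees import DatedTree, cophenetic, read_tree

__all__ = [
    "AssemblyScenario",
    "simulate_yule_tree",
    "evolve_trait",
    "shuffle_traits_outside_clade",
    "assemble_communities",
    "generate_scenario",
]

ELEVATION_RANGE = (375.0, 3200.0)


@dataclass(frozen=True)
class AssemblyScenario:
    """Fully specifies one reproducible synthetic dataset."""

    n_tips: int = 64
    birth_rate: float = 1.0
    trait_sigma2: float = 50_000.0       # Brownian rate, m^2 / Myr
    trait_root: float = 1800.0           # root optimum elevation, m
    n_plots: int = 200
    mean_richness: float = 12.0
    filter_strength: float = 0.0
    competition_strength: float = 0.0
    filter_scale: float = 300.0          # m; width of the filtering kernel
    elevation_range: tuple[float, float] = ELEVATION_RANGE
    allow_mixed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.birth_rate <= 0 or self.trait_sigma2 <= 0:
            raise ValueError("rates must be positive")
        if self.filter_strength < 0 or self.competition_strength < 0:
            raise ValueError("strengths must be >= 0")
        if self.mean_richness < 2:
            raise ValueError("mean_richness must be >= 2")
        if (
            self.filter_strength > 0
            and self.competition_strength > 0
            and not self.allow_mixed
        ):
            raise ValueError(
                "only one of filter/competition strength may be positive "
                "(set allow_mixed=True to combine)"
            )


class _Lineage:
    __slots__ = ("birth", "split", "children", "label")

    def __init__(self, birth: float):
        self.birth = birth
        self.split = None
        self.children = None
        self.label = None


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_yule_tree(n_tips: int, birth_rate: float, seed=None) -> DatedTree:
    """Pure-birth ultrametric tree with exactly ``n_tips`` extant tips.

    Starts from two lineages at the root; with ``k`` lineages alive the
    waiting time to the next split is Exp(k * birth_rate) and a uniformly
    chosen lineage splits.  After the last split every tip is extended by a
    final Exp(n_tips * birth_rate) interval, so the expected tree height is
    ``(H_n - 1) / birth_rate`` where ``H_n`` is the n-th harmonic number.
    Identical seeds yield identical Newick strings.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = _rng(seed)
    t = 0.0
    left, right = _Lineage(0.0), _Lineage(0.0)
    active = [left, right]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        parent = active[i]
        parent.split = t
        c1, c2 = _Lineage(t), _Lineage(t)
        parent.children = (c1, c2)
        active[i] = c1
        active.append(c2)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    height = t
    for i, tip in enumerate(active):
        tip.label = f"t{i + 1}"

    def render(lin: _Lineage) -> str:
        end = lin.split if lin.children else height
        edge = end - lin.birth
        if lin.children:
            a, b = lin.children
            return f"({render(a)},{render(b)}):{edge:.10f}"
        return f"{lin.label}:{edge:.10f}"

    newick = f"({render(left)},{render(right)});"
    return read_tree(newick)


def evolve_trait(
    tree: DatedTree, sigma2: float, root_value: float, seed=None
) -> dict[str, float]:
    """Brownian motion of a trait along the tree; returns tip values.

    Increments along a branch of length ``b`` are Normal(0, sigma2 * b), so
    the expected squared difference between two tips equals sigma2 times
    their patristic distance.  Traversal order is deterministic (preorder).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = _rng(seed)
    root = tree._tree.seed_node
    values = {id(root): float(root_value)}
    out: dict[str, float] = {}
    for node in tree._tree.preorder_node_iter():
        if node is root:
            continue
        step = rng.normal(0.0, np.sqrt(sigma2 * node.edge.length))
        val = values[id(node.parent_node)] + step
        values[id(node)] = val
        if node.is_leaf():
            out[node.taxon.label] = float(val)
    return out


def shuffle_traits_outside_clade(
    tree: DatedTree, node_id: int, traits: dict[str, float], seed=None
) -> dict[str, float]:
    """Permute trait values among tips *outside* a focal clade.

    Destroys phylogenetic trait signal everywhere except within the clade,
    so assembly driven by the trait produces structure concentrated at that
    clade's node.
    """
    rng = _rng(seed)
    clade = tree.subtree_tips(node_id)
    outside = [s for s in tree.tip_labels if s not in clade]
    vals = np.array([traits[s] for s in outside])
    perm = rng.permutation(len(outside))
    out = dict(traits)
    for s, j in zip(outside, perm):
        out[s] = float(vals[j])
    return out


def assemble_communities(
    tree: DatedTree,
    traits: dict[str, float],
    scenario: AssemblyScenario,
) -> tuple[CommunityMatrix, PlotMetadata]:
    """Sample plot communities along the elevation gradient.

    Plots are placed on an even elevation grid.  Plot richness is
    Poisson(mean_richness) clipped to [2, n_tips].  Species are drawn
    without replacement under the scenario's assembly process; covers are
    log-normal, rescaled so each plot sums to 100%.
    """
    species = list(tree.tip_labels)
    missing = [s for s in species if s not in traits]
    if missing:
        raise ValueError(f"traits missing for tips: {missing[:5]}")
    rng = np.random.default_rng(scenario.seed)
    n_sp = len(species)
    trait_vec = np.array([traits[s] for s in species])
    lo, hi = scenario.elevation_range
    elevations = np.linspace(lo, hi, scenario.n_plots)
    dist = None
    if scenario.competition_strength > 0:
        dist = cophenetic(tree, species).values

    cover = np.zeros((scenario.n_plots, n_sp))
    for p in range(scenario.n_plots):
        k = int(np.clip(rng.poisson(scenario.mean_richness), 2, n_sp))
        if k > n_sp:
            raise ValueError("plot richness exceeds the number of species")
        if scenario.filter_strength > 0:
            z = (trait_vec - elevations[p]) / scenario.filter_scale
            logw = -scenario.filter_strength * z * z
        else:
            logw = np.zeros(n_sp)
        if scenario.competition_strength > 0:
            chosen = _sequential_competitive(
                rng, logw, dist, k, scenario.competition_strength
            )
        else:
            keys = rng.gumbel(size=n_sp) + logw
            chosen = np.argpartition(keys, n_sp - k)[n_sp - k:]
        raw = rng.lognormal(mean=0.0, sigma=1.0, size=k)
        cover[p, chosen] = 100.0 * raw / raw.sum()

    plot_ids = [f"p{p + 1:04d}" for p in range(scenario.n_plots)]
    cm = CommunityMatrix(
        pd.DataFrame(np.round(cover, 6), index=plot_ids, columns=species)
    )
    meta = PlotMetadata(
        pd.DataFrame({"elevation": np.round(elevations, 3)}, index=plot_ids)
    )
    return cm, meta


def _sequential_competitive(
    rng: np.random.Generator,
    base_logw: np.ndarray,
    dist: np.ndarray,
    k: int,
    strength: float,
) -> np.ndarray:
    """Pick k species one by one, penalising proximity to those selected."""
    n = len(base_logw)
    chosen: list[int] = []
    available = np.ones(n, dtype=bool)
    dmin = np.full(n, np.inf)  # distance to the nearest already-chosen species
    for _ in range(k):
        with np.errstate(divide="ignore"):
            penalty = -strength / np.where(dmin > 0, dmin, 1e-12)
        w = np.where(available, base_logw + penalty, -np.inf)
        # Gumbel-max draw == categorical draw proportional to exp(w)
        pick = int(np.argmax(rng.gumbel(size=n) + w))
        chosen.append(pick)
        available[pick] = False
        dmin = np.minimum(dmin, dist[pick])
    return np.array(chosen)


def generate_scenario(
    scenario: AssemblyScenario,
) -> tuple[DatedTree, dict[str, float], CommunityMatrix, PlotMetadata]:
    """Tree + traits + communities from one scenario (single seed)."""
    ss = np.random.SeedSequence(scenario.seed)
    tree_rng, trait_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    tree = simulate_yule_tree(scenario.n_tips, scenario.birth_rate, tree_rng)
    traits = evolve_trait(tree, scenario.trait_sigma2, scenario.trait_root,
                          trait_rng)
    cm, meta = assemble_communities(tree, traits, scenario)
    return tree, traits, cm, meta
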