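"""Per-node NRI gradients along elevation, node-age/size models, robustness.

Each internal node's per-plot NRI values are regressed on plot elevation by
ordinary least squares; the slope's t-statistic and two-sided p-value
summarise whether the lineage becomes more clustered or more overdispersed
uphill.  Node-level averages are related to node age and mean community
size with a Gaussian-identity GLM, and per-node stability across posterior
tree samples is quantified by matching clades on descendant tip sets.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .communities import CommunityMatrix
from .nri import node_nri_scan
from .trees import DatedTree

__all__ = [
    "GradientFit",
    "NodeModelFit",
    "nri_elevation_regression",
    "gradient_table",
    "fit_age_size_model",
    "richness_nri_correlation",
    "posterior_tree_scan",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class GradientFit:
    node_id: int
    slope: float
    intercept: float
    t_statistic: float
    p_value: float
    n_points: int
    direction: str          # "increasing" | "decreasing"
    significant: bool


@dataclass(frozen=True)
class NodeModelFit:
    coefficients: dict[str, float]
    p_values: dict[str, float]
    n_nodes: int


def nri_elevation_regression(
    records: pd.DataFrame,
    elevations,
    node_id: int | None = None,
    alpha: float = 0.05,
) -> GradientFit:
    """OLS of per-plot NRI on plot elevation for a single node."""
    df = records
    if node_id is not None:
        df = df[df["node_id"] == node_id]
    elif df["node_id"].nunique() > 1:
        raise ValueError("records span multiple nodes; pass node_id")
    df = df[np.isfinite(df["nri"])]
    if len(df) < 3:
        raise ValueError("need >= 3 finite NRI points for a regression")
    elev_map = elevations if isinstance(elevations, dict) else dict(elevations)
    x = np.array([elev_map[p] for p in df["plot_id"]], dtype=float)
    y = df["nri"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("elevation is constant; slope not identifiable")
    fit = stats.linregress(x, y)
    t = fit.slope / fit.stderr if fit.stderr > 0 else math.inf * np.sign(fit.slope)
    nid = int(df["node_id"].iloc[0]) if node_id is None else int(node_id)
    return GradientFit(
        node_id=nid,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        t_statistic=float(t),
        p_value=float(fit.pvalue),
        n_points=len(df),
        direction="increasing" if fit.slope >= 0 else "decreasing",
        significant=bool(fit.pvalue < alpha),
    )


def gradient_table(
    records: pd.DataFrame,
    elevations,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Elevation regressions for every node with enough data.

    Nodes with <3 finite points or constant elevation are silently skipped.
    With ``adjust=True`` a Benjamini-Hochberg adjusted p-value column is
    appended (raw significance is always reported).
    """
    fits = []
    for nid, grp in records.groupby("node_id"):
        try:
            fits.append(nri_elevation_regression(grp, elevations,
                                                 node_id=int(nid), alpha=alpha))
        except ValueError:
            continue
    df = pd.DataFrame(
        [(f.node_id, f.slope, f.intercept, f.t_statistic, f.p_value,
          f.n_points, f.direction, f.significant) for f in fits],
        columns=["node_id", "slope", "intercept", "t_statistic", "p_value",
                 "n_points", "direction", "significant"],
    )
    if adjust and len(df):
        df["p_adjusted"] = benjamini_hochberg(df["p_value"].to_numpy())
        df["significant_adjusted"] = df["p_adjusted"] < alpha
    return df


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def fit_age_size_model(node_table: pd.DataFrame) -> NodeModelFit:
    """Gaussian-identity GLM: mean NRI ~ mean community size + node age."""
    df = node_table[np.isfinite(node_table["mean_nri"])]
    if len(df) < 10:
        raise ValueError("need >= 10 estimable nodes to fit the model")
    x_size = df["mean_community_size"].to_numpy(dtype=float)
    x_age = df["node_age"].to_numpy(dtype=float)
    r = np.corrcoef(x_size, x_age)[0, 1]
    if abs(r) > 0.999:
        raise ValueError("community size and node age are collinear")
    X = sm.add_constant(np.column_stack([x_size, x_age]))
    y = df["mean_nri"].to_numpy(dtype=float)
    names = ["intercept", "community_size", "node_age"]
    if np.ptp(y) == 0:
        # degenerate response: slopes are exactly zero and the GLM deviance
        # is undefined, so return the closed form directly
        return NodeModelFit(
            coefficients={"intercept": float(y[0]), "community_size": 0.0,
                          "node_age": 0.0},
            p_values={n: math.nan for n in names},
            n_nodes=len(df),
        )
    res = sm.GLM(y, X, family=sm.families.Gaussian()).fit()
    return NodeModelFit(
        coefficients=dict(zip(names, map(float, res.params))),
        p_values=dict(zip(names, map(float, res.pvalues))),
        n_nodes=len(df),
    )


def richness_nri_correlation(records: pd.DataFrame) -> pd.DataFrame:
    """Per-node Spearman correlation of per-plot NRI with clade richness.

    Nodes whose per-plot richness is constant get ``rho = NaN`` and are
    flagged ``undefined``.
    """
    rows = []
    for nid, grp in records.groupby("node_id"):
        grp = grp[np.isfinite(grp["nri"])]
        if len(grp) < 3:
            continue
        sizes = grp["n_species"].to_numpy(dtype=float)
        if np.ptp(sizes) == 0:
            rows.append((int(nid), math.nan, math.nan, len(grp), True))
            continue
        rho, p = stats.spearmanr(grp["nri"], sizes)
        rows.append((int(nid), float(rho), float(p), len(grp), False))
    return pd.DataFrame(
        rows, columns=["node_id", "rho", "p_value", "n_points", "undefined"]
    )


def clade_key(tips) -> str:
    """Canonical topology-free identifier of a clade (its tip set)."""
    joined = "\x1f".join(sorted(tips))
    return hashlib.md5(joined.encode()).hexdigest()[:16]


def posterior_tree_scan(
    trees: list[DatedTree],
    cm: CommunityMatrix,
    elevations,
    n_null: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Elevation-slope stability of each clade across posterior tree samples.

    Clades are matched between trees by descendant tip-set identity
    (restricted to the species analysed).  Clades appearing in fewer than
    half the trees are flagged unstable.  Returns one row per clade with
    slope mean/SD and occupancy.
    """
    if len(trees) < 2:
        raise ValueError("need >= 2 trees")
    species = set(cm.species)
    if not any(species & set(t.tip_labels) for t in trees):
        raise ValueError("trees share no species with the community matrix")
    slopes: dict[str, list[float]] = {}
    tipsets: dict[str, frozenset] = {}
    for tree in trees:
        # same seed for every tree: identical trees then yield identical
        # NRI draws, so slope SD isolates tree uncertainty alone
        node_table, records = node_nri_scan(tree, cm, n_null=n_null, seed=seed)
        grads = gradient_table(records, elevations, alpha=alpha)
        id_to_clade = {
            nid: frozenset(tree.subtree_tips(nid) & species)
            for nid in tree.node_ids
        }
        for _, row in grads.iterrows():
            clade = id_to_clade[int(row["node_id"])]
            key = clade_key(clade)
            slopes.setdefault(key, []).append(float(row["slope"]))
            tipsets[key] = clade
    n_trees = len(trees)
    rows = []
    for key, vals in sorted(slopes.items()):
        arr = np.asarray(vals)
        rows.append(
            (key, len(tipsets[key]), len(arr), float(arr.mean()),
             float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
             len(arr) < 0.5 * n_trees)
        )
    return pd.DataFrame(
        rows, columns=["clade", "clade_size", "n_trees", "slope_mean",
                       "slope_sd", "unstable"],
    )
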