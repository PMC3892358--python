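"""End-to-end orchestration: filters, global test, node NRI scan, gradients.

A :class:`RunConfig` (typically loaded from YAML) names the inputs and all
thresholds; :func:`run_all` executes each stage in order, writes CSV/Newick
outputs, and records a JSON manifest with the seed and per-stage counts so
any run can be reproduced and audited.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .communities import (
    DEFAULT_ZONE_BREAKPOINTS,
    assign_vegetation_zones,
    filter_plots_by_relative_cover,
    filter_species_by_frequency,
    read_community_csv,
    read_metadata_csv,
)
from .cooccur import global_phylo_cooccurrence_test, pair_table
from .gradients import fit_age_size_model, gradient_table, posterior_tree_scan, \
    richness_nri_correlation
from .nri import node_nri_scan
from .trees import cophenetic, read_tree, read_trees

logger = logging.getLogger("cladecomm")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    tree: str
    matrix: str
    metadata: str
    outdir: str
    cover: str = "percent"              # or "classes"
    min_occurrences: int = 20
    min_cover_fraction: float = 0.8
    zone_breakpoints: tuple = DEFAULT_ZONE_BREAKPOINTS
    n_rand: int = 9999
    n_null: int = 999
    nri_band: float = 0.5
    alpha: float = 0.05
    seed: int = 0
    posterior_trees: str | None = None
    drop_tips: tuple = ()               # e.g. outgroup labels

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for path_field in ("tree", "matrix", "metadata"):
            p = getattr(cfg, path_field)
            if not os.path.exists(p):
                raise FileNotFoundError(f"{path_field} file not found: {p}")
        if cfg.posterior_trees and not os.path.exists(cfg.posterior_trees):
            raise FileNotFoundError(
                f"posterior_trees file not found: {cfg.posterior_trees}"
            )
        return cfg


def _write_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns (and writes) the run manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "cladecomm_version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "errors": [],
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    # -- load ----------------------------------------------------------------
    info = stage("load")
    tree = read_tree(config.tree)
    if config.drop_tips:
        tree = tree.prune(config.drop_tips)
    cm = read_community_csv(config.matrix, cover=config.cover)
    meta = read_metadata_csv(config.metadata)
    meta.check_covers(cm)
    info.update(n_tips=tree.n_tips, n_plots=len(cm.plot_ids),
                n_species=len(cm.species))

    # -- filters -------------------------------------------------------------
    info = stage("filter")
    retained = filter_species_by_frequency(cm, config.min_occurrences)
    cm_f = filter_plots_by_relative_cover(
        cm, retained.species, config.min_cover_fraction
    )
    in_tree = [s for s in cm_f.species if s in set(tree.tip_labels)]
    n_dropped = len(cm_f.species) - len(in_tree)
    if n_dropped:
        logger.warning("%d retained species absent from tree; dropped", n_dropped)
        cm_f = cm_f.subset_species(in_tree)
    meta = assign_vegetation_zones(meta, config.zone_breakpoints)
    info.update(
        n_species_retained=len(cm_f.species),
        n_plots_retained=len(cm_f.plot_ids),
        n_species_not_in_tree=n_dropped,
    )

    dist = cophenetic(tree, cm_f.species)
    elevations = {p: float(meta.elevations[p]) for p in cm_f.plot_ids}
    zones = meta.table.loc[list(cm_f.plot_ids), "zone"]

    # -- co-occurrence (global + strata) ------------------------------------
    info = stage("cooccurrence")
    pairs = pair_table(cm_f, dist)
    _write_csv(pairs, os.path.join(config.outdir, "pair_table.csv"))
    results = [
        global_phylo_cooccurrence_test(
            cm_f, dist, n_rand=config.n_rand, seed=config.seed, stratum="all"
        )
    ]
    for zone in sorted(zones.unique()):
        zone_plots = zones.index[zones == zone]
        sub = cm_f.subset_plots(zone_plots)
        sub_occ = sub.occurrences
        stratum_sp = list(sub_occ.index[sub_occ > 0])
        if len(stratum_sp) < 3:
            logger.warning("zone %s has <3 occurring species; skipped", zone)
            continue
        results.append(
            global_phylo_cooccurrence_test(
                sub, dist, n_rand=config.n_rand, seed=config.seed,
                stratum=str(zone),
            )
        )
    summary = pd.DataFrame(
        [(r.stratum, r.rho, r.p_value, r.n_pairs, r.n_randomizations, r.seed)
         for r in results],
        columns=["stratum", "rho", "p_value", "n_pairs", "n_rand", "seed"],
    )
    _write_csv(summary, os.path.join(config.outdir, "global_test.csv"))
    info.update(n_strata=len(results), n_pairs=int(results[0].n_pairs))

    # -- node NRI scan -------------------------------------------------------
    info = stage("nri")
    node_table, records = node_nri_scan(
        tree, cm_f, n_null=config.n_null, seed=config.seed,
        band=config.nri_band, dist=dist,
    )
    _write_csv(node_table, os.path.join(config.outdir, "node_nri.csv"))
    _write_csv(records, os.path.join(config.outdir, "nri_records.csv"))
    ann = {
        int(r.node_id): f"{int(r.node_id)}|{r.mean_nri:.4f}|{r.classification}"
        for r in node_table.itertuples()
        if np.isfinite(r.mean_nri)
    }
    tree.write_annotated(os.path.join(config.outdir, "annotated_tree.nwk"), ann)
    info.update(
        n_nodes=len(node_table),
        n_estimable=int(np.isfinite(node_table["mean_nri"]).sum()),
        classifications=node_table["classification"].value_counts().to_dict(),
    )

    # -- gradients -----------------------------------------------------------
    info = stage("gradients")
    grads = gradient_table(records, elevations, alpha=config.alpha, adjust=True)
    _write_csv(grads, os.path.join(config.outdir, "elevation_gradients.csv"))
    rich = richness_nri_correlation(records)
    _write_csv(rich, os.path.join(config.outdir, "richness_correlation.csv"))
    info.update(n_fits=len(grads))
    try:
        glm = fit_age_size_model(node_table)
        info.update(glm_coefficients=glm.coefficients, glm_p=glm.p_values,
                    glm_n=glm.n_nodes)
        _write_csv(
            pd.DataFrame(
                {"term": list(glm.coefficients),
                 "estimate": list(glm.coefficients.values()),
                 "p_value": list(glm.p_values.values())}
            ),
            os.path.join(config.outdir, "age_size_model.csv"),
        )
    except ValueError as exc:
        logger.warning("age/size model skipped: %s", exc)
        manifest["errors"].append(f"gradients: {exc}")

    # -- posterior robustness (optional) ------------------------------------
    if config.posterior_trees:
        info = stage("posterior")
        trees = read_trees(config.posterior_trees)
        rob = posterior_tree_scan(
            trees, cm_f, elevations, n_null=config.n_null, seed=config.seed,
            alpha=config.alpha,
        )
        _write_csv(rob, os.path.join(config.outdir, "posterior_robustness.csv"))
        info.update(n_trees=len(trees), n_clades=len(rob))

    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
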