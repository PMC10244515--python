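"""End-to-end pipeline orchestration.

Stages: simulate (optional) -> construct networks -> curvatures -> global
measures -> group comparison -> term enrichment -> phenotype correlation.
Every output table carries a provenance header (package version, config
hash, seeds); re-running with identical configuration reproduces identical
numeric content.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .behavior import correlate_curvature_phenotypes
from .construct import DensityGrid, construct_fcn_stack
from .curvature import (all_edge_curvatures, average_edge_curvature,
                        node_curvatures)
from .enrichment import enrich
from .groupstats import (ALPHA, compare_global, compare_nodes, node_auc_table,
                         significant_rois)
from .measures import GlobalMeasureRecord, global_measures
from .simulate import CohortBundle, SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    out_dir: str = "connricci_out"
    grid_lo: float = 0.02
    grid_hi: float = 0.50
    grid_step: float = 0.01
    methods: tuple = ("frc",)
    alpha: float = ALPHA
    n_draws: int = 1000
    louvain_seed: int = 0
    enrichment_seed: int = 0
    equal_var: bool = True
    compute_global_measures: bool = False
    clique_budget: float = 60.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @property
    def grid(self) -> DensityGrid:
        return DensityGrid.from_spec(self.grid_lo, self.grid_hi,
                                     self.grid_step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        sim = d.pop("simulation")
        sim["effect_rois"] = sorted(sim["effect_rois"])
        sim["enriched_terms"] = list(sim["enriched_terms"])
        d["methods"] = list(d["methods"])
        d["simulation"] = sim
        return d


@dataclass
class PipelineResult:
    """In-memory results of a full run."""

    cohort: CohortBundle
    node_auc: pd.DataFrame
    avg_edge_curvature: pd.DataFrame
    global_measures: pd.DataFrame | None
    global_comparison: pd.DataFrame
    node_comparison: pd.DataFrame
    enrichment: dict          # method -> DataFrame
    correlations: dict        # method -> DataFrame
    significant_rois: dict    # method -> list of roi ids


def compute_cohort_curvatures(cohort: CohortBundle, grid: DensityGrid,
                              methods=("frc",), idleness: float = 0.0):
    """Per-subject network stacks, node curvatures and average edge
    curvatures across the grid.

    Returns (node_curves, avg_curves): tidy frames with columns
    (subject_id, method, roi, density, value) and
    (subject_id, method, density, value).
    """
    node_rows, avg_rows = [], []
    for fc in cohort.fc_matrices:
        stack = construct_fcn_stack(fc, grid)
        for fcn in stack:
            for method in methods:
                ec = all_edge_curvatures(fcn, method, idleness=idleness)
                nc = node_curvatures(ec, fcn)
                avg_rows.append({"subject_id": fc.subject_id, "method": method,
                                 "density": fcn.density,
                                 "value": average_edge_curvature(ec)})
                for node, val in nc.values.items():
                    node_rows.append({"subject_id": fc.subject_id,
                                      "method": method,
                                      "roi": fc.roi_ids[node],
                                      "density": fcn.density, "value": val})
        logger.info("curvatures done for subject %s", fc.subject_id)
    return pd.DataFrame(node_rows), pd.DataFrame(avg_rows)


def compute_cohort_measures(cohort: CohortBundle, grid: DensityGrid,
                            seed: int = 0,
                            clique_budget: float = 60.0) -> pd.DataFrame:
    """The eight global measures per subject x density."""
    rows = []
    for fc in cohort.fc_matrices:
        for fcn in construct_fcn_stack(fc, grid):
            rec = global_measures(fcn, seed=seed, clique_budget=clique_budget)
            rows.append(dataclasses.asdict(rec))
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute every stage on a synthetic cohort and write all tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": io.config_hash(config.to_dict()),
            "seed": config.simulation.seed,
            "enrichment_seed": config.enrichment_seed}
    grid = config.grid

    logger.info("stage simulate")
    cohort = generate_cohort(config.simulation)
    manifest = cohort.manifest
    io.write_manifest(manifest, out / "manifest.tsv")
    io.write_table(cohort.annotations, out / "annotations.tsv", prov)
    io.write_table(cohort.term_table, out / "terms.tsv", prov)
    io.write_table(cohort.phenotypes, out / "phenotypes.tsv", prov)

    logger.info("stage construct+curvature")
    node_curves, avg_curves = compute_cohort_curvatures(
        cohort, grid, methods=config.methods)

    logger.info("stage node AUC + comparisons")
    auc = node_auc_table(node_curves, grid)
    io.write_table(auc, out / "node_auc.tsv", prov)

    gm = None
    global_records = avg_curves.pivot(
        index=["subject_id", "density"], columns="method",
        values="value").reset_index()
    global_records.columns = ["subject_id", "density"] + [
        f"avg_edge_{m}" for m in global_records.columns[2:]]
    if config.compute_global_measures:
        logger.info("stage global measures")
        gm = compute_cohort_measures(cohort, grid, seed=config.louvain_seed,
                                     clique_budget=config.clique_budget)
        io.write_table(gm, out / "global_measures.tsv", prov)
        global_records = global_records.merge(
            gm.drop(columns=["assortativity"]).fillna(np.nan),
            on=["subject_id", "density"], how="left")

    global_cmp = compare_global(global_records, manifest, alpha=config.alpha,
                                equal_var=config.equal_var)
    io.write_table(global_cmp, out / "global_comparison.tsv", prov)

    node_cmp = compare_nodes(auc, manifest, alpha=config.alpha,
                             equal_var=config.equal_var)
    io.write_table(node_cmp, out / "node_comparison.tsv", prov)

    logger.info("stage enrichment + correlations")
    enrich_tables, corr_tables, sig = {}, {}, {}
    for method in config.methods:
        sig[method] = significant_rois(node_cmp, method)
        if sig[method]:
            enrich_tables[method] = enrich(
                sig[method], cohort.annotations, cohort.term_table,
                n_draws=config.n_draws, seed=config.enrichment_seed,
                alpha=config.alpha)
            io.write_table(enrich_tables[method],
                           out / f"enrichment_{method}.tsv", prov)
            corr_tables[method] = correlate_curvature_phenotypes(
                auc, sig[method], cohort.phenotypes, method,
                alpha=config.alpha)
            io.write_table(corr_tables[method],
                           out / f"correlations_{method}.tsv", prov)
        else:
            logger.info("no significant ROIs for %s; enrichment and "
                        "correlation stages skipped", method)
    return PipelineResult(
        cohort=cohort, node_auc=auc, avg_edge_curvature=avg_curves,
        global_measures=gm, global_comparison=global_cmp,
        node_comparison=node_cmp, enrichment=enrich_tables,
        correlations=corr_tables, significant_rois=sig)
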