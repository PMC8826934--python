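"""End-to-end orchestration of the temporal-pattern analysis.

Stage order: missing-data exclusion (on the raw draw schedule, so the cell
budget counts the duplicate fasting draw when present) -> fasting collapse
-> differencing -> normalization -> responder calling -> panel clustering
and labelling -> PCA -> similarity indices (TPSI/TVRI/TPSM) ->
fasting-correlation clustering of responders -> similarity network
(components, betweenness, deg_Normalized) -> per-individual AUC / T_AUC1/2
feature screen. Every stage writes its CSV into the output directory and
contributes a block to a JSON summary; rerunning on the same inputs
overwrites the outputs identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    core_data,
    network_analysis,
    pattern_decomposition,
    preprocessing,
    response_detection,
    similarity_indices,
    temporal_features,
)
from .core_data import TimecourseDataset

logger = logging.getLogger("tempomics")

STAGES = (
    "filter",
    "normalize",
    "respond",
    "cluster",
    "pca",
    "similarity",
    "network",
    "features",
)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, serializable to YAML."""

    input_csv: str | None = None
    annotation_csv: str | None = None
    output_dir: str = "tempomics_out"

    fc_threshold: float = response_detection.FC_THRESHOLD     # |log2 FC| > 0.585
    q_threshold: float = response_detection.Q_THRESHOLD       # q < 0.1
    tpsm_threshold: float = network_analysis.TPSM_THRESHOLD   # |TPSM| > 0.6
    amplitude_small: float = pattern_decomposition.AMPLITUDE_SMALL
    amplitude_large: float = pattern_decomposition.AMPLITUDE_LARGE
    transience_fraction: float = pattern_decomposition.TRANSIENCE_FRACTION
    missing_top_fraction: float = 0.05

    n_clusters_panel: int = 13
    n_clusters_fasting: int = 4

    qvalue_lambda: float = 0.5
    qvalue_family: str = "pooled"
    qvalue_smoother: bool = False

    reference_molecules: list[str] | None = None
    skip: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value, lo, hi in (
            ("q_threshold", self.q_threshold, 0.0, 1.0),
            ("tpsm_threshold", self.tpsm_threshold, 0.0, 1.0),
            ("transience_fraction", self.transience_fraction, 0.0, 1.0),
            ("missing_top_fraction", self.missing_top_fraction, 0.0, 1.0),
            ("qvalue_lambda", self.qvalue_lambda, 0.0, 1.0),
        ):
            if not lo <= value <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}], got {value}")
        if self.fc_threshold < 0:
            raise ValueError("fc_threshold must be non-negative")
        if self.amplitude_small > self.amplitude_large:
            raise ValueError("amplitude_small must not exceed amplitude_large")
        unknown = set(self.skip) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in skip: {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_pipeline(
    cfg: PipelineConfig, dataset: TimecourseDataset | None = None
) -> dict:
    """Execute all stages; returns the JSON-ready summary dictionary.

    ``dataset`` may be supplied directly (e.g. a synthetic cohort);
    otherwise it is read from ``cfg.input_csv`` / ``cfg.annotation_csv``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    skip = set(cfg.skip)

    if dataset is None:
        if cfg.input_csv is None:
            raise ValueError("no dataset supplied and no input_csv configured")
        dataset = core_data.read_timecourse_csv(cfg.input_csv, cfg.annotation_csv)

    summary: dict = {
        "config": _jsonable(asdict(cfg)),
        "input": {
            "n_subjects": dataset.n_subjects,
            "n_molecules": len(dataset.molecules),
            "n_times_raw": dataset.grid.n_times,
            "n_missing_cells": int(np.isnan(dataset.values).sum()),
        },
    }

    # -- missing-data exclusion on the raw draw schedule ---------------------
    if "filter" not in skip:
        dataset, report = preprocessing.filter_missing_molecules(
            dataset, cfg.missing_top_fraction
        )
        report.to_csv(out / "missing_report.csv", index=False)
        summary["filter"] = {
            "threshold_cells": int(report["threshold"].iloc[0]) if len(report) else 0,
            "n_excluded": int(report["excluded"].sum()),
            "excluded": list(report.loc[report["excluded"], "molecule"]),
        }
        logger.info("filter: %d molecules excluded", summary["filter"]["n_excluded"])

    dataset = core_data.collapse_fasting_duplicates(dataset)
    dd = core_data.difference_from_fasting(dataset)
    groups = dataset.groups

    # -- normalization -------------------------------------------------------
    norm = None
    if "normalize" not in skip:
        norm = preprocessing.normalize_timecourses(dataset)
        norm.y_frame().to_csv(out / "normalized.csv", index=False)
        pd.DataFrame(
            {"molecule": norm.molecule_ids, "Sbar": norm.Sbar}
        ).to_csv(out / "normalization_summary.csv", index=False)
        summary["normalize"] = {
            "n_retained": len(norm.molecule_ids),
            "excluded": [list(e) for e in norm.excluded],
        }

    # -- responder calling ---------------------------------------------------
    response = None
    if "respond" not in skip:
        response = response_detection.call_responders(
            dataset,
            fc_threshold=cfg.fc_threshold,
            q_threshold=cfg.q_threshold,
            family=cfg.qvalue_family,
            lam=cfg.qvalue_lambda,
            smoother=cfg.qvalue_smoother,
        )
        response.per_time.to_csv(out / "response.csv", index=False)
        response.per_molecule.to_csv(out / "responders.csv", index=False)
        directions = response.per_molecule["direction"].value_counts().to_dict()
        summary["respond"] = {
            "n_responders": int(response.per_molecule["responder"].sum()),
            "n_increase": int(directions.get("increase", 0)),
            "n_decrease": int(directions.get("decrease", 0)),
            "responders": response.responders,
        }
        logger.info("respond: %d responders", summary["respond"]["n_responders"])

    # -- panel clustering and labelling --------------------------------------
    clusters = None
    if "cluster" not in skip and norm is not None:
        ybar = norm.ybar_frame()
        complete = ybar.dropna(axis=0)
        if len(complete) < len(ybar):
            logger.warning(
                "cluster: %d molecules with incomplete mean trajectories excluded",
                len(ybar) - len(complete),
            )
        k = min(cfg.n_clusters_panel, len(complete))
        clusters = pattern_decomposition.hierarchical_cluster(complete, k)
        table = clusters.assignment.rename("cluster").to_frame()
        table = table.join(clusters.labels.set_index("cluster"), on="cluster")
        table.index.name = "molecule"
        table.to_csv(out / "clusters.csv")
        pd.DataFrame(
            clusters.linkage, columns=["left", "right", "height", "size"]
        ).to_csv(out / "linkage.csv", index=False)
        summary["cluster"] = {
            "n_clusters": clusters.n_clusters,
            "labels": clusters.labels.to_dict(orient="records"),
        }

    # -- PCA -----------------------------------------------------------------
    pca = None
    if "pca" not in skip and norm is not None:
        ybar = norm.ybar_frame().dropna(axis=0)
        pca = pattern_decomposition.pca_decompose(ybar)
        pca.scores.to_csv(out / "pca_scores.csv")
        pca.loadings.to_csv(out / "pca_loadings.csv")
        evr = pca.explained_variance_ratio
        summary["pca"] = {
            "explained_variance_ratio": [float(v) for v in evr[:5]],
            "pc1_pc2_cumulative": float(evr[:2].sum()),
        }

    # -- similarity indices --------------------------------------------------
    sim = None
    if "similarity" not in skip:
        responders = response.responders if response is not None else None
        sim = similarity_indices.similarity_table(dataset, dd, responders)
        sim.per_molecule.to_csv(out / "similarity_indices.csv", index=False)
        sim.tpsm.to_csv(out / "tpsm.csv")
        if sim.fasting_correlation is not None:
            sim.fasting_correlation.to_csv(out / "fasting_correlation.csv")
            fast = sim.fasting_correlation.dropna(axis=0)
            if len(fast) >= cfg.n_clusters_fasting:
                fc_clusters = pattern_decomposition.hierarchical_cluster(
                    fast, cfg.n_clusters_fasting
                )
                fc_clusters.assignment.rename("cluster").to_frame().to_csv(
                    out / "fasting_correlation_clusters.csv"
                )
                summary["fasting_correlation_clusters"] = {
                    "n_clusters": fc_clusters.n_clusters,
                    "sizes": fc_clusters.assignment.value_counts().sort_index().tolist(),
                }
        valid = sim.per_molecule.dropna(subset=["tpsi", "tvri"])
        summary["similarity"] = {
            "n_molecules": len(sim.per_molecule),
            "n_skipped_tvri": len(sim.skipped),
            "mean_tpsi": float(valid["tpsi"].mean()) if len(valid) else None,
            "mean_tvri": float(valid["tvri"].mean()) if len(valid) else None,
        }

    # -- similarity network --------------------------------------------------
    if "network" not in skip and sim is not None:
        mg = network_analysis.analyse_network(
            sim.tpsm, groups, threshold=cfg.tpsm_threshold
        )
        mg.edges.to_csv(out / "network_edges.csv", index=False)
        mg.node_table().to_csv(out / "network_nodes.csv", index=False)
        comp_sizes: dict[int, int] = {}
        for cid in mg.components.values():
            comp_sizes[cid] = comp_sizes.get(cid, 0) + 1
        top = max(mg.betweenness, key=mg.betweenness.get) if mg.betweenness else None
        summary["network"] = {
            "n_edges": mg.graph.number_of_edges(),
            "n_connected": len(mg.components),
            "n_isolated": len(mg.isolated),
            "n_components": len(comp_sizes),
            "component_sizes": sorted(comp_sizes.values(), reverse=True),
            "top_betweenness_molecule": top,
            "top_betweenness": float(mg.betweenness[top]) if top else None,
        }
        logger.info(
            "network: %d edges, %d components",
            summary["network"]["n_edges"], summary["network"]["n_components"],
        )

    # -- per-individual feature screen ---------------------------------------
    if "features" not in skip:
        targets = _screen_targets(response, clusters)
        ft = temporal_features.feature_table(dd, targets or None)
        ft.table.to_csv(out / "features.csv", index=False)
        references = cfg.reference_molecules or _default_references(pca, response)
        screen = temporal_features.feature_correlation_screen(
            ft,
            references=references,
            targets=targets or list(dd.molecule_ids),
            q_threshold=cfg.q_threshold,
            lam=cfg.qvalue_lambda,
        )
        screen.to_csv(out / "feature_screen.csv", index=False)
        summary["features"] = {
            "references": references,
            "n_targets": len(targets) if targets else len(dd.molecule_ids),
            "n_pairs_tested": len(screen),
            "n_significant": int(screen["significant"].sum()) if len(screen) else 0,
        }

    summary_json = json.dumps(_jsonable(summary), indent=2, sort_keys=True)
    (out / "summary.json").write_text(summary_json)
    return summary


def _screen_targets(response, clusters) -> list[str]:
    """Responders in the first six panel clusters (the clearly responsive
    branches of the dendrogram); falls back to all responders when the panel
    clustering was skipped."""
    if response is None:
        return []
    responders = set(response.responders)
    if clusters is None:
        return sorted(responders)
    in_first_six = {
        m for m, c in clusters.assignment.items() if c <= 6 and m in responders
    }
    return sorted(in_first_six)


def _default_references(pca, response) -> list[str]:
    """Reference molecules for the feature screen when none are configured:
    the two responders with the largest positive amplitude (PC1) scores,
    which in a glucose-challenge panel are the glucose/insulin-like pair."""
    if pca is None or response is None:
        return []
    responders = [m for m in response.responders if m in pca.scores.index]
    if not responders:
        return []
    ranked = pca.scores.loc[responders, "PC1"].sort_values(ascending=False)
    return list(ranked.index[:2])
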