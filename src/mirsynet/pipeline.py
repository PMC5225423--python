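"""End-to-end discovery pipeline with a reproducible run summary.

Stages: missing-value preprocessing -> differential screen -> Pearson CE
pairs and strata -> cross-validated SVM/AUC evaluation -> co-target
synergy network -> clique-percolation modules -> global topology.  Every
intermediate table is written under ``out_dir`` and a ``summary.json``
records parameters, seed and headline numbers so a run can be reproduced
exactly.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__, classify, correlation, cpm, diffexpr, io, simulate, synergy, topology
from .containers import ExpressionMatrix, PathwayAnnotation, TargetMap

__all__ = ["RunConfig", "PipelineError", "run_discovery"]

log = logging.getLogger("mirsynet")


class PipelineError(RuntimeError):
    """A stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str) -> None:
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """All inputs and stage parameters of one discovery run.

    When ``expression_path`` is None, inputs are simulated from
    ``simulation`` / ``annotation`` dictionaries (fields of
    SimulationConfig / AnnotationConfig); otherwise expression, labels,
    target tables and a GMT file are read from disk.  Defaults equal the
    screening thresholds the pipeline is built around (p < 0.05,
    |log2FC| >= 0.8, FDR < 0.05, CE strata at 0.6/0.7/0.8, 5-fold CV,
    synergy alpha 0.05, CPM k = 3).
    """

    out_dir: str = "mirsynet_run"
    seed: int = 0
    # file inputs (optional; simulated when absent)
    expression_path: str | None = None
    labels_path: str | None = None
    target_paths: list[str] = field(default_factory=list)
    min_db: int = 4
    gmt_path: str | None = None
    # simulation settings (used when expression_path is None)
    simulation: dict = field(default_factory=dict)
    annotation: dict = field(default_factory=dict)
    n_synergy_pairs: int = 3
    # stage parameters
    max_missing_frac: float = 0.2
    de_method: str = "moderated_t"
    p_thr: float = diffexpr.P_THRESHOLD
    lfc_thr: float = diffexpr.LFC_THRESHOLD
    fdr_thr: float = diffexpr.FDR_THRESHOLD
    ce_bin_edges: tuple[float, ...] = correlation.DEFAULT_BIN_EDGES
    n_folds: int = 5
    regularization: float = 1.0
    kernel_width: float | str = "auto"
    alpha: float = synergy.ALPHA
    k: int = 3
    n_top_singles: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.ce_bin_edges = tuple(cfg.ce_bin_edges)
        return cfg


def _simulate_inputs(config: RunConfig):
    sim = simulate.SimulationConfig(seed=config.seed, **config.simulation)
    matrix, truth = simulate.generate_expression(sim)
    de_ids = sorted(truth.de_effects)
    planted = [
        (de_ids[2 * i], de_ids[2 * i + 1])
        for i in range(min(config.n_synergy_pairs, len(de_ids) // 2))
    ]
    ann = simulate.AnnotationConfig(
        mirna_ids=matrix.mirna_ids,
        planted_synergy_pairs=planted,
        seed=config.seed + 1,
        **config.annotation,
    )
    target_map, pathways, ann_truth = simulate.generate_annotation(ann)
    truth.synergy_pairs = ann_truth.synergy_pairs
    return matrix, target_map, pathways, truth


def _load_inputs(config: RunConfig):
    matrix = io.read_expression(config.expression_path, config.labels_path)
    target_map = (
        io.read_consensus_targets(config.target_paths, config.min_db)
        if config.target_paths
        else TargetMap({})
    )
    pathways = io.read_gmt(config.gmt_path) if config.gmt_path else PathwayAnnotation({"none": frozenset({"_"})})
    return matrix, target_map, pathways, None


def run_discovery(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run summary."""
    out = Path(config.out_dir)
    tables = out / "tables"
    networks = out / "networks"
    tables.mkdir(parents=True, exist_ok=True)
    networks.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        summary = _run_stages(config, tables, networks)
    finally:
        log.removeHandler(handler)
        handler.close()
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, type(exc).__name__, str(exc)) from exc
        return wrapped
    return deco


def _run_stages(config: RunConfig, tables: Path, networks: Path) -> dict:
    # ---- inputs
    load = _stage("input")(_load_inputs if config.expression_path else _simulate_inputs)
    matrix, target_map, pathways, truth = load(config)
    log.info("input: %d miRNAs x %d samples, %d missing cells",
             len(matrix.mirna_ids), len(matrix.sample_ids), matrix.n_missing)
    if config.expression_path is None:
        io.write_expression(matrix, tables / "expression.tsv", tables / "labels.tsv")
        io.write_targets(target_map, tables / "targets.tsv")
        io.write_gmt(pathways, tables / "pathways.gmt")
        if truth is not None:
            (tables / "ground_truth.json").write_text(
                json.dumps(truth.to_jsonable(), indent=2, sort_keys=True) + "\n"
            )

    # ---- differential screen
    clean = _stage("preprocess")(diffexpr.preprocess)(matrix, config.max_missing_frac)
    log.info("preprocess: kept %d/%d rows", len(clean.mirna_ids), len(matrix.mirna_ids))
    results = _stage("differential_test")(diffexpr.differential_test)(clean, config.de_method)
    results["fdr"] = diffexpr.bh_adjust(results["p_value"].to_numpy())
    results = _stage("filter_demirs")(diffexpr.filter_demirs)(
        results, config.p_thr, config.lfc_thr, config.fdr_thr
    )
    results.to_csv(tables / "differential.tsv", sep="\t", index_label="mirna_id")
    demirs = results.index[results["passes"]].tolist()
    n_up = int((results["passes"] & (results["direction"] == "up")).sum())
    n_down = int((results["passes"] & (results["direction"] == "down")).sum())
    log.info("differential screen: %d DEmiRs (%d up, %d down)", len(demirs), n_up, n_down)

    # ---- correlation pairs and strata
    if len(demirs) >= 2:
        pairs = _stage("pairwise_ce")(correlation.pairwise_ce)(clean, demirs)
        strata = correlation.stratify_pairs(pairs, config.ce_bin_edges)
    else:
        pairs, strata = [], {}
        log.warning("fewer than 2 DEmiRs; correlation and network stages are empty")
    correlation.pairs_table(pairs, strata).to_csv(tables / "pairs.tsv", sep="\t", index=False)
    n_pos = sum(1 for p in pairs if p.ce > 0)
    n_neg = len(pairs) - n_pos
    log.info("correlation: %d pairs (%d positive, %d negative)", len(pairs), n_pos, n_neg)

    # ---- classifier evaluation
    cv = classify.CVConfig(
        n_folds=config.n_folds, seed=config.seed,
        kernel_width=config.kernel_width, regularization=config.regularization,
    )
    feature_sets = classify.stratum_feature_sets(strata)
    ranked = results.loc[demirs].reindex(
        results.loc[demirs, "log2fc"].abs().sort_values(ascending=False).index
    )
    for m in ranked.index[: config.n_top_singles]:
        feature_sets[f"single: {m}"] = [m]
    top_up = [m for m in ranked.index if ranked.at[m, "direction"] == "up"][:2]
    top_down = [m for m in ranked.index if ranked.at[m, "direction"] == "down"][:2]
    if top_up or top_down:
        feature_sets["panel: top up+down"] = top_up + top_down
    if feature_sets:
        auc_table = _stage("classify")(classify.evaluate_feature_sets)(clean, feature_sets, cv)
    else:
        auc_table = pd.DataFrame(columns=["set_name", "n_features", "auc"])
    auc_table.to_csv(tables / "auc.tsv", sep="\t", index=False)

    # ---- synergy network
    candidates = list(itertools.combinations(sorted(demirs), 2))
    graph = _stage("build_network")(synergy.build_network)(
        candidates, clean, target_map, pathways, config.alpha
    )
    _edge_table(graph).to_csv(tables / "network_edges.tsv", sep="\t", index=False)
    if graph.number_of_edges() > 0:
        io.write_network(graph, networks / "synergy.sif", "SIF")
        io.write_network(graph, networks / "synergy.graphml", "GraphML")
    log.info("network: %d nodes, %d edges (%d positive, %d negative)",
             graph.number_of_nodes(), graph.number_of_edges(),
             graph.graph.get("n_positive_edges", 0), graph.graph.get("n_negative_edges", 0))

    # ---- modules and topology
    modules = _stage("clique_percolation")(cpm.clique_percolation)(graph, config.k)
    pd.DataFrame(
        [
            {"module_index": m.index, "k": m.k, "mirnas": ",".join(sorted(m.members))}
            for m in modules
        ],
        columns=["module_index", "k", "mirnas"],
    ).to_csv(tables / "modules.tsv", sep="\t", index=False)
    if graph.number_of_nodes() > 0:
        topo = _stage("global_topology")(topology.global_topology)(graph)
        topo.to_frame().to_csv(tables / "topology.tsv", sep="\t", index=False)
        topo_dict = asdict(topo)
    else:
        topo_dict = None

    summary = {
        "version": __version__,
        "seed": config.seed,
        "parameters": _jsonable_config(config),
        "n_mirnas_input": len(matrix.mirna_ids),
        "n_mirnas_screened": len(clean.mirna_ids),
        "n_samples": len(matrix.sample_ids),
        "n_demirs": len(demirs),
        "n_demirs_up": n_up,
        "n_demirs_down": n_down,
        "n_pairs": len(pairs),
        "n_pairs_positive": n_pos,
        "n_pairs_negative": n_neg,
        "auc": {r.set_name: round(float(r.auc), 6) for r in auc_table.itertuples()},
        "network_nodes": graph.number_of_nodes(),
        "network_edges": graph.number_of_edges(),
        "network_edges_positive": graph.graph.get("n_positive_edges", 0),
        "network_edges_negative": graph.graph.get("n_negative_edges", 0),
        "n_modules": len(modules),
        "modules": [sorted(m.members) for m in modules],
        "topology": topo_dict,
    }
    return summary


def _edge_table(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "mirna_a": a,
            "mirna_b": b,
            "ce": data["ce"],
            "sign_class": data["sign_class"],
            "co_target_count": data["co_target_count"],
            "best_pathway": data["best_pathway"],
            "best_adjusted_p": data["best_adjusted_p"],
        }
        for a, b, data in sorted(graph.edges(data=True))
    ]
    return pd.DataFrame(
        rows,
        columns=["mirna_a", "mirna_b", "ce", "sign_class",
                 "co_target_count", "best_pathway", "best_adjusted_p"],
    )


def _jsonable_config(config: RunConfig) -> dict:
    data = asdict(config)
    data["ce_bin_edges"] = list(config.ce_bin_edges)
    return data
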