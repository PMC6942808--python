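"""End-to-end pipeline orchestration.

Runs the six stages in order — expert-consensus screening, cohort
description, Lasso core-symptom selection, boosted-tree diagnostic model,
symptom-gene-pathway network analysis, and multilayer assembly — from a
single YAML-able configuration, persisting each stage's outputs plus a
manifest of every tunable and seed.

Inputs default to the packaged synthetic generators; any stage input can
instead point at files on disk (expert scores CSV, cohort CSV, knowledge
base snapshot directory).  One master seed is fanned out to per-stage
seeds as ``master_seed + stage offset`` (offsets 1..5 in stage order), so
runs are reproducible and stages are decoupled.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import boost, cohort, delphi, lasso, netbio, simulate, tripartite

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("delphi", "cohort", "select", "model", "network", "multilayer")
_STAGE_SEED_OFFSET = {name: i + 1 for i, name in enumerate(STAGES)}


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # inputs; None = generate synthetically
    expert_scores_csv: str | None = None
    cohort_csv: str | None = None
    knowledge_base_dir: str | None = None
    # synthetic-generation parameters
    n_experts: int = 54
    n_subjects: int = simulate.DEFAULT_N
    prevalence_target: float = simulate.DEFAULT_PREVALENCE
    kb_n_genes: int = 300
    kb_n_terms: int = 20
    kb_n_pathways: int = 12
    kb_hub_fraction: float = 0.1
    # stage tunables
    cv_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    standardize: bool = False
    test_fraction: float = 0.3
    model_params: dict = field(default_factory=lambda: dict(boost.PAPER_OPTIMAL_PARAMS))
    run_grid_search: bool = False
    param_grid: dict | None = None
    grid_folds: int = 5
    min_interaction_score: float = 0.4
    hub_multiplier: float = 2.0
    enrichment_alpha: float = 0.05
    enrichment_top_n: int = 20

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def validate(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        for name, path in (
            ("expert_scores_csv", self.expert_scores_csv),
            ("cohort_csv", self.cohort_csv),
            ("knowledge_base_dir", self.knowledge_base_dir),
        ):
            if path is not None and not Path(path).exists():
                raise ValueError(f"configured {name} does not exist: {path}")

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + _STAGE_SEED_OFFSET[stage]

    def manifest(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        out["stage_seeds"] = {s: self.stage_seed(s) for s in self.stages}
        return out


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the configured stages; returns the run directory.

    Each stage writes its report under ``outdir/<stage>/``.  A stage
    failure propagates as an exception whose message names the stage;
    outputs of earlier stages are retained.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_json(outdir / "manifest.json", config.manifest())

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        stage_dir = outdir / stage
        stage_dir.mkdir(exist_ok=True)
        try:
            _STAGE_RUNNERS[stage](config, stage_dir, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s complete", stage)
    return outdir


def _stage_delphi(config: PipelineConfig, outdir: Path, state: dict) -> None:
    if config.expert_scores_csv:
        matrix = delphi.ExpertScoreMatrix.from_csv(config.expert_scores_csv)
    else:
        matrix = simulate.generate_expert_scores(
            config.n_experts, simulate.default_expert_items(), seed=config.stage_seed("delphi")
        )
    stats, thresholds, screening = delphi.screen_items(matrix)
    alpha = delphi.cronbach_alpha(matrix)
    stats.round(4).to_csv(outdir / "item_statistics.csv")
    screening.to_frame().to_csv(outdir / "screening.csv", index=False)
    _write_json(
        outdir / "summary.json",
        {
            "thresholds": dataclasses.asdict(thresholds),
            "n_retained": screening.n_retained,
            "n_deleted": screening.n_deleted,
            "cronbach_alpha": alpha.alpha,
        },
    )
    state["screening"] = screening


def _stage_cohort(config: PipelineConfig, outdir: Path, state: dict) -> None:
    if config.cohort_csv:
        dataset = simulate.ClinicalDataset.from_csv(config.cohort_csv)
        truth = None
    else:
        dataset, truth = simulate.generate_clinical_cohort(
            n=config.n_subjects,
            prevalence_target=config.prevalence_target,
            seed=config.stage_seed("cohort"),
        )
        dataset.to_csv(outdir / "cohort.csv")
    rows = []
    for covariate in ("gender", "age_group"):
        table = cohort.crosstab(dataset, covariate)
        result = cohort.pearson_chi_square(table)
        rows.append(
            {
                "covariate": covariate,
                "counts": table.counts.tolist(),
                "levels": list(table.col_labels),
                "chi2": round(result.statistic, 3),
                "p_value": result.p_value,
            }
        )
    _write_json(
        outdir / "group_comparisons.json",
        {"n": len(dataset), "prevalence": dataset.prevalence, "tests": rows},
    )
    state["dataset"] = dataset
    state["truth"] = truth


def _stage_select(config: PipelineConfig, outdir: Path, state: dict) -> None:
    dataset = state["dataset"]
    selected, path, curve = lasso.select_core_symptoms(
        dataset,
        k=config.cv_folds,
        seed=config.stage_seed("select"),
        standardize=config.standardize,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    import pandas as pd

    pd.DataFrame(
        {
            "lambda": curve.lambda_grid,
            "mean_deviance": curve.mean_deviance,
            "se_deviance": curve.se_deviance,
        }
    ).to_csv(outdir / "cv_curve.csv", index=False)
    pd.DataFrame(
        {"symptom": selected.names, "coefficient": [selected.coefficients[s] for s in selected.names]}
    ).to_csv(outdir / "core_symptoms.csv", index=False)
    _write_json(
        outdir / "selection.json",
        {
            "lambda_min": curve.lambda_min,
            "lambda_1se": curve.lambda_1se,
            "n_selected": len(selected.names),
        },
    )
    state["selected"] = selected


def _stage_model(config: PipelineConfig, outdir: Path, state: dict) -> None:
    dataset = state["dataset"]
    selected = state.get("selected")
    features = selected.names if selected and selected.names else list(dataset.symptoms)
    reduced = simulate.ClinicalDataset(
        dataset.frame[["subject_id", "gender", "age_group", *features, "label"]].copy(), features
    )
    seed = config.stage_seed("model")
    train, test = boost.split_train_test(reduced, config.test_fraction, seed=seed)
    if config.run_grid_search:
        params, cv_acc = boost.grid_search(
            train, config.param_grid, k=config.grid_folds, seed=seed
        )
    else:
        params, cv_acc = dict(config.model_params), None
    model = boost.fit_model(train, params, seed=seed)
    model.threshold = boost.optimal_threshold(model, train)
    metrics = boost.classification_metrics(test.y, model.predict_proba(test.X), model.threshold)
    points, _ = boost.roc_auc(test.y, model.predict_proba(test.X))
    import pandas as pd

    pd.DataFrame(points, columns=["fpr", "tpr"]).to_csv(outdir / "roc_points.csv", index=False)
    boost.gain_importance(model).to_csv(outdir / "gain_importance.csv", index=False)
    model.save(outdir / "model.json")
    _write_json(
        outdir / "metrics.json",
        {
            "params": params,
            "cv_accuracy": cv_acc,
            "threshold": model.threshold,
            "test_metrics": metrics.to_dict(),
        },
    )
    state["model"] = model
    state["metrics"] = metrics


def _stage_network(config: PipelineConfig, outdir: Path, state: dict) -> None:
    if config.knowledge_base_dir:
        kb = simulate.read_knowledge_base(config.knowledge_base_dir)
    else:
        kb = simulate.generate_knowledge_base(
            n_genes=config.kb_n_genes,
            n_terms=config.kb_n_terms,
            n_pathways=config.kb_n_pathways,
            hub_fraction=config.kb_hub_fraction,
            seed=config.stage_seed("network"),
        )
        simulate.write_knowledge_base(kb, outdir / "knowledge_base")
    selected = state.get("selected")
    core = [s for s in (selected.names if selected else []) if s in kb.symptom_term_map]
    if not core:
        core = list(kb.symptom_term_map)
    terms, unmapped = netbio.map_symptoms_to_terms(core, kb.symptom_term_map)
    genes = netbio.genes_for_terms(terms, kb.term_gene_table)
    graph = netbio.build_interaction_graph(
        genes, kb.interaction_edges, min_score=config.min_interaction_score
    )
    hubs = netbio.select_hub_nodes(graph, multiplier=config.hub_multiplier)
    hub_graph = graph.subgraph(hubs)
    universe = sorted(kb.gene_universe)
    enrichment = netbio.enrich_gene_sets(
        hubs or genes, kb.pathway_sets, universe,
        alpha=config.enrichment_alpha, top_n=config.enrichment_top_n,
    )
    enrichment.to_csv(outdir / "enrichment.csv", index=False)
    (outdir / "hub_genes.csv").write_text("gene\n" + "\n".join(sorted(hubs)) + "\n")
    payload = {
        "n_terms": len(terms),
        "unmapped_symptoms": unmapped,
        "n_query_genes": len(genes),
        "n_hub_genes": len(hubs),
        "topology": dataclasses.asdict(netbio.graph_topology(graph)),
    }
    if hub_graph.number_of_nodes():
        payload["hub_topology"] = dataclasses.asdict(netbio.graph_topology(hub_graph))
    _write_json(outdir / "network.json", payload)
    state.update({"kb": kb, "hubs": hubs, "enrichment": enrichment, "core": core})


def _stage_multilayer(config: PipelineConfig, outdir: Path, state: dict) -> None:
    kb = state["kb"]
    net = tripartite.assemble_tripartite(
        {s: kb.symptom_term_map[s] for s in state["core"]},
        state["hubs"],
        kb.term_gene_table,
        kb.pathway_sets,
        state["enrichment"]["name"].tolist(),
    )
    tripartite.validate_multilayer(net)
    tripartite.export_network(net, outdir)
    _write_json(outdir / "layer_counts.json", tripartite.layer_counts(net))


_STAGE_RUNNERS = {
    "delphi": _stage_delphi,
    "cohort": _stage_cohort,
    "select": _stage_select,
    "model": _stage_model,
    "network": _stage_network,
    "multilayer": _stage_multilayer,
}
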