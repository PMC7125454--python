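"""End-to-end orchestration: simulate/ingest -> DE -> risk genes ->
pathway scores -> correlated pairs -> network -> topology -> CV ranking.

Every stage writes its artifact as plain TSV (plus SIF/GraphML for the
network) under the output directory, and a JSON run manifest records the
resolved configuration, the per-stage record counts and the seed.  The
manifest is deterministic for a fixed seed (wall-clock timestamps go to
the log, not the manifest, so that identical runs produce identical
manifests).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import rank_candidates
from .diffexpr import differential_expression, normalize_library_sizes, depth_adjusted_counts
from .io import (
    read_count_matrix,
    read_gene_sets,
    read_interactions,
    read_labels,
    write_count_matrix,
    write_gene_sets,
    write_interactions,
    write_labels,
    write_network,
)
from .network import build_network, topology_report
from .pathways import correlated_pairs, pathway_differential, score_pathways
from .risk import map_risk_genes
from .simulate import HubSpec, SimulationConfig, simulate_all
from .types import TUMOR, significant_features

logger = logging.getLogger(__name__)

STAGES = ("simulate", "de", "pathways", "network", "topology", "classify")


class ConfigError(ValueError):
    """Invalid or out-of-range pipeline configuration."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    # inputs: either file paths ...
    mrna_path: str | None = None
    mirna_path: str | None = None
    labels_path: str | None = None
    gene_sets_path: str | None = None
    targets_path: str | None = None
    # ... or a simulation
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # thresholds (printed defaults of the study design)
    alpha: float = 0.05
    lfc_genes: float = 1.0       # strict >
    lfc_pathways: float = 1.0    # inclusive >=
    r_threshold: float = 0.8     # strict >
    min_pathway_members: int = 1
    # behavior flags
    restrict_pairs_to_de_pathways: bool = True
    include_pathway_pathway_edges: bool = True
    pathway_de_backend: str = "nb"
    k_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0 <= self.r_threshold <= 1:
            raise ConfigError("r_threshold must be in [0, 1]")
        if self.lfc_genes < 0 or self.lfc_pathways < 0:
            raise ConfigError("log2FC cutoffs must be >= 0")
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")
        if self.pathway_de_backend not in ("nb", "wilcoxon"):
            raise ConfigError(f"unknown pathway_de_backend: {self.pathway_de_backend!r}")
        if not self.simulate:
            needed = ["mrna_path", "mirna_path", "labels_path", "gene_sets_path", "targets_path"]
            missing = [k for k in needed if getattr(self, k) is None]
            if missing:
                raise ConfigError(f"file inputs required when simulate=false: {missing}")


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a YAML key-value config, applying defaults and rejecting unknowns."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    sim_raw = raw.pop("simulation", {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)} - {"simulation"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
    sim_unknown = set(sim_raw) - sim_known
    if sim_unknown:
        raise ConfigError(f"unknown simulation keys: {sorted(sim_unknown)}")
    try:
        hub = sim_raw.get("hub")
        if isinstance(hub, dict):
            sim_raw["hub"] = HubSpec(**hub)
        for key in ("lib_size_range", "pathway_size_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        sim = SimulationConfig(**sim_raw)
        cfg = PipelineConfig(simulation=sim, **raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    if "seed" in raw and "seed" not in sim_raw:
        cfg.simulation.seed = cfg.seed
    logger.info("resolved config: %s", cfg)
    return cfg


def _write_de(df, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False,
              columns=["feature", "log2fc", "p_value", "p_adj", "direction", "mean_expr"])


def run_pipeline(config: PipelineConfig, out_dir: str | Path, stop_after: str = "classify") -> dict:
    """Execute the pipeline, writing every intermediate artifact plus a manifest.

    ``stop_after`` truncates the run after the named stage (one of
    simulate/de/pathways/network/topology/classify).  Returns the manifest
    dict; also written as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if stop_after not in STAGES:
        raise ConfigError(f"unknown stage: {stop_after!r}")
    last = STAGES.index(stop_after)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "counts": {},
    }
    truth = None
    stage = "ingest"
    t0 = time.perf_counter()
    try:
        # --- inputs ---------------------------------------------------
        if config.simulate:
            stage = "simulate"
            config.simulation.seed = config.seed if config.simulation.seed == 0 else config.simulation.seed
            mrna, mirna, sets, targets, truth = simulate_all(config.simulation)
            write_count_matrix(mrna, out / "mrna_counts.tsv")
            write_count_matrix(mirna, out / "mirna_counts.tsv")
            write_labels(mrna, out / "labels.tsv")
            write_gene_sets(sets, out / "pathways.gmt")
            write_interactions(targets, out / "targets.tsv")
            manifest["ground_truth"] = {
                "hub_gene": truth.hub_gene_id,
                "n_de_genes_planted": len(truth.de_gene_ids),
                "n_de_mirnas_planted": len(truth.de_mirna_ids),
                "planted_correlated_pairs": [list(p) for p in truth.correlated_pair_ids],
            }
        else:
            labels = read_labels(config.labels_path)
            mrna = read_count_matrix(config.mrna_path, labels)
            mirna = read_count_matrix(config.mirna_path, labels)
            sets = read_gene_sets(config.gene_sets_path)
            targets = read_interactions(config.targets_path)
        if last <= STAGES.index("simulate"):
            return _finish(manifest, out, t0)

        # --- differential expression ---------------------------------
        stage = "de"
        de_genes_tab = differential_expression(mrna, alpha=config.alpha, lfc_cut=config.lfc_genes)
        de_mirnas_tab = differential_expression(mirna, alpha=config.alpha, lfc_cut=config.lfc_genes)
        _write_de(de_genes_tab, out / "de_genes.tsv")
        _write_de(de_mirnas_tab, out / "de_mirnas.tsv")
        de_genes = significant_features(de_genes_tab)
        de_mirnas = significant_features(de_mirnas_tab)
        manifest["counts"]["n_de_genes"] = len(de_genes)
        manifest["counts"]["n_de_mirnas"] = len(de_mirnas)

        # --- risk genes ----------------------------------------------
        stage = "risk_genes"
        risk = map_risk_genes(de_mirnas, de_genes, targets)
        (out / "risk_genes.tsv").write_text(
            "gene\n" + "".join(f"{g}\n" for g in sorted(risk.risk_gene_ids))
        )
        (out / "mirna_gene_pairs.tsv").write_text(
            "mirna\tgene\n" + "".join(f"{m}\t{g}\n" for m, g in risk.pairs)
        )
        manifest["counts"]["n_risk_genes"] = len(risk.risk_gene_ids)
        manifest["counts"]["n_mirna_gene_pairs"] = len(risk.pairs)
        if not len(targets):
            logger.warning("empty target table: downstream network will be empty")
        if last <= STAGES.index("de"):
            return _finish(manifest, out, t0)

        # --- pathway scoring, DE, correlated pairs -------------------
        stage = "pathways"
        scores = score_pathways(mrna, sets, min_members=config.min_pathway_members)
        scores.scores.to_csv(out / "pathway_scores.tsv", sep="\t", index_label="pathway")
        de_path_tab = pathway_differential(
            scores, alpha=config.alpha, lfc_cut=config.lfc_pathways,
            backend=config.pathway_de_backend,
        )
        _write_de(de_path_tab, out / "de_pathways.tsv")
        de_pathways = significant_features(de_path_tab)
        restrict = set(de_pathways) if config.restrict_pairs_to_de_pathways else None
        pairs = correlated_pairs(scores, threshold=config.r_threshold, restrict_to=restrict)
        pairs.to_csv(out / "correlated_pairs.tsv", sep="\t", index=False)
        manifest["counts"]["n_de_pathways"] = len(de_pathways)
        manifest["counts"]["n_correlated_pairs"] = len(pairs)
        if last <= STAGES.index("pathways"):
            return _finish(manifest, out, t0)

        # --- network --------------------------------------------------
        stage = "network"
        directions = dict(zip(de_genes_tab["feature"], de_genes_tab["direction"]))
        net = build_network(
            pairs, risk, sets,
            include_pathway_pathway_edges=config.include_pathway_pathway_edges,
            gene_directions=directions,
        )
        write_network(net, out / "network.sif", "sif")
        write_network(net, out / "network.graphml", "graphml")
        manifest["counts"]["n_nodes"] = net.number_of_nodes()
        manifest["counts"]["n_edges"] = net.number_of_edges()
        if last <= STAGES.index("network"):
            return _finish(manifest, out, t0)

        # --- topology -------------------------------------------------
        stage = "topology"
        report = topology_report(net)
        report.to_csv(out / "topology.tsv", sep="\t", index=False)
        gene_rank = report[report["node_type"] == "gene"]
        manifest["top_gene_by_degree"] = (
            gene_rank.iloc[0]["node"] if len(gene_rank) else None
        )
        manifest["top_pathway_by_degree"] = (
            report[report["node_type"] == "pathway"].iloc[0]["node"]
            if (report["node_type"] == "pathway").any() else None
        )
        if last <= STAGES.index("topology"):
            return _finish(manifest, out, t0)

        # --- classification ------------------------------------------
        stage = "classify"
        labels01 = (mrna.condition == TUMOR).to_numpy().astype(int)
        gene_candidates = sorted(n for n, d in net.nodes(data=True) if d["node_type"] == "gene")
        mirna_candidates = sorted(n for n, d in net.nodes(data=True) if d["node_type"] == "mirna")
        results = []
        if gene_candidates:
            adj = depth_adjusted_counts(mrna, normalize_library_sizes(mrna))
            results += rank_candidates(adj, gene_candidates, labels01,
                                       k=config.k_folds, seed=config.seed)
        if mirna_candidates:
            adj = depth_adjusted_counts(mirna, normalize_library_sizes(mirna))
            results += rank_candidates(adj, mirna_candidates, labels01,
                                       k=config.k_folds, seed=config.seed)
        results.sort(key=lambda r: (-r.pooled_auc, r.feature))
        with open(out / "cv_ranking.tsv", "w", encoding="utf-8") as fh:
            fh.write("feature\tpooled_auc\tn_folds\tseed\tfold_aucs\n")
            for r in results:
                folds = ",".join(f"{a:.6g}" for a in r.fold_aucs)
                fh.write(f"{r.feature}\t{r.pooled_auc:.6g}\t{r.n_folds}\t{r.seed}\t{folds}\n")
        manifest["counts"]["n_candidates_ranked"] = len(results)
        if results:
            manifest["top_candidate_by_auc"] = results[0].feature
        return _finish(manifest, out, t0)
    except (ConfigError, StageError):
        raise
    except Exception as exc:  # pragma: no cover - wrapped for CLI exit codes
        raise StageError(stage, exc) from exc


def _config_echo(config: PipelineConfig) -> dict:
    echo = dataclasses.asdict(config)
    if echo.get("simulation", {}).get("hub") is not None:
        echo["simulation"]["hub"] = dataclasses.asdict(config.simulation.hub)
    return echo


def _finish(manifest: dict, out: Path, t0: float) -> dict:
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
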