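"""End-to-end orchestration of the co-expression analysis.

Stage order: probe collapsing (optional) -> per-time and injured-vs-
healthier differential expression -> gene selection (FDR < 0.005) ->
Pearson correlation -> soft threshold (beta = 6) -> edge filter
(tau = 0.26) -> module detection by both algorithms -> Jaccard comparison
-> permutation hub test -> module enrichment -> hub conservation ->
miR-target mapping. Every artifact is written as plain text under the
output directory, and results.json is byte-identical across runs with the
same inputs, config and seed.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .containers import ExpressionMatrix, GeneSet
from .diffexpr import (
    INJURED_VS_HEALTHIER,
    collapse_probes,
    moderated_t_test,
    per_time_contrasts,
    select_genes,
)
from .enrichment import conservation_chisq, hypergeometric_enrichment, map_mir_targets
from .hubs import permutation_hub_test
from .io import read_expression, read_gmt, read_table, write_network, write_table
from .modules import (
    compare_modules_jaccard,
    detect_modules_clusterone,
    detect_modules_hierarchical,
    topological_overlap,
)
from .network import correlation_matrix, network_stats, soft_threshold, tau_from_correlation, threshold_edges

__all__ = ["PipelineConfig", "ResultBundle", "PipelineError", "run_pipeline"]

log = logging.getLogger("heartnet")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All thresholds and paths of one pipeline run.

    Defaults are the study's analysis settings: selection at FDR < 0.005,
    per-time DEGs at FDR < 0.001, beta = 6, edge-weight filter 0.26
    (equivalently |r| >= 0.8 with ``edge_filter='correlation'``), hub test
    at adjusted p < 0.05, enrichment at FDR < 0.05.
    """

    expression: str = ""
    metadata: str = ""
    probe_map: str | None = None
    annotations: str | None = None
    orthology: str | None = None
    mir_table: str | None = None
    outdir: str = "heartnet_results"

    collapse_rule: str = "max-variance"
    fdr_select: float = 0.005
    fdr_pertime: float = 0.001
    beta: int = 6
    tau: float = 0.26
    edge_filter: str = "weight"  # 'weight' (tau on a_ij) or 'correlation' (|r| >= tau_r)
    tau_r: float = 0.8

    hier_min_size: int = 30
    hier_cut_quantile: float | None = None  # None = largest-gap cut rule
    hier_merge_threshold: float = 0.75
    c1_penalty: float = 2.0
    c1_min_size: int = 5
    c1_min_density: float = 0.5
    c1_overlap_merge: float = 0.8
    c1_alpha: float = 0.05

    hub_permutations: int = 1000
    hub_null: str = "weight-shuffle"
    hub_alpha: float = 0.05

    enrichment_alpha: float = 0.05
    species: tuple[str, ...] = ("human", "mouse", "rat")
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("fdr_select", 0, 1), ("fdr_pertime", 0, 1), ("tau", 0, 1),
            ("hub_alpha", 0, 1), ("enrichment_alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not lo < v < 1 if hi == 1 else not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.edge_filter not in ("weight", "correlation"):
            raise ValueError("edge_filter must be 'weight' or 'correlation'")
        self.species = tuple(self.species)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["species"] = list(self.species)
        return d


@dataclass
class ResultBundle:
    """All stage outputs of one run plus the provenance summary."""

    de_results: dict
    selected: GeneSet
    net_stats: object
    modules_hier: object
    modules_c1: object
    jaccard: object | None
    hubres: object
    enrichment: object | None
    conservation: list
    mir_interactions: object | None
    summary: dict = field(default_factory=dict)


def _effective_tau(cfg: PipelineConfig) -> float:
    if cfg.edge_filter == "correlation":
        return tau_from_correlation(cfg.tau_r, cfg.beta)
    return cfg.tau


def run_pipeline(
    config: PipelineConfig,
    expr: ExpressionMatrix | None = None,
) -> ResultBundle:
    """Run the full analysis and write all artifacts under ``config.outdir``.

    ``expr`` may be passed directly (e.g. from the simulator); otherwise the
    expression/metadata paths in the config are read. Deterministic given
    the same inputs, config and seed.
    """
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"config": cfg.to_dict(), "version": __version__, "stages": {}}

    def stage(name):
        log.info("stage %s", name)

        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                summary["stages"][name] = "failed"
                (outdir / "INCOMPLETE").write_text(f"failed at stage {name}: {exc}\n")
                raise PipelineError(name, exc) from exc

        return wrap

    try:
        if expr is None:
            expr = stage("read_expression")(read_expression, cfg.expression, cfg.metadata)
        if cfg.probe_map:
            probe_map = read_table(cfg.probe_map, ("probe", "gene"))
            expr = stage("collapse_probes")(collapse_probes, expr, probe_map, cfg.collapse_rule)
        summary["stages"]["input"] = {"n_genes": expr.n_genes, "n_samples": expr.n_samples}

        # differential expression: per-time contrasts and the selection contrast
        de_results = {}
        pertime_counts = {}
        present = set(expr.groups())
        for c in per_time_contrasts(tuple(g for g in ("4hpi", "1dpi", "3dpi", "7dpi", "14dpi", "90dpi") if g in present)):
            res = stage(f"de_{c.name}")(moderated_t_test, expr, c)
            de_results[c.name] = res
            pertime_counts[c.name] = int((res.table["fdr"] < cfg.fdr_pertime).sum())
            write_table(
                res.table.round(6).reset_index(names="gene"), outdir / f"de_{c.name}.tsv"
            )
        main_de = stage("de_injured_vs_healthier")(moderated_t_test, expr, INJURED_VS_HEALTHIER)
        de_results[INJURED_VS_HEALTHIER.name] = main_de
        write_table(
            main_de.table.round(6).reset_index(names="gene"),
            outdir / "de_injured_vs_healthier.tsv",
        )
        selected = stage("select_genes")(select_genes, main_de, cfg.fdr_select)
        (outdir / "selected_genes.txt").write_text("\n".join(selected.genes) + "\n")
        summary["stages"]["diffexpr"] = {
            "pertime_deg_counts": pertime_counts,
            "fdr_pertime": cfg.fdr_pertime,
            "n_selected": len(selected),
            "fdr_select": cfg.fdr_select,
            "d0": main_de.d0,
            "s02": main_de.s02,
        }
        if len(selected) < 10:
            exc = ValueError("fewer than 10 selected genes")
            (outdir / "INCOMPLETE").write_text(f"failed at stage select_genes: {exc}\n")
            raise PipelineError("select_genes", exc)

        corr = stage("correlation")(correlation_matrix, expr, selected.genes)
        net = stage("soft_threshold")(soft_threshold, corr, cfg.beta)
        tau = _effective_tau(cfg)
        net_t = stage("threshold_edges")(threshold_edges, net, tau)
        stats_t = stage("network_stats")(network_stats, net_t)
        summary["stages"]["network"] = {
            "beta": cfg.beta,
            "tau": tau,
            "n_nodes": net_t.n_nodes,
            "n_edges": stats_t.n_edges,
            "density": round(stats_t.density, 6),
            "heterogeneity": round(stats_t.heterogeneity, 6),
            "median_connectivity": round(stats_t.median_connectivity, 6),
            "scale_free_r2": round(stats_t.scale_free_r2, 6),
        }

        tom = stage("topological_overlap")(topological_overlap, net_t)
        sel_expr = expr.subset_genes(list(net_t.nodes))
        mod_h = stage("modules_hierarchical")(
            detect_modules_hierarchical,
            tom,
            sel_expr,
            cut_quantile=cfg.hier_cut_quantile,
            min_size=cfg.hier_min_size,
            merge_threshold=cfg.hier_merge_threshold,
        )
        mod_c = stage("modules_cohesiveness")(
            detect_modules_clusterone,
            net_t,
            penalty=cfg.c1_penalty,
            min_size=cfg.c1_min_size,
            min_density=cfg.c1_min_density,
            overlap_merge=cfg.c1_overlap_merge,
            alpha=cfg.c1_alpha,
        )
        jac = None
        if mod_h.modules and mod_c.modules:
            jac = stage("compare_modules")(compare_modules_jaccard, mod_h, mod_c)
            jac.matrix.round(6).to_csv(outdir / "module_jaccard.tsv", sep="\t")
        modules_payload = {
            ms.method: {
                m.id: list(m.genes) for m in ms.modules
            }
            for ms in (mod_h, mod_c)
        }
        with open(outdir / "modules.json", "w") as fh:
            json.dump(modules_payload, fh, indent=1, sort_keys=True)
        summary["stages"]["modules"] = {
            "n_hierarchical": len(mod_h),
            "n_cohesiveness": len(mod_c),
            "hier_sizes": [len(m) for m in mod_h],
            "c1_sizes": [len(m) for m in mod_c],
            "best_jaccard": None if jac is None else
                {"pair": list(jac.best_pair), "value": round(jac.best_value, 6)},
        }

        hubres = stage("hub_test")(
            permutation_hub_test,
            net_t,
            B=cfg.hub_permutations,
            seed=cfg.seed,
            null=cfg.hub_null,
            alpha=cfg.hub_alpha,
        )
        write_table(
            hubres.table.round(6).reset_index(names="gene"), outdir / "hubs.tsv"
        )
        summary["stages"]["hubs"] = {
            "n_hubs": hubres.n_hubs,
            "B": cfg.hub_permutations,
            "alpha": cfg.hub_alpha,
            "null": cfg.hub_null,
        }

        stage("write_network")(
            write_network, net_t, outdir / "network_edges.tsv", "edgelist"
        )
        stage("write_graphml")(
            write_network, net_t, outdir / "network.graphml", "graphml", mod_h, hubres
        )

        enr = None
        if cfg.annotations:
            ann = read_gmt(cfg.annotations)
            universe = set(net_t.nodes)
            enr = stage("enrichment")(
                hypergeometric_enrichment, mod_h, ann, universe, cfg.enrichment_alpha
            )
            write_table(enr.table.round(6), outdir / "enrichment.tsv")
            summary["stages"]["enrichment"] = {
                "n_tested_pairs": len(enr.table),
                "n_significant_pairs": int(enr.table["significant"].sum()) if len(enr.table) else 0,
                "n_enriched_modules": enr.n_enriched_modules() if len(enr.table) else 0,
            }

        conservation = []
        mir = None
        if cfg.orthology:
            orthology = read_table(cfg.orthology, ("gene", "species", "ortholog"))
            for sp in cfg.species:
                test = stage(f"conservation_{sp}")(conservation_chisq, hubres, orthology, sp)
                conservation.append(test)
            summary["stages"]["conservation"] = {
                t.species: {
                    "chi2": None if not t.defined else round(t.chi2, 4),
                    "pval": None if not t.defined else round(t.pval, 6),
                    "hub_ortholog_fraction": None
                    if np.isnan(t.hub_ortholog_fraction)
                    else round(t.hub_ortholog_fraction, 4),
                }
                for t in conservation
            }
            if cfg.mir_table:
                mir_df = read_table(cfg.mir_table, ("mir", "target", "species", "evidence"))
                mir = stage("mir_targets")(
                    map_mir_targets, hubres, orthology, mir_df, cfg.species
                )
                write_table(mir.table, outdir / "mir_interactions.tsv")
                summary["stages"]["mir_targets"] = {
                    f"{sp}_{ev}": n for (sp, ev), n in sorted(mir.summary.items())
                }

        with open(outdir / "results.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        return ResultBundle(
            de_results=de_results,
            selected=selected,
            net_stats=stats_t,
            modules_hier=mod_h,
            modules_c1=mod_c,
            jaccard=jac,
            hubres=hubres,
            enrichment=enr,
            conservation=conservation,
            mir_interactions=mir,
            summary=summary,
        )
    finally:
        log.removeHandler(handler)
        handler.close()
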