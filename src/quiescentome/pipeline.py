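"""End-to-end pipeline runner: simulate -> differential expression ->
enrichment -> regulator network -> interactome, with a run manifest.

Each stage writes plot-ready TSV tables into the run directory and records
itself in ``manifest.json`` (config echo + hash, seed, package versions,
coverage reports). Thresholds actually applied are logged at INFO once per
stage. Stage failures raise :class:`StageError` naming the stage.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, enrich, interactome, io, regnet, synthdata
from .types import CONTRASTS, ExpressionMatrix, ValidationError, contrast_name

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All thresholds of the analysis; defaults are the study settings."""

    outdir: str = "run"
    seed: int = 17
    simulate: bool = True
    # input paths (used when simulate is False)
    expr_path: str | None = None
    samples_path: str | None = None
    gmt_path: str | None = None
    annotations_path: str | None = None
    edges_path: str | None = None
    cell_profiles_path: str | None = None

    reference: str = "uM"
    donor_blocking: bool = True
    quantile_norm: bool = False         # synthetic data are already on one scale

    fdr: float = 0.05
    lfc: float = 0.58
    input_fdr: float = 0.1              # enrichment input-gene rule
    chord_lfc: float = 2.5
    de_p: float = 0.05                  # regulator-enrichment DE gene rule
    enrich_adj_p: float = 0.05
    enrich_q: float = 0.2
    r2_min: float = 0.85
    edge_keep: float = 0.05
    ppi_min_conf: float = 0.900
    top_k_regulators: int = 5
    top_n_heatmap: int = 25
    top_n_bar: int = 20
    background_bins: int = 10

    stages: tuple = ("simulate", "de", "enrich", "regnet", "interactome")
    sim: synthdata.SimConfig | None = None

    def validate(self) -> None:
        for name in ("fdr", "input_fdr", "de_p", "enrich_adj_p", "enrich_q",
                     "edge_keep", "ppi_min_conf"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name}={v} outside (0, 1]")
        if self.lfc < 0 or self.chord_lfc < 0:
            raise ValidationError("logFC cutoffs must be >= 0")
        if not 0.0 < self.r2_min <= 1.0:
            raise ValidationError("r2_min must lie in (0, 1]")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        return d


def _deg_union(deg_tables: dict) -> set:
    out: set = set()
    for t in deg_tables.values():
        out |= set(t["gene"])
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # the hash covers the analysis settings, not where results are written
    chash = io.config_hash({k: v for k, v in config.echo().items()
                            if k != "outdir"})
    comment = f"config_hash={chash}"
    manifest = {
        "config": config.echo(), "config_hash": chash, "seed": config.seed,
        "versions": _versions(), "stages": [], "coverage": [],
        "score_definition": regnet.SCORE_DEFINITION,
    }
    state: dict = {}

    def run_stage(name, fn):
        if name not in config.stages:
            return
        try:
            fn()
        except Exception as exc:             # noqa: BLE001 - rethrown with stage
            _write_manifest(manifest, outdir)
            raise StageError(name, exc) from exc
        manifest["stages"].append(name)

    def stage_simulate():
        sim_cfg = config.sim or synthdata.SimConfig(seed=config.seed)
        log.info("simulate: seed=%d n_genes=%d n_donors=%d",
                 sim_cfg.seed, sim_cfg.n_genes, sim_cfg.n_donors)
        study = synthdata.simulate(sim_cfg)
        state["study"] = study
        state["expr"] = study.expression
        state["sets"] = study.gene_sets
        state["ann"] = study.annotations
        state["edges"] = study.edges
        state["profiles"] = study.cell_profiles
        io.write_expression(study.expression, outdir / "expression.tsv",
                            outdir / "samples.tsv", comment=comment)
        io.write_gmt(study.gene_sets, outdir / "gene_sets.gmt")
        io.write_annotations(study.annotations, outdir / "annotations.tsv",
                             comment=comment)
        io.write_edges(study.edges, outdir / "edges.tsv", comment=comment)
        io.write_cell_profiles(study.cell_profiles, outdir / "cell_profiles.tsv",
                               comment=comment)
        io.write_truth(study.truth.table, outdir / "truth.tsv", comment=comment)

    def load_inputs():
        if "expr" in state:
            return
        needed = {"expr_path": config.expr_path, "samples_path": config.samples_path}
        missing = [k for k, v in needed.items() if v is None]
        if missing:
            raise ValidationError(
                f"no simulated data and no input paths for: {missing}; "
                "run the simulate stage or provide inputs")
        state["expr"] = io.read_expression(config.expr_path, config.samples_path)
        if config.gmt_path:
            state["sets"] = io.read_gmt(config.gmt_path)
        if config.annotations_path:
            state["ann"] = io.read_annotations(config.annotations_path,
                                               genes=state["expr"].genes)
        if config.edges_path:
            state["edges"] = io.read_edges(config.edges_path)
        if config.cell_profiles_path:
            state["profiles"] = io.read_cell_profiles(config.cell_profiles_path)

    def stage_de():
        load_inputs()
        expr = state["expr"]
        if config.quantile_norm:
            expr = diffexpr.quantile_normalize(expr)
            state["expr"] = expr
        log.info("de: fdr<%.3g |logFC|>%.3g donor_blocking=%s",
                 config.fdr, config.lfc, config.donor_blocking)
        results = diffexpr.run_contrasts(expr, donor_blocking=config.donor_blocking,
                                         reference=config.reference)
        state["results"] = results
        state["deg"] = {}
        for name, res in results.items():
            io.write_table(res.table, outdir / f"contrast_{name}.tsv", comment=comment)
            deg = diffexpr.select_deg(res, config.fdr, config.lfc)
            state["deg"][name] = deg
            io.write_table(deg, outdir / f"deg_{name}.tsv", comment=comment)

    def stage_enrich():
        if "sets" not in state:
            raise ValidationError("enrichment needs a gene-set collection "
                                  "(missing upstream simulate stage or --gmt)")
        expr, sets = state["expr"], state["sets"]
        log.info("enrich: input fdr<%.3g, theme padj<%.3g, chord |logFC|>%.3g, "
                 "%d background bins", config.input_fdr, enrich.THEME_SIG_ADJ_P,
                 config.chord_lfc, config.background_bins)
        ora_tables, theme_inputs = {}, []
        for name, res in state["results"].items():
            input_genes = set(res.table.loc[res.table["fdr"] < config.input_fdr,
                                            "gene"])
            if not input_genes:
                ora_tables[name] = pd.DataFrame(
                    columns=["set", "k", "K", "n", "N", "p", "padj"])
                continue
            bg = enrich.matched_background(input_genes, expr,
                                           bins=config.background_bins)
            ora_tables[name] = enrich.ora_hypergeometric(input_genes, bg, sets)
        for name, table in ora_tables.items():
            io.write_table(table, outdir / f"enrichment_{name}.tsv", comment=comment)
        # theme comparison on the strict DEG definition
        for name, res in state["results"].items():
            deg = state["deg"][name]
            if len(deg):
                bg = enrich.matched_background(set(deg["gene"]), expr,
                                               bins=config.background_bins)
                theme_inputs.append((name, enrich.ora_hypergeometric(
                    set(deg["gene"]), bg, sets)))
            else:
                theme_inputs.append((name, pd.DataFrame(
                    columns=["set", "k", "K", "n", "N", "p", "padj"])))
        theme = enrich.theme_compare(theme_inputs, state["deg"], sets)
        io.write_table(theme, outdir / "theme_comparison.tsv", comment=comment)
        state["enrichment"] = ora_tables
        # chord adjacency for the primary treatment contrast
        primary = contrast_name("hlf", config.reference)
        table = ora_tables.get(primary)
        enriched = list(table.loc[table["padj"] < config.enrich_adj_p, "set"]) \
            if table is not None and len(table) else []
        deg = state["deg"].get(primary, pd.DataFrame(columns=["gene", "logFC"]))
        adjacency, chord = enrich.deg_pathway_adjacency(
            deg, enriched, sets, lfc_filter=config.chord_lfc)
        state["adjacency"] = adjacency
        io.write_table(chord, outdir / "chord_edges.tsv", comment=comment)

    def stage_regnet():
        if "ann" not in state:
            raise ValidationError("regnet needs annotations (regulator class)")
        expr = state["expr"]
        regulators = set(state["ann"].loc[state["ann"]["class"] == "regulator",
                                          "gene"])
        deg_union = _deg_union(state["deg"])
        if len(deg_union) < 5:
            raise ValidationError("too few DEG to infer a network")
        log.info("regnet: R^2>=%.2f, top %.1f%% edges, DE p<%.3g, "
                 "adj p<%.3g, q<%.3g", config.r2_min, 100 * config.edge_keep,
                 config.de_p, config.enrich_adj_p, config.enrich_q)
        network = regnet.build_coexpression_network(
            expr.subset_genes(deg_union), regulators,
            r2_min=config.r2_min, edge_keep=config.edge_keep)
        io.write_table(network.edges, outdir / "network_edges.tsv",
                       comment=f"{comment} beta={network.beta} r2={network.r2:.4f}")
        primary = contrast_name("hlf", config.reference)
        res = state["results"][primary].table.set_index("gene")
        de_genes = set(res.index[res["p"] < config.de_p])
        enr = regnet.regulator_enrichment(network, de_genes, set(expr.genes),
                                          adj_p_cut=config.enrich_adj_p,
                                          q_cut=config.enrich_q)
        diff_p = np.array([
            float(res.loc[r, "p"]) if r in res.index else 1.0
            for r in enr["regulator"]])
        scores = regnet.regenrich_score(diff_p, enr["p"].to_numpy(),
                                        regulators=list(enr["regulator"]))
        scores = scores.merge(enr[["regulator", "n_targets", "overlap", "padj",
                                   "q", "significant"]], on="regulator")
        io.write_table(scores, outdir / "regulator_scores.tsv",
                       comment=f"{comment} score: {regnet.SCORE_DEFINITION}")
        io.write_table(regnet.top_regulators(scores, config.top_n_heatmap),
                       outdir / "top_regulators_heatmap.tsv", comment=comment)
        io.write_table(regnet.top_regulators(scores, config.top_n_bar),
                       outdir / "top_regulators_bar.tsv", comment=comment)
        state["network"], state["scores"] = network, scores
        adjacency = state.get("adjacency")
        if adjacency is not None and not adjacency.empty:
            sankey = regnet.attribute_regulators_to_pathways(
                network, adjacency, scores=scores, top_k=config.top_k_regulators)
            io.write_table(sankey, outdir / "sankey.tsv", comment=comment)
        if "edges" in state:
            physical = state["edges"][state["edges"]["channel"] == "physical"]
            ppi = regnet.filter_ppi_edges(physical, min_conf=config.ppi_min_conf)
            io.write_table(ppi, outdir / "ppi_filtered.tsv", comment=comment)

    def stage_interactome():
        for key in ("ann", "edges", "profiles"):
            if key not in state:
                raise ValidationError(f"interactome needs {key!r} from simulate "
                                      "or input paths")
        expr = state["expr"]
        log.info("interactome: reference=%s, channels physical+soluble",
                 config.reference)
        deg_union = _deg_union(state["deg"])
        all_deg = pd.DataFrame({"gene": sorted(deg_union)})
        class_of = {"soluble": "cytokine", "physical": "membrane"}
        macro_profile = interactome.condition_profile(expr)
        cell_z = interactome.standardize(state["profiles"])
        all_scores, drivers = [], {}
        for channel, cls in class_of.items():
            members = interactome.filter_by_annotation(all_deg, state["ann"], cls)
            macro_genes = [g for g in macro_profile.index if g in set(members["gene"])]
            macro_z = interactome.standardize(macro_profile.loc[macro_genes]) \
                if macro_genes else macro_profile.iloc[:0]
            scores, coverage = interactome.interaction_propensity(
                macro_z, cell_z, state["edges"], channel)
            manifest["coverage"].append(coverage)
            all_scores.append(scores)
            drivers[channel] = interactome.interaction_drivers(
                macro_z, cell_z, state["edges"], channel,
                cond_a="hlf_LPS", cond_b="uM_LPS",
                cell_profiles=state["profiles"],
                mean_expression=expr.values.mean(axis=1))
        scores = interactome.relative_to_reference(
            pd.concat(all_scores, ignore_index=True), reference=config.reference)
        io.write_table(scores, outdir / "propensity.tsv", comment=comment)
        for channel, table in drivers.items():
            io.write_table(table, outdir / f"drivers_{channel}.tsv", comment=comment)
        io.write_table(pd.DataFrame(manifest["coverage"]),
                       outdir / "coverage.tsv", comment=comment)
        # targeted ANOVA/Tukey on the strongest cytokine DEG
        cyto = interactome.filter_by_annotation(all_deg, state["ann"], "cytokine")
        targets = list(cyto["gene"][:10])
        if targets:
            io.write_table(diffexpr.anova_tukey(expr, targets),
                           outdir / "targeted_anova.tsv", comment=comment)

    run_stage("simulate", stage_simulate)
    run_stage("de", stage_de)
    run_stage("enrich", stage_enrich)
    run_stage("regnet", stage_regnet)
    run_stage("interactome", stage_interactome)
    _write_manifest(manifest, outdir)
    return outdir


def _versions() -> dict:
    import scipy
    from . import __version__
    return {"quiescentome": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__}


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
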