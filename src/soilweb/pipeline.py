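"""End-to-end orchestration: simulate -> metaweb -> SBM -> metrics -> beta -> stats.

Every stage reads and writes files under ``<workdir>/inputs`` and
``<workdir>/outputs`` so the CLI subcommands can run stages independently.
All artifacts are plain text (TSV / CSV / JSON / GraphML) and byte-stable
under fixed seeds.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import beta as beta_mod
from . import luistats, metaweb, netmetrics, sbm, synth
from .config import PipelineConfig
from .io import (export_graph, import_graph, read_tables, write_manifest,
                 write_tsv)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _outdir(config: PipelineConfig) -> Path:
    p = Path(config.workdir) / "outputs"
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(config: PipelineConfig) -> dict:
    scenario = synth.generate_scenario(config.scenario)
    paths = synth.write_scenario(scenario, Path(config.workdir) / "inputs")
    return {"paths": paths, "scenario": scenario}


def stage_metaweb(config: PipelineConfig) -> dict:
    tables = read_tables(config)
    kb, report = metaweb.compile_kb(tables["interactions"], tables["taxonomy"])
    kb = metaweb.generalize_within_families(kb, tables["taxonomy"])
    audit = {
        "n_input": report.n_input, "n_compiled": report.n_kept,
        "n_duplicates": report.n_duplicates,
        "n_rejects": len(report.rejects),
        "n_after_generalization": int(len(kb)),
    }
    if config.habitat_filter:
        kb = metaweb.filter_by_habitat(kb, tables["annotations"])
        audit["n_after_habitat"] = int(len(kb))
    if config.geography_filter:
        kb = metaweb.filter_by_geography(kb, tables["annotations"],
                                         config.target_region)
        audit["n_after_geography"] = int(len(kb))
    observed = list(tables["taxonomy"]["taxon_id"])
    if config.geography_filter:
        keep = metaweb.geography_survivors(observed, tables["annotations"],
                                           config.target_region)
        observed = [t for t in observed if t in keep]
    web = metaweb.build_metaweb(observed, kb, tables["annotations"])
    out = _outdir(config)
    export_graph(web, out / "metaweb.graphml", "graphml")
    export_graph(web, out / "metaweb", "tsv")
    (out / "filter_audit.json").write_text(
        json.dumps(audit, indent=1, sort_keys=True) + "\n")
    return {"metaweb": web, "kb": kb, "audit": audit, "tables": tables}


def _load_metaweb(config: PipelineConfig):
    return import_graph(_outdir(config) / "metaweb.graphml", "graphml")


def stage_sbm(config: PipelineConfig, web=None) -> dict:
    if web is None:
        web = _load_metaweb(config)
    import networkx as nx

    nodes = list(web.nodes)
    A = nx.to_numpy_array(web, nodelist=nodes, weight=None)
    A = (A > 0).astype(float)
    np.fill_diagonal(A, 0.0)
    fit = sbm.select_Q(A, Q_range=range(config.q_min, config.q_max + 1),
                       restarts=config.sbm_restarts, seed=config.sbm_seed,
                       tol=config.sbm_tol, max_iter=config.sbm_max_iter)
    guilds = {n: d.get("guild", "") for n, d in web.nodes(data=True)}
    gweb = sbm.group_metaweb(fit, nodes, guilds)
    out = _outdir(config)
    (out / "sbm_fit.json").write_text(
        json.dumps(fit.to_dict(), sort_keys=True) + "\n")
    write_tsv(pd.DataFrame({"taxon_id": nodes,
                            "group": [gweb.membership[n] for n in nodes]}),
              out / "membership.tsv")
    pd.DataFrame(fit.icl_table, columns=["Q", "icl"]).to_csv(
        out / "icl_table.csv", index=False, lineterminator="\n")
    return {"fit": fit, "group_metaweb": gweb, "nodes": nodes}


def _load_membership(config: PipelineConfig) -> dict[str, int]:
    df = pd.read_csv(_outdir(config) / "membership.tsv", sep="\t")
    return dict(zip(df["taxon_id"], df["group"].astype(int)))


def _group_level_web(local, membership, group_pi: np.ndarray | None,
                     group_guild: dict[int, str]):
    """Collapse one local web onto the groups present in it."""
    import networkx as nx

    g = nx.DiGraph()
    reads: dict[int, int] = {}
    for n in local.graph.nodes:
        if n not in membership:
            continue
        q = membership[n]
        reads[q] = reads.get(q, 0) + int(local.read_counts.get(n, 0))
    for q in sorted(reads):
        g.add_node(q, guild=group_guild.get(q, ""), reads=reads[q])
    present = set(reads)
    if group_pi is not None:
        for q in sorted(present):
            for r in sorted(present):
                if q != r and group_pi[q, r] >= 0.5:
                    g.add_edge(q, r, type="predation",
                               weight=float(group_pi[q, r]))
    return g, reads


def stage_metrics(config: PipelineConfig, web=None, sbm_result=None) -> dict:
    tables = read_tables(config)
    if web is None:
        web = _load_metaweb(config)
    if sbm_result is not None:
        membership = sbm_result["group_metaweb"].membership
        group_pi = sbm_result["group_metaweb"].pi
        group_guild = sbm_result["group_metaweb"].group_guild
    else:
        membership = _load_membership(config)
        fit = json.loads((_outdir(config) / "sbm_fit.json").read_text())
        group_pi = np.array(fit["pi"])
        group_guild = {}
    webs = metaweb.extract_all_webs(
        web, tables["observations"], tables["design"],
        n_replicates=config.n_replicates,
        aggregation=config.replicate_aggregation)
    rows = []
    for lw in webs:
        mem = {n: membership.get(n, -1) for n in lw.graph.nodes}
        m = netmetrics.compute_all(lw, membership=mem,
                                   read_counts=lw.read_counts,
                                   weighted_tl=config.tl_weighted)
        rows.append({"site_id": lw.site_id, "field_id": lw.field_id,
                     "plot_id": lw.plot_id, "level": "taxa", **m.to_dict()})
        gw, greads = _group_level_web(lw, membership, group_pi, group_guild)
        gm = netmetrics.compute_all(
            gw, membership={q: q for q in gw.nodes}, read_counts=greads,
            weighted_tl=config.tl_weighted)
        rows.append({"site_id": lw.site_id, "field_id": lw.field_id,
                     "plot_id": lw.plot_id, "level": "group", **gm.to_dict()})
    metrics = pd.DataFrame(rows)
    metrics.to_csv(_outdir(config) / "metrics.csv", index=False,
                   lineterminator="\n")
    return {"metrics": metrics, "webs": webs}


def stage_beta(config: PipelineConfig, webs=None, membership=None) -> dict:
    out = _outdir(config)
    if webs is None:
        tables = read_tables(config)
        web = _load_metaweb(config)
        webs = metaweb.extract_all_webs(
            web, tables["observations"], tables["design"],
            n_replicates=config.n_replicates,
            aggregation=config.replicate_aggregation)
    if membership is None:
        membership = _load_membership(config)
    nonempty = [w for w in webs if w.graph.number_of_nodes() > 0]
    labeled = {w.plot_id: w for w in nonempty}
    dm = beta_mod.dissimilarity_matrix(labeled, q=config.beta_q,
                                       mode=config.beta_mode)
    pd.DataFrame(dm.D, index=dm.labels, columns=dm.labels).to_csv(
        out / "dissimilarity_taxa.csv", lineterminator="\n")
    # group-level node sets through the same machinery
    group_webs = {}
    for w in nonempty:
        groups: dict[int, int] = {}
        for n in w.graph.nodes:
            if n in membership:
                q = membership[n]
                groups[q] = groups.get(q, 0) + int(w.read_counts.get(n, 0))
        if groups:
            group_webs[w.plot_id] = groups
    dm_g = beta_mod.dissimilarity_matrix(group_webs, q=config.beta_q,
                                         mode=config.beta_mode)
    pd.DataFrame(dm_g.D, index=dm_g.labels, columns=dm_g.labels).to_csv(
        out / "dissimilarity_group.csv", lineterminator="\n")

    ord_res = beta_mod.pcoa(dm.D)
    coords = pd.DataFrame(
        ord_res.coordinates[:, :min(2, ord_res.coordinates.shape[1])],
        index=dm.labels,
        columns=[f"PCoA{i+1}" for i in
                 range(min(2, ord_res.coordinates.shape[1]))])
    coords.to_csv(out / "pcoa_coordinates.csv", lineterminator="\n")

    field_of = {w.plot_id: w.field_id for w in nonempty}
    site_of = {w.plot_id: w.site_id for w in nonempty}
    results = {}
    for name, mapping in (("field", field_of), ("site", site_of)):
        grouping = [mapping[p] for p in dm.labels]
        if len(set(grouping)) >= 2:
            for lvl, mat in (("taxa", dm), ("group", dm_g)):
                labels = [mapping[p] for p in mat.labels]
                res = beta_mod.permutation_f(mat.D, labels,
                                            n_perm=config.n_perm,
                                            seed=config.stats_seed)
                results[f"{name}_{lvl}"] = {
                    "df_between": res.df_between, "df_within": res.df_within,
                    "F": res.F, "p": res.p, "n_perm": res.n_perm,
                }
    (out / "permanova.json").write_text(
        json.dumps(results, indent=1, sort_keys=True) + "\n")
    return {"dissimilarity": dm, "dissimilarity_group": dm_g,
            "pcoa": ord_res, "permanova": results}


def stage_lui(config: PipelineConfig) -> dict:
    tables = read_tables(config)
    res = luistats.lui_index(tables["criteria"])
    out = _outdir(config)
    design = tables["design"][["site_id", "field_id"]].drop_duplicates()
    lui_df = design.merge(
        res.scores.rename("lui").reset_index().rename(
            columns={"index": "field_id"}),
        on="field_id", how="left").sort_values(["site_id", "field_id"])
    lui_df.to_csv(out / "lui_scores.csv", index=False, lineterminator="\n")
    res.loadings.rename("loading").to_csv(out / "lui_loadings.csv",
                                          lineterminator="\n")
    return {"lui": res, "design": design}


def stage_stats(config: PipelineConfig, metrics: pd.DataFrame | None = None,
                lui_result=None) -> dict:
    out = _outdir(config)
    if metrics is None:
        metrics = pd.read_csv(out / "metrics.csv")
    tables = read_tables(config)
    if lui_result is None:
        lui_result = luistats.lui_index(tables["criteria"])
    site_of = dict(zip(tables["design"]["field_id"],
                       tables["design"]["site_id"]))
    results = {}
    for level in ("taxa", "group"):
        sub = metrics[metrics["level"] == level]
        field_means = sub.groupby("field_id")[
            list(netmetrics.METRIC_NAMES)].mean(numeric_only=True)
        lui = lui_result.scores.reindex(field_means.index)
        site = pd.Series({f: site_of[f] for f in field_means.index})
        table = luistats.metric_lui_tests(field_means, lui, site,
                                          reml=config.reml)
        table.to_csv(out / f"model_results_{level}.csv", lineterminator="\n")
        results[level] = table
    return {"model_results": results}


_STAGES = ("simulate", "metaweb", "sbm", "metrics", "beta", "lui", "stats",
           "report")


def stage_report(config: PipelineConfig) -> dict:
    out = _outdir(config)
    inputs = Path(config.workdir) / "inputs"
    artifacts = {p.name: p for p in sorted(out.glob("*")) if p.is_file()}
    input_files = {p.name: p for p in sorted(inputs.glob("*.tsv"))}
    manifest = write_manifest(
        {**{f"inputs/{k}": v for k, v in input_files.items()},
         **{f"outputs/{k}": v for k, v in artifacts.items()}},
        out / "manifest.json",
        extra={"seeds": {"scenario": config.scenario.seed,
                         "sbm": config.sbm_seed,
                         "stats": config.stats_seed}},
    )
    summary: dict = {"config": json.loads(config.to_json())}
    summary["config"].pop("workdir", None)  # path is environment-specific
    for name in ("filter_audit", "permanova"):
        p = out / f"{name}.json"
        if p.exists():
            summary[name] = json.loads(p.read_text())
    fitp = out / "sbm_fit.json"
    if fitp.exists():
        fit = json.loads(fitp.read_text())
        summary["sbm"] = {"Q": fit["Q"], "icl": fit["icl"],
                          "icl_table": fit["icl_table"]}
    model_tables = {}
    for level in ("taxa", "group"):
        p = out / f"model_results_{level}.csv"
        if p.exists():
            model_tables[level] = pd.read_csv(p, index_col=0)
            summary[f"model_results_{level}"] = json.loads(
                model_tables[level].to_json(orient="index"))
    (out / "report.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, allow_nan=True
                   ).replace("NaN", "null") + "\n")
    lines = ["# Pipeline report", ""]
    if "sbm" in summary:
        lines += [f"Selected Q = {summary['sbm']['Q']} "
                  f"(ICL = {summary['sbm']['icl']:.2f})", ""]
    for level, tbl in model_tables.items():
        lines += [f"## Metric ~ LUI mixed models ({level}-level webs)", "",
                  tbl.to_markdown(), ""]
    (out / "report.md").write_text("\n".join(lines) + "\n")
    return {"manifest": manifest, "summary": summary}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; a failing stage raises ``PipelineError``
    naming the stage while earlier artifacts stay on disk."""
    config.validate()
    state: dict = {}
    try:
        stage = "simulate"
        state["simulate"] = stage_simulate(config)
        stage = "metaweb"
        mw = stage_metaweb(config)
        state["metaweb"] = mw
        stage = "sbm"
        fit = stage_sbm(config, web=mw["metaweb"])
        state["sbm"] = fit
        stage = "metrics"
        met = stage_metrics(config, web=mw["metaweb"], sbm_result=fit)
        state["metrics"] = met
        if config.run_beta:
            stage = "beta"
            state["beta"] = stage_beta(
                config, webs=met["webs"],
                membership=fit["group_metaweb"].membership)
        stage = "lui"
        state["lui"] = stage_lui(config)
        stage = "stats"
        state["stats"] = stage_stats(config, metrics=met["metrics"],
                                     lui_result=state["lui"]["lui"])
        stage = "report"
        state["report"] = stage_report(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    return state
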