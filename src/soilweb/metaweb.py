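"""Knowledge-base compilation, trimming rules, metaweb and local-web extraction.

The interaction knowledge base is a table of directed resource->consumer
records typed as predation / parasitism / symbiosis and carrying an evidence
rank.  Records given at genus or family rank are generalized to all observed
member taxa; edges are trimmed when the endpoints cannot co-occur in a soil
layer or when a non-microbial taxon falls outside the target geographic
region.  The metaweb is the trimmed record set over the observed taxa pool;
local plot webs are its induced subgraphs on detected taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

INTERACTION_TYPES = ("predation", "parasitism", "symbiosis")

#: most specific evidence wins when duplicate pairs conflict
EVIDENCE_RANKS = ("species", "genus", "family", "generalized")
_RANK_ORDER = {r: i for i, r in enumerate(EVIDENCE_RANKS)}

KB_COLUMNS = ["resource", "consumer", "type", "evidence_rank", "source"]


@dataclass
class CompileReport:
    n_input: int = 0
    n_kept: int = 0
    n_duplicates: int = 0
    n_self_loops: int = 0
    rejects: pd.DataFrame = field(default_factory=pd.DataFrame)


def compile_kb(records: pd.DataFrame, taxonomy: pd.DataFrame):
    """Validate, deduplicate and rank-resolve raw interaction records.

    Unknown endpoints (resolvable neither as a taxon id nor as a genus/family
    name in ``taxonomy``) go to a rejects table rather than raising.  For
    duplicate (resource, consumer) pairs the record with the most specific
    evidence rank is kept; ties keep the first occurrence.  Self-loops are
    dropped.  Returns ``(kb, report)``.
    """
    records = records.copy()
    for col in KB_COLUMNS[:4]:
        if col not in records.columns:
            raise ValueError(f"interaction table missing column {col!r}")
    if "source" not in records.columns:
        records["source"] = ""
    bad_type = ~records["type"].isin(INTERACTION_TYPES)
    bad_rank = ~records["evidence_rank"].isin(EVIDENCE_RANKS)
    known = set(taxonomy["taxon_id"])
    known |= set(taxonomy.get("genus", pd.Series(dtype=str)).dropna())
    known |= set(taxonomy.get("family", pd.Series(dtype=str)).dropna())
    unknown = ~(records["resource"].isin(known) & records["consumer"].isin(known))
    self_loop = records["resource"] == records["consumer"]

    report = CompileReport(n_input=len(records))
    reject_mask = bad_type | bad_rank | unknown
    report.rejects = records[reject_mask].copy()
    report.n_self_loops = int((self_loop & ~reject_mask).sum())
    kb = records[~reject_mask & ~self_loop].copy()

    kb["_rank"] = kb["evidence_rank"].map(_RANK_ORDER)
    kb = kb.sort_values("_rank", kind="stable")
    before = len(kb)
    kb = kb.drop_duplicates(subset=["resource", "consumer"], keep="first")
    report.n_duplicates = before - len(kb)
    kb = kb.drop(columns="_rank").sort_index().reset_index(drop=True)
    report.n_kept = len(kb)
    log.info(
        "compile_kb: %d in, %d kept, %d duplicates, %d self-loops, %d rejects",
        report.n_input, report.n_kept, report.n_duplicates,
        report.n_self_loops, len(report.rejects),
    )
    return kb, report


def generalize_within_families(kb: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Expand genus/family-level record endpoints to all observed member taxa.

    Expanded records are tagged ``evidence_rank='generalized'``.  The original
    coarse record is retained for audit with ``is_coarse=True`` and is
    excluded from graph construction.  Endpoints that resolve neither as a
    taxon id nor as a known genus/family pass through unexpanded with a
    warning in the log.
    """
    taxon_ids = set(taxonomy["taxon_id"])
    members: dict[str, list[str]] = {}
    for rank in ("genus", "family"):
        if rank in taxonomy.columns:
            for name, grp in taxonomy.groupby(rank)["taxon_id"]:
                members.setdefault(str(name), []).extend(grp.tolist())

    out_rows = []
    for rec in kb.itertuples(index=False):
        rec = rec._asdict()
        rec.setdefault("is_coarse", False)
        res_ok = rec["resource"] in taxon_ids
        con_ok = rec["consumer"] in taxon_ids
        if res_ok and con_ok:
            out_rows.append(rec)
            continue
        res_set = [rec["resource"]] if res_ok else members.get(rec["resource"])
        con_set = [rec["consumer"]] if con_ok else members.get(rec["consumer"])
        if res_set is None or con_set is None:
            log.warning(
                "generalize: unresolvable endpoint in %s -> %s; passed through",
                rec["resource"], rec["consumer"],
            )
            out_rows.append(rec)
            continue
        coarse = dict(rec)
        coarse["is_coarse"] = True
        out_rows.append(coarse)
        for r in res_set:
            for c in con_set:
                if r == c:
                    continue
                expanded = dict(rec)
                expanded.update(
                    resource=r, consumer=c, evidence_rank="generalized",
                    is_coarse=False,
                )
                out_rows.append(expanded)
    out = pd.DataFrame(out_rows)
    # expansion may create duplicates of existing specific records
    out = out.sort_values("is_coarse", kind="stable").drop_duplicates(
        subset=["resource", "consumer", "is_coarse"], keep="first"
    )
    return out.reset_index(drop=True)


def _layer_sets(annotations: pd.DataFrame) -> dict[str, frozenset]:
    out = {}
    for tid, layers in zip(annotations["taxon_id"], annotations["habitat_layers"]):
        if pd.isna(layers):
            continue
        out[tid] = frozenset(str(layers).split("|")) - {""}
    return out


def filter_by_habitat(kb: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Keep an edge iff resource and consumer share at least one soil layer.

    Taxa without a habitat annotation are treated permissively (edge kept).
    """
    layers = _layer_sets(annotations)

    def keep(row) -> bool:
        a = layers.get(row.resource)
        b = layers.get(row.consumer)
        if a is None or b is None:
            return True
        return bool(a & b)

    mask = kb.apply(keep, axis=1) if len(kb) else pd.Series(dtype=bool)
    removed = int((~mask).sum()) if len(kb) else 0
    log.info("filter_by_habitat: removed %d of %d edges", removed, len(kb))
    return kb[mask].reset_index(drop=True) if len(kb) else kb.copy()


def filter_by_geography(
    kb: pd.DataFrame,
    annotations: pd.DataFrame,
    target_region: str = "temperate_europe",
) -> pd.DataFrame:
    """Drop non-microbial taxa outside the target region, with incident edges.

    Micro-organisms (``is_microorganism`` truthy) are always retained: they
    are assumed to have a broad geographic distribution.
    """
    micro = {}
    tags = {}
    for row in annotations.itertuples(index=False):
        micro[row.taxon_id] = bool(row.is_microorganism) if not pd.isna(
            row.is_microorganism) else False
        raw = "" if pd.isna(row.geographic_tags) else str(row.geographic_tags)
        tags[row.taxon_id] = set(raw.split("|")) - {""}

    def taxon_ok(t: str) -> bool:
        if t not in micro:  # unannotated: keep (permissive, like habitat)
            return True
        return micro[t] or target_region in tags[t]

    if not len(kb):
        return kb.copy()
    mask = kb["resource"].map(taxon_ok) & kb["consumer"].map(taxon_ok)
    log.info("filter_by_geography: removed %d of %d edges",
             int((~mask).sum()), len(kb))
    return kb[mask].reset_index(drop=True)


def geography_survivors(
    taxa, annotations: pd.DataFrame, target_region: str = "temperate_europe"
) -> set[str]:
    """Node-level view of the geography rule over a taxa list."""
    ann = annotations.set_index("taxon_id")
    out = set()
    for t in taxa:
        if t not in ann.index:
            out.add(t)
            continue
        row = ann.loc[t]
        tags = set(str(row["geographic_tags"]).split("|")) - {"", "nan"}
        if bool(row["is_microorganism"]) or target_region in tags:
            out.add(t)
    return out


def build_metaweb(
    taxa, kb: pd.DataFrame, annotations: pd.DataFrame | None = None
) -> nx.DiGraph:
    """Directed metaweb over the observed taxa pool.

    Nodes are all observed taxa (interaction-less taxa stay as isolates);
    edges are the KB records whose endpoints are both observed, excluding
    retained coarse audit records.  Edge attributes: type, evidence_rank,
    weight (1.0 in the metaweb).
    """
    taxa = list(taxa)
    if not taxa:
        raise ValueError("empty taxa list")
    g = nx.DiGraph()
    g.add_nodes_from(taxa)
    if annotations is not None:
        ann = annotations.set_index("taxon_id")
        for t in taxa:
            if t in ann.index:
                row = ann.loc[t]
                g.nodes[t]["guild"] = row.get("guild", "")
                g.nodes[t]["habitat_layers"] = str(row.get("habitat_layers", ""))
    observed = set(taxa)
    if len(kb):
        rows = kb
        if "is_coarse" in kb.columns:
            rows = kb[~kb["is_coarse"].astype(bool)]
        for rec in rows.itertuples(index=False):
            if rec.resource in observed and rec.consumer in observed:
                g.add_edge(
                    rec.resource, rec.consumer,
                    type=rec.type, evidence_rank=rec.evidence_rank, weight=1.0,
                )
    return g


@dataclass
class LocalFoodWeb:
    """Induced plot-level web: detected taxa + metaweb edges among them."""

    plot_id: str
    field_id: str
    site_id: str
    graph: nx.DiGraph
    read_counts: dict[str, int]

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


def extract_local_web(
    metaweb: nx.DiGraph,
    plot_detections: pd.DataFrame,
    plot_id: str = "",
    field_id: str = "",
    site_id: str = "",
    n_replicates: int = 4,
    aggregation: str = "union",
) -> LocalFoodWeb:
    """Extract the plot-level food web from replicate detection lists.

    ``plot_detections`` holds one plot's rows with columns replicate /
    taxon_id / reads.  The node set is the union (or intersection, by flag) of
    the replicate lists; read counts are summed over replicates; each induced
    edge is weighted by the product of the endpoint detection fractions across
    the ``n_replicates`` replicates.  Detected taxa absent from the metaweb
    are kept as isolated nodes.
    """
    if aggregation not in ("union", "intersection"):
        raise ValueError("aggregation must be 'union' or 'intersection'")
    det: dict[str, set] = {}
    reads: dict[str, int] = {}
    for row in plot_detections.itertuples(index=False):
        det.setdefault(row.taxon_id, set()).add(row.replicate)
        reads[row.taxon_id] = reads.get(row.taxon_id, 0) + int(row.reads)
    if aggregation == "union":
        taxa = sorted(det)
    else:
        taxa = sorted(t for t, reps in det.items() if len(reps) >= n_replicates)
    if not taxa:
        log.warning("extract_local_web: zero detected taxa in plot %s", plot_id)
    frac = {t: len(det[t]) / n_replicates for t in taxa}
    g = nx.DiGraph()
    for t in taxa:
        attrs = dict(metaweb.nodes[t]) if t in metaweb else {}
        g.add_node(t, reads=reads[t], detection_fraction=frac[t], **attrs)
    present = set(taxa)
    for u, v, data in metaweb.edges(data=True):
        if u in present and v in present:
            g.add_edge(u, v, type=data.get("type", "predation"),
                       weight=frac[u] * frac[v])
    return LocalFoodWeb(
        plot_id=plot_id, field_id=field_id, site_id=site_id, graph=g,
        read_counts={t: reads[t] for t in taxa},
    )


def extract_all_webs(
    metaweb: nx.DiGraph,
    observations: pd.DataFrame,
    design: pd.DataFrame,
    n_replicates: int = 4,
    aggregation: str = "union",
) -> list[LocalFoodWeb]:
    """One LocalFoodWeb per plot in the design table (possibly empty webs)."""
    by_plot = dict(tuple(observations.groupby("plot_id")))
    empty = observations.iloc[0:0]
    webs = []
    for row in design.itertuples(index=False):
        webs.append(
            extract_local_web(
                metaweb, by_plot.get(row.plot_id, empty),
                plot_id=row.plot_id, field_id=row.field_id, site_id=row.site_id,
                n_replicates=n_replicates, aggregation=aggregation,
            )
        )
    return webs
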