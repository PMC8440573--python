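"""Food-web topology metrics for taxa- or group-level webs.

All functions accept a directed ``networkx`` graph whose edges point from
resource to consumer.  Edge attribute ``type`` distinguishes predation /
parasitism / symbiosis; node attribute ``guild`` feeds the energy-channel
ratios.  Undefined values (empty webs, empty denominators) are returned as
``None`` and serialized as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import networkx as nx
import numpy as np

from .beta import hill_number

__all__ = [
    "NetworkMetrics", "node_richness", "trophic_group_richness",
    "trophic_group_entropy", "average_degree", "trophic_levels",
    "mean_trophic_level", "omnivory_level", "link_density", "path_lengths",
    "pct_parasitic_links", "channel_total_path_length", "channel_path_ratio",
    "compute_all", "METRIC_NAMES",
]

METRIC_NAMES = (
    "node_richness", "trophic_group_richness", "trophic_group_entropy",
    "average_degree", "mean_trophic_level", "omnivory_level", "link_density",
    "average_path_length", "max_path_length", "pct_parasitic_links",
    "bf_path_ratio", "dh_path_ratio",
)


@dataclass
class NetworkMetrics:
    """One record of all twelve indices; ``None`` marks undefined."""

    node_richness: int
    trophic_group_richness: int | None
    trophic_group_entropy: float | None
    average_degree: float | None
    mean_trophic_level: float | None
    omnivory_level: float | None
    link_density: float | None
    average_path_length: float | None
    max_path_length: int
    pct_parasitic_links: float | None
    bf_path_ratio: float | None
    dh_path_ratio: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def _graph(web) -> nx.DiGraph:
    return web.graph if hasattr(web, "graph") and isinstance(
        getattr(web, "graph"), nx.DiGraph) else web


def node_richness(web) -> int:
    """Number of nodes, isolates included."""
    return _graph(web).number_of_nodes()


def trophic_group_richness(web, membership: Mapping) -> int:
    """Number of distinct group labels among present nodes."""
    g = _graph(web)
    labels = set()
    for n in g.nodes:
        if n not in membership:
            raise KeyError(f"node {n!r} has no group label")
        labels.add(membership[n])
    return len(labels)


def trophic_group_entropy(read_counts: Mapping, membership: Mapping,
                          q: float = 1.0) -> float:
    """Hill number of order q of the group-level read-count distribution."""
    totals: dict = {}
    for node, c in read_counts.items():
        if c < 0:
            raise ValueError("negative read count")
        grp = membership[node]
        totals[grp] = totals.get(grp, 0) + c
    total = sum(totals.values())
    if total <= 0:
        raise ValueError("all-zero read counts")
    p = np.array([v / total for v in totals.values()])
    return hill_number(p, q)


def average_degree(web) -> float:
    """Mean total degree over nodes; identically 2L/S.  Empty web -> 0."""
    g = _graph(web)
    s = g.number_of_nodes()
    if s == 0:
        return 0.0
    return 2.0 * g.number_of_edges() / s


def trophic_levels(web, weighted: bool = False, with_flag: bool = False):
    """Trophic level of every node: basal = 1, else 1 + mean resource level.

    Solves TL = 1 + W TL with W the row-normalized diet matrix (equal weight
    per resource, or edge-weight-proportional when ``weighted``).  When the
    system is singular — consumers sitting in cycles with no basal support —
    it is re-solved with ridge damping 1e-6 and flagged.
    """
    g = _graph(web)
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 0:
        return ({}, False) if with_flag else {}
    idx = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((n, n))
    for v in nodes:
        resources = list(g.predecessors(v))
        if not resources:
            continue
        if weighted:
            w = np.array([g.edges[r, v].get("weight", 1.0) for r in resources],
                         dtype=float)
            if w.sum() <= 0:
                w = np.ones(len(resources))
            w = w / w.sum()
        else:
            w = np.full(len(resources), 1.0 / len(resources))
        for r, wi in zip(resources, w):
            W[idx[v], idx[r]] = wi
    A = np.eye(n) - W
    b = np.ones(n)
    damped = False
    try:
        tl = np.linalg.solve(A, b)
        if not np.all(np.isfinite(tl)) or np.abs(A @ tl - b).max() > 1e-6:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        damped = True
        A = (1.0 + 1e-6) * np.eye(n) - W
        try:
            tl = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            comp = [c for c in nx.strongly_connected_components(g) if len(c) > 1]
            raise np.linalg.LinAlgError(
                f"trophic-level system singular after damping; cycles: {comp}"
            ) from exc
    levels = {v: float(tl[idx[v]]) for v in nodes}
    return (levels, damped) if with_flag else levels


def mean_trophic_level(web, weighted: bool = False) -> float | None:
    """Unweighted mean of node trophic levels; None on the empty web."""
    levels = trophic_levels(web, weighted=weighted)
    if not levels:
        return None
    return float(np.mean(list(levels.values())))


def omnivory_level(web, weighted: bool = False) -> float:
    """Mean over consumers of the population SD of their resources' levels.

    Consumers with a single resource contribute 0; webs without consumers
    score 0.
    """
    g = _graph(web)
    levels = trophic_levels(web, weighted=weighted)
    vals = []
    for v in g.nodes:
        resources = list(g.predecessors(v))
        if not resources:
            continue
        tls = np.array([levels[r] for r in resources])
        vals.append(float(tls.std(ddof=0)))
    return float(np.mean(vals)) if vals else 0.0


def link_density(web) -> float | None:
    """Edges per node L/S; None when S = 0."""
    g = _graph(web)
    s = g.number_of_nodes()
    if s == 0:
        return None
    return g.number_of_edges() / s


def path_lengths(web):
    """(average, maximum, n_finite_pairs) over directed shortest paths.

    The average runs over ordered pairs i != j with a finite distance (the
    count of such pairs is returned alongside); the maximum is the largest
    finite shortest-path length.  No reachable pair -> (None, 0, 0).
    """
    g = _graph(web)
    total = 0
    n_pairs = 0
    longest = 0
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for dst, d in dists.items():
            if dst == src:
                continue
            total += d
            n_pairs += 1
            longest = max(longest, d)
    if n_pairs == 0:
        return None, 0, 0
    return total / n_pairs, longest, n_pairs


def pct_parasitic_links(web) -> float | None:
    """100 * (# parasitism-typed edges) / L; None when L = 0."""
    g = _graph(web)
    L = g.number_of_edges()
    if L == 0:
        return None
    k = sum(1 for _, _, t in g.edges(data="type") if t == "parasitism")
    return 100.0 * k / L


def channel_total_path_length(web, seed_guilds) -> float:
    """Total pathway length of the energy channel rooted in given guilds.

    Seeds are all nodes whose guild is in ``seed_guilds``; the channel total
    is the sum, over nodes reachable from any seed, of the shortest directed
    distance from the nearest seed (seeds themselves contribute 0).
    """
    g = _graph(web)
    seeds = [n for n, gu in g.nodes(data="guild") if gu in set(seed_guilds)]
    if not seeds:
        return 0.0
    dist = nx.multi_source_dijkstra_path_length(g, seeds, weight=None)
    return float(sum(dist.values()))


def channel_path_ratio(web, seed_guilds_num, seed_guilds_den) -> float | None:
    """Ratio of two channel totals; None when the denominator channel is 0."""
    num = channel_total_path_length(web, seed_guilds_num)
    den = channel_total_path_length(web, seed_guilds_den)
    if den == 0.0:
        return None
    return num / den


def compute_all(web, membership: Mapping | None = None,
                read_counts: Mapping | None = None,
                weighted_tl: bool = False) -> NetworkMetrics:
    """All twelve indices for one web; group metrics need membership+counts."""
    g = _graph(web)
    if read_counts is None and hasattr(web, "read_counts"):
        read_counts = web.read_counts
    s = g.number_of_nodes()
    tg_rich = tg_ent = None
    if membership is not None and s > 0:
        tg_rich = trophic_group_richness(g, membership)
        if read_counts and sum(read_counts.values()) > 0:
            tg_ent = trophic_group_entropy(read_counts, membership)
    avg_d, longest, _ = path_lengths(g)
    return NetworkMetrics(
        node_richness=s,
        trophic_group_richness=tg_rich,
        trophic_group_entropy=tg_ent,
        average_degree=average_degree(g) if s else None,
        mean_trophic_level=mean_trophic_level(g, weighted=weighted_tl),
        omnivory_level=omnivory_level(g, weighted=weighted_tl) if s else None,
        link_density=link_density(g),
        average_path_length=avg_d,
        max_path_length=longest,
        pct_parasitic_links=pct_parasitic_links(g),
        bf_path_ratio=channel_path_ratio(
            g, ("bacteria_decomposer",), ("fungi_saprotroph",)),
        dh_path_ratio=channel_path_ratio(
            g, ("detritivore",), ("root_herbivore",)),
    )
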