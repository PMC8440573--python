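"""Tabular and graph I/O: strict TSV dialect, GraphML round-trips, manifests.

Dialect: tab-separated, UTF-8, mandatory header row, ``NA`` for missing.
Malformed rows (wrong field count) are collected into a rejects table instead
of aborting the load.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

NA = "NA"


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=NA, lineterminator="\n")
    return path


def read_tsv(path: str | Path, required_columns=None, dtype=None):
    """Read a TSV; returns ``(frame, rejects)`` with malformed rows separated.

    A row is malformed when its field count differs from the header's.
    Missing required columns and empty files are fatal.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].strip():
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    good, bad = [], []
    for ln_no, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        fields = line.split("\t")
        (good if len(fields) == len(header) else bad).append((ln_no, fields))
    df = pd.DataFrame([f for _, f in good], columns=header)
    df = df.replace(NA, pd.NA)
    if dtype:
        for col, t in dtype.items():
            if col in df.columns:
                df[col] = df[col].astype(t)
    else:
        for col in df.columns:  # numeric columns only if every value parses
            converted = pd.to_numeric(df[col], errors="coerce")
            if converted.notna().sum() == df[col].notna().sum():
                df[col] = converted
    rejects = pd.DataFrame(
        {"line": [n for n, _ in bad],
         "content": ["\t".join(f) for _, f in bad]}
    )
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(bad):
        log.warning("%s: %d malformed row(s) rejected", path, len(bad))
    return df, rejects


def read_tables(config) -> dict:
    """Load and validate all pipeline input tables named in a config.

    Returns a dict with keys taxonomy / annotations / interactions /
    observations / design / criteria plus a ``rejects`` dict.  Duplicate
    taxon ids in the taxonomy are fatal.
    """
    base = Path(config.workdir) / "inputs"
    spec = {
        "taxonomy": ["taxon_id", "phylum", "family", "genus", "species"],
        "annotations": ["taxon_id", "guild", "habitat_layers",
                        "geographic_tags", "is_microorganism"],
        "interactions": ["resource", "consumer", "type", "evidence_rank"],
        "observations": ["plot_id", "replicate", "taxon_id", "reads"],
        "design": ["site_id", "field_id", "plot_id"],
        "criteria": ["field_id"],
    }
    out: dict = {"rejects": {}}
    for name, cols in spec.items():
        df, rejects = read_tsv(base / f"{name}.tsv", required_columns=cols)
        out[name] = df
        out["rejects"][name] = rejects
        log.info("read %s: %d rows x %d cols (%d rejected)",
                 name, len(df), df.shape[1], len(rejects))
    if out["taxonomy"]["taxon_id"].duplicated().any():
        dups = out["taxonomy"]["taxon_id"][
            out["taxonomy"]["taxon_id"].duplicated()].tolist()
        raise ValueError(f"duplicate taxon ids: {dups[:5]}")
    out["annotations"]["is_microorganism"] = (
        out["annotations"]["is_microorganism"].astype(str).str.lower()
        .isin(("true", "1"))
    )
    for col in ("replicate", "reads"):
        out["observations"][col] = out["observations"][col].astype(int)
    out["criteria"] = out["criteria"].set_index("field_id").astype(float)
    return out


def export_graph(graph: nx.DiGraph, path: str | Path, fmt: str = "graphml"):
    """Write a web as GraphML or as an edge-list + node-list TSV pair.

    The TSV format writes ``<stem>.edges.tsv`` and ``<stem>.nodes.tsv`` so
    isolated nodes and attributes survive a round trip.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
        return path
    if fmt == "tsv":
        stem = path.with_suffix("") if path.suffix else path
        node_rows = [{"node": n, **{k: v for k, v in d.items()}}
                     for n, d in graph.nodes(data=True)]
        edge_rows = [{"resource": u, "consumer": v, **d}
                     for u, v, d in graph.edges(data=True)]
        write_tsv(pd.DataFrame(node_rows, columns=None if node_rows else ["node"]),
                  stem.with_suffix(".nodes.tsv"))
        write_tsv(pd.DataFrame(edge_rows,
                               columns=None if edge_rows else ["resource", "consumer"]),
                  stem.with_suffix(".edges.tsv"))
        return stem
    raise ValueError(f"unsupported graph format {fmt!r}")


def import_graph(path: str | Path, fmt: str = "graphml") -> nx.DiGraph:
    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        return nx.DiGraph(g)
    if fmt == "tsv":
        stem = path.with_suffix("") if path.suffix else path
        nodes, _ = read_tsv(stem.with_suffix(".nodes.tsv"))
        g = nx.DiGraph()
        for row in nodes.to_dict("records"):
            n = row.pop("node")
            g.add_node(n, **{k: v for k, v in row.items() if not pd.isna(v)})
        edge_path = stem.with_suffix(".edges.tsv")
        edges, _ = read_tsv(edge_path)
        for row in edges.to_dict("records"):
            u, v = row.pop("resource"), row.pop("consumer")
            g.add_edge(u, v, **{k: w for k, w in row.items() if not pd.isna(w)})
        return g
    raise ValueError(f"unsupported graph format {fmt!r}")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(paths: dict[str, str | Path], out_path: str | Path,
                   extra: dict | None = None) -> Path:
    """Record sha256 of every artifact plus seeds/versions; no timestamps so
    reruns stay byte-identical."""
    from . import __version__

    manifest = {
        "version": __version__,
        "files": {name: file_sha256(p) for name, p in sorted(paths.items())
                  if Path(p).is_file()},
    }
    if extra:
        manifest.update(extra)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out_path
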