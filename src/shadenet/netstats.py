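"""Post-processing of externally predicted protein–protein interaction
edge lists: confidence filtering, connected components, hub statistics,
size-limited chunking, and a top-hub meta-network.

Edges carry a confidence score in [0, 1] (exports on a 0–1000 integer scale
are autodetected and rescaled). The default filter keeps scores >= 0.18 —
a deliberately permissive "approximate probability of a predictive link".
A node is a *key hub* when it has strictly more than 10 links after
filtering. Because interaction-prediction services cap the query size
(2000 proteins), large gene sets are split into randomly assigned,
evenly sized groups; the top five hubs of each group (including ties at
rank five) are then joined into a meta-network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class EdgeList:
    edges: pd.DataFrame  # columns node_a, node_b, score (deduplicated)
    n_self_loops: int = 0
    n_below_threshold: int = 0
    rescaled_from_1000: bool = False


def filter_edges(df: pd.DataFrame, min_score: float = 0.18) -> EdgeList:
    """Normalize a raw scored edge table: autodetect a 0–1000 score scale,
    drop self-loops, deduplicate undirected pairs keeping the max score, and
    apply the confidence filter (>= rule)."""
    required = {"node_a", "node_b", "score"}
    if not required.issubset(df.columns):
        raise ParseError(f"edge table needs columns {sorted(required)}")
    df = df.copy()
    df["score"] = df["score"].astype(float)
    rescaled = False
    if df["score"].max() > 1.0:
        df["score"] = df["score"] / 1000.0
        rescaled = True
        logger.info("scores look like a 0-1000 export; rescaled to 0-1")
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ParseError("scores outside [0, 1] after scale normalization")
    df["node_a"] = df["node_a"].astype(str)
    df["node_b"] = df["node_b"].astype(str)
    loops = df["node_a"] == df["node_b"]
    n_loops = int(loops.sum())
    if n_loops:
        logger.info("dropping %d self-loops", n_loops)
    df = df[~loops]
    lo = df[["node_a", "node_b"]].min(axis=1)
    hi = df[["node_a", "node_b"]].max(axis=1)
    df = pd.DataFrame({"node_a": lo, "node_b": hi, "score": df["score"]})
    df = df.groupby(["node_a", "node_b"], as_index=False)["score"].max()
    below = int((df["score"] < min_score).sum())
    df = df[df["score"] >= min_score].reset_index(drop=True)
    return EdgeList(edges=df, n_self_loops=n_loops, n_below_threshold=below, rescaled_from_1000=rescaled)


def load_edges(path: str | Path, min_score: float = 0.18) -> EdgeList:
    """Read a tab-separated scored edge list (node_a, node_b, score; a
    header with different names or no header is accepted) and filter it."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ParseError("edge TSV needs two node columns and a score column")
    first = df.columns[2]
    try:
        float(first)
        # header-less file: the column names are the first data row
        df = pd.read_csv(path, sep="\t", header=None)
    except ValueError:
        pass
    df = df.iloc[:, :3]
    df.columns = ["node_a", "node_b", "score"]
    return filter_edges(df, min_score=min_score)


def build_graph(edges: EdgeList | pd.DataFrame) -> nx.Graph:
    df = edges.edges if isinstance(edges, EdgeList) else edges
    g = nx.Graph()
    for rec in df.itertuples(index=False):
        g.add_edge(rec.node_a, rec.node_b, score=rec.score)
    return g


def components(graph: nx.Graph, candidates=None) -> pd.DataFrame:
    """Connected-component assignment, components numbered by decreasing
    size (ties by smallest member id). When ``candidates`` is given, nodes
    from that list absent from the graph are reported as isolated
    (component_id = -1, size 0)."""
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    rows = []
    for cid, members in enumerate(comps, start=1):
        for node in members:
            rows.append({"node": node, "component_id": cid, "size": len(members)})
    if candidates is not None:
        in_graph = set(graph.nodes)
        for node in candidates:
            if node not in in_graph:
                rows.append({"node": node, "component_id": -1, "size": 0})
    return pd.DataFrame(rows, columns=["node", "component_id", "size"])


def component_sizes(graph: nx.Graph) -> list[int]:
    return sorted((len(c) for c in nx.connected_components(graph)), reverse=True)


def hubs(graph: nx.Graph, hub_threshold: int = 10) -> pd.DataFrame:
    """Degree table with the key-hub flag: strictly more than
    ``hub_threshold`` links (degree >= threshold + 1)."""
    rows = [
        {"node": n, "degree": d, "is_key_hub": d > hub_threshold}
        for n, d in sorted(graph.degree, key=lambda t: (-t[1], t[0]))
    ]
    return pd.DataFrame(rows, columns=["node", "degree", "is_key_hub"])


def chunk(nodes, max_size: int = 2000, seed: int = 0) -> pd.Series:
    """Random, even split into ceil(n / max_size) groups whose sizes differ
    by at most one. Returns a Series node -> group id (1-based)."""
    if max_size < 1:
        raise ValidationError("max_size must be >= 1")
    nodes = list(nodes)
    n = len(nodes)
    k = max(math.ceil(n / max_size), 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    groups = np.empty(n, dtype=int)
    for gid, idx in enumerate(np.array_split(perm, k), start=1):
        groups[idx] = gid
    return pd.Series(groups, index=nodes, name="group")


def top_hubs_meta(
    group_hubs: dict[int, pd.DataFrame],
    edges: EdgeList | pd.DataFrame,
    k: int = 5,
) -> tuple[pd.DataFrame, nx.Graph]:
    """Per group, the k highest-degree nodes *including every node tied with
    the k-th* (so a tie at rank k can yield more than k hubs), plus the
    induced meta-network among all selected hubs from the full edge list.

    Groups smaller than k contribute all their nodes (with a log warning).
    Ordering is by descending degree with node id as the deterministic
    tie-break for presentation; inclusion depends on degree only.
    """
    selected = []
    for gid in sorted(group_hubs):
        table = group_hubs[gid].sort_values(["degree", "node"], ascending=[False, True], kind="stable")
        if len(table) == 0:
            continue
        if len(table) <= k:
            if len(table) < k:
                logger.warning("group %s has fewer than %d nodes; taking all", gid, k)
            chosen = table
        else:
            cutoff = table["degree"].iloc[k - 1]
            chosen = table[table["degree"] >= cutoff]
        for rec in chosen.itertuples(index=False):
            selected.append({"group": gid, "node": rec.node, "degree": rec.degree})
    sel = pd.DataFrame(selected, columns=["group", "node", "degree"])

    df = edges.edges if isinstance(edges, EdgeList) else edges
    nodes = set(sel["node"])
    meta = nx.Graph()
    meta.add_nodes_from(sorted(nodes))
    for rec in df.itertuples(index=False):
        if rec.node_a in nodes and rec.node_b in nodes:
            meta.add_edge(rec.node_a, rec.node_b, score=rec.score)
    return sel, meta
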