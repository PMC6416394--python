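"""Interactome graph core: loading, connectivity, BFS distances, degree-matched sampling.

The interactome is an undirected, unweighted graph of proteins (nodes keyed by
string gene identifiers).  All distance computations downstream are unweighted
shortest-path (hop) distances on this graph.  Randomization of protein sets is
degree-preserving: nodes are drawn from *degree bins*, groups of nodes with
similar connectivity, so that a random set mirrors the degree profile of the
set it replaces.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The interactome is represented as a plain :class:`networkx.Graph`
#: (undirected, no self-loops, no multi-edges — enforced at load time).
Interactome = nx.Graph


def load_interactome(
    path,
    sep: str = "\t",
    columns: tuple = (0, 1),
    header: bool = False,
) -> nx.Graph:
    """Read a two-column edge list into an undirected protein–protein network.

    Parameters
    ----------
    path:
        Delimited text file; lines starting with ``#`` are skipped.
    sep:
        Field separator (tab by default).
    columns:
        The two identifier columns, by integer position or (with
        ``header=True``) by column name.
    header:
        Whether the first non-comment line is a header row.

    Duplicate edges and self-loops are dropped (counts logged).  Identifiers
    are whitespace-trimmed, case-preserving strings.
    """
    try:
        table = pd.read_csv(
            path,
            sep=sep,
            comment="#",
            header=0 if header else None,
            dtype=str,
            skip_blank_lines=True,
        )
    except OSError as exc:  # unreadable file
        raise OSError(f"cannot read edge list {path!r}: {exc}") from exc
    if table.shape[1] < 2:
        raise ValueError(f"edge list {path!r} has fewer than 2 columns")
    try:
        u_col = table.columns[columns[0]] if isinstance(columns[0], int) else columns[0]
        v_col = table.columns[columns[1]] if isinstance(columns[1], int) else columns[1]
        pairs = table[[u_col, v_col]]
    except (IndexError, KeyError) as exc:
        raise ValueError(f"edge columns {columns!r} not found in {path!r}") from exc

    g = nx.Graph()
    n_self = 0
    n_dup = 0
    n_rows = 0
    for u, v in pairs.itertuples(index=False, name=None):
        if u is None or v is None or (isinstance(u, float)) or (isinstance(v, float)):
            continue  # missing fields
        u, v = u.strip(), v.strip()
        if not u or not v:
            continue
        n_rows += 1
        if u == v:
            n_self += 1
            continue
        if g.has_edge(u, v):
            n_dup += 1
            continue
        g.add_edge(u, v)
    if n_self:
        logger.warning("dropped %d self-loop rows from %s", n_self, path)
    if n_dup:
        logger.info("collapsed %d duplicate edges from %s", n_dup, path)
    logger.info(
        "loaded interactome %s: %d nodes, %d edges (%d rows)",
        path, g.number_of_nodes(), g.number_of_edges(), n_rows,
    )
    return g


def largest_connected_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties in component size are broken by the lexicographically smallest
    member node, so the result is deterministic.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no connected component")
    best = max(nx.connected_components(g), key=lambda c: (len(c), min(c)))
    # (len, min) orders ties toward the lexicographically *largest* min; we
    # want the smallest member, so invert the tie-break explicitly.
    size = len(best)
    candidates = [c for c in nx.connected_components(g) if len(c) == size]
    best = min(candidates, key=lambda c: min(c))
    return g.subgraph(best).copy()


def shortest_path_lengths_from(g: nx.Graph, sources: Iterable) -> dict:
    """Multi-source BFS distances from ``sources`` to every reachable node.

    Returns ``{node: hop distance to the nearest source}``.  Nodes unreachable
    from every source are absent from the map (downstream averages skip them).
    """
    sources = set(sources)
    unknown = sources - set(g.nodes)
    if unknown:
        raise KeyError(f"source nodes not in graph: {sorted(unknown)[:5]}")
    dist = {s: 0 for s in sources}
    queue = deque(sources)
    adj = g.adj
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in adj[u]:
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


@dataclass(frozen=True)
class DegreeBinning:
    """Partition of the node set into groups of similar degree.

    ``bins[i]`` is a sorted tuple of nodes; ``bin_of`` maps every node to its
    bin index.  Bins are built from exact-degree groups, merging the sparse
    high-degree tail downward until every bin holds at least
    ``min_bin_size`` nodes.
    """

    bins: tuple
    bin_of: dict
    min_bin_size: int

    def __post_init__(self):
        total = sum(len(b) for b in self.bins)
        if total != len(self.bin_of):
            raise ValueError("bins do not partition the node set")


def build_degree_bins(g: nx.Graph, min_bin_size: int = 100) -> DegreeBinning:
    """Group nodes by degree into bins of at least ``min_bin_size`` members.

    Nodes are first grouped by exact degree; groups are then accumulated from
    the highest degree downward, flushing a bin whenever the accumulated
    count reaches ``min_bin_size``.  A small leftover group at the low-degree
    end is merged into the previously flushed bin.
    """
    n = g.number_of_nodes()
    if not 1 <= min_bin_size <= n:
        raise ValueError(f"min_bin_size must be in [1, {n}], got {min_bin_size}")
    by_degree: dict[int, list] = {}
    for node, deg in g.degree():
        by_degree.setdefault(deg, []).append(node)

    bins: list[tuple] = []
    current: list = []
    for deg in sorted(by_degree, reverse=True):
        current.extend(by_degree[deg])
        if len(current) >= min_bin_size:
            bins.append(tuple(sorted(current)))
            current = []
    if current:
        if bins:
            merged = tuple(sorted(bins[-1] + tuple(current)))
            bins[-1] = merged
        else:
            bins.append(tuple(sorted(current)))
    bin_of = {node: i for i, members in enumerate(bins) for node in members}
    return DegreeBinning(bins=tuple(bins), bin_of=bin_of, min_bin_size=min_bin_size)


def sample_degree_matched(
    g: nx.Graph,
    binning: DegreeBinning,
    template: Iterable,
    rng,
) -> set:
    """Draw a random node set matching the degree-bin profile of ``template``.

    One node is drawn uniformly, without replacement within each bin, for
    every template node in that bin.  If a bin holds fewer members than the
    template demands (possible only when ``min_bin_size`` is tiny), sampling
    falls back to with-replacement within the bin and logs a warning.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    template = set(template)
    missing = template - binning.bin_of.keys()
    if missing:
        raise KeyError(f"template nodes outside binning: {sorted(missing)[:5]}")
    demand: dict[int, int] = {}
    for node in template:
        b = binning.bin_of[node]
        demand[b] = demand.get(b, 0) + 1
    out: set = set()
    for b in sorted(demand):
        members = binning.bins[b]
        k = demand[b]
        if k <= len(members):
            idx = rng.choice(len(members), size=k, replace=False)
        else:
            logger.warning(
                "degree bin %d exhausted (%d needed, %d members); "
                "sampling with replacement", b, k, len(members),
            )
            idx = rng.choice(len(members), size=k, replace=True)
        out.update(members[i] for i in idx)
    return out


class DistanceCache:
    """Lazily cached single-source BFS distance maps, keyed by source node.

    Pair-wise set measures touch the same drug-target nodes across many drug
    pairs; caching per-node BFS maps makes an all-pairs separation matrix a
    few thousand traversals instead of millions of repeated ones.
    """

    def __init__(self, g: nx.Graph):
        self.graph = g
        self._maps: dict = {}

    def from_node(self, node) -> Mapping:
        try:
            return self._maps[node]
        except KeyError:
            dist = shortest_path_lengths_from(self.graph, [node])
            self._maps[node] = dist
            return dist

    def pairwise(self, a_nodes: Sequence, b_nodes: Sequence) -> np.ndarray:
        """|A| × |B| matrix of hop distances; unreachable pairs are ``inf``."""
        a_nodes = list(a_nodes)
        b_nodes = list(b_nodes)
        out = np.full((len(a_nodes), len(b_nodes)), np.inf)
        for i, a in enumerate(a_nodes):
            dist = self.from_node(a)
            for j, b in enumerate(b_nodes):
                d = dist.get(b)
                if d is not None:
                    out[i, j] = d
        return out
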