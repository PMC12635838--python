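"""Link graphs: FC links as nodes, significant meta-links as edges.

A subject's MC matrix is turned into a graph whose nodes are the L unique
FC links and whose edges connect link pairs that survive the group
significance mask and a magnitude threshold.  Node features default to the
mean and SD of the link's dFC time course (strength and volatility);
each edge carries its MC value.  Depth-d neighborhood balls bound the
attention receptive field of the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import DFCStream, MCMatrix, SignificanceMask

__all__ = ["LinkGraph", "SubgraphSet", "build_link_graph", "depth_ball", "subgraph_set"]


@dataclass
class LinkGraph:
    """Undirected graph over FC links with node and edge feature vectors."""

    n_nodes: int
    node_features: np.ndarray            # L x F_n
    edges: np.ndarray                    # E x 2 unique undirected pairs (a < b)
    edge_features: np.ndarray            # E x F_e (first column: MC value)
    subject_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.edges) and (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ValueError("self-loops are not allowed")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self) -> list[np.ndarray]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return [np.array(sorted(x), dtype=int) for x in adj]


@dataclass
class SubgraphSet:
    """Per-node depth-d balls plus their induced edges."""

    balls: dict[int, tuple[int, ...]]
    induced_edges: dict[int, np.ndarray]
    depth: int


def build_link_graph(
    mc: MCMatrix,
    dfc: DFCStream | None,
    mask: SignificanceMask,
    edge_threshold: float = 0.1,
    include_mc_row: bool = False,
    subject_id: str = "",
    label: int | None = None,
) -> LinkGraph:
    """Graph over links: edge (a, b) iff mask[a, b] and |MC[a, b]| >= threshold."""
    m = mc.compact
    l = m.shape[0]
    if mask.values.shape != m.shape:
        raise ValueError("mask shape does not match MC")
    if dfc is not None and dfc.n_links != l:
        raise ValueError("dFC stream link count does not match MC")
    keep = mask.values & (np.abs(m) >= edge_threshold)
    np.fill_diagonal(keep, False)
    a_idx, b_idx = np.where(np.triu(keep, k=1))
    if len(a_idx) == 0:
        raise ValueError(
            "empty edge set: no meta-link passes the significance mask and "
            f"|MC| >= {edge_threshold}; relax edge_threshold or the mask"
        )
    edges = np.stack([a_idx, b_idx], axis=1)
    edge_features = m[a_idx, b_idx][:, None]
    if dfc is not None:
        node_features = np.stack([dfc.values.mean(axis=1), dfc.values.std(axis=1)], axis=1)
    else:
        node_features = np.zeros((l, 2))
    if include_mc_row:
        node_features = np.hstack([node_features, np.where(mask.values, m, 0.0)])
    return LinkGraph(
        n_nodes=l, node_features=node_features, edges=edges,
        edge_features=edge_features, subject_id=subject_id, label=label,
    )


def depth_ball(graph: LinkGraph, node: int, d: int, adj: list[np.ndarray] | None = None) -> set[int]:
    """All nodes within hop distance <= d of ``node``.

    Uses a depth-limited depth-first traversal that re-expands a node
    whenever it is reached with more remaining budget, so the result is the
    true hop-distance ball regardless of traversal order.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if not 0 <= node < graph.n_nodes:
        raise ValueError(f"node {node} not in graph")
    if adj is None:
        adj = graph.neighbors()
    best = {node: d}
    stack = [(node, d)]
    while stack:
        v, budget = stack.pop()
        if budget == 0:
            continue
        for w in adj[v]:
            if best.get(w, -1) < budget - 1:
                best[w] = budget - 1
                stack.append((w, budget - 1))
    return set(best)


def subgraph_set(graph: LinkGraph, d: int) -> SubgraphSet:
    """Depth-d ball and induced edges for every node of the graph."""
    if not 1 <= d <= 5:
        raise ValueError("d must be in [1, 5]")
    adj = graph.neighbors()
    balls: dict[int, tuple[int, ...]] = {}
    induced: dict[int, np.ndarray] = {}
    for v in range(graph.n_nodes):
        ball = depth_ball(graph, v, d, adj)
        balls[v] = tuple(sorted(ball))
        if graph.n_edges:
            inside = np.isin(graph.edges[:, 0], list(ball)) & np.isin(
                graph.edges[:, 1], list(ball)
            )
            induced[v] = graph.edges[inside]
        else:
            induced[v] = np.empty((0, 2), dtype=int)
    return SubgraphSet(balls=balls, induced_edges=induced, depth=d)
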