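"""Molecular-complex detection (MCODE) on an undirected PPI graph.

Vertices are weighted by the density of the highest k-core of their
closed neighborhood, dense modules are grown from high-weight seeds,
and modules are post-processed (k-core requirement, haircut, optional
fluff) and kept when density x size exceeds the module-score cutoff.
Hub genes are ranked by plain node degree.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from cernet.dge import ValidationError


@dataclass
class MCODEParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    min_module_score: float = 5.0  # strict >
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if self.degree_cutoff < 1:
            raise ValidationError("degree_cutoff must be >= 1")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValidationError("node_score_cutoff must lie in [0, 1]")
        if self.k_core < 2:
            raise ValidationError("k_core must be >= 2")
        if self.max_depth < 1:
            raise ValidationError("max_depth must be >= 1")


@dataclass
class MCODEModule:
    members: frozenset[str]
    seed: str
    density: float
    score: float  # density x size

    @property
    def size(self) -> int:
        return len(self.members)


def graph_density(graph: nx.Graph) -> float:
    """2e / (n(n-1)); zero for graphs with fewer than two vertices."""
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def highest_k_core(graph: nx.Graph) -> tuple[int, nx.Graph]:
    """Maximum k with a nonempty k-core, plus that core subgraph.

    Found by iterative pruning: for increasing k, repeatedly delete
    vertices of degree < k until stable; the last nonempty survivor wins.
    Empty graph -> (0, empty graph).
    """
    if graph.number_of_nodes() == 0:
        return 0, nx.Graph()
    work = graph.copy()
    best_k, best_core = 0, graph.copy()
    k = 1
    while True:
        changed = True
        while changed:
            drop = [v for v, d in work.degree() if d < k]
            changed = bool(drop)
            work.remove_nodes_from(drop)
        if work.number_of_nodes() == 0:
            return best_k, best_core
        best_k, best_core = k, work.copy()
        k += 1


def vertex_weight(graph: nx.Graph, v, degree_cutoff: int = 2) -> float:
    """Core-clustering weight of v: 0 below the degree cutoff, otherwise
    (highest core number) x (density of that core) over the closed
    neighborhood of v."""
    if v not in graph:
        raise ValidationError(f"vertex {v!r} not in graph")
    if graph.degree(v) < degree_cutoff:
        return 0.0
    closed = graph.subgraph([v, *graph.neighbors(v)])
    k, core = highest_k_core(closed)
    return k * graph_density(core)


def _grow_module(
    graph: nx.Graph,
    seed,
    weights: dict,
    used: set,
    params: MCODEParams,
) -> set:
    """Breadth-first seed expansion over unassigned vertices whose weight
    clears (1 - node_score_cutoff) x seed weight, bounded by max_depth."""
    threshold = (1.0 - params.node_score_cutoff) * weights[seed]
    members = {seed}
    frontier = deque([(seed, 0)])
    while frontier:
        node, depth = frontier.popleft()
        if depth >= params.max_depth:
            continue
        for nbr in graph.neighbors(node):
            if nbr in members or nbr in used:
                continue
            if weights[nbr] >= threshold:
                members.add(nbr)
                frontier.append((nbr, depth + 1))
    return members


def _post_process(
    graph: nx.Graph, members: set, used: set, params: MCODEParams
) -> set | None:
    """k-core requirement, haircut, optional fluff; None = discard."""
    sub = graph.subgraph(members)
    k, _ = highest_k_core(sub)
    if k < params.k_core:
        return None
    if params.haircut:
        # iterative removal of vertices with < 2 connections into the module
        sub = sub.copy()
        changed = True
        while changed:
            drop = [v for v, d in sub.degree() if d < 2]
            changed = bool(drop)
            sub.remove_nodes_from(drop)
        members = set(sub.nodes())
        if not members:
            return None
    if params.fluff:
        extra = set()
        for v in sorted(members):
            nbhd = graph.subgraph([v, *graph.neighbors(v)])
            if graph_density(nbhd) > params.fluff_density_cutoff:
                extra.update(
                    n for n in graph.neighbors(v) if n not in members and n not in used
                )
        members = members | extra
    return members


def find_complexes(graph: nx.Graph, params: MCODEParams | None = None) -> list[MCODEModule]:
    """Detect dense modules; returns them sorted by score descending
    (ties: larger first, then lexicographic seed). Deterministic."""
    params = params or MCODEParams()
    if any(a == b for a, b in graph.edges()):
        raise ValidationError("graph must not contain self-loops")
    weights = {v: vertex_weight(graph, v, params.degree_cutoff) for v in graph}
    order = sorted(weights, key=lambda v: (-weights[v], str(v)))
    used: set = set()
    modules: list[MCODEModule] = []
    for seed in order:
        if seed in used:
            continue
        members = _grow_module(graph, seed, weights, used, params)
        used.update(members)  # vertices examined are never reused
        final = _post_process(graph, members, used, params)
        if final is None:
            continue
        used.update(final)
        sub = graph.subgraph(final)
        density = graph_density(sub)
        score = density * len(final)
        if score > params.min_module_score:
            modules.append(
                MCODEModule(frozenset(str(v) for v in final), str(seed), density, score)
            )
    modules.sort(key=lambda m: (-m.score, -m.size, m.seed))
    return modules


def rank_hubs(graph: nx.Graph, top_k: int = 4) -> list[tuple[str, int]]:
    """Top-k nodes by degree, lexicographic tie-break; top_k beyond the
    node count returns every node."""
    if graph.number_of_nodes() == 0:
        raise ValidationError("graph is empty")
    ranked = sorted(graph.degree(), key=lambda item: (-item[1], str(item[0])))
    return [(str(v), int(d)) for v, d in ranked[:top_k]]


def modules_table(modules: list[MCODEModule]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "module": range(1, len(modules) + 1),
            "score": [m.score for m in modules],
            "size": [m.size for m in modules],
            "seed": [m.seed for m in modules],
            "members": [",".join(sorted(m.members)) for m in modules],
        }
    )


def write_modules_graphml(graph: nx.Graph, modules: list[MCODEModule], path) -> None:
    annotated = graph.copy()
    membership = {}
    for i, mod in enumerate(modules, start=1):
        for v in mod.members:
            membership[v] = i
    nx.set_node_attributes(
        annotated, {v: membership.get(str(v), 0) for v in annotated}, "module"
    )
    nx.write_graphml(annotated, path)
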