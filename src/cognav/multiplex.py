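"""Multiplex lexical networks and viable-cluster detection.

A multiplex network replicates one shared set of nodes (the lexicon) across
several layers, each layer carrying a single relation type — free
associations, synonymy, phonological similarity, taxonomic links.  The
structural core of such a network is its *largest viable cluster* (LVC): the
largest set of nodes whose induced subgraph is connected in **every** layer
simultaneously.  This module provides layer/multiplex containers, edge-list
ingestion, LVC detection (with an exhaustive oracle for small instances),
per-layer largest connected components, the aggregate (union) graph, and
deterministic shortest paths.

All tie-breaking is lexicographic so that outputs are bit-reproducible.
"""

from __future__ import annotations

import itertools
import json
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .errors import ConfigurationError, DataError, EdgeListParseError

logger = logging.getLogger(__name__)

__all__ = [
    "Layer",
    "MultiplexNetwork",
    "ViableCluster",
    "PathOracle",
    "read_edge_list",
    "build_multiplex",
    "aggregate_graph",
    "largest_viable_cluster",
    "brute_force_viable_cluster",
    "layer_lcc",
    "shortest_path",
    "normalize_label",
    "write_multiplex_dir",
    "read_multiplex_dir",
]


def normalize_label(label: str) -> str:
    """Canonical node label: case-folded, surrounding whitespace stripped.

    Internal spaces of multiword entries are preserved so that e.g.
    ``"guinea pig"`` stays a single label.
    """
    return label.strip().casefold()


class Layer:
    """One relation's undirected edge set over a node set.

    Edges are stored once per unordered pair; self-loops are rejected.
    Nodes without edges are legitimate isolates.
    """

    def __init__(self, name: str, edges: Iterable[tuple[str, str]] = (),
                 nodes: Iterable[str] = ()):
        self.name = name
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                raise DataError(f"layer {name!r}: self-loop on {u!r}")
            g.add_edge(u, v)
        self._graph = g

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._graph.nodes)

    @property
    def edges(self) -> frozenset:
        return frozenset(tuple(sorted(e)) for e in self._graph.edges)

    def add_isolates(self, nodes: Iterable[str]) -> None:
        self._graph.add_nodes_from(nodes)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"Layer({self.name!r}, {self._graph.number_of_nodes()} nodes, "
                f"{self._graph.number_of_edges()} edges)")


@dataclass
class MultiplexNetwork:
    """Ordered layers sharing one node universe.

    Every layer's node set equals ``node_universe``; nodes absent from a
    layer's edge list are isolates in that layer.
    """

    layers: list[Layer]
    node_universe: frozenset = field(default_factory=frozenset)

    @property
    def layer_names(self) -> list[str]:
        return [layer.name for layer in self.layers]

    def layer(self, name: str) -> Layer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(name)


@dataclass(frozen=True)
class ViableCluster:
    """Node set simultaneously connected in every layer, plus the number of
    refinement passes the fixed-point computation needed."""

    members: frozenset
    iterations: int


def read_edge_list(path, layer_name: str, min_weight: float = 0.0) -> Layer:
    """Read a delimited (TSV or CSV) edge list into a :class:`Layer`.

    Rows have 2 or 3 columns: ``node1, node2[, weight]``.  Weighted rows are
    kept only when ``weight > min_weight`` (strictly greater — a threshold of
    10 keeps links elicited *more than* 10 times); unweighted rows are always
    kept.  ``#``-prefixed comment lines and blank lines are skipped.  Labels
    are normalized via :func:`normalize_label`; self-loops (possibly created
    by normalization) are dropped with a warning.
    """
    path = Path(path)
    if min_weight < 0:
        raise ConfigurationError("min_weight must be nonnegative")
    edges: list[tuple[str, str]] = []
    nodes: set[str] = set()
    with path.open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            fields = [f.strip() for f in fields]
            if len(fields) not in (2, 3):
                raise EdgeListParseError(
                    path, lineno,
                    f"expected 2 or 3 columns, found {len(fields)}")
            u, v = normalize_label(fields[0]), normalize_label(fields[1])
            if not u or not v:
                raise EdgeListParseError(path, lineno, "empty node label")
            if len(fields) == 3:
                try:
                    weight = float(fields[2])
                except ValueError:
                    raise EdgeListParseError(
                        path, lineno,
                        f"non-numeric weight {fields[2]!r}") from None
                if weight <= min_weight:
                    continue
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %r",
                               path, lineno, u)
                continue
            edges.append((u, v))
            nodes.update((u, v))
    layer = Layer(layer_name, edges, nodes)
    logger.info("layer %r: read %d nodes, %d edges from %s (min_weight=%g)",
                layer_name, len(layer.nodes),
                layer.graph.number_of_edges(), path, min_weight)
    return layer


def build_multiplex(layers: Sequence[Layer]) -> MultiplexNetwork:
    """Assemble layers into a multiplex over the union of their node sets.

    Each layer is extended with isolates so all layers share the universe.
    """
    layers = list(layers)
    if len(layers) < 2:
        raise ConfigurationError(
            f"a multiplex needs at least 2 layers, got {len(layers)}")
    names = [layer.name for layer in layers]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate layer names: {names}")
    universe = frozenset().union(*(layer.nodes for layer in layers))
    for layer in layers:
        layer.add_isolates(universe)
    return MultiplexNetwork(layers=layers, node_universe=universe)


def aggregate_graph(mpx: MultiplexNetwork) -> nx.Graph:
    """Union of all layer edge sets over the shared universe (unweighted,
    duplicate edges collapsed): the edge-colored condensation with the
    colors forgotten."""
    g = nx.Graph()
    g.add_nodes_from(mpx.node_universe)
    for layer in mpx.layers:
        g.add_edges_from(layer.graph.edges)
    return g


def _components(graph: nx.Graph, nodes: frozenset) -> list[frozenset]:
    """Connected components of the induced subgraph (isolates included)."""
    sub = graph.subgraph(nodes)
    return [frozenset(c) for c in nx.connected_components(sub)]


def _best_set(candidates: Iterable[frozenset]) -> frozenset:
    """Largest set; ties broken by lexicographically smallest sorted list."""
    best: Optional[frozenset] = None
    best_key = None
    for cand in candidates:
        key = (-len(cand), sorted(cand))
        if best_key is None or key < best_key:
            best, best_key = cand, key
    return best if best is not None else frozenset()


def largest_viable_cluster(mpx: MultiplexNetwork) -> ViableCluster:
    """Largest node set whose induced subgraph is connected in every layer.

    Computed by partition refinement: start with the whole universe as one
    candidate cell and repeatedly split each cell into the connected
    components of its induced subgraph, layer by layer, until no cell splits.
    At the fixed point every cell is connected in every layer (viable), and
    every viable set is contained in some cell — a viable set is connected in
    each layer, so each split leaves it inside a single component.  The
    largest final cell is therefore the maximum viable cluster, which the
    exhaustive oracle :func:`brute_force_viable_cluster` confirms on small
    instances.
    """
    if not mpx.node_universe:
        return ViableCluster(members=frozenset(), iterations=0)
    cells: list[frozenset] = [frozenset(mpx.node_universe)]
    iterations = 0
    while True:
        iterations += 1
        new_cells: list[frozenset] = []
        changed = False
        for cell in cells:
            pieces = [cell]
            for layer in mpx.layers:
                pieces = [comp
                          for piece in pieces
                          for comp in _components(layer.graph, piece)]
            if len(pieces) > 1:
                changed = True
            new_cells.extend(pieces)
        cells = new_cells
        if not changed:
            break
    members = _best_set(cells)
    return ViableCluster(members=members, iterations=iterations)


def brute_force_viable_cluster(mpx: MultiplexNetwork,
                               max_nodes: int = 12) -> frozenset:
    """Exhaustive maximum viable cluster for tiny instances (test oracle).

    Enumerates node subsets from largest to smallest and returns the first
    one connected in every layer; within a size, subsets are visited in
    lexicographic order, so ties resolve to the lexicographically smallest
    sorted member list.
    """
    universe = sorted(mpx.node_universe)
    if len(universe) > max_nodes:
        raise ConfigurationError(
            f"brute force refused: {len(universe)} nodes > max_nodes="
            f"{max_nodes}")
    for size in range(len(universe), 0, -1):
        for subset in itertools.combinations(universe, size):
            nodes = frozenset(subset)
            if all(len(_components(layer.graph, nodes)) == 1
                   for layer in mpx.layers):
                return nodes
    return frozenset()


def layer_lcc(layer: Layer) -> frozenset:
    """Largest connected component of one layer (isolates count as size-1
    components); ties broken lexicographically.  The single-layer analogue
    of the LVC, used by the null models."""
    comps = [frozenset(c) for c in nx.connected_components(layer.graph)]
    return _best_set(comps)


def shortest_path(graph: nx.Graph, source, target):
    """Deterministic shortest path: BFS expanding neighbors in lexicographic
    order.

    Returns a tuple of nodes from ``source`` to ``target`` inclusive, or
    ``None`` when the two nodes are in different components (a well-defined
    "disconnected" outcome, distinct from the :class:`KeyError` raised for
    nodes absent from the graph).
    """
    if source not in graph:
        raise KeyError(f"source {source!r} not in graph")
    if target not in graph:
        raise KeyError(f"target {target!r} not in graph")
    if source == target:
        return (source,)
    parents = {source: None}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in sorted(graph[u]):
            if v not in parents:
                parents[v] = u
                if v == target:
                    path = [v]
                    while parents[path[-1]] is not None:
                        path.append(parents[path[-1]])
                    return tuple(reversed(path))
                queue.append(v)
    return None


class PathOracle:
    """Memoized lexicographic-BFS shortest paths on a fixed graph.

    Caches one full BFS parent tree per source so that repeated queries
    (every consecutive response pair, every response-to-category path) cost
    one BFS per distinct source.  Paths are identical to
    :func:`shortest_path`.
    """

    def __init__(self, graph: nx.Graph):
        self._graph = graph
        self._trees: dict = {}

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    def _tree(self, source) -> dict:
        tree = self._trees.get(source)
        if tree is None:
            if source not in self._graph:
                raise KeyError(f"source {source!r} not in graph")
            tree = {source: None}
            queue = deque([source])
            while queue:
                u = queue.popleft()
                for v in sorted(self._graph[u]):
                    if v not in tree:
                        tree[v] = u
                        queue.append(v)
            self._trees[source] = tree
        return tree

    def path(self, source, target):
        """Same contract as :func:`shortest_path`."""
        if target not in self._graph:
            raise KeyError(f"target {target!r} not in graph")
        tree = self._tree(source)
        if target not in tree:
            return None
        path = [target]
        while tree[path[-1]] is not None:
            path.append(tree[path[-1]])
        return tuple(reversed(path))

    def distance(self, source, target):
        """Edge count of the shortest path, or ``None`` if disconnected."""
        p = self.path(source, target)
        return None if p is None else len(p) - 1


# ---------------------------------------------------------------------------
# Serialization: one directory per multiplex (manifest + per-layer TSV).

def write_multiplex_dir(mpx: MultiplexNetwork, directory,
                        min_weight: Optional[float] = None,
                        lvc: Optional[frozenset] = None) -> dict:
    """Write a multiplex to ``directory``: ``manifest.json`` plus one TSV
    edge list per layer, and optionally ``lvc.txt`` (one label per line)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "schema": "cognav-multiplex-1",
        "layers": [],
        "node_count": len(mpx.node_universe),
        "min_weight": min_weight,
    }
    for layer in mpx.layers:
        fname = f"layer_{layer.name}.tsv"
        with (directory / fname).open("w", encoding="utf-8") as handle:
            handle.write("# node1\tnode2\n")
            for u, v in sorted(layer.edges):
                handle.write(f"{u}\t{v}\n")
        manifest["layers"].append({
            "name": layer.name,
            "file": fname,
            "n_edges": layer.graph.number_of_edges(),
        })
    if lvc is not None:
        with (directory / "lvc.txt").open("w", encoding="utf-8") as handle:
            for node in sorted(lvc):
                handle.write(f"{node}\n")
        manifest["lvc_size"] = len(lvc)
        manifest["lvc_file"] = "lvc.txt"
    with (directory / "manifest.json").open("w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest


def read_multiplex_dir(directory) -> MultiplexNetwork:
    """Load a multiplex written by :func:`write_multiplex_dir`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    layers = [read_edge_list(directory / entry["file"], entry["name"])
              for entry in manifest["layers"]]
    return build_multiplex(layers)
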