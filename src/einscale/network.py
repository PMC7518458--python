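"""Weighted digraph model and row-stochastic transition structures.

A directed, non-negatively weighted network is the common substrate for all
scale analysis in this package: nodes may be genes, proteins, or the global
states of a Boolean model.  Normalizing each node's out-weights to sum to one
turns the network into the transition structure of a random walker, which is
the object effective information is defined on.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import numbers
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-9

__all__ = [
    "WeightedDigraph",
    "TransitionStructure",
    "normalize",
    "read_edge_list",
    "read_graphml",
    "write_graphml",
    "write_json_report",
]


class WeightedDigraph:
    """A directed graph with non-negative edge weights and a fixed node order.

    Node order is insertion order; every vector or matrix produced downstream
    is indexed in this order, so results are reproducible bit-for-bit.
    """

    def __init__(self, nodes: Iterable[str] = (),
                 edges: Iterable[tuple[str, str, float]] = ()):
        self._order: list[str] = []
        self._index: dict[str, int] = {}
        self.graph = nx.DiGraph()
        for n in nodes:
            self.add_node(n)
        for u, v, w in edges:
            self.add_edge(u, v, w)

    def add_node(self, label: str) -> None:
        if label not in self._index:
            self._index[label] = len(self._order)
            self._order.append(label)
            self.graph.add_node(label)

    def add_edge(self, source: str, target: str, weight: float = 1.0) -> None:
        """Add an edge; a repeated (source, target) pair accumulates weight."""
        if not isinstance(weight, numbers.Real) or not np.isfinite(weight):
            raise ValueError(
                f"edge {source}->{target}: weight must be a finite number, "
                f"got {weight!r}")
        if weight < 0:
            raise ValueError(
                f"edge {source}->{target}: negative weight {weight}")
        self.add_node(source)
        self.add_node(target)
        if self.graph.has_edge(source, target):
            logger.warning("duplicate edge %s->%s: weights summed",
                           source, target)
            self.graph[source][target]["weight"] += float(weight)
        else:
            self.graph.add_edge(source, target, weight=float(weight))

    @property
    def node_labels(self) -> tuple[str, ...]:
        return tuple(self._order)

    @property
    def n_nodes(self) -> int:
        return len(self._order)

    def node_index(self, label: str) -> int:
        return self._index[label]

    def out_weights(self, label: str) -> dict[str, float]:
        return {v: d["weight"] for v, d in self.graph[label].items()}

    def weight_matrix(self) -> sp.csr_matrix:
        """Out-weight matrix in node order (rows = sources)."""
        n = self.n_nodes
        rows, cols, vals = [], [], []
        for u, v, d in self.graph.edges(data=True):
            rows.append(self._index[u])
            cols.append(self._index[v])
            vals.append(d["weight"])
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def __eq__(self, other) -> bool:
        if not isinstance(other, WeightedDigraph):
            return NotImplemented
        if self.node_labels != other.node_labels:
            return False
        a = {(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}
        b = {(u, v): d["weight"] for u, v, d in other.graph.edges(data=True)}
        return a == b

    def __repr__(self) -> str:
        return (f"WeightedDigraph(n_nodes={self.n_nodes}, "
                f"n_edges={self.graph.number_of_edges()})")


class TransitionStructure:
    """Row-stochastic out-weight vectors ``W_i^out`` over N nodes.

    Rows are stored sparsely; every row must sum to one within ``1e-9`` and
    entries lie in [0, 1].  This invariant is enforced at construction, so a
    ``TransitionStructure`` is always a valid random-walker kernel.
    """

    def __init__(self, node_labels: Sequence[str], matrix) -> None:
        labels = tuple(str(x) for x in node_labels)
        if len(labels) == 0:
            raise ValueError("a transition structure needs at least one node")
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique")
        M = sp.csr_matrix(matrix, dtype=np.float64)
        if M.shape != (len(labels), len(labels)):
            raise ValueError(
                f"matrix shape {M.shape} does not match {len(labels)} labels")
        if M.nnz and M.data.min() < 0:
            i = int(np.argmin(M.tocoo().data))
            row = M.tocoo().row[i]
            raise ValueError(
                f"node {labels[row]!r}: negative transition probability")
        if M.nnz and M.data.max() > 1 + ROW_SUM_TOL:
            raise ValueError("transition probabilities must lie in [0, 1]")
        sums = np.asarray(M.sum(axis=1)).ravel()
        bad = np.where(np.abs(sums - 1.0) > ROW_SUM_TOL)[0]
        if bad.size:
            raise ValueError(
                f"row for node {labels[bad[0]]!r} sums to {sums[bad[0]]!r}, "
                "not 1.0")
        self.node_labels = labels
        self.matrix = M

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def row(self, i: int) -> np.ndarray:
        return np.asarray(self.matrix.getrow(i).todense()).ravel()

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())

    def mean_out_vector(self) -> np.ndarray:
        """<W_i^out>: the unweighted mean of the rows."""
        return np.asarray(self.matrix.mean(axis=0)).ravel()

    def is_deterministic(self, tol: float = 1e-12) -> bool:
        """True when every row places all its mass on a single node."""
        M = self.matrix
        max_per_row = np.zeros(self.n_nodes)
        if M.nnz:
            max_per_row = np.maximum.reduceat(
                np.concatenate([M.data, [0.0]]),
                np.minimum(M.indptr[:-1], M.nnz - 1))
            max_per_row[np.diff(M.indptr) == 0] = 0.0
        return bool(np.all(max_per_row > 1 - tol))

    def successors(self) -> np.ndarray:
        """For a deterministic structure, the index each node maps onto."""
        if not self.is_deterministic():
            raise ValueError("transition structure is not deterministic")
        return np.asarray(self.matrix.argmax(axis=1)).ravel()

    def __eq__(self, other) -> bool:
        if not isinstance(other, TransitionStructure):
            return NotImplemented
        return (self.node_labels == other.node_labels
                and (self.matrix != other.matrix).nnz == 0)

    def __repr__(self) -> str:
        return f"TransitionStructure(n_nodes={self.n_nodes})"


def normalize(g: WeightedDigraph | TransitionStructure,
              dangling_policy: str = "self_loop") -> TransitionStructure:
    """Normalize each node's out-weights to a probability row.

    A node with zero total out-weight (a dangling node) is given a self-loop
    of probability one, the traditional convention in Boolean analysis for
    nodes whose targets are outside the modelled subnetwork.  Normalizing an
    already-stochastic structure is the identity.
    """
    if dangling_policy != "self_loop":
        raise ValueError(f"unknown dangling policy {dangling_policy!r}")
    if isinstance(g, TransitionStructure):
        return TransitionStructure(g.node_labels, g.matrix.copy())
    W = g.weight_matrix().tolil()
    sums = np.asarray(W.sum(axis=1)).ravel()
    for i in np.where(sums == 0)[0]:
        W[i, i] = 1.0
        sums[i] = 1.0
    W = W.tocsr()
    inv = sp.diags(1.0 / sums)
    return TransitionStructure(g.node_labels, inv @ W)


def read_edge_list(path: str | Path, directed: bool = True,
                   weight_column: str = "weight") -> WeightedDigraph:
    """Read a CSV edge list with header ``source,target[,weight]``.

    Missing weights default to 1.0; duplicate edges are summed with a
    warning.  Pure-target nodes are kept (they are dangling until
    normalization).
    """
    if not directed:
        raise ValueError("only directed networks are supported; "
                         "pass directed=True")
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    for col in ("source", "target"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    g = WeightedDigraph()
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        u, v = rec["source"], rec["target"]
        if not isinstance(u, str) or not isinstance(v, str):
            raise ValueError(f"{path}:{pos}: malformed row {tuple(rec.values())}")
        w = rec.get(weight_column)
        if w is None or (isinstance(w, float) and np.isnan(w)):
            weight = 1.0
        else:
            try:
                weight = float(w)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{pos}: weight {w!r} is not a number") from exc
        try:
            g.add_edge(u, v, weight)
        except ValueError as exc:
            raise ValueError(f"{path}:{pos}: {exc}") from exc
    if g.n_nodes == 0:
        raise ValueError(f"{path}: edge list contains no edges")
    return g


def read_graphml(path: str | Path) -> WeightedDigraph:
    """Read a directed GraphML file; absent weight attributes become 1.0."""
    path = Path(path)
    gx = nx.read_graphml(path)
    if not gx.is_directed():
        raise ValueError(
            f"{path}: GraphML graph is undirected; re-export it with "
            "edgedefault=\"directed\"")
    if gx.number_of_nodes() == 0:
        raise ValueError(f"{path}: graph file contains no nodes")
    g = WeightedDigraph()
    for n in gx.nodes():
        g.add_node(str(n))
    for u, v, d in gx.edges(data=True):
        g.add_edge(str(u), str(v), float(d.get("weight", 1.0)))
    return g


def write_graphml(g: WeightedDigraph | TransitionStructure,
                  path: str | Path) -> None:
    path = Path(path)
    gx = nx.DiGraph()
    if isinstance(g, TransitionStructure):
        gx.add_nodes_from(g.node_labels)
        coo = g.matrix.tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            gx.add_edge(g.node_labels[i], g.node_labels[j], weight=float(w))
    else:
        gx.add_nodes_from(g.node_labels)
        for u, v, d in g.graph.edges(data=True):
            gx.add_edge(u, v, weight=float(d["weight"]))
    nx.write_graphml(gx, path)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, TransitionStructure):
        return {"node_labels": list(obj.node_labels),
                "rows": obj.to_dense().tolist()}
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return repr(obj)


def write_json_report(result, path: str | Path) -> None:
    """Serialize any result object (dataclass, mapping, array...) to JSON."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(result), fh, indent=2)
        fh.write("\n")
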