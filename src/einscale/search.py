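"""Searching the space of coarse-grainings for causal emergence.

Causal emergence is when some macro-scale of a network -- a partition of its
nodes into macro-nodes -- has higher effective information than the
micro-scale.  The partition space is astronomically large (Bell numbers), so
three strategies are provided:

``exhaustive_search``
    enumerates every partition (N <= 10); the ground-truth oracle.
``greedy_search``
    best-improvement hill climbing over pairwise group merges, with the
    candidate pairs restricted to nodes within undirected graph distance two
    (nodes further apart share no inputs or outputs, so merging them cannot
    reduce noise).
``spectral_search``
    embeds nodes by the leading eigenvectors of the transition matrix (nodes
    with similar causal roles embed close together; nodes with identical
    out-rows embed identically), proposes candidate macro-nodes by
    density-based clustering at a swept resolution, and keeps the subset of
    candidate clusters whose joint merge maximizes EI.  Subset selection
    matters: a group of degenerate nodes often raises EI only together with
    its sibling groups, so validating clusters one at a time can strand the
    search below an available macro-scale.

All macro-nodes are average coarse-grains (see :mod:`einscale.macro`).
Every returned non-identity mapping satisfies ei_macro > ei_micro + epsilon.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .info import effective_information
from .macro import MacroMapping, apply_mapping
from .network import TransitionStructure

logger = logging.getLogger(__name__)

__all__ = [
    "EmergenceResult",
    "exhaustive_search",
    "greedy_search",
    "spectral_search",
    "causal_emergence_report",
]

EXHAUSTIVE_MAX_NODES = 10
DEFAULT_EPSILON = 1e-10
#: DBSCAN reachability sweep, in units of the embedding's scale.  The finest
#: level isolates exact duplicates of the eigenvector embedding.
DEFAULT_EPS_GRID = (1e-8, 1e-5, 1e-3, 1e-2, 0.05, 0.1, 0.2, 0.5)


@dataclass
class EmergenceResult:
    """Outcome of an emergence search, micro vs macro EI in bits."""

    mapping: MacroMapping
    ei_micro: float
    ei_macro: float
    n_micro: int
    n_macro: int
    participation: float
    algorithm: str
    seed: int | None = None
    parameters: dict = field(default_factory=dict)

    @property
    def gain(self) -> float:
        return self.ei_macro - self.ei_micro

    def as_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "seed": self.seed,
            "parameters": self.parameters,
            "n_micro": self.n_micro,
            "n_macro": self.n_macro,
            "ei_micro": self.ei_micro,
            "ei_macro": self.ei_macro,
            "gain": self.gain,
            "participation": self.participation,
            "mapping": dict(self.mapping.assignment),
        }


# --- partition evaluation ---------------------------------------------------


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _partition_ei(T: np.ndarray, assign: np.ndarray, m: int) -> float:
    """EI of the average coarse-grain induced by an assignment vector.

    Matches effective_information(apply_mapping(...).macro_ts).ei; kept as a
    dense fast path for search inner loops.
    """
    n = T.shape[0]
    Ind = np.zeros((n, m))
    Ind[np.arange(n), assign] = 1.0
    C = T @ Ind
    counts = Ind.sum(axis=0)
    M = (Ind.T @ C) / counts[:, None]
    logs = np.zeros_like(M)
    np.log2(M, where=M > 0, out=logs)
    h_rows = -(M * logs).sum(axis=1)
    return _entropy(M.mean(axis=0)) - float(h_rows.mean())


def _result_from_assignment(ts: TransitionStructure, assign: np.ndarray,
                            ei_micro: float, algorithm: str,
                            seed: int | None,
                            parameters: dict) -> EmergenceResult:
    labels = ts.node_labels
    n = ts.n_nodes
    groups: dict[int, list[str]] = {}
    for i, a in enumerate(assign):
        groups.setdefault(int(a), []).append(labels[i])
    assignment = {}
    k = 0
    for a in sorted(groups, key=lambda a: labels.index(groups[a][0])):
        members = groups[a]
        name = members[0] if len(members) == 1 else f"mu_{k}"
        if len(members) > 1:
            k += 1
        for mlabel in members:
            assignment[mlabel] = name
    mapping = MacroMapping(assignment=assignment, method="average")
    macro = apply_mapping(ts, mapping)
    ei_macro = effective_information(macro.macro_ts).ei
    return EmergenceResult(
        mapping=mapping,
        ei_micro=ei_micro,
        ei_macro=ei_macro,
        n_micro=n,
        n_macro=macro.n_macro,
        participation=mapping.participation(labels),
        algorithm=algorithm,
        seed=seed,
        parameters=parameters,
    )


def _identity_result(ts: TransitionStructure, ei_micro: float,
                     algorithm: str, seed: int | None,
                     parameters: dict) -> EmergenceResult:
    return _result_from_assignment(
        ts, np.arange(ts.n_nodes), ei_micro, algorithm, seed, parameters)


# --- exhaustive oracle ------------------------------------------------------


def _iter_partitions(n: int):
    """All set partitions of range(n) as restricted-growth assignment
    vectors, in lexicographic order of the encoding."""
    assign = np.zeros(n, dtype=np.int64)
    maxes = np.zeros(n, dtype=np.int64)

    def rec(i):
        if i == n:
            yield assign
            return
        top = maxes[i - 1] if i > 0 else -1
        for v in range(top + 2):
            assign[i] = v
            maxes[i] = max(top, v)
            yield from rec(i + 1)

    yield from rec(0)


def exhaustive_search(ts: TransitionStructure,
                      epsilon: float = DEFAULT_EPSILON) -> EmergenceResult:
    """Globally EI-maximal partition by full enumeration (N <= 10).

    Ties are broken toward the lexicographically smallest restricted-growth
    encoding, which enumerates first; the identity mapping is returned when
    no partition beats the micro-scale by more than epsilon.
    """
    n = ts.n_nodes
    if n > EXHAUSTIVE_MAX_NODES:
        raise ValueError(
            f"exhaustive search enumerates Bell({n}) partitions; for "
            f"N > {EXHAUSTIVE_MAX_NODES} use greedy_search or "
            "spectral_search")
    T = ts.to_dense()
    ei_micro = effective_information(ts).ei
    best_val, best_assign = -np.inf, None
    for assign in _iter_partitions(n):
        m = int(assign.max()) + 1
        val = _partition_ei(T, assign, m)
        if val > best_val + 1e-15:
            best_val, best_assign = val, assign.copy()
    params = {"epsilon": epsilon}
    if best_val <= ei_micro + epsilon:
        return _identity_result(ts, ei_micro, "exhaustive", None, params)
    return _result_from_assignment(ts, best_assign, ei_micro, "exhaustive",
                                   None, params)


# --- greedy merge search ----------------------------------------------------


def _distance2_mask(ts: TransitionStructure) -> np.ndarray:
    """allowed[i, j] when i and j are within undirected distance two."""
    A = (ts.matrix > 0)
    U = (A + A.T).astype(bool)
    close = (U + U @ U).toarray().astype(bool)
    np.fill_diagonal(close, True)
    return close


def greedy_search(ts: TransitionStructure, epsilon: float = DEFAULT_EPSILON,
                  order_seed: int = 0,
                  full_pairwise: bool = False) -> EmergenceResult:
    """Best-improvement hill climbing over pairwise group merges.

    Each round evaluates merging every candidate pair of current groups (in
    an order shuffled by ``order_seed``, which also breaks exact ties) and
    accepts the merge with maximal EI gain if that gain exceeds epsilon;
    the search stops when no merge improves.  By default candidate pairs
    are restricted to groups containing nodes within undirected graph
    distance two of each other; ``full_pairwise=True`` lifts the
    restriction.
    """
    n = ts.n_nodes
    T = ts.to_dense()
    ei_micro = effective_information(ts).ei
    rng = np.random.default_rng(order_seed)
    allowed = (np.ones((n, n), dtype=bool) if full_pairwise
               else _distance2_mask(ts))
    assign = np.arange(n)
    m = n
    cur = ei_micro
    while m > 1:
        members: dict[int, np.ndarray] = {
            g: np.where(assign == g)[0] for g in range(m)}
        pairs = [(a, b) for a in range(m) for b in range(a + 1, m)
                 if allowed[np.ix_(members[a], members[b])].any()]
        order = rng.permutation(len(pairs))
        best_val, best_pair = cur + epsilon, None
        for idx in order:
            a, b = pairs[idx]
            trial = assign.copy()
            trial[trial == b] = a
            trial[trial > b] -= 1
            val = _partition_ei(T, trial, m - 1)
            if val > best_val:
                best_val, best_pair = val, (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        assign[assign == b] = a
        assign[assign > b] -= 1
        m -= 1
        cur = best_val
    params = {"epsilon": epsilon, "full_pairwise": full_pairwise}
    return _result_from_assignment(ts, assign, ei_micro, "greedy",
                                   order_seed, params)


# --- spectral search --------------------------------------------------------


def _spectral_embedding(T: np.ndarray, k: int) -> np.ndarray:
    """Node coordinates from the k leading right eigenvectors of T,
    augmented with the one- and two-step transition profiles.

    Right eigenvectors with nonzero eigenvalue are constant across nodes
    with identical out-rows, so dynamically interchangeable nodes embed at
    exactly the same point; each eigenvector is weighted by |lambda| and
    complex pairs contribute their real and imaginary parts.  The raw
    eigenbasis alone degenerates on deterministic state-transition graphs
    (the matrix is defective: transient structure puts almost all
    eigenvalues at zero, and the surviving eigenvectors are constant on
    attractor basins), so the rows of T and T^2 are appended: they preserve
    the identical-row coincidence property while keeping dynamically
    distinct nodes apart.
    """
    vals, vecs = np.linalg.eig(T)
    order = np.argsort(-np.abs(vals))[:k]
    cols = []
    for j in order:
        lam, v = vals[j], vecs[:, j]
        if np.abs(lam) < 1e-12:
            continue  # defective zero-eigenvalue vectors are arbitrary
        norm = np.max(np.abs(v))
        if norm > 0:
            v = v / norm
        cols.append(np.abs(lam) * v.real)
        if np.abs(lam.imag) > 1e-12:
            cols.append(np.abs(lam) * v.imag)
    profile = [T, T @ T]
    return np.column_stack([np.column_stack(cols) if cols
                            else np.zeros((T.shape[0], 1))] + profile)


def _best_cluster_subset(T: np.ndarray, clusters: list[np.ndarray],
                         base_ei: float, max_exhaustive: int = 12
                         ) -> tuple[float, tuple[int, ...]]:
    """EI-maximal subset of disjoint candidate clusters to merge."""
    n = T.shape[0]

    def ei_of(sub: tuple[int, ...]) -> float:
        assign = np.full(n, -1)
        k = 0
        for ci in sub:
            assign[clusters[ci]] = k
            k += 1
        for i in range(n):
            if assign[i] < 0:
                assign[i] = k
                k += 1
        return _partition_ei(T, assign, k)

    nc = len(clusters)
    if nc <= max_exhaustive:
        best_val, best_sub = base_ei, ()
        for r in range(1, nc + 1):
            for sub in itertools.combinations(range(nc), r):
                val = ei_of(sub)
                if val > best_val + 1e-15:
                    best_val, best_sub = val, sub
        return best_val, best_sub
    # forward selection by marginal gain, then backward elimination
    chosen: list[int] = []
    cur = base_ei
    improved = True
    while improved:
        improved = False
        gains = [(ei_of(tuple(sorted(chosen + [c]))), c)
                 for c in range(nc) if c not in chosen]
        if gains:
            val, c = max(gains)
            if val > cur + 1e-15:
                chosen.append(c)
                cur = val
                improved = True
    for c in list(chosen):
        rest = tuple(sorted(x for x in chosen if x != c))
        val = ei_of(rest) if rest else base_ei
        if val > cur + 1e-15:
            chosen.remove(c)
            cur = val
    return cur, tuple(sorted(chosen))


def spectral_search(ts: TransitionStructure,
                    epsilon: float = DEFAULT_EPSILON,
                    n_eigenvectors: int | None = None,
                    eps_grid: tuple[float, ...] = DEFAULT_EPS_GRID,
                    seed: int = 0) -> EmergenceResult:
    """Macro-scale search via eigenvector embedding and density clustering.

    At each reachability level of the sweep, DBSCAN (min_samples=2) on the
    embedding proposes disjoint candidate clusters; the EI-maximal subset of
    those clusters is evaluated as a joint merge.  The best level wins; if
    no level beats the micro-scale EI by more than epsilon the identity
    mapping is returned.
    """
    from sklearn.cluster import DBSCAN

    n = ts.n_nodes
    ei_micro = effective_information(ts).ei
    params = {"epsilon": epsilon, "eps_grid": list(eps_grid)}
    if n == 1:
        return _identity_result(ts, ei_micro, "spectral", seed, params)
    k = min(n - 1, 20) if n_eigenvectors is None else n_eigenvectors
    T = ts.to_dense()
    try:
        X = _spectral_embedding(T, k)
    except np.linalg.LinAlgError as exc:
        logger.warning("eigensolver failed (%s); falling back to greedy", exc)
        res = greedy_search(ts, epsilon=epsilon, order_seed=seed)
        res.algorithm = "spectral(greedy-fallback)"
        return res
    scale = float(np.abs(X).max()) or 1.0
    best_val, best_assign = ei_micro, None
    best_level = None
    for eps in eps_grid:
        db = DBSCAN(eps=eps * scale, min_samples=2).fit(X)
        labels = db.labels_
        clusters = [np.where(labels == c)[0]
                    for c in sorted(set(labels)) if c != -1]
        clusters = [c for c in clusters if c.size >= 2]
        if not clusters:
            continue
        val, sub = _best_cluster_subset(T, clusters, ei_micro)
        if val > best_val + 1e-15:
            assign = np.full(n, -1)
            g = 0
            for ci in sub:
                assign[clusters[ci]] = g
                g += 1
            for i in range(n):
                if assign[i] < 0:
                    assign[i] = g
                    g += 1
            best_val, best_assign, best_level = val, assign, eps
    if best_assign is None or best_val <= ei_micro + epsilon:
        return _identity_result(ts, ei_micro, "spectral", seed, params)
    params["eps_level"] = best_level
    return _result_from_assignment(ts, best_assign, ei_micro, "spectral",
                                   seed, params)


_ALGORITHMS = {
    "exhaustive": exhaustive_search,
    "greedy": greedy_search,
    "spectral": spectral_search,
}


def causal_emergence_report(ts: TransitionStructure,
                            algorithm: str = "spectral",
                            **kwargs) -> EmergenceResult:
    """Run an emergence search and report micro/macro EI and participation.

    Participation is the fraction of micro-nodes assigned to macro-nodes of
    size two or more -- how much of the network takes part in the
    macro-scale.
    """
    if algorithm not in _ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; "
            f"choose from {sorted(_ALGORITHMS)}")
    if algorithm == "greedy" and "seed" in kwargs:
        kwargs["order_seed"] = kwargs.pop("seed")
    return _ALGORITHMS[algorithm](ts, **kwargs)
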