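"""Macro-node construction: coarse-graining a transition structure.

A macro-scale model replaces a subgraph S of micro-nodes with a single
macro-node mu whose out-row summarizes the members' out-rows.  Two
constructions are provided:

``average``
    W_mu^out is the unweighted mean of the members' rows -- the simplest
    coarse-grain, appropriate for deterministic state-transition graphs
    whose transient states carry no stationary mass.

``stationary_weighted``
    members' rows are weighted by their stationary probabilities
    (renormalized within the group), which preserves the stationary
    distribution of the walk: the macro chain's stationary mass on mu equals
    the summed micro mass of its members.  Appropriate for networks with
    well-occupied stationary dynamics.

In both cases destination mass is aggregated by summing columns within each
group, so mass flowing between members of a group becomes self-loop mass on
mu -- the unique choice that preserves one-step walker flow.  The
:func:`walker_consistency` score quantifies how closely random walkers on the
macro network track group-projected walkers on the micro network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import TransitionStructure

logger = logging.getLogger(__name__)

__all__ = [
    "MacroMapping",
    "MacroNetwork",
    "apply_mapping",
    "stationary_distribution",
    "walker_consistency",
    "read_mapping_csv",
    "write_mapping_csv",
]


@dataclass(frozen=True)
class MacroMapping:
    """A total assignment of micro-nodes to macro-node labels.

    Singleton groups are allowed (a node mapped to a group of one is simply
    carried through).  Macro-node order is the order of first appearance by
    micro-node index, so the induced macro network is reproducible.
    """

    assignment: Mapping[str, str]
    method: str = "average"

    def __post_init__(self):
        if self.method not in ("average", "stationary_weighted"):
            raise ValueError(f"unknown macro-node method {self.method!r}")
        if not self.assignment:
            raise ValueError("empty macro mapping")

    @classmethod
    def from_groups(cls, groups: Sequence[Sequence[str]],
                    method: str = "average",
                    all_nodes: Sequence[str] | None = None) -> "MacroMapping":
        """Build a mapping from explicit groups; ungrouped nodes (from
        ``all_nodes``) become singletons."""
        assignment: dict[str, str] = {}
        grouped = set()
        for k, members in enumerate(groups):
            for m in members:
                if m in assignment:
                    raise ValueError(f"node {m!r} assigned twice")
                assignment[m] = f"mu_{k}"
                grouped.add(m)
        if all_nodes is not None:
            for n in all_nodes:
                if n not in assignment:
                    assignment[n] = str(n)
        return cls(assignment=assignment, method=method)

    @classmethod
    def identity(cls, nodes: Sequence[str],
                 method: str = "average") -> "MacroMapping":
        return cls(assignment={n: n for n in nodes}, method=method)

    def groups(self, node_order: Sequence[str]) -> list[list[str]]:
        """Groups of micro-nodes, ordered by first appearance."""
        seen: dict[str, list[str]] = {}
        order: list[str] = []
        for n in node_order:
            macro = self.assignment[n]
            if macro not in seen:
                seen[macro] = []
                order.append(macro)
            seen[macro].append(n)
        return [seen[m] for m in order]

    def macro_labels(self, node_order: Sequence[str]) -> list[str]:
        out, seen = [], set()
        for n in node_order:
            m = self.assignment[n]
            if m not in seen:
                seen.add(m)
                out.append(m)
        return out

    def participation(self, node_order: Sequence[str]) -> float:
        """Fraction of micro-nodes in groups of size >= 2."""
        groups = self.groups(node_order)
        grouped = sum(len(g) for g in groups if len(g) >= 2)
        return grouped / len(node_order)


@dataclass
class MacroNetwork:
    """The induced macro-scale transition structure plus provenance."""

    macro_ts: TransitionStructure
    mapping: MacroMapping
    provenance: dict = field(default_factory=dict)

    @property
    def n_macro(self) -> int:
        return self.macro_ts.n_nodes


def _indicator(ts: TransitionStructure,
               mapping: MacroMapping) -> tuple[sp.csr_matrix, list[str]]:
    macro_labels = mapping.macro_labels(ts.node_labels)
    macro_index = {m: k for k, m in enumerate(macro_labels)}
    cols = np.array([macro_index[mapping.assignment[n]]
                     for n in ts.node_labels])
    n, m = ts.n_nodes, len(macro_labels)
    Ind = sp.csr_matrix((np.ones(n), (np.arange(n), cols)), shape=(n, m))
    return Ind, macro_labels


def apply_mapping(ts: TransitionStructure, m: MacroMapping) -> MacroNetwork:
    """Coarse-grain a transition structure under a macro mapping.

    Member rows are combined per the mapping's method, then destination mass
    is aggregated by summing columns within each group; intra-group mass
    becomes macro self-loop mass.  Macro node count never exceeds the micro
    node count.
    """
    missing = [n for n in ts.node_labels if n not in m.assignment]
    if missing:
        raise ValueError(
            f"mapping does not cover micro-node {missing[0]!r}")
    Ind, macro_labels = _indicator(ts, m)
    n_micro, n_macro = Ind.shape
    if m.method == "average":
        weights = np.ones(n_micro)
    else:
        pi = stationary_distribution(ts)
        weights = pi.copy()
        group_mass = np.asarray(Ind.T @ pi).ravel()
        # transient groups carry only numerical-noise mass; weighting by it
        # would amplify solver noise, so fall back to the unweighted mean
        for k in np.where(group_mass <= 1e-10)[0]:
            members = np.where(np.asarray(Ind[:, k].todense()).ravel())[0]
            logger.warning(
                "group %r has zero stationary mass; falling back to "
                "unweighted mean", macro_labels[k])
            weights[members] = 1.0
    # per-group row weights, normalized within each group
    totals = np.asarray(Ind.T @ weights).ravel()
    B = sp.diags(1.0 / totals) @ Ind.T @ sp.diags(weights)  # (macro x micro)
    Mmat = B @ ts.matrix @ Ind
    macro_ts = TransitionStructure(macro_labels, Mmat)
    return MacroNetwork(
        macro_ts=macro_ts,
        mapping=m,
        provenance={"n_micro": n_micro, "n_macro": n_macro,
                    "method": m.method},
    )


def stationary_distribution(ts: TransitionStructure, tol: float = 1e-12,
                            max_iter: int = 200_000,
                            damping: float = 0.99) -> np.ndarray:
    """Stationary distribution pi with pi.T = pi, by damped power iteration.

    The iteration runs on the lazy chain ``damping*T + (1-damping)*I``,
    which has the same stationary distributions as T but is aperiodic, so
    plain power iteration converges geometrically even for periodic chains
    (e.g. cycles); for reducible chains it converges to the well-defined
    mixture determined by the uniform start.  Raises if the residual
    ``||pi T - pi||_1`` does not fall below ``tol``.
    """
    T = ts.matrix
    n = ts.n_nodes
    pi = np.full(n, 1.0 / n)
    for it in range(1, max_iter + 1):
        pi = damping * (pi @ T) + (1.0 - damping) * pi
        pi = np.asarray(pi).ravel()
        pi = np.maximum(pi, 0.0)
        pi /= pi.sum()
        if it % 8 == 0 or it == max_iter:
            resid = np.abs(np.asarray(pi @ T).ravel() - pi).sum()
            if resid < tol:
                return pi
    resid = np.abs(np.asarray(pi @ T).ravel() - pi).sum()
    raise RuntimeError(
        f"stationary distribution did not converge in {max_iter} "
        f"iterations (residual {resid:.3e})")


def walker_consistency(ts: TransitionStructure, macro: MacroNetwork,
                       horizon: int = 10, eps: float = 1e-12) -> float:
    """Dynamical inaccuracy of a macro network, in bits (0 = consistent).

    Both walks start from the micro stationary distribution (projected onto
    groups for the macro walk).  At each step t = 1..horizon the micro
    walker's distribution is projected onto the groups and compared with the
    macro walker's distribution by Kullback-Leibler divergence; the score is
    the mean divergence.  Exactly lumpable mappings score 0.
    """
    Ind, _ = _indicator(ts, macro.mapping)
    pi = stationary_distribution(ts)
    p_micro = pi.copy()
    q_macro = np.asarray(Ind.T @ pi).ravel()
    T, M = ts.matrix, macro.macro_ts.matrix
    total = 0.0
    smoothed = False
    for _ in range(horizon):
        p_micro = np.asarray(p_micro @ T).ravel()
        q_macro = np.asarray(q_macro @ M).ravel()
        p_proj = np.asarray(Ind.T @ p_micro).ravel()
        if np.any((p_proj > 0) & (q_macro <= 0)):
            smoothed = True
        p = p_proj + eps
        q = q_macro + eps
        p /= p.sum()
        q /= q.sum()
        total += float(np.sum(p * np.log2(p / q)))
    if smoothed:
        logger.warning("zero-support mismatch between micro and macro "
                       "walkers; KL smoothed with eps=%g", eps)
    return total / horizon


def read_mapping_csv(path: str | Path,
                     method: str = "average") -> MacroMapping:
    """Read a two-column CSV ``micro_node,macro_node``."""
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    if cols[:2] != ["micro_node", "macro_node"]:
        raise ValueError(
            f"{path}: expected header 'micro_node,macro_node', got {cols}")
    assignment = dict(zip(df["micro_node"], df["macro_node"]))
    return MacroMapping(assignment=assignment, method=method)


def write_mapping_csv(mapping: MacroMapping, path: str | Path) -> None:
    rows = [{"micro_node": k, "macro_node": v}
            for k, v in mapping.assignment.items()]
    pd.DataFrame(rows).to_csv(path, index=False)
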