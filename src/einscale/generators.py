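"""Synthetic network families and the cardiac GRN fixture.

The generator families realize the analytic cases the EI decomposition is
calibrated against -- fully deterministic and non-degenerate (permutation),
fully noisy (uniform complete graph), fully degenerate (star) -- plus random
nulls and a small constructed network with known causal emergence.  Every
family is reproducible byte-for-byte given (family, n, params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np

from .boolean import BooleanNetwork, BooleanRule, read_bnet
from .network import WeightedDigraph

__all__ = ["GeneratorSpec", "generate", "cardiac_fixture", "two_block_noisy"]

FAMILIES = ("permutation", "complete_uniform", "star_degenerate",
            "erdos_renyi", "two_block_noisy", "boolean_random")


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for a synthetic network; the seed is part of the provenance."""

    family: str
    n: int
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _labels(n: int) -> list[str]:
    return [f"n{i}" for i in range(n)]


def permutation_network(n: int, seed: int = 0) -> WeightedDigraph:
    """Each node deterministically targets a unique node: EI = log2(N)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = _labels(n)
    g = WeightedDigraph(nodes=labels)
    for i in range(n):
        g.add_edge(labels[i], labels[perm[i]], 1.0)
    return g


def complete_uniform(n: int) -> WeightedDigraph:
    """All-to-all connectivity with uniform out-weights: EI = 0."""
    labels = _labels(n)
    g = WeightedDigraph(nodes=labels)
    for i in range(n):
        for j in range(n):
            g.add_edge(labels[i], labels[j], 1.0)
    return g


def star_degenerate(n: int) -> WeightedDigraph:
    """Complete degeneracy: every node targets node 0, so H(<W_out>) = 0."""
    labels = _labels(n)
    g = WeightedDigraph(nodes=labels)
    for i in range(n):
        g.add_edge(labels[i], labels[0], 1.0)
    return g


def erdos_renyi(n: int, p: float = 0.05, seed: int = 0) -> WeightedDigraph:
    """Directed G(n, p) null model; dangling nodes self-loop on
    normalization."""
    if not 0 <= p <= 1:
        raise ValueError(f"edge probability p={p} outside [0, 1]")
    gx = nx.gnp_random_graph(n, p, seed=seed, directed=True)
    labels = _labels(n)
    g = WeightedDigraph(nodes=labels)
    for u, v in gx.edges():
        g.add_edge(labels[u], labels[v], 1.0)
    return g


def two_block_noisy(n: int = 6, block_sizes: tuple[int, int] = (4, 2)
                    ) -> WeightedDigraph:
    """Two unequal blocks, each node spreading uniformly over the other
    block.

    Within a block every node is maximally noisy (uniform over the other
    block's members), but the blocks map onto each other exactly, so
    grouping each block yields a deterministic two-node swap with EI of
    1 bit.  The unequal sizes make the micro-scale degenerate (the larger
    block concentrates in-weight on the smaller), which is why the
    macro-scale carries more information -- with equal blocks the micro EI
    already equals 1 bit and the gain vanishes.
    """
    n1, n2 = block_sizes
    if n1 + n2 != n:
        raise ValueError(f"block sizes {block_sizes} do not sum to n={n}")
    if n1 < 1 or n2 < 1:
        raise ValueError("both blocks need at least one node")
    labels = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    g = WeightedDigraph(nodes=labels)
    for i in range(n1):
        for j in range(n2):
            g.add_edge(labels[i], labels[n1 + j], 1.0)
    for j in range(n2):
        for i in range(n1):
            g.add_edge(labels[n1 + j], labels[i], 1.0)
    return g


def boolean_random(n: int, k: int = 2, seed: int = 0) -> BooleanNetwork:
    """A random Boolean network: each variable gets k regulators and a
    random truth table (an N-K model)."""
    if k > n:
        raise ValueError(f"fan-in k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    names = [f"v{i}" for i in range(n)]
    rules = {}
    for i, name in enumerate(names):
        regs = tuple(names[j] for j in rng.choice(n, size=k, replace=False))
        table = tuple(int(b) for b in rng.integers(0, 2, size=2 ** k))
        rules[name] = BooleanRule(regs, table)
    return BooleanNetwork(tuple(names), rules)


def generate(spec: GeneratorSpec) -> WeightedDigraph | BooleanNetwork:
    """Build the network described by a GeneratorSpec."""
    fam, n, p, seed = spec.family, spec.n, dict(spec.params), spec.seed
    if fam == "permutation":
        return permutation_network(n, seed=seed)
    if fam == "complete_uniform":
        return complete_uniform(n)
    if fam == "star_degenerate":
        return star_degenerate(n)
    if fam == "erdos_renyi":
        return erdos_renyi(n, p=p.get("p", 0.05), seed=seed)
    if fam == "two_block_noisy":
        return two_block_noisy(n, block_sizes=tuple(
            p.get("block_sizes", (n - n // 3, n // 3))))
    if fam == "boolean_random":
        return boolean_random(n, k=p.get("k", 2), seed=seed)
    raise AssertionError(fam)


def cardiac_fixture() -> BooleanNetwork:
    """The five-gene Boolean model of early mammalian cardiac development.

    Variables, in state-label order: exogen_canWnt_II, Foxc1_2, Fgf8,
    CanWnt, Isl1.  The exogenous canonical-Wnt-II signal re-activates
    canonical Wnt signalling, which (with the Foxc1/Foxc2-Fgf8 axis)
    controls the Isl1-positive second-heart-field program; Isl1's onward
    targets lie outside the subnetwork, so it carries a self-loop.  The
    rule set is a reconstruction validated against the model's published
    behaviour: a deterministic 32-state transition graph whose only
    attractors are {00001} (Isl1 ON; basin of 31 states) and {00000}
    (basin of 1).
    """
    ref = resources.files("einscale.data").joinpath("cardiac_grn.bnet")
    return read_bnet(ref)  # type: ignore[arg-type]
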