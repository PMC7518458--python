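"""Boolean gene-regulatory networks and their state-transition graphs.

A Boolean network is a set of ON/OFF variables, each updated by a total
Boolean function of its regulators.  Under synchronous update the network
induces a deterministic map on its 2^n global states; the directed graph of
that map (the state-transition graph, STG) is itself a transition structure,
so the same effective-information machinery applies to the dynamics of the
model, not just its wiring diagram.

Rule files use the BoolNet dialect (`targets, factors` header; operators
``&``, ``|``, ``!``; parentheses; constants ``0``/``1``), the format Cell
Collective exports.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .network import TransitionStructure

__all__ = [
    "BooleanRule",
    "BooleanNetwork",
    "StateTransitionGraph",
    "AttractorSet",
    "read_bnet",
    "parse_bnet",
    "expand_state_space",
    "find_attractors",
]

DEFAULT_VARIABLE_CAP = 20


# --- rule expressions -------------------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|&|\||!|[A-Za-z_][A-Za-z0-9_.]*|[01])")


def _tokenize(expr: str) -> list[str]:
    pos, out = 0, []
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if m is None:
            if expr[pos:].strip() == "":
                break
            raise ValueError(f"cannot parse rule near {expr[pos:]!r}")
        out.append(m.group(1))
        pos = m.end()
    return out


class _Parser:
    """Recursive-descent parser: OR > AND > NOT > atom."""

    def __init__(self, tokens: list[str]):
        self.toks = tokens
        self.i = 0

    def peek(self):
        return self.toks[self.i] if self.i < len(self.toks) else None

    def take(self):
        tok = self.peek()
        self.i += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            raise ValueError(f"unexpected token {self.peek()!r}")
        return node

    def parse_or(self):
        node = self.parse_and()
        while self.peek() == "|":
            self.take()
            node = ("or", node, self.parse_and())
        return node

    def parse_and(self):
        node = self.parse_not()
        while self.peek() == "&":
            self.take()
            node = ("and", node, self.parse_not())
        return node

    def parse_not(self):
        if self.peek() == "!":
            self.take()
            return ("not", self.parse_not())
        return self.parse_atom()

    def parse_atom(self):
        tok = self.take()
        if tok == "(":
            node = self.parse_or()
            if self.take() != ")":
                raise ValueError("unbalanced parentheses")
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if tok is None:
            raise ValueError("unexpected end of rule")
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", tok):
            raise ValueError(f"unexpected token {tok!r}")
        return ("var", tok)


def _ast_vars(node, acc):
    kind = node[0]
    if kind == "var" and node[1] not in acc:
        acc.append(node[1])
    for child in node[1:]:
        if isinstance(child, tuple):
            _ast_vars(child, acc)
    return acc


def _ast_eval(node, env) -> int:
    kind = node[0]
    if kind == "const":
        return node[1]
    if kind == "var":
        return env[node[1]]
    if kind == "not":
        return 1 - _ast_eval(node[1], env)
    if kind == "and":
        return _ast_eval(node[1], env) & _ast_eval(node[2], env)
    if kind == "or":
        return _ast_eval(node[1], env) | _ast_eval(node[2], env)
    raise AssertionError(kind)


@dataclass(frozen=True)
class BooleanRule:
    """A total update rule: a truth table over an ordered regulator tuple."""

    regulators: tuple[str, ...]
    table: tuple[int, ...]  # 2^k entries; index bit b = regulator b
    expression: str = ""

    def __post_init__(self):
        if len(self.table) != 2 ** len(self.regulators):
            raise ValueError(
                f"rule table has {len(self.table)} entries for "
                f"{len(self.regulators)} regulators")
        if any(v not in (0, 1) for v in self.table):
            raise ValueError("rule table entries must be 0 or 1")

    @classmethod
    def from_expression(cls, expr: str) -> "BooleanRule":
        ast = _Parser(_tokenize(expr)).parse()
        regs = tuple(_ast_vars(ast, []))
        table = []
        for combo in itertools.product((0, 1), repeat=len(regs)):
            # index bit b corresponds to regulator b
            env = dict(zip(regs, combo))
            table.append(_ast_eval(ast, env))
        # itertools.product varies the LAST regulator fastest; reorder so the
        # table index encodes regulator b in bit b.
        ordered = [0] * len(table)
        for idx, combo in enumerate(
                itertools.product((0, 1), repeat=len(regs))):
            key = sum(bit << b for b, bit in enumerate(combo))
            ordered[key] = table[idx]
        return cls(regulators=regs, table=tuple(ordered),
                   expression=expr.strip())


@dataclass
class BooleanNetwork:
    """Ordered binary variables with total synchronous update rules.

    A variable declared without a rule receives the self-copy rule (its value
    persists), the conventional treatment of inputs whose regulators are
    outside the modelled subnetwork.
    """

    variables: tuple[str, ...]
    rules: dict[str, BooleanRule] = field(default_factory=dict)

    def __post_init__(self):
        self.variables = tuple(self.variables)
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names must be unique")
        declared = set(self.variables)
        for var in self.variables:
            if var not in self.rules:
                self.rules[var] = BooleanRule((var,), (0, 1), var)
        for var, rule in self.rules.items():
            if var not in declared:
                raise ValueError(f"rule for undeclared variable {var!r}")
            missing = [r for r in rule.regulators if r not in declared]
            if missing:
                raise ValueError(
                    f"rule for {var!r} references undeclared regulator "
                    f"{missing[0]!r}")

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def step(self, state: dict[str, int]) -> dict[str, int]:
        """One synchronous update of a state given as {variable: 0/1}."""
        out = {}
        for var in self.variables:
            rule = self.rules[var]
            idx = sum(state[r] << b for b, r in enumerate(rule.regulators))
            out[var] = rule.table[idx]
        return out

    def to_bnet(self) -> str:
        lines = ["targets, factors"]
        for var in self.variables:
            rule = self.rules[var]
            expr = rule.expression if rule.expression else var
            lines.append(f"{var}, {expr}")
        return "\n".join(lines) + "\n"


def parse_bnet(text: str) -> BooleanNetwork:
    """Parse BoolNet-style rules from a string."""
    variables: list[str] = []
    raw: list[tuple[str, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "," not in stripped:
            raise ValueError(f"line {lineno}: expected 'target, factors'")
        target, expr = stripped.split(",", 1)
        target, expr = target.strip(), expr.strip()
        if target.lower() == "targets" and expr.lower() == "factors":
            continue  # header
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", target):
            raise ValueError(f"line {lineno}: bad variable name {target!r}")
        if target in variables:
            raise ValueError(f"line {lineno}: duplicate rule for {target!r}")
        variables.append(target)
        raw.append((target, expr))
    if not variables:
        raise ValueError("no rules found")
    rules = {}
    for target, expr in raw:
        try:
            rules[target] = BooleanRule.from_expression(expr)
        except ValueError as exc:
            raise ValueError(f"rule for {target!r}: {exc}") from exc
    return BooleanNetwork(tuple(variables), rules)


def read_bnet(path: str | Path) -> BooleanNetwork:
    """Read a BoolNet `.bnet` rule file (`targets, factors` dialect)."""
    path = Path(path)
    try:
        return parse_bnet(path.read_text(encoding="utf-8"))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


@dataclass
class StateTransitionGraph:
    """Deterministic transition structure over all 2^n binary states.

    State labels are binary strings in declared variable order: bit i of the
    label (leftmost first) is the value of variable i, so for the cardiac
    model {00001} means only the last-declared gene (Isl1) is ON.
    """

    variables: tuple[str, ...]
    successors: np.ndarray  # successors[s] = integer of the next state
    deterministic_flag: bool = True

    @property
    def n_states(self) -> int:
        return int(self.successors.size)

    def state_label(self, s: int) -> str:
        return format(s, f"0{len(self.variables)}b")

    @property
    def node_labels(self) -> tuple[str, ...]:
        n = len(self.variables)
        return tuple(format(s, f"0{n}b") for s in range(self.n_states))

    def transition_structure(self) -> TransitionStructure:
        n = self.n_states
        M = sp.csr_matrix(
            (np.ones(n), (np.arange(n), self.successors)), shape=(n, n))
        return TransitionStructure(self.node_labels, M)


def expand_state_space(bn: BooleanNetwork, update: str = "synchronous",
                       max_variables: int = DEFAULT_VARIABLE_CAP
                       ) -> StateTransitionGraph:
    """Expand a Boolean network into its full synchronous state space.

    All 2^n states are enumerated; each state has the single successor
    obtained by applying every rule simultaneously.
    """
    if update != "synchronous":
        raise ValueError(
            f"unsupported update scheme {update!r}; only synchronous "
            "(parallel) update is implemented")
    n = bn.n_variables
    if n > max_variables:
        raise ValueError(
            f"network has {n} variables, above the cap of {max_variables} "
            f"(2^{n} states); pass max_variables={n} to override")
    n_states = 1 << n
    states = np.arange(n_states)
    # value of variable i in every state; leftmost label bit = variable 0
    var_bits = {v: (states >> (n - 1 - i)) & 1
                for i, v in enumerate(bn.variables)}
    succ = np.zeros(n_states, dtype=np.int64)
    for i, var in enumerate(bn.variables):
        rule = bn.rules[var]
        idx = np.zeros(n_states, dtype=np.int64)
        for b, reg in enumerate(rule.regulators):
            idx |= var_bits[reg] << b
        nxt_bit = np.asarray(rule.table, dtype=np.int64)[idx]
        succ |= nxt_bit << (n - 1 - i)
    return StateTransitionGraph(bn.variables, succ)


@dataclass
class AttractorSet:
    """Terminal cycles of a deterministic STG and their basins.

    ``attractors`` lists each cycle as a tuple of state labels in transition
    order, rotated to start at the lexicographically smallest label; fixed
    points are cycles of length one.  ``basin_sizes[k]`` counts every state
    that flows into attractor k (cycle states included), so basin sizes sum
    to the number of states.
    """

    attractors: list[tuple[str, ...]]
    basin_sizes: list[int]
    assignment: np.ndarray  # state index -> attractor index

    def fixed_points(self) -> list[str]:
        return [cyc[0] for cyc in self.attractors if len(cyc) == 1]


def find_attractors(stg: StateTransitionGraph | TransitionStructure
                    ) -> AttractorSet:
    """Locate all terminal cycles and assign every state to its basin."""
    if isinstance(stg, TransitionStructure):
        if not stg.is_deterministic():
            raise ValueError(
                "attractor analysis requires a deterministic transition "
                "structure")
        succ = stg.successors()
        labels = list(stg.node_labels)
    else:
        if not stg.deterministic_flag:
            raise ValueError("attractor analysis requires a deterministic STG")
        succ = stg.successors
        labels = list(stg.node_labels)
    n = succ.size
    state_attr = np.full(n, -1, dtype=np.int64)  # -1 unknown
    attractors: list[tuple[int, ...]] = []
    WORKING = -2
    for start in range(n):
        if state_attr[start] != -1:
            continue
        path = []
        s = start
        while state_attr[s] == -1:
            state_attr[s] = WORKING
            path.append(s)
            s = int(succ[s])
        if state_attr[s] == WORKING:
            # found a new cycle; s is on it
            cyc_start = path.index(s)
            cycle = path[cyc_start:]
            k = min(range(len(cycle)), key=lambda i: cycle[i])
            cycle = tuple(cycle[k:] + cycle[:k])
            attr_id = len(attractors)
            attractors.append(cycle)
        else:
            attr_id = int(state_attr[s])
        for v in path:
            state_attr[v] = attr_id
    basin_sizes = np.bincount(state_attr, minlength=len(attractors))
    return AttractorSet(
        attractors=[tuple(labels[s] for s in cyc) for cyc in attractors],
        basin_sizes=[int(b) for b in basin_sizes],
        assignment=state_attr,
    )
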