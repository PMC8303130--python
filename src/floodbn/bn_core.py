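"""Discrete Bayesian networks: variables, DAG structure, CPTs and the joint
factorization.

A Bayesian network over categorical variables ``X1..Xn`` is the pair
``B = {G, theta}``: a directed acyclic graph ``G`` plus one conditional
probability table (CPT) per variable, defining the joint distribution

    P(X1, ..., Xn) = prod_i P(Xi | parents(Xi)).

All variables are categorical with explicit, ordered state lists. CPT rows
are stored in lexicographic order over the declared parent order and each
parent's declared state order, so serialized networks are bit-stable.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

#: tolerance for a CPT row to count as normalized
ROW_SUM_TOL = 1e-9
#: loaders renormalize rows whose sum is off by at most this much
ROW_RENORM_TOL = 1e-6
#: default cap on the joint state-space size for full enumeration
ENUMERATION_CAP = 2 ** 20


class NetworkValidationError(ValueError):
    """Raised when an operation requires a valid network but validation fails."""


class StateSpaceError(ValueError):
    """Raised when a requested enumeration exceeds the state-space cap."""


@dataclass(frozen=True)
class CategoricalVariable:
    """A named categorical variable with an ordered list of >=2 state labels."""

    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise ValueError(f"variable {self.name!r} needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"variable {self.name!r} has duplicate state labels")

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(
                f"unknown state {state!r} for variable {self.name!r}; "
                f"declared states are {list(self.states)}"
            ) from None


@dataclass(frozen=True)
class DagStructure:
    """Directed acyclic graph over declared variables.

    ``arcs`` is an ordered tuple of (parent, child) name pairs; ordering is
    normalized (sorted) so two structures with the same arc set compare equal.
    """

    variables: tuple[CategoricalVariable, ...]
    arcs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "arcs", tuple(sorted(set(self.arcs))))

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def variable(self, name: str) -> CategoricalVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(f"unknown variable {name!r}")

    def parents(self, name: str) -> tuple[str, ...]:
        """Parents of ``name`` in declared-variable order (deterministic)."""
        ps = {p for p, c in self.arcs if c == name}
        return tuple(v for v in self.variable_names if v in ps)

    def children(self, name: str) -> tuple[str, ...]:
        cs = {c for p, c in self.arcs if p == name}
        return tuple(v for v in self.variable_names if v in cs)

    def roots(self) -> tuple[str, ...]:
        return tuple(v for v in self.variable_names if not self.parents(v))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variable_names)
        g.add_edges_from(self.arcs)
        return g

    def topological_sort(self) -> list[str]:
        """Deterministic topological order (ties broken by declared order)."""
        order_index = {n: i for i, n in enumerate(self.variable_names)}
        return list(
            nx.lexicographical_topological_sort(
                self.to_networkx(), key=lambda n: order_index[n]
            )
        )


def parent_configurations(
    structure: DagStructure, parents: tuple[str, ...]
) -> list[tuple[str, ...]]:
    """All joint parent-state assignments, lexicographic in declared orders."""
    state_lists = [structure.variable(p).states for p in parents]
    return [tuple(c) for c in itertools.product(*state_lists)]


@dataclass(frozen=True)
class ConditionalProbabilityTable:
    """CPT for one child: a probability vector over child states per joint
    parent configuration. Root nodes have a single row keyed by ``()``."""

    child: str
    parents: tuple[str, ...]
    rows: dict[tuple[str, ...], tuple[float, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(
            self,
            "rows",
            {tuple(k): tuple(float(x) for x in v) for k, v in self.rows.items()},
        )

    def row(self, parent_states: tuple[str, ...]) -> tuple[float, ...]:
        try:
            return self.rows[tuple(parent_states)]
        except KeyError:
            raise KeyError(
                f"CPT for {self.child!r} has no row for parent assignment "
                f"{parent_states!r}"
            ) from None


@dataclass(frozen=True)
class BayesianNetwork:
    """The pair ``{G, theta}``: structure plus one CPT per variable."""

    structure: DagStructure
    cpts: dict[str, ConditionalProbabilityTable] = field(default_factory=dict)

    def variable(self, name: str) -> CategoricalVariable:
        return self.structure.variable(name)

    @property
    def variable_names(self) -> tuple[str, ...]:
        return self.structure.variable_names

    def cpt(self, name: str) -> ConditionalProbabilityTable:
        return self.cpts[name]

    def require_valid(self) -> None:
        report = validate_network(self)
        if report:
            raise NetworkValidationError(
                "invalid network: " + "; ".join(report)
            )


@dataclass
class FactorTable:
    """Nonnegative table over a subset of variables — the working object of
    variable elimination. ``values`` has one axis per scope variable, with
    axis lengths equal to the variables' cardinalities."""

    scope: tuple[str, ...]
    cardinalities: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.scope = tuple(self.scope)
        self.cardinalities = tuple(self.cardinalities)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.cardinalities:
            raise ValueError(
                f"factor shape {self.values.shape} does not match "
                f"cardinalities {self.cardinalities}"
            )
        if (self.values < 0).any():
            raise ValueError("factor values must be nonnegative")

    @classmethod
    def from_cpt(
        cls, net: BayesianNetwork, child: str
    ) -> "FactorTable":
        """Factor P(child | parents) with scope (parents..., child)."""
        cpt = net.cpt(child)
        parents = cpt.parents
        scope = parents + (child,)
        cards = tuple(net.variable(v).cardinality for v in scope)
        values = np.empty(cards)
        for config in parent_configurations(net.structure, parents):
            idx = tuple(
                net.variable(p).state_index(s) for p, s in zip(parents, config)
            )
            values[idx] = cpt.row(config)
        return cls(scope, cards, values)

    def multiply(self, other: "FactorTable") -> "FactorTable":
        """Pointwise product on the union scope (own scope order first)."""
        joint_scope = self.scope + tuple(
            v for v in other.scope if v not in self.scope
        )
        card_map = dict(zip(self.scope, self.cardinalities))
        card_map.update(dict(zip(other.scope, other.cardinalities)))
        joint_cards = tuple(card_map[v] for v in joint_scope)

        def broadcast(f: "FactorTable") -> np.ndarray:
            # move axes into joint order, add singleton axes for absent vars
            shape = tuple(
                card_map[v] if v in f.scope else 1 for v in joint_scope
            )
            perm = [f.scope.index(v) for v in joint_scope if v in f.scope]
            return np.transpose(f.values, perm).reshape(shape)

        return FactorTable(
            joint_scope, joint_cards, broadcast(self) * broadcast(other)
        )

    def sum_out(self, variable: str) -> "FactorTable":
        if variable not in self.scope:
            raise KeyError(f"{variable!r} not in factor scope {self.scope}")
        axis = self.scope.index(variable)
        scope = tuple(v for v in self.scope if v != variable)
        cards = tuple(
            c for v, c in zip(self.scope, self.cardinalities) if v != variable
        )
        return FactorTable(scope, cards, self.values.sum(axis=axis))

    def reduce(self, variable: str, state_index: int) -> "FactorTable":
        """Slice the factor at an observed state, dropping the axis."""
        axis = self.scope.index(variable)
        scope = tuple(v for v in self.scope if v != variable)
        cards = tuple(
            c for v, c in zip(self.scope, self.cardinalities) if v != variable
        )
        return FactorTable(scope, cards, np.take(self.values, state_index, axis=axis))

    def total(self) -> float:
        return float(self.values.sum())


def validate_network(net: BayesianNetwork) -> list[str]:
    """Check every structural and numerical invariant of a network.

    Violations are data, not exceptions: the return value is a list of
    human-readable violation strings, empty iff the network is valid.
    """
    report: list[str] = []
    structure = net.structure
    declared = set(structure.variable_names)

    if len(declared) != len(structure.variables):
        report.append("duplicate variable names in structure")

    for p, c in structure.arcs:
        if p == c:
            report.append(f"self-loop on {p!r}")
        for end in (p, c):
            if end not in declared:
                report.append(f"arc endpoint {end!r} is not a declared variable")

    g = structure.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
        report.append(f"directed cycle: {path}")

    for name in structure.variable_names:
        cpt = net.cpts.get(name)
        if cpt is None:
            report.append(f"missing CPT for {name!r}")
            continue
        expected_parents = structure.parents(name)
        if tuple(cpt.parents) != expected_parents:
            report.append(
                f"CPT for {name!r} declares parents {list(cpt.parents)} but "
                f"structure has {list(expected_parents)}"
            )
            continue
        var = structure.variable(name)
        expected_rows = parent_configurations(structure, expected_parents)
        if set(cpt.rows) != set(expected_rows):
            report.append(
                f"CPT for {name!r} has {len(cpt.rows)} rows, expected "
                f"{len(expected_rows)} (one per joint parent configuration)"
            )
            continue
        for config, row in cpt.rows.items():
            if len(row) != var.cardinality:
                report.append(
                    f"CPT row {config} for {name!r} has arity {len(row)}, "
                    f"expected {var.cardinality}"
                )
                continue
            if any(p < 0 or p > 1 for p in row):
                report.append(
                    f"CPT row {config} for {name!r} has entries outside [0, 1]"
                )
            if abs(sum(row) - 1.0) > ROW_SUM_TOL:
                report.append(
                    f"CPT row {config} for {name!r} sums to {sum(row):.10g}, "
                    f"not 1"
                )

    extra = set(net.cpts) - declared
    for name in sorted(extra):
        report.append(f"CPT for undeclared variable {name!r}")

    return report


def _check_assignment(net: BayesianNetwork, assignment: dict[str, str]) -> None:
    for name in net.variable_names:
        if name not in assignment:
            raise KeyError(f"assignment is missing variable {name!r}")
    for name, state in assignment.items():
        var = net.variable(name)  # raises KeyError for unknown variable
        var.state_index(state)  # raises KeyError for unknown state


def joint_probability(net: BayesianNetwork, assignment: dict[str, str]) -> float:
    """P(X1=x1, ..., Xn=xn) as the product of the selected CPT entries."""
    _check_assignment(net, assignment)
    prob = 1.0
    for name in net.variable_names:
        cpt = net.cpt(name)
        config = tuple(assignment[p] for p in cpt.parents)
        row = cpt.row(config)
        prob *= row[net.variable(name).state_index(assignment[name])]
    return prob


def enumerate_joint(
    net: BayesianNetwork, cap: int = ENUMERATION_CAP
) -> FactorTable:
    """Brute-force joint table over all variables (the inference oracle).

    Refuses state spaces larger than ``cap`` cells.
    """
    names = net.variable_names
    cards = tuple(net.variable(v).cardinality for v in names)
    size = math.prod(cards)
    if size > cap:
        raise StateSpaceError(
            f"joint state space has {size} cells, exceeding the cap of {cap}"
        )
    values = np.empty(cards)
    state_lists = [net.variable(v).states for v in names]
    for idx in itertools.product(*(range(c) for c in cards)):
        assignment = {
            v: state_lists[i][idx[i]] for i, v in enumerate(names)
        }
        values[idx] = joint_probability(net, assignment)
    return FactorTable(names, cards, values)
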