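"""CPT parameter learning, BIC structure scoring, greedy structure search,
and the size of DAG space.

Learning is complete-data only: every record assigns a declared state to
every variable. CPT estimation is maximum likelihood with an optional
Dirichlet pseudocount (``pseudocount=1`` is Laplace smoothing, the default
for command-line learning; ``pseudocount=0`` gives exact relative
frequencies for count-level tests).

Structure search is score-based hill climbing over add/delete/reverse arc
moves under the BIC score

    BIC(G) = log L_hat - (k / 2) * ln N,

where ``k`` is the number of free CPT parameters and ``N`` the record
count. BIC decomposes over node families, so each move only rescores the
families it touches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .bn_core import (
    BayesianNetwork,
    CategoricalVariable,
    ConditionalProbabilityTable,
    DagStructure,
    parent_configurations,
    validate_network,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RecordTable",
    "StructureScore",
    "fit_cpts",
    "bic_score",
    "family_score",
    "hill_climb_structure",
    "count_dags",
]


@dataclass(frozen=True)
class RecordTable:
    """Complete categorical observations, one row per individual.

    Wraps a pandas DataFrame of string state labels; every cell must be a
    declared state of its column's variable (checked at fit time, when the
    variable declarations are available).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame.isna().any().any():
            raise ValueError("records contain missing cells; learning requires complete data")

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @classmethod
    def from_csv(cls, path) -> "RecordTable":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class StructureScore:
    """BIC decomposition: ``total = log_likelihood + penalty`` (penalty <= 0)."""

    log_likelihood: float
    penalty: float

    @property
    def total(self) -> float:
        return self.log_likelihood + self.penalty


def _check_states(
    structure: DagStructure, data: RecordTable
) -> None:
    for var in structure.variables:
        if var.name not in data.columns:
            raise ValueError(f"data has no column for variable {var.name!r}")
        col = data.frame[var.name]
        bad = ~col.isin(var.states)
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"row {row}, column {var.name!r}: state {col.iloc[row]!r} "
                f"is not declared (declared: {list(var.states)})"
            )


def _family_counts(
    structure: DagStructure, data: RecordTable, child: str
) -> dict[tuple[str, ...], np.ndarray]:
    """Counts of child states per joint parent configuration."""
    var = structure.variable(child)
    parents = structure.parents(child)
    configs = parent_configurations(structure, parents)
    counts = {config: np.zeros(var.cardinality) for config in configs}
    if parents:
        grouped = data.frame.groupby(
            [*parents, child], observed=True
        ).size()
        for key, n in grouped.items():
            key = (key,) if not isinstance(key, tuple) else key
            config, state = tuple(key[:-1]), key[-1]
            counts[config][var.state_index(state)] = n
    else:
        vc = data.frame[child].value_counts()
        for state, n in vc.items():
            counts[()][var.state_index(state)] = n
    return counts


def fit_cpts(
    structure: DagStructure,
    data: RecordTable,
    pseudocount: float = 1.0,
) -> BayesianNetwork:
    """Estimate every CPT from complete records.

    Each entry is ``(count + pseudocount) / (row_total + pseudocount * r)``
    with ``r`` the child cardinality. A parent configuration never observed
    with ``pseudocount=0`` falls back to a uniform row (logged).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    _check_states(structure, data)
    cpts = {}
    for var in structure.variables:
        parents = structure.parents(var.name)
        counts = _family_counts(structure, data, var.name)
        rows = {}
        for config, c in counts.items():
            denom = c.sum() + pseudocount * var.cardinality
            if denom == 0:
                logger.warning(
                    "no observations for %r given parents %r=%r and zero "
                    "pseudocount; using a uniform row",
                    var.name,
                    parents,
                    config,
                )
                row = np.full(var.cardinality, 1.0 / var.cardinality)
            else:
                row = (c + pseudocount) / denom
            rows[config] = tuple(row)
        cpts[var.name] = ConditionalProbabilityTable(var.name, parents, rows)
    return BayesianNetwork(structure, cpts)


def family_score(
    structure: DagStructure, data: RecordTable, child: str
) -> StructureScore:
    """BIC contribution of one node family (child plus its parents)."""
    var = structure.variable(child)
    counts = _family_counts(structure, data, child)
    ll = 0.0
    for c in counts.values():
        total = c.sum()
        if total == 0:
            continue
        nz = c[c > 0]
        ll += float((nz * np.log(nz / total)).sum())
    n_configs = len(counts)
    k = n_configs * (var.cardinality - 1)
    penalty = -(k / 2.0) * math.log(data.n_records)
    return StructureScore(ll, penalty)


def bic_score(net_or_structure, data: RecordTable) -> StructureScore:
    """BIC of a structure given records (CPTs, if present, are ignored:
    the score uses the maximized likelihood)."""
    structure = (
        net_or_structure.structure
        if isinstance(net_or_structure, BayesianNetwork)
        else net_or_structure
    )
    if data.n_records == 0:
        raise ValueError("cannot score a structure against empty data")
    _check_states(structure, data)
    ll = 0.0
    penalty = 0.0
    for var in structure.variables:
        fs = family_score(structure, data, var.name)
        ll += fs.log_likelihood
        penalty += fs.penalty
    return StructureScore(ll, penalty)


def _would_create_cycle(
    arcs: set[tuple[str, str]], parent: str, child: str
) -> bool:
    """True if adding parent->child creates a directed cycle."""
    # DFS from child along existing arcs looking for parent
    stack, seen = [child], set()
    children: dict[str, list[str]] = {}
    for p, c in arcs:
        children.setdefault(p, []).append(c)
    while stack:
        node = stack.pop()
        if node == parent:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(children.get(node, []))
    return False


def hill_climb_structure(
    data: RecordTable,
    variables: list[CategoricalVariable] | None = None,
    max_parents: int = 3,
    seed: int = 0,
) -> tuple[DagStructure, StructureScore]:
    """Greedy BIC hill climbing over add/delete/reverse arc moves.

    Starts from the empty graph and applies the single best-improving move
    until none improves the score. Ties between equally scoring moves break
    lexicographically on the move description, so the search is fully
    deterministic; ``seed`` is accepted for interface symmetry but unused.

    Returns the final structure and its BIC score (always >= the
    empty-graph score). With ``variables=None``, binary-or-wider variables
    are inferred from the observed state labels of each column (sorted).
    """
    if max_parents < 0:
        raise ValueError("max_parents must be nonnegative")
    if len(data.columns) < 2:
        raise ValueError("structure search needs at least 2 columns")
    del seed  # deterministic search; kept for a stable call signature
    if variables is None:
        variables = [
            CategoricalVariable(c, tuple(sorted(data.frame[c].unique())))
            for c in data.columns
        ]
    names = [v.name for v in variables]

    arcs: set[tuple[str, str]] = set()

    def structure_for(arc_set: set[tuple[str, str]]) -> DagStructure:
        return DagStructure(tuple(variables), tuple(sorted(arc_set)))

    def parents_of(arc_set: set[tuple[str, str]], node: str) -> int:
        return sum(1 for p, c in arc_set if c == node)

    current = structure_for(arcs)
    family_cache: dict[tuple[str, tuple[str, ...]], StructureScore] = {}

    def cached_family(structure: DagStructure, child: str) -> StructureScore:
        key = (child, structure.parents(child))
        if key not in family_cache:
            family_cache[key] = family_score(structure, data, child)
        return family_cache[key]

    def total_score(structure: DagStructure) -> float:
        return sum(
            cached_family(structure, v).total for v in names
        )

    current_score = total_score(current)

    while True:
        best_move: tuple[str, str, str] | None = None  # (kind, parent, child)
        best_gain = 0.0
        candidates: list[tuple[str, str, str]] = []
        for p in names:
            for c in names:
                if p == c:
                    continue
                if (p, c) in arcs:
                    candidates.append(("delete", p, c))
                    candidates.append(("reverse", p, c))
                else:
                    candidates.append(("add", p, c))
        # lexicographic on the move description fixes the tie-break
        for kind, p, c in sorted(candidates):
            new_arcs = set(arcs)
            if kind == "add":
                if parents_of(arcs, c) >= max_parents:
                    continue
                if _would_create_cycle(arcs, p, c):
                    continue
                new_arcs.add((p, c))
            elif kind == "delete":
                new_arcs.discard((p, c))
            else:  # reverse
                if parents_of(arcs, p) >= max_parents:
                    continue
                new_arcs.discard((p, c))
                if _would_create_cycle(new_arcs, c, p):
                    continue
                new_arcs.add((c, p))
            new_structure = structure_for(new_arcs)
            # families whose parent sets changed
            touched = {c} if kind != "reverse" else {p, c}
            gain = sum(
                cached_family(new_structure, t).total
                - cached_family(current, t).total
                for t in touched
            )
            if gain > best_gain + 1e-12:
                best_gain = gain
                best_move = (kind, p, c)
        if best_move is None:
            break
        kind, p, c = best_move
        if kind == "add":
            arcs.add((p, c))
        elif kind == "delete":
            arcs.discard((p, c))
        else:
            arcs.discard((p, c))
            arcs.add((c, p))
        current = structure_for(arcs)
        current_score += best_gain
        assert not validate_network(
            fit_cpts(current, data, pseudocount=1.0)
        ), "hill-climb intermediate structure failed validation"

    final_score = bic_score(current, data)
    return current, final_score


@lru_cache(maxsize=None)
def count_dags(p: int) -> int:
    """Number of labeled DAGs on ``p`` nodes (exact integer arithmetic).

    Uses Robinson's alternating-sum recurrence

        a(p) = sum_{k=1..p} (-1)^(k+1) C(p, k) 2^(k (p-k)) a(p-k),

    with ``a(0) = 1``: the sum classifies DAGs by a chosen nonempty set of
    k "source-side" nodes, with inclusion-exclusion correcting overcounts.
    Grows super-exponentially (1, 3, 25, 543, 29281, ...), which is why
    exhaustive structure search is hopeless beyond a handful of nodes and
    greedy search is used instead.
    """
    if p <= 0:
        raise ValueError("p must be a positive integer")
    if p > 20:
        raise ValueError("p > 20 not supported (exact arithmetic cap)")
    total = 0
    for k in range(1, p + 1):
        term = math.comb(p, k) * 2 ** (k * (p - k)) * (
            1 if p - k == 0 else count_dags(p - k)
        )
        total += term if k % 2 == 1 else -term
    return total
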