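"""Shared fixtures: tiny hand-built networks and seeded random networks."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from floodbn import (
    BayesianNetwork,
    CategoricalVariable,
    ConditionalProbabilityTable,
    DagStructure,
    build_flood_network,
)


def binary(name: str) -> CategoricalVariable:
    return CategoricalVariable(name, ("present", "absent"))


def root_cpt(name: str, p_present: float) -> ConditionalProbabilityTable:
    return ConditionalProbabilityTable(
        name, (), {(): (p_present, 1.0 - p_present)}
    )


def single_node_net(name: str = "Flood", p: float = 0.201) -> BayesianNetwork:
    structure = DagStructure((binary(name),), ())
    return BayesianNetwork(structure, {name: root_cpt(name, p)})


def two_node_net(
    p_a: float = 0.3, p_b_given_a: float = 0.9, p_b_given_not_a: float = 0.2
) -> BayesianNetwork:
    """A -> B with binary states (present/absent)."""
    structure = DagStructure((binary("A"), binary("B")), (("A", "B"),))
    cpts = {
        "A": root_cpt("A", p_a),
        "B": ConditionalProbabilityTable(
            "B",
            ("A",),
            {
                ("present",): (p_b_given_a, 1.0 - p_b_given_a),
                ("absent",): (p_b_given_not_a, 1.0 - p_b_given_not_a),
            },
        ),
    }
    return BayesianNetwork(structure, cpts)


def chain3_net(rng: np.random.Generator | None = None) -> BayesianNetwork:
    """X -> Y -> Z with arbitrary (seeded) CPT entries."""
    rng = rng or np.random.default_rng(2024)
    ps = rng.uniform(0.05, 0.95, size=5)
    structure = DagStructure(
        (binary("X"), binary("Y"), binary("Z")), (("X", "Y"), ("Y", "Z"))
    )
    cpts = {
        "X": root_cpt("X", ps[0]),
        "Y": ConditionalProbabilityTable(
            "Y",
            ("X",),
            {
                ("present",): (ps[1], 1 - ps[1]),
                ("absent",): (ps[2], 1 - ps[2]),
            },
        ),
        "Z": ConditionalProbabilityTable(
            "Z",
            ("Y",),
            {
                ("present",): (ps[3], 1 - ps[3]),
                ("absent",): (ps[4], 1 - ps[4]),
            },
        ),
    }
    return BayesianNetwork(structure, cpts)


def random_binary_network(seed: int, n_nodes: int) -> BayesianNetwork:
    """Random DAG (arcs only old -> new, so acyclic) with random CPTs."""
    rng = np.random.default_rng(seed)
    names = [f"V{i}" for i in range(n_nodes)]
    variables = tuple(binary(n) for n in names)
    arcs = []
    for j in range(1, n_nodes):
        for i in range(j):
            if rng.random() < 0.4:
                arcs.append((names[i], names[j]))
    structure = DagStructure(variables, tuple(arcs))
    cpts = {}
    for name in names:
        parents = structure.parents(name)
        rows = {}
        for config in itertools.product(
            *[("present", "absent")] * len(parents)
        ):
            p = float(rng.uniform(0.02, 0.98))
            rows[config] = (p, 1.0 - p)
        cpts[name] = ConditionalProbabilityTable(name, parents, rows)
    return BayesianNetwork(structure, cpts)


@pytest.fixture(scope="session")
def flood_net() -> BayesianNetwork:
    return build_flood_network()
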