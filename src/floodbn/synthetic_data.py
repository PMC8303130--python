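"""Forward (ancestral) sampling of individual-level survey records.

The study population this emulates is a flooding-and-health survey: one row
per individual, with binary columns for flood exposure, loss of sentimental
items, probable depression and the two depression-severity states. No such
individual-level dataset is distributed, so learning and inference are
exercised against records sampled from the model itself — which also makes
the generating truth available for parameter-recovery checks.

Sampling visits variables in topological order and draws each from its CPT
row given the already-sampled parents, vectorized over records per node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bn_core import BayesianNetwork
from .flood_model import FloodNetworkConfig, build_flood_network
from .learning import RecordTable

__all__ = ["SimulationSpec", "forward_sample", "make_survey_fixture"]


@dataclass(frozen=True)
class SimulationSpec:
    """What to simulate: a network, a record count, a seed, and optionally a
    subset of columns to keep (e.g. to drop latent nodes)."""

    network: BayesianNetwork
    n: int
    seed: int
    columns: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("record count must be nonnegative")
        if self.columns is not None:
            unknown = set(self.columns) - set(self.network.variable_names)
            if unknown:
                raise ValueError(
                    f"column subset names undeclared variables: {sorted(unknown)}"
                )


def forward_sample(spec: SimulationSpec) -> RecordTable:
    """Draw ``spec.n`` records by ancestral sampling.

    Deterministic given the seed. Columns are emitted in the network's
    declared variable order (restricted to ``spec.columns`` if given) so
    CSV output is byte-stable.
    """
    net = spec.network
    net.require_valid()
    rng = np.random.default_rng(spec.seed)
    order = net.structure.topological_sort()

    columns: dict[str, np.ndarray] = {}
    for name in order:
        var = net.variable(name)
        cpt = net.cpt(name)
        states = np.asarray(var.states, dtype=object)
        if not cpt.parents:
            probs = np.asarray(cpt.row(()))
            idx = rng.choice(var.cardinality, size=spec.n, p=probs)
        else:
            # group records by joint parent state and draw each group at once
            idx = np.empty(spec.n, dtype=np.int64)
            parent_cols = [columns[p] for p in cpt.parents]
            keys = (
                pd.MultiIndex.from_arrays(parent_cols).to_numpy()
                if len(parent_cols) > 1
                else parent_cols[0]
            )
            # iterate rows in the CPT's deterministic order so the draw
            # sequence (hence the output) is seed-stable
            for config, row in sorted(cpt.rows.items()):
                if len(cpt.parents) == 1:
                    mask = keys == config[0]
                else:
                    mask = np.fromiter(
                        (tuple(k) == config for k in keys),
                        dtype=bool,
                        count=spec.n,
                    )
                count = int(mask.sum())
                if count:
                    idx[mask] = rng.choice(
                        var.cardinality, size=count, p=np.asarray(row)
                    )
        columns[name] = states[idx] if spec.n else np.empty(0, dtype=object)

    keep = spec.columns if spec.columns is not None else net.variable_names
    frame = pd.DataFrame(
        {name: pd.Series(columns[name], dtype=str) for name in keep}
    )
    return RecordTable(frame)


#: the flood survey's observable columns (the value nodes CU/CQALY are
#: deterministic arithmetic, not survey responses)
SURVEY_COLUMNS = ("Flood", "LOSI", "PPD", "Lsever", "Msever")


def make_survey_fixture(
    n: int, seed: int, cfg: FloodNetworkConfig | None = None
) -> tuple[RecordTable, BayesianNetwork]:
    """Survey-style records from the flood network plus the generating
    network itself, for parameter-recovery tests."""
    if n < 1:
        raise ValueError("a survey fixture needs at least one record")
    net = build_flood_network(cfg)
    records = forward_sample(
        SimulationSpec(net, n, seed, columns=SURVEY_COLUMNS)
    )
    return records, net
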