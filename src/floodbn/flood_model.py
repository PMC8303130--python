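"""The flood / mental-health network and its QALY cost-effectiveness layer.

The probabilistic core is a five-node binary network over

    Flood -> LOSI -> PPD -> {Lsever, Msever}

where Flood is exposure to flooding, LOSI the loss of sentimental items (a
secondary stressor), PPD probable depression, and Lsever/Msever less- and
more-severe depression. Each node takes states ``present``/``absent``. The
elicited inputs are *marginal* prevalences:

    Flood 20.1%, LOSI 62%, PPD 18.6%, Lsever 48.3%, Msever 21.1%.

Marginals do not pin down conditionals, so :func:`build_flood_network`
solves each child's conditional rows against its parents' already-calibrated
joint distribution under a configurable exposed-vs-unexposed risk ratio
(default 2.0). When the requested ratio is infeasible for a child (the
exposed probability would exceed 1), it is clamped to the largest feasible
ratio and a warning is logged; the elicited marginal is always honored
exactly. Severity is modeled as two separate binary nodes because the two
states may overlap in an individual.

Downstream of the network sit two deterministic value nodes (they carry
arithmetic, not CPTs): CU, the change in utility of a depression state
relative to remission, and CQALY, the change in quality-adjusted life years
over the monitoring horizon. Utility weights come from elicited Beta
distributions (remission 0.85 = Be(923,163), Lsever 0.60 = Be(182,122),
Msever 0.42 = Be(54,75)). QALY changes are monetized at a cost-effectiveness
threshold (NICE range £20,000–£30,000 per QALY).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

from .bn_core import (
    BayesianNetwork,
    CategoricalVariable,
    ConditionalProbabilityTable,
    DagStructure,
    parent_configurations,
)
from .inference import Query, query

logger = logging.getLogger(__name__)

__all__ = [
    "PRESENT",
    "ABSENT",
    "FLOOD_MARGINALS",
    "FLOOD_ARCS",
    "FloodNetworkConfig",
    "UtilityTable",
    "InterventionScenario",
    "CostEffectivenessResult",
    "build_flood_network",
    "change_in_utility",
    "beta_mean",
    "compute_cqaly",
    "evaluate_intervention",
    "default_utilities",
    "default_scenario",
]

PRESENT = "present"
ABSENT = "absent"

#: elicited marginal prevalence of each node (probability of ``present``)
FLOOD_MARGINALS: dict[str, float] = {
    "Flood": 0.201,
    "LOSI": 0.62,
    "PPD": 0.186,
    "Lsever": 0.483,
    "Msever": 0.211,
}

#: default arc set: flooding causes loss of sentimental items, which raises
#: probable depression, which splits into the two severity states
FLOOD_ARCS: tuple[tuple[str, str], ...] = (
    ("Flood", "LOSI"),
    ("LOSI", "PPD"),
    ("PPD", "Lsever"),
    ("PPD", "Msever"),
)

#: NICE cost-effectiveness threshold range, £ per QALY
NICE_LOWER = 20_000.0
NICE_UPPER = 30_000.0


@dataclass(frozen=True)
class FloodNetworkConfig:
    """Marginal prevalences plus an arc set for the flood network.

    ``risk_ratio`` is the ratio of a child's ``present`` probability per
    additional ``present`` parent, the single degree of freedom left once
    the marginal is fixed.
    """

    marginals: dict[str, float] = field(
        default_factory=lambda: dict(FLOOD_MARGINALS)
    )
    arcs: tuple[tuple[str, str], ...] = FLOOD_ARCS
    risk_ratio: float = 2.0

    def __post_init__(self) -> None:
        for node, p in self.marginals.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"marginal for {node!r} must be in [0, 1], got {p}"
                )
        missing = set(FLOOD_MARGINALS) - set(self.marginals)
        if missing:
            raise ValueError(f"missing marginals for {sorted(missing)}")
        if self.risk_ratio <= 0:
            raise ValueError("risk_ratio must be positive")


def _node_order(marginals: dict[str, float]) -> list[str]:
    """Declared variable order: the canonical five nodes first, extras after."""
    canonical = [n for n in FLOOD_MARGINALS if n in marginals]
    extras = sorted(set(marginals) - set(canonical))
    return canonical + extras


def _calibrate_child(
    net_so_far: BayesianNetwork,
    structure: DagStructure,
    child: str,
    target: float,
    risk_ratio: float,
) -> dict[tuple[str, ...], tuple[float, float]]:
    """Solve conditional rows so the child's marginal equals ``target``.

    Row weights are ``risk_ratio ** (#present parents)``; a scalar ``s``
    is solved so that ``sum_config P(config) * min(1, s * weight) = target``,
    clamping rows that would exceed probability 1 (equivalently, clamping
    the risk ratio to its feasible maximum) with a logged warning.
    """
    parents = structure.parents(child)
    configs = parent_configurations(structure, parents)
    if not parents:
        return {(): (target, 1.0 - target)}

    post = query(net_so_far, Query(parents, {}))
    weights = {}
    probs = {}
    for config in configs:
        k = sum(1 for s in config if s == PRESENT)
        weights[config] = risk_ratio ** k
        probs[config] = post.probability(dict(zip(parents, config)))

    # water-filling: clamp saturated rows at 1 and re-solve on the rest
    clamped: set[tuple[str, ...]] = set()
    for _ in range(len(configs) + 1):
        free_mass = sum(
            probs[c] * weights[c] for c in configs if c not in clamped
        )
        clamped_mass = sum(probs[c] for c in clamped)
        remaining = target - clamped_mass
        if free_mass <= 0:
            s = 0.0
        else:
            s = remaining / free_mass
        newly = {
            c for c in configs
            if c not in clamped and s * weights[c] > 1.0 + 1e-12
        }
        if not newly:
            break
        clamped |= newly
    else:  # pragma: no cover - loop always terminates by construction
        raise RuntimeError("calibration failed to converge")

    if clamped:
        logger.warning(
            "risk ratio %.3g infeasible for %r (marginal %.3g); clamping %d "
            "conditional row(s) at probability 1",
            risk_ratio,
            child,
            target,
            len(clamped),
        )
    if remaining < -1e-12:
        raise ValueError(
            f"cannot calibrate {child!r}: parents already exceed the target "
            f"marginal {target}"
        )

    rows = {}
    for config in configs:
        p = 1.0 if config in clamped else min(1.0, s * weights[config])
        rows[config] = (p, 1.0 - p)
    return rows


def build_flood_network(
    cfg: FloodNetworkConfig | None = None,
) -> BayesianNetwork:
    """Build the flood network, honoring every elicited marginal exactly.

    Children are calibrated in topological order, each against the joint
    distribution of its (already calibrated) parents, so all marginals hold
    simultaneously to machine precision.
    """
    if cfg is None:
        cfg = FloodNetworkConfig()
    names = _node_order(cfg.marginals)
    variables = tuple(
        CategoricalVariable(n, (PRESENT, ABSENT)) for n in names
    )
    structure = DagStructure(variables, cfg.arcs)

    cpts: dict[str, ConditionalProbabilityTable] = {}
    for node in structure.topological_sort():
        partial = BayesianNetwork(
            DagStructure(
                tuple(v for v in variables if v.name in cpts),
                tuple(a for a in cfg.arcs if a[1] in cpts),
            ),
            dict(cpts),
        )
        rows = _calibrate_child(
            partial, structure, node, cfg.marginals[node], cfg.risk_ratio
        )
        cpts[node] = ConditionalProbabilityTable(
            node, structure.parents(node), rows
        )

    net = BayesianNetwork(structure, cpts)
    net.require_valid()
    return net


# ---------------------------------------------------------------------------
# utilities and QALYs


def beta_mean(alpha: float, beta: float) -> float:
    """Mean of Beta(alpha, beta): alpha / (alpha + beta)."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("Beta parameters must be positive")
    return alpha / (alpha + beta)


@dataclass(frozen=True)
class UtilityTable:
    """Elicited utility weights per mental-health state.

    ``states`` maps a state name to ``(mean utility, beta_alpha, beta_beta)``.
    Remission is the reference state: the change in utility (CU) of any
    other state is remission's mean minus that state's mean. ``horizon`` is
    the monitoring duration in years (QALY change = CU x horizon).
    """

    states: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "Remission": (0.85, 923.0, 163.0),
            "Lsever": (0.60, 182.0, 122.0),
            "Msever": (0.42, 54.0, 75.0),
        }
    )
    reference: str = "Remission"
    horizon: float = 1.0

    def __post_init__(self) -> None:
        if self.reference not in self.states:
            raise ValueError(f"reference state {self.reference!r} not declared")
        for name, (mean, a, b) in self.states.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"Beta parameters for {name!r} must be positive")
            if abs(beta_mean(a, b) - mean) > 0.005:
                raise ValueError(
                    f"utility mean {mean} for {name!r} disagrees with "
                    f"Be({a:g},{b:g}) mean {beta_mean(a, b):.4f} by more than 0.005"
                )
        ref_mean = self.states[self.reference][0]
        for name, (mean, _, _) in self.states.items():
            if ref_mean - mean < -1e-12:
                raise ValueError(
                    f"state {name!r} has higher utility than the reference; "
                    "change in utility would be negative"
                )

    def mean(self, state: str) -> float:
        self._check_state(state)
        return self.states[state][0]

    def beta_params(self, state: str) -> tuple[float, float]:
        self._check_state(state)
        _, a, b = self.states[state]
        return a, b

    def health_states(self) -> tuple[str, ...]:
        """Non-reference states, in declaration order."""
        return tuple(s for s in self.states if s != self.reference)

    def _check_state(self, state: str) -> None:
        if state not in self.states:
            raise KeyError(
                f"unknown health state {state!r}; declared: {list(self.states)}"
            )


def change_in_utility(utilities: UtilityTable, state: str) -> float:
    """CU of a health state: reference (remission) mean minus state mean.

    Full precision; round to 2 dp only for reporting.
    """
    utilities._check_state(state)
    return utilities.mean(utilities.reference) - utilities.mean(state)


def compute_cqaly(
    net: BayesianNetwork,
    utilities: UtilityTable,
    state: str,
    *,
    override: float | None = None,
    cu: float | None = None,
) -> float:
    """Change in QALY attributed to a severity state along the LOSI pathway.

    Default formula:

        CQALY_state = P(state=present, LOSI=present | Flood=present)
                      x CU_state x horizon

    i.e. the probability, among flooded individuals, of both losing
    sentimental items and being in the severity state, times the utility
    loss of that state over the horizon. This is one documented reading of
    the pathway; externally supplied CQALY values can be passed via
    ``override`` (then only CU rescaling via ``cu`` applies). ``cu``, if
    given, replaces the table's CU (used by sensitivity analysis).
    """
    if state == utilities.reference:
        raise ValueError(
            f"the reference state {state!r} has no change in QALY by definition"
        )
    cu_value = change_in_utility(utilities, state) if cu is None else cu
    if override is not None:
        return override
    post = query(net, Query((state, "LOSI"), {"Flood": PRESENT}))
    pathway = post.probability({state: PRESENT, "LOSI": PRESENT})
    return pathway * cu_value * utilities.horizon


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (banker's rounding would distort pennies)."""
    import decimal

    d = decimal.Decimal(repr(x)).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


@dataclass(frozen=True)
class InterventionScenario:
    """Before/after model states for one intervention.

    ``before`` and ``after`` are either both per-state CQALY mappings
    (e.g. ``{"Msever": 0.055, "Lsever": 0.062}``) or both
    :class:`FloodNetworkConfig` objects; mixing forms is an error.
    """

    label: str
    before: dict[str, float] | FloodNetworkConfig
    after: dict[str, float] | FloodNetworkConfig
    threshold: float = NICE_LOWER

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive (£ per QALY)")
        before_is_cfg = isinstance(self.before, FloodNetworkConfig)
        after_is_cfg = isinstance(self.after, FloodNetworkConfig)
        if before_is_cfg != after_is_cfg:
            raise ValueError(
                "before and after must be supplied in the same form "
                "(both CQALY mappings or both network configs)"
            )
        if not before_is_cfg and set(self.before) != set(self.after):
            raise ValueError(
                "before and after CQALY mappings must cover the same states"
            )

    @property
    def is_cqaly_form(self) -> bool:
        return not isinstance(self.before, FloodNetworkConfig)


@dataclass(frozen=True)
class CostEffectivenessResult:
    """Per-state incremental QALYs and their monetized value.

    ``rows`` maps state -> (cqaly_before, cqaly_after, delta_qaly,
    monetary_value). ``delta_qaly = before - after``; ``monetary_value =
    delta_qaly x threshold`` (full precision; round for reporting).
    """

    label: str
    threshold: float
    rows: dict[str, tuple[float, float, float, float]]

    def delta_qaly(self, state: str) -> float:
        return self.rows[state][2]

    def monetary_value(self, state: str) -> float:
        return self.rows[state][3]

    def monetary_value_rounded(self, state: str) -> float:
        """Monetary value to the nearest pound, half away from zero."""
        return round_half_away(self.rows[state][3])


def _scenario_cqalys(
    side: dict[str, float] | FloodNetworkConfig,
    utilities: UtilityTable,
    cu_override: dict[str, float] | None,
) -> dict[str, float]:
    if isinstance(side, FloodNetworkConfig):
        net = build_flood_network(side)
        return {
            s: compute_cqaly(
                net,
                utilities,
                s,
                cu=None if cu_override is None else cu_override[s],
            )
            for s in utilities.health_states()
        }
    if cu_override is None:
        return dict(side)
    # CQALY-form scenarios scale proportionally with CU (CQALY = path x CU)
    return {
        s: v * cu_override[s] / change_in_utility(utilities, s)
        for s, v in side.items()
    }


def evaluate_intervention(
    scn: InterventionScenario,
    utilities: UtilityTable | None = None,
    *,
    cu_override: dict[str, float] | None = None,
) -> CostEffectivenessResult:
    """Incremental QALYs and monetized value of an intervention.

    For each severity state, ``delta_qaly = CQALY_before - CQALY_after``
    and ``monetary_value = delta_qaly x threshold``. ``cu_override`` maps
    state -> CU value, used by probabilistic sensitivity analysis to
    re-evaluate the scenario under sampled utilities.
    """
    if utilities is None:
        utilities = UtilityTable()
    before = _scenario_cqalys(scn.before, utilities, cu_override)
    after = _scenario_cqalys(scn.after, utilities, cu_override)
    rows = {}
    for state in before:
        delta = before[state] - after[state]
        rows[state] = (
            before[state],
            after[state],
            delta,
            delta * scn.threshold,
        )
    return CostEffectivenessResult(scn.label, scn.threshold, rows)


# ---------------------------------------------------------------------------
# packaged fixtures


def _load_packaged(name: str) -> dict:
    with resources.files("floodbn").joinpath("data", name).open() as fh:
        return json.load(fh)


def default_utilities() -> UtilityTable:
    """The packaged elicited utility table (remission / Lsever / Msever)."""
    doc = _load_packaged("utilities.json")
    states = {
        name: (row["mean"], row["beta_alpha"], row["beta_beta"])
        for name, row in doc["states"].items()
    }
    return UtilityTable(states, doc["reference"], doc["horizon_years"])


def default_scenario() -> InterventionScenario:
    """The packaged early-warning-system scenario (printed CQALY inputs)."""
    doc = _load_packaged("scenario_ews.json")
    return InterventionScenario(
        doc["label"], doc["before"], doc["after"], doc["threshold"]
    )
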