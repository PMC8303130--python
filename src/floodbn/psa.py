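"""Probabilistic sensitivity analysis over Beta-distributed utilities, and a
Monte-Carlo estimator of the expected value of perfect information (EVPI).

PSA propagates the elicitation uncertainty in the health-state utilities
through the cost-effectiveness calculation: each draw samples every state's
utility from its Beta distribution, recomputes the change in utility (CU)
against the sampled remission utility, re-evaluates the intervention and
records the per-state QALY change and net monetary benefit. Scenarios given
directly in CQALY form are perturbed multiplicatively by CU_draw / CU_mean
per state, where CU_mean is the change in utility at the Beta means (the
CQALY pathway is linear in CU, and the draws are centered on the Beta
means, so the degenerate-variance limit recovers the deterministic result).

EVPI for a decision set is ``E[max_d NB_d] - max_d E[NB_d]`` estimated on
common draws, which is nonnegative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flood_model import (
    InterventionScenario,
    UtilityTable,
    beta_mean,
    evaluate_intervention,
)

__all__ = ["PsaSample", "PsaSummary", "draw_psa_samples", "run_psa", "evpi"]


@dataclass(frozen=True)
class PsaSample:
    """One PSA draw: sampled utilities and the resulting outcomes."""

    index: int
    utilities: dict[str, float]
    delta_qaly: dict[str, float]
    monetary_value: dict[str, float]


@dataclass(frozen=True)
class PsaSummary:
    """Summary of a PSA run.

    Per state: mean and central 95% interval (2.5th/97.5th percentiles) of
    the QALY change and of its monetized value; plus the per-person EVPI
    for the {intervene, do nothing} decision at the scenario threshold.
    """

    n_samples: int
    seed: int
    threshold: float
    delta_qaly: dict[str, dict[str, float]]
    monetary_value: dict[str, dict[str, float]]
    evpi: float

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "seed": self.seed,
            "threshold": self.threshold,
            "delta_qaly": self.delta_qaly,
            "monetary_value": self.monetary_value,
            "evpi": self.evpi,
        }


def _summaries(draws: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(draws.mean()),
        "p2.5": float(np.percentile(draws, 2.5)),
        "p97.5": float(np.percentile(draws, 97.5)),
    }


def sample_utilities(
    utilities: UtilityTable, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """n Beta draws per declared state, in declaration (state-major) order."""
    return {
        state: rng.beta(*utilities.beta_params(state), size=n)
        for state in utilities.states
    }


def _psa_arrays(
    scn: InterventionScenario,
    utilities: UtilityTable,
    n: int,
    seed: int,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-draw utilities, QALY changes and monetary values (state -> array)."""
    rng = np.random.default_rng(seed)
    draws = sample_utilities(utilities, n, rng)
    states = utilities.health_states()

    # the QALY change is linear in CU, so evaluate once and scale every draw
    # by CU_draw / CU_mean, normalizing by the *Beta* means (the draws are
    # centered there, so the degenerate-variance limit recovers the
    # deterministic result exactly)
    base = evaluate_intervention(scn, utilities)
    cu_beta_mean = {
        s: max(
            0.0,
            beta_mean(*utilities.beta_params(utilities.reference))
            - beta_mean(*utilities.beta_params(s)),
        )
        for s in states
    }
    ref_draws = draws[utilities.reference]
    delta = {}
    money = {}
    for s in states:
        cu_draws = np.maximum(0.0, ref_draws - draws[s])
        if cu_beta_mean[s] > 0:
            delta[s] = base.delta_qaly(s) * cu_draws / cu_beta_mean[s]
        else:
            delta[s] = np.full(n, base.delta_qaly(s))
        money[s] = delta[s] * scn.threshold
    return draws, delta, money


def draw_psa_samples(
    scn: InterventionScenario,
    utilities: UtilityTable | None = None,
    n: int = 1_000,
    seed: int = 0,
) -> list[PsaSample]:
    """Materialize individual PSA draws (same stream as :func:`run_psa`)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if utilities is None:
        utilities = UtilityTable()
    draws, delta, money = _psa_arrays(scn, utilities, n, seed)
    states = utilities.health_states()
    return [
        PsaSample(
            index=i,
            utilities={s: float(draws[s][i]) for s in utilities.states},
            delta_qaly={s: float(delta[s][i]) for s in states},
            monetary_value={s: float(money[s][i]) for s in states},
        )
        for i in range(n)
    ]


def run_psa(
    scn: InterventionScenario,
    utilities: UtilityTable | None = None,
    n: int = 10_000,
    seed: int = 0,
) -> PsaSummary:
    """Monte-Carlo PSA: ``n`` utility draws, re-evaluating the intervention
    for each. Deterministic given ``seed`` (one seeded generator per run,
    state-major draw order).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if utilities is None:
        utilities = UtilityTable()
    states = utilities.health_states()
    _, delta, money = _psa_arrays(scn, utilities, n, seed)

    # decision set {intervene, do nothing}: intervening gains the summed
    # monetized QALY change; doing nothing gains 0
    nb_intervene = sum(money[s] for s in states)
    nb_nothing = np.zeros(n)
    evpi_value = evpi(np.column_stack([nb_intervene, nb_nothing]))

    return PsaSummary(
        n_samples=n,
        seed=seed,
        threshold=scn.threshold,
        delta_qaly={s: _summaries(delta[s]) for s in states},
        monetary_value={s: _summaries(money[s]) for s in states},
        evpi=evpi_value,
    )


def evpi(net_benefits: np.ndarray) -> float:
    """Expected value of perfect information from a per-draw NB table.

    ``net_benefits`` has shape (n_draws, n_options) with common draws
    across options (each row is one realization of the uncertain
    parameters). EVPI = mean over draws of the best option's NB, minus the
    best option's mean NB; >= 0 by construction.
    """
    nb = np.asarray(net_benefits, dtype=float)
    if nb.ndim != 2:
        raise ValueError(
            "net benefits must be a 2-D table (draws x options); ragged or "
            f"{nb.ndim}-D input is not accepted"
        )
    if nb.shape[0] < 1 or nb.shape[1] < 2:
        raise ValueError("EVPI needs >= 1 draw and >= 2 decision options")
    perfect = nb.max(axis=1).mean()
    current = nb.mean(axis=0).max()
    return float(max(0.0, perfect - current))
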