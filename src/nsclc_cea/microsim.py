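"""Patient-level microsimulation: a brute-force oracle for the cohort tree.

Individual patients are pushed through the same event logic as the
decision tree — a categorical draw over the three postoperative outcomes,
then (for survivors) a Bernoulli draw for a grade >=3 chemotherapy AE —
and priced with the same per-path payoff functions.  Cohort means
therefore converge to the analytic rollback; a persistent discrepancy
would indicate that the tree structure or probability wiring disagrees
with the event logic it claims to encode.

The cohort also doubles as a synthetic stand-in dataset: one row per
patient with strategy, events, cost and QALY, reproducible from a seed.
Overall survival is a cohort-level scalar (no per-patient survival
heterogeneity), matching the model's single-OS-figure horizon.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_CONVENTIONS,
    PathDescriptor,
    StructuralConventions,
    path_cost,
    path_qaly,
)
from .params import ParameterSet

__all__ = ["PatientRecord", "CohortResult", "simulate_patient", "simulate_cohort"]

_OUTCOMES = ("none", "ge3_recovered", "death")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: int
    strategy: str
    complication_outcome: str  # "none" | "ge3_recovered" | "death"
    ae: bool
    cost: float
    qaly: float


@dataclass(frozen=True)
class CohortResult:
    strategy: str
    n: int
    seed: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    records: pd.DataFrame | None

    def summary(self) -> dict:
        return {
            "strategy": self.strategy,
            "n": self.n,
            "seed": self.seed,
            "mean_cost": self.mean_cost,
            "mean_qaly": self.mean_qaly,
            "se_cost": self.se_cost,
            "se_qaly": self.se_qaly,
        }


def _payoff_table(
    strategy: str, p: ParameterSet, conventions: StructuralConventions
) -> dict[tuple[str, bool], tuple[float, float]]:
    table: dict[tuple[str, bool], tuple[float, float]] = {}
    for comp in _OUTCOMES:
        for ae in (False, True):
            if comp == "death" and ae:
                continue
            d = PathDescriptor(strategy, comp, "ge3" if ae else "none")
            table[(comp, ae)] = (path_cost(d, p, conventions), path_qaly(d, p, conventions))
    return table


def simulate_patient(
    strategy: str,
    p: ParameterSet,
    rng: np.random.Generator,
    patient_id: int = 0,
    conventions: StructuralConventions = DEFAULT_CONVENTIONS,
) -> PatientRecord:
    """Draw one patient trajectory and price it with the tree's payoffs."""
    pr = p.arm(strategy).probabilities
    probs = [pr.p_no_complication, pr.p_complication_ge3, pr.p_postop_death]
    outcome = _OUTCOMES[rng.choice(3, p=probs)]
    ae = bool(rng.random() < pr.p_ae_ge3) if outcome != "death" else False
    d = PathDescriptor(strategy, outcome, "ge3" if ae else "none")
    return PatientRecord(
        patient_id=patient_id,
        strategy=strategy,
        complication_outcome=outcome,
        ae=ae,
        cost=path_cost(d, p, conventions),
        qaly=path_qaly(d, p, conventions),
    )


def simulate_cohort(
    strategy: str,
    p: ParameterSet,
    n: int,
    seed: int,
    conventions: StructuralConventions = DEFAULT_CONVENTIONS,
    return_records: bool = True,
) -> CohortResult:
    """Simulate ``n`` patients (vectorized) and report cohort means with
    standard errors.  The draw sequence is fully determined by ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    strategy = strategy.upper()
    pr = p.arm(strategy).probabilities
    rng = np.random.default_rng(seed)
    outcome_idx = rng.choice(3, size=n, p=[pr.p_no_complication, pr.p_complication_ge3, pr.p_postop_death])
    ae = rng.random(n) < pr.p_ae_ge3
    ae[outcome_idx == 2] = False

    table = _payoff_table(strategy, p, conventions)
    cost = np.empty(n)
    qaly = np.empty(n)
    for i_outcome, comp in enumerate(_OUTCOMES):
        for ae_flag in (False, True):
            if comp == "death" and ae_flag:
                continue
            mask = (outcome_idx == i_outcome) & (ae == ae_flag)
            c, q = table[(comp, ae_flag)]
            cost[mask] = c
            qaly[mask] = q

    records = None
    if return_records:
        records = pd.DataFrame(
            {
                "patient_id": np.arange(n),
                "strategy": strategy,
                "complication_outcome": [_OUTCOMES[i] for i in outcome_idx],
                "ae": ae,
                "cost": cost,
                "qaly": qaly,
            }
        )
    ddof = 1 if n > 1 else 0
    return CohortResult(
        strategy=strategy,
        n=n,
        seed=seed,
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=ddof) / np.sqrt(n)),
        se_qaly=float(qaly.std(ddof=ddof) / np.sqrt(n)),
        records=records,
    )
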