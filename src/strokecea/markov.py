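"""Long-term Markov cohort engine.

Starting from the decision-tree month-3 mRS distribution, the cohort is
propagated through 119 quarter-year cycles (a 30-year horizon in total).
Cycle ``t`` starts at age ``start_age + 0.25 t`` and its accruals are
discounted at ``(1 + rate)^(-0.25 t)``; the decision-tree period is year 0
and undiscounted.  No half-cycle correction is applied.

Per cycle the cohort accrues
  cost  = 0.25 x (occupancy mRS 0-1 x annual post-hospitalization cost (0-1)
                  + occupancy mRS 2-5 x annual cost (2-5))
          + newly-recurred mass x recurrent-stroke event cost,
  QALYs = 0.25 x (non-recurring alive occupancy . state utilities
                  + surviving new recurrences x recurrence utility),
  LYs   = 0.25 x alive occupancy,
with end-of-cycle occupancy; recurrence decedents incur the event cost but
accrue no utility in their death cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acute import AcutePhaseResult
from .params import ParameterSet
from .transitions import (
    DEAD,
    annual_rate_to_cycle_prob,
    build_transition_matrix,
    recurrence_redistribution,
)

__all__ = ["CohortTrace", "ArmResult", "discount_factor", "cycle_accruals", "run_markov"]


def discount_factor(time_years: float, rate: float) -> float:
    """Present-value factor ``(1 + rate)^(-time)``; 1 at time zero."""
    if rate < 0 or time_years < 0:
        raise ValueError("discounting requires non-negative time and rate")
    return (1.0 + rate) ** (-time_years)


@dataclass
class CohortTrace:
    """Per-cycle record of the Markov phase for one arm.

    Arrays are indexed by Markov cycle ``t = 1..n`` (row ``t-1``); ``occupancy``
    holds the end-of-cycle state distribution.
    """

    cycles: np.ndarray          # cycle index t
    ages: np.ndarray            # cohort age at cycle start
    occupancy: np.ndarray       # (n, 7) end-of-cycle state occupancy
    new_recurrence: np.ndarray  # (n, 7) surviving newly-recurred mass by state
    cost: np.ndarray            # undiscounted per-cycle accruals
    qaly: np.ndarray
    ly: np.ndarray
    cost_disc: np.ndarray       # discounted twins
    qaly_disc: np.ndarray
    ly_disc: np.ndarray

    def to_frame(self):
        """Tidy per-cycle trace (cycle, age, per-state occupancy, accruals)."""
        import pandas as pd

        df = pd.DataFrame({"cycle": self.cycles, "age": self.ages})
        for s in range(7):
            df[f"mrs{s}"] = self.occupancy[:, s]
        for name in ("cost", "qaly", "ly", "cost_disc", "qaly_disc", "ly_disc"):
            df[name] = getattr(self, name)
        return df


@dataclass
class ArmResult:
    """Discounted and undiscounted lifetime totals for one strategy arm."""

    arm_label: str
    total_cost: float
    total_qaly: float
    total_ly: float
    total_cost_undiscounted: float
    total_qaly_undiscounted: float
    total_ly_undiscounted: float
    acute: AcutePhaseResult
    trace: CohortTrace = field(repr=False)


def cycle_accruals(
    occupancy: np.ndarray,
    new_recurrence_mass: np.ndarray,
    total_newly_recurred: float,
    params: ParameterSet,
) -> tuple[float, float, float]:
    """Undiscounted (cost, QALY, LY) accrued over one cycle.

    ``occupancy`` is the end-of-cycle state distribution,
    ``new_recurrence_mass`` the surviving newly-recurred mass per state, and
    ``total_newly_recurred`` includes recurrence decedents (who incur the
    event cost but no utility).
    """
    occupancy = np.asarray(occupancy, dtype=float)
    new_recurrence_mass = np.asarray(new_recurrence_mass, dtype=float)
    c = params.costs
    cycle = params.cycle_length
    cost = cycle * (occupancy[0:2].sum() * c.annual_post_mrs01.value
                    + occupancy[2:6].sum() * c.annual_post_mrs25.value)
    cost += total_newly_recurred * c.recurrent_stroke_cost.value
    u = params.utilities.as_array()
    stable = occupancy - new_recurrence_mass
    qaly = cycle * (float(stable @ u)
                    + new_recurrence_mass.sum() * params.utilities.u_recurrence.value)
    ly = cycle * float(1.0 - occupancy[DEAD])
    return cost, qaly, ly


def run_markov(acute: AcutePhaseResult, params: ParameterSet) -> ArmResult:
    """Propagate one arm's cohort through the Markov phase and total the arm.

    Lifetime totals are the acute-phase contribution plus the per-cycle
    (discounted) Markov accruals.
    """
    n = params.n_markov_cycles
    rate = params.discount_rate.value
    p_rec = annual_rate_to_cycle_prob(params.annual_recurrence.value)
    cf = params.recurrence_case_fatality.value
    # survivors of a recurrence from state j land on redistribution row j
    redist = np.vstack([recurrence_redistribution(j) for j in range(6)] + [np.zeros(7)])

    x = acute.initial_markov_distribution.as_array()
    trace = CohortTrace(
        cycles=np.arange(1, n + 1),
        ages=params.start_age + params.cycle_length * np.arange(1, n + 1),
        occupancy=np.zeros((n, 7)),
        new_recurrence=np.zeros((n, 7)),
        cost=np.zeros(n), qaly=np.zeros(n), ly=np.zeros(n),
        cost_disc=np.zeros(n), qaly_disc=np.zeros(n), ly_disc=np.zeros(n),
    )
    for t in range(1, n + 1):
        age = params.start_age + params.cycle_length * t
        M = build_transition_matrix(age, params)
        recurred = x[:6] * p_rec                      # all recurrences this cycle
        new_rec_surv = (recurred * (1.0 - cf)) @ redist[:6]
        x = x @ M
        cost, qaly, ly = cycle_accruals(x, new_rec_surv, float(recurred.sum()), params)
        df = discount_factor(params.cycle_length * t, rate)
        i = t - 1
        trace.occupancy[i] = x
        trace.new_recurrence[i] = new_rec_surv
        trace.cost[i], trace.qaly[i], trace.ly[i] = cost, qaly, ly
        trace.cost_disc[i] = cost * df
        trace.qaly_disc[i] = qaly * df
        trace.ly_disc[i] = ly * df

    return ArmResult(
        arm_label=acute.arm_label,
        total_cost=acute.acute_cost + float(trace.cost_disc.sum()),
        total_qaly=acute.acute_qaly + float(trace.qaly_disc.sum()),
        total_ly=acute.acute_ly + float(trace.ly_disc.sum()),
        total_cost_undiscounted=acute.acute_cost + float(trace.cost.sum()),
        total_qaly_undiscounted=acute.acute_qaly + float(trace.qaly.sum()),
        total_ly_undiscounted=acute.acute_ly + float(trace.ly.sum()),
        acute=acute,
        trace=trace,
    )
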