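"""Decision-tree stage: the first 3 months after the index stroke.

The treatment effect enters here and only here: the argatroban arm's month-3
mRS distribution is the control distribution reweighted category-wise by the
published risk ratios (then renormalized).  Each arm accrues its acute-phase
cost (state-dependent acute care, priced sICH complication, and - in the
intervention arm - the drug course plus infusion fees), QALYs and life-years
over the 0.25-year period.  Nothing in this phase is discounted (year 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._validate import ValidationError
from .params import CostTable, MRSDistribution, ParameterSet, RRVector

__all__ = ["AcutePhaseResult", "apply_rr", "drug_course_cost", "run_decision_tree",
           "ARGATROBAN", "CONTROL", "TOTAL_DOSE_MG", "INFUSION_HOURS"]

ARGATROBAN = "argatroban"
CONTROL = "control"

#: 60 mg/day for 2 days + 20 mg/day for 5 days
TOTAL_DOSE_MG = 60 * 2 + 20 * 5
#: continuous infusion over the 7-day course
INFUSION_HOURS = 7 * 24

CYCLE_YEARS = 0.25


@dataclass(frozen=True)
class AcutePhaseResult:
    """One arm's decision-tree output: the distribution seeding the Markov
    model plus the undiscounted first-3-month accruals."""

    arm_label: str
    initial_markov_distribution: MRSDistribution
    acute_cost: float
    acute_qaly: float
    acute_ly: float
    rr_renormalizer: float = 1.0

    def __post_init__(self) -> None:
        if self.acute_cost < 0:
            raise ValidationError("acute cost must be non-negative")
        if not 0.0 <= self.acute_qaly <= CYCLE_YEARS + 1e-12:
            raise ValidationError(f"acute QALY must lie in [0, 0.25], got {self.acute_qaly}")
        if not 0.0 <= self.acute_ly <= CYCLE_YEARS + 1e-12:
            raise ValidationError(f"acute life-years must lie in [0, 0.25], got {self.acute_ly}")

    def to_record(self) -> dict:
        """Flat arm summary (arm, accruals, initial state probabilities)."""
        rec = {"arm": self.arm_label, "acute_cost": self.acute_cost,
               "acute_qaly": self.acute_qaly, "acute_ly": self.acute_ly}
        for i, p in enumerate(self.initial_markov_distribution.probs):
            rec[f"p{i}"] = p
        return rec


def apply_rr(control: MRSDistribution, rr: RRVector) -> tuple[MRSDistribution, float]:
    """Reweight the control mRS distribution by per-category risk ratios.

    Returns the renormalized treatment distribution and the renormalization
    constant (the sum of the raw products, ~1.0006 at the published values -
    rounding noise in the printed CIs).
    """
    raw = control.as_array() * rr.as_array()
    total = raw.sum()
    if total <= 0:
        raise ValidationError("risk-ratio weighting produced an all-zero distribution")
    return MRSDistribution(tuple(raw / total)), float(total)


def drug_course_cost(price_per_mg: float, costs: CostTable) -> float:
    """Total cost of the 7-day argatroban course.

    220 mg at the per-mg price, plus infusion administration fees for 168 h of
    continuous infusion (first-hour fee once, then the additional-hour fee).
    """
    if price_per_mg <= 0:
        raise ValidationError(f"drug price must be positive, got {price_per_mg}")
    drug = TOTAL_DOSE_MG * price_per_mg
    infusion = (costs.infusion_first_hour.value
                + (INFUSION_HOURS - 1) * costs.infusion_additional_hour.value)
    return drug + infusion


def run_decision_tree(arm: str, params: ParameterSet) -> AcutePhaseResult:
    """Evaluate the decision tree for one arm.

    The month-3 mRS distribution prices acute care (mRS 0-1 / 2-5 / death
    tiers); the arm-specific sICH probability adds the complication's cost and
    a one-cycle utility decrement.  QALYs use the month-3 distribution as the
    whole-period average; life-years count the surviving mass over 0.25 years.
    """
    if arm == CONTROL:
        dist, renorm = params.control_mrs_dist, 1.0
        p_sich = params.p_sich_control.value
    elif arm == ARGATROBAN:
        dist, renorm = apply_rr(params.control_mrs_dist, params.rr)
        p_sich = params.p_sich_argatroban.value
    else:
        raise ValidationError(f"unknown arm {arm!r}")

    d = dist.as_array()
    c = params.costs
    cost = (d[0:2].sum() * c.acute_mrs01.value
            + d[2:6].sum() * c.acute_mrs25.value
            + d[6] * c.acute_death.value
            + p_sich * c.sich_cost.value)
    if arm == ARGATROBAN:
        cost += drug_course_cost(c.drug_price_per_mg.value, c)

    u = params.utilities.as_array()
    qaly = CYCLE_YEARS * float(d @ u) \
        - p_sich * params.utilities.sich_disutility.value * CYCLE_YEARS
    ly = CYCLE_YEARS * float(1.0 - d[6])
    return AcutePhaseResult(arm, dist, cost, max(qaly, 0.0), ly, renorm)
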