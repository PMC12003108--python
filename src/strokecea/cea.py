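"""Incremental cost-effectiveness: ICER, dominance, and threshold rules.

Classification against the Chinese willingness-to-pay thresholds (1x and 3x
2023 per-capita GDP): dominant if cheaper and more effective; dominated if
costlier and less effective; otherwise highly cost-effective below the 1x
threshold, cost-effective between 1x and 3x, not cost-effective above 3x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .acute import ARGATROBAN, CONTROL, run_decision_tree
from .markov import ArmResult, run_markov
from .params import ParameterSet

__all__ = ["CEAResult", "compute_icer", "net_monetary_benefit", "run_arm", "run_base_case"]

DOMINANT = "dominant"
HIGHLY_CE = "highly cost-effective"
CE = "cost-effective"
NOT_CE = "not cost-effective"
DOMINATED = "dominated"


def net_monetary_benefit(delta_cost: float, delta_effect: float, wtp: float) -> float:
    """NMB = dE x WTP - dC; positive means acceptable at that threshold."""
    return delta_effect * wtp - delta_cost


@dataclass(frozen=True)
class CEAResult:
    """Two-arm comparison: per-arm totals, incremental quantities, ICERs, and
    the threshold classification."""

    intervention: ArmResult
    comparator: ArmResult
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: float            # CNY per QALY (may be +-inf when dQALY = 0)
    icer_ly: float         # CNY per life-year
    classification: str
    wtp_1x: float
    wtp_3x: float

    def nmb(self, wtp: float | None = None) -> float:
        return net_monetary_benefit(self.delta_cost, self.delta_qaly,
                                    self.wtp_1x if wtp is None else wtp)

    def to_record(self) -> dict:
        """Flat full-precision record mirroring the published results table."""
        return {
            "intervention_cost": self.intervention.total_cost,
            "intervention_qaly": self.intervention.total_qaly,
            "intervention_ly": self.intervention.total_ly,
            "comparator_cost": self.comparator.total_cost,
            "comparator_qaly": self.comparator.total_qaly,
            "comparator_ly": self.comparator.total_ly,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_ly": self.delta_ly,
            "icer": self.icer,
            "icer_ly": self.icer_ly,
            "classification": self.classification,
        }


def _ratio(dc: float, de: float) -> float:
    if de == 0.0:
        return math.copysign(math.inf, dc) if dc != 0.0 else math.nan
    return dc / de


def compute_icer(
    intervention: ArmResult,
    comparator: ArmResult,
    wtp_1x: float,
    wtp_3x: float,
) -> CEAResult:
    """Incremental comparison of two arms computed under the same inputs."""
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.total_qaly - comparator.total_qaly
    dl = intervention.total_ly - comparator.total_ly
    icer = _ratio(dc, dq)

    if dc < 0.0 and dq > 0.0:
        cls = DOMINANT
    elif dc > 0.0 and dq < 0.0:
        cls = DOMINATED
    elif dq == 0.0:
        cls = DOMINATED if dc > 0.0 else (DOMINANT if dc < 0.0 else HIGHLY_CE)
    elif dq < 0.0:
        # less effective and cheaper: acceptable only if savings beat the
        # forgone health at the 3x threshold
        cls = NOT_CE if net_monetary_benefit(dc, dq, wtp_3x) <= 0 else CE
    elif icer < wtp_1x:
        cls = HIGHLY_CE
    elif icer <= wtp_3x:
        cls = CE
    else:
        cls = NOT_CE
    return CEAResult(intervention, comparator, dc, dq, dl,
                     icer, _ratio(dc, dl), cls, wtp_1x, wtp_3x)


def run_arm(arm: str, params: ParameterSet) -> ArmResult:
    """Decision tree + Markov phase for one strategy arm."""
    return run_markov(run_decision_tree(arm, params), params)


def run_base_case(params: ParameterSet) -> CEAResult:
    """Deterministic two-arm run at the point values."""
    return compute_icer(run_arm(ARGATROBAN, params), run_arm(CONTROL, params),
                        params.wtp_1x, params.wtp_3x)
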