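"""Per-cycle transition machinery for the 7-state Markov model.

States are mRS 0-5 (alive, by disability grade) and mRS 6 (dead, absorbing).
Within one 3-month cycle a patient can experience at most one clinical event:
a recurrent stroke (fatal with the per-event case fatality, otherwise
redistributing the survivor uniformly over the same-or-worse mRS states), or
a non-stroke death driven by age-banded background mortality scaled by the
state-specific hazard ratio.  No spontaneous improvement is modelled.

Annual incidences are converted to 3-month probabilities on the rate scale:
``r = -ln(1 - R) / 4`` then ``p = 1 - exp(-r)``.  Hazard ratios multiply the
annual rate, which is then split into quarter-year cycles the same way.
"""

from __future__ import annotations

import math

import numpy as np

from ._validate import ValidationError
from .params import HazardRatioVector, MortalityTable, ParameterSet

__all__ = [
    "annual_rate_to_cycle_prob",
    "background_annual_mortality",
    "nonstroke_death_cycle_prob",
    "recurrence_redistribution",
    "build_transition_matrix",
    "export_transition_matrices",
]

DEAD = 6
CYCLES_PER_YEAR = 4


def annual_rate_to_cycle_prob(annual_incidence: float) -> float:
    """3-month transition probability implied by an annual incidence.

    Uses ``r = -ln(1 - R) / 4`` and ``p = 1 - exp(-r)``; monotone in the
    incidence and never larger than it.
    """
    if not 0.0 <= annual_incidence < 1.0:
        raise ValidationError(
            f"annual incidence must lie in [0, 1), got {annual_incidence}"
        )
    r = -math.log(1.0 - annual_incidence) / CYCLES_PER_YEAR
    return -math.expm1(-r)


def background_annual_mortality(age: float, table: MortalityTable) -> float:
    """Annual all-cause death probability for the band containing ``age``."""
    return table.annual_probability(age)


def nonstroke_death_cycle_prob(
    age: float, mrs: int, table: MortalityTable, hr: HazardRatioVector
) -> float:
    """Per-cycle non-stroke death probability for an alive state.

    The background annual probability is moved to the rate scale, multiplied
    by the state's death hazard ratio, split into quarter-year cycles, and
    transformed back to a probability.
    """
    if not 0 <= mrs <= 5:
        raise ValidationError(f"mrs must be an alive state 0-5, got {mrs}")
    p_annual = background_annual_mortality(age, table)
    rate = -math.log(1.0 - p_annual) * hr.point[mrs] / CYCLES_PER_YEAR
    return -math.expm1(-rate)


def recurrence_redistribution(origin: int) -> np.ndarray:
    """Distribution of a recurrence survivor over the alive states.

    Survivors are spread uniformly over the same-or-worse disability grades:
    weight ``1 / (6 - origin)`` on each of states ``origin..5``.
    """
    if not 0 <= origin <= 5:
        raise ValidationError(f"recurrence origin must be an alive state 0-5, got {origin}")
    out = np.zeros(7)
    out[origin:DEAD] = 1.0 / (DEAD - origin)
    return out


def build_transition_matrix(age: float, params: ParameterSet) -> np.ndarray:
    """The 7x7 one-cycle transition matrix for a cohort aged ``age``.

    From each alive state ``j``: a recurrence occurs with the cycle-converted
    recurrence probability; recurrence deaths (per-event case fatality) move
    to mRS 6; surviving recurrences redistribute over states ``j..5``; the
    non-recurrence fraction dies of non-stroke causes with the HR-adjusted
    background probability or else remains in ``j``.  Row mRS 6 is absorbing.
    """
    p_rec = annual_rate_to_cycle_prob(params.annual_recurrence.value)
    cf = params.recurrence_case_fatality.value
    M = np.zeros((7, 7))
    for j in range(6):
        p_ns = nonstroke_death_cycle_prob(age, j, params.mortality, params.hr)
        M[j] = p_rec * (1.0 - cf) * recurrence_redistribution(j)
        M[j, DEAD] = p_rec * cf + (1.0 - p_rec) * p_ns
        M[j, j] += (1.0 - p_rec) * (1.0 - p_ns)
    M[DEAD, DEAD] = 1.0
    return M


def export_transition_matrices(params: ParameterSet):
    """Tidy per-cycle transition probabilities for audit.

    One row per (cycle, from_state, to_state); cycle ``t`` starts at age
    ``start_age + t * cycle_length``.
    """
    import pandas as pd

    rows = []
    for t in range(1, params.n_markov_cycles + 1):
        age = params.start_age + t * params.cycle_length
        M = build_transition_matrix(age, params)
        for i in range(7):
            for j in range(7):
                rows.append({"cycle": t, "age": age, "from_state": i,
                             "to_state": j, "probability": M[i, j]})
    return pd.DataFrame(rows)
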