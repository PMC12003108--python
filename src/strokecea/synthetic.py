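"""Synthetic inputs with the statistical structure the model consumes.

The real analysis is built from published trial summaries (a month-3 mRS
distribution, per-category risk ratios with 95% CIs, and arm-specific sICH
probabilities).  This module simulates the two-arm trial that would produce
such summaries (multinomial mRS counts, binomial sICH counts), re-estimates
the summaries from the counts, and generates random-but-valid parameter sets
and life tables for property-based testing of every downstream stage.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from ._validate import ValidationError
from .acute import apply_rr
from .params import (
    CostTable,
    HazardRatioVector,
    MortalityBand,
    MortalityTable,
    MRSDistribution,
    ParameterSet,
    Quantity,
    RRVector,
    UtilityTable,
)

__all__ = [
    "SyntheticTrial",
    "EstimatedParameters",
    "simulate_trial",
    "estimate_parameters",
    "trial_parameter_set",
    "random_parameter_set",
]

Z95 = 1.959963984540054


@dataclass(frozen=True)
class SyntheticTrial:
    """Simulated two-arm trial outcome counts plus the generating truth."""

    n_per_arm: int
    control_counts: tuple[int, ...]
    treatment_counts: tuple[int, ...]
    control_sich: int
    treatment_sich: int
    true_control: MRSDistribution
    true_rr: RRVector
    seed: int

    def __post_init__(self) -> None:
        for name in ("control_counts", "treatment_counts"):
            counts = tuple(int(c) for c in getattr(self, name))
            if len(counts) != 7 or any(c < 0 for c in counts):
                raise ValidationError(f"{name} must be 7 non-negative integers")
            if sum(counts) != self.n_per_arm:
                raise ValidationError(f"{name} must sum to n_per_arm")
            object.__setattr__(self, name, counts)

    def to_frame(self):
        import pandas as pd

        rows = []
        for arm, counts in (("control", self.control_counts),
                            ("argatroban", self.treatment_counts)):
            for cat, count in enumerate(counts):
                rows.append({"arm": arm, "mrs_category": cat, "count": count})
        return pd.DataFrame(rows)


def simulate_trial(
    true_control: MRSDistribution,
    true_rr: RRVector,
    n_per_arm: int,
    p_sich: tuple[float, float] = (0.009, 0.007),
    seed: int = 0,
) -> SyntheticTrial:
    """Draw one two-arm trial: multinomial mRS counts per arm (treatment arm
    under the risk-ratio-weighted distribution) and binomial sICH counts.

    ``p_sich`` is (treatment, control).
    """
    if n_per_arm < 1:
        raise ValidationError("n_per_arm must be at least 1")
    rng = np.random.default_rng(seed)
    treat_dist, _ = apply_rr(true_control, true_rr)
    control_counts = rng.multinomial(n_per_arm, true_control.as_array())
    treatment_counts = rng.multinomial(n_per_arm, treat_dist.as_array())
    sich_t = int(rng.binomial(n_per_arm, p_sich[0]))
    sich_c = int(rng.binomial(n_per_arm, p_sich[1]))
    return SyntheticTrial(
        n_per_arm=n_per_arm,
        control_counts=tuple(int(c) for c in control_counts),
        treatment_counts=tuple(int(c) for c in treatment_counts),
        control_sich=sich_c,
        treatment_sich=sich_t,
        true_control=true_control,
        true_rr=true_rr,
        seed=seed,
    )


@dataclass(frozen=True)
class EstimatedParameters:
    """Trial summaries re-estimated from counts, in the shapes the model loads."""

    mrs_control: MRSDistribution
    rr: RRVector
    p_sich_argatroban: Quantity
    p_sich_control: Quantity
    continuity_corrected: tuple[int, ...]  # mRS categories where 0.5 was added


def _binomial_range(p: float, n: int) -> tuple[float, float]:
    half = Z95 * math.sqrt(max(p * (1 - p), 1e-12) / n)
    return max(0.0, p - half), min(1.0, p + half)


def estimate_parameters(trial: SyntheticTrial) -> EstimatedParameters:
    """Proportions, per-category risk ratios with delta-method 95% CIs, and
    sICH probabilities with binomial ranges.

    Categories with a zero cell in either arm get the Haldane-Anscombe
    continuity correction (0.5 added to all four cells of that category's
    2x2 table) and are flagged.
    """
    n = trial.n_per_arm
    c = np.asarray(trial.control_counts, dtype=float)
    t = np.asarray(trial.treatment_counts, dtype=float)

    p_control = c / n
    # point distribution: raw proportions (they sum to 1 exactly)
    lows, highs = zip(*(_binomial_range(p, n) for p in p_control))
    mrs = MRSDistribution(tuple(p_control), tuple(lows), tuple(highs))

    rr_point, rr_low, rr_high, corrected = [], [], [], []
    for i in range(7):
        ci, ti = c[i], t[i]
        nc, nt = float(n), float(n)
        if ci == 0 or ti == 0:
            ci, ti, nc, nt = ci + 0.5, ti + 0.5, nc + 1.0, nt + 1.0
            corrected.append(i)
        rr = (ti / nt) / (ci / nc)
        se = math.sqrt(1.0 / ti - 1.0 / nt + 1.0 / ci - 1.0 / nc)
        rr_point.append(rr)
        rr_low.append(rr * math.exp(-Z95 * se))
        rr_high.append(rr * math.exp(Z95 * se))
    rrv = RRVector(tuple(rr_point), tuple(rr_low), tuple(rr_high))

    pt = trial.treatment_sich / n
    pc = trial.control_sich / n
    return EstimatedParameters(
        mrs_control=mrs,
        rr=rrv,
        p_sich_argatroban=Quantity(pt, *_binomial_range(pt, n)),
        p_sich_control=Quantity(pc, *_binomial_range(pc, n)),
        continuity_corrected=tuple(corrected),
    )


def trial_parameter_set(trial: SyntheticTrial, base: ParameterSet) -> ParameterSet:
    """Splice trial-estimated summaries into a base parameter set, so the
    estimate -> model pipeline can be exercised end to end."""
    est = estimate_parameters(trial)
    return base.replace(
        control_mrs_dist=est.mrs_control,
        rr=est.rr,
        p_sich_argatroban=est.p_sich_argatroban,
        p_sich_control=est.p_sich_control,
    )


def _quantity_around(rng, value: float, rel: float = 0.2,
                     lo: float = 0.0, hi: float = math.inf) -> Quantity:
    low = max(lo, value * (1 - rel))
    high = min(hi, value * (1 + rel) + 1e-9)
    return Quantity(value, low, high)


def random_parameter_set(seed: int, start_age: float = 66.0,
                         horizon_years: float = 30.0) -> ParameterSet:
    """A random but fully valid :class:`ParameterSet` for property testing.

    Utilities are non-increasing in mRS grade (worse disability never scores
    higher), hazard ratios are >= 1 and non-decreasing, the synthetic life
    table rises with age, and every scalar carries a bracketing range.
    """
    rng = np.random.default_rng(seed)

    mrs = rng.dirichlet(np.full(7, 2.0))
    dist = MRSDistribution.from_array(mrs, normalize=True)
    lows = tuple(max(0.0, p * 0.7) for p in dist.probs)
    highs = tuple(min(1.0, p * 1.3 + 0.01) for p in dist.probs)
    dist = MRSDistribution(dist.probs, lows, highs)

    rr_point = np.exp(rng.normal(0.0, 0.3, size=7))
    rr = RRVector(tuple(rr_point), tuple(rr_point * 0.7), tuple(rr_point * 1.4))

    hr_point = np.sort(1.0 + rng.gamma(1.0, 0.5, size=6))
    hr = HazardRatioVector(tuple(hr_point), tuple(hr_point * 0.95),
                           tuple(hr_point * 1.15))

    n_bands = 6
    width = horizon_years / (n_bands - 1)
    p0 = rng.uniform(0.005, 0.02)
    growth = rng.uniform(1.3, 2.0, size=n_bands - 1)
    probs = np.minimum(p0 * np.concatenate([[1.0], np.cumprod(growth)]), 0.6)
    bands = []
    for i, p in enumerate(probs):
        lo = start_age + i * width
        hi = None if i == n_bands - 1 else start_age + (i + 1) * width
        bands.append(MortalityBand(lo, hi, float(p)))
    mortality = MortalityTable(tuple(bands))

    u_alive = np.sort(rng.uniform(0.05, 0.99, size=6))[::-1]
    u = tuple(u_alive) + (0.0,)
    u_low = tuple(max(0.0, v - 0.05) for v in u[:6]) + (0.0,)
    u_high = tuple(min(1.0, v + 0.05) for v in u[:6]) + (0.0,)
    utilities = UtilityTable(
        u, u_low, u_high,
        _quantity_around(rng, float(rng.uniform(0.1, 0.7)), hi=1.0),
        _quantity_around(rng, float(rng.uniform(0.1, 0.5)), hi=1.0),
    )

    def cost(scale: float) -> Quantity:
        return _quantity_around(rng, float(rng.lognormal(math.log(scale), 0.3)), rel=0.3)

    costs = CostTable(
        drug_price_per_mg=cost(2.0),
        acute_mrs01=cost(12_000.0),
        acute_mrs25=cost(16_000.0),
        acute_death=cost(14_000.0),
        sich_cost=cost(3_000.0),
        annual_post_mrs01=cost(9_000.0),
        annual_post_mrs25=cost(13_000.0),
        recurrent_stroke_cost=cost(18_000.0),
        infusion_first_hour=cost(15.0),
        infusion_additional_hour=cost(1.0),
    )

    def prob(lo: float, hi: float) -> Quantity:
        v = float(rng.uniform(lo, hi))
        return Quantity(v, max(0.0, v * 0.8), min(1.0, v * 1.2 + 1e-9))

    return ParameterSet(
        control_mrs_dist=dist,
        rr=rr,
        p_sich_argatroban=prob(0.0, 0.05),
        p_sich_control=prob(0.0, 0.05),
        annual_recurrence=prob(0.01, 0.3),
        recurrence_case_fatality=prob(0.05, 0.4),
        hr=hr,
        mortality=mortality,
        costs=costs,
        utilities=utilities,
        discount_rate=Quantity(float(rng.uniform(0.0, 0.08)), 0.0, 0.08),
        start_age=start_age,
        horizon_years=horizon_years,
    )
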