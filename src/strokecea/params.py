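"""Model inputs: typed parameter records, validation, configuration I/O, and
fitting of probabilistic-sensitivity distributions from published summaries.

Every model input (3-month mRS distribution, treatment risk ratios, event
probabilities, death hazard ratios, background life-table, utilities, costs,
and analysis settings) is carried by :class:`ParameterSet`.  Each scalar input
holds a point value together with the published (low, high) range; ranges are
read as 95% intervals, so an uncertainty sd of ``(high - low) / 3.92`` is used
when fitting beta / gamma / lognormal distributions by moment matching.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from ._validate import (
    ConfigurationError,
    ValidationError,
    check_nonnegative,
    check_positive,
    check_probability,
    check_range,
)

__all__ = [
    "Quantity",
    "MRSDistribution",
    "RRVector",
    "HazardRatioVector",
    "MortalityTable",
    "CostTable",
    "UtilityTable",
    "ParameterSet",
    "FittedDistribution",
    "fit_beta_from_summary",
    "fit_gamma_from_summary",
    "fit_lognormal_from_ci",
    "fit_dirichlet_from_ranges",
    "load_parameters",
    "save_parameters",
    "default_parameters",
    "scalar_parameter_names",
    "get_scalar",
    "set_scalar",
    "psa_distributions",
    "export_psa_distributions",
]

#: number of modified Rankin Scale health states (mRS 0-5 plus mRS 6 = dead)
N_STATES = 7
#: width of a 95% interval in standard-deviation units
Z95_WIDTH = 3.92


# ---------------------------------------------------------------------------
# value records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Quantity:
    """A scalar model input: point value plus its published (low, high) range."""

    value: float
    low: float
    high: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", float(self.value))
        object.__setattr__(self, "low", float(self.low))
        object.__setattr__(self, "high", float(self.high))
        check_range("quantity", self.low, self.value, self.high)

    def __float__(self) -> float:
        return self.value

    @property
    def width(self) -> float:
        return self.high - self.low

    @classmethod
    def fixed(cls, value: float) -> "Quantity":
        return cls(value, value, value)


def _tuple7(x: Sequence[float]) -> tuple[float, ...]:
    t = tuple(float(v) for v in x)
    if len(t) != N_STATES:
        raise ValidationError(f"expected {N_STATES} values (mRS 0-6), got {len(t)}")
    return t


@dataclass(frozen=True)
class MRSDistribution:
    """Probability vector over the seven mRS categories (0-6).

    ``low``/``high`` carry the published per-category 95% ranges used for
    Dirichlet fitting and defaulting to the point values when absent.
    """

    probs: tuple[float, ...]
    low: tuple[float, ...] | None = None
    high: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        probs = _tuple7(self.probs)
        for i, p in enumerate(probs):
            check_probability(f"mRS {i} probability", p)
        total = sum(probs)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"mRS probabilities must sum to 1, got {total!r}")
        object.__setattr__(self, "probs", probs)
        low = _tuple7(self.low) if self.low is not None else probs
        high = _tuple7(self.high) if self.high is not None else probs
        for i in range(N_STATES):
            check_range(f"mRS {i}", low[i], probs[i], high[i])
        object.__setattr__(self, "low", low)
        object.__setattr__(self, "high", high)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float], *, normalize: bool = False) -> "MRSDistribution":
        arr = np.asarray(values, dtype=float)
        if normalize:
            total = arr.sum()
            if total <= 0:
                raise ValidationError("cannot normalize a non-positive probability vector")
            arr = arr / total
        return cls(tuple(arr))


@dataclass(frozen=True)
class RRVector:
    """Per-category risk ratios (treatment vs control) for the month-3 mRS
    distribution, with 95% confidence bounds."""

    point: tuple[float, ...]
    low: tuple[float, ...]
    high: tuple[float, ...]

    def __post_init__(self) -> None:
        point, low, high = _tuple7(self.point), _tuple7(self.low), _tuple7(self.high)
        for i in range(N_STATES):
            check_positive(f"rr mRS {i}", point[i])
            check_positive(f"rr mRS {i} low", low[i])
            check_positive(f"rr mRS {i} high", high[i])
            check_range(f"rr mRS {i}", low[i], point[i], high[i])
        object.__setattr__(self, "point", point)
        object.__setattr__(self, "low", low)
        object.__setattr__(self, "high", high)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.point, dtype=float)

    @classmethod
    def ones(cls) -> "RRVector":
        one = (1.0,) * N_STATES
        return cls(one, one, one)


@dataclass(frozen=True)
class HazardRatioVector:
    """Death hazard ratios of the stroke cohort relative to the general
    population, one per alive mRS state (0-5)."""

    point: tuple[float, ...]
    low: tuple[float, ...]
    high: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("point", "low", "high"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) != 6:
                raise ValidationError(f"hazard ratios: expected 6 values (mRS 0-5), got {len(vals)}")
            for i, v in enumerate(vals):
                check_positive(f"hr mRS {i} {name}", v)
            object.__setattr__(self, name, vals)
        for i in range(6):
            check_range(f"hr mRS {i}", self.low[i], self.point[i], self.high[i])

    def as_array(self) -> np.ndarray:
        return np.asarray(self.point, dtype=float)


@dataclass(frozen=True)
class MortalityBand:
    age_low: float
    age_high: float | None  # None = open-ended
    annual_probability: float

    def __post_init__(self) -> None:
        check_probability(f"background mortality for ages {self.age_low}+", self.annual_probability)

    def contains(self, age: float) -> bool:
        return age >= self.age_low and (self.age_high is None or age < self.age_high)


@dataclass(frozen=True)
class MortalityTable:
    """Age-banded annual all-cause death probabilities.  Bands are half-open
    ``[age_low, age_high)``; the last band may be open-ended."""

    bands: tuple[MortalityBand, ...]

    def __post_init__(self) -> None:
        bands = tuple(
            b if isinstance(b, MortalityBand) else MortalityBand(**b) for b in self.bands
        )
        if not bands:
            raise ValidationError("mortality table must contain at least one band")
        for prev, nxt in zip(bands, bands[1:]):
            if prev.age_high is None:
                raise ValidationError("only the last mortality band may be open-ended")
            if not math.isclose(prev.age_high, nxt.age_low):
                raise ValidationError(
                    f"mortality bands must be contiguous: band ending at {prev.age_high} "
                    f"followed by band starting at {nxt.age_low}"
                )
        object.__setattr__(self, "bands", bands)

    @property
    def min_age(self) -> float:
        return self.bands[0].age_low

    @property
    def max_age(self) -> float | None:
        return self.bands[-1].age_high

    def covers(self, age_low: float, age_high: float) -> bool:
        top = self.bands[-1].age_high
        return age_low >= self.min_age and (top is None or age_high <= top)

    def annual_probability(self, age: float) -> float:
        if age < self.min_age:
            raise ValidationError(
                f"age {age} is below the mortality table's first band ({self.min_age})"
            )
        for band in self.bands:
            if band.contains(age):
                return band.annual_probability
        if self.bands[-1].age_high is not None and age >= self.bands[-1].age_high:
            raise ValidationError(
                f"age {age} exceeds mortality table coverage (< {self.bands[-1].age_high})"
            )
        raise ValidationError(f"age {age} not covered by the mortality table")


_COST_FIELDS = (
    "drug_price_per_mg",
    "acute_mrs01",
    "acute_mrs25",
    "acute_death",
    "sich_cost",
    "annual_post_mrs01",
    "annual_post_mrs25",
    "recurrent_stroke_cost",
    "infusion_first_hour",
    "infusion_additional_hour",
)


@dataclass(frozen=True)
class CostTable:
    """All unit costs, in 2023 CNY."""

    drug_price_per_mg: Quantity
    acute_mrs01: Quantity
    acute_mrs25: Quantity
    acute_death: Quantity
    sich_cost: Quantity
    annual_post_mrs01: Quantity
    annual_post_mrs25: Quantity
    recurrent_stroke_cost: Quantity
    infusion_first_hour: Quantity
    infusion_additional_hour: Quantity

    def __post_init__(self) -> None:
        for name in _COST_FIELDS:
            q = getattr(self, name)
            check_nonnegative(f"cost {name}", q.value)
            check_nonnegative(f"cost {name} low", q.low)


@dataclass(frozen=True)
class UtilityTable:
    """QALY weights per mRS state (u6 = 0 for death), the utility applied in a
    recurrence cycle, and the one-off sICH utility decrement."""

    u: tuple[float, ...]
    u_low: tuple[float, ...]
    u_high: tuple[float, ...]
    u_recurrence: Quantity
    sich_disutility: Quantity

    def __post_init__(self) -> None:
        u, lo, hi = _tuple7(self.u), _tuple7(self.u_low), _tuple7(self.u_high)
        for i in range(N_STATES):
            check_probability(f"utility mRS {i}", u[i])
            check_range(f"utility mRS {i}", lo[i], u[i], hi[i])
        if u[6] != 0.0:
            raise ValidationError(f"utility of the dead state (mRS 6) must be 0, got {u[6]}")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "u_low", lo)
        object.__setattr__(self, "u_high", hi)
        check_probability("u_recurrence", self.u_recurrence.value)
        check_probability("sich_disutility", self.sich_disutility.value)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.u, dtype=float)


@dataclass(frozen=True)
class ParameterSet:
    """The complete, validated set of model inputs."""

    control_mrs_dist: MRSDistribution
    rr: RRVector
    p_sich_argatroban: Quantity
    p_sich_control: Quantity
    annual_recurrence: Quantity
    recurrence_case_fatality: Quantity
    hr: HazardRatioVector
    mortality: MortalityTable
    costs: CostTable
    utilities: UtilityTable
    discount_rate: Quantity
    start_age: float = 66.0
    horizon_years: float = 30.0
    cycle_length: float = 0.25
    wtp_1x: float = 89_358.0
    wtp_3x: float = 268_074.0

    def __post_init__(self) -> None:
        for name in ("p_sich_argatroban", "p_sich_control", "annual_recurrence",
                     "recurrence_case_fatality"):
            q = getattr(self, name)
            check_probability(name, q.value)
            check_probability(f"{name} low", q.low)
            check_probability(f"{name} high", q.high)
        if not 0.0 <= self.discount_rate.value <= 0.2:
            raise ValidationError(
                f"discount_rate must lie in [0, 0.2], got {self.discount_rate.value}"
            )
        check_positive("cycle_length", self.cycle_length)
        n = self.horizon_years / self.cycle_length
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                f"horizon_years / cycle_length must be an integer number of cycles, got {n}"
            )
        if not self.mortality.covers(self.start_age, self.start_age + self.horizon_years):
            raise ValidationError(
                f"mortality table (ages {self.mortality.min_age}-"
                f"{self.mortality.max_age or 'open'}) does not cover the simulated ages "
                f"[{self.start_age}, {self.start_age + self.horizon_years}]"
            )

    @property
    def n_cycles_total(self) -> int:
        """Total number of 3-month periods over the horizon (decision tree + Markov)."""
        return round(self.horizon_years / self.cycle_length)

    @property
    def n_markov_cycles(self) -> int:
        """Markov cycles after the decision-tree period (119 in the base case)."""
        return self.n_cycles_total - 1

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# distribution fitting from published summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FittedDistribution:
    """A sampling distribution fitted from a published point value and range.

    ``params`` is family-specific: beta ``(alpha, beta)``, gamma
    ``(shape, scale)``, lognormal ``(mu, sigma)`` on the log scale, dirichlet
    the concentration vector, and point the single value.
    """

    family: str
    params: tuple[float, ...]
    source_point: float | tuple[float, ...]
    source_low: float | tuple[float, ...]
    source_high: float | tuple[float, ...]

    def mean(self):
        if self.family == "point":
            return self.params[0]
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        if self.family == "gamma":
            shape, scale = self.params
            return shape * scale
        if self.family == "lognormal":
            mu, sigma = self.params
            return math.exp(mu + sigma**2 / 2)
        if self.family == "dirichlet":
            alphas = np.asarray(self.params)
            return alphas / alphas.sum()
        raise ValueError(f"unknown family {self.family!r}")

    def sd(self):
        if self.family == "point":
            return 0.0
        if self.family == "beta":
            a, b = self.params
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        if self.family == "gamma":
            shape, scale = self.params
            return math.sqrt(shape) * scale
        if self.family == "lognormal":
            mu, sigma = self.params
            return math.exp(mu + sigma**2 / 2) * math.sqrt(math.expm1(sigma**2))
        if self.family == "dirichlet":
            alphas = np.asarray(self.params)
            a0 = alphas.sum()
            m = alphas / a0
            return np.sqrt(m * (1 - m) / (a0 + 1))
        raise ValueError(f"unknown family {self.family!r}")

    def median(self):
        if self.family == "lognormal":
            return math.exp(self.params[0])
        if self.family == "point":
            return self.params[0]
        raise ValueError(f"median not implemented for family {self.family!r}")

    def rvs(self, rng: np.random.Generator, size=None):
        if self.family == "point":
            return self.params[0] if size is None else np.full(size, self.params[0])
        if self.family == "beta":
            return rng.beta(self.params[0], self.params[1], size=size)
        if self.family == "gamma":
            return rng.gamma(self.params[0], self.params[1], size=size)
        if self.family == "lognormal":
            return rng.lognormal(self.params[0], self.params[1], size=size)
        if self.family == "dirichlet":
            return rng.dirichlet(self.params, size=size)
        raise ValueError(f"unknown family {self.family!r}")


#: beta/gamma means are clamped away from the boundary before moment matching
_MEAN_CLAMP = 1e-6


def fit_beta_from_summary(point: float, low: float, high: float) -> FittedDistribution:
    """Moment-match a beta distribution to mean ``point`` and
    sd ``(high - low) / 3.92`` (the range read as a 95% interval)."""
    check_probability("point", point)
    check_probability("low", low)
    check_probability("high", high)
    check_range("beta summary", low, point, high)
    sd = (high - low) / Z95_WIDTH
    if sd == 0.0:
        return FittedDistribution("point", (point,), point, low, high)
    m = min(max(point, _MEAN_CLAMP), 1.0 - _MEAN_CLAMP)
    var = sd**2
    if var >= m * (1 - m):
        if _MEAN_CLAMP < point < 1.0 - _MEAN_CLAMP:
            raise ValidationError(
                f"range ({low}, {high}) is too wide for a beta distribution with mean {point}"
            )
        # boundary mean: the clamped mean cannot carry the range-implied
        # spread, so cap the sd at 95% of the feasible maximum
        var = 0.95**2 * m * (1 - m)
    nu = m * (1 - m) / var - 1.0
    return FittedDistribution("beta", (m * nu, (1 - m) * nu), point, low, high)


def fit_gamma_from_summary(point: float, low: float, high: float) -> FittedDistribution:
    """Moment-match a gamma distribution to mean ``point`` and
    sd ``(high - low) / 3.92``."""
    check_positive("point", point)
    check_nonnegative("low", low)
    check_range("gamma summary", low, point, high)
    sd = (high - low) / Z95_WIDTH
    if sd == 0.0:
        return FittedDistribution("point", (point,), point, low, high)
    shape = (point / sd) ** 2
    scale = sd**2 / point
    return FittedDistribution("gamma", (shape, scale), point, low, high)


def fit_lognormal_from_ci(point: float, low: float, high: float) -> FittedDistribution:
    """Fit a lognormal with median ``point`` and log-scale sd
    ``(ln high - ln low) / 3.92`` from a ratio's 95% confidence interval."""
    check_positive("point", point)
    check_positive("low", low)
    check_positive("high", high)
    check_range("lognormal summary", low, point, high)
    sigma = (math.log(high) - math.log(low)) / Z95_WIDTH
    if sigma == 0.0:
        return FittedDistribution("point", (point,), point, low, high)
    return FittedDistribution("lognormal", (math.log(point), sigma), point, low, high)


def fit_dirichlet_from_ranges(
    dist: MRSDistribution, ranges: Sequence[tuple[float, float]] | None = None
) -> FittedDistribution:
    """Fit a Dirichlet with mean equal to ``dist``.

    The single concentration budget is set from the published per-category
    ranges: each category implies an effective sample size
    ``n_i = m_i (1 - m_i) / sd_i^2`` with ``sd_i = (high_i - low_i) / 3.92``;
    the across-category mean of the ``n_i`` scales the mean vector into the
    concentration vector.
    """
    m = dist.as_array()
    if ranges is None:
        ranges = list(zip(dist.low, dist.high))
    ns = []
    for i, (lo, hi) in enumerate(ranges):
        check_range(f"mRS {i}", lo, m[i], hi)
        sd = (hi - lo) / Z95_WIDTH
        if sd > 0 and 0 < m[i] < 1:
            ns.append(m[i] * (1 - m[i]) / sd**2)
    if not ns:
        return FittedDistribution("point", tuple(m), tuple(m), tuple(m), tuple(m))
    n_eff = float(np.mean(ns))
    return FittedDistribution(
        "dirichlet",
        tuple(m * n_eff),
        tuple(m),
        tuple(lo for lo, _ in ranges),
        tuple(hi for _, hi in ranges),
    )


# ---------------------------------------------------------------------------
# named-scalar registry (drives one-way sensitivity and the PSA)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _ScalarSpec:
    kind: str       # "rr" | "hr" | "utility" | "quantity" | "util_quantity" | "cost"
    key: object     # index or attribute name
    psa_family: str | None  # None = held fixed in the PSA


def _scalar_registry() -> dict[str, _ScalarSpec]:
    reg: dict[str, _ScalarSpec] = {}
    for i in range(N_STATES):
        reg[f"rr_mrs{i}"] = _ScalarSpec("rr", i, "lognormal")
    for i in range(6):
        reg[f"hr_mrs{i}"] = _ScalarSpec("hr", i, "lognormal")
    for i in range(6):
        reg[f"utility_mrs{i}"] = _ScalarSpec("utility", i, "beta")
    reg["utility_recurrence"] = _ScalarSpec("util_quantity", "u_recurrence", "beta")
    reg["sich_disutility"] = _ScalarSpec("util_quantity", "sich_disutility", "beta")
    for name in ("p_sich_argatroban", "p_sich_control", "annual_recurrence",
                 "recurrence_case_fatality"):
        reg[name] = _ScalarSpec("quantity", name, "beta")
    reg["discount_rate"] = _ScalarSpec("quantity", "discount_rate", None)
    for field in _COST_FIELDS:
        reg[f"cost_{field}"] = _ScalarSpec("cost", field, "gamma")
    return reg


_SCALARS = _scalar_registry()


def scalar_parameter_names() -> tuple[str, ...]:
    """Names of every scalar input addressable by the sensitivity analyses."""
    return tuple(_SCALARS)


def get_scalar(ps: ParameterSet, name: str) -> Quantity:
    """Return the named scalar's point value and range."""
    try:
        spec = _SCALARS[name]
    except KeyError:
        raise KeyError(f"unknown parameter {name!r}") from None
    if spec.kind == "rr":
        return Quantity(ps.rr.point[spec.key], ps.rr.low[spec.key], ps.rr.high[spec.key])
    if spec.kind == "hr":
        return Quantity(ps.hr.point[spec.key], ps.hr.low[spec.key], ps.hr.high[spec.key])
    if spec.kind == "utility":
        u = ps.utilities
        return Quantity(u.u[spec.key], u.u_low[spec.key], u.u_high[spec.key])
    if spec.kind == "util_quantity":
        return getattr(ps.utilities, spec.key)
    if spec.kind == "quantity":
        return getattr(ps, spec.key)
    if spec.kind == "cost":
        return getattr(ps.costs, spec.key)
    raise AssertionError(spec.kind)


def _replace_index(values: tuple, i: int, v: float) -> tuple:
    out = list(values)
    out[i] = float(v)
    return tuple(out)


def set_scalar(ps: ParameterSet, name: str, value: float) -> ParameterSet:
    """Return a new ParameterSet with the named scalar's point value replaced.

    The stored range is widened if needed so the record stays internally
    consistent when a sensitivity analysis pushes the point to an extreme.
    """
    spec = _SCALARS[name]
    value = float(value)

    def _q(old: Quantity) -> Quantity:
        return Quantity(value, min(old.low, value), max(old.high, value))

    if spec.kind == "rr":
        i = spec.key
        rr = RRVector(
            _replace_index(ps.rr.point, i, value),
            _replace_index(ps.rr.low, i, min(ps.rr.low[i], value)),
            _replace_index(ps.rr.high, i, max(ps.rr.high[i], value)),
        )
        return ps.replace(rr=rr)
    if spec.kind == "hr":
        i = spec.key
        hr = HazardRatioVector(
            _replace_index(ps.hr.point, i, value),
            _replace_index(ps.hr.low, i, min(ps.hr.low[i], value)),
            _replace_index(ps.hr.high, i, max(ps.hr.high[i], value)),
        )
        return ps.replace(hr=hr)
    if spec.kind == "utility":
        i = spec.key
        u = ps.utilities
        util = dataclasses.replace(
            u,
            u=_replace_index(u.u, i, value),
            u_low=_replace_index(u.u_low, i, min(u.u_low[i], value)),
            u_high=_replace_index(u.u_high, i, max(u.u_high[i], value)),
        )
        return ps.replace(utilities=util)
    if spec.kind == "util_quantity":
        util = dataclasses.replace(
            ps.utilities, **{spec.key: _q(getattr(ps.utilities, spec.key))}
        )
        return ps.replace(utilities=util)
    if spec.kind == "quantity":
        return ps.replace(**{spec.key: _q(getattr(ps, spec.key))})
    if spec.kind == "cost":
        costs = dataclasses.replace(ps.costs, **{spec.key: _q(getattr(ps.costs, spec.key))})
        return ps.replace(costs=costs)
    raise AssertionError(spec.kind)


def psa_distributions(ps: ParameterSet) -> dict[str, FittedDistribution]:
    """Fit the PSA sampling distribution for every stochastic input.

    Costs are gamma, probabilities and utilities beta, risk and hazard ratios
    lognormal (from their 95% intervals), and the control mRS distribution
    Dirichlet (under key ``control_mrs_dist``).  Background mortality and the
    discount rate carry no published range and are held fixed.
    """
    fits: dict[str, FittedDistribution] = {}
    for name, spec in _SCALARS.items():
        if spec.psa_family is None:
            continue
        q = get_scalar(ps, name)
        if spec.psa_family == "beta":
            fits[name] = fit_beta_from_summary(q.value, q.low, q.high)
        elif spec.psa_family == "gamma":
            fits[name] = fit_gamma_from_summary(q.value, q.low, q.high)
        elif spec.psa_family == "lognormal":
            fits[name] = fit_lognormal_from_ci(q.value, q.low, q.high)
        else:  # pragma: no cover
            raise AssertionError(spec.psa_family)
    fits["control_mrs_dist"] = fit_dirichlet_from_ranges(ps.control_mrs_dist)
    return fits


def export_psa_distributions(ps: ParameterSet):
    """Tabulate the fitted PSA distributions (parameter, family, par1, par2)."""
    import pandas as pd

    rows = []
    for name, fit in psa_distributions(ps).items():
        if fit.family == "dirichlet":
            for i, alpha in enumerate(fit.params):
                rows.append({"parameter": f"{name}_mrs{i}", "family": "dirichlet",
                             "par1": alpha, "par2": float(np.sum(fit.params))})
        else:
            par2 = fit.params[1] if len(fit.params) > 1 else float("nan")
            rows.append({"parameter": name, "family": fit.family,
                         "par1": fit.params[0], "par2": par2})
    return pd.DataFrame(rows, columns=["parameter", "family", "par1", "par2"])


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------

_SETTING_DEFAULTS = {
    "discount_rate": {"point": 0.05, "low": 0.0, "high": 0.08},
    "start_age": 66.0,
    "horizon_years": 30.0,
    "cycle_length": 0.25,
    "wtp_1x": 89_358.0,
    "wtp_3x": 268_074.0,
}


def _require(mapping: Mapping, key: str, context: str):
    try:
        return mapping[key]
    except (KeyError, TypeError):
        raise ConfigurationError(f"missing required configuration key {context}.{key}") from None


def _quantity_from(entry, context: str) -> Quantity:
    if isinstance(entry, Mapping):
        point = _require(entry, "point", context)
        return Quantity(point, entry.get("low", point), entry.get("high", point))
    return Quantity.fixed(float(entry))


def load_parameters(config) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a configuration document.

    ``config`` may be a mapping, a YAML string, or a path to a YAML file.
    Missing optional settings fall back to the base-case defaults (5% annual
    discount, start age 66, 30-year horizon, 3-month cycles, Chinese per-capita
    GDP willingness-to-pay thresholds).
    """
    if isinstance(config, (str, bytes)) and "\n" not in str(config):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    elif isinstance(config, str):
        config = yaml.safe_load(config)
    if not isinstance(config, Mapping):
        raise ConfigurationError("configuration must be a mapping")

    mrs = _require(config, "mrs_distribution", "config")
    dist = MRSDistribution(
        _require(mrs, "point", "mrs_distribution"),
        mrs.get("low"),
        mrs.get("high"),
    )
    rrs = _require(config, "risk_ratios", "config")
    rr = RRVector(
        _require(rrs, "point", "risk_ratios"),
        _require(rrs, "low", "risk_ratios"),
        _require(rrs, "high", "risk_ratios"),
    )
    probs = _require(config, "probabilities", "config")
    quantities = {
        name: _quantity_from(_require(probs, name, "probabilities"), f"probabilities.{name}")
        for name in ("p_sich_argatroban", "p_sich_control", "annual_recurrence",
                     "recurrence_case_fatality")
    }
    hrs = _require(config, "hazard_ratios", "config")
    hr = HazardRatioVector(
        _require(hrs, "point", "hazard_ratios"),
        _require(hrs, "low", "hazard_ratios"),
        _require(hrs, "high", "hazard_ratios"),
    )
    bands = _require(config, "mortality_table", "config")
    mortality = MortalityTable(tuple(
        MortalityBand(
            float(_require(b, "age_low", "mortality_table")),
            None if b.get("age_high") is None else float(b["age_high"]),
            float(_require(b, "annual_probability", "mortality_table")),
        )
        for b in bands
    ))
    util = _require(config, "utilities", "config")
    u_point = _require(util, "point", "utilities")
    utilities = UtilityTable(
        u_point,
        util.get("low", u_point),
        util.get("high", u_point),
        _quantity_from(_require(util, "u_recurrence", "utilities"), "utilities.u_recurrence"),
        _quantity_from(_require(util, "sich_disutility", "utilities"), "utilities.sich_disutility"),
    )
    cost_cfg = _require(config, "costs", "config")
    costs = CostTable(**{
        field: _quantity_from(_require(cost_cfg, field, "costs"), f"costs.{field}")
        for field in _COST_FIELDS
    })
    settings = config.get("settings", {}) or {}
    dr_entry = settings.get("discount_rate", _SETTING_DEFAULTS["discount_rate"])
    return ParameterSet(
        control_mrs_dist=dist,
        rr=rr,
        hr=hr,
        mortality=mortality,
        costs=costs,
        utilities=utilities,
        discount_rate=_quantity_from(dr_entry, "settings.discount_rate"),
        start_age=float(settings.get("start_age", _SETTING_DEFAULTS["start_age"])),
        horizon_years=float(settings.get("horizon_years", _SETTING_DEFAULTS["horizon_years"])),
        cycle_length=float(settings.get("cycle_length", _SETTING_DEFAULTS["cycle_length"])),
        wtp_1x=float(settings.get("wtp_1x", _SETTING_DEFAULTS["wtp_1x"])),
        wtp_3x=float(settings.get("wtp_3x", _SETTING_DEFAULTS["wtp_3x"])),
        **quantities,
    )


def _quantity_dict(q: Quantity) -> dict:
    return {"point": q.value, "low": q.low, "high": q.high}


def parameters_to_dict(ps: ParameterSet) -> dict:
    """Serialize a ParameterSet back into the configuration-document shape."""
    return {
        "mrs_distribution": {
            "point": list(ps.control_mrs_dist.probs),
            "low": list(ps.control_mrs_dist.low),
            "high": list(ps.control_mrs_dist.high),
        },
        "risk_ratios": {
            "point": list(ps.rr.point), "low": list(ps.rr.low), "high": list(ps.rr.high),
        },
        "probabilities": {
            name: _quantity_dict(getattr(ps, name))
            for name in ("p_sich_argatroban", "p_sich_control", "annual_recurrence",
                         "recurrence_case_fatality")
        },
        "hazard_ratios": {
            "point": list(ps.hr.point), "low": list(ps.hr.low), "high": list(ps.hr.high),
        },
        "mortality_table": [
            {"age_low": b.age_low, "age_high": b.age_high,
             "annual_probability": b.annual_probability}
            for b in ps.mortality.bands
        ],
        "utilities": {
            "point": list(ps.utilities.u),
            "low": list(ps.utilities.u_low),
            "high": list(ps.utilities.u_high),
            "u_recurrence": _quantity_dict(ps.utilities.u_recurrence),
            "sich_disutility": _quantity_dict(ps.utilities.sich_disutility),
        },
        "costs": {field: _quantity_dict(getattr(ps.costs, field)) for field in _COST_FIELDS},
        "settings": {
            "discount_rate": _quantity_dict(ps.discount_rate),
            "start_age": ps.start_age,
            "horizon_years": ps.horizon_years,
            "cycle_length": ps.cycle_length,
            "wtp_1x": ps.wtp_1x,
            "wtp_3x": ps.wtp_3x,
        },
    }


def save_parameters(ps: ParameterSet, path) -> None:
    """Write a ParameterSet as YAML; a reload reproduces every value exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(parameters_to_dict(ps), fh, sort_keys=False)


def default_parameters() -> ParameterSet:
    """The bundled base-case parameter set (published Chinese inputs)."""
    ref = resources.files("strokecea").joinpath("data/default_ease_china.yaml")
    return load_parameters(yaml.safe_load(ref.read_text(encoding="utf-8")))
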