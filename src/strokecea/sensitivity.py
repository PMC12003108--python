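"""Sensitivity and scenario analyses.

One-way (tornado) analysis re-runs the deterministic model with each scalar
input pushed to the ends of its published range.  The probabilistic analysis
draws every stochastic input jointly from its fitted family (gamma costs,
beta probabilities/utilities, lognormal risk and hazard ratios, Dirichlet
mRS distribution), runs the full two-arm model per draw, and summarizes the
incremental cost-effectiveness cloud and acceptability curve.  Scenario runs
apply named overrides (drug price, start age, horizon, mortality table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._validate import ValidationError
from .cea import CEAResult, net_monetary_benefit, run_base_case
from .params import (
    MortalityTable,
    MRSDistribution,
    ParameterSet,
    get_scalar,
    psa_distributions,
    scalar_parameter_names,
    set_scalar,
)

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "one_way_sensitivity",
    "run_psa",
    "run_scenario",
    "DEFAULT_WTP_GRID",
]

#: CEAC evaluation grid: 0 to 300,000 CNY/QALY in 1,000-CNY steps
DEFAULT_WTP_GRID = np.arange(0, 300_001, 1000, dtype=float)


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the tornado diagram."""

    parameter: str
    low_value: float
    high_value: float
    icer_low: float        # ICER with the parameter at its low value
    icer_high: float
    width: float           # |icer_high - icer_low|
    crosses_sign: bool     # dominance/sign flip at an extreme
    delta_qaly_low: float
    delta_qaly_high: float


def one_way_sensitivity(params: ParameterSet) -> list[TornadoEntry]:
    """Tornado analysis over every scalar input that carries a range.

    Each parameter is set to its low then high value with everything else at
    the point estimates; entries are sorted by descending bar width.  The
    multinomial mRS distribution and the background life-table have no scalar
    range and are not varied.
    """
    base = run_base_case(params)
    entries = []
    for name in scalar_parameter_names():
        q = get_scalar(params, name)
        if q.width == 0.0:
            entries.append(TornadoEntry(name, q.low, q.high, base.icer, base.icer,
                                        0.0, False, base.delta_qaly, base.delta_qaly))
            continue
        res_low = run_base_case(set_scalar(params, name, q.low))
        res_high = run_base_case(set_scalar(params, name, q.high))
        crosses = (
            np.sign(res_low.delta_qaly) != np.sign(res_high.delta_qaly)
            or np.sign(res_low.delta_cost) != np.sign(res_high.delta_cost)
        )
        entries.append(TornadoEntry(
            name, q.low, q.high, res_low.icer, res_high.icer,
            abs(res_high.icer - res_low.icer), bool(crosses),
            res_low.delta_qaly, res_high.delta_qaly,
        ))
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def tornado_to_frame(entries: list[TornadoEntry]):
    import pandas as pd

    return pd.DataFrame([{
        "parameter": e.parameter, "low": e.low_value, "high": e.high_value,
        "icer_low": e.icer_low, "icer_high": e.icer_high, "width": e.width,
        "crosses_sign": e.crosses_sign,
    } for e in entries])


@dataclass
class PSAResult:
    """Monte-Carlo output: per-draw incremental pairs and their summaries."""

    n: int
    seed: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    wtp_grid: np.ndarray
    ceac: np.ndarray                 # P(NMB > 0) per grid point
    fraction_highly_ce: float        # P(NMB > 0) at the 1x-GDP threshold
    fraction_dominant: float
    n_rejected: int = 0

    def acceptability(self, wtp: float) -> float:
        return float(np.mean(
            net_monetary_benefit(self.delta_cost, self.delta_qaly, wtp) > 0
        ))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"draw": np.arange(self.n),
                             "delta_cost": self.delta_cost,
                             "delta_qaly": self.delta_qaly})

    def ceac_frame(self):
        import pandas as pd

        return pd.DataFrame({"wtp": self.wtp_grid, "probability": self.ceac})


def _draw_parameter_set(params: ParameterSet, fits, rng) -> ParameterSet:
    """One joint PSA draw; independent across parameters."""
    ps = params
    for name, fit in fits.items():
        if name == "control_mrs_dist":
            continue
        ps = set_scalar(ps, name, float(fit.rvs(rng)))
    mrs_fit = fits["control_mrs_dist"]
    if mrs_fit.family == "dirichlet":
        mrs = rng.dirichlet(mrs_fit.params)
        ps = ps.replace(control_mrs_dist=MRSDistribution.from_array(mrs, normalize=True))
    return ps


def run_psa(
    params: ParameterSet,
    n: int = 10_000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis with ``n`` Monte-Carlo draws.

    A single master seed spawns one substream per draw, so results are
    reproducible and independent of evaluation order.  Draws that violate a
    hard parameter invariant are rejected and redrawn (counted).
    """
    if n < 1:
        raise ValidationError("PSA requires at least one draw")
    if wtp_grid is None:
        wtp_grid = DEFAULT_WTP_GRID
    fits = psa_distributions(params)
    streams = np.random.SeedSequence(seed).spawn(n)
    dc = np.empty(n)
    dq = np.empty(n)
    rejected = 0
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        while True:
            try:
                ps = _draw_parameter_set(params, fits, rng)
                break
            except ValidationError:
                rejected += 1
        res = run_base_case(ps)
        dc[i] = res.delta_cost
        dq[i] = res.delta_qaly

    nmb_1x = net_monetary_benefit(dc, dq, params.wtp_1x)
    ceac = np.array([np.mean(net_monetary_benefit(dc, dq, w) > 0) for w in wtp_grid])
    return PSAResult(
        n=n, seed=seed, delta_cost=dc, delta_qaly=dq,
        wtp_grid=np.asarray(wtp_grid, dtype=float), ceac=ceac,
        fraction_highly_ce=float(np.mean(nmb_1x > 0)),
        fraction_dominant=float(np.mean((dc < 0) & (dq > 0))),
        n_rejected=rejected,
    )


_SCENARIO_KEYS = {"drug_price_per_mg", "start_age", "horizon_years", "mortality_table"}


def run_scenario(params: ParameterSet, **overrides) -> CEAResult:
    """Deterministic run with named overrides applied.

    Supported overrides: ``drug_price_per_mg`` (CNY/mg), ``start_age``
    (years; the mortality table must cover the shifted age span),
    ``horizon_years``, and ``mortality_table`` (a :class:`MortalityTable`,
    enabling sex-specific or younger-cohort scenarios).
    """
    unknown = set(overrides) - _SCENARIO_KEYS
    if unknown:
        raise KeyError(f"unknown scenario override(s): {sorted(unknown)}")
    ps = params
    if "mortality_table" in overrides:
        table = overrides["mortality_table"]
        if not isinstance(table, MortalityTable):
            table = MortalityTable(tuple(table))
        ps = ps.replace(mortality=table)
    if "drug_price_per_mg" in overrides:
        ps = set_scalar(ps, "cost_drug_price_per_mg", float(overrides["drug_price_per_mg"]))
    replacements = {}
    if "start_age" in overrides:
        replacements["start_age"] = float(overrides["start_age"])
    if "horizon_years" in overrides:
        replacements["horizon_years"] = float(overrides["horizon_years"])
    if replacements:
        ps = ps.replace(**replacements)  # re-validates mortality coverage
    return run_base_case(ps)
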