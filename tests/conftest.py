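import numpy as np
import pytest

import strokecea as sc
from strokecea.params import parameters_to_dict, load_parameters


@pytest.fixture(scope="session")
def params():
    """Bundled base-case parameter set."""
    return sc.default_parameters()


@pytest.fixture(scope="session")
def base_result(params):
    """Deterministic base-case two-arm comparison (computed once)."""
    return sc.run_base_case(params)


@pytest.fixture(scope="session")
def degenerate_params(params):
    """Base-case values with every range collapsed to the point estimate."""
    doc = parameters_to_dict(params)
    for section in ("mrs_distribution", "risk_ratios", "hazard_ratios", "utilities"):
        doc[section]["low"] = list(doc[section]["point"])
        doc[section]["high"] = list(doc[section]["point"])
    for section in ("probabilities", "costs"):
        for entry in doc[section].values():
            entry["low"] = entry["point"]
            entry["high"] = entry["point"]
    for name in ("u_recurrence", "sich_disutility"):
        doc["utilities"][name]["low"] = doc["utilities"][name]["point"]
        doc["utilities"][name]["high"] = doc["utilities"][name]["point"]
    dr = doc["settings"]["discount_rate"]
    dr["low"] = dr["high"] = dr["point"]
    return load_parameters(doc)


def microsimulate(initial, params, n_cycles, n_walkers, seed):
    """Individual-level oracle: simulate walkers through the per-cycle
    transition matrices and return state occupancy after each cycle."""
    from strokecea.transitions import build_transition_matrix

    rng = np.random.default_rng(seed)
    state = rng.choice(7, size=n_walkers, p=np.asarray(initial, dtype=float))
    occ = np.zeros((n_cycles, 7))
    for t in range(1, n_cycles + 1):
        age = params.start_age + params.cycle_length * t
        cum = np.cumsum(build_transition_matrix(age, params), axis=1)
        u = rng.random(n_walkers)
        state = (u[:, None] > cum[state]).sum(axis=1)
        occ[t - 1] = np.bincount(state, minlength=7) / n_walkers
    return occ
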