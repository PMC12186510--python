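import numpy as np
import pytest

import mibcsim as m
from mibcsim.model import HealthState, StrategyModel, TransitionRule
from mibcsim.parameters import Parameter, ParameterSet


@pytest.fixture(scope="session")
def default_params() -> ParameterSet:
    return m.generate_parameter_set()


@pytest.fixture(scope="session")
def models() -> tuple[StrategyModel, StrategyModel]:
    """(reference, comparator) = (RC, TMT)."""
    return m.build_rc_model(), m.build_tmt_model()


@pytest.fixture(scope="session")
def calibration(default_params):
    """Calibration of the shipped defaults to the published 5-y base case."""
    return m.calibrate(default_params)


@pytest.fixture(scope="session")
def calibrated(calibration) -> ParameterSet:
    return calibration[1]


def make_param(key, kind, base, low=None, high=None, **kw) -> Parameter:
    low = base if low is None else low
    high = base if high is None else high
    return Parameter(key=key, kind=kind, base=base, low=low, high=high, **kw)


def two_state_model(name="toy") -> StrategyModel:
    """Alive -> death chain: per-cycle cost/utility while alive."""
    return StrategyModel(
        name=name,
        states=(
            HealthState("alive", utility_key="u_alive", cost_keys=(("c_alive", 1.0),)),
            HealthState("death", absorbing=True),
        ),
        rules=(TransitionRule("alive", "death", "p_die"),),
        entry_state="alive",
    )


def two_state_params(p_die, cost, utility=1.0, discount=0.0, horizon=0.75) -> ParameterSet:
    return ParameterSet(
        entries={
            "p_die": make_param("p_die", "probability", p_die, 0.0, 1.0, distribution="beta"),
            "c_alive": make_param("c_alive", "cost", cost, distribution="fixed"),
            "u_alive": make_param("u_alive", "utility", utility, distribution="fixed"),
        },
        discount_rate=discount,
        horizon_years=horizon,
    )


def random_chain_model(rng: np.random.Generator, n_states: int):
    """Random acyclic-ish chain with tolls, for cohort-vs-microsim property tests."""
    names = [f"s{i}" for i in range(n_states)] + ["death"]
    states, entries, rules = [], {}, []
    for i, name in enumerate(names[:-1]):
        u_key, c_key = f"u{i}", f"c{i}"
        entries[u_key] = make_param(u_key, "utility", float(rng.uniform(0.3, 1.0)),
                                    distribution="fixed")
        entries[c_key] = make_param(c_key, "cost", float(rng.uniform(0, 5000)),
                                    distribution="fixed")
        tolls = ()
        if i > 0 and rng.random() < 0.5:
            t_key = f"t{i}"
            entries[t_key] = make_param(t_key, "toll_cost", float(rng.uniform(0, 2000)),
                                        distribution="fixed")
            tolls = (t_key,)
        states.append(HealthState(name, utility_key=u_key, cost_keys=((c_key, 1.0),),
                                  entry_toll_keys=tolls))
        # forward transitions plus death; residual mass stays
        budget = 0.8
        for j in range(i + 1, len(names)):
            p_key = f"p{i}_{j}"
            p = float(rng.uniform(0, budget / (len(names) - i)))
            entries[p_key] = make_param(p_key, "probability", p, distribution="fixed")
            window = (0, int(rng.integers(1, 4))) if rng.random() < 0.3 else None
            rules.append(TransitionRule(name, names[j], p_key, window=window))
    states.append(HealthState("death", absorbing=True))
    model = StrategyModel(name="random", states=tuple(states), rules=tuple(rules),
                          entry_state="s0")
    params = ParameterSet(entries=entries, discount_rate=0.03, horizon_years=3.0)
    return model, params
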