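"""Independent individual-level microsimulation oracle.

Steps individual patients through the same transition matrix and reward
rules as the cohort engine, by brute-force simulation of each patient's
state path.  The cohort model's aggregates are expectations of this
process, so the two must agree within Monte Carlo error.  Deliberately
written without reusing the cohort engine's accrual code.
"""

from __future__ import annotations

import numpy as np

from mrcc_cea.parameters import ModelSettings, StrategyParameters


def microsimulate(
    strategy: StrategyParameters,
    settings: ModelSettings,
    n_patients: int,
    seed: int,
) -> dict[str, tuple[float, float]]:
    """Mean and standard error of discounted LY, QALY and cost per patient.

    Supports the 'begin' state-counting convention and the 'per_cycle' or
    'one_time' adverse-event disutility modes (the conventions under test).
    """
    if settings.state_counting != "begin":
        raise NotImplementedError("oracle implements begin-of-cycle counting only")
    rng = np.random.default_rng(seed)
    p = strategy.transitions
    horizon = settings.horizon_cycles
    rate = settings.cycle_discount
    discount = (1.0 + rate) ** (-np.arange(1, horizon + 1, dtype=float))
    ypc = settings.years_per_cycle

    has_ae = rng.random(n_patients) < strategy.ae_rate
    u = strategy.utilities
    if settings.ae_disutility_mode == "per_cycle":
        u_stable = np.where(has_ae, max(u.stable - u.ae_disutility, 0.0), u.stable)
    elif settings.ae_disutility_mode == "one_time":
        u_stable = np.full(n_patients, u.stable)
    else:
        raise NotImplementedError(settings.ae_disutility_mode)

    c = strategy.costs
    stable_cost = c.drug + c.tests + c.outpatient + c.adverse_events + c.societal
    progressive_cost = c.progressive_state
    if settings.societal_cost_in_progressive:
        progressive_cost += c.societal
    if settings.treatment_cost_in_progressive:
        progressive_cost += c.drug + c.tests + c.outpatient

    state = np.zeros(n_patients, dtype=np.int8)  # 0 stable, 1 progressive, 2 dead
    ly = np.zeros(n_patients)
    qaly = np.zeros(n_patients)
    cost = np.zeros(n_patients)
    for t in range(1, horizon + 1):
        stable = state == 0
        progressive = state == 1
        d = discount[t - 1]
        ly += (stable | progressive) * ypc * d
        qaly += (stable * u_stable + progressive * u.progressive) * ypc * d
        cost += (stable * stable_cost + progressive * progressive_cost) * d
        draw = rng.random(n_patients)
        to_prog = stable & (draw < p.stable_to_progressive)
        to_dead_s = stable & ~to_prog & (draw < p.stable_to_progressive + p.stable_to_dead)
        to_dead_p = progressive & (draw < p.progressive_to_dead)
        state[to_prog] = 1
        state[to_dead_s | to_dead_p] = 2
    if settings.ae_disutility_mode == "one_time":
        qaly -= has_ae * u.ae_disutility

    out = {}
    for name, values in (("life_years", ly), ("qalys", qaly), ("total_cost", cost)):
        out[name] = (float(values.mean()), float(values.std(ddof=1) / np.sqrt(n_patients)))
    return out
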