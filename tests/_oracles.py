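"""Independent oracles used by the test suite.

These deliberately re-derive quantities by brute force — exhaustive path
enumeration for the cohort process, fine-grid Riemann sums for step-function
integrals, explicit per-cycle accumulation for restricted mean survival —
and never call the code paths they check.
"""

from __future__ import annotations

import math

import numpy as np

CYCLE = 0.25


def brute_force_rmst(qx_by_age, start_age: float, horizon_years: float) -> float:
    """Per-cycle survival accumulation from a dict age -> annual qx."""
    n = int(round(horizon_years / CYCLE))
    surv = 1.0
    total = 0.0
    for t in range(n):
        total += surv * CYCLE
        q = qx_by_age[math.floor(start_age + t * CYCLE)]
        surv *= (1.0 - q) ** CYCLE
    return total


def grid_step_integral(times, survival, t0, t1, dx=1e-4):
    """Riemann-sum integral of a right-continuous step function."""
    times = np.asarray(times, float)
    survival = np.asarray(survival, float)
    xs = np.arange(t0, t1, dx)
    idx = np.searchsorted(times, xs, side="right") - 1
    return float(survival[idx].sum() * dx)


def path_enumeration_trace(config):
    """Exhaustive path enumeration of the cohort process.

    Walks every possible individual trajectory through the state tree,
    multiplying branch probabilities, and accumulates occupancy at each
    cycle boundary plus incident progression fractions.  Exponential in the
    number of cycles — intended for horizons of a few cycles only.

    Conventions mirrored (independently) from the model description:
    complication-free persons are allocated low/high at each cycle start
    with the trajectory proportion, face a multinomial split over
    {AL, MF, thrombosis, background death, stay}, and anyone occupying a
    progression state at a cycle start faces that state's mortality (so a
    new entrant is first at risk the cycle after entry).
    """
    from pvmarkov.engine import State
    from pvmarkov.life_table import cycle_death_prob

    T = config.n_cycles
    occupancy = np.zeros((T + 1, 6))
    new_events = np.zeros((T, 3))
    prog_states = (State.AL, State.MF, State.THROMBOSIS)

    def record(t, state, mass):
        if state == "P1":
            ph = config.proportion_high(t)
            occupancy[t, State.LOW_JAK2] += mass * (1.0 - ph)
            occupancy[t, State.HIGH_JAK2] += mass * ph
        else:
            occupancy[t, state] += mass

    def visit(t, state, mass):
        record(t, state, mass)
        if t == T or mass == 0.0:
            return
        if state == "P1":
            ph = config.proportion_high(t)
            age = config.start_age + t * CYCLE
            q_bg = cycle_death_prob(config.life_table, age)
            for is_high, p_group in ((False, 1.0 - ph), (True, ph)):
                p_al, p_mf, p_th = config.risk_set.progression_probs(is_high)
                exits = {State.AL: p_al, State.MF: p_mf, State.THROMBOSIS: p_th}
                for k, s in enumerate(prog_states):
                    new_events[t, k] += mass * p_group * exits[s]
                    visit(t + 1, s, mass * p_group * exits[s])
                visit(t + 1, State.DEAD, mass * p_group * q_bg)
                stay = 1.0 - p_al - p_mf - p_th - q_bg
                visit(t + 1, "P1", mass * p_group * stay)
        elif state == State.DEAD:
            visit(t + 1, State.DEAD, mass)
        else:
            m = config.risk_set.mortality(state)
            visit(t + 1, State.DEAD, mass * m)
            visit(t + 1, state, mass * (1.0 - m))

    visit(0, "P1", 1.0)
    return occupancy, new_events
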