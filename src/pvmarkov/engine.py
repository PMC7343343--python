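"""Deterministic Markov cohort engine.

Six health states, 13-week cycles.  The complication-free phase holds two
states split by JAK2 allele burden (< 50% vs >= 50%); progression states are
acute leukemia, myelofibrosis and thrombosis; death is absorbing.

Each cycle, every complication-free state is split multinomially between
staying, the three progression events and background (general-population)
death, with the stay probability ``1 - sum(exits)`` — the supplied cycle
probabilities are used directly, not added as rates.  Progression states
carry their complication-specific mortality, independent of age; by default
a patient entering a progression state is first exposed to that mortality in
the following cycle.  After the transitions, the surviving complication-free
mass is re-split between the low- and high-burden states to track the
cohort-level JAK2 trajectory.  The engine contains no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
import pandas as pd

from .conversions import CYCLE_YEARS
from .life_table import LifeTable, cycle_death_prob
from .trajectory import Jak2Trajectory


class State(IntEnum):
    LOW_JAK2 = 0
    HIGH_JAK2 = 1
    AL = 2
    MF = 3
    THROMBOSIS = 4
    DEAD = 5


#: Progression states, in the order used by ``new_events`` columns.
PROGRESSION_STATES = (State.AL, State.MF, State.THROMBOSIS)

N_STATES = len(State)


class ConfigurationError(ValueError):
    """Raised when a model configuration cannot produce a valid transition."""


@dataclass(frozen=True)
class RiskSet:
    """Per-cycle progression and complication-mortality probabilities.

    The leukemia risk is a single value applied to both burden groups (no
    evidence links allele burden to leukemic transformation); myelofibrosis
    and thrombosis risks differ by group.  ``sources`` optionally records
    the literature source behind each entry.
    """

    p_thrombosis_low: float
    p_thrombosis_high: float
    p_al: float
    p_mf_low: float
    p_mf_high: float
    m_thrombosis: float
    m_al: float
    m_mf: float
    sources: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "p_thrombosis_low", "p_thrombosis_high", "p_al",
            "p_mf_low", "p_mf_high", "m_thrombosis", "m_al", "m_mf",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {v!r}")

    def progression_probs(self, high: bool) -> tuple[float, float, float]:
        """(AL, MF, thrombosis) cycle probabilities for one burden group."""
        if high:
            return self.p_al, self.p_mf_high, self.p_thrombosis_high
        return self.p_al, self.p_mf_low, self.p_thrombosis_low

    def mortality(self, state: State) -> float:
        return {
            State.AL: self.m_al,
            State.MF: self.m_mf,
            State.THROMBOSIS: self.m_thrombosis,
        }[state]


@dataclass(frozen=True)
class ModelConfig:
    """Complete specification of one cohort run.

    Exactly one of ``trajectory`` or ``fixed_group`` chooses the JAK2
    allocation; ``fixed_group`` keeps the whole complication-free cohort in
    one burden group throughout (the subgroup analyses).
    """

    start_age: float
    horizon_years: float
    risk_set: RiskSet
    life_table: LifeTable
    trajectory: Jak2Trajectory | None = None
    fixed_group: str | None = None  # "ALL_LOW" | "ALL_HIGH"
    half_cycle_correction: bool = False
    same_cycle_progression_death: bool = False
    phase2_background_floor: bool = False

    def __post_init__(self) -> None:
        n = self.horizon_years / CYCLE_YEARS
        if self.horizon_years < 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"horizon must be a whole number of 13-week cycles; got {self.horizon_years}"
            )
        if (self.trajectory is None) == (self.fixed_group is None):
            raise ValueError("provide exactly one of trajectory or fixed_group")
        if self.fixed_group is not None and self.fixed_group not in ("ALL_LOW", "ALL_HIGH"):
            raise ValueError(f"fixed_group must be 'ALL_LOW' or 'ALL_HIGH'; got {self.fixed_group!r}")
        last_age = self.start_age + max(self.n_cycles - 1, 0) * CYCLE_YEARS
        if self.start_age < self.life_table.min_age or last_age > self.life_table.max_age + 1:
            raise ValueError(
                f"ages {self.start_age}..{last_age:.2f} not covered by life table "
                f"[{self.life_table.min_age}, {self.life_table.max_age}]"
            )

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / CYCLE_YEARS))

    def proportion_high(self, cycle: int) -> float:
        if self.fixed_group is not None:
            return 1.0 if self.fixed_group == "ALL_HIGH" else 0.0
        return self.trajectory.proportion_at(cycle)

    def with_(self, **changes) -> "ModelConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy per cycle plus incident progression events.

    ``occupancy`` has ``n_cycles + 1`` rows over the six states;
    ``new_events[t]`` holds the fractions newly entering (AL, MF,
    thrombosis) during cycle ``t`` (between rows ``t`` and ``t + 1``).
    """

    occupancy: np.ndarray
    new_events: np.ndarray
    start_age: float
    config: ModelConfig | None = None

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + CYCLE_YEARS * np.arange(self.occupancy.shape[0])

    @property
    def times(self) -> np.ndarray:
        return CYCLE_YEARS * np.arange(self.occupancy.shape[0])

    def to_frame(self) -> pd.DataFrame:
        T = self.n_cycles
        new = np.zeros((T + 1, 3))
        new[1:] = self.new_events  # events during cycle t land on row t+1
        return pd.DataFrame(
            {
                "cycle": np.arange(T + 1),
                "age": self.ages,
                "low": self.occupancy[:, State.LOW_JAK2],
                "high": self.occupancy[:, State.HIGH_JAK2],
                "al": self.occupancy[:, State.AL],
                "mf": self.occupancy[:, State.MF],
                "thrombosis": self.occupancy[:, State.THROMBOSIS],
                "dead": self.occupancy[:, State.DEAD],
                "new_al": new[:, 0],
                "new_mf": new[:, 1],
                "new_thrombosis": new[:, 2],
            }
        )


def _phase1_exit_probs(config: ModelConfig, high: bool, cycle: int) -> np.ndarray:
    """(AL, MF, thrombosis, background death) exits for one burden group."""
    age = config.start_age + cycle * CYCLE_YEARS
    p_al, p_mf, p_th = config.risk_set.progression_probs(high)
    q_bg = cycle_death_prob(config.life_table, age)
    probs = np.array([p_al, p_mf, p_th, q_bg])
    total = probs.sum()
    if total > 1.0:
        name = State.HIGH_JAK2.name if high else State.LOW_JAK2.name
        raise ConfigurationError(
            f"exit probabilities from {name} sum to {total:.6g} > 1 at cycle {cycle}"
        )
    return probs


def step(occupancy: np.ndarray, cycle: int, config: ModelConfig):
    """Advance the cohort one cycle.

    Returns ``(occupancy', new_events)`` where ``new_events`` holds the
    incident (AL, MF, thrombosis) fractions of this cycle.
    """
    occ = np.asarray(occupancy, dtype=float)
    low, high = occ[State.LOW_JAK2], occ[State.HIGH_JAK2]
    exits_low = _phase1_exit_probs(config, high=False, cycle=cycle)
    exits_high = _phase1_exit_probs(config, high=True, cycle=cycle)

    new_events = low * exits_low[:3] + high * exits_high[:3]
    bg_deaths = low * exits_low[3] + high * exits_high[3]
    stayers = low * (1.0 - exits_low.sum()) + high * (1.0 - exits_high.sum())

    # Complication-specific mortality in the progression states.  With the
    # default convention, this cycle's entrants are exposed from next cycle.
    new_occ = np.zeros(N_STATES)
    prog_deaths = 0.0
    for k, state in enumerate(PROGRESSION_STATES):
        m = config.risk_set.mortality(state)
        if config.phase2_background_floor:
            age = config.start_age + cycle * CYCLE_YEARS
            q_bg = cycle_death_prob(config.life_table, age)
            m = 1.0 - (1.0 - m) * (1.0 - q_bg)
        at_risk = occ[state] + (new_events[k] if config.same_cycle_progression_death else 0.0)
        prog_deaths += at_risk * m
        new_occ[state] = occ[state] + new_events[k] - at_risk * m

    # Re-allocate surviving complication-free mass to the target JAK2 split.
    p_high = config.proportion_high(cycle + 1)
    new_occ[State.LOW_JAK2] = stayers * (1.0 - p_high)
    new_occ[State.HIGH_JAK2] = stayers * p_high
    new_occ[State.DEAD] = occ[State.DEAD] + bg_deaths + prog_deaths
    return new_occ, new_events


def run(config: ModelConfig) -> CohortTrace:
    """Run the cohort over the full horizon.  Bit-deterministic."""
    T = config.n_cycles
    occupancy = np.zeros((T + 1, N_STATES))
    p0 = config.proportion_high(0)
    occupancy[0, State.LOW_JAK2] = 1.0 - p0
    occupancy[0, State.HIGH_JAK2] = p0
    new_events = np.zeros((T, 3))
    for t in range(T):
        occupancy[t + 1], new_events[t] = step(occupancy[t], t, config)
    return CohortTrace(
        occupancy=occupancy,
        new_events=new_events,
        start_age=config.start_age,
        config=config,
    )


def cumulative_incidence(trace: CohortTrace, state: State) -> float:
    """Fraction of the cohort ever entering a progression state.

    Progression states are absorbing apart from death, so summing incident
    entries never double-counts.
    """
    if state not in PROGRESSION_STATES:
        raise ValueError(f"cumulative incidence is defined for progression states, not {state!r}")
    return float(trace.new_events[:, PROGRESSION_STATES.index(state)].sum())
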