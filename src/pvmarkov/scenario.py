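"""Risk-source catalog and scenario (sensitivity) analysis.

Every transition in the model has one or more published sources for its
cycle probability, with one source flagged as the base case.  The scenario
analysis enumerates the full Cartesian product of source choices — with the
shipped catalog, 2 x 2 x 3 (progression) times 2 x 5 x 3 (mortality) = 360
risk sets — reruns the cohort under each, and reports the spread of
restricted mean overall survival.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .conversions import CYCLE_YEARS
from .engine import ModelConfig, RiskSet, run
from .survival import os_curve, restricted_auc

#: Transition slots, in enumeration order.
SLOTS = (
    "thrombosis",
    "leukemia",
    "myelofibrosis",
    "mortality_thrombosis",
    "mortality_leukemia",
    "mortality_myelofibrosis",
)


@dataclass(frozen=True)
class RiskAlternative:
    """One published source for one transition's cycle probability."""

    source: str
    low: float
    high: float
    base_case: bool = False

    def __post_init__(self) -> None:
        for v in (self.low, self.high):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"cycle probability must lie in [0, 1]; got {v!r}")


@dataclass(frozen=True)
class RiskCatalog:
    """Alternatives per transition slot; exactly one base case in each."""

    alternatives: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(SLOTS) - set(self.alternatives)
        if missing:
            raise ValueError(f"catalog lacks transition slots {sorted(missing)}")
        for slot in SLOTS:
            alts = self.alternatives[slot]
            if not alts:
                raise ValueError(f"slot {slot!r} has no alternatives")
            n_base = sum(a.base_case for a in alts)
            if n_base != 1:
                raise ValueError(
                    f"slot {slot!r} must flag exactly one base-case source; found {n_base}"
                )

    @property
    def n_combinations(self) -> int:
        out = 1
        for slot in SLOTS:
            out *= len(self.alternatives[slot])
        return out


def _risk_set_from_choice(choice: dict) -> RiskSet:
    th, al, mf = choice["thrombosis"], choice["leukemia"], choice["myelofibrosis"]
    m_th, m_al, m_mf = (
        choice["mortality_thrombosis"],
        choice["mortality_leukemia"],
        choice["mortality_myelofibrosis"],
    )
    return RiskSet(
        p_thrombosis_low=th.low,
        p_thrombosis_high=th.high,
        p_al=al.low,
        p_mf_low=mf.low,
        p_mf_high=mf.high,
        m_thrombosis=m_th.low,
        m_al=m_al.low,
        m_mf=m_mf.low,
        sources={slot: choice[slot].source for slot in SLOTS},
    )


#: Published per-cycle risks: progression to thrombosis / leukemia /
#: myelofibrosis for the two burden groups and mortality within each
#: progression state.  One source per slot is flagged as the base case.
DEFAULT_RISK_CATALOG = RiskCatalog(
    alternatives={
        "thrombosis": [
            RiskAlternative("Alvarez-Larran 2014", 0.004, 0.009, base_case=True),
            RiskAlternative("Vannuchi 2007", 0.005, 0.016),
        ],
        "leukemia": [
            RiskAlternative("Finazzi 2005", 0.00073, 0.00073, base_case=True),
            RiskAlternative("Tefferi 2013", 0.00058, 0.00058),
        ],
        "myelofibrosis": [
            RiskAlternative("Alvarez-Larran 2014", 0.0003, 0.007, base_case=True),
            RiskAlternative("Bai 2015", 0.0003, 0.002),
            RiskAlternative("Passamonti 2010", 0.0006, 0.007),
        ],
        "mortality_thrombosis": [
            RiskAlternative("Marchioli 2005", 0.018, 0.018, base_case=True),
            RiskAlternative("Di Veroli 2018", 0.012, 0.012),
        ],
        "mortality_leukemia": [
            RiskAlternative("Chihara 2016", 0.26, 0.26, base_case=True),
            RiskAlternative("Juliusson 2009", 0.16, 0.16),
            RiskAlternative("Kennedy 2013", 0.27, 0.27),
            RiskAlternative("Lancman 2018", 0.30, 0.30),
            RiskAlternative("Passamonti 2005", 0.51, 0.51),
        ],
        "mortality_myelofibrosis": [
            RiskAlternative("Passamonti 2017", 0.021, 0.021, base_case=True),
            RiskAlternative("Cervantes 2009", 0.029, 0.029),
            RiskAlternative("Masarova 2017", 0.042, 0.042),
        ],
    }
)


def base_case_risk_set(catalog: RiskCatalog = DEFAULT_RISK_CATALOG) -> RiskSet:
    """The risk set formed by each slot's base-case source."""
    choice = {
        slot: next(a for a in catalog.alternatives[slot] if a.base_case)
        for slot in SLOTS
    }
    return _risk_set_from_choice(choice)


def enumerate_risk_sets(catalog: RiskCatalog = DEFAULT_RISK_CATALOG) -> list[RiskSet]:
    """Cartesian product of source choices, in catalog row order."""
    out = []
    for combo in itertools.product(*(catalog.alternatives[s] for s in SLOTS)):
        out.append(_risk_set_from_choice(dict(zip(SLOTS, combo))))
    return out


def _os_of(config: ModelConfig, _cache: dict = {}) -> float:
    key = (
        id(config.life_table),
        None if config.trajectory is None else id(config.trajectory),
        config.fixed_group,
        config.start_age,
        config.horizon_years,
        config.half_cycle_correction,
        config.same_cycle_progression_death,
        config.phase2_background_floor,
        tuple(
            getattr(config.risk_set, f)
            for f in (
                "p_thrombosis_low", "p_thrombosis_high", "p_al",
                "p_mf_low", "p_mf_high", "m_thrombosis", "m_al", "m_mf",
            )
        ),
    )
    if key not in _cache:
        _cache[key] = restricted_auc(
            os_curve(run(config)),
            0.0,
            config.horizon_years,
            half_cycle=config.half_cycle_correction,
        )
    return _cache[key]


def scenario_table(
    config: ModelConfig, catalog: RiskCatalog = DEFAULT_RISK_CATALOG
) -> pd.DataFrame:
    """One row per risk-set combination: source choices and resulting OS.

    All runs share the configuration's age, trajectory and horizon; only the
    risk set varies.
    """
    rows = []
    for risk_set in enumerate_risk_sets(catalog):
        os_ly = _os_of(config.with_(risk_set=risk_set))
        row = {slot: risk_set.sources[slot] for slot in SLOTS}
        row["os_ly"] = os_ly
        rows.append(row)
    return pd.DataFrame(rows)


def os_range(
    config: ModelConfig, catalog: RiskCatalog = DEFAULT_RISK_CATALOG
) -> tuple[float, float, float]:
    """(min, max, base-case) 20-year mean OS across the risk enumeration."""
    table = scenario_table(config, catalog)
    base = _os_of(config.with_(risk_set=base_case_risk_set(catalog)))
    return float(table["os_ly"].min()), float(table["os_ly"].max()), base
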