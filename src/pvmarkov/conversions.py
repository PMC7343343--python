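"""Rate / probability / cumulative-incidence conversions.

All transition parameters in the cohort model are probabilities per 13-week
cycle (0.25 years).  Published sources report risks on heterogeneous scales
— cumulative incidences over a follow-up window, annual rates, annual
probabilities — and everything is mapped onto the cycle scale under a
constant-hazard (exponential) assumption:

    cumulative incidence P over t years  ->  annual rate r = -ln(1 - P) / t
    annual rate r, cycle length dt       ->  cycle probability p = 1 - exp(-r dt)
    annual probability q                 ->  cycle probability 1 - (1 - q)^dt

Probabilities are stored as fractions in [0, 1]; percentage formatting is an
I/O concern only.
"""

from __future__ import annotations

import math

#: Length of one model cycle in years (13 weeks out of 52).
CYCLE_YEARS: float = 13.0 / 52.0


def annual_rate_from_cumulative(proportion: float, horizon_years: float) -> float:
    """Annual event rate implied by a cumulative incidence over a horizon.

    Parameters
    ----------
    proportion
        Cumulative incidence as a fraction in [0, 1).  A proportion of 1
        implies an infinite rate and is rejected.
    horizon_years
        Length of the observation window in years (> 0).

    Returns
    -------
    float
        Constant hazard r (events per person-year) such that
        ``1 - exp(-r * horizon_years) == proportion``.
    """
    if not 0.0 <= proportion < 1.0:
        raise ValueError(
            f"cumulative incidence must lie in [0, 1); got {proportion!r}"
        )
    if not horizon_years > 0.0:
        raise ValueError(f"horizon must be positive; got {horizon_years!r}")
    return -math.log1p(-proportion) / horizon_years


def prob_from_rate(rate: float, dt_years: float = CYCLE_YEARS) -> float:
    """Transition probability over ``dt_years`` under a constant hazard."""
    if rate < 0.0:
        raise ValueError(f"rate must be non-negative; got {rate!r}")
    if not dt_years > 0.0:
        raise ValueError(f"dt must be positive; got {dt_years!r}")
    return -math.expm1(-rate * dt_years)


def rate_from_prob(prob: float, dt_years: float = CYCLE_YEARS) -> float:
    """Constant hazard implied by a transition probability over ``dt_years``.

    Inverse of :func:`prob_from_rate`.
    """
    if not 0.0 <= prob < 1.0:
        raise ValueError(f"probability must lie in [0, 1); got {prob!r}")
    if not dt_years > 0.0:
        raise ValueError(f"dt must be positive; got {dt_years!r}")
    return -math.log1p(-prob) / dt_years


def annual_prob_to_cycle_prob(q: float, dt_years: float = CYCLE_YEARS) -> float:
    """Convert an annual probability to a per-cycle probability.

    Uses ``p = 1 - (1 - q)**dt``, the standard actuarial sub-division of an
    annual death probability; identical to routing through
    :func:`rate_from_prob` / :func:`prob_from_rate` but well defined at
    ``q == 1`` (certain within the year implies certain within the cycle
    under a constant hazard).
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"annual probability must lie in [0, 1]; got {q!r}")
    if q == 1.0:
        return 1.0
    return -math.expm1(dt_years * math.log1p(-q))
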