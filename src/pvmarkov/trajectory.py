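"""JAK2 V617F allele-burden trajectories.

The engine tracks the complication-free cohort as two pooled groups, below
and at-or-above 50% allele burden.  What it needs per cycle is the
proportion of that pool in the high-burden group.  The reference trajectory
emulates the hydroxyurea arm of a three-year randomized trial: mean burden
42.8% at baseline, a modest cytoreductive response over the first twelve
cycles (156 weeks), and — because nothing is observed beyond week 156 — a
constant level thereafter.

Two constructors are provided.  :func:`synthesize_trajectory` works directly
in proportion space.  :func:`trajectory_from_mean_burden` works in burden
space and maps the mean to a proportion through a Normal cross-sectional
burden distribution with fixed dispersion; trajectories built this way carry
their mean-burden path, which lets a study-baseline adjustment rescale the
mean and recover the (nonlinear) proportion response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

#: Cycle index of week 156; burden is held constant from here on.
PLATEAU_CYCLE: int = 12

#: Baseline mean allele burden (%) of the reference trial arm.
BASELINE_MEAN_BURDEN: float = 42.8

#: Mean burden (%) reached at week 156 in the shipped reference trajectory.
DEFAULT_PLATEAU_BURDEN: float = 37.0

#: Cross-sectional standard deviation (percentage points) of allele burden
#: across patients, used to map a cohort mean to a proportion >= 50%.
DEFAULT_BURDEN_SD: float = 20.0

#: Dichotomisation threshold (%).
HIGH_BURDEN_THRESHOLD: float = 50.0


def proportion_above_threshold(mean_burden, sd: float = DEFAULT_BURDEN_SD):
    """P(burden >= 50%) for a Normal burden distribution with given mean."""
    return norm.sf((HIGH_BURDEN_THRESHOLD - np.asarray(mean_burden, float)) / sd)


def mean_burden_from_proportion(prop_high: float, sd: float = DEFAULT_BURDEN_SD) -> float:
    """Inverse of :func:`proportion_above_threshold` (Normal model)."""
    if not 0.0 < prop_high < 1.0:
        raise ValueError(f"proportion must lie in (0, 1); got {prop_high!r}")
    return float(HIGH_BURDEN_THRESHOLD - sd * norm.isf(prop_high))


@dataclass(frozen=True)
class Jak2Trajectory:
    """Per-cycle proportion of the complication-free pool with burden >= 50%.

    ``proportion_high[k]`` applies at cycle ``k``; cycles beyond the stored
    range repeat the final value (the week-156 constancy rule).  When the
    trajectory was built from a mean-burden path, ``mean_burden`` and
    ``burden_sd`` record it so baseline adjustments can act on the mean.
    """

    proportion_high: np.ndarray
    mean_burden: np.ndarray | None = None
    burden_sd: float | None = None
    label: str = "trajectory"

    def __post_init__(self) -> None:
        p = np.asarray(self.proportion_high, dtype=float)
        object.__setattr__(self, "proportion_high", p)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("trajectory needs a non-empty 1-d proportion array")
        if np.any((p < 0.0) | (p > 1.0)) or not np.all(np.isfinite(p)):
            raise ValueError("trajectory proportions must lie in [0, 1]")
        if self.mean_burden is not None:
            m = np.asarray(self.mean_burden, dtype=float)
            object.__setattr__(self, "mean_burden", m)
            if m.shape != p.shape:
                raise ValueError("mean_burden path must match proportion path in length")
            if self.burden_sd is None or not self.burden_sd > 0.0:
                raise ValueError("a mean-burden path requires a positive burden_sd")

    def proportion_at(self, cycle: int) -> float:
        """Proportion high at ``cycle``, constant beyond the stored range."""
        if cycle < 0:
            raise ValueError(f"cycle must be non-negative; got {cycle}")
        idx = min(cycle, self.proportion_high.size - 1)
        return float(self.proportion_high[idx])

    @property
    def baseline_proportion(self) -> float:
        return float(self.proportion_high[0])

    def rescale_mean_burden(self, factor: float, label: str | None = None) -> "Jak2Trajectory":
        """Trajectory with the underlying mean-burden path scaled by ``factor``.

        When the trajectory carries its mean-burden path, proportions are
        recomputed through the Normal burden model, so the response to a
        baseline shift is properly nonlinear.  Otherwise the proportions
        themselves are scaled multiplicatively and clamped to [0, 1].
        """
        if factor < 0.0:
            raise ValueError(f"scale factor must be non-negative; got {factor}")
        new_label = label or f"{self.label} x{factor:.3f}"
        if self.mean_burden is not None:
            m = self.mean_burden * factor
            return Jak2Trajectory(
                proportion_high=proportion_above_threshold(m, self.burden_sd),
                mean_burden=m,
                burden_sd=self.burden_sd,
                label=new_label,
            )
        return Jak2Trajectory(
            proportion_high=np.clip(self.proportion_high * factor, 0.0, 1.0),
            label=new_label,
        )


def _interpolate(start: float, stop: float, n_to_plateau: int, shape: str) -> np.ndarray:
    k = np.arange(n_to_plateau + 1, dtype=float)
    if shape == "linear":
        frac = k / max(n_to_plateau, 1)
    elif shape == "exponential":
        # ~95% of the move completed at the plateau cycle
        tau = max(n_to_plateau, 1) / 3.0
        frac = (1.0 - np.exp(-k / tau)) / (1.0 - np.exp(-max(n_to_plateau, 1) / tau))
    else:
        raise ValueError(f"unknown shape {shape!r}; use 'linear' or 'exponential'")
    return start + (stop - start) * frac


def synthesize_trajectory(
    baseline_prop_high: float,
    plateau_prop_high: float,
    plateau_cycle: int = PLATEAU_CYCLE,
    shape: str = "linear",
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> Jak2Trajectory:
    """Monotone proportion-space trajectory, constant after ``plateau_cycle``.

    Interpolates from baseline to plateau over cycles ``0..plateau_cycle``.
    Deterministic given its arguments; ``seed`` only matters when
    ``noise_sd > 0`` requests jitter (clamped back into [0, 1]).
    """
    for name, v in (("baseline", baseline_prop_high), ("plateau", plateau_prop_high)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} proportion must lie in [0, 1]; got {v!r}")
    if plateau_cycle < 0:
        raise ValueError(f"plateau_cycle must be non-negative; got {plateau_cycle}")
    p = _interpolate(baseline_prop_high, plateau_prop_high, plateau_cycle, shape)
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        p = np.clip(p + rng.normal(0.0, noise_sd, size=p.size), 0.0, 1.0)
        p[-1] = plateau_prop_high  # constancy rule survives the jitter
    return Jak2Trajectory(proportion_high=p, label="synthetic proportion trajectory")


def trajectory_from_mean_burden(
    baseline_burden: float = BASELINE_MEAN_BURDEN,
    plateau_burden: float = DEFAULT_PLATEAU_BURDEN,
    sd: float = DEFAULT_BURDEN_SD,
    plateau_cycle: int = PLATEAU_CYCLE,
    shape: str = "linear",
) -> Jak2Trajectory:
    """Trajectory defined by a mean-burden path mapped through a Normal model."""
    for name, v in (("baseline", baseline_burden), ("plateau", plateau_burden)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} mean burden must lie in [0, 100]%; got {v!r}")
    if not sd > 0.0:
        raise ValueError(f"burden sd must be positive; got {sd!r}")
    m = _interpolate(baseline_burden, plateau_burden, plateau_cycle, shape)
    return Jak2Trajectory(
        proportion_high=proportion_above_threshold(m, sd),
        mean_burden=m,
        burden_sd=sd,
        label="mean-burden trajectory",
    )


def default_trajectory() -> Jak2Trajectory:
    """The shipped reference trajectory (hydroxyurea-arm emulation)."""
    return trajectory_from_mean_burden()
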