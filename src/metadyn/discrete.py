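"""Discrete per-lesion simulation of occult metastatic disease.

The continuous model gives the expected number of lesions N(t).  For
forward clinical predictions the small lesion counts matter individually,
so the disease is realized lesion by lesion: the i-th lesion is born at

    T_i = inf{ t > 0 : N(t) >= i },

i.e. the expectation of an inhomogeneous Poisson birth process replaces
the random count (the lesion census at time t is floor(N(t))).  Each
lesion then sits at its birth size S0 for the dormancy duration tau (if
any) and grows along the closed-form BM Gompertz law.  A true stochastic
counterpart (Poisson thinning, with generational seeding for the
secondary variant) is provided for simulation studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .growth import PTTrajectory, gompertz_log_size, gompertz_time_to_size
from .dissemination import (
    DisseminationParams,
    ScenarioSpec,
    expected_count_interpolator,
)

__all__ = [
    "LesionRecord",
    "DiseaseSnapshot",
    "birth_times",
    "lesion_size",
    "snapshot",
    "visible_count_curve",
    "stochastic_realization",
]


@dataclass(frozen=True)
class LesionRecord:
    """A single simulated lesion: birth rank, birth time, generation."""

    index: int
    birth_time: float
    generation: int = 1

    def size_at(self, t: float, scenario: ScenarioSpec) -> float:
        """Size in cells at time t (0 before birth; S0 while dormant)."""
        return lesion_size(t, self.birth_time, scenario)


def lesion_size(t, birth_time: float, scenario: ScenarioSpec):
    """Closed-form size of a lesion born at ``birth_time``.

    0 before birth; exactly S0 during the dormancy window
    [birth, birth + tau]; Gompertz growth from S0 afterwards.
    """
    t_arr = np.asarray(t, dtype=float)
    age = t_arr - birth_time
    # clock offset so that growth starts from S0; during dormancy the
    # growing age is 0 and the size is exactly S0
    grow_age = np.maximum(age - scenario.tau, 0.0)
    offset = gompertz_time_to_size(scenario.S0, scenario.bm_growth)
    ln_sz = gompertz_log_size(grow_age + offset, scenario.bm_growth)
    out = np.where(age < 0, 0.0, np.exp(ln_sz))
    return float(out) if np.isscalar(t) else out


@dataclass(frozen=True)
class DiseaseSnapshot:
    """Per-lesion state of the cerebral disease at one time point."""

    time: float
    lesion_sizes: tuple[float, ...]
    S_vis: float

    @property
    def n_total(self) -> int:
        return len(self.lesion_sizes)

    @property
    def n_visible(self) -> int:
        return sum(1 for s in self.lesion_sizes if s >= self.S_vis)

    @property
    def n_occult(self) -> int:
        return self.n_total - self.n_visible

    @property
    def total_burden(self) -> float:
        return float(sum(self.lesion_sizes))

    @property
    def occult_burden(self) -> float:
        return float(sum(s for s in self.lesion_sizes if s < self.S_vis))

    @property
    def largest(self) -> float:
        return max(self.lesion_sizes) if self.lesion_sizes else 0.0


def birth_times(
    traj: PTTrajectory,
    p: DisseminationParams,
    horizon: float,
    t0: float = 0.0,
    grid_step: float = 1.0,
    xtol: float = 1e-3,
) -> list[float]:
    """Birth times T_i = inf{t : N(t) >= i} for i = 1..floor(N(horizon)).

    Root solving is done on a cached monotone interpolant of N (daily grid
    by default) so that thousands of solves stay cheap; each root is
    bracketed bisection (Brent) to ``xtol`` days.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if p.mu == 0.0:
        return []
    N = expected_count_interpolator(traj, p, horizon, t0=t0, step=grid_step)
    n = int(math.floor(N(horizon)))
    times: list[float] = []
    lo = t0
    for i in range(1, n + 1):
        T_i = optimize.brentq(lambda t: N(t) - i, lo, horizon, xtol=xtol)
        times.append(T_i)
        lo = T_i  # N is non-decreasing, so roots are ordered
    return times


def snapshot(
    t: float,
    traj: PTTrajectory,
    scenario: ScenarioSpec,
    grid_step: float = 1.0,
) -> DiseaseSnapshot:
    """Discrete disease snapshot at time t: all lesions born by t, grown
    (through dormancy if applicable) to their closed-form sizes.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if scenario.variant == "secondary":
        raise ValueError(
            "the expectation-mode simulator does not support the secondary "
            "variant; use stochastic_realization"
        )
    births = birth_times(traj, scenario.dissemination, t, t0=scenario.t0, grid_step=grid_step) if t > 0 else []
    sizes = tuple(float(lesion_size(t, T_i, scenario)) for T_i in births)
    return DiseaseSnapshot(time=t, lesion_sizes=sizes, S_vis=scenario.S_vis)


def visible_count_curve(
    times,
    traj: PTTrajectory,
    scenario: ScenarioSpec,
    grid_step: float = 1.0,
) -> np.ndarray:
    """Number of lesions at or above the visibility threshold per time point."""
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    if times.size == 0:
        return np.zeros(0, dtype=int)
    horizon = float(times[-1])
    births = (
        birth_times(traj, scenario.dissemination, horizon, t0=scenario.t0, grid_step=grid_step)
        if horizon > 0
        else []
    )
    counts = np.zeros(times.size, dtype=int)
    for j, t in enumerate(times):
        counts[j] = sum(
            1 for T_i in births if lesion_size(t, T_i, scenario) >= scenario.S_vis
        )
    return counts


def stochastic_realization(
    traj: PTTrajectory,
    scenario: ScenarioSpec,
    seed: int,
    horizon: float,
    max_generations: int = 5,
) -> list[LesionRecord]:
    """One stochastic disease history: inhomogeneous Poisson births by thinning.

    Candidate birth times are drawn from a homogeneous process at the peak
    intensity over [0, horizon] and accepted with probability
    d(source size)/peak.  For the secondary variant each accepted lesion is
    itself a seeding source from its birth time onward (generational
    thinning), up to ``max_generations``.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    p = scenario.dissemination
    if p.mu == 0.0 or horizon <= 0:
        return []

    def thin(intensity, start: float, lam_max: float) -> list[float]:
        out = []
        t = start
        if lam_max <= 0:
            return out
        while True:
            t += rng.exponential(1.0 / lam_max)
            if t > horizon:
                return out
            if rng.uniform() * lam_max <= intensity(t):
                out.append(t)

    # PT source: intensity mu * S_p(t)^gamma, peaks at T_d (growth then response)
    grid = np.linspace(0.0, horizon, 2048)
    pt_intensity = lambda t: p.mu * math.exp(p.gamma * float(traj.log_size(t)))
    lam_pt = float(np.max(p.mu * np.exp(p.gamma * traj.log_size(grid)))) * 1.000001
    records: list[LesionRecord] = []
    frontier = [(T, 1) for T in thin(pt_intensity, scenario.t0, lam_pt)]
    while frontier:
        birth, gen = frontier.pop(0)
        records.append(LesionRecord(index=0, birth_time=birth, generation=gen))
        if scenario.variant == "secondary" and gen < max_generations:
            def bm_intensity(t, _b=birth):
                return p.mu * lesion_size(t, _b, scenario) ** p.gamma
            # lesion size is non-decreasing, so the intensity peaks at horizon
            lam_bm = p.mu * lesion_size(horizon, birth, scenario) ** p.gamma
            frontier.extend((T, gen + 1) for T in thin(bm_intensity, birth, lam_bm * 1.000001))
    records.sort(key=lambda r: r.birth_time)
    return [
        LesionRecord(index=i + 1, birth_time=r.birth_time, generation=r.generation)
        for i, r in enumerate(records)
    ]
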