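"""Continuous size-structured metastasis models.

The metastatic population is described by a size-structured density
rho(t, s) transported along lesion growth characteristics (the Iwata
framework).  The primary tumor seeds new lesions at the dissemination rate

    d(S_p) = mu * S_p**gamma,

the expected number of successfully founded brain metastases (BMs) per
day; gamma encodes which cells can seed (1 = all cells, 2/3 = surface,
0 = a fixed stem-cell pool).  For primary-only seeding the method of
characteristics gives the cumulative size distribution in closed form,

    f(t, s) = N(t - t(s)),     N(t) = integral_0^t d(S_p(u)) du,

where t(s) is the time for a one-cell lesion growing under the BM Gompertz
law to reach size s.  Five scenario variants are supported: basic,
different_growth (BM growth law differs from the PT's), delay (seeding
starts only at t0), dormancy (newborn lesions sit at S0 for tau days
before growing), and secondary (lesions seed lesions, turning the
boundary flux into a Volterra renewal equation solved numerically here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate
from scipy.interpolate import PchipInterpolator

from .growth import (
    GompertzParams,
    PTTrajectory,
    cells_from_diameter,
    gompertz_log_size,
    gompertz_time_to_size,
)

__all__ = [
    "VARIANTS",
    "DisseminationParams",
    "ScenarioSpec",
    "MetastaticState",
    "dissemination_rate",
    "expected_count",
    "expected_count_interpolator",
    "cumulative_size_distribution",
    "solve_secondary",
]

VARIANTS = ("basic", "different_growth", "secondary", "delay", "dormancy")


@dataclass(frozen=True)
class DisseminationParams:
    """Dissemination law d(S) = mu * S**gamma.

    mu : per-cell per-day probability of completing the metastatic cascade
        (cell^-1 day^-1).
    gamma : geometric exponent in [0, 1] (dimensionless).
    """

    mu: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")


def dissemination_rate(s, p: DisseminationParams):
    """d(s) = mu * s**gamma, per day.  gamma=0 gives a constant rate mu."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValueError("size must be non-negative")
    out = p.mu * s_arr**p.gamma
    return float(out) if np.isscalar(s) else out


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the five dissemination/colonization scenarios.

    Only the fields relevant to the variant are active: ``t0`` for the
    delay variant, ``tau`` for dormancy, ``bm_growth`` for
    different_growth (otherwise it mirrors the PT law).
    """

    variant: str
    dissemination: DisseminationParams
    bm_growth: GompertzParams
    t0: float = 0.0
    tau: float = 0.0
    S0: float = 1.0
    S_vis: float = cells_from_diameter(3.0)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.t0 < 0 or self.tau < 0:
            raise ValueError("t0 and tau must be non-negative")
        if self.S0 < 1:
            raise ValueError("S0 must be at least one cell")
        if self.variant != "delay" and self.t0 != 0.0:
            raise ValueError("t0 is only meaningful for the delay variant")
        if self.variant != "dormancy" and self.tau != 0.0:
            raise ValueError("tau is only meaningful for the dormancy variant")

    def with_params(self, **kwargs) -> "ScenarioSpec":
        return replace(self, **kwargs)

    def growth_clock(self, s):
        """Time for a BM to grow from S0 to size s (excluding dormancy)."""
        s_arr = np.asarray(s, dtype=float)
        t0_off = gompertz_time_to_size(self.S0, self.bm_growth)
        return gompertz_time_to_size(s_arr, self.bm_growth) - t0_off


def expected_count(
    t: float,
    traj: PTTrajectory,
    p: DisseminationParams,
    t0: float = 0.0,
    rtol: float = 1e-8,
) -> float:
    """Expected number of primary-seeded BMs, N(t) = int_{t0}^{t} d(S_p(u)) du.

    The integrand is evaluated in log space (S_p spans 1 to ~1e12 cells)
    and integrated with adaptive quadrature to relative tolerance ``rtol``.
    """
    if t <= t0:
        return 0.0

    def integrand(u):
        return p.mu * np.exp(p.gamma * traj.log_size(u))

    points = [traj.T_d] if t0 < traj.T_d < t else None
    val, err = integrate.quad(integrand, t0, t, epsrel=rtol, epsabs=0.0, limit=200, points=points)
    if val > 0 and err > max(1e3 * rtol * val, 1e-12):
        raise RuntimeError(
            f"quadrature for N({t:g}) did not converge: value {val:g}, error estimate {err:g}"
        )
    return val


def expected_count_interpolator(
    traj: PTTrajectory,
    p: DisseminationParams,
    horizon: float,
    t0: float = 0.0,
    step: float = 1.0,
):
    """Monotone interpolant of N on [0, horizon], cheap to evaluate repeatedly.

    Cumulative trapezoid of d(S_p) on a uniform grid (default 1 day) with a
    PCHIP (monotone) interpolant; N is clamped to 0 before ``t0``.  Used by
    the discrete simulator, which needs thousands of root solves on N.
    """
    n = max(int(math.ceil((horizon - t0) / step)), 8)
    grid = np.linspace(t0, horizon, n + 1)
    # refine around T_d where S_p has a kink
    if t0 < traj.T_d < horizon:
        grid = np.unique(np.concatenate([grid, [traj.T_d]]))
    rate = p.mu * np.exp(p.gamma * traj.log_size(grid))
    cum = integrate.cumulative_trapezoid(rate, grid, initial=0.0)
    interp = PchipInterpolator(grid, cum, extrapolate=False)

    def N(t):
        t_arr = np.asarray(t, dtype=float)
        out = np.where(
            t_arr <= t0,
            0.0,
            interp(np.clip(t_arr, t0, horizon)),
        )
        return float(out) if np.isscalar(t) else out

    return N


def cumulative_size_distribution(
    t,
    s,
    traj: PTTrajectory,
    scenario: ScenarioSpec,
    count_fn=None,
) -> float:
    """Expected number of BMs of size >= s at time t, f(t, s).

    Variant semantics (all through the BM growth clock t(s)):

    - basic / different_growth: ``f = N(t - t(s))``
    - delay:    ``f = max(N(t - t(s)) - N(t0), 0)``
    - dormancy: ``f = N(t - t(s) - tau)`` for s > S0; at s = S0 the census
      includes dormant lesions, so ``f(t, S0) = N(t)``.
    - secondary: integral of the renewal birth flux (see
      :func:`solve_secondary`); pass its state as ``count_fn``.

    ``count_fn`` may be any callable N(t) (e.g. a cached interpolant);
    defaults to adaptive quadrature.
    """
    if s < scenario.S0:
        raise ValueError("size below the birth size S0")
    K_bm = scenario.bm_growth.carrying_capacity
    if s >= K_bm:
        raise ValueError("size at or beyond the BM carrying capacity is unreachable")
    if scenario.variant == "secondary":
        if count_fn is None or not isinstance(count_fn, MetastaticState):
            raise ValueError("secondary variant requires a MetastaticState from solve_secondary")
        return count_fn.cumulative_size_distribution(t, s, scenario)

    if count_fn is None:
        def count_fn(u):  # noqa: E731 - local default
            return expected_count(u, traj, scenario.dissemination)

    clock = float(scenario.growth_clock(s))
    if scenario.variant == "dormancy":
        if s == scenario.S0:
            return max(float(count_fn(t)), 0.0)
        arg = t - clock - scenario.tau
        return max(float(count_fn(arg)), 0.0) if arg > 0 else 0.0
    if scenario.variant == "delay":
        arg = t - clock
        if arg <= 0:
            return 0.0
        val = float(count_fn(arg)) - float(count_fn(scenario.t0))
        return max(val, 0.0)
    # basic / different_growth
    arg = t - clock
    return max(float(count_fn(arg)), 0.0) if arg > 0 else 0.0


@dataclass(frozen=True)
class MetastaticState:
    """Birth flux of the secondary-dissemination model on a uniform mesh.

    ``birth_rate[k]`` is b(grid[k]) = g(S0) rho(t, S0), the total rate of
    new lesion foundings (primary + secondary) per day.  The cumulative
    size distribution is recovered along characteristics:
    f(t, s) = integral_0^{t - t(s)} b(u) du.
    """

    grid: np.ndarray
    birth_rate: np.ndarray
    bm_growth: GompertzParams
    S0: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("mesh must be strictly increasing")
        if np.any(self.birth_rate < 0):
            raise ValueError("birth rate must be non-negative on the mesh")

    def total_count(self, t) -> float:
        """Expected total number of lesions born by time t."""
        t = float(t)
        if t <= self.grid[0]:
            return 0.0
        cum = integrate.cumulative_trapezoid(self.birth_rate, self.grid, initial=0.0)
        return float(np.interp(t, self.grid, cum))

    def cumulative_size_distribution(self, t, s, scenario: ScenarioSpec | None = None) -> float:
        clock = gompertz_time_to_size(s, self.bm_growth) - gompertz_time_to_size(
            self.S0, self.bm_growth
        )
        return self.total_count(float(t) - float(clock))


def solve_secondary(
    traj: PTTrajectory,
    p: DisseminationParams,
    bm_growth: GompertzParams,
    horizon: float,
    step: float = 1.0,
    check: bool = False,
    _bm_source: bool = True,
) -> MetastaticState:
    """Solve the secondary-dissemination renewal equation by trapezoid marching.

    The total birth flux satisfies the Volterra equation

        b(t) = d(S_p(t)) + integral_0^t b(u) d(S_bm(t - u)) du,

    where S_bm(a) is the Gompertz size of a lesion of age a (every lesion
    follows the same growth law, so a lesion born at u has dissemination
    rate d(S_bm(t-u)) at time t).  Marching uses the trapezoid rule on a
    uniform mesh of the given step (days), implicit in the diagonal term.

    ``check=True`` re-solves at half the step and raises if the final
    cumulative count differs by more than 0.5% (mesh too coarse).
    ``_bm_source=False`` is a test hook that zeroes the secondary source,
    reducing the model to the basic one.
    """
    if step <= 0 or horizon <= 0:
        raise ValueError("step and horizon must be positive")

    def march(h: float) -> tuple[np.ndarray, np.ndarray]:
        n = int(math.ceil(horizon / h))
        grid = np.linspace(0.0, n * h, n + 1)
        primary = p.mu * np.exp(p.gamma * traj.log_size(grid))
        if not _bm_source:
            return grid, primary
        # kernel K(a) = d(S_bm(a)) for lesion age a
        kernel = p.mu * np.exp(p.gamma * gompertz_log_size(grid, bm_growth))
        b = np.empty(n + 1)
        b[0] = primary[0]
        denom = 1.0 - 0.5 * h * kernel[0]
        if denom <= 0:
            raise RuntimeError("step too coarse for the renewal kernel (implicit term)")
        for k in range(1, n + 1):
            # trapezoid: 0.5*b0*K_k + sum_{j=1}^{k-1} b_j K_{k-j} + 0.5*b_k*K_0
            conv = 0.5 * b[0] * kernel[k]
            if k > 1:
                conv += float(np.dot(b[1:k], kernel[k - 1 : 0 : -1]))
            b[k] = (primary[k] + h * conv) / denom
        return grid, b

    grid, b = march(step)
    if check:
        grid2, b2 = march(step / 2.0)
        tot = np.trapezoid(b, grid)
        tot2 = np.trapezoid(b2, grid2)
        if tot2 > 0 and abs(tot - tot2) / tot2 > 0.005:
            raise RuntimeError(
                f"renewal mesh too coarse: count {tot:g} vs {tot2:g} at half step"
            )
        grid, b = grid2, b2
    return MetastaticState(grid=grid, birth_rate=b, bm_growth=bm_growth)
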