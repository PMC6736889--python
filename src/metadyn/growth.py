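"""Tumor growth laws and their calibration.

The primary tumor (PT) is modeled in cell number, starting from a single
cell at t = 0.  Its untreated ("natural") history follows a Gompertz law

    dS/dt = (alpha0 - beta * ln S) * S,   S(0) = 1,

whose closed form is ``S(t) = exp(alpha0/beta * (1 - exp(-beta t)))`` with
carrying capacity ``K = exp(alpha0/beta)``.  After the diagnosis/treatment
time ``T_d`` the PT switches to a tumor-growth-inhibition (TGI) law:
exponential regrowth at rate alpha1 minus a log-kill treatment effect of
initial efficacy kappa that wanes exponentially with half-life t_res.

Because longitudinal pre-diagnosis measurements are never available, the
Gompertz pair (alpha0, beta) is calibrated from two clinical anchors: the
carrying capacity of a human tumor (1e12 cells by default) and the
histology-dependent volume doubling time at the diagnosis size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "DEFAULT_CARRYING_CAPACITY",
    "DOUBLING_TIME_DAYS",
    "GompertzParams",
    "TGIParams",
    "TumorSizeScale",
    "PTTrajectory",
    "cells_from_diameter",
    "diameter_from_cells",
    "gompertz_size",
    "gompertz_log_size",
    "gompertz_time_to_size",
    "gompertz_doubling_time",
    "calibrate_gompertz",
    "calibrate_exponential",
    "tgi_size",
    "tgi_log_size",
    "make_pt_trajectory",
]

#: Reporting conversions; internal unit is always days with t=0 at the first PT cell.
DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

#: Maximal reachable size of a human tumor, in cells.
DEFAULT_CARRYING_CAPACITY = 1e12

#: Histology -> volume doubling time at diagnosis size (days), from published
#: meta-analyses of natural lung-tumor growth.  The squamous entry equals the
#: undifferentiated-carcinoma value; calibrating with it reproduces published
#: squamous parameter sets to their printed precision.  User-extensible.
DOUBLING_TIME_DAYS: dict[str, float] = {
    "adenocarcinoma": 201.0,
    "undifferentiated": 104.0,
    "squamous": 104.0,
}


class CalibrationError(RuntimeError):
    """Raised when growth-parameter calibration cannot bracket a solution."""


@dataclass(frozen=True)
class TumorSizeScale:
    """Diameter <-> cell-count conversion for spherical lesions.

    The classical radiological assumption is 1 mm^3 = 1e6 cells.
    """

    cells_per_mm3: float = 1e6

    def __post_init__(self) -> None:
        if self.cells_per_mm3 <= 0:
            raise ValueError("cells_per_mm3 must be positive")


#: Module-wide default scale (1 mm^3 = 1e6 cells, spherical shape).
DEFAULT_SCALE = TumorSizeScale()


def cells_from_diameter(d_mm, scale: TumorSizeScale = DEFAULT_SCALE):
    """Convert a largest-diameter measurement (mm) to a cell count.

    Assumes a spherical lesion: ``cells = (pi/6) d^3 * cells_per_mm3``.
    """
    d = np.asarray(d_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    out = (np.pi / 6.0) * d**3 * scale.cells_per_mm3
    return float(out) if np.isscalar(d_mm) else out


def diameter_from_cells(s_cells, scale: TumorSizeScale = DEFAULT_SCALE):
    """Inverse of :func:`cells_from_diameter` (cells -> diameter in mm)."""
    s = np.asarray(s_cells, dtype=float)
    if np.any(s < 0):
        raise ValueError("cell count must be non-negative")
    out = np.cbrt(6.0 * s / (np.pi * scale.cells_per_mm3))
    return float(out) if np.isscalar(s_cells) else out


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz growth law parameters.

    Parameters
    ----------
    alpha0 : float
        Specific growth rate at one cell (day^-1).
    beta : float
        Exponential decay rate of the specific growth rate (day^-1).
    """

    alpha0: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha0 > 0 and self.beta > 0):
            raise ValueError("alpha0 and beta must be positive")

    @property
    def carrying_capacity(self) -> float:
        """K = exp(alpha0/beta), in cells (inf in the exponential limit beta->0)."""
        try:
            return math.exp(self.alpha0 / self.beta)
        except OverflowError:
            return math.inf

    def growth_rate(self, s):
        """Size growth rate g(s) = (alpha0 - beta ln s) * s (cells/day)."""
        s = np.asarray(s, dtype=float)
        return (self.alpha0 - self.beta * np.log(s)) * s


def gompertz_log_size(t, p: GompertzParams):
    """ln S(t) for Gompertz growth from one cell; valid for any real t >= 0."""
    t = np.asarray(t, dtype=float)
    return p.alpha0 / p.beta * (1.0 - np.exp(-p.beta * t))


def gompertz_size(t, p: GompertzParams):
    """Gompertz size S(t) = exp(alpha0/beta (1 - e^{-beta t})), in cells.

    S(0) = 1 and S(t) -> K = exp(alpha0/beta) as t -> infinity.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = np.exp(gompertz_log_size(t_arr, p))
    return float(out) if np.isscalar(t) else out


def gompertz_time_to_size(s, p: GompertzParams):
    """Time (days) for a one-cell Gompertz tumor to reach size ``s`` cells.

    Closed form: ``t(s) = -(1/beta) ln(1 - (beta/alpha0) ln s)``; the inverse
    of :func:`gompertz_size` on [1, K).
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 1):
        raise ValueError("size must be >= 1 cell")
    x = p.beta / p.alpha0 * np.log(s_arr)
    if np.any(x >= 1.0):
        raise ValueError("size at or beyond carrying capacity is unreachable")
    out = -np.log1p(-x) / p.beta  # log1p keeps precision in the beta -> 0 limit
    return float(out) if np.isscalar(s) else out


def gompertz_doubling_time(s, p: GompertzParams):
    """Size-dependent volume doubling time DT(s) = t(2s) - t(s), in days.

    Increases with s (growth deceleration); converges to ln2/alpha0 as
    beta -> 0 (exponential limit).
    """
    return gompertz_time_to_size(2.0 * np.asarray(s, dtype=float), p) - gompertz_time_to_size(s, p)


def calibrate_gompertz(
    S_d: float,
    DT_d: float,
    K: float = DEFAULT_CARRYING_CAPACITY,
) -> GompertzParams:
    """Calibrate (alpha0, beta) from diagnosis size, doubling time and capacity.

    Solves DT(S_d; alpha0 = beta ln K, beta) = DT_d for beta by bracketed
    root finding (Brent) on beta in [1e-6, 1] day^-1, where DT is the
    doubling time at the diagnosis size.  The constraint exp(alpha0/beta)=K
    holds exactly by construction.

    Parameters
    ----------
    S_d : diagnosis size in cells (1 < S_d < K/2).
    DT_d : doubling time at the diagnosis size, days.
    K : carrying capacity, cells.
    """
    if not (1.0 < S_d < K / 2.0):
        raise CalibrationError(
            f"diagnosis size {S_d:g} must lie in (1, K/2) = (1, {K / 2.0:g}): "
            "doubling is impossible at or beyond half the carrying capacity"
        )
    if DT_d <= 0:
        raise CalibrationError("doubling time must be positive")
    ln_K = math.log(K)

    def mismatch(beta: float) -> float:
        p = GompertzParams(alpha0=beta * ln_K, beta=beta)
        return gompertz_doubling_time(S_d, p) - DT_d

    lo, hi = 1e-6, 1.0
    f_lo, f_hi = mismatch(lo), mismatch(hi)
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"no root in beta bracket [{lo:g}, {hi:g}] "
            f"(DT mismatch {f_lo:.3g} .. {f_hi:.3g}); "
            "check S_d, DT_d and K for consistency"
        )
    beta = optimize.brentq(mismatch, lo, hi, xtol=1e-14, rtol=1e-14)
    return GompertzParams(alpha0=beta * ln_K, beta=beta)


def calibrate_exponential(S_d: float, DT: float) -> tuple[float, float]:
    """Exponential-growth calibration from diagnosis size and doubling time.

    Returns ``(rate, age)`` where rate = ln2/DT (day^-1) and
    age = ln(S_d)/rate is the time (days) to grow from one cell to S_d.
    """
    if S_d <= 1:
        raise ValueError("diagnosis size must exceed one cell")
    if DT <= 0:
        raise ValueError("doubling time must be positive")
    rate = math.log(2.0) / DT
    return rate, math.log(S_d) / rate


@dataclass(frozen=True)
class TGIParams:
    """Tumor-growth-inhibition (treatment-phase) parameters.

    Parameters
    ----------
    alpha1 : regrowth rate under treatment (day^-1).
    kappa : initial log-kill efficacy of the therapy (day^-1).
    t_res : half-life of the treatment effect, lost to resistance (days).
    T_d : treatment start / diagnosis time, days from the first PT cell.
    """

    alpha1: float
    kappa: float
    t_res: float
    T_d: float

    def __post_init__(self) -> None:
        if self.alpha1 < 0 or self.kappa < 0:
            raise ValueError("alpha1 and kappa must be non-negative")
        if self.t_res <= 0:
            raise ValueError("t_res must be positive")


def tgi_log_size(t, S_Td: float, p: TGIParams):
    """ln S(t) under the TGI law, for t >= T_d, starting from S(T_d)=S_Td.

    Closed form of dS/dt = alpha1 S - kappa e^{-(t-T_d) ln2 / t_res} S:

        ln S(t) = ln S_Td + alpha1 (t-T_d)
                  - kappa (t_res/ln2) (1 - e^{-(t-T_d) ln2 / t_res}).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < p.T_d - 1e-9):
        raise ValueError("TGI law only applies for t >= T_d")
    dt = t_arr - p.T_d
    ln2 = math.log(2.0)
    return (
        math.log(S_Td)
        + p.alpha1 * dt
        - p.kappa * (p.t_res / ln2) * (1.0 - np.exp(-dt * ln2 / p.t_res))
    )


def tgi_size(t, S_Td: float, p: TGIParams):
    """Size (cells) under the TGI law; see :func:`tgi_log_size`."""
    out = np.exp(tgi_log_size(t, S_Td, p))
    return float(out) if np.isscalar(t) else out


@dataclass(frozen=True)
class PTTrajectory:
    """Piecewise primary-tumor size trajectory S_p(t), in cells.

    Gompertz from one cell for t <= T_d, then (optionally) the TGI
    treatment-response law; continuous at T_d by construction.  Callable
    and vector-evaluable; ``log_size`` avoids overflow when integrating
    over ten orders of magnitude.
    """

    pre: GompertzParams
    post: TGIParams | None = None
    T_d: float = field(default=math.inf)

    def __post_init__(self) -> None:
        if self.post is not None and not math.isclose(self.post.T_d, self.T_d):
            raise ValueError("post-phase T_d must equal trajectory T_d")

    def log_size(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("time must be non-negative")
        pre_ln = gompertz_log_size(np.minimum(t_arr, self.T_d), self.pre)
        if self.post is None:
            out = gompertz_log_size(t_arr, self.pre)
        else:
            ln_S_Td = gompertz_log_size(self.T_d, self.pre)
            dt = np.maximum(t_arr - self.T_d, 0.0)
            ln2 = math.log(2.0)
            post_ln = (
                ln_S_Td
                + self.post.alpha1 * dt
                - self.post.kappa
                * (self.post.t_res / ln2)
                * (1.0 - np.exp(-dt * ln2 / self.post.t_res))
            )
            out = np.where(t_arr <= self.T_d, pre_ln, post_ln)
        return float(out) if np.isscalar(t) else out

    def __call__(self, t):
        out = np.exp(self.log_size(t))
        return float(out) if np.isscalar(t) else out


def make_pt_trajectory(
    pre: GompertzParams,
    post: TGIParams | None = None,
    T_d: float | None = None,
) -> PTTrajectory:
    """Compose the pre-diagnosis Gompertz and post-diagnosis TGI laws.

    If ``post`` is given, ``T_d`` defaults to ``post.T_d``; with neither,
    the trajectory is pure Gompertz for all times.
    """
    if post is not None:
        if T_d is None:
            T_d = post.T_d
        return PTTrajectory(pre=pre, post=post, T_d=T_d)
    return PTTrajectory(pre=pre, post=None, T_d=math.inf if T_d is None else T_d)
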