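"""Patient-level model fitting and identifiability analysis.

Clinical imaging yields, per scan time t_j, the diameters of the visible
brain metastases.  Sorting sizes descending within a scan and assigning
ranks y = 1, 2, ... produces the empirical cumulative size distribution:
y_j^i is the number of lesions of size >= x_j^i.  The model counterpart
is f(t_j, x_j^i; theta), and estimation minimizes the sum of squared
errors SSE(theta) = sum (y - f)^2 (maximum likelihood under additive
Gaussian count noise).

Parameter identifiability is assessed from the asymptotic covariance
Cov = sigma2_hat (J^T J)^{-1}, with J the finite-difference Jacobian of
the model predictions at the optimum and sigma2_hat = SSE/(N - P); the
per-parameter relative standard error (percent) flags practically
non-identifiable parameters.

mu and gamma are jointly unidentifiable from cumulative-size data, so
gamma is profiled over a small physical grid (0, 0.4, 0.5, 2/3, 1) with
gamma-matched initializations of mu, and the remaining parameters are
optimized on log scale by multi-start Nelder-Mead.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import PchipInterpolator

from .growth import (
    GompertzParams,
    PTTrajectory,
    TGIParams,
    cells_from_diameter,
    gompertz_log_size,
    make_pt_trajectory,
)
from .dissemination import (
    DisseminationParams,
    ScenarioSpec,
    solve_secondary,
)

__all__ = [
    "GAMMA_GRID",
    "MU_INITS",
    "TAU_INITS",
    "T0_INITS",
    "BMMeasurementSet",
    "FitResult",
    "build_cumulative_targets",
    "sse_objective",
    "fit_tgi",
    "fit_bm_scenario",
    "standard_errors",
    "compare_models",
]

#: Physically motivated gamma values (stem-cell pool ... full tumor) and the
#: matching order-of-magnitude initializations of mu.
GAMMA_GRID = (0.0, 0.4, 0.5, 2.0 / 3.0, 1.0)
MU_INITS = (1e-3, 1e-5, 1e-8, 1e-9, 1e-12)
#: Initialization grids for the lag parameters (days).
TAU_INITS = (0.0, 50.0, 100.0, 350.0)
T0_INITS = (0.0, 500.0, 1700.0, 2000.0)


@dataclass(frozen=True)
class BMMeasurementSet:
    """Cumulative-size-distribution observations (t_j, x_j^i, y_j^i).

    ``scans`` maps each observation time (days from the first PT cell) to
    the lesion sizes in cells, sorted descending; the rank of each size
    (1-based) is its cumulative count y.
    """

    scans: tuple[tuple[float, tuple[float, ...]], ...]
    #: optional per-scan observed counts y (defaults to the ranks); used to
    #: carry the additive count-noise error model y = f + sigma*eps
    counts: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        for t_j, sizes in self.scans:
            if any(s <= 0 for s in sizes):
                raise ValueError("lesion sizes must be positive")
            if list(sizes) != sorted(sizes, reverse=True):
                raise ValueError("sizes within a scan must be sorted descending")
        if self.counts is not None:
            if tuple(len(c) for c in self.counts) != tuple(len(s) for _, s in self.scans):
                raise ValueError("counts must parallel the scans")

    @property
    def n_obs(self) -> int:
        return sum(len(sizes) for _, sizes in self.scans)

    def triples(self) -> list[tuple[float, float, float]]:
        """Flattened (t_j, x_j^i, y_j^i) observation triples."""
        out = []
        for j, (t_j, sizes) in enumerate(self.scans):
            for rank, x in enumerate(sizes, start=1):
                y = self.counts[j][rank - 1] if self.counts is not None else rank
                out.append((t_j, x, y))
        return out

    def with_count_noise(self, sigma: float, rng: np.random.Generator) -> "BMMeasurementSet":
        """Perturb the cumulative counts: y = rank + sigma * eps, eps ~ N(0,1)."""
        noisy = tuple(
            tuple(rank + sigma * rng.standard_normal() for rank in range(1, len(sizes) + 1))
            for _, sizes in self.scans
        )
        return BMMeasurementSet(scans=self.scans, counts=noisy)


def build_cumulative_targets(
    raw: dict[float, list[float]] | pd.DataFrame,
    time_offset: float = 0.0,
) -> BMMeasurementSet:
    """Build the cumulative size distribution from per-scan lesion diameters.

    ``raw`` is either a mapping {scan time -> list of diameters (mm)} or a
    DataFrame with columns time_days_from_diagnosis, diameter_mm (and
    optionally lesion_id).  ``time_offset`` shifts I/O times (anchored at
    diagnosis) to the model clock (anchored at the first PT cell).  Ties
    keep input order (stable sort); empty scans contribute no points.
    """
    if isinstance(raw, pd.DataFrame):
        grouped: dict[float, list[float]] = {}
        for t, sub in raw.groupby("time_days_from_diagnosis", sort=True):
            grouped[float(t)] = [float(d) for d in sub["diameter_mm"]]
        raw = grouped
    scans = []
    for t_j in sorted(raw):
        diameters = raw[t_j]
        if any(d <= 0 for d in diameters):
            raise ValueError(f"non-positive diameter in scan at t={t_j}")
        sizes = sorted((cells_from_diameter(d) for d in diameters), reverse=True)
        if sizes:
            scans.append((float(t_j) + time_offset, tuple(sizes)))
    return BMMeasurementSet(scans=tuple(scans))


@dataclass
class FitResult:
    """Outcome of a least-squares fit."""

    theta_hat: dict[str, float]
    sse: float
    n_obs: int
    n_free: int
    sigma2_hat: float | None = None
    cov: np.ndarray | None = None
    rse_percent: dict[str, float] | None = None
    non_identifiable: tuple[str, ...] = ()
    trace: list = field(default_factory=list)
    converged: bool = True
    flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# model prediction machinery


class _ScenarioPredictor:
    """Fast f(t, s; theta) evaluator for one (trajectory, variant, gamma).

    For primary-seeding variants N(t) = mu * B(t) with
    B(t) = integral S_p^gamma, which depends only on (trajectory, gamma);
    B is tabulated once on a daily grid so each objective evaluation is a
    handful of monotone-interpolant lookups.  The secondary variant
    re-solves its renewal equation per evaluation.
    """

    def __init__(
        self,
        traj: PTTrajectory,
        variant: str,
        gamma: float,
        horizon: float,
        grid_step: float = 1.0,
        secondary_step: float = 2.0,
    ) -> None:
        self.traj = traj
        self.variant = variant
        self.gamma = gamma
        self.horizon = horizon
        self.secondary_step = secondary_step
        n = max(int(math.ceil(horizon / grid_step)), 16)
        grid = np.linspace(0.0, horizon, n + 1)
        if 0.0 < traj.T_d < horizon:
            grid = np.unique(np.concatenate([grid, [traj.T_d]]))
        rate = np.exp(gamma * traj.log_size(grid))
        from scipy.integrate import cumulative_trapezoid

        B = cumulative_trapezoid(rate, grid, initial=0.0)
        self._B = PchipInterpolator(grid, B, extrapolate=False)

    def base_integral(self, t):
        t_arr = np.asarray(t, dtype=float)
        out = np.where(t_arr <= 0, 0.0, self._B(np.clip(t_arr, 0.0, self.horizon)))
        return out

    def predict(self, data: BMMeasurementSet, theta: dict[str, float]) -> np.ndarray:
        """Model cumulative counts f(t_j, x_j^i) for every observation."""
        mu = theta["mu"]
        bm = GompertzParams(theta["alpha0_bm"], theta["beta_bm"]) if self.variant == "different_growth" else self.traj.pre
        tau = theta.get("tau", 0.0)
        t0 = theta.get("t0", 0.0)
        triples = data.triples()
        times = np.array([t for t, _, _ in triples])
        sizes = np.array([x for _, x, _ in triples])
        arg_clock = 1.0 - bm.beta / bm.alpha0 * np.log(sizes)
        if np.any(arg_clock <= 0):
            raise FloatingPointError("observed size beyond BM carrying capacity")
        clock = -np.log(arg_clock) / bm.beta
        if self.variant == "secondary":
            state = solve_secondary(
                self.traj,
                DisseminationParams(mu=mu, gamma=self.gamma),
                bm,
                horizon=self.horizon,
                step=self.secondary_step,
            )
            from scipy.integrate import cumulative_trapezoid

            cum = cumulative_trapezoid(state.birth_rate, state.grid, initial=0.0)
            f = np.interp(times - clock, state.grid, cum, left=0.0)
            return f
        shift = times - clock - (tau if self.variant == "dormancy" else 0.0)
        f = mu * self.base_integral(shift)
        if self.variant == "delay":
            f = f - mu * float(self.base_integral(t0))
        return np.maximum(f, 0.0)


def sse_objective(
    theta: dict[str, float],
    data: BMMeasurementSet,
    traj: PTTrajectory,
    variant: str,
    gamma: float,
    predictor: _ScenarioPredictor | None = None,
) -> float:
    """SSE(theta) = sum over observations of (y - f(t, x; theta))^2.

    Returns +inf (with a warning) if the model cannot be evaluated at
    theta, so optimizers can step over pathological regions.
    """
    if predictor is None:
        horizon = max(t for t, _ in data.scans) + 1.0
        predictor = _ScenarioPredictor(traj, variant, gamma, horizon)
    y = np.array([r for _, _, r in data.triples()], dtype=float)
    try:
        f = predictor.predict(data, {**theta, "mu": theta["mu"]})
    except (FloatingPointError, ValueError, OverflowError, RuntimeError) as exc:
        warnings.warn(f"model evaluation failed at theta={theta}: {exc}")
        return float("inf")
    return float(np.sum((y - f) ** 2))


# ---------------------------------------------------------------------------
# TGI fit


def fit_tgi(
    pt_data: pd.DataFrame,
    S_Td: float,
    T_d: float = 0.0,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Fit the treatment-phase law (alpha1, kappa, t_res) to PT measurements.

    ``pt_data`` columns: time_days_from_diagnosis (>= 0), diameter_mm.
    Least squares on log sizes (imaging error is multiplicative), with
    parameters on log scale, multi-start Nelder-Mead.  A kappa estimate
    collapsing to ~0 (no measurable response) is flagged.
    """
    post = pt_data[pt_data["time_days_from_diagnosis"] >= 0]
    if len(post) < 4:
        raise ValueError("need at least 4 post-diagnosis points to fit 3 parameters")
    t_obs = post["time_days_from_diagnosis"].to_numpy(dtype=float) + T_d
    ln_y = np.log(cells_from_diameter(post["diameter_mm"].to_numpy(dtype=float)))
    ln2 = math.log(2.0)
    ln_S_Td = math.log(S_Td)

    def ln_model(x):
        alpha1, kappa, t_res = np.exp(x)
        dt = t_obs - T_d
        return ln_S_Td + alpha1 * dt - kappa * (t_res / ln2) * (1.0 - np.exp(-dt * ln2 / t_res))

    def objective(x):
        return float(np.sum((ln_y - ln_model(x)) ** 2))

    rng = np.random.default_rng(seed)
    starts = [np.log([1e-3, 5e-3, 100.0])]
    for _ in range(n_starts - 1):
        starts.append(
            np.log(
                [
                    10 ** rng.uniform(-4, -1.5),
                    10 ** rng.uniform(-3.5, -1),
                    10 ** rng.uniform(1, 2.7),
                ]
            )
        )
    best, trace = None, []
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        res = optimize.minimize(  # one restart from the incumbent
            objective, res.x, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        trace.append({"x0": np.exp(x0).tolist(), "sse": float(res.fun)})
        if best is None or res.fun < best.fun:
            best = res
    alpha1, kappa, t_res = np.exp(best.x)
    theta = {"alpha1": alpha1, "kappa": kappa, "t_res": t_res}
    flags = {}
    if kappa < 1e-8:
        flags["no_response"] = "kappa at lower boundary: no measurable treatment effect"
    fit = FitResult(
        theta_hat=theta,
        sse=float(best.fun),
        n_obs=len(post),
        n_free=3,
        trace=trace,
        converged=bool(best.success),
        flags=flags,
    )

    def predict(th: dict[str, float]) -> np.ndarray:
        return ln_model(np.log([th["alpha1"], th["kappa"], th["t_res"]]))

    _attach_standard_errors(fit, predict, ln_y)
    return fit


# ---------------------------------------------------------------------------
# BM scenario fits


_FREE_PARAMS = {
    "basic": ("mu",),
    "different_growth": ("mu", "alpha0_bm", "beta_bm"),
    "secondary": ("mu",),
    "delay": ("mu", "t0"),
    "dormancy": ("mu", "tau"),
}

#: floor used when optimizing non-negative lag parameters on log scale
_LOG_FLOOR = 1e-3


def _theta_from_x(x: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    return {name: float(math.exp(v)) for name, v in zip(names, x)}


def fit_bm_scenario(
    variant: str,
    data: BMMeasurementSet,
    traj: PTTrajectory,
    gamma_grid: tuple[float, ...] = GAMMA_GRID,
    mu_inits: tuple[float, ...] = MU_INITS,
    lag_inits: tuple[float, ...] | None = None,
    horizon: float | None = None,
    secondary_step: float = 2.0,
    maxiter: int = 2000,
) -> FitResult:
    """Fit one dissemination scenario to cumulative-size data.

    gamma is profiled over ``gamma_grid`` (never continuously optimized);
    for each gamma the free parameters (mu, plus tau or t0, plus the BM
    growth pair for different_growth) are optimized on log scale by
    Nelder-Mead from a grid of initializations (each mu init crossed with
    each lag init), with one restart from the incumbent.  The global best
    across all starts and gamma values is returned.
    """
    if variant not in _FREE_PARAMS:
        raise ValueError(f"unknown variant {variant!r}")
    if data.n_obs == 0:
        raise ValueError("no observations")
    names = _FREE_PARAMS[variant]
    if lag_inits is None:
        lag_inits = TAU_INITS if variant == "dormancy" else T0_INITS
    if horizon is None:
        horizon = max(t for t, _ in data.scans) + 1.0
    y = np.array([r for _, _, r in data.triples()], dtype=float)

    best = None
    best_gamma = None
    trace = []
    n_fail = 0
    for gamma, mu0 in zip(gamma_grid, mu_inits):
        predictor = _ScenarioPredictor(
            traj, variant, gamma, horizon, secondary_step=secondary_step
        )

        def objective(x):
            theta = _theta_from_x(x, names)
            try:
                f = predictor.predict(data, theta)
            except (FloatingPointError, ValueError, OverflowError, RuntimeError):
                return float("inf")
            return float(np.sum((y - f) ** 2))

        if len(names) == 1:
            start_sets = [(mu0,)]
        elif names[1] in ("tau", "t0"):
            start_sets = [(m, max(lag, _LOG_FLOOR)) for m, lag in itertools.product((mu0,), lag_inits)]
        else:  # different_growth: mu + BM growth pair, seeded at the PT law
            start_sets = [
                (mu0, traj.pre.alpha0, traj.pre.beta),
                (mu0, traj.pre.alpha0 * 2, traj.pre.beta * 2),
                (mu0, traj.pre.alpha0 / 2, traj.pre.beta / 2),
                (mu0 * 10, traj.pre.alpha0, traj.pre.beta),
            ]
        for start in start_sets:
            x0 = np.log(np.asarray(start, dtype=float))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    objective, x0, method="Nelder-Mead",
                    options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-10},
                )
                res = optimize.minimize(
                    objective, res.x, method="Nelder-Mead",
                    options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-10},
                )
            if not np.isfinite(res.fun):
                n_fail += 1
                continue
            trace.append(
                {"gamma": gamma, "x0": list(start), "sse": float(res.fun),
                 "theta": _theta_from_x(res.x, names)}
            )
            if best is None or res.fun < best.fun:
                best, best_gamma, best_pred = res, gamma, predictor
    if best is None:
        raise RuntimeError(f"all optimization starts failed for variant {variant!r}; trace: {trace}")
    theta = _theta_from_x(best.x, names)
    theta["gamma"] = best_gamma
    fit = FitResult(
        theta_hat=theta,
        sse=float(best.fun),
        n_obs=data.n_obs,
        n_free=len(names),
        trace=trace,
        converged=bool(best.success),
        flags={"n_failed_starts": n_fail} if n_fail else {},
    )

    def predict(th: dict[str, float]) -> np.ndarray:
        return best_pred.predict(data, th)

    _attach_standard_errors(fit, predict, y, theta_full=theta, free_names=names)
    return fit


# ---------------------------------------------------------------------------
# identifiability


def standard_errors(
    predict,
    theta_hat: dict[str, float],
    free_names: tuple[str, ...],
    y_obs: np.ndarray,
    sse: float,
    rel_step: float = 1e-4,
) -> dict:
    """Asymptotic covariance and relative standard errors at the optimum.

    J is the central finite-difference Jacobian of the model predictions
    with respect to the free parameters (relative step 1e-4);
    sigma2_hat = SSE/(N-P) and Cov = sigma2_hat (J^T J)^{-1}.  The RSE of
    a parameter is 100 * sqrt(Cov_ii) / |estimate|.  A singular (or
    numerically rank-deficient) J^T J is reported through
    ``non_identifiable`` rather than raised.
    """
    n_obs = len(y_obs)
    n_free = len(free_names)
    if n_obs <= n_free:
        raise ValueError("need more observations than free parameters")
    J = np.empty((n_obs, n_free))
    for k, name in enumerate(free_names):
        v = theta_hat[name]
        h = rel_step * abs(v) if v != 0 else rel_step
        up = dict(theta_hat)
        dn = dict(theta_hat)
        up[name] = v + h
        dn[name] = v - h
        J[:, k] = (np.asarray(predict(up)) - np.asarray(predict(dn))) / (2.0 * h)
    sigma2 = sse / (n_obs - n_free)
    JtJ = J.T @ J
    non_identifiable: list[str] = []
    cond = np.linalg.cond(JtJ)
    if not np.isfinite(cond) or cond > 1e12:
        # identify the offending directions from the small singular values
        _, s, vt = np.linalg.svd(JtJ)
        tol = s[0] * 1e-12 if s[0] > 0 else 0.0
        for i, sv in enumerate(s):
            if sv <= tol:
                worst = int(np.argmax(np.abs(vt[i])))
                non_identifiable.append(free_names[worst])
        cov = sigma2 * np.linalg.pinv(JtJ)
    else:
        cov = sigma2 * np.linalg.inv(JtJ)
    rse = {}
    for k, name in enumerate(free_names):
        est = theta_hat[name]
        var = max(cov[k, k], 0.0)
        rse[name] = float("inf") if est == 0 else 100.0 * math.sqrt(var) / abs(est)
    return {
        "sigma2_hat": sigma2,
        "cov": cov,
        "rse_percent": rse,
        "non_identifiable": tuple(non_identifiable),
    }


def _attach_standard_errors(fit, predict, y_obs, theta_full=None, free_names=None):
    theta = theta_full if theta_full is not None else fit.theta_hat
    names = free_names if free_names is not None else tuple(fit.theta_hat)
    try:
        se = standard_errors(predict, theta, names, np.asarray(y_obs), fit.sse)
    except (ValueError, np.linalg.LinAlgError) as exc:
        fit.flags["standard_errors"] = f"unavailable: {exc}"
        return
    fit.sigma2_hat = se["sigma2_hat"]
    fit.cov = se["cov"]
    fit.rse_percent = se["rse_percent"]
    fit.non_identifiable = se["non_identifiable"]


# ---------------------------------------------------------------------------
# model comparison


def compare_models(
    data: BMMeasurementSet,
    traj: PTTrajectory,
    variants: tuple[str, ...] = ("basic", "different_growth", "secondary", "delay", "dormancy"),
    **fit_kwargs,
) -> pd.DataFrame:
    """Minimal SSE per scenario variant, ranked (best first).

    Per-variant failures are recorded in the ``error`` column and do not
    abort the comparison.
    """
    rows = []
    fits = {}
    for variant in variants:
        try:
            fit = fit_bm_scenario(variant, data, traj, **fit_kwargs)
            fits[variant] = fit
            rows.append(
                {"variant": variant, "sse": fit.sse, "n_free": fit.n_free,
                 "gamma": fit.theta_hat.get("gamma"), "error": ""}
            )
        except Exception as exc:  # noqa: BLE001 - isolate per-variant failures
            rows.append(
                {"variant": variant, "sse": float("nan"), "n_free": None,
                 "gamma": None, "error": str(exc)}
            )
    table = pd.DataFrame(rows).sort_values("sse", na_position="last").reset_index(drop=True)
    table.attrs["fits"] = fits
    return table
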