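"""Population-level probability of brain metastasis vs primary-tumor size.

A patient with diagnosis size S has, under gamma = 1, an expected
metastasis count N(T_D) = mu * I(S) with the seeding integral

    I(S) = integral_0^{T_D(S)} S_p(t) dt    (cell * days),

where the Gompertz trajectory is re-calibrated for each S from the
histology doubling time and the fixed carrying capacity.  Inter-patient
heterogeneity is carried entirely by mu, lognormally distributed in the
population (ln mu ~ Normal(ln mu_pop, sigma_log^2)).  The probability
that a patient with size S harbors at least one metastasis at diagnosis
is then P(mu * I(S) > 1), which for gamma = 1 has the closed form
Phi((ln I(S) + ln mu_pop) / sigma_log).  Cohort frequency data binned by
PT diameter (uniform within each bin) are fitted by least squares over
(mu_pop, sigma_log).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats

from .growth import (
    DEFAULT_CARRYING_CAPACITY,
    DOUBLING_TIME_DAYS,
    TumorSizeScale,
    DEFAULT_SCALE,
    calibrate_gompertz,
    cells_from_diameter,
    gompertz_time_to_size,
)

__all__ = [
    "MuPopulationDistribution",
    "CohortSizeBin",
    "PopulationRiskModel",
    "seeding_integral",
    "sigma_log_from_natural_sd",
    "fit_population",
]


@dataclass(frozen=True)
class MuPopulationDistribution:
    """Lognormal population law of the dissemination coefficient mu.

    mu_pop : median of mu (cell^-1 day^-1).
    sigma_log : standard deviation of ln mu (dimensionless).
    """

    mu_pop: float
    sigma_log: float

    def __post_init__(self) -> None:
        if self.mu_pop <= 0:
            raise ValueError("mu_pop must be positive")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be non-negative")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.exp(rng.normal(math.log(self.mu_pop), self.sigma_log, size=n))


def sigma_log_from_natural_sd(mu_pop: float, sd_natural: float) -> float:
    """Convert a natural-scale standard deviation of mu to sigma_log.

    For a lognormal with median m and log-SD s the variance is
    m^2 e^{s^2} (e^{s^2} - 1); this inverts that moment relation, for use
    when heterogeneity is reported in mu's own units rather than on the
    log scale.
    """
    if sd_natural < 0:
        raise ValueError("standard deviation must be non-negative")
    if sd_natural == 0:
        return 0.0
    r2 = (sd_natural / mu_pop) ** 2
    # solve e^{2x} - e^{x} = r2 with x = s^2
    ex = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * r2))
    return math.sqrt(math.log(ex))


@dataclass(frozen=True)
class CohortSizeBin:
    """One diameter interval of a cohort frequency table."""

    d_min: float
    d_max: float
    n_patients: int
    n_with_bm: int

    def __post_init__(self) -> None:
        if not self.d_min < self.d_max:
            raise ValueError("require d_min < d_max")
        if not 0 <= self.n_with_bm <= self.n_patients:
            raise ValueError("require 0 <= n_with_bm <= n_patients")

    @property
    def frequency(self) -> float:
        return self.n_with_bm / self.n_patients


def seeding_integral(
    S: float,
    DT_d: float,
    K: float = DEFAULT_CARRYING_CAPACITY,
    rtol: float = 1e-8,
) -> float:
    """I(S) = integral of the Gompertz trajectory from first cell to T_D(S).

    (alpha0, beta) are re-calibrated for each S from the doubling time at
    that size and the carrying capacity; the integral is adaptive
    quadrature to relative tolerance ``rtol``.  Increasing in S.
    """
    if S <= 1.0:
        return 0.0
    p = calibrate_gompertz(S, DT_d, K)
    T_D = gompertz_time_to_size(S, p)
    a_over_b = p.alpha0 / p.beta

    def integrand(t):
        return np.exp(a_over_b * (1.0 - np.exp(-p.beta * t)))

    val, _ = integrate.quad(integrand, 0.0, T_D, epsrel=rtol, epsabs=0.0, limit=200)
    return val


class PopulationRiskModel:
    """BM-probability-vs-size model for one histology.

    Caches ln I(S) so that repeated evaluations during least-squares
    fitting cost nothing beyond the first pass.
    """

    def __init__(
        self,
        histology: str = "adenocarcinoma",
        K: float = DEFAULT_CARRYING_CAPACITY,
        scale: TumorSizeScale = DEFAULT_SCALE,
        dt_table: dict[str, float] | None = None,
    ) -> None:
        table = dict(DOUBLING_TIME_DAYS)
        if dt_table:
            table.update(dt_table)
        if histology not in table:
            raise KeyError(f"unknown histology {histology!r}; known: {sorted(table)}")
        self.histology = histology
        self.DT_d = table[histology]
        self.K = K
        self.scale = scale
        self._log_I_cache: dict[float, float] = {}

    def log_seeding_integral(self, d_mm: float) -> float:
        key = round(float(d_mm), 9)
        if key not in self._log_I_cache:
            S = cells_from_diameter(d_mm, self.scale)
            self._log_I_cache[key] = math.log(seeding_integral(S, self.DT_d, self.K))
        return self._log_I_cache[key]

    def prob_bm_given_size(self, d_mm: float, dist: MuPopulationDistribution) -> float:
        """P(at least one BM at diagnosis | PT diameter), closed form.

        mu I > 1  <=>  ln mu > -ln I, so the probability is
        Phi((ln I + ln mu_pop)/sigma_log); a step function when
        sigma_log = 0.
        """
        z = self.log_seeding_integral(d_mm) + math.log(dist.mu_pop)
        if dist.sigma_log == 0.0:
            return float(z > 0.0)
        return float(stats.norm.cdf(z / dist.sigma_log))

    def prob_bm_in_bin(
        self,
        bin_: CohortSizeBin,
        dist: MuPopulationDistribution,
        n_mc: int | None = None,
        seed: int | None = None,
        n_quad: int = 64,
    ) -> tuple[float, float]:
        """Mean BM probability over a diameter bin (uniform diameters).

        Deterministic Gauss-Legendre quadrature (``n_quad`` nodes) by
        default; pass ``n_mc`` for the Monte-Carlo estimator.  Returns
        ``(probability, standard_error)`` (SE is 0 for the quadrature).
        """
        if bin_.d_min == bin_.d_max:
            return self.prob_bm_given_size(bin_.d_min, dist), 0.0
        if n_mc is None:
            nodes, weights = np.polynomial.legendre.leggauss(n_quad)
            d = 0.5 * (bin_.d_max - bin_.d_min) * nodes + 0.5 * (bin_.d_max + bin_.d_min)
            probs = self._prob_vec(d, dist)
            return float(np.sum(weights * probs) / 2.0), 0.0
        if n_mc < 1:
            raise ValueError("n_mc must be >= 1")
        rng = np.random.default_rng(seed)
        d = rng.uniform(bin_.d_min, bin_.d_max, size=n_mc)
        probs = self._prob_vec(d, dist)
        se = float(probs.std(ddof=1) / math.sqrt(n_mc)) if n_mc > 1 else float("nan")
        return float(probs.mean()), se

    def _prob_vec(self, d_arr: np.ndarray, dist: MuPopulationDistribution) -> np.ndarray:
        ln_I = np.array([self.log_seeding_integral(x) for x in d_arr])
        z = ln_I + math.log(dist.mu_pop)
        if dist.sigma_log == 0.0:
            return (z > 0.0).astype(float)
        return stats.norm.cdf(z / dist.sigma_log)


def fit_population(
    bins: list[CohortSizeBin],
    model: PopulationRiskModel,
    init: MuPopulationDistribution | None = None,
    n_quad: int = 64,
    mu_pop_floor: float = 1e-20,
) -> dict:
    """Least-squares fit of (mu_pop, sigma_log) to binned cohort frequencies.

    Minimizes sum over bins of (p_model - n_with_bm/n_patients)^2 by
    Nelder-Mead on (ln mu_pop, ln sigma_log).  Returns a dict with the
    fitted distribution, SSE, residuals, and convergence/boundary flags.
    """
    if len(bins) < 2:
        raise ValueError("need at least two bins to fit two parameters")
    if init is None:
        init = MuPopulationDistribution(mu_pop=1e-11, sigma_log=10.0)
    freqs = np.array([b.frequency for b in bins])

    def probs(dist: MuPopulationDistribution) -> np.ndarray:
        return np.array([model.prob_bm_in_bin(b, dist, n_quad=n_quad)[0] for b in bins])

    def objective(x) -> float:
        dist = MuPopulationDistribution(mu_pop=math.exp(x[0]), sigma_log=math.exp(x[1]))
        return float(np.sum((probs(dist) - freqs) ** 2))

    x0 = np.array([math.log(init.mu_pop), math.log(max(init.sigma_log, 1e-6))])
    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-12},
    )
    mu_hat = math.exp(res.x[0])
    best = MuPopulationDistribution(mu_pop=max(mu_hat, mu_pop_floor), sigma_log=math.exp(res.x[1]))
    model_probs = probs(best)
    residuals = model_probs - freqs
    # mu driven toward zero (e.g. all-zero frequencies) => degenerate fit
    degenerate = mu_hat < init.mu_pop * 1e-3 and float(np.max(model_probs)) < 1e-6
    return {
        "distribution": best,
        "sse": float(res.fun),
        "residuals": residuals,
        "converged": bool(res.success),
        "at_lower_bound": mu_hat <= mu_pop_floor or degenerate,
        "n_iter": int(res.nit),
    }
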