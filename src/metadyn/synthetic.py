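"""Synthetic patients and cohorts with the statistical structure the
analysis assumes.

Virtual patients carry a fully known ground truth: a Gompertz-then-TGI
primary-tumor trajectory sampled at scan times with multiplicative
lognormal measurement noise, and brain-metastasis lesions generated
either deterministically (expectation mode: the i-th lesion is born when
the expected count crosses i) or stochastically (inhomogeneous Poisson
thinning), with dormancy lag, Gompertz lesion growth and an imaging
visibility threshold.  Only visible lesions appear in the measurement
tables; the truth record keeps every latent lesion and every generating
parameter, so recovery experiments can score estimates exactly.

Virtual cohorts emulate frequency tables of BM presence per PT-diameter
bin: each patient draws a diameter (uniform within a bin) and a
dissemination coefficient mu (lognormal across patients) and is
BM-positive iff mu * I(S) > 1, with I the pre-diagnosis seeding integral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .growth import (
    DEFAULT_CARRYING_CAPACITY,
    DOUBLING_TIME_DAYS,
    GompertzParams,
    PTTrajectory,
    TGIParams,
    calibrate_gompertz,
    cells_from_diameter,
    diameter_from_cells,
    gompertz_time_to_size,
    make_pt_trajectory,
)
from .dissemination import DisseminationParams, ScenarioSpec
from .discrete import birth_times, lesion_size, stochastic_realization
from .population import (
    CohortSizeBin,
    MuPopulationDistribution,
    PopulationRiskModel,
)

__all__ = [
    "VirtualPatientConfig",
    "VirtualCohortConfig",
    "patient_fixture_path",
    "load_patient_config",
    "build_patient_model",
    "generate_patient",
    "generate_cohort",
]

_FIXTURE_DIR = Path(__file__).parent / "fixtures"


def patient_fixture_path(name: str) -> Path:
    """Path to a bundled virtual-patient YAML fixture ('patient1', 'patient2')."""
    path = _FIXTURE_DIR / f"{name}.yaml"
    if not path.exists():
        raise FileNotFoundError(f"no bundled fixture {name!r} in {_FIXTURE_DIR}")
    return path


@dataclass(frozen=True)
class VirtualPatientConfig:
    """Everything needed to simulate one virtual patient."""

    histology: str
    diameter_at_diagnosis_mm: float
    scenario_variant: str = "dormancy"
    mu: float = 2.0e-12
    gamma: float = 1.0
    tau_days: float = 0.0
    t0_days: float = 0.0
    tgi_alpha1: float = 0.0
    tgi_kappa: float = 0.0
    tgi_t_res: float = 100.0
    bm_visibility_mm: float = 3.0
    ct_visibility_mm: float = 5.0
    carrying_capacity_cells: float = DEFAULT_CARRYING_CAPACITY
    dt_override_days: float | None = None
    bm_growth: tuple[float, float] | None = None  # (alpha0, beta) override
    pt_scan_times_days: tuple[float, ...] = ()  # days from diagnosis
    bm_scan_times_days: tuple[float, ...] = ()
    pt_diameter_cv: float = 0.0
    bm_diameter_cv: float = 0.05
    count_noise_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.pt_scan_times_days) != sorted(self.pt_scan_times_days):
            raise ValueError("PT scan times must be sorted")
        if list(self.bm_scan_times_days) != sorted(self.bm_scan_times_days):
            raise ValueError("BM scan times must be sorted")
        for name in ("pt_diameter_cv", "bm_diameter_cv", "count_noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def doubling_time_days(self) -> float:
        if self.dt_override_days is not None:
            return self.dt_override_days
        return DOUBLING_TIME_DAYS[self.histology]


def load_patient_config(path: str | Path) -> VirtualPatientConfig:
    """Read a virtual-patient YAML config (see the bundled fixtures)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = set(VirtualPatientConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}; known keys: {sorted(known)}")
    for key in ("pt_scan_times_days", "bm_scan_times_days"):
        if key in raw:
            raw[key] = tuple(float(v) for v in raw[key])
    if raw.get("bm_growth") is not None:
        raw["bm_growth"] = tuple(float(v) for v in raw["bm_growth"])
    return VirtualPatientConfig(**raw)


def build_patient_model(cfg: VirtualPatientConfig) -> tuple[PTTrajectory, ScenarioSpec]:
    """Calibrate growth from the config and assemble trajectory + scenario."""
    S_d = cells_from_diameter(cfg.diameter_at_diagnosis_mm)
    pre = calibrate_gompertz(S_d, cfg.doubling_time_days, cfg.carrying_capacity_cells)
    T_d = gompertz_time_to_size(S_d, pre)
    post = None
    if cfg.tgi_alpha1 > 0 or cfg.tgi_kappa > 0:
        post = TGIParams(alpha1=cfg.tgi_alpha1, kappa=cfg.tgi_kappa, t_res=cfg.tgi_t_res, T_d=T_d)
    traj = make_pt_trajectory(pre, post, T_d)
    bm_growth = GompertzParams(*cfg.bm_growth) if cfg.bm_growth is not None else pre
    scenario = ScenarioSpec(
        variant=cfg.scenario_variant,
        dissemination=DisseminationParams(mu=cfg.mu, gamma=cfg.gamma),
        bm_growth=bm_growth,
        t0=cfg.t0_days if cfg.scenario_variant == "delay" else 0.0,
        tau=cfg.tau_days if cfg.scenario_variant == "dormancy" else 0.0,
        S_vis=cells_from_diameter(cfg.bm_visibility_mm),
    )
    return traj, scenario


def generate_patient(
    cfg: VirtualPatientConfig,
    mode: str = "expectation",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate one virtual patient.

    Returns ``(pt_table, bm_table, truth)``: the PT measurement table
    (time_days_from_diagnosis, diameter_mm), the visible-BM table
    (time_days_from_diagnosis, lesion_id, diameter_mm), and the truth
    record with all latent lesions and generating parameters.
    ``mode`` is "expectation" (deterministic births at expected-count
    crossings) or "poisson" (stochastic thinning realization).
    Reproducible given ``cfg.seed``.
    """
    if mode not in ("expectation", "poisson"):
        raise ValueError("mode must be 'expectation' or 'poisson'")
    rng = np.random.default_rng(cfg.seed)
    traj, scenario = build_patient_model(cfg)
    T_d = traj.T_d

    # --- PT table ------------------------------------------------------
    pt_times = np.asarray(cfg.pt_scan_times_days, dtype=float)
    pt_true_mm = diameter_from_cells(traj(pt_times + T_d))
    pt_noise = np.exp(rng.normal(0.0, cfg.pt_diameter_cv, size=pt_times.size)) if cfg.pt_diameter_cv > 0 else 1.0
    pt_table = pd.DataFrame(
        {"time_days_from_diagnosis": pt_times, "diameter_mm": pt_true_mm * pt_noise}
    )

    # --- lesions -------------------------------------------------------
    bm_times = np.asarray(cfg.bm_scan_times_days, dtype=float)
    horizon = T_d + (float(bm_times[-1]) if bm_times.size else 0.0) + 1.0
    if mode == "expectation":
        births = birth_times(traj, scenario.dissemination, horizon, t0=scenario.t0)
    else:
        births = [r.birth_time for r in stochastic_realization(traj, scenario, cfg.seed, horizon)]

    rows = []
    for t_rel in bm_times:
        t = T_d + t_rel
        for lesion_id, T_i in enumerate(births, start=1):
            size = lesion_size(t, T_i, scenario)
            if size >= scenario.S_vis:
                d_mm = diameter_from_cells(size)
                if cfg.bm_diameter_cv > 0:
                    d_mm *= math.exp(rng.normal(0.0, cfg.bm_diameter_cv))
                rows.append(
                    {"time_days_from_diagnosis": t_rel, "lesion_id": lesion_id, "diameter_mm": d_mm}
                )
    bm_table = pd.DataFrame(rows, columns=["time_days_from_diagnosis", "lesion_id", "diameter_mm"])

    truth = {
        "mode": mode,
        "seed": cfg.seed,
        "T_d_days": T_d,
        "gompertz": {"alpha0": traj.pre.alpha0, "beta": traj.pre.beta},
        "tgi": None
        if traj.post is None
        else {"alpha1": traj.post.alpha1, "kappa": traj.post.kappa, "t_res": traj.post.t_res},
        "scenario": {
            "variant": scenario.variant,
            "mu": scenario.dissemination.mu,
            "gamma": scenario.dissemination.gamma,
            "tau": scenario.tau,
            "t0": scenario.t0,
            "S_vis_cells": scenario.S_vis,
        },
        "lesions": [
            {
                "lesion_id": i + 1,
                "birth_time_days": T_i,
                "birth_days_from_diagnosis": T_i - T_d,
            }
            for i, T_i in enumerate(births)
        ],
    }
    return pt_table, bm_table, truth


@dataclass(frozen=True)
class VirtualCohortConfig:
    """Cohort generator settings: diameter bins and mu heterogeneity."""

    bins_mm: tuple[tuple[float, float], ...]
    n_patients_per_bin: tuple[int, ...]
    mu_distribution: MuPopulationDistribution = field(
        default_factory=lambda: MuPopulationDistribution(mu_pop=1.4e-11, sigma_log=6.0)
    )
    histology: str = "adenocarcinoma"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.bins_mm) != len(self.n_patients_per_bin):
            raise ValueError("one patient count per bin required")
        if any(n < 1 for n in self.n_patients_per_bin):
            raise ValueError("each bin needs at least one patient")


def generate_cohort(
    cfg: VirtualCohortConfig,
    model: PopulationRiskModel | None = None,
) -> pd.DataFrame:
    """Simulate a cohort frequency table (one row per diameter bin).

    Per patient: draw a diameter uniformly within the bin and mu from the
    lognormal population law; the patient is BM-positive iff
    mu * I(S) > 1.  Returns columns d_min_mm, d_max_mm, n_patients,
    n_with_bm.  Reproducible given ``cfg.seed``.
    """
    if model is None:
        model = PopulationRiskModel(histology=cfg.histology)
    rng = np.random.default_rng(cfg.seed)
    ln_mu_pop = math.log(cfg.mu_distribution.mu_pop)
    # ln I(d) is smooth; tabulate once and interpolate so that large
    # cohorts do not re-run the calibration chain per patient
    d_lo = min(b[0] for b in cfg.bins_mm)
    d_hi = max(b[1] for b in cfg.bins_mm)
    d_grid = np.linspace(d_lo, d_hi, 201)
    ln_I_grid = np.array([model.log_seeding_integral(x) for x in d_grid])
    rows = []
    for (d_min, d_max), n in zip(cfg.bins_mm, cfg.n_patients_per_bin):
        d = rng.uniform(d_min, d_max, size=n)
        ln_mu = rng.normal(ln_mu_pop, cfg.mu_distribution.sigma_log, size=n)
        ln_I = np.interp(d, d_grid, ln_I_grid)
        n_pos = int(np.sum(ln_mu + ln_I > 0.0))
        rows.append(
            {"d_min_mm": d_min, "d_max_mm": d_max, "n_patients": n, "n_with_bm": n_pos}
        )
    return pd.DataFrame(rows)


def cohort_bins_from_table(table: pd.DataFrame) -> list[CohortSizeBin]:
    """Convert a cohort frequency table to typed bins."""
    return [
        CohortSizeBin(
            d_min=row.d_min_mm, d_max=row.d_max_mm,
            n_patients=int(row.n_patients), n_with_bm=int(row.n_with_bm),
        )
        for row in table.itertuples()
    ]
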