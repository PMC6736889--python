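"""Fitting machinery: cumulative targets, SSE objective, TGI and scenario
fits, identifiability, nested-model behavior and model comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from metadyn.growth import (
    TGIParams,
    cells_from_diameter,
    diameter_from_cells,
    make_pt_trajectory,
    tgi_size,
)
from metadyn.inference import (
    BMMeasurementSet,
    build_cumulative_targets,
    compare_models,
    fit_bm_scenario,
    fit_tgi,
    sse_objective,
    standard_errors,
)
from metadyn.synthetic import generate_patient


class TestBuildTargets:
    def test_ranks_from_descending_sizes(self):
        data = build_cumulative_targets({100.0: [8.0, 5.0, 3.0]})
        triples = data.triples()
        assert [y for _, _, y in triples] == [1, 2, 3]
        assert [x for _, x, _ in triples] == sorted(
            (cells_from_diameter(d) for d in (8.0, 5.0, 3.0)), reverse=True
        )

    def test_ties_get_sequential_ranks(self):
        data = build_cumulative_targets({50.0: [5.0, 5.0]})
        assert [y for _, _, y in data.triples()] == [1, 2]

    def test_reference_fixture_structure(self, patient1_tables):
        """The bundled virtual patient yields 47 points across 6 scans."""
        _, bm, _ = patient1_tables
        data = build_cumulative_targets(bm)
        assert len(data.scans) == 6
        assert data.n_obs == 47

    def test_empty_scans_contribute_nothing(self):
        data = build_cumulative_targets({10.0: [], 20.0: [4.0]})
        assert len(data.scans) == 1

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            build_cumulative_targets({10.0: [3.0, 0.0]})


class TestSSEObjective:
    def test_zero_at_generating_parameters(self, patient1, patient1_tables):
        _, traj, scenario = patient1
        _, bm, truth = patient1_tables
        data = build_cumulative_targets(bm, time_offset=traj.T_d)
        theta = {"mu": truth["scenario"]["mu"], "tau": truth["scenario"]["tau"]}
        sse = sse_objective(theta, data, traj, "dormancy", gamma=1.0)
        assert sse < 1e-6

    def test_perturbing_mu_increases_sse(self, patient1, patient1_tables):
        _, traj, _ = patient1
        _, bm, truth = patient1_tables
        data = build_cumulative_targets(bm, time_offset=traj.T_d)
        mu, tau = truth["scenario"]["mu"], truth["scenario"]["tau"]
        base = sse_objective({"mu": mu, "tau": tau}, data, traj, "dormancy", 1.0)
        up = sse_objective({"mu": mu * 1.3, "tau": tau}, data, traj, "dormancy", 1.0)
        dn = sse_objective({"mu": mu / 1.3, "tau": tau}, data, traj, "dormancy", 1.0)
        assert up > base and dn > base

    def test_invariant_to_scan_order_and_tie_permutation(self, patient1):
        _, traj, _ = patient1
        raw_a = {700.0: [6.0, 4.0, 4.0], 400.0: [3.0]}
        raw_b = {400.0: [3.0], 700.0: [6.0, 4.0, 4.0]}
        theta = {"mu": 2e-12, "tau": 133.0}
        a = sse_objective(theta, build_cumulative_targets(raw_a, traj.T_d), traj, "dormancy", 1.0)
        b = sse_objective(theta, build_cumulative_targets(raw_b, traj.T_d), traj, "dormancy", 1.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_optimizer_matches_brute_force_grid(self, patient1, patient1_tables):
        """2-parameter dormancy problem: grid search cannot beat the optimizer."""
        _, traj, _ = patient1
        _, bm, _ = patient1_tables
        data = build_cumulative_targets(bm, time_offset=traj.T_d)
        fit = fit_bm_scenario("dormancy", data, traj, gamma_grid=(1.0,), mu_inits=(1e-12,))
        grid_best = min(
            sse_objective({"mu": mu, "tau": tau}, data, traj, "dormancy", 1.0)
            for mu in np.geomspace(5e-13, 8e-12, 12)
            for tau in np.linspace(0.0, 400.0, 12)
        )
        assert fit.sse <= grid_best + 1e-9


class TestTGIFit:
    TRUE = dict(alpha1=5.72e-4, kappa=4.46e-3, t_res=149.0)

    def _table(self, noise_cv=0.0, seed=0, n=8, t_max=700.0):
        p = TGIParams(**self.TRUE, T_d=0.0)
        t = np.linspace(0.0, t_max, n)
        cells = np.array([tgi_size(ti, 2.44e10, p) for ti in t])
        if noise_cv > 0:
            rng = np.random.default_rng(seed)
            cells = cells * np.exp(rng.normal(0.0, noise_cv, size=n))
        return pd.DataFrame(
            {"time_days_from_diagnosis": t, "diameter_mm": diameter_from_cells(cells)}
        )

    def test_noiseless_exact_recovery(self):
        fit = fit_tgi(self._table(), S_Td=2.44e10)
        assert fit.theta_hat["alpha1"] == pytest.approx(self.TRUE["alpha1"], rel=1e-4)
        assert fit.theta_hat["kappa"] == pytest.approx(self.TRUE["kappa"], rel=1e-4)
        assert fit.theta_hat["t_res"] == pytest.approx(self.TRUE["t_res"], rel=1e-4)
        assert fit.sse < 1e-12

    def test_noisy_recovery_within_25_percent(self):
        """5% lognormal imaging noise over a 1400-day follow-up (response
        and regrowth both observed): alpha1 recovers to ~25% typically."""
        errs = []
        for seed in (1, 3, 5, 7, 9):
            fit = fit_tgi(
                self._table(noise_cv=0.05, seed=seed, n=14, t_max=1400.0),
                S_Td=2.44e10,
                n_starts=4,
            )
            errs.append(abs(fit.theta_hat["alpha1"] - self.TRUE["alpha1"]) / self.TRUE["alpha1"])
        assert np.median(errs) < 0.25

    def test_monotone_data_flags_no_response(self):
        t = np.linspace(0.0, 700.0, 8)
        cells = 2.44e10 * np.exp(1e-3 * t)
        table = pd.DataFrame(
            {"time_days_from_diagnosis": t, "diameter_mm": diameter_from_cells(cells)}
        )
        fit = fit_tgi(table, S_Td=2.44e10)
        assert fit.theta_hat["kappa"] < 1e-6 or "no_response" in fit.flags

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_tgi(self._table(n=3), S_Td=2.44e10)


class TestScenarioFit:
    def test_noiseless_dormancy_recovery(self, patient1, patient1_tables):
        """Exact recovery of (mu, tau) and selection of gamma=1."""
        _, traj, _ = patient1
        _, bm, truth = patient1_tables
        data = build_cumulative_targets(bm, time_offset=traj.T_d)
        fit = fit_bm_scenario("dormancy", data, traj)
        assert fit.theta_hat["gamma"] == 1.0
        assert fit.theta_hat["mu"] == pytest.approx(truth["scenario"]["mu"], rel=1e-3)
        assert fit.theta_hat["tau"] == pytest.approx(truth["scenario"]["tau"], rel=1e-3)
        assert fit.sse < 1e-6

    def test_basic_data_fitted_by_dormancy_gives_zero_lag(self, patient1):
        _, traj, _ = patient1
        sc = {"mu": 2e-12}
        from metadyn.dissemination import DisseminationParams, ScenarioSpec
        from metadyn.synthetic import VirtualPatientConfig

        cfg = VirtualPatientConfig(
            histology="adenocarcinoma",
            diameter_at_diagnosis_mm=36.0,
            scenario_variant="basic",
            mu=2e-12,
            tgi_alpha1=5.72e-4,
            tgi_kappa=4.46e-3,
            tgi_t_res=149.0,
            bm_scan_times_days=(500.0, 700.0, 900.0, 1100.0),
            bm_diameter_cv=0.0,
        )
        _, bm, _ = generate_patient(cfg)
        data = build_cumulative_targets(bm, time_offset=traj.T_d)
        fit = fit_bm_scenario(
            "dormancy", data, traj, gamma_grid=(1.0,), mu_inits=(1e-12,)
        )
        assert fit.theta_hat["tau"] < 1.0

    def test_stochastic_recovery_over_seeds(self, patient1, patient1_tables):
        """With additive count noise (sigma=0.5), mu and tau recover to
        median relative errors below 30% and 20% across seeds."""
        _, traj, _ = patient1
        _, bm, truth = patient1_tables
        clean = build_cumulative_targets(bm, time_offset=traj.T_d)
        mu_true = truth["scenario"]["mu"]
        tau_true = truth["scenario"]["tau"]
        mu_err, tau_err = [], []
        for seed in range(20):
            noisy = clean.with_count_noise(0.5, np.random.default_rng(seed))
            fit = fit_bm_scenario(
                "dormancy", noisy, traj, gamma_grid=(1.0,), mu_inits=(1e-12,)
            )
            mu_err.append(abs(fit.theta_hat["mu"] - mu_true) / mu_true)
            tau_err.append(abs(fit.theta_hat["tau"] - tau_true) / tau_true)
        assert np.median(mu_err) < 0.30
        assert np.median(tau_err) < 0.20

    def test_nested_model_inequality(self, patient1, patient1_tables):
        """Adding a free lag parameter never worsens the optimal SSE."""
        _, traj, _ = patient1
        _, bm, _ = patient1_tables
        noisy = build_cumulative_targets(bm, time_offset=traj.T_d).with_count_noise(
            0.5, np.random.default_rng(99)
        )
        kw = dict(gamma_grid=(1.0,), mu_inits=(1e-12,))
        sse_basic = fit_bm_scenario("basic", noisy, traj, **kw).sse
        sse_dorm = fit_bm_scenario("dormancy", noisy, traj, **kw).sse
        sse_delay = fit_bm_scenario("delay", noisy, traj, **kw).sse
        assert sse_dorm <= sse_basic + 1e-6
        assert sse_delay <= sse_basic + 1e-6


class TestStandardErrors:
    def test_linear_model_matches_textbook_formula(self):
        """y = theta * t: SE^2 = sigma2 / sum(t^2)."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        theta_true = 2.0
        y = theta_true * t + np.array([0.1, -0.2, 0.15, -0.05, 0.0])
        theta_hat = float(np.dot(t, y) / np.dot(t, t))
        sse = float(np.sum((y - theta_hat * t) ** 2))

        se = standard_errors(
            predict=lambda th: th["slope"] * t,
            theta_hat={"slope": theta_hat},
            free_names=("slope",),
            y_obs=y,
            sse=sse,
        )
        expected_var = sse / (len(t) - 1) / float(np.dot(t, t))
        assert se["cov"][0, 0] == pytest.approx(expected_var, rel=1e-6)
        assert se["rse_percent"]["slope"] == pytest.approx(
            100.0 * math.sqrt(expected_var) / theta_hat, rel=1e-6
        )

    def test_duplicated_parameter_detected_as_singular(self):
        t = np.linspace(1.0, 5.0, 6)
        y = 3.0 * t
        se = standard_errors(
            predict=lambda th: (th["a"] + th["b"]) * t,
            theta_hat={"a": 1.5, "b": 1.5},
            free_names=("a", "b"),
            y_obs=y,
            sse=0.01,
        )
        assert len(se["non_identifiable"]) >= 1

    def test_covariance_within_factor_two_of_bootstrap(self):
        rng = np.random.default_rng(5)
        t = np.linspace(1.0, 10.0, 30)
        sigma = 0.5
        y = 2.0 * t + rng.normal(0.0, sigma, size=t.size)

        def ols(yy):
            return float(np.dot(t, yy) / np.dot(t, t))

        theta_hat = ols(y)
        sse = float(np.sum((y - theta_hat * t) ** 2))
        se = standard_errors(
            predict=lambda th: th["slope"] * t,
            theta_hat={"slope": theta_hat},
            free_names=("slope",),
            y_obs=y,
            sse=sse,
        )
        boots = []
        resid = y - theta_hat * t
        for _ in range(400):
            idx = rng.integers(0, t.size, t.size)
            boots.append(ols(theta_hat * t + resid[idx]))
        boot_se = float(np.std(boots, ddof=1))
        asym_se = math.sqrt(se["cov"][0, 0])
        assert 0.5 < asym_se / boot_se < 2.0

    def test_dormancy_fit_identifiable_at_generous_n(self, patient1, patient1_tables):
        _, traj, _ = patient1
        _, bm, _ = patient1_tables
        noisy = build_cumulative_targets(bm, time_offset=traj.T_d).with_count_noise(
            0.5, np.random.default_rng(1)
        )
        fit = fit_bm_scenario("dormancy", noisy, traj, gamma_grid=(1.0,), mu_inits=(1e-12,))
        assert fit.rse_percent is not None
        assert fit.rse_percent["mu"] < 5.0
        assert fit.rse_percent["tau"] < 5.0


class TestCompareModels:
    def test_dormancy_generated_data_ranks_dormancy_family_first(
        self, patient1, patient1_tables
    ):
        _, traj, _ = patient1
        _, bm, _ = patient1_tables
        data = build_cumulative_targets(bm, time_offset=traj.T_d)
        table = compare_models(data, traj)
        assert len(table) == 5
        assert np.all(table["sse"].dropna() >= 0)
        assert table.iloc[0]["variant"] in ("dormancy", "different_growth")

    def test_failures_are_isolated(self, patient1, patient1_tables):
        _, traj, _ = patient1
        _, bm, _ = patient1_tables
        data = build_cumulative_targets(bm, time_offset=traj.T_d)
        table = compare_models(
            data, traj, variants=("basic", "nonexistent"), gamma_grid=(1.0,), mu_inits=(1e-12,)
        )
        ok = table[table["variant"] == "basic"]
        bad = table[table["variant"] == "nonexistent"]
        assert ok["error"].iloc[0] == ""
        assert bad["error"].iloc[0] != ""
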