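"""NLME engine: objective correctness, empirical Bayes, population fits."""

import math

import numpy as np
import pytest
from scipy import optimize

import stpdosim as sd
from stpdosim.nlme import (
    FitSettings,
    PopulationParams,
    _blocks_from_dataset,
    _ModelOps,
    _Profile,
)


def _make_single_patient(model, params, times, rng=None, noise=0.0):
    obs = []
    for t in times:
        f = sd.evaluate(model, params, t)
        y = f * math.exp(rng.normal(0.0, noise)) if noise else f
        obs.append(sd.Observation("P1", t, y))
    return obs


class TestMarginalObjective:
    def test_zero_residuals_value(self):
        """With exact predictions and no random effects the joint -2 log
        density reduces to N log(2 pi sigma2)."""
        model = sd.get_model("f3a")
        p = {"A1": 3.0, "lambda1": 2e-4, "lambda2": 3e-3}
        times = [200.0, 1500.0, 4000.0]
        obs = [sd.Observation("P1", t, sd.evaluate(model, p, t))
               for t in times]
        obs += [sd.Observation("P2", t, sd.evaluate(model, p, t))
                for t in times]
        data = sd.BiokineticDataset(obs)
        sigma2 = 0.04
        pop = PopulationParams(tvp=np.array([3.0, 2e-4, 3e-3]),
                               omega2=np.zeros(3), sigma2_intra=sigma2)
        etas = {pid: np.zeros(3) for pid in data.patients}
        val = sd.marginal_objective(model, pop, etas, data)
        assert val == pytest.approx(6 * math.log(2 * math.pi * sigma2))
        pop2 = PopulationParams(tvp=pop.tvp, omega2=np.zeros(3),
                                sigma2_intra=2 * sigma2)
        val2 = sd.marginal_objective(model, pop2, etas, data)
        assert val2 - val == pytest.approx(6 * math.log(2.0))

    def test_invalid_individual_gives_infinite_objective(self):
        model = sd.get_model("f4d")
        p = {"A1": 100.0, "alpha": 0.9, "lambda1": 1e-4, "lambda2": 1e-3}
        obs = [sd.Observation("P1", 1000.0, sd.evaluate(model, p, 1000.0)),
               sd.Observation("P2", 1000.0, sd.evaluate(model, p, 1000.0))]
        data = sd.BiokineticDataset(obs)
        pop = PopulationParams(tvp=np.array([100.0, 0.9, 1e-4, 1e-3]),
                               omega2=np.full(4, 0.1), sigma2_intra=0.04)
        etas = {"P1": np.array([0.0, 0.5, 0.0, 0.0]),  # alpha -> 1.48
                "P2": np.zeros(4)}
        assert sd.marginal_objective(model, pop, etas, data) == math.inf

    def test_laplace_exact_for_linear_random_effect(self):
        """For a model linear in its random effect the Laplace OFV equals
        the closed-form Gaussian marginal."""
        model = sd.get_model("f3a")
        rng = np.random.default_rng(0)
        tvp = np.array([5.0, 2e-4, 3e-3])
        w, sig2 = 0.09, 0.04
        obs = []
        for pid in range(4):
            eta = rng.normal(0, math.sqrt(w))
            for t in (180.0, 300.0, 1400.0, 2800.0, 4200.0):
                f = sd.evaluate(model, {"A1": tvp[0] * math.exp(eta),
                                        "lambda1": tvp[1],
                                        "lambda2": tvp[2]}, t)
                obs.append(sd.Observation(
                    f"P{pid}", t, f * math.exp(rng.normal(0, math.sqrt(sig2)))))
        data = sd.BiokineticDataset(obs)

        s = FitSettings(fixed_omega2=[w, 0.0, 0.0])
        ops = _ModelOps(model, sd.DecayConstants(), "lognormal")
        prof = _Profile(ops, _blocks_from_dataset(data), s)
        theta = np.concatenate([ops.x_from_tvp(tvp), [math.log(sig2)]])
        laplace = prof.ofv(theta)

        exact = 0.0
        for pid in data.patients:
            t, y = data.patient_arrays(pid)
            f0 = sd.evaluate(model, dict(zip(model.param_names, tvp)), t)
            r = np.log(y) - np.log(f0)
            S = sig2 * np.eye(len(t)) + w * np.ones((len(t), len(t)))
            _, logdet = np.linalg.slogdet(2 * np.pi * S)
            exact += logdet + r @ np.linalg.solve(S, r)
        assert laplace == pytest.approx(exact, abs=1e-6)


class TestEmpiricalBayes:
    def test_grid_search_oracle_single_eta(self, f4d_fit):
        """1-D posterior mode matches a brute-force grid search."""
        model = sd.get_model("f4d")
        p = {"A1": 129.36, "alpha": 0.31, "lambda1": 1.5e-4,
             "lambda2": 8.8e-4}
        rng = np.random.default_rng(3)
        obs = _make_single_patient(model, p, [1400.0], rng, noise=0.2)
        data = sd.BiokineticDataset(obs)
        w = 0.09
        pop = PopulationParams(tvp=np.array(
            [129.36, 0.31, 1.5e-4, 8.8e-4]),
            omega2=np.array([w, 0.0, 0.0, 0.0]), sigma2_intra=0.044)

        grid = np.linspace(-0.9, 0.9, 4001)
        vals = [sd.marginal_objective(
            model, pop, {"P1": np.array([g, 0, 0, 0])}, data)
            for g in grid]
        eta_grid = grid[int(np.argmin(vals))]

        fit = sd.PopulationFit(
            model=model, pop=pop, individuals=[], ofv=0.0,
            fixed_effect_cov=None, cv_percent=None, converged=True,
            n_obs=1, alpha_scale="lognormal", dc=sd.DecayConstants())
        est = sd.empirical_bayes(fit, obs)
        assert est.eta[0] == pytest.approx(eta_grid, abs=1e-3)
        assert np.all(est.eta[1:] == 0.0)

    def test_no_observations_shrinks_to_population(self, f4d_fit):
        est = sd.empirical_bayes(f4d_fit, [])
        assert np.all(est.eta == 0.0)
        np.testing.assert_allclose(
            [est.params[n] for n in f4d_fit.model.param_names],
            f4d_fit.pop.tvp)

    def test_shrinkage_with_fewer_observations(self, cohort, f4d_fit):
        """Mean |eta| over patients decreases as observations are removed
        (posterior modes shrink toward the population)."""
        data, _ = cohort
        means = []
        for k in (5, 3, 1):
            norms = []
            for pid in data.patients:
                obs = sorted(data.of_patient(pid), key=lambda o: o.time)
                sub = [sd.Observation("new", o.time, o.activity)
                       for o in obs[:k]]
                est = sd.empirical_bayes(f4d_fit, sub)
                norms.append(float(np.mean(np.abs(est.eta))))
            means.append(float(np.mean(norms)))
        assert means[0] >= means[1] >= means[2]


class TestFitPopulation:
    def test_single_patient_rejected(self, cohort, fast_settings):
        data, _ = cohort
        solo = sd.BiokineticDataset(data.of_patient(data.patients[0]))
        with pytest.raises(ValueError, match="2 patients"):
            sd.fit_population(solo, sd.get_model("f4d"), fast_settings)

    def test_pooled_limit_matches_least_squares(self, cohort):
        """With all random effects off, the fit reduces to pooled NLS on
        log-activities (independent least-squares oracle)."""
        data, truth = cohort
        model = sd.get_model("f4d")
        s = FitSettings(multistarts=3, seed=0, compute_cov=False,
                        fixed_omega2=np.zeros(4), max_restarts=1)
        fit = sd.fit_population(data, model, s)

        t = np.concatenate([data.patient_arrays(p)[0]
                            for p in data.patients])
        logy = np.log(np.concatenate([data.patient_arrays(p)[1]
                                      for p in data.patients]))

        def resid(z):
            p = {"A1": math.exp(z[0]), "alpha": 1 / (1 + math.exp(-z[1])),
                 "lambda1": math.exp(z[2]), "lambda2": math.exp(z[3])}
            if p["lambda1"] > p["lambda2"]:
                return np.full(t.size, 1e3)
            f = sd.evaluate(model, p, t)
            if np.any(f <= 0):
                return np.full(t.size, 1e3)
            return logy - np.log(f)

        z0 = [math.log(129.36), math.log(0.31 / 0.69), math.log(1.5e-4),
              math.log(8.8e-4)]
        res = optimize.least_squares(resid, z0, method="lm", max_nfev=2000)
        oracle = np.array([math.exp(res.x[0]),
                           1 / (1 + math.exp(-res.x[1])),
                           math.exp(res.x[2]), math.exp(res.x[3])])
        np.testing.assert_allclose(fit.pop.tvp, oracle, rtol=1e-3)

    def test_predict_curve(self, cohort, f4d_fit):
        data, _ = cohort
        pid = data.patients[0]
        assert sd.predict_curve(f4d_fit, pid, 0.0) == 0.0
        t = np.array([60.0, 600.0, 6000.0])
        curve = sd.predict_curve(f4d_fit, pid, t)
        assert np.all(curve > 0.0)
        with pytest.raises(KeyError):
            sd.predict_curve(f4d_fit, "nobody", 100.0)

    def test_fit_reports_finite_ofv_and_individuals(self, cohort, f4d_fit):
        data, _ = cohort
        assert math.isfinite(f4d_fit.ofv)
        assert len(f4d_fit.individuals) == len(data.patients)
        for ind in f4d_fit.individuals:
            vals = np.array([ind.params[n]
                             for n in f4d_fit.model.param_names])
            assert np.all(vals > 0.0)
            assert ind.params["alpha"] <= 1.0
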