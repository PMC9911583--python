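"""Synthetic cohort generator: design fidelity and statistical structure."""

import numpy as np
import pytest

import stpdosim as sd
from stpdosim.nlme import PopulationParams


class TestDesign:
    def test_default_cohort_size(self, cohort):
        data, truth = cohort
        assert len(data.patients) == 8
        assert data.n_obs == 40
        assert truth.model_id == "f4d"

    def test_schedule_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            sd.StudyDesign(schedule=((4.6, 0.4), (2.9, 0.6)))
        with pytest.raises(ValueError, match="SDs"):
            sd.StudyDesign(schedule=((2.9, -0.1), (4.6, 0.4)))

    def test_default_truth_matches_published_estimates(self):
        pop = sd.default_population_params()
        np.testing.assert_allclose(pop.tvp, [129.36, 0.31, 1.5e-4, 8.8e-4])
        np.testing.assert_allclose(pop.omega2, [0.08, 0.01, 2.9e-4, 1.1])
        assert pop.sigma2_intra == pytest.approx(4.4e-2)


class TestReproducibility:
    def test_same_seed_identical(self):
        d1, _ = sd.simulate_cohort(seed=11)
        d2, _ = sd.simulate_cohort(seed=11)
        assert [(o.patient_id, o.time, o.activity)
                for o in d1.observations] == \
               [(o.patient_id, o.time, o.activity)
                for o in d2.observations]

    def test_different_seeds_differ(self):
        d1, _ = sd.simulate_cohort(seed=11)
        d2, _ = sd.simulate_cohort(seed=12)
        assert [o.activity for o in d1.observations] != \
               [o.activity for o in d2.observations]


class TestNoiseStructure:
    def test_zero_variance_cohort_lies_on_population_curve(self):
        truth = sd.GroundTruth(pop=PopulationParams(
            tvp=np.array([129.36, 0.31, 1.5e-4, 8.8e-4]),
            omega2=np.zeros(4), sigma2_intra=0.0))
        data, filled = sd.simulate_cohort(truth=truth, seed=5)
        model = sd.get_model("f4d")
        p = dict(zip(model.param_names, truth.pop.tvp))
        for obs in data.observations:
            assert obs.activity == pytest.approx(
                sd.evaluate(model, p, obs.time), rel=1e-12)
        for pt in filled.patients:
            assert pt.tia == pytest.approx(129.36)

    def test_log_variance_converges_to_omega2(self):
        """Law of large numbers: the log-scale spread of simulated
        individual parameters approaches the generating variances."""
        design = sd.StudyDesign(n_patients=10000)
        data, truth = sd.simulate_cohort(design, seed=42)
        model = sd.get_model("f4d")
        P = np.array([[pt.params[n] for n in model.param_names]
                      for pt in truth.patients])
        logvar = np.log(P).var(axis=0, ddof=1)
        # alpha is clipped by the redraw rule; compare the unclipped ones
        for j in (0, 2, 3):
            assert logvar[j] == pytest.approx(truth.pop.omega2[j], rel=0.05)

    def test_alpha_redraw_keeps_fraction_in_unit_interval(self):
        truth = sd.GroundTruth(pop=PopulationParams(
            tvp=np.array([129.36, 0.9, 1.5e-4, 8.8e-4]),
            omega2=np.array([0.01, 1.0, 1e-4, 0.01]),
            sigma2_intra=1e-3))
        _, filled = sd.simulate_cohort(
            sd.StudyDesign(n_patients=50), truth, seed=7)
        alphas = [pt.params["alpha"] for pt in filled.patients]
        assert all(0.0 <= a <= 1.0 for a in alphas)

    def test_schedule_draws_mostly_ordered(self):
        design = sd.StudyDesign(n_patients=500)
        data, _ = sd.simulate_cohort(design, seed=3)
        ordered = 0
        for pid in data.patients:
            t, _ = data.patient_arrays(pid)
            ordered += bool(np.all(np.diff(t) > 0))
        assert ordered / len(data.patients) >= 0.99
        assert all(o.time > 0 for o in data.observations)


class TestDesignInformation:
    def test_default_noise_makes_4param_cvs_exceed_gate(self):
        """Best-case Fisher CVs at the default design: the fraction and
        rate parameters of the 4-parameter model cannot be estimated below
        the 50% goodness-of-fit threshold, so gate rejections of f4d on
        synthetic cohorts reflect the assumed noise level, not fit bugs."""
        from stpdosim.experiments import design_cv_bound

        cv = design_cv_bound()
        assert cv["A1"] < 50.0
        assert cv["alpha"] > 50.0
        assert cv["lambda1"] > 50.0
        assert cv["lambda2"] > 50.0


class TestTrueTIA:
    def test_zero_eta_reproduces_population_tia(self):
        truth = sd.GroundTruth(pop=PopulationParams(
            tvp=np.array([129.36, 0.31, 1.5e-4, 8.8e-4]),
            omega2=np.zeros(4), sigma2_intra=1e-3))
        _, filled = sd.simulate_cohort(truth=truth, seed=1)
        assert sd.true_tia(filled, "P1") == pytest.approx(129.36)

    def test_tia_scales_with_amplitude_effect(self):
        data, truth = sd.simulate_cohort(seed=9)
        for pt in truth.patients:
            expected = 129.36 * np.exp(pt.eta[0])
            assert pt.tia == pytest.approx(expected, rel=1e-9)

    def test_non_f4d_truth_matches_quadrature(self):
        truth = sd.GroundTruth(
            model_id="f3a",
            pop=PopulationParams(tvp=np.array([5.0, 2e-4, 3e-3]),
                                 omega2=np.array([0.05, 1e-4, 1e-4]),
                                 sigma2_intra=0.01))
        _, filled = sd.simulate_cohort(truth=truth, seed=2)
        model = sd.get_model("f3a")
        for pt in filled.patients[:3]:
            oracle = sd.tia_numeric(model, pt.params, t_end=1e7)
            assert sd.true_tia(filled, pt.patient_id) == pytest.approx(
                oracle, rel=1e-4)
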