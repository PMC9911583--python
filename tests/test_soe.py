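"""Sum-of-exponential models: evaluation, integrals, constraints."""

import math

import numpy as np
import pytest
from scipy import integrate

import stpdosim as sd
from stpdosim.soe import (
    ALL_MODEL_IDS,
    DecayConstants,
    DegenerateParameterError,
    InfiniteTIAError,
    ParameterBoundError,
    get_model,
)

from conftest import random_valid_params

# published population estimates for 111In-DOTATATE kidney kinetics
KIDNEY_F4D = {"A1": 129.36, "alpha": 0.31, "lambda1": 1.5e-4,
             "lambda2": 8.8e-4}


def quad_tia(model, params):
    """Independent quadrature oracle for the time-integral."""
    f = lambda t: sd.evaluate(model, params, t)  # noqa: E731
    total = 0.0
    for a, b in [(0.0, 50.0), (50.0, 1e5), (1e5, 1e7)]:
        val, _ = integrate.quad(f, a, b, epsrel=1e-10, limit=400)
        total += val
    return total


class TestDecayConstants:
    def test_indium_physical_rate(self):
        dc = DecayConstants()
        assert dc.lambda_phys == pytest.approx(1.72e-4, rel=5e-3)
        assert dc.lambda_bc == math.log(2.0)

    def test_other_nuclide(self):
        dc = DecayConstants.for_nuclide(6.0)
        assert dc.lambda_phys == pytest.approx(math.log(2) / 360.0)
        with pytest.raises(ValueError):
            DecayConstants.for_nuclide(0.0)


@pytest.mark.parametrize("model_id", ALL_MODEL_IDS)
def test_curve_starts_at_zero(model_id):
    """f(0) = 0 exactly for every model and random valid parameters."""
    model = get_model(model_id)
    rng = np.random.default_rng(hash(model_id) % 2**31)
    for _ in range(20):
        p = random_valid_params(model, rng)
        assert sd.evaluate(model, p, 0.0) == 0.0


@pytest.mark.parametrize("model_id", ALL_MODEL_IDS)
def test_analytic_tia_matches_quadrature(model_id):
    """Closed-form integral agrees with adaptive quadrature to 0.01%."""
    model = get_model(model_id)
    rng = np.random.default_rng(1 + hash(model_id) % 2**31)
    for _ in range(5):
        p = random_valid_params(model, rng)
        tia = sd.analytic_tia(model, p)
        oracle = quad_tia(model, p)
        assert tia == pytest.approx(oracle, rel=1e-4, abs=1e-12)


def test_f4e_is_mirrored_f4d():
    """f4e(alpha') equals f4d(1 - alpha') at all times (same function)."""
    t = np.array([60.0, 1440.0, 4320.0])
    pd_ = dict(KIDNEY_F4D)
    pe = dict(KIDNEY_F4D, alpha=1.0 - KIDNEY_F4D["alpha"])
    vd = sd.evaluate(get_model("f4d"), pd_, t)
    ve = sd.evaluate(get_model("f4e"), pe, t)
    np.testing.assert_allclose(ve, vd, rtol=1e-12)


def test_f3a_fast_uptake_limit():
    """With instant uptake the curve reduces to pure physical decay."""
    p = {"A1": 1.0, "lambda1": 0.0, "lambda2": 1e3}
    val = sd.evaluate(get_model("f3a"), p, 1440.0)
    dc = DecayConstants()
    assert val == pytest.approx(math.exp(-dc.lambda_phys * 1440.0), rel=1e-9)


@pytest.mark.parametrize("model_id", ["f3a", "f3c", "f4a", "f4b", "f4c",
                                      "f4d", "f4e", "f5a", "f5b"])
def test_prefactor_homogeneity(model_id):
    """Doubling every prefactor doubles the curve."""
    model = get_model(model_id)
    rng = np.random.default_rng(7)
    p = random_valid_params(model, rng)
    p2 = {k: (2.0 * v if k.startswith("A") else v) for k, v in p.items()}
    t = np.array([100.0, 1000.0, 5000.0])
    np.testing.assert_allclose(
        sd.evaluate(model, p2, t), 2.0 * sd.evaluate(model, p, t), rtol=1e-12)


class TestAnalyticTIA:
    def test_f4d_equals_prefactor(self):
        assert sd.analytic_tia(get_model("f4d"), KIDNEY_F4D) == pytest.approx(
            129.36, rel=1e-12)

    def test_f3d_reciprocal(self):
        p = {"A1": 2.0, "lambda1": 1e-4, "lambda2": 1e-3}
        assert sd.analytic_tia(get_model("f3d"), p) == pytest.approx(0.5)

    def test_f3c_equals_prefactor(self):
        p = {"A1": 42.0, "lambda1": 1e-4, "lambda2": 1e-3}
        assert sd.analytic_tia(get_model("f3c"), p) == pytest.approx(42.0)

    def test_zero_prefactors(self):
        p = {"A1": 0.0, "A2": 0.0, "lambda1": 1e-4, "lambda2": 1e-3}
        assert sd.analytic_tia(get_model("f4a"), p) == 0.0

    def test_zero_prefactor_reciprocal_is_error(self):
        p = {"A1": 0.0, "lambda1": 1e-4, "lambda2": 1e-3}
        with pytest.raises(DegenerateParameterError):
            sd.analytic_tia(get_model("f3d"), p)

    def test_nondecaying_term_diverges(self):
        # with no physical decay, a zero biological rate leaves a
        # constant term whose integral diverges
        dc = DecayConstants(lambda_phys=0.0)
        p = {"A1": 2.0, "lambda1": 0.0, "lambda2": 1e-3}
        with pytest.raises(InfiniteTIAError):
            sd.analytic_tia(get_model("f3a"), p, dc)


class TestHalfLife:
    def test_biological_half_lives(self):
        assert sd.half_life_hours(1.5e-4) == pytest.approx(77.0, abs=0.05)
        assert sd.half_life_hours(8.8e-4) == pytest.approx(13.1, abs=0.05)

    def test_one_minute(self):
        assert sd.half_life_hours(math.log(2.0)) == pytest.approx(1 / 60)

    def test_nonpositive_rate(self):
        with pytest.raises(ValueError):
            sd.half_life_hours(0.0)


class TestValidation:
    def test_alpha_out_of_range(self):
        v = sd.validate_params(get_model("f4d"), dict(KIDNEY_F4D, alpha=1.2))
        assert any("alpha" in msg for msg in v)

    def test_negative_rate(self):
        v = sd.validate_params(
            get_model("f3a"), {"A1": 1.0, "lambda1": -0.1, "lambda2": 1e-3})
        assert any("lambda1" in msg for msg in v)

    def test_ordering_violation(self):
        v = sd.validate_params(
            get_model("f3a"), {"A1": 1.0, "lambda1": 1e-3, "lambda2": 1e-4})
        assert any("ordering" in msg for msg in v)

    def test_published_estimates_are_valid(self):
        assert sd.validate_params(get_model("f4d"), KIDNEY_F4D) == []

    def test_evaluate_rejects_bad_params(self):
        with pytest.raises(ParameterBoundError):
            sd.evaluate(get_model("f4d"), dict(KIDNEY_F4D, alpha=1.2), 10.0)

    def test_degenerate_rates(self):
        p = {"A1": 1.0, "lambda1": 1e-3, "lambda2": 1e-3}
        for mid in ("f3b", "f3c", "f3d"):
            with pytest.raises(DegenerateParameterError):
                sd.evaluate(get_model(mid), p, 10.0)

    def test_unknown_model(self):
        with pytest.raises(ValueError, match="unknown model"):
            get_model("f9z")
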