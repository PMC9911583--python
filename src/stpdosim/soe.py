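"""Sum-of-exponential (SOE) time-activity models for organ dosimetry.

Eleven parameterisations of mono-, bi- and tri-exponential kinetics with
3, 4 or 5 adjustable parameters, used to describe the percentage of
administered activity in an organ as a function of time after injection.
All models satisfy ``f(0) = 0`` exactly: activity enters the organ from the
blood, so nothing is present at the moment of injection.  The 4- and
5-parameter forms additionally carry a fixed fast uptake term with a
half-life of 1 min (``lambda_bc``) representing blood circulation, which is
not an adjustable parameter because the first imaging session takes place
hours after injection.

Every model is represented internally as a plain sum of exponential terms
``f(t) = sum_k c_k * exp(-r_k * t)`` whose coefficients sum to zero.  This
single representation provides evaluation and the closed-form time-integral
``TIA = sum_k c_k / r_k``.

Units: time in minutes, rates in 1/min, activities in % of administered
activity.  The prefactor ``A1`` is an amplitude (%) for most models; for
``f4d``/``f4e`` it is the time-integrated activity itself (%*min) and for
``f3b``/``f3d`` its reciprocal is the time-integrated activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

LN2 = math.log(2.0)

#: physical half-life of 111In in hours; ln2 / (67.31 h) = 1.72e-4 / min
INDIUM111_HALF_LIFE_H = 67.31


class SOEError(ValueError):
    """Base class for model-evaluation errors."""


class ParameterBoundError(SOEError):
    """A parameter violates its bounds (A, lambda >= 0; alpha in [0, 1])."""


class DegenerateParameterError(SOEError):
    """Parameters make the model ill-defined (e.g. lambda1 == lambda2)."""


class InfiniteTIAError(SOEError):
    """The time-integral of the curve diverges."""


@dataclass(frozen=True)
class DecayConstants:
    """Fixed rate constants shared by all models, in 1/min.

    ``lambda_phys`` is the physical decay constant of the nuclide
    (default: 111In).  ``lambda_bc`` is the fast blood-circulation uptake
    rate, fixed at ln(2)/1 min.
    """

    lambda_phys: float = LN2 / (INDIUM111_HALF_LIFE_H * 60.0)
    lambda_bc: float = LN2

    @classmethod
    def for_nuclide(cls, half_life_h: float) -> "DecayConstants":
        """Constants for a nuclide with the given physical half-life (h)."""
        if half_life_h <= 0:
            raise ValueError("physical half-life must be positive")
        return cls(lambda_phys=LN2 / (half_life_h * 60.0))


DEFAULT_DECAY = DecayConstants()

# A term list is [(rate, coefficient), ...]; the *last* coefficient is
# recomputed as minus the sum of the others so f(0) = 0 holds exactly in
# floating point.
_Terms = list


def _terms_f3a(p: Mapping[str, float], dc: DecayConstants) -> _Terms:
    lp = dc.lambda_phys
    return [(p["lambda1"] + lp, p["A1"]), (p["lambda2"] + lp, -p["A1"])]


def _terms_f3b(p: Mapping[str, float], dc: DecayConstants) -> _Terms:
    lp = dc.lambda_phys
    r1, r2 = p["lambda1"] + lp, p["lambda2"] + lp
    if np.any(np.asarray(p["A1"]) == 0.0):
        raise DegenerateParameterError("f3b: A1 = 0 (curve undefined)")
    if np.any(np.asarray(r1) == np.asarray(r2)):
        raise DegenerateParameterError("f3b: lambda1 == lambda2")
    c = r1 * r2 / (p["A1"] * (r2 - r1))
    return [(r1, c), (r2, -c)]


def _terms_f3c(p: Mapping[str, float], dc: DecayConstants) -> _Terms:
    lp = dc.lambda_phys
    r1, r2 = p["lambda1"] + lp, p["lambda2"] + lp
    if np.any(np.asarray(r1) == np.asarray(r2)):
        raise DegenerateParameterError("f3c: lambda1 == lambda2")
    c = p["A1"] * r1 * r2 / (r2 - r1)
    return [(r1, c), (r2, -c)]


def _terms_f3d(p: Mapping[str, float], dc: DecayConstants) -> _Terms:
    # Bi-exponential without an explicit physical-decay factor: lambda1 and
    # lambda2 are effective rates that already include physical decay.
    l1, l2 = p["lambda1"], p["lambda2"]
    if np.any(np.asarray(p["A1"]) == 0.0):
        raise DegenerateParameterError("f3d: A1 = 0 (curve undefined)")
    if np.any(np.asarray(l1) == np.asarray(l2)):
        raise DegenerateParameterError("f3d: lambda1 == lambda2")
    c = l1 * l2 / (p["A1"] * (l2 - l1))
    return [(l1, c), (l2, -c)]


def _terms_f4a(p: Mapping[str, float], dc: DecayConstants) -> _Terms:
    lp, lbc = dc.lambda_phys, dc.lambda_bc
    return [
        (p["lambda1"] + lp, p["A1"]),
        (p["lambda2"] + lp, -p["A2"]),
        (lbc + lp, -(p["A1"] - p["A2"])),
    ]


def _terms_f4b(p: Mapping[str, float], dc: DecayConstants) -> _Terms:
    lp, lbc = dc.lambda_phys, dc.lambda_bc
    a1, al = p["A1"], p["alpha"]
    return [
        (p["lambda1"] + lp, a1 * al),
        (p["lambda2"] + lp, -a1 * (1.0 - al)),
        (lbc + lp, -a1 * (2.0 * al - 1.0)),
    ]


def _terms_f4c(p: Mapping[str, float], dc: DecayConstants) -> _Terms:
    lp, lbc = dc.lambda_phys, dc.lambda_bc
    a1, al = p["A1"], p["alpha"]
    return [
        (p["lambda1"] + lp, a1 * (1.0 - al)),
        (p["lambda2"] + lp, -a1 * al),
        (lbc + lp, -a1 * (1.0 - 2.0 * al)),
    ]


def _terms_f4d(p: Mapping[str, float], dc: DecayConstants) -> _Terms:
    lp, lbc = dc.lambda_phys, dc.lambda_bc
    al = p["alpha"]
    r1, r2, rbc = p["lambda1"] + lp, p["lambda2"] + lp, lbc + lp
    denom = (1.0 - al) / r1 - al / r2 - (1.0 - 2.0 * al) / rbc
    if np.any(np.asarray(denom) == 0.0):
        raise DegenerateParameterError("f4d: normalisation denominator is 0")
    s = p["A1"] / denom
    return [(r1, s * (1.0 - al)), (r2, -s * al), (rbc, -s * (1.0 - 2.0 * al))]


def _terms_f4e(p: Mapping[str, float], dc: DecayConstants) -> _Terms:
    # Same underlying function as f4d with alpha replaced by 1 - alpha.
    q = dict(p)
    q["alpha"] = 1.0 - np.asarray(p["alpha"]) if np.ndim(p["alpha"]) else 1.0 - p["alpha"]
    try:
        return _terms_f4d(q, dc)
    except DegenerateParameterError as exc:
        raise DegenerateParameterError(str(exc).replace("f4d", "f4e")) from None


def _terms_f5a(p: Mapping[str, float], dc: DecayConstants) -> _Terms:
    lp = dc.lambda_phys
    return [
        (p["lambda1"] + lp, p["A1"]),
        (p["lambda2"] + lp, -p["A2"]),
        (p["lambda3"] + lp, -(p["A1"] - p["A2"])),
    ]


def _terms_f5b(p: Mapping[str, float], dc: DecayConstants) -> _Terms:
    lp, lbc = dc.lambda_phys, dc.lambda_bc
    return [
        (p["lambda1"] + lp, p["A1"]),
        (lp, p["A2"]),
        (p["lambda2"] + lp, -p["A3"]),
        (lbc + lp, -(p["A1"] + p["A2"] - p["A3"])),
    ]


@dataclass(frozen=True)
class SOEModel:
    """One sum-of-exponentials parameterisation.

    ``param_names`` gives the adjustable parameters in canonical order;
    ``ordered_rates`` lists rate parameters constrained to be nondecreasing
    (imposed on exchange-symmetric forms to remove label switching).
    """

    model_id: str
    param_names: tuple
    terms_fn: Callable[[Mapping[str, float], DecayConstants], _Terms]
    ordered_rates: tuple = ()
    has_closed_form_tia: bool = True
    #: rate ordering imposed on the *population* fixed effects only, to
    #: remove exact label-switching symmetries that leave the curve
    #: unchanged (f4d/f4e are invariant under alpha -> 1-alpha with
    #: lambda1 <-> lambda2); individual parameters stay unconstrained.
    pop_ordered_rates: tuple = ()

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def params_dict(self, values: Sequence[float]) -> dict:
        if len(values) != self.n_params:
            raise ValueError(
                f"{self.model_id}: expected {self.n_params} values, "
                f"got {len(values)}"
            )
        return dict(zip(self.param_names, values))

    def balanced_terms(self, params: Mapping[str, float], dc: DecayConstants):
        """Rates and coefficients with the last coefficient balancing the
        rest so that the coefficients sum to exactly zero."""
        terms = self.terms_fn(params, dc)
        rates = np.array([r for r, _ in terms], dtype=float)
        coefs = np.array([c for _, c in terms], dtype=float)
        coefs[-1] = -coefs[:-1].sum()
        return rates, coefs


MODELS: dict = {}


def _register(model_id, param_names, terms_fn, ordered_rates=(),
              pop_ordered_rates=None):
    if pop_ordered_rates is None:
        pop_ordered_rates = ordered_rates
    MODELS[model_id] = SOEModel(
        model_id=model_id,
        param_names=tuple(param_names),
        terms_fn=terms_fn,
        ordered_rates=tuple(ordered_rates),
        pop_ordered_rates=tuple(pop_ordered_rates),
    )


_register("f3a", ("A1", "lambda1", "lambda2"), _terms_f3a, ("lambda1", "lambda2"))
_register("f3b", ("A1", "lambda1", "lambda2"), _terms_f3b, ("lambda1", "lambda2"))
_register("f3c", ("A1", "lambda1", "lambda2"), _terms_f3c, ("lambda1", "lambda2"))
_register("f3d", ("A1", "lambda1", "lambda2"), _terms_f3d, ("lambda1", "lambda2"))
_register("f4a", ("A1", "A2", "lambda1", "lambda2"), _terms_f4a)
_register("f4b", ("A1", "alpha", "lambda1", "lambda2"), _terms_f4b)
_register("f4c", ("A1", "alpha", "lambda1", "lambda2"), _terms_f4c)
_register("f4d", ("A1", "alpha", "lambda1", "lambda2"), _terms_f4d,
          pop_ordered_rates=("lambda1", "lambda2"))
_register("f4e", ("A1", "alpha", "lambda1", "lambda2"), _terms_f4e,
          pop_ordered_rates=("lambda1", "lambda2"))
_register("f5a", ("A1", "A2", "lambda1", "lambda2", "lambda3"), _terms_f5a,
          ("lambda1", "lambda2", "lambda3"))
_register("f5b", ("A1", "A2", "A3", "lambda1", "lambda2"), _terms_f5b)

ALL_MODEL_IDS = tuple(MODELS)


def get_model(model_id: str) -> SOEModel:
    try:
        return MODELS[model_id]
    except KeyError:
        raise ValueError(
            f"unknown model id {model_id!r}; known: {', '.join(MODELS)}"
        ) from None


def validate_params(model: SOEModel, params: Mapping[str, float]) -> list:
    """Return a list of human-readable bound violations (empty if valid).

    Total function: never raises on bad values, only reports them.
    """
    violations = []
    for name in model.param_names:
        if name not in params:
            violations.append(f"missing parameter {name!r}")
    if violations:
        return violations
    for name in model.param_names:
        v = params[name]
        if not np.isfinite(v):
            violations.append(f"{name} = {v} is not finite")
        elif name.startswith("A") and v < 0:
            violations.append(f"{name} = {v} violates {name} >= 0")
        elif name.startswith("lambda") and v < 0:
            violations.append(f"{name} = {v} violates {name} >= 0")
        elif name == "alpha" and not (0.0 <= v <= 1.0):
            violations.append(f"alpha = {v} outside [0, 1]")
    for lo, hi in zip(model.ordered_rates[:-1], model.ordered_rates[1:]):
        if params.get(lo, 0.0) > params.get(hi, 0.0):
            violations.append(f"ordering violated: {lo} > {hi}")
    return violations


def _check_params(model, params):
    violations = validate_params(model, params)
    if violations:
        raise ParameterBoundError(
            f"{model.model_id}: " + "; ".join(violations)
        )


def evaluate(model: SOEModel, params: Mapping[str, float], times,
             dc: DecayConstants = DEFAULT_DECAY):
    """Evaluate ``f(t)`` at times given in minutes.

    Returns a float for scalar input, else an ndarray.  Raises
    :class:`ParameterBoundError` for out-of-bound parameters and
    :class:`DegenerateParameterError` for ill-defined ones.
    """
    _check_params(model, params)
    rates, coefs = model.balanced_terms(params, dc)
    t = np.asarray(times, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    f = np.exp(-t[:, None] * rates[None, :]) @ coefs
    return float(f[0]) if scalar else f


def analytic_tia(model: SOEModel, params: Mapping[str, float],
                 dc: DecayConstants = DEFAULT_DECAY) -> float:
    """Closed-form time-integrated activity ``int_0^inf f dt`` in %*min.

    Term-by-term integration of the exponentials: ``sum_k c_k / r_k``.
    For ``f4d``/``f4e`` this equals ``A1``; for ``f3b``/``f3d`` it equals
    ``1/A1``; for ``f3c`` it equals ``A1``.
    """
    _check_params(model, params)
    rates, coefs = model.balanced_terms(params, dc)
    nonzero = coefs != 0.0
    if np.any(rates[nonzero] <= 0.0):
        raise InfiniteTIAError(
            f"{model.model_id}: a nondecaying term has nonzero weight"
        )
    if not np.any(nonzero):
        return 0.0
    return float(np.sum(coefs[nonzero] / rates[nonzero]))


def half_life_hours(rate_per_min: float) -> float:
    """Convert a rate constant (1/min) to the corresponding half-life (h)."""
    if rate_per_min <= 0:
        raise ValueError("rate must be > 0")
    return LN2 / rate_per_min / 60.0
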