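"""Synthetic patient cohorts with the statistical structure the fits assume.

The generator emulates a kidney-dosimetry study design: eight patients
imaged at five nominal sessions (2.9, 4.6, 22.8, 46.7 and 70.9 h post
injection, each with its own scheduling spread), time-activity curves drawn
from a population sum-of-exponentials model with log-normal inter-patient
variability on every parameter, and multiplicative log-normal residual
error on each measurement.  The defaults reproduce the published
population estimates for [111In]In-DOTATATE kidney kinetics under the
``f4d`` parameterisation, in which the fixed effect ``A1`` is itself the
population time-integrated activity.

The generator does not emulate imaging physics (counting statistics,
background or attenuation): noise enters only through the fitted log-scale
residual model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import BiokineticDataset, Observation
from .nlme import PopulationParams, _ModelOps
from .soe import DEFAULT_DECAY, DecayConstants, analytic_tia, get_model

#: nominal imaging schedule as (mean, SD) pairs in hours
DEFAULT_SCHEDULE = (
    (2.9, 0.6),
    (4.6, 0.4),
    (22.8, 1.6),
    (46.7, 1.7),
    (70.9, 1.0),
)


@dataclass(frozen=True)
class StudyDesign:
    n_patients: int = 8
    schedule: tuple = DEFAULT_SCHEDULE
    min_time_h: float = 0.1
    max_redraws: int = 1000

    def __post_init__(self):
        means = [m for m, _ in self.schedule]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("schedule means must be strictly increasing")
        if any(sd < 0 for _, sd in self.schedule):
            raise ValueError("schedule SDs must be >= 0")


def default_population_params() -> PopulationParams:
    """Population estimates for f4d kidney kinetics of 111In-DOTATATE:
    A1 = 129.36 %*min, alpha = 0.31, lambda1 = 1.5e-4/min (77 h biological
    half-life), lambda2 = 8.8e-4/min (13 h), with inter-patient variances
    (0.08, 0.01, 2.9e-4, 1.1) and residual log-scale variance 4.4e-2."""
    return PopulationParams(
        tvp=np.array([129.36, 0.31, 1.5e-4, 8.8e-4]),
        omega2=np.array([0.08, 0.01, 2.9e-4, 1.1]),
        sigma2_intra=4.4e-2,
    )


@dataclass
class PatientTruth:
    patient_id: str
    eta: np.ndarray
    params: dict
    tia: float


@dataclass
class GroundTruth:
    """Generating model with population parameters and, after simulation,
    the per-patient true parameters and TIAs."""

    model_id: str = "f4d"
    pop: PopulationParams = field(default_factory=default_population_params)
    patients: list = field(default_factory=list)

    def patient(self, patient_id: str) -> PatientTruth:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "tvp": list(map(float, self.pop.tvp)),
            "omega2": list(map(float, self.pop.omega2)),
            "sigma2_intra": float(self.pop.sigma2_intra),
            "patients": [
                {
                    "patient_id": p.patient_id,
                    "eta": list(map(float, p.eta)),
                    "params": {k: float(v) for k, v in p.params.items()},
                    "tia": float(p.tia),
                }
                for p in self.patients
            ],
        }


def true_tia(truth: GroundTruth, patient_id: str,
             dc: DecayConstants = DEFAULT_DECAY) -> float:
    """Closed-form TIA of a simulated patient's true curve."""
    p = truth.patient(patient_id)
    return analytic_tia(get_model(truth.model_id), p.params, dc)


def simulate_cohort(design: Optional[StudyDesign] = None,
                    truth: Optional[GroundTruth] = None,
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None,
                    dc: DecayConstants = DEFAULT_DECAY):
    """Draw one virtual cohort.

    Per patient: random effects ETA_j ~ N(0, omega2_j) give
    P_j = TVP_j * exp(ETA_j) (the fraction parameter is redrawn until it
    stays inside [0, 1]); each session time is drawn around its nominal
    mean, truncated positive; each observation is the true curve value
    times exp(eps), eps ~ N(0, sigma2_intra).  Deterministic for a fixed
    seed.  Returns ``(BiokineticDataset, GroundTruth)`` with the truth's
    per-patient entries filled in.
    """
    design = design or StudyDesign()
    truth = truth or GroundTruth()
    if rng is None:
        rng = np.random.default_rng(seed)
    model = get_model(truth.model_id)
    ops = _ModelOps(model, dc, "lognormal")
    sig = float(np.sqrt(truth.pop.sigma2_intra))
    om = np.sqrt(truth.pop.omega2)
    alpha_idx = ops.alpha_idx

    observations = []
    truth.patients = []
    for m in range(design.n_patients):
        pid = f"P{m + 1}"
        for _ in range(design.max_redraws):
            eta = rng.normal(0.0, 1.0, model.n_params) * om
            for i in alpha_idx:
                for _ in range(design.max_redraws):
                    cand = truth.pop.tvp[i] * np.exp(eta[i])
                    if 0.0 <= cand <= 1.0:
                        break
                    eta[i] = rng.normal(0.0, om[i])
                else:
                    raise RuntimeError(
                        "could not draw a fraction parameter inside [0, 1]"
                    )
            vals = ops.individual(truth.pop.tvp, eta)
            times_h = np.array([
                _truncated_normal(rng, mu, sd, design.min_time_h)
                for mu, sd in design.schedule
            ])
            t_min = times_h * 60.0
            logf = ops.log_curve(vals, t_min)
            if logf is not None:
                break
        else:
            raise RuntimeError(
                f"{pid}: could not draw a positive curve in "
                f"{design.max_redraws} attempts"
            )
        eps = rng.normal(0.0, sig, len(t_min))
        y = np.exp(logf + eps)
        for t, act in zip(t_min, y):
            observations.append(Observation(pid, float(t), float(act)))
        params = dict(zip(model.param_names, vals))
        truth.patients.append(PatientTruth(
            patient_id=pid, eta=eta, params=params,
            tia=analytic_tia(model, params, dc),
        ))
    return BiokineticDataset(observations), truth


def _truncated_normal(rng, mu, sd, lower):
    for _ in range(1000):
        v = rng.normal(mu, sd)
        if v > lower:
            return v
    raise RuntimeError("could not draw a positive sampling time")
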