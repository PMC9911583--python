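"""Single-time-point (STP) dosimetry and accuracy metrics.

The reference ("all-time-point", ATP) time-integrated activity (TIA) of a
patient is the integral over 0-100,000 min of the empirical-Bayes curve
from a population fit that uses every measurement of every patient.  The
STP TIA of a target patient keeps only one of the target's measurements
(by default the one nearest the nominal 22.8 h or 46.7 h imaging session)
and refits the population jointly on the other patients' complete data
plus that single point; the target's empirical-Bayes curve then yields the
TIA.  Accuracy is summarised by per-patient relative deviations

    RD_m = (TIA_m - TIA_ref,m) / TIA_ref,m

and their root-mean-square error RMSE = sqrt(MeanRD^2 + SDRD^2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import integrate

from .data import BiokineticDataset, Observation
from .nlme import (
    FitSettings,
    PopulationFit,
    empirical_bayes,
    fit_population,
)
from .soe import DEFAULT_DECAY, DecayConstants, SOEModel, get_model

#: nominal imaging schedule, hours post injection
NOMINAL_TIMES_H = {"T1": 2.9, "T2": 4.6, "T3": 22.8, "T4": 46.7, "T5": 70.9}

DEFAULT_T_END_MIN = 1e5


@dataclass
class TIAResult:
    patient_id: str
    tia: float  # %*min
    method: str  # "ATP" | "STP"
    model_id: str
    stp_time_label: Optional[str] = None
    stp_time_min: Optional[float] = None


@dataclass
class AccuracyReport:
    """Relative deviations of one STP method against the ATP reference."""

    model_id: str
    stp_time_label: Optional[str]
    rds: dict  # patient_id -> RD (dimensionless)
    mean_rd: float
    sd_rd: float
    rmse: float
    sd_convention: str

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "stp_time_label": self.stp_time_label,
            "rds": {k: float(v) for k, v in self.rds.items()},
            "mean_rd": self.mean_rd,
            "sd_rd": self.sd_rd,
            "rmse": self.rmse,
            "sd_convention": self.sd_convention,
        }


def tia_numeric(model: SOEModel, params, t_end: float = DEFAULT_T_END_MIN,
                dc: DecayConstants = DEFAULT_DECAY,
                rel_tol: float = 1e-6) -> float:
    """Adaptive quadrature of the curve over [0, t_end] minutes."""
    rates, coefs = model.balanced_terms(dict(params), dc)
    if not np.any(coefs != 0.0):
        return 0.0

    def f(t):
        return float(coefs @ np.exp(-rates * t))

    # the 1-min uptake term dies within the first hour; split there so the
    # adaptive rule resolves both scales
    split = min(60.0, t_end)
    val1, _ = integrate.quad(f, 0.0, split, epsrel=rel_tol, limit=200)
    val2 = 0.0
    if t_end > split:
        val2, _ = integrate.quad(f, split, t_end, epsrel=rel_tol, limit=200)
    return val1 + val2


def relative_deviation(tia: float, reference_tia: float) -> float:
    if reference_tia == 0:
        raise ZeroDivisionError("reference TIA is zero")
    return (tia - reference_tia) / reference_tia


def rmse(rds: Sequence[float], sd_convention: str = "population",
         model_id: str = "", stp_time_label: Optional[str] = None,
         rd_labels: Optional[Sequence[str]] = None) -> AccuracyReport:
    """Accuracy summary of relative deviations.

    With the default population-SD convention (divide by n), the RMSE
    equals the literal root-mean-square of the deviations.
    """
    arr = np.asarray(list(rds), dtype=float)
    if arr.size == 0:
        raise ValueError("empty RD list")
    mean = float(arr.mean())
    if sd_convention == "population":
        sd = float(arr.std(ddof=0))
    elif sd_convention == "sample":
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    else:
        raise ValueError("sd_convention must be 'population' or 'sample'")
    labels = list(rd_labels) if rd_labels is not None else [
        str(i) for i in range(arr.size)]
    return AccuracyReport(
        model_id=model_id, stp_time_label=stp_time_label,
        rds=dict(zip(labels, arr)), mean_rd=mean, sd_rd=sd,
        rmse=math.sqrt(mean * mean + sd * sd), sd_convention=sd_convention,
    )


def atp_reference_tias(data: BiokineticDataset, model,
                       settings: Optional[FitSettings] = None,
                       dc: DecayConstants = DEFAULT_DECAY,
                       t_end: float = DEFAULT_T_END_MIN,
                       fit: Optional[PopulationFit] = None):
    """Per-patient reference TIAs from the all-time-point population fit.

    Returns ``(results, fit)`` so the fit can seed later STP refits.
    """
    model = get_model(model) if isinstance(model, str) else model
    if fit is None:
        fit = fit_population(data, model, settings, dc)
    results = [
        TIAResult(patient_id=ind.patient_id,
                  tia=tia_numeric(model, ind.params, t_end, dc),
                  method="ATP", model_id=model.model_id)
        for ind in fit.individuals
    ]
    return results, fit


def select_stp_observation(data: BiokineticDataset, patient_id: str,
                           time_label: str = "T4",
                           tolerance_h: float = 3.0) -> Observation:
    """The patient's observation nearest the nominal session time.

    Warns (but still returns the nearest point) when the gap exceeds the
    schedule tolerance.
    """
    nominal_min = NOMINAL_TIMES_H[time_label] * 60.0
    obs = data.of_patient(patient_id)
    if not obs:
        raise KeyError(f"no observations for patient {patient_id!r}")
    best = min(obs, key=lambda o: abs(o.time - nominal_min))
    if abs(best.time - nominal_min) > tolerance_h * 60.0:
        warnings.warn(
            f"{patient_id}: nearest observation to {time_label} is "
            f"{abs(best.time - nominal_min) / 60.0:.1f} h away "
            f"(tolerance {tolerance_h} h)",
            stacklevel=2,
        )
    return best


def stp_fit(data_without_target: BiokineticDataset,
            target_obs, model,
            settings: Optional[FitSettings] = None,
            dc: DecayConstants = DEFAULT_DECAY,
            mode: str = "refit",
            t_end: float = DEFAULT_T_END_MIN,
            stp_time_label: Optional[str] = None,
            allow_multiple: bool = False):
    """TIA of a target patient from limited data plus the population.

    ``target_obs`` is a single :class:`Observation` (or a list when
    ``allow_multiple`` is set, e.g. to check consistency against the ATP
    reference).  ``mode="refit"`` re-estimates all population parameters on
    the augmented dataset; ``mode="frozen"`` fits the population on the
    other patients only and computes a MAP estimate for the target.

    Returns ``(TIAResult, PopulationFit)``.
    """
    model = get_model(model) if isinstance(model, str) else model
    settings = settings or FitSettings()
    obs_list = (list(target_obs) if isinstance(target_obs, (list, tuple))
                else [target_obs])
    if len(obs_list) != 1 and not allow_multiple:
        raise ValueError(
            f"target must contribute exactly one observation "
            f"(got {len(obs_list)}); pass allow_multiple=True to override"
        )
    if not data_without_target.patients:
        raise ValueError("population is empty: no other patients")
    pid = obs_list[0].patient_id
    if pid in data_without_target.patients:
        raise ValueError(
            f"target {pid!r} already present in the population data"
        )

    if mode == "refit":
        augmented = data_without_target.extended(obs_list)
        fit = fit_population(augmented, model, settings, dc)
        ind = fit.individual_for(pid)
    elif mode == "frozen":
        fit = fit_population(data_without_target, model, settings, dc)
        ind = empirical_bayes(fit, obs_list)
    else:
        raise ValueError("mode must be 'refit' or 'frozen'")
    result = TIAResult(
        patient_id=pid, tia=tia_numeric(model, ind.params, t_end, dc),
        method="STP", model_id=model.model_id,
        stp_time_label=stp_time_label, stp_time_min=obs_list[0].time,
    )
    return result, fit


def stp_accuracy(data: BiokineticDataset, stp_model, reference_model,
                 time_label: str = "T4",
                 settings: Optional[FitSettings] = None,
                 dc: DecayConstants = DEFAULT_DECAY,
                 mode: str = "refit",
                 sd_convention: str = "population",
                 t_end: float = DEFAULT_T_END_MIN,
                 tolerance_h: float = 3.0,
                 reference_fit: Optional[PopulationFit] = None):
    """Full STP experiment: every patient in turn becomes the target.

    Reference TIAs use ``reference_model`` on all data; each target's STP
    TIA uses ``stp_model`` with the single observation nearest the nominal
    ``time_label`` session.  Refits are warm-started from the full-data fit
    of ``stp_model``.

    Returns ``(AccuracyReport, stp_results, atp_results)``.
    """
    settings = settings or FitSettings()
    stp_model = get_model(stp_model) if isinstance(stp_model, str) else stp_model
    atp_results, ref_fit = atp_reference_tias(
        data, reference_model, settings, dc, t_end, fit=reference_fit)
    atp_map = {r.patient_id: r.tia for r in atp_results}

    if (isinstance(reference_model, str)
            and reference_model == stp_model.model_id):
        warm = ref_fit
    elif getattr(reference_model, "model_id", reference_model) == \
            stp_model.model_id:
        warm = ref_fit
    else:
        warm = fit_population(data, stp_model, settings, dc)

    warm_settings = replace(settings, init_theta=warm.theta_opt,
                            multistarts=1, compute_cov=False,
                            n_finalists=1, max_restarts=0,
                            outer_maxiter=150, explore_maxiter=150)
    stp_results = []
    rds = {}
    for pid in data.patients:
        obs = select_stp_observation(data, pid, time_label, tolerance_h)
        others = data.without(pid)
        result, _ = stp_fit(others, obs, stp_model, warm_settings, dc,
                            mode=mode, t_end=t_end,
                            stp_time_label=time_label)
        stp_results.append(result)
        rds[pid] = relative_deviation(result.tia, atp_map[pid])

    report = rmse(list(rds.values()), sd_convention,
                  model_id=stp_model.model_id, stp_time_label=time_label,
                  rd_labels=list(rds.keys()))
    return report, stp_results, atp_results
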