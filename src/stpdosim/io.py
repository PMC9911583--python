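"""CSV and JSON input/output.

The interchange format for biokinetic data is a plain CSV with header
``patient_id,time_h,activity_pct`` (case-insensitive): one row per
measurement, times in hours post injection, activities in % of the
administered activity.  Reports are written as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import BiokineticDataset, Observation

REQUIRED_COLUMNS = ("patient_id", "time_h", "activity_pct")


def read_biokinetics(path) -> BiokineticDataset:
    """Read and validate a biokinetics CSV; times are converted to minutes.

    Raises ``ValueError`` listing every offending line (1-based, counting
    the header as line 1) for nonpositive activities or times, malformed
    numbers, and duplicate (patient, time) pairs.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {', '.join(missing)}; "
            f"expected header {','.join(REQUIRED_COLUMNS)}"
        )
    errors = []
    observations = []
    seen = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            t_h = float(row["time_h"])
            act = float(row["activity_pct"])
        except (TypeError, ValueError):
            errors.append(f"line {line}: malformed numeric value")
            continue
        pid = str(row["patient_id"])
        if not np.isfinite(t_h) or t_h <= 0:
            errors.append(f"line {line}: time_h must be > 0 (got {t_h})")
            continue
        if not np.isfinite(act) or act <= 0:
            errors.append(
                f"line {line}: activity_pct must be > 0 (got {act})"
            )
            continue
        key = (pid, t_h)
        if key in seen:
            errors.append(
                f"line {line}: duplicate (patient, time) pair {key}, "
                f"first seen at line {seen[key]}"
            )
            continue
        seen[key] = line
        observations.append(Observation(pid, t_h * 60.0, act))
    if errors:
        raise ValueError(f"{path}: invalid rows:\n" + "\n".join(errors))
    return BiokineticDataset(observations)


def write_biokinetics(dataset: BiokineticDataset, path) -> None:
    dataset.to_dataframe().to_csv(path, index=False)


def _jsonable(o):
    if isinstance(o, np.generic):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o).__name__}")


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def fit_to_dict(fit) -> dict:
    """Serialisable summary of a population fit."""
    return {
        "model_id": fit.model_id,
        "tvp": {n: float(v) for n, v in
                zip(fit.model.param_names, fit.pop.tvp)},
        "omega2": {n: float(v) for n, v in
                   zip(fit.model.param_names, fit.pop.omega2)},
        "sigma2_intra": float(fit.pop.sigma2_intra),
        "ofv": float(fit.ofv),
        "converged": bool(fit.converged),
        "cv_percent": (None if fit.cv_percent is None else
                       {n: float(v) for n, v in
                        zip(fit.model.param_names, fit.cv_percent)}),
        "n_obs": int(fit.n_obs),
        "alpha_scale": fit.alpha_scale,
        "individuals": [
            {
                "patient_id": ind.patient_id,
                "eta": [float(e) for e in ind.eta],
                "params": {k: float(v) for k, v in ind.params.items()},
            }
            for ind in fit.individuals
        ],
    }


def tia_results_to_dataframe(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "tia_pct_min": [r.tia for r in results],
            "method": [r.method for r in results],
            "model_id": [r.model_id for r in results],
            "stp_time_label": [r.stp_time_label for r in results],
        }
    )
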