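"""Model selection by corrected AIC and Akaike weights.

Each candidate sum-of-exponentials model is fitted to the full cohort; the
small-sample corrected Akaike criterion

    AICc = OFV + 2K + 2K(K+1)/(N-K-1),   K = 2p + 1,

ranks the fits, where OFV is -2 log of the maximised (Laplace) marginal
likelihood, p the number of adjustable model parameters (each contributing
one fixed effect and one random-effect variance) and the residual variance
adds one.  Models whose fit did not converge or whose maximum fixed-effect
coefficient of variation exceeds a threshold (default 50%) fail the
goodness-of-fit gate and are excluded before the weights are computed.
Stability of the ranking is assessed by a leave-one-patient-out jackknife.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .data import BiokineticDataset
from .nlme import FitSettings, PopulationFit, fit_population
from .soe import ALL_MODEL_IDS, DEFAULT_DECAY, DecayConstants, SOEModel, get_model


def parameter_count(model: SOEModel) -> int:
    """Total NLME parameter count K = 2p + 1 (fixed effects, random-effect
    variances, residual variance)."""
    return 2 * model.n_params + 1


def aicc(ofv: float, K: int, N: int) -> float:
    """Corrected Akaike information criterion for -2 log likelihood
    ``ofv`` with ``K`` parameters and ``N`` observations."""
    if N <= K + 1:
        raise ValueError(
            f"AICc undefined for N={N} <= K+1={K + 1} (correction diverges)"
        )
    return ofv + 2.0 * K + 2.0 * K * (K + 1.0) / (N - K - 1.0)


def akaike_weights(aiccs: Sequence[float]) -> np.ndarray:
    """Akaike weights exp(-Delta/2) normalised over the candidate set."""
    a = np.asarray(aiccs, dtype=float)
    if a.size == 0:
        raise ValueError("empty AICc list")
    if not np.all(np.isfinite(a)):
        raise ValueError("AICc values must be finite")
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


@dataclass
class SelectionEntry:
    model_id: str
    K: int
    ofv: Optional[float]
    aicc: Optional[float]
    delta: Optional[float]
    weight: Optional[float]
    gof_pass: bool
    max_cv_percent: float
    converged: bool
    failure: Optional[str] = None


@dataclass
class SelectionReport:
    entries: list
    n_obs: int
    best_model_id: Optional[str]
    fits: dict = field(default_factory=dict, repr=False)

    def entry(self, model_id: str) -> SelectionEntry:
        for e in self.entries:
            if e.model_id == model_id:
                return e
        raise KeyError(model_id)

    def to_dict(self) -> dict:
        return {
            "n_obs": self.n_obs,
            "best_model_id": self.best_model_id,
            "entries": [
                {
                    "model_id": e.model_id,
                    "K": e.K,
                    "ofv": e.ofv,
                    "aicc": e.aicc,
                    "delta": e.delta,
                    "weight": e.weight,
                    "gof_pass": e.gof_pass,
                    "max_cv_percent": e.max_cv_percent,
                    "converged": e.converged,
                    "failure": e.failure,
                }
                for e in self.entries
            ],
        }

    def to_table(self) -> str:
        """Plain-text ranking table; weights in % rounded to two decimals,
        dashes for models excluded by the goodness-of-fit gate."""
        lines = [f"{'function':<10}{'K':>4}{'weight %':>10}{'max CV %':>10}"]
        for e in self.entries:
            w = f"{100.0 * e.weight:.2f}" if e.weight is not None else "-"
            cv = ("inf" if math.isinf(e.max_cv_percent)
                  else f"{e.max_cv_percent:.1f}")
            lines.append(f"{e.model_id:<10}{e.K:>4}{w:>10}{cv:>10}")
        return "\n".join(lines)


def goodness_of_fit_gate(fits: Sequence[PopulationFit],
                         cv_threshold: float = 50.0):
    """Partition fits into (passing, failing).

    A fit passes iff it converged and every fixed-effect CV is at most the
    threshold (in %)."""
    passed, failed = [], []
    for fit in fits:
        if fit.converged and fit.max_cv_percent <= cv_threshold:
            passed.append(fit)
        else:
            failed.append(fit)
    return passed, failed


def select_best(data: BiokineticDataset,
                models: Optional[Sequence] = None,
                settings: Optional[FitSettings] = None,
                cv_threshold: float = 50.0,
                dc: DecayConstants = DEFAULT_DECAY) -> SelectionReport:
    """Fit all candidate models, gate, weight and rank them.

    Ties in weight are broken toward smaller K, then lexicographic id.
    Raises if no model passes the gate.
    """
    settings = settings or FitSettings()
    if models is None:
        models = list(ALL_MODEL_IDS)
    models = [get_model(m) if isinstance(m, str) else m for m in models]
    N = data.n_obs

    fits: dict = {}
    failures: dict = {}
    for model in models:
        try:
            fits[model.model_id] = fit_population(data, model, settings, dc)
        except Exception as exc:  # noqa: BLE001 - fit failure excludes model
            failures[model.model_id] = str(exc)

    passed, _ = goodness_of_fit_gate(list(fits.values()), cv_threshold)
    passed_ids = [f.model_id for f in passed]
    if not passed_ids:
        raise RuntimeError("no model passed the goodness-of-fit gate")

    aiccs = {f.model_id: aicc(f.ofv, parameter_count(f.model), N)
             for f in passed}
    weights = akaike_weights([aiccs[m] for m in passed_ids])
    wmap = dict(zip(passed_ids, weights))
    amin = min(aiccs.values())

    entries = []
    for model in models:
        mid = model.model_id
        K = parameter_count(model)
        fit = fits.get(mid)
        if fit is None:
            entries.append(SelectionEntry(
                model_id=mid, K=K, ofv=None, aicc=None, delta=None,
                weight=None, gof_pass=False, max_cv_percent=math.inf,
                converged=False, failure=failures.get(mid)))
            continue
        in_set = mid in wmap
        entries.append(SelectionEntry(
            model_id=mid, K=K, ofv=fit.ofv,
            aicc=aiccs.get(mid), delta=(aiccs[mid] - amin) if in_set else None,
            weight=wmap.get(mid), gof_pass=in_set,
            max_cv_percent=fit.max_cv_percent, converged=fit.converged))

    entries.sort(key=lambda e: (
        -(e.weight if e.weight is not None else -1.0), e.K, e.model_id))
    return SelectionReport(entries=entries, n_obs=N,
                           best_model_id=entries[0].model_id, fits=fits)


@dataclass
class JackknifeSummary:
    """Per-fold Akaike weights from leave-one-patient-out refits."""

    model_ids: list
    folds: list  # left-out patient per fold
    weights_percent: dict  # model_id -> array over folds (nan = failed fold)
    failed_folds: list

    def stats(self) -> dict:
        out = {}
        for mid in self.model_ids:
            w = np.asarray(self.weights_percent[mid], dtype=float)
            w = w[np.isfinite(w)]
            out[mid] = {
                "mean": float(w.mean()),
                "sd": float(w.std(ddof=1)) if w.size > 1 else 0.0,
                "median": float(np.median(w)),
                "min": float(w.min()),
                "max": float(w.max()),
            }
        return out

    def to_dict(self) -> dict:
        return {
            "model_ids": self.model_ids,
            "folds": self.folds,
            "weights_percent": {
                m: list(map(float, w))
                for m, w in self.weights_percent.items()
            },
            "failed_folds": self.failed_folds,
            "stats": self.stats(),
        }


def jackknife(data: BiokineticDataset,
              candidate_models: Sequence,
              settings: Optional[FitSettings] = None,
              warm_fits: Optional[dict] = None,
              dc: DecayConstants = DEFAULT_DECAY) -> JackknifeSummary:
    """Leave-one-patient-out stability of the Akaike weights.

    Refits every candidate on each reduced cohort and recomputes the
    weights among the candidates.  ``warm_fits`` (model_id -> full-data
    PopulationFit) seeds the refits for speed.  Folds in which any
    candidate fit fails are flagged and excluded from the summary.
    """
    settings = settings or FitSettings()
    candidates = [get_model(m) if isinstance(m, str) else m
                  for m in candidate_models]
    if not candidates:
        raise ValueError("candidate_models must be nonempty")
    if len(data.patients) < 3:
        raise ValueError("jackknife needs at least 3 patients")

    ids = [m.model_id for m in candidates]
    weights = {mid: [] for mid in ids}
    failed = []
    for pid in data.patients:
        sub = data.without(pid)
        fold_aiccs = []
        ok = True
        for model in candidates:
            s = replace(settings, compute_cov=False)
            if warm_fits and model.model_id in warm_fits:
                s = replace(s, init_theta=warm_fits[model.model_id].theta_opt,
                            multistarts=1, n_finalists=1, max_restarts=1,
                            explore_maxiter=settings.outer_maxiter)
            try:
                fit = fit_population(sub, model, s, dc)
                fold_aiccs.append(
                    aicc(fit.ofv, parameter_count(model), sub.n_obs))
            except Exception:  # noqa: BLE001
                ok = False
                break
        if ok:
            w = akaike_weights(fold_aiccs)
            for mid, wi in zip(ids, w):
                weights[mid].append(100.0 * float(wi))
        else:
            failed.append(pid)
            for mid in ids:
                weights[mid].append(math.nan)
    return JackknifeSummary(
        model_ids=ids, folds=list(data.patients),
        weights_percent={m: np.array(w) for m, w in weights.items()},
        failed_folds=failed,
    )
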