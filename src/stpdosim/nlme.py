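"""Nonlinear mixed-effects (NLME) estimation for sum-of-exponential models.

Population model: each adjustable model parameter j of patient m is

    P_{j,m} = TVP_j * exp(ETA_{j,m}),     ETA_{j,m} ~ N(0, omega2_j),

and observations follow an exponential (log-scale additive) error model

    log y_{i,m} = log f(t_{i,m}; P_m) + eps_{i,m},  eps ~ N(0, sigma2_intra).

The marginal likelihood integrates the random effects out per patient.  The
integral is approximated by the Laplace method at the per-patient posterior
mode (empirical-Bayes estimate), with a Gauss-Newton approximation of the
inner Hessian (first-order conditional style).  The reported objective
function value (OFV) is -2 log of the approximated marginal likelihood.

The fraction parameter ``alpha`` of the 4-parameter models may carry its
random effect either multiplicatively on the log scale (default, with a
hard rejection of individual values outside [0, 1]) or additively on the
logit scale (``alpha_scale="logit"``), under which the two mirrored
parameterisations of the same curve are exactly equivalent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from .data import BiokineticDataset, Observation
from .soe import (
    DEFAULT_DECAY,
    DecayConstants,
    DegenerateParameterError,
    SOEModel,
)

LOG2PI = math.log(2.0 * math.pi)
_BIG = 1e10


@dataclass
class FitSettings:
    """Estimation settings for :func:`fit_population`.

    ``multistarts`` counts independent outer optimisations (the first uses a
    pooled least-squares heuristic, the rest jitter it).  ``fixed_omega2``
    freezes the random-effect variances (zeros allowed; a zero deactivates
    that random effect entirely), in which case only the fixed effects and
    the residual variance are estimated.
    """

    multistarts: int = 10
    seed: int = 0
    pooled_starts: int = 8
    outer_maxiter: int = 300
    outer_gtol: float = 1e-7
    outer_ftol: float = 1e-7
    outer_fd_step: float = 1e-5
    explore_maxiter: int = 60
    n_finalists: int = 2
    max_restarts: int = 3
    inner_maxiter: int = 60
    inner_gtol: float = 1e-9
    alpha_scale: str = "lognormal"  # or "logit"
    fixed_omega2: Optional[Sequence[float]] = None
    omega2_init: float = 0.1
    sigma2_init: float = 0.05
    omega2_bounds: tuple = (1e-8, 1e3)
    sigma2_bounds: tuple = (1e-8, 10.0)
    compute_cov: bool = True
    cov_rel_step: float = 1e-3
    init_theta: Optional[np.ndarray] = None


@dataclass
class PopulationParams:
    """Fixed effects, random-effect variances and residual variance."""

    tvp: np.ndarray
    omega2: np.ndarray
    sigma2_intra: float

    def __post_init__(self):
        self.tvp = np.asarray(self.tvp, dtype=float)
        self.omega2 = np.asarray(self.omega2, dtype=float)
        if np.any(self.omega2 < 0):
            raise ValueError("omega2 must be >= 0 elementwise")
        # zero is allowed so noise-free cohorts can be simulated; the
        # fitter itself always estimates a strictly positive value
        if not self.sigma2_intra >= 0:
            raise ValueError("sigma2_intra must be >= 0")


@dataclass
class IndividualEstimate:
    patient_id: str
    eta: np.ndarray
    params: dict  # individual parameters keyed by model param names


@dataclass
class PopulationFit:
    """Result of a population fit for one model."""

    model: SOEModel
    pop: PopulationParams
    individuals: list
    ofv: float
    fixed_effect_cov: Optional[np.ndarray]
    cv_percent: Optional[np.ndarray]
    converged: bool
    n_obs: int
    alpha_scale: str
    dc: DecayConstants
    theta_opt: Optional[np.ndarray] = None
    n_outer_evals: int = 0

    @property
    def model_id(self) -> str:
        return self.model.model_id

    @property
    def max_cv_percent(self) -> float:
        if self.cv_percent is None:
            return math.inf
        return float(np.max(self.cv_percent))

    def individual_for(self, patient_id: str) -> IndividualEstimate:
        for ind in self.individuals:
            if ind.patient_id == patient_id:
                return ind
        raise KeyError(f"patient {patient_id!r} not in fit")


class _PatientBlock:
    __slots__ = ("patient_id", "t", "logy", "n")

    def __init__(self, patient_id, t, y):
        self.patient_id = patient_id
        self.t = np.asarray(t, dtype=float)
        self.logy = np.log(np.asarray(y, dtype=float))
        self.n = len(self.t)


class _ModelOps:
    """Precomputed metadata and hot-path helpers for one model."""

    def __init__(self, model: SOEModel, dc: DecayConstants, alpha_scale: str):
        self.model = model
        self.dc = dc
        self.names = model.param_names
        self.q = len(self.names)
        self.alpha_idx = [i for i, n in enumerate(self.names) if n == "alpha"]
        self.logit_alpha = alpha_scale == "logit" and bool(self.alpha_idx)
        order_idx = [self.names.index(n) for n in model.ordered_rates]
        self.order_pairs = list(zip(order_idx[:-1], order_idx[1:]))
        pop_idx = [self.names.index(n) for n in model.pop_ordered_rates]
        self.pop_order_pairs = list(zip(pop_idx[:-1], pop_idx[1:]))

    def pop_valid(self, tvp: np.ndarray) -> bool:
        """Population fixed effects satisfy the label-switching ordering."""
        return all(tvp[lo] <= tvp[hi] for lo, hi in self.pop_order_pairs)

    def canonicalize(self, vals: np.ndarray) -> np.ndarray:
        """Map a parameter vector to the canonical symmetry representative.

        f4d/f4e are invariant under (alpha, l1, l2) -> (1-alpha, l2, l1);
        the representative has l1 <= l2.
        """
        vals = np.asarray(vals, dtype=float).copy()
        if self.model.model_id in ("f4d", "f4e") and not self.pop_valid(vals):
            i_a = self.names.index("alpha")
            i1 = self.names.index("lambda1")
            i2 = self.names.index("lambda2")
            vals[i_a] = 1.0 - vals[i_a]
            vals[i1], vals[i2] = vals[i2], vals[i1]
        return vals

    # individual parameter values from fixed effects and random effects
    def individual(self, tvp: np.ndarray, eta: np.ndarray) -> np.ndarray:
        vals = tvp * np.exp(eta)
        if self.logit_alpha:
            for i in self.alpha_idx:
                vals[i] = expit(logit(tvp[i]) + eta[i])
        return vals

    def individual_batch(self, tvp: np.ndarray, etas: np.ndarray) -> np.ndarray:
        """(B, q) eta matrix -> (B, q) individual parameter matrix."""
        vals = tvp[None, :] * np.exp(etas)
        if self.logit_alpha:
            for i in self.alpha_idx:
                vals[:, i] = expit(logit(tvp[i]) + etas[:, i])
        return vals

    def quick_valid(self, vals: np.ndarray) -> bool:
        for i in self.alpha_idx:
            if not (0.0 <= vals[i] <= 1.0):
                return False
        for lo, hi in self.order_pairs:
            if vals[lo] > vals[hi]:
                return False
        return bool(np.all(np.isfinite(vals)))

    def log_curve_batch(self, vals: np.ndarray, t: np.ndarray) -> np.ndarray:
        """(B, q) parameter matrix -> (B, n) log-curve matrix.

        ``t`` is either one shared time vector (n,) or per-row times
        (B, n).  Rows that are invalid anywhere (bounds, ordering,
        nonpositive or nonfinite curve values) come back as all-NaN.
        """
        B = vals.shape[0]
        valid = np.all(np.isfinite(vals), axis=1)
        for i in self.alpha_idx:
            valid &= (vals[:, i] >= 0.0) & (vals[:, i] <= 1.0)
        for lo, hi in self.order_pairs:
            valid &= vals[:, lo] <= vals[:, hi]
        tmat = t[None, :] if t.ndim == 1 else t
        out = np.full((B, tmat.shape[-1]), np.nan)
        if not np.any(valid):
            return out
        cols = {n: vals[:, i] for i, n in enumerate(self.names)}
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            try:
                terms = self.model.terms_fn(cols, self.dc)
            except DegenerateParameterError:
                return out
            K = len(terms)
            rates = np.empty((K, B))
            coefs = np.empty((K, B))
            for k, (r, c) in enumerate(terms):
                rates[k] = r  # broadcasting assignment accepts scalars
                coefs[k] = c
            coefs[-1] = -coefs[:-1].sum(axis=0)
            # f[b, i] = sum_k coefs[k, b] * exp(-rates[k, b] * t[b, i])
            f = np.einsum(
                "kb,kbi->bi", coefs,
                np.exp(-rates[:, :, None] * tmat[None, :, :]))
            good = valid & np.all(np.isfinite(f) & (f > 0.0), axis=1)
            out[good] = np.log(f[good])
        return out

    def log_curve(self, vals: np.ndarray, t: np.ndarray):
        """log f(t) for one parameter vector, or None if invalid there."""
        row = self.log_curve_batch(np.asarray(vals, dtype=float)[None, :], t)[0]
        if np.any(np.isnan(row)):
            return None
        return row

    # outer optimisation coordinates for the fixed effects
    def x_from_tvp(self, tvp: np.ndarray) -> np.ndarray:
        x = np.log(tvp)
        if self.logit_alpha:
            for i in self.alpha_idx:
                x[i] = logit(tvp[i])
        return x

    def tvp_from_x(self, x: np.ndarray) -> np.ndarray:
        tvp = np.exp(x)
        if self.logit_alpha:
            for i in self.alpha_idx:
                tvp[i] = expit(x[i])
        return tvp


def _inner_g(ops, block, tvp, eta_full, act, om2_act, sigma2):
    """Joint -log density (up to no constant) for one patient: residual
    likelihood plus random-effect prior, i.e. the inner Laplace objective."""
    logf = ops.log_curve(ops.individual(tvp, eta_full), block.t)
    if logf is None:
        return math.inf
    r = block.logy - logf
    val = 0.5 * float(r @ r) / sigma2 + 0.5 * block.n * math.log(
        2.0 * math.pi * sigma2
    )
    if act.size:
        ea = eta_full[act]
        val += 0.5 * float(np.sum(ea * ea / om2_act))
        val += 0.5 * float(np.sum(np.log(2.0 * math.pi * om2_act)))
    return val


_LS_SCALES = 0.5 ** np.arange(12)  # backtracking line-search trial scales


class _CohortArrays:
    """Padded per-patient time/observation matrices for batched solves.

    Patients with fewer observations than the widest one are padded with a
    repeat of their first time point and masked out of the residuals.
    """

    def __init__(self, blocks):
        self.blocks = blocks
        self.P = len(blocks)
        self.nmax = max((b.n for b in blocks), default=1)
        self.T = np.empty((self.P, self.nmax))
        self.LOGY = np.zeros((self.P, self.nmax))
        self.MASK = np.zeros((self.P, self.nmax))
        self.nvec = np.array([b.n for b in blocks], dtype=float)
        for p, b in enumerate(blocks):
            self.T[p] = b.t[0]
            self.T[p, : b.n] = b.t
            self.LOGY[p, : b.n] = b.logy
            self.MASK[p, : b.n] = 1.0


def _eb_solve_all(ops, ca, tvp, om2_act, act, sigma2, eta0s=None,
                  maxiter=60, gtol=1e-9, probe=False):
    """Posterior-mode etas for every patient, batched.

    Damped Gauss-Newton on the active random-effect dimensions; each sweep
    evaluates all unconverged patients' centers, finite-difference
    Jacobians and line-search trials in single batched curve calls.
    Returns ``(etas (P, q), g (P,), H (P, qa, qa))`` or None when the
    population parameters are invalid for some patient even at eta = 0.
    """
    P, q, qa = ca.P, ops.q, act.size
    sig2 = sigma2
    res_const = 0.5 * ca.nvec * math.log(2.0 * math.pi * sig2)
    pri_const = (0.5 * float(np.sum(np.log(2.0 * math.pi * om2_act)))
                 if qa else 0.0)

    def g_of(etas_act, rows):
        full = np.zeros((etas_act.shape[0], q))
        if qa:
            full[:, act] = etas_act
        logf = ops.log_curve_batch(
            ops.individual_batch(tvp, full), ca.T[rows])
        r = (ca.LOGY[rows] - logf) * ca.MASK[rows]
        with np.errstate(invalid="ignore"):
            g = (0.5 * np.einsum("bi,bi->b", r, r) / sig2
                 + res_const[rows] + pri_const)
            if qa:
                g = g + 0.5 * np.sum(
                    etas_act * etas_act / om2_act[None, :], axis=1)
        return np.where(np.isnan(g), np.inf, g), logf

    allp = np.arange(P)
    etas = np.zeros((P, qa))
    g, _ = g_of(etas, allp)
    if eta0s is not None and qa and np.any(eta0s[:, act]):
        cand = eta0s[:, act]
        gc, _ = g_of(cand, allp)
        take = gc < g
        etas[take] = cand[take]
        g = np.minimum(g, gc)
    if probe and qa:
        # the inner posterior can be multimodal at large omega2: probe a
        # step of +-1 SD along each dimension so the reported objective
        # does not depend on the warm-start history
        sd_steps = np.sqrt(om2_act)
        for j in range(qa):
            for sgn in (1.0, -1.0):
                cand = etas.copy()
                cand[:, j] += sgn * sd_steps[j]
                gc, _ = g_of(cand, allp)
                take = gc < g
                etas[take] = cand[take]
                g = np.minimum(g, gc)
    if not np.all(np.isfinite(g)):
        return None
    if qa == 0:
        full = np.zeros((P, q))
        return full, g, np.zeros((P, 0, 0))

    h = 1e-6
    H = np.tile(np.diag(1.0 / om2_act), (P, 1, 1))
    active = np.ones(P, dtype=bool)
    eye_h = np.vstack([np.zeros((1, qa)), np.eye(qa) * h])
    for _ in range(maxiter):
        S = np.flatnonzero(active)
        if S.size == 0:
            break
        reps = qa + 1
        rows = np.repeat(S, reps)
        pts = np.repeat(etas[S], reps, axis=0) + np.tile(eye_h, (S.size, 1))
        _, logf = g_of(pts, rows)
        logf = logf.reshape(S.size, reps, ca.nmax)
        steps = np.zeros((S.size, qa))
        needs_step = np.zeros(S.size, dtype=bool)
        for si, p in enumerate(S):
            center = logf[si, 0]
            J = (logf[si, 1:] - center[None, :]).T / h
            bad = np.isnan(J).any(axis=0)
            if np.any(bad):
                # forward step left the valid region: backward differences
                for k in np.flatnonzero(bad):
                    pt = etas[p].copy()
                    pt[k] -= h
                    _, lf = g_of(pt[None, :], np.array([p]))
                    if np.any(np.isnan(lf[0])):
                        return None
                    J[:, k] = (center - lf[0]) / h
            J = J * ca.MASK[p][:, None]
            r = (ca.LOGY[p] - center) * ca.MASK[p]
            grad = -(J.T @ r) / sig2 + etas[p] / om2_act
            H[p] = (J.T @ J) / sig2 + np.diag(1.0 / om2_act)
            if np.max(np.abs(grad)) < gtol:
                active[p] = False
                continue
            try:
                steps[si] = -np.linalg.solve(H[p], grad)
            except np.linalg.LinAlgError:
                steps[si] = -grad * om2_act
            needs_step[si] = True
        S2 = S[needs_step]
        if S2.size == 0:
            continue
        nls = _LS_SCALES.size
        rows2 = np.repeat(S2, nls)
        trials = (np.repeat(etas[S2], nls, axis=0)
                  + np.tile(_LS_SCALES[:, None], (S2.size, 1))
                  * np.repeat(steps[needs_step], nls, axis=0))
        gt, _ = g_of(trials, rows2)
        gt = gt.reshape(S2.size, nls)
        for si, p in enumerate(S2):
            better = np.flatnonzero(gt[si] < g[p])
            if better.size == 0:
                active[p] = False
                continue
            k = better[0]
            etas[p] = trials[si * nls + k]
            g[p] = gt[si, k]
    full = np.zeros((P, q))
    full[:, act] = etas
    return full, g, H


def _eb_solve(ops, block, tvp, om2_act, act, sigma2, eta0=None,
              maxiter=60, gtol=1e-9):
    """Single-patient wrapper around :func:`_eb_solve_all`."""
    if block.n == 0 or act.size == 0:
        eta = np.zeros(ops.q)
        g = _inner_g(ops, block, tvp, eta, act, om2_act, sigma2)
        if not np.isfinite(g):
            return None
        return (eta, g,
                np.diag(1.0 / om2_act) if act.size else np.zeros((0, 0)))
    ca = _CohortArrays([block])
    eta0s = None if eta0 is None else np.asarray(eta0, dtype=float)[None, :]
    res = _eb_solve_all(ops, ca, tvp, om2_act, act, sigma2, eta0s,
                        maxiter, gtol)
    if res is None:
        return None
    etas, g, H = res
    return etas[0], float(g[0]), H[0]


def _laplace_term(g, H, qa):
    if qa == 0:
        return 2.0 * g
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return math.inf
    return 2.0 * g + logdet - qa * LOG2PI


def _blocks_from_dataset(data: BiokineticDataset):
    return [
        _PatientBlock(pid, *data.patient_arrays(pid)) for pid in data.patients
    ]


def marginal_objective(model: SOEModel, pop: PopulationParams,
                       etas: Mapping[str, Sequence[float]],
                       data: BiokineticDataset,
                       dc: DecayConstants = DEFAULT_DECAY,
                       alpha_scale: str = "lognormal") -> float:
    """Joint -2 log density of residuals and random effects at given etas.

    This is the inner objective of the Laplace scheme summed over patients
    (no Laplace determinant term).  Random-effect dimensions with
    ``omega2 == 0`` carry no prior and their etas must be 0.
    """
    ops = _ModelOps(model, dc, alpha_scale)
    act = np.flatnonzero(pop.omega2 > 0.0)
    om2_act = pop.omega2[act]
    total = 0.0
    for block in _blocks_from_dataset(data):
        eta = np.asarray(etas[block.patient_id], dtype=float)
        if eta.shape != (ops.q,):
            raise ValueError(
                f"eta for {block.patient_id!r} must have length {ops.q}"
            )
        inactive = np.setdiff1d(np.arange(ops.q), act)
        if np.any(eta[inactive] != 0.0):
            raise ValueError(
                "eta must be 0 on dimensions with omega2 == 0"
            )
        total += 2.0 * _inner_g(
            ops, block, pop.tvp, eta, act, om2_act, pop.sigma2_intra
        )
    return total


# ---------------------------------------------------------------------------
# pooled (no random effects) heuristic start

def _data_features(blocks):
    t = np.concatenate([b.t for b in blocks])
    y = np.exp(np.concatenate([b.logy for b in blocks]))
    order = np.argsort(t)
    ts, ys = t[order], y[order]
    ymax = float(ys.max())
    tia = float(np.trapezoid(ys, ts)) + float(ys[-1]) / 3e-4
    return ymax, max(tia, 1e-12)


def _random_start(model, ymax, tia, rng):
    mid = model.model_id
    l_slow = float(np.exp(rng.uniform(np.log(2e-5), np.log(6e-4))))
    l_fast = l_slow * float(np.exp(rng.uniform(np.log(3.0), np.log(60.0))))
    l_3 = l_fast * float(np.exp(rng.uniform(np.log(2.0), np.log(20.0))))
    alpha = float(rng.uniform(0.1, 0.9))
    amp = ymax * float(np.exp(rng.uniform(np.log(0.8), np.log(3.0))))
    scale = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
    p = {}
    if mid in ("f3a", "f3c"):
        p = {"A1": amp, "lambda1": l_slow, "lambda2": l_fast}
    elif mid in ("f3b", "f3d"):
        p = {"A1": scale / tia, "lambda1": l_slow, "lambda2": l_fast}
    elif mid == "f4a":
        p = {"A1": amp, "A2": amp * float(rng.uniform(0.2, 0.8)),
             "lambda1": l_slow, "lambda2": l_fast}
    elif mid in ("f4b", "f4c"):
        p = {"A1": amp, "alpha": alpha, "lambda1": l_slow, "lambda2": l_fast}
    elif mid in ("f4d", "f4e"):
        p = {"A1": tia * scale, "alpha": alpha,
             "lambda1": l_slow, "lambda2": l_fast}
    elif mid == "f5a":
        p = {"A1": amp, "A2": amp * float(rng.uniform(0.2, 0.8)),
             "lambda1": l_slow, "lambda2": l_fast, "lambda3": l_3}
    elif mid == "f5b":
        p = {"A1": amp, "A2": amp * float(rng.uniform(0.05, 0.5)),
             "A3": amp * float(rng.uniform(0.3, 1.2)),
             "lambda1": l_slow, "lambda2": l_fast}
    else:  # pragma: no cover
        raise ValueError(mid)
    return np.array([p[n] for n in model.param_names])


def _to_z(ops, vals):
    z = np.log(vals)
    for i in ops.alpha_idx:
        z[i] = logit(vals[i])
    return z


def _from_z(ops, z):
    vals = np.exp(z)
    for i in ops.alpha_idx:
        vals[i] = expit(z[i])
    return vals


def _nls(ops, t, logy, vals0, max_nfev=400):
    """Log-scale least squares from one start; (params, cost) or None."""

    def resid(z):
        logf = ops.log_curve(_from_z(ops, z), t)
        if logf is None:
            return np.full(t.size, 30.0)
        return logy - logf

    try:
        res = optimize.least_squares(resid, _to_z(ops, vals0), method="lm",
                                     max_nfev=max_nfev)
    except Exception:
        return None
    return ops.canonicalize(_from_z(ops, res.x)), float(res.cost)


def _pooled_start(ops, blocks, rng, tries, keep=3):
    """Pooled log-scale least squares over random starts.

    Returns up to ``keep`` distinct solutions (best first, each as a
    parameter vector) and the mean squared residual of the best one.  The
    pooled surface is multimodal -- notably a confluent lambda1 == lambda2
    ridge -- so later population fits start from several distinct basins
    rather than only the best pooled optimum.
    """
    model = ops.model
    t = np.concatenate([b.t for b in blocks])
    logy = np.concatenate([b.logy for b in blocks])
    ymax, tia = _data_features(blocks)
    sols = []
    for _ in range(tries):
        out = _nls(ops, t, logy, _random_start(model, ymax, tia, rng))
        if out is not None and np.isfinite(out[1]):
            sols.append(out)
    if not sols:
        return [_random_start(model, ymax, tia, rng)], math.inf
    sols.sort(key=lambda vc: vc[1])
    best_cost = sols[0][1]
    distinct = []
    for vals, cost in sols:
        if cost > best_cost + 0.5 * abs(best_cost) + 2.0:
            break
        z = _to_z(ops, np.clip(vals, 1e-300, None))
        if all(np.max(np.abs(z - _to_z(ops, np.clip(v, 1e-300, None)))) > 0.3
               for v in distinct):
            distinct.append(vals)
        if len(distinct) >= keep:
            break
    msr = 2.0 * best_cost / max(t.size, 1)
    return distinct, msr


def _two_stage_start(ops, blocks, pooled_vals):
    """Classical two-stage estimates as a starting point.

    Fits every patient separately (seeded at the pooled solution); the
    fixed-effect start is the geometric mean of the individual estimates
    (plain mean on the logit scale for the fraction parameter) and the
    random-effect variance start is their log-scale variance.  Patients
    whose individual fit fails are skipped.
    """
    zs, msrs = [], []
    for b in blocks:
        out = _nls(ops, b.t, b.logy, pooled_vals.copy(), max_nfev=200)
        if out is None:
            continue
        vals, ssr = out
        vals = np.clip(vals, 1e-12, None)
        for i in ops.alpha_idx:
            vals[i] = float(np.clip(vals[i], 1e-4, 1.0 - 1e-4))
        zs.append(_to_z(ops, vals))
        dof = max(b.n - ops.q, 1)
        msrs.append(2.0 * ssr / dof)
    if len(zs) < 2:
        return None
    Z = np.vstack(zs)
    tvp = _from_z(ops, Z.mean(axis=0))
    om2 = np.clip(Z.var(axis=0, ddof=1), 1e-3, 50.0)
    sig2 = float(np.clip(np.median(msrs), 1e-4, 1.0))
    return tvp, om2, sig2


# ---------------------------------------------------------------------------
# population fit

class _Profile:
    """Laplace profile objective over the outer parameter vector."""

    def __init__(self, ops, blocks, settings):
        self.ops = ops
        self.blocks = blocks
        self.s = settings
        self.q = ops.q
        if settings.fixed_omega2 is None:
            self.est_omega = True
            self.act = np.arange(self.q)
            self.fixed_om2 = None
        else:
            self.est_omega = False
            self.fixed_om2 = np.asarray(settings.fixed_omega2, dtype=float)
            self.act = np.flatnonzero(self.fixed_om2 > 0.0)
        self.ca = _CohortArrays(blocks)
        self.cache = np.zeros((len(blocks), self.q))
        self.n_evals = 0

    @property
    def n_theta(self):
        return self.q + (self.q if self.est_omega else 0) + 1

    def unpack(self, theta):
        q = self.q
        tvp = self.ops.tvp_from_x(theta[:q])
        if self.est_omega:
            om2 = np.exp(theta[q:2 * q])
        else:
            om2 = self.fixed_om2
        sigma2 = float(np.exp(theta[-1]))
        return tvp, om2, sigma2

    def pack(self, tvp, om2, sigma2):
        parts = [self.ops.x_from_tvp(np.asarray(tvp, dtype=float))]
        if self.est_omega:
            parts.append(np.log(np.asarray(om2, dtype=float)))
        parts.append(np.array([math.log(sigma2)]))
        return np.concatenate(parts)

    def bounds(self):
        s = self.s
        b = []
        for i, name in enumerate(self.ops.names):
            if name == "alpha" and not self.ops.logit_alpha:
                b.append((math.log(1e-6), 0.0))
            elif name == "alpha":
                b.append((-13.0, 13.0))
            else:
                b.append((-30.0, 30.0))
        if self.est_omega:
            b += [(math.log(s.omega2_bounds[0]),
                   math.log(s.omega2_bounds[1]))] * self.q
        b.append((math.log(s.sigma2_bounds[0]), math.log(s.sigma2_bounds[1])))
        return b

    def ofv(self, theta, update_cache=True, tight=False):
        self.n_evals += 1
        tvp, om2, sigma2 = self.unpack(theta)
        if not self.ops.pop_valid(tvp):
            return _BIG
        om2_act = om2[self.act]
        gtol = self.s.inner_gtol * (0.01 if tight else 1.0)
        res = _eb_solve_all(
            self.ops, self.ca, tvp, om2_act, self.act, sigma2,
            eta0s=self.cache, maxiter=self.s.inner_maxiter, gtol=gtol,
            probe=tight,
        )
        if res is None:
            return _BIG
        etas, g, H = res
        if update_cache:
            self.cache = etas
        qa = self.act.size
        total = 2.0 * float(g.sum())
        if qa:
            signs, logdets = np.linalg.slogdet(H)
            if np.any(signs <= 0):
                return _BIG
            total += float(logdets.sum()) - self.ca.P * qa * LOG2PI
        return total if np.isfinite(total) else _BIG

    def ofv_natural(self, phi):
        """OFV as a function of (tvp, estimated omega2, sigma2) in natural
        scale; used for the finite-difference information matrix."""
        q = self.q
        tvp = phi[:q]
        if np.any(tvp <= 0) and not self.ops.logit_alpha:
            pass
        if self.est_omega:
            om2 = phi[q:2 * q]
            if np.any(om2 <= 0):
                return _BIG
        else:
            om2 = self.fixed_om2
        sigma2 = float(phi[-1])
        if sigma2 <= 0 or np.any(tvp <= 0):
            return _BIG
        for i in self.ops.alpha_idx:
            if tvp[i] >= 1.0:
                return _BIG
        theta = self.pack(tvp, om2, sigma2)
        return self.ofv(theta, update_cache=False)


def _fd_hessian(fun, phi0, rel_step):
    n = phi0.size
    h = rel_step * np.maximum(np.abs(phi0), 1e-10)
    H = np.empty((n, n))
    f0 = fun(phi0)
    for a in range(n):
        ea = np.zeros(n)
        ea[a] = h[a]
        fpp = fun(phi0 + ea)
        fmm = fun(phi0 - ea)
        H[a, a] = (fpp - 2.0 * f0 + fmm) / (h[a] ** 2)
        for b in range(a + 1, n):
            eb = np.zeros(n)
            eb[b] = h[b]
            f1 = fun(phi0 + ea + eb)
            f2 = fun(phi0 + ea - eb)
            f3 = fun(phi0 - ea + eb)
            f4 = fun(phi0 - ea - eb)
            H[a, b] = H[b, a] = (f1 - f2 - f3 + f4) / (4.0 * h[a] * h[b])
    return H


def fit_population(data: BiokineticDataset, model: SOEModel,
                   settings: Optional[FitSettings] = None,
                   dc: DecayConstants = DEFAULT_DECAY) -> PopulationFit:
    """Maximise the Laplace-approximated marginal likelihood.

    Fixed effects, random-effect variances and the residual variance are
    estimated jointly; each outer objective evaluation re-solves every
    patient's empirical-Bayes mode (warm-started).  Requires at least two
    patients.
    """
    settings = settings or FitSettings()
    if len(data.patients) < 2:
        raise ValueError("population fitting requires >= 2 patients")
    ops = _ModelOps(model, dc, settings.alpha_scale)
    blocks = _blocks_from_dataset(data)
    prof = _Profile(ops, blocks, settings)
    rng = np.random.default_rng(settings.seed)

    starts = []
    if settings.init_theta is not None:
        theta = np.asarray(settings.init_theta, dtype=float)
        if theta.size != prof.n_theta:
            raise ValueError("init_theta has wrong length for these settings")
        starts.append(theta)
        if settings.multistarts <= 1:
            # warm start is the only start: skip the heuristic machinery
            return _finish_fit(prof, ops, blocks, starts, settings, model,
                               data, dc)
    pooled_sols, msr = _pooled_start(ops, blocks, rng, settings.pooled_starts)
    sig2_0 = float(np.clip(msr if np.isfinite(msr) else settings.sigma2_init,
                           1e-4, 1.0))
    two_stage = _two_stage_start(ops, blocks, pooled_sols[0])
    bases = []  # (tvp, om2) start bases in priority order
    if two_stage is not None:
        bases.append((two_stage[0], two_stage[1]))
    for vals in pooled_sols:
        bases.append((vals, np.full(ops.q, settings.omega2_init)))
    for tvp_b, om2_b in bases:
        starts.append(prof.pack(tvp_b, om2_b, sig2_0))
    n_starts = max(settings.multistarts, 1)
    if settings.init_theta is not None:
        n_starts += 1  # warm start comes on top of the regular ones
    k = 0
    while len(starts) < n_starts:
        base_tvp, base_om2 = bases[k % len(bases)]
        k += 1
        jit_tvp = base_tvp * np.exp(rng.normal(0.0, 0.25, ops.q))
        for i in ops.alpha_idx:
            jit_tvp[i] = float(np.clip(
                base_tvp[i] * np.exp(rng.normal(0.0, 0.25)), 0.02, 0.98
            ))
        jit_om2 = base_om2 * np.exp(rng.normal(0.0, 1.0, ops.q))
        jit_om2 = np.clip(jit_om2, 1e-4, 50.0)
        jit_sig2 = sig2_0 * float(np.exp(rng.normal(0.0, 0.5)))
        starts.append(prof.pack(jit_tvp, jit_om2,
                                float(np.clip(jit_sig2, 1e-4, 1.0))))
    starts = starts[:n_starts]
    return _finish_fit(prof, ops, blocks, starts, settings, model,
                       data, dc)


def _finish_fit(prof, ops, blocks, starts, settings, model, data, dc):
    """Optimise from the given outer starts and assemble the result."""
    bounds = prof.bounds()
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def _opts(maxiter):
        return {
            "maxiter": maxiter,
            "ftol": settings.outer_ftol,
            "gtol": settings.outer_gtol,
            "maxcor": 20,
            # FD step for the outer gradient, well above the noise floor
            # of the warm-started inner solves
            "eps": settings.outer_fd_step,
        }

    # successive halving: a cheap exploratory pass from every start, then
    # full-length polishing of the best finalists
    explored = []
    for theta0 in starts:
        theta0 = np.clip(theta0, lo, hi)
        if prof.ofv(theta0) >= _BIG:
            continue
        res = optimize.minimize(prof.ofv, theta0, method="L-BFGS-B",
                                bounds=bounds,
                                options=_opts(settings.explore_maxiter))
        explored.append(res)
    if not explored or min(r.fun for r in explored) >= _BIG:
        raise RuntimeError(
            f"{model.model_id}: no feasible starting point / fit failed"
        )
    explored.sort(key=lambda r: r.fun)
    best = None
    if settings.explore_maxiter >= settings.outer_maxiter:
        best = explored[0]  # exploration already ran at full length
    else:
        for res in explored[: max(settings.n_finalists, 1)]:
            res = optimize.minimize(prof.ofv, res.x, method="L-BFGS-B",
                                    bounds=bounds,
                                    options=_opts(settings.outer_maxiter))
            if best is None or res.fun < best.fun:
                best = res
    # restarts from the winner: a fresh quasi-Newton memory often makes
    # further progress on this ridged surface
    for _ in range(settings.max_restarts):
        res = optimize.minimize(prof.ofv, best.x, method="L-BFGS-B",
                                bounds=bounds,
                                options=_opts(settings.outer_maxiter))
        improved = res.fun < best.fun - 1e-3
        if res.fun < best.fun:
            best = res
        if not improved:
            break

    theta_opt = best.x
    ofv = float(prof.ofv(theta_opt, tight=True))
    tvp, om2, sigma2 = prof.unpack(theta_opt)
    converged = bool(best.success) and np.isfinite(ofv)

    om2_act = om2[prof.act]
    eb = _eb_solve_all(ops, prof.ca, tvp, om2_act, prof.act, sigma2,
                       eta0s=prof.cache, maxiter=2 * settings.inner_maxiter,
                       gtol=0.01 * settings.inner_gtol)
    etas_final = eb[0] if eb is not None else np.zeros((len(blocks), ops.q))
    individuals = [
        IndividualEstimate(
            patient_id=block.patient_id,
            eta=etas_final[i],
            params=dict(zip(ops.names, ops.individual(tvp, etas_final[i]))),
        )
        for i, block in enumerate(blocks)
    ]

    cov = cv = None
    if settings.compute_cov:
        phi_parts = [tvp]
        if prof.est_omega:
            phi_parts.append(om2)
        phi_parts.append(np.array([sigma2]))
        phi0 = np.concatenate(phi_parts)
        try:
            H = _fd_hessian(prof.ofv_natural, phi0, settings.cov_rel_step)
            full_cov = 2.0 * np.linalg.inv(H)
            cov = full_cov[: ops.q, : ops.q]
            var = np.diag(cov).copy()
            cv = np.where(var > 0, 100.0 * np.sqrt(np.abs(var)) / tvp,
                          math.inf)
            if np.any(var <= 0):
                cv = np.where(var > 0, cv, math.inf)
        except np.linalg.LinAlgError:
            cov, cv = None, None

    pop = PopulationParams(tvp=tvp, omega2=om2 if prof.est_omega
                           else np.asarray(prof.fixed_om2), sigma2_intra=sigma2)
    return PopulationFit(
        model=model, pop=pop, individuals=individuals, ofv=ofv,
        fixed_effect_cov=cov, cv_percent=cv, converged=converged,
        n_obs=data.n_obs, alpha_scale=settings.alpha_scale, dc=dc,
        theta_opt=theta_opt, n_outer_evals=prof.n_evals,
    )


def initial_theta(model: SOEModel, pop: PopulationParams,
                  settings: Optional[FitSettings] = None,
                  dc: DecayConstants = DEFAULT_DECAY) -> np.ndarray:
    """Outer-coordinate start vector from population parameters.

    For locally initialised fits in the style of estimation tools that
    require user-supplied initial estimates: pass the result as
    ``FitSettings.init_theta``.
    """
    settings = settings or FitSettings()
    ops = _ModelOps(model, dc, settings.alpha_scale)
    prof = _Profile(ops, [], settings)
    return prof.pack(pop.tvp, pop.omega2, pop.sigma2_intra)


def local_fit_settings(model: SOEModel, pop: PopulationParams,
                       settings: Optional[FitSettings] = None,
                       dc: DecayConstants = DEFAULT_DECAY) -> FitSettings:
    """Settings for one local optimisation from given initial estimates.

    Mirrors the classical workflow in which the population fit is a single
    local maximisation started at values from prior knowledge: no
    multistart exploration, no basin-hopping restarts.
    """
    settings = settings or FitSettings()
    # deep convergence: weakly identified rate parameters move slowly
    # along flat likelihood directions, so the local protocol grinds to
    # machine-level progress rather than stopping at the noise floor
    return replace(
        settings,
        multistarts=1,
        init_theta=initial_theta(model, pop, settings, dc),
        outer_maxiter=400,
        outer_ftol=1e-12,
        explore_maxiter=400,
        n_finalists=1,
        max_restarts=0,
    )


def empirical_bayes(fit: PopulationFit,
                    observations: Sequence[Observation]) -> IndividualEstimate:
    """Posterior-mode random effects for one patient given a fitted
    population.  With no observations the estimate shrinks fully to the
    population (eta = 0)."""
    ops = _ModelOps(fit.model, fit.dc, fit.alpha_scale)
    obs = list(observations)
    pid = obs[0].patient_id if obs else "new-patient"
    block = _PatientBlock(
        pid,
        np.array([o.time for o in obs]),
        np.array([o.activity for o in obs]),
    )
    act = np.flatnonzero(fit.pop.omega2 > 0.0)
    res = _eb_solve(ops, block, fit.pop.tvp, fit.pop.omega2[act], act,
                    fit.pop.sigma2_intra, maxiter=120, gtol=1e-11)
    if res is None:
        raise RuntimeError("population parameters invalid for this patient")
    eta = res[0]
    return IndividualEstimate(
        patient_id=pid, eta=eta,
        params=dict(zip(ops.names, ops.individual(fit.pop.tvp, eta))),
    )


def predict_curve(fit: PopulationFit, patient_id: str, times_min):
    """Individual (empirical-Bayes) curve of a fitted patient."""
    from .soe import evaluate

    ind = fit.individual_for(patient_id)
    return evaluate(fit.model, ind.params, times_min, fit.dc)
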