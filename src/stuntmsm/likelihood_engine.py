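"""Panel-data likelihood and maximum-likelihood fitting.

The chain is observed only at visit ages (panel observation): between
visits the path is latent, so each consecutive observation pair
(state u at age t, state v at age t + dt) contributes the (u, v) entry
of the matrix exponential ``P(dt) = expm(dt * Q)`` to the likelihood.
Covariates enter each transition intensity proportionally,
``q_uv(x) = exp(alpha_uv0 + alpha_uv @ x)``, and are held
piecewise-constant at their interval-start value.

The total log-likelihood is a sum over children and over their
consecutive visit pairs; children are independent.  Maximization is by
quasi-Newton (BFGS) iteration on the unconstrained scale (log for
baseline intensities, linear for coefficients), with gradients by
central finite differences and the covariance taken as the inverse of
the finite-difference Hessian of the negative log-likelihood at the
optimum.

Matrix exponentials use scipy's scaling-and-squaring Pade
implementation (robust to repeated eigenvalues).  Evaluation groups
observation pairs by unique (covariate pattern, interval length), so
each distinct matrix exponential is computed once per likelihood
evaluation; the grouped result is identical to the naive pair-by-pair
computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import norm

from .core_model import (
    N_STATES,
    CovariateDesign,
    IntensityMatrix,
    ModelParameters,
    StructureError,
    TransitionStructure,
    parameter_count,
)
from .panel_data import PanelDataset

__all__ = [
    "FitResult",
    "build_intensity_matrix",
    "transition_probability",
    "log_likelihood",
    "fit",
    "confidence_intervals",
    "pack_parameters",
    "unpack_parameters",
    "parameter_names",
]

Z_95 = 1.959964  # standard normal 97.5% quantile


def build_intensity_matrix(
    params: ModelParameters, x: np.ndarray, structure: TransitionStructure
) -> IntensityMatrix:
    """Intensity matrix at covariate profile ``x`` (dummy vector).

    Allowed entries are ``exp(alpha_uv0 + alpha_uv @ x)``; diagonals are
    negated row sums.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n_dummies,):
        raise StructureError(
            f"covariate vector has length {x.shape}, expected ({params.n_dummies},)"
        )
    if params.n_transitions != structure.n_transitions:
        raise StructureError("parameter/structure transition count mismatch")
    log_rates = params.baseline_log_intensity + params.coefficients @ x
    q = np.zeros((N_STATES, N_STATES))
    for i, (u, v) in enumerate(structure.pairs):
        q[u - 1, v - 1] = np.exp(log_rates[i])
    np.fill_diagonal(q, -q.sum(axis=1))
    return IntensityMatrix(q, structure)


def transition_probability(q: IntensityMatrix | np.ndarray, dt: float) -> np.ndarray:
    """Transition probability matrix P(dt) = expm(dt * Q).

    Rows sum to one; entries lie in [0, 1] (tiny negative rounding is
    clipped to zero).  ``dt`` is in months and must be non-negative.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    qm = q.q if isinstance(q, IntensityMatrix) else np.asarray(q, dtype=float)
    p = expm(dt * qm)
    return np.where(p < 0.0, 0.0, p)


# ---------------------------------------------------------------------------
# compiled pair representation

@dataclass(frozen=True)
class _PatternGroup:
    x: np.ndarray  # dummy vector shared by the group
    dts: np.ndarray  # unique interval lengths
    # per dt: parallel index arrays and counts
    from_idx: tuple[np.ndarray, ...]
    to_idx: tuple[np.ndarray, ...]
    counts: tuple[np.ndarray, ...]


@dataclass(frozen=True)
class CompiledPanel:
    """Observation pairs grouped by (covariate pattern, interval length)."""

    groups: tuple[_PatternGroup, ...]
    n_pairs: int
    pair_counts: np.ndarray  # 4x4 observed (u, v) pair counts
    pair_time_by_state: np.ndarray  # total interval time by starting state


def compile_panel(data: PanelDataset, design: CovariateDesign | None) -> CompiledPanel:
    """Pre-aggregate a dataset for repeated likelihood evaluation."""
    n_dum = design.n_dummies if design is not None else 0
    acc: dict[bytes, tuple[np.ndarray, dict[float, dict[tuple[int, int], int]]]] = {}
    n_pairs = 0
    pair_counts = np.zeros((N_STATES, N_STATES), dtype=int)
    pair_time = np.zeros(N_STATES)
    for traj in data.trajectories:
        for a, b in traj.pairs():
            x = design.vector(a.covariates) if design is not None else np.zeros(0)
            dt = float(b.age_months - a.age_months)
            key = x.tobytes()
            if key not in acc:
                acc[key] = (x, {})
            by_dt = acc[key][1].setdefault(dt, {})
            uv = (a.state - 1, b.state - 1)
            by_dt[uv] = by_dt.get(uv, 0) + 1
            n_pairs += 1
            pair_counts[uv] += 1
            pair_time[a.state - 1] += dt
    groups = []
    for x, by_dt in acc.values():
        dts = np.array(sorted(by_dt))
        fr, to, cnt = [], [], []
        for dt in dts:
            items = sorted(by_dt[dt].items())
            fr.append(np.array([uv[0] for uv, _ in items]))
            to.append(np.array([uv[1] for uv, _ in items]))
            cnt.append(np.array([c for _, c in items], dtype=float))
        groups.append(_PatternGroup(x, dts, tuple(fr), tuple(to), tuple(cnt)))
    return CompiledPanel(tuple(groups), n_pairs, pair_counts, pair_time)


def _loglik_compiled(
    params: ModelParameters, compiled: CompiledPanel, structure: TransitionStructure
) -> float:
    total = 0.0
    for g in compiled.groups:
        try:
            q = build_intensity_matrix(params, g.x, structure).q
        except ValueError:
            # overflowing rates (diverging parameters) -> zero likelihood
            return -np.inf
        for k, dt in enumerate(g.dts):
            p = transition_probability(q, dt)
            probs = p[g.from_idx[k], g.to_idx[k]]
            if np.any(probs <= 0.0):
                bad = int(np.argmax(probs <= 0.0))
                warnings.warn(
                    "transition probability underflow for pair "
                    f"({g.from_idx[k][bad] + 1}->{g.to_idx[k][bad] + 1}, dt={dt})"
                )
                return -np.inf
            total += float(g.counts[k] @ np.log(probs))
    return total


def log_likelihood(
    params: ModelParameters,
    data: PanelDataset,
    structure: TransitionStructure,
    design: CovariateDesign | None = None,
) -> float:
    """Panel log-likelihood of ``params`` for the dataset.

    Children observed once contribute nothing (empty product); repeated
    same-state observations contribute the log staying probability.
    """
    return _loglik_compiled(params, compile_panel(data, design), structure)


# ---------------------------------------------------------------------------
# parameter vector packing

def pack_parameters(params: ModelParameters) -> np.ndarray:
    """Flatten to [baselines..., coefficients row-major...]."""
    return np.concatenate([params.baseline_log_intensity, params.coefficients.ravel()])


def unpack_parameters(theta: np.ndarray, n_transitions: int, n_dummies: int) -> ModelParameters:
    theta = np.asarray(theta, dtype=float)
    b = theta[:n_transitions]
    c = theta[n_transitions:].reshape(n_transitions, n_dummies)
    return ModelParameters(b, c)


def parameter_names(
    structure: TransitionStructure, design: CovariateDesign | None
) -> list[str]:
    """Flat names matching :func:`pack_parameters` order."""
    names = [f"State {u}-State {v}" for u, v in structure.pairs]
    if design is not None:
        for u, v in structure.pairs:
            for var, level in design.dummies:
                names.append(f"State {u}-State {v}:{var}={level}")
    return names


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of the multi-state model."""

    params: ModelParameters
    structure: TransitionStructure
    design: CovariateDesign | None
    loglik: float
    n_params: int
    covariance: np.ndarray | None
    converged: bool
    n_iter: int

    @property
    def minus2loglik(self) -> float:
        return -2.0 * self.loglik

    @property
    def parameter_names(self) -> list[str]:
        return parameter_names(self.structure, self.design)

    @property
    def theta(self) -> np.ndarray:
        return pack_parameters(self.params)

    def to_dict(self) -> dict:
        return {
            "parameter_names": self.parameter_names,
            "theta": self.theta.tolist(),
            "loglik": self.loglik,
            "minus2loglik": self.minus2loglik,
            "n_params": self.n_params,
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "structure": self.structure.to_dict(),
            "design": None if self.design is None else self.design.to_dict(),
        }


def _central_gradient(f, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(x.size):
        h = rel_step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g


def _fd_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        hess[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
        for j in range(i + 1, n):
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[[i, j]] += [h[i], h[j]]
            xpm[i] += h[i]
            xpm[j] -= h[j]
            xmp[i] -= h[i]
            xmp[j] += h[j]
            xmm[[i, j]] -= [h[i], h[j]]
            hess[i, j] = hess[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                4 * h[i] * h[j]
            )
    return hess


def crude_initial_parameters(
    compiled: CompiledPanel, structure: TransitionStructure, n_dummies: int
) -> ModelParameters:
    """Occurrence/exposure starting values from the observed pair table.

    Baseline rate for (u, v) is the number of observed u->v pairs over
    the total interval time spent starting in u (a half-count floor
    keeps never-observed transitions finite); coefficients start at 0.
    """
    b = np.empty(structure.n_transitions)
    for i, (u, v) in enumerate(structure.pairs):
        cnt = max(float(compiled.pair_counts[u - 1, v - 1]), 0.5)
        t = max(float(compiled.pair_time_by_state[u - 1]), 1e-8)
        b[i] = np.log(cnt / t)
    return ModelParameters(b, np.zeros((structure.n_transitions, n_dummies)))


def fit(
    data: PanelDataset,
    structure: TransitionStructure,
    design: CovariateDesign | None = None,
    init: ModelParameters | str = "crude",
    options: Mapping | None = None,
) -> FitResult:
    """Maximize the panel likelihood by quasi-Newton iteration.

    ``init="crude"`` starts from occurrence/exposure rates; any
    :class:`ModelParameters` may be supplied instead.  ``options`` keys:
    ``maxiter`` (default 500), ``gtol`` (gradient norm, 1e-5),
    ``n_starts`` and ``start_scale``/``seed`` for optional multi-start
    around the initial point.  Non-convergence returns a result flagged
    ``converged=False`` rather than raising; a non-invertible Hessian
    leaves ``covariance`` as None with a warning.
    """
    opts = dict(options or {})
    maxiter = int(opts.get("maxiter", 500))
    gtol = float(opts.get("gtol", 1e-5))
    n_starts = int(opts.get("n_starts", 1))
    start_scale = float(opts.get("start_scale", 0.5))
    seed = int(opts.get("seed", 0))
    compute_cov = bool(opts.get("covariance", True))

    n_dum = design.n_dummies if design is not None else 0
    compiled = compile_panel(data, design)

    for u, v in structure.pairs:
        if compiled.pair_counts[u - 1, v - 1] == 0:
            warnings.warn(
                f"allowed transition ({u},{v}) never observed as a panel pair; "
                "its parameter may diverge"
            )

    if isinstance(init, str):
        if init != "crude":
            raise ValueError(f"unknown init {init!r}")
        init_params = crude_initial_parameters(compiled, structure, n_dum)
    else:
        init_params = init
    theta0 = pack_parameters(init_params)

    def negloglik(theta: np.ndarray) -> float:
        p = unpack_parameters(theta, structure.n_transitions, n_dum)
        ll = _loglik_compiled(p, compiled, structure)
        return np.inf if not np.isfinite(ll) else -ll

    def grad(theta: np.ndarray) -> np.ndarray:
        return _central_gradient(negloglik, theta)

    rng = np.random.default_rng(seed)
    starts = [theta0] + [
        theta0 + rng.normal(scale=start_scale, size=theta0.size)
        for _ in range(n_starts - 1)
    ]
    best = None
    for s in starts:
        res = minimize(
            negloglik, s, jac=grad, method="BFGS",
            options={"maxiter": maxiter, "gtol": gtol},
        )
        if best is None or res.fun < best.fun:
            best = res

    theta_hat = best.x
    params_hat = unpack_parameters(theta_hat, structure.n_transitions, n_dum)
    covariance = None
    if compute_cov:
        hess = _fd_hessian(negloglik, theta_hat)
        try:
            covariance = np.linalg.inv(hess)
            if not np.all(np.isfinite(covariance)) or np.any(np.diag(covariance) < 0):
                raise np.linalg.LinAlgError("covariance not positive on the diagonal")
        except np.linalg.LinAlgError as err:
            warnings.warn(f"Hessian not invertible at the optimum ({err}); covariance absent")
            covariance = None

    return FitResult(
        params=params_hat,
        structure=structure,
        design=design,
        loglik=-float(best.fun),
        n_params=parameter_count(structure, design),
        covariance=covariance,
        converged=bool(best.success),
        n_iter=int(best.nit),
    )


def confidence_intervals(fit_result: FitResult, level: float = 0.95):
    """Wald intervals for every free parameter.

    Built on the working scale — log scale for baseline intensities,
    linear for covariate coefficients — then back-transformed, so
    intensity intervals are asymmetric about the estimate.
    """
    import pandas as pd

    if fit_result.covariance is None:
        raise ValueError("covariance absent; intervals unavailable")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf(0.5 + level / 2)
    theta = fit_result.theta
    se = np.sqrt(np.diag(fit_result.covariance))
    names = fit_result.parameter_names
    m = fit_result.structure.n_transitions
    rows = []
    for i, name in enumerate(names):
        lo, hi = theta[i] - z * se[i], theta[i] + z * se[i]
        if i < m:  # baseline log-intensity: back-transform
            rows.append(
                {"parameter": name, "kind": "intensity", "estimate": np.exp(theta[i]),
                 "lower": np.exp(lo), "upper": np.exp(hi), "se_working": se[i]}
            )
        else:
            rows.append(
                {"parameter": name, "kind": "coefficient", "estimate": theta[i],
                 "lower": lo, "upper": hi, "se_working": se[i]}
            )
    return pd.DataFrame(rows)
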