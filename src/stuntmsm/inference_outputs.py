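"""Reported quantities derived from a fitted multi-state model.

Every headline number of the analysis is a deterministic function of
the fitted intensity parameters: mean sojourn times ``-1/q_uu`` per
state, next-state jump probabilities ``-q_uv/q_uu``, hazard-ratio
tables ``exp(coefficient)`` with Wald intervals, AIC, intensity tables
at a stated covariate profile, and transition-probability curves
``P(t) = expm(t Q)`` over a forty-month horizon.

Unless a profile is given, quantities refer to the all-reference
covariate profile (every dummy indicator zero); the profile used is
echoed in the outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    N_STATES,
    STATE_LABELS,
    IntensityMatrix,
)
from .likelihood_engine import (
    Z_95,
    FitResult,
    build_intensity_matrix,
    transition_probability,
)

__all__ = [
    "SojournSummary",
    "TransitionProbabilityCurve",
    "mean_sojourn",
    "sojourn_times_from_matrix",
    "jump_probability",
    "hazard_ratios",
    "probability_curves",
    "aic",
    "intensity_table",
]


def aic(minus2loglik: float, n_params: int) -> float:
    """Akaike information criterion: -2 log-likelihood + 2 x parameters."""
    if n_params < 0:
        raise ValueError("n_params must be non-negative")
    return minus2loglik + 2 * n_params


def sojourn_times_from_matrix(q: IntensityMatrix) -> np.ndarray:
    """Mean sojourn time -1/q_uu (months) per state; inf for zero exit."""
    exits = -np.diag(q.q)
    with np.errstate(divide="ignore"):
        return np.where(exits > 0, 1.0 / exits, np.inf)


def jump_probability(q: IntensityMatrix, u: int, v: int) -> float:
    """Probability the next jump from state u goes to v: q_uv / (-q_uu)."""
    if u == v:
        raise ValueError("u and v must differ")
    exit_rate = q.exit_rate(u)
    if exit_rate <= 0:
        raise ValueError(f"state {u} has zero exit intensity; jump undefined")
    return q.rate(u, v) / exit_rate


@dataclass(frozen=True)
class SojournSummary:
    """Per-state mean sojourn times with 95% delta-method intervals."""

    table: pd.DataFrame  # columns: state, label, mean_months, lower, upper
    profile: np.ndarray

    def mean(self, state: int) -> float:
        return float(self.table.loc[self.table.state == state, "mean_months"].iloc[0])


def _profile_or_reference(fit_result: FitResult, profile: np.ndarray | None) -> np.ndarray:
    n = fit_result.params.n_dummies
    if profile is None:
        return np.zeros(n)
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (n,):
        raise ValueError(f"profile must have length {n}")
    return profile


def _exit_rate_terms(fit_result: FitResult, profile: np.ndarray):
    """Per-state exit rate, with the gradient of its log wrt theta."""
    m = fit_result.structure.n_transitions
    d = fit_result.params.n_dummies
    log_rates = (
        fit_result.params.baseline_log_intensity + fit_result.params.coefficients @ profile
    )
    rates = np.exp(log_rates)
    out = {}
    for s in range(1, N_STATES + 1):
        idx = [i for i, (u, _) in enumerate(fit_result.structure.pairs) if u == s]
        total = float(rates[idx].sum()) if idx else 0.0
        grad = np.zeros(m + m * d)
        if total > 0:
            for i in idx:
                w = rates[i] / total
                grad[i] = w
                grad[m + i * d : m + (i + 1) * d] = w * profile
        out[s] = (total, grad)
    return out


def mean_sojourn(fit_result: FitResult, profile: np.ndarray | None = None) -> SojournSummary:
    """Mean sojourn time per state at a covariate profile.

    The mean is ``1 / exit_rate`` with the exit rate evaluated at the
    profile; the 95% interval comes from the delta method on the log
    exit rate, giving an asymmetric interval on the time scale.  States
    with zero exit intensity are reported with infinite sojourn and no
    interval.
    """
    profile = _profile_or_reference(fit_result, profile)
    terms = _exit_rate_terms(fit_result, profile)
    cov = fit_result.covariance
    rows = []
    for s in range(1, N_STATES + 1):
        total, grad = terms[s]
        if total <= 0:
            rows.append(
                {"state": s, "label": STATE_LABELS[s - 1], "mean_months": np.inf,
                 "lower": np.nan, "upper": np.nan}
            )
            continue
        mean = 1.0 / total
        if cov is not None:
            sd = float(np.sqrt(grad @ cov @ grad))
            lo, hi = mean * np.exp(-Z_95 * sd), mean * np.exp(Z_95 * sd)
        else:
            lo = hi = np.nan
        rows.append(
            {"state": s, "label": STATE_LABELS[s - 1], "mean_months": mean,
             "lower": lo, "upper": hi}
        )
    return SojournSummary(pd.DataFrame(rows), profile)


def hazard_ratios(fit_result: FitResult) -> pd.DataFrame:
    """Hazard ratios exp(coefficient) per transition and dummy term.

    Wald 95% bounds are ``exp(coef +/- 1.959964 * SE)``; grouped by
    covariate with the reference level annotated.  Without a covariance
    the point ratios are returned with missing bounds and a warning.
    """
    if fit_result.design is None:
        raise ValueError("fit has no covariate design")
    cov = fit_result.covariance
    if cov is None:
        warnings.warn("covariance absent; hazard ratios reported without intervals")
    m = fit_result.structure.n_transitions
    d = fit_result.params.n_dummies
    se = np.sqrt(np.diag(cov)) if cov is not None else np.full(m + m * d, np.nan)
    rows = []
    for i, (u, v) in enumerate(fit_result.structure.pairs):
        for j, (var, level) in enumerate(fit_result.design.dummies):
            coef = float(fit_result.params.coefficients[i, j])
            s = se[m + i * d + j]
            rows.append(
                {
                    "transition": f"State {u}-State {v}",
                    "variable": var,
                    "level": level,
                    "reference": fit_result.design.variable(var).reference,
                    "ratio": np.exp(coef),
                    "lower": np.exp(coef - Z_95 * s),
                    "upper": np.exp(coef + Z_95 * s),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TransitionProbabilityCurve:
    """P(t) evaluated on a time grid over the follow-up horizon."""

    times: np.ndarray  # (T,)
    probabilities: np.ndarray  # (T, 4, 4)
    profile: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long format (time, from, to, probability) for plotting."""
        rows = []
        for k, t in enumerate(self.times):
            for u in range(N_STATES):
                for v in range(N_STATES):
                    rows.append(
                        {"time": float(t), "from": u + 1, "to": v + 1,
                         "probability": float(self.probabilities[k, u, v])}
                    )
        return pd.DataFrame(rows)

    def at(self, t: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.times - t)))
        return self.probabilities[k]


def probability_curves(
    fit_result: FitResult | IntensityMatrix,
    profile: np.ndarray | None = None,
    horizon: float = 40.0,
    step: float = 0.5,
) -> TransitionProbabilityCurve:
    """Transition probabilities on the grid {0, step, ..., horizon}.

    The default forty-month horizon matches the study's follow-up; the
    half-month step is a display resolution choice.
    """
    if horizon <= 0 or step <= 0:
        raise ValueError("horizon and step must be positive")
    if step > horizon:
        raise ValueError("step must not exceed horizon")
    if isinstance(fit_result, IntensityMatrix):
        q = fit_result
        profile = np.zeros(0) if profile is None else np.asarray(profile)
    else:
        profile = _profile_or_reference(fit_result, profile)
        q = build_intensity_matrix(fit_result.params, profile, fit_result.structure)
    times = np.arange(0.0, horizon + step / 2, step)
    probs = np.stack([transition_probability(q, t) for t in times])
    return TransitionProbabilityCurve(times, probs, profile)


def intensity_table(
    fit_result: FitResult, profile: np.ndarray | None = None
) -> pd.DataFrame:
    """Transition-intensity table at a profile, in the reported layout.

    One row per allowed off-diagonal intensity and per state diagonal
    (the negated exit rate), each with a 95% interval from the delta
    method on the log scale, followed by -2loglik, parameter-count and
    AIC summary rows.
    """
    profile = _profile_or_reference(fit_result, profile)
    m = fit_result.structure.n_transitions
    d = fit_result.params.n_dummies
    cov = fit_result.covariance
    log_rates = (
        fit_result.params.baseline_log_intensity + fit_result.params.coefficients @ profile
    )
    terms = _exit_rate_terms(fit_result, profile)

    rows = []
    for s in range(1, N_STATES + 1):
        total, grad = terms[s]
        if cov is not None and total > 0:
            sd = float(np.sqrt(grad @ cov @ grad))
            lo, hi = -total * np.exp(Z_95 * sd), -total * np.exp(-Z_95 * sd)
        else:
            lo = hi = np.nan
        rows.append(
            {"row": f"State {s}-State {s}", "estimate": -total, "lower": lo, "upper": hi}
        )
        for i, (u, v) in enumerate(fit_result.structure.pairs):
            if u != s:
                continue
            rate = float(np.exp(log_rates[i]))
            if cov is not None:
                g = np.zeros(m + m * d)
                g[i] = 1.0
                g[m + i * d : m + (i + 1) * d] = profile
                sd = float(np.sqrt(g @ cov @ g))
                lo, hi = rate * np.exp(-Z_95 * sd), rate * np.exp(Z_95 * sd)
            else:
                lo = hi = np.nan
            rows.append(
                {"row": f"State {u}-State {v}", "estimate": rate, "lower": lo, "upper": hi}
            )
    rows.append({"row": "-2loglik", "estimate": fit_result.minus2loglik,
                 "lower": np.nan, "upper": np.nan})
    rows.append({"row": "n_params", "estimate": float(fit_result.n_params),
                 "lower": np.nan, "upper": np.nan})
    rows.append({"row": "AIC", "estimate": aic(fit_result.minus2loglik, fit_result.n_params),
                 "lower": np.nan, "upper": np.nan})
    return pd.DataFrame(rows)
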