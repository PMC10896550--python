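"""Synthetic panel cohorts with the structure the analysis assumes.

The generator emulates an urban-slum child-growth surveillance cohort:
children enter between 0 and 36 months of age, are seen at irregular
visits (at most about three per year) until a 40-month horizon, and
their latent stunting severity follows a continuous-time Markov chain
on the four HAZ bands with adjacent-state moves.  Covariates are drawn
independently per variable from the cohort's entry marginals; only the
child-age band varies within a child (it is re-derived from age at
each visit), all other covariates are frozen at entry.

Trajectories are simulated exactly, event by event: sojourn times are
exponential with the state's exit rate and the next state is chosen
with probability rate/exit-rate (Gillespie's algorithm), piecewise per
observation interval so time-varying covariates take their
interval-start value — the same convention the likelihood uses.  The
recorded data are only the latent state at each visit age, so
consecutive recorded states can differ by more than one band even
though every latent jump is adjacent.

Everything is reproducible from a single integer seed, and every
generated dataset is returned together with the exact truth used, so
parameter-recovery tests can close the loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    N_STATES,
    CovariateDesign,
    IntensityMatrix,
    ModelParameters,
    TransitionStructure,
    default_study_design,
    make_adjacent_structure,
)
from .likelihood_engine import build_intensity_matrix
from .panel_data import PanelDataset, PanelObservation, Trajectory

__all__ = [
    "SyntheticConfig",
    "ENTRY_COVARIATE_MARGINALS",
    "ENTRY_STATE_PROBS",
    "ENTRY_AGE_BAND_PROBS",
    "age_band",
    "make_study_truth",
    "sample_covariates",
    "sample_sojourns",
    "simulate_trajectory",
    "generate_dataset",
    "write_panel_csv",
]

#: Entry marginals (column percentages) of the study cohort, per variable.
#: Values are normalized at sampling time (printed columns round to
#: 99-101%).  The time-varying ``child_age`` band is derived from age,
#: never sampled here.
ENTRY_COVARIATE_MARGINALS: dict[str, dict[str, float]] = {
    "slum": {"Korogocho": 61, "Viwandani": 39},
    "sex": {"Female": 51, "Male": 49},
    "ethnicity": {"Kikuyu": 37, "Luhya": 14, "Luo": 14, "Kamba": 18, "Other": 18},
    "food_security": {"Secure": 20, "Moderate": 17, "Severe": 62},
    "marital_status": {"Never Married": 22, "Ever Married": 78},
    "mother_education": {"Less than Primary": 7, "Primary": 71, "Post Primary": 23},
    "sanitation": {"No": 99, "Yes": 1},
    "breastfeeding": {"No": 99, "Yes": 1},
    "safe_water": {"No": 96, "Yes": 4},
    "wealth": {"lowest": 37, "middle": 32, "highest": 31},
}

#: Entry stunting-state shares (Normal, Marginal, Moderate, Severe).
ENTRY_STATE_PROBS = (0.22, 0.29, 0.27, 0.22)

#: Entry age-band shares for bands [0,6), [6,12), [12,24), [24,36].
ENTRY_AGE_BAND_PROBS = (11, 18, 41, 31)
_AGE_BAND_EDGES = ((0.0, 6.0), (6.0, 12.0), (12.0, 24.0), (24.0, 36.0))

#: Fitted baseline transition intensities (per month) of the study's
#: with-covariate model, in canonical pair order
#: (1,2),(2,1),(2,3),(3,2),(3,4),(4,3).
STUDY_BASELINE_INTENSITIES = (0.4214, 0.4114, 0.1714, 0.1909, 0.2845, 0.4390)


def age_band(age_months: float) -> str:
    """Child-age band label for an age in months (ages > 36 keep '24-36')."""
    if age_months < 6:
        return "0-5"
    if age_months < 12:
        return "6-11"
    if age_months < 24:
        return "12-23"
    return "24-36"


def make_study_truth(
    coefficients: np.ndarray | None = None, n_dummies: int = 0
) -> ModelParameters:
    """Ground-truth parameters set to the study's fitted baselines.

    Baseline log-intensities are the logs of the six reported adjacent
    transition rates; coefficients default to zero (``n_dummies`` wide)
    unless an explicit array is supplied.
    """
    b = np.log(STUDY_BASELINE_INTENSITIES)
    if coefficients is None:
        coefficients = np.zeros((6, n_dummies))
    return ModelParameters(b, np.asarray(coefficients, dtype=float))


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_children: int = 676
    true_params: ModelParameters | None = None
    structure: TransitionStructure = field(default_factory=make_adjacent_structure)
    design: CovariateDesign | None = field(default_factory=default_study_design)
    covariate_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: ENTRY_COVARIATE_MARGINALS
    )
    initial_state_distribution: tuple[float, ...] = ENTRY_STATE_PROBS
    entry_age_band_probs: tuple[float, ...] = ENTRY_AGE_BAND_PROBS
    visit_rate: float = 3.0  # expected visits per child-year (cap)
    max_visits: int = 10
    horizon: float = 40.0  # months
    visits_per_child: int | None = None  # fixed-schedule override
    visit_gap: float | None = None  # months, fixed-schedule override
    gap_jitter: float = 0.3  # fraction of the mean gap
    entry_age_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None
    joint_covariate_sampler: Callable[[np.random.Generator, int], pd.DataFrame] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        p = np.asarray(self.initial_state_distribution, dtype=float)
        if p.shape != (N_STATES,) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("initial_state_distribution must be 4 probabilities summing to 1")
        if self.true_params is None:
            n_dum = self.design.n_dummies if self.design is not None else 0
            object.__setattr__(self, "true_params", make_study_truth(n_dummies=n_dum))

    def resolved_params(self) -> ModelParameters:
        assert self.true_params is not None
        return self.true_params


def _normalized(probs: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    levels = list(probs)
    p = np.asarray([probs[l] for l in levels], dtype=float)
    if np.any(p < 0) or p.sum() <= 0:
        raise ValueError("marginal probabilities must be non-negative with positive sum")
    return levels, p / p.sum()


def sample_covariates(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-child covariate assignments from the configured marginals.

    Variables are sampled independently (the cohort's weak pairwise
    associations justify this simplification); a joint sampler hook in
    the config overrides it.  The child-age band is never drawn here.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_children
    if config.joint_covariate_sampler is not None:
        return config.joint_covariate_sampler(rng, n)
    cols = {}
    for var, probs in config.covariate_marginals.items():
        levels, p = _normalized(probs)
        # tolerance for printed percentages that round to 99-101
        if abs(sum(probs.values()) - 100) > 5 and abs(sum(probs.values()) - 1.0) > 0.05:
            raise ValueError(f"marginal for {var!r} sums to neither ~1 nor ~100")
        cols[var] = rng.choice(levels, size=n, p=p)
    return pd.DataFrame(cols)


def sample_sojourns(rate: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exponential sojourn times (months) at a given exit rate."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return rng.exponential(1.0 / rate, size=n)


def simulate_trajectory(
    q_of_interval: Callable[[int], IntensityMatrix],
    visit_ages: Sequence[float],
    initial_state: int,
    rng: np.random.Generator,
    child_id: str = "child",
    covariates_per_visit: Sequence[Mapping[str, str]] | None = None,
) -> Trajectory:
    """Exact event-by-event simulation observed at panel visit ages.

    ``q_of_interval(j)`` supplies the intensity matrix in force on the
    interval between visits j and j+1 (interval-start covariates).  The
    first visit age is the entry age; the returned trajectory records
    the latent state at each visit.
    """
    ages = np.asarray(visit_ages, dtype=float)
    if ages.size == 0:
        raise ValueError("visit_ages must be non-empty")
    if np.any(np.diff(ages) <= 0):
        raise ValueError("visit_ages must be strictly increasing")
    states = [int(initial_state)]
    state = int(initial_state)
    t = float(ages[0])
    for j in range(ages.size - 1):
        q = q_of_interval(j)
        t_end = float(ages[j + 1])
        while True:
            exit_rate = q.exit_rate(state)
            if exit_rate <= 0:
                break
            t_jump = t + float(sample_sojourns(exit_rate, 1, rng)[0])
            if t_jump >= t_end:
                break
            t = t_jump
            p = np.array([q.rate(state, v) for v in range(1, N_STATES + 1)])
            p[state - 1] = 0.0
            state = int(rng.choice(N_STATES, p=p / p.sum())) + 1
        t = t_end
        states.append(state)
    obs = []
    for k, age in enumerate(ages):
        cov = dict(covariates_per_visit[k]) if covariates_per_visit is not None else {}
        obs.append(PanelObservation(age_months=float(age), state=states[k], covariates=cov))
    return Trajectory(child_id, tuple(obs))


def _sample_entry_ages(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if config.entry_age_sampler is not None:
        return np.asarray(config.entry_age_sampler(rng, config.n_children), dtype=float)
    p = np.asarray(config.entry_age_band_probs, dtype=float)
    p = p / p.sum()
    bands = rng.choice(len(_AGE_BAND_EDGES), size=config.n_children, p=p)
    lo = np.array([_AGE_BAND_EDGES[b][0] for b in bands])
    hi = np.array([_AGE_BAND_EDGES[b][1] for b in bands])
    return lo + rng.uniform(size=config.n_children) * (hi - lo)


def _visit_schedule(
    config: SyntheticConfig, entry: float, rng: np.random.Generator
) -> np.ndarray:
    if config.visits_per_child is not None and config.visit_gap is not None:
        ages = entry + config.visit_gap * np.arange(config.visits_per_child)
        ages = ages[ages <= config.horizon]
        return ages if ages.size else np.array([entry])
    span = config.horizon - entry
    years = span / 12.0
    cap = max(2, min(int(round(config.visit_rate * years)), config.max_visits))
    n = int(rng.integers(2, cap + 1))
    base = entry + span * np.arange(n) / (n - 1)
    gap = span / (n - 1)
    jitter = rng.uniform(-config.gap_jitter, config.gap_jitter, size=n) * gap
    jitter[0] = 0.0
    ages = base + jitter
    # enforce strict ordering and the horizon bound, tightening from the end
    ages[-1] = min(ages[-1], config.horizon)
    for k in range(n - 2, 0, -1):
        ages[k] = min(ages[k], ages[k + 1] - 1e-3)
    for k in range(1, n):
        if ages[k] <= ages[k - 1]:
            ages[k] = ages[k - 1] + 1e-3
    return np.minimum(ages, config.horizon)


def generate_dataset(config: SyntheticConfig) -> tuple[PanelDataset, dict]:
    """Simulate a full panel cohort; returns (dataset, truth record).

    The truth record echoes the exact parameters, structure and seed
    used, so recovery tests can compare estimates against it.
    """
    rng = np.random.default_rng(config.seed)
    params = config.resolved_params()
    covariates = (
        sample_covariates(config, rng) if config.design is not None else None
    )
    entries = _sample_entry_ages(config, rng)
    init_p = np.asarray(config.initial_state_distribution, dtype=float)
    initial_states = rng.choice(N_STATES, size=config.n_children, p=init_p) + 1

    has_age_var = config.design is not None and any(
        v.name == "child_age" for v in config.design.variables
    )
    q_cache: dict[bytes, IntensityMatrix] = {}

    def q_for(x: np.ndarray) -> IntensityMatrix:
        key = x.tobytes()
        if key not in q_cache:
            q_cache[key] = build_intensity_matrix(params, x, config.structure)
        return q_cache[key]

    trajectories = []
    for i in range(config.n_children):
        ages = _visit_schedule(config, float(entries[i]), rng)
        fixed = (
            {k: str(covariates.iloc[i][k]) for k in covariates.columns}
            if covariates is not None
            else {}
        )
        cov_per_visit = []
        for a in ages:
            cov = dict(fixed)
            if has_age_var:
                cov["child_age"] = age_band(a)
            cov_per_visit.append(cov)
        if config.design is not None:
            xs = [config.design.vector(c) for c in cov_per_visit]
        else:
            xs = [np.zeros(0) for _ in cov_per_visit]
        traj = simulate_trajectory(
            lambda j: q_for(xs[j]),
            ages,
            int(initial_states[i]),
            rng,
            child_id=f"C{i + 1:05d}",
            covariates_per_visit=cov_per_visit,
        )
        trajectories.append(traj)

    dataset = PanelDataset(tuple(trajectories), config.design)
    truth = {
        "baseline_log_intensity": params.baseline_log_intensity.tolist(),
        "baseline_intensity": np.exp(params.baseline_log_intensity).tolist(),
        "coefficients": params.coefficients.tolist(),
        "structure": config.structure.to_dict(),
        "seed": config.seed,
        "n_children": config.n_children,
        "horizon": config.horizon,
    }
    return dataset, truth


def write_panel_csv(
    dataset: PanelDataset, path: str | Path, truth: Mapping | None = None
) -> None:
    """Write a dataset in the CSV dialect ``read_panel`` consumes.

    If a truth record is given it is written as JSON next to the CSV.
    """
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    if truth is not None:
        path.with_suffix(".truth.json").write_text(json.dumps(dict(truth), indent=2))
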