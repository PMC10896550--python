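"""Panel-data ingestion, HAZ classification and descriptive summaries.

A panel dataset holds one age-ordered trajectory per child: the stunting
state (or the HAZ score it is classified from) observed at each visit,
plus categorical covariates.  This module reads such data from CSV,
classifies HAZ into the four severity bands, tabulates observed
consecutive-pair transitions, prunes the transition structure, and
computes entry descriptives and the Cramér's V collinearity screen.

Note on the severity bands: some published descriptions print the
normal band as "HAZ >= 1", but the adjacent marginal band (-2 <= HAZ <
-1) forces the normal cut point to be -1; we use HAZ >= -1.  Each band
is closed at its lower cut and open at its upper cut, so HAZ = -1 is
classified Normal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import (
    HAZ_CUTS,
    N_STATES,
    STATE_LABELS,
    CovariateDesign,
    TransitionStructure,
    make_adjacent_structure,
)

__all__ = [
    "PanelObservation",
    "Trajectory",
    "PanelDataset",
    "TransitionCountTable",
    "classify_haz",
    "read_panel",
    "count_transitions",
    "prune_structure",
    "cramers_v",
    "cramers_v_from_table",
    "cramers_v_screen",
    "entry_descriptives",
    "EntryDescriptives",
]

logger = logging.getLogger(__name__)

DEFAULT_HORIZON = 40.0  # months of follow-up

#: Accepted spellings for each state in input files.
_STATE_ALIASES: dict[str, int] = {}
for _i, _label in enumerate(STATE_LABELS, start=1):
    _STATE_ALIASES[str(_i)] = _i
    _STATE_ALIASES[f"s{_i}"] = _i
    _STATE_ALIASES[_label.lower()] = _i


class PanelValidationError(ValueError):
    """Input panel data violates a structural requirement."""


def classify_haz(haz: float | np.ndarray) -> int | np.ndarray:
    """Classify a height-for-age Z-score into severity state 1..4.

    Normal (1): HAZ >= -1; marginal (2): -2 <= HAZ < -1; moderate (3):
    -3 <= HAZ < -2; severe (4): HAZ < -3.  Accepts scalars or arrays.
    """
    arr = np.asarray(haz, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise PanelValidationError("HAZ values must be finite")
    c1, c2, c3 = HAZ_CUTS
    state = np.select([arr >= c1, arr >= c2, arr >= c3], [1, 2, 3], default=4)
    if np.isscalar(haz) or arr.ndim == 0:
        return int(state)
    return state


@dataclass(frozen=True)
class PanelObservation:
    """One child-visit record: age, state (or HAZ) and covariate levels."""

    age_months: float
    state: int
    haz: float | None = None
    covariates: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.state <= N_STATES:
            raise PanelValidationError(f"state must be 1..{N_STATES}, got {self.state}")
        if self.age_months < 0:
            raise PanelValidationError("age_months must be non-negative")
        if self.haz is not None and classify_haz(self.haz) != self.state:
            raise PanelValidationError(
                f"state {self.state} inconsistent with HAZ {self.haz}"
            )


@dataclass(frozen=True)
class Trajectory:
    """A child's age-ordered observation sequence."""

    child_id: str
    observations: tuple[PanelObservation, ...]

    def __post_init__(self) -> None:
        if len(self.observations) == 0:
            raise PanelValidationError(f"child {self.child_id}: empty trajectory")
        ages = [o.age_months for o in self.observations]
        if not all(a < b for a, b in zip(ages, ages[1:])):
            raise PanelValidationError(
                f"child {self.child_id}: visit ages must be strictly increasing"
            )

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def pairs(self) -> Iterable[tuple[PanelObservation, PanelObservation]]:
        """Consecutive observation pairs, the likelihood units."""
        return zip(self.observations, self.observations[1:])


@dataclass(frozen=True)
class PanelDataset:
    """A collection of trajectories with a shared covariate design."""

    trajectories: tuple[Trajectory, ...]
    design: CovariateDesign | None = None

    def __post_init__(self) -> None:
        ids = [t.child_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelValidationError(f"duplicate child ids: {dup[:5]}")
        if self.design is not None:
            known = {v.name: set(v.levels) for v in self.design.variables}
            for t in self.trajectories:
                for o in t.observations:
                    for name, level in o.covariates.items():
                        if name in known and level not in known[name]:
                            raise PanelValidationError(
                                f"child {t.child_id}: level {level!r} of {name!r} "
                                "absent from the design"
                            )

    @property
    def n_children(self) -> int:
        return len(self.trajectories)

    @property
    def n_observations(self) -> int:
        return sum(t.n_obs for t in self.trajectories)

    @property
    def n_pairs(self) -> int:
        return sum(t.n_obs - 1 for t in self.trajectories)

    def entry_frame(self) -> pd.DataFrame:
        """One row per child: entry age, entry state, entry covariates."""
        rows = []
        for t in self.trajectories:
            o = t.observations[0]
            row = {"child_id": t.child_id, "age_months": o.age_months, "state": o.state}
            row.update(o.covariates)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per child-visit."""
        rows = []
        for t in self.trajectories:
            for o in t.observations:
                row = {
                    "child_id": t.child_id,
                    "age_months": o.age_months,
                    "state": o.state,
                    "haz": o.haz,
                }
                row.update(o.covariates)
                rows.append(row)
        return pd.DataFrame(rows)


def _parse_state(value) -> int:
    key = str(value).strip().lower()
    if key.endswith(".0"):  # integer state read back as float
        key = key[:-2]
    if key not in _STATE_ALIASES:
        raise PanelValidationError(f"unknown state label {value!r}")
    return _STATE_ALIASES[key]


def read_panel(
    path: str | Path,
    child_col: str = "child_id",
    age_col: str = "age_months",
    haz_col: str | None = None,
    state_col: str | None = None,
    covariate_cols: Mapping[str, str] | None = None,
    design: CovariateDesign | None = None,
    horizon: float = DEFAULT_HORIZON,
) -> PanelDataset:
    """Read a long-format CSV panel into a validated :class:`PanelDataset`.

    One row per child-visit.  Exactly one of ``haz_col`` / ``state_col``
    is required (if only HAZ is given, states are classified from it).
    ``covariate_cols`` maps design variable names to CSV column names
    (identity mapping for ``design`` variables when omitted).  Rows with
    a missing required field are dropped complete-case, with the count
    logged.  Visit ages must be strictly increasing within each child.
    """
    if haz_col is None and state_col is None:
        raise ValueError("one of haz_col or state_col must be given")
    df = pd.read_csv(path)
    for col in [child_col, age_col] + [c for c in (haz_col, state_col) if c]:
        if col not in df.columns:
            raise PanelValidationError(f"required column {col!r} missing from {path}")

    if covariate_cols is None:
        covariate_cols = (
            {v.name: v.name for v in design.variables if v.name in df.columns}
            if design is not None
            else {}
        )

    required = [child_col, age_col] + [c for c in (haz_col, state_col) if c]
    required += list(covariate_cols.values())
    n_raw = len(df)
    df = df.dropna(subset=[c for c in required if c in df.columns])
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.info("read_panel: dropped %d incomplete rows of %d", n_dropped, n_raw)

    trajectories = []
    for child_id, sub in df.groupby(child_col, sort=False):
        ages = sub[age_col].to_numpy(dtype=float)
        if np.any(np.diff(ages) <= 0):
            raise PanelValidationError(
                f"child {child_id}: visit ages not strictly increasing"
            )
        if np.any(ages < 0) or np.any(ages > horizon):
            raise PanelValidationError(
                f"child {child_id}: ages must lie in [0, {horizon}] months"
            )
        obs = []
        for _, row in sub.iterrows():
            haz = float(row[haz_col]) if haz_col else None
            if state_col:
                state = _parse_state(row[state_col])
            else:
                state = classify_haz(haz)
            cov = {var: str(row[col]) for var, col in covariate_cols.items()}
            obs.append(
                PanelObservation(
                    age_months=float(row[age_col]), state=state, haz=haz, covariates=cov
                )
            )
        trajectories.append(Trajectory(str(child_id), tuple(obs)))
    return PanelDataset(tuple(trajectories), design)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with halves away from zero (display rule)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass(frozen=True)
class TransitionCountTable:
    """4x4 observed consecutive-pair transition counts and row percentages."""

    counts: np.ndarray
    row_percent: np.ndarray

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "TransitionCountTable":
        counts = np.asarray(counts, dtype=int)
        if counts.shape != (N_STATES, N_STATES) or np.any(counts < 0):
            raise ValueError("counts must be a non-negative 4x4 table")
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals > 0, 100.0 * counts / totals, 0.0)
        return cls(counts, pct)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def rounded_percent(self) -> np.ndarray:
        """Whole-percent display values (half-up rounding)."""
        return _round_half_up(self.row_percent)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(STATE_LABELS, name="from")
        cols = pd.Index(STATE_LABELS, name="to")
        return pd.DataFrame(self.counts, index=idx, columns=cols)


def count_transitions(data: PanelDataset) -> TransitionCountTable:
    """Tabulate consecutive observation pairs by (earlier, later) state."""
    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    for t in data.trajectories:
        for a, b in t.pairs():
            counts[a.state - 1, b.state - 1] += 1
    if counts.sum() == 0:
        raise PanelValidationError("no consecutive observation pairs in the dataset")
    return TransitionCountTable.from_counts(counts)


def prune_structure(
    table: TransitionCountTable,
    mode: str = "figure2",
    threshold_percent: float = 10.0,
) -> TransitionStructure:
    """Select the transition structure to fit.

    ``mode="figure2"`` returns the adjacent-only structure regardless of
    the table — this is what the published model actually fitted.
    ``mode="threshold"`` keeps every off-diagonal pair whose row share
    is at least ``threshold_percent``; applied to the published counts
    this keeps some non-adjacent pairs (e.g. a 15% normal-to-moderate
    cell), so the stated drop-below-10% rule and the fitted structure
    genuinely disagree, and the fitted structure is the default.
    """
    if mode == "figure2":
        return make_adjacent_structure()
    if mode != "threshold":
        raise ValueError(f"unknown mode {mode!r}")
    if not 0 < threshold_percent < 100:
        raise ValueError("threshold_percent must be in (0, 100)")
    pairs = {
        (u, v)
        for u in range(1, N_STATES + 1)
        for v in range(1, N_STATES + 1)
        if u != v and table.row_percent[u - 1, v - 1] >= threshold_percent
    }
    return TransitionStructure(frozenset(pairs))


def cramers_v_from_table(table: np.ndarray) -> float:
    """Cramér's V from a contingency table (uncorrected Pearson chi-square).

    V = sqrt(chi2 / (n * (min(r, c) - 1))), in [0, 1].
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must have at least 2 rows and 2 columns")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column has zero total")
    chi2 = stats.chi2_contingency(table, correction=False).statistic
    n = table.sum()
    k = min(table.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))


def cramers_v(data: PanelDataset, var_a: str, var_b: str) -> float:
    """Cramér's V between two categorical covariates at study entry."""
    entry = data.entry_frame()
    for v in (var_a, var_b):
        if v not in entry.columns:
            raise KeyError(f"covariate {v!r} not present")
        if entry[v].nunique() < 2:
            raise ValueError(f"variable {v!r} has a single observed level")
    table = pd.crosstab(entry[var_a], entry[var_b]).to_numpy()
    return cramers_v_from_table(table)


def cramers_v_screen(
    data: PanelDataset, variables: Sequence[str] | None = None, weak_below: float = 0.2
) -> pd.DataFrame:
    """Pairwise Cramér's V over covariates, flagging weak (< 0.2) pairs.

    The flag follows the conventional rule of thumb for dismissing
    multicollinearity concerns; it is informational, not a filter.
    """
    if variables is None:
        if data.design is None:
            raise ValueError("no design attached; pass variables explicitly")
        entry = data.entry_frame()
        variables = [
            v.name
            for v in data.design.variables
            if v.name in entry.columns and entry[v.name].nunique() >= 2
        ]
    rows = []
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            v = cramers_v(data, a, b)
            rows.append({"var_a": a, "var_b": b, "cramers_v": v, "weak": v < weak_below})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EntryDescriptives:
    """Column-percentage table by group with per-variable Pearson p-values."""

    table: pd.DataFrame  # rows (variable, level); columns groups + "Combined"
    p_values: pd.Series  # per variable; NaN when undefined (single group)
    group_sizes: pd.Series


def entry_descriptives(
    data: PanelDataset,
    grouping: str,
    variables: Sequence[str] | None = None,
) -> EntryDescriptives:
    """Entry-visit descriptive statistics split by a grouping variable.

    For each categorical variable, reports column percentages within
    each group plus a combined column, and an (uncorrected) Pearson
    chi-square p-value for group-by-level association.  Covariates are
    taken at each child's first observation.  With a single group the
    p-values are reported as missing.
    """
    entry = data.entry_frame()
    if grouping not in entry.columns:
        raise KeyError(f"grouping variable {grouping!r} not present")
    if variables is None:
        variables = [
            c for c in entry.columns if c not in ("child_id", "age_months", grouping)
        ]

    group_sizes = entry.groupby(grouping).size()
    empty = group_sizes[group_sizes == 0]
    if len(empty):
        warnings.warn(f"dropping empty groups: {list(empty.index)}")
    groups = list(group_sizes.index)

    blocks = []
    pvals = {}
    for var in variables:
        ct = pd.crosstab(entry[var].astype(str), entry[grouping])
        ct = ct.reindex(columns=groups, fill_value=0)
        pct = 100.0 * ct / ct.sum(axis=0)
        combined = 100.0 * ct.sum(axis=1) / ct.to_numpy().sum()
        pct["Combined"] = combined
        pct.index = pd.MultiIndex.from_product([[var], pct.index], names=["variable", "level"])
        blocks.append(pct)
        if len(groups) >= 2 and ct.shape[0] >= 2:
            pvals[var] = float(stats.chi2_contingency(ct.to_numpy(), correction=False).pvalue)
        else:
            pvals[var] = np.nan
    table = pd.concat(blocks)
    return EntryDescriptives(table, pd.Series(pvals, name="p_value"), group_sizes)
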