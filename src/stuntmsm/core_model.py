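"""State space, transition structure and intensity-matrix parameterization.

The model is a continuous-time Markov chain on four ordered stunting
severity states defined by height-for-age Z-score (HAZ) bands:

====  =====================  ==================
code  label                  HAZ band
====  =====================  ==================
1     Normal                 HAZ >= -1
2     Marginally stunted     -2 <= HAZ < -1
3     Moderately stunted     -3 <= HAZ < -2
4     Severely stunted       HAZ < -3
====  =====================  ==================

The chain is parameterized by a 4x4 generator ("intensity") matrix Q
whose off-diagonal entry ``q[u, v]`` is the instantaneous rate of moving
from state ``u`` to state ``v`` (events per month) and whose rows sum to
zero.  Intensities are stored on the log scale so that likelihood
optimization is unconstrained, and covariates act multiplicatively
(proportional intensities): ``q_uv(x) = exp(alpha_uv0 + alpha_uv @ x)``.

State indices are 1-based in every user-facing representation ("State
1-State 2"); internal numpy arrays are 0-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "N_STATES",
    "STATE_LABELS",
    "StateSpace",
    "TransitionStructure",
    "IntensityMatrix",
    "CategoricalVariable",
    "CovariateDesign",
    "ModelParameters",
    "make_adjacent_structure",
    "parameter_count",
    "assemble_intensity",
    "default_study_design",
    "save_config",
    "load_config",
]

N_STATES = 4

STATE_LABELS = (
    "Normal",
    "Marginally stunted",
    "Moderately stunted",
    "Severely stunted",
)

# Band edges on the HAZ scale, strictly decreasing.  Each band is closed
# at its lower cut and open at its upper cut, so HAZ = -1 is Normal.
HAZ_CUTS = (-1.0, -2.0, -3.0)


class StructureError(ValueError):
    """A parameter set does not match the transition structure."""


@dataclass(frozen=True)
class StateSpace:
    """The ordered four-state stunting severity scale."""

    labels: tuple[str, ...] = STATE_LABELS
    haz_cuts: tuple[float, ...] = HAZ_CUTS

    def __post_init__(self) -> None:
        if len(self.labels) != N_STATES:
            raise ValueError(f"exactly {N_STATES} states required, got {len(self.labels)}")
        cuts = np.asarray(self.haz_cuts, dtype=float)
        if len(cuts) != N_STATES - 1 or not np.all(np.diff(cuts) < 0):
            raise ValueError("haz_cuts must be three strictly decreasing cut points")


@dataclass(frozen=True)
class TransitionStructure:
    """The set of state pairs with a free instantaneous transition rate.

    ``allowed`` holds ordered 1-based pairs ``(u, v)``, ``u != v``.  The
    fitted model of the study permits only adjacent-severity moves
    (1<->2, 2<->3, 3<->4); see :func:`make_adjacent_structure`.
    """

    allowed: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for u, v in self.allowed:
            if u == v:
                raise ValueError(f"self-pair ({u},{u}) not allowed")
            if not (1 <= u <= N_STATES and 1 <= v <= N_STATES):
                raise ValueError(f"state indices must be in 1..{N_STATES}: ({u},{v})")
        if self.allowed and not self._strongly_connected():
            warnings.warn(
                "transition structure is not irreducible: some state cannot "
                "reach some other state",
                stacklevel=3,
            )

    def _strongly_connected(self) -> bool:
        def reach(start: int, edges: set[tuple[int, int]]) -> set[int]:
            seen = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for a, b in edges:
                    if a == u and b not in seen:
                        seen.add(b)
                        stack.append(b)
            return seen

        edges = set(self.allowed)
        nodes = set(range(1, N_STATES + 1))
        return all(reach(s, edges) == nodes for s in nodes)

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        """Allowed pairs in canonical (sorted) order."""
        return tuple(sorted(self.allowed))

    @property
    def n_transitions(self) -> int:
        return len(self.allowed)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return tuple(pair) in self.allowed

    def index(self, u: int, v: int) -> int:
        """Position of pair (u, v) in canonical order."""
        try:
            return self.pairs.index((u, v))
        except ValueError:
            raise StructureError(f"({u},{v}) is not an allowed transition") from None

    def to_dict(self) -> dict:
        return {"allowed": [f"{u}-{v}" for u, v in self.pairs]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransitionStructure":
        pairs = set()
        for s in d["allowed"]:
            u, v = s.split("-")
            pairs.add((int(u), int(v)))
        return cls(frozenset(pairs))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "TransitionStructure":
        return cls(frozenset(tuple(p) for p in pairs))


def make_adjacent_structure() -> TransitionStructure:
    """The fitted adjacent-only structure: {1<->2, 2<->3, 3<->4}.

    Direct jumps over more than one severity level (e.g. Normal to
    Moderately stunted) carry no instantaneous rate; panel observations
    may still show such moves because several latent jumps can occur
    between visits.
    """
    pairs = {(u, u + 1) for u in range(1, N_STATES)} | {(u + 1, u) for u in range(1, N_STATES)}
    return TransitionStructure(frozenset(pairs))


@dataclass(frozen=True)
class IntensityMatrix:
    """A validated 4x4 generator matrix Q (events per month).

    Off-diagonal entries are non-negative transition intensities; each
    diagonal is the negated sum of its off-diagonal row, so rows sum to
    zero.  If ``structure`` is given, entries outside it must be zero.
    """

    q: np.ndarray
    structure: TransitionStructure | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        if q.shape != (N_STATES, N_STATES):
            raise ValueError(f"Q must be {N_STATES}x{N_STATES}, got {q.shape}")
        off = q[~np.eye(N_STATES, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal intensities must be non-negative")
        if np.max(np.abs(q.sum(axis=1))) > 1e-9:
            raise ValueError("rows of an intensity matrix must sum to zero")
        if self.structure is not None:
            for u in range(1, N_STATES + 1):
                for v in range(1, N_STATES + 1):
                    if u != v and (u, v) not in self.structure and q[u - 1, v - 1] != 0.0:
                        raise ValueError(
                            f"entry ({u},{v}) outside the allowed structure is nonzero"
                        )

    @classmethod
    def from_rates(
        cls, rates: Mapping[tuple[int, int], float], structure: TransitionStructure | None = None
    ) -> "IntensityMatrix":
        """Build Q from a mapping of 1-based (u, v) pairs to rates."""
        q = np.zeros((N_STATES, N_STATES))
        for (u, v), r in rates.items():
            q[u - 1, v - 1] = r
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return cls(q, structure)

    def rate(self, u: int, v: int) -> float:
        """Intensity for the 1-based pair (u, v)."""
        return float(self.q[u - 1, v - 1])

    def exit_rate(self, u: int) -> float:
        """Total exit intensity -q_uu of 1-based state u."""
        return float(-self.q[u - 1, u - 1])


@dataclass(frozen=True)
class CategoricalVariable:
    """A categorical covariate with an ordered level list and a reference."""

    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"{self.name}: duplicate levels")
        if self.reference not in self.levels:
            raise ValueError(f"{self.name}: reference {self.reference!r} not among levels")

    @property
    def dummy_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)


@dataclass(frozen=True)
class CovariateDesign:
    """An ordered set of categorical variables expanded to dummy terms.

    Each variable contributes one indicator per non-reference level, in
    level order; the full dummy vector concatenates variables in order.
    """

    variables: tuple[CategoricalVariable, ...]

    @property
    def dummies(self) -> tuple[tuple[str, str], ...]:
        """Ordered (variable, level) labels, one per indicator term."""
        return tuple((v.name, l) for v in self.variables for l in v.dummy_levels)

    @property
    def n_dummies(self) -> int:
        return sum(len(v.levels) - 1 for v in self.variables)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def variable(self, name: str) -> CategoricalVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def vector(self, covariates: Mapping[str, str]) -> np.ndarray:
        """Dummy-encode one observation's covariate levels."""
        x = np.zeros(self.n_dummies)
        pos = 0
        for var in self.variables:
            level = covariates[var.name]
            if level not in var.levels:
                raise ValueError(f"unknown level {level!r} for variable {var.name!r}")
            for l in var.dummy_levels:
                if level == l:
                    x[pos] = 1.0
                pos += 1
        return x

    def to_dict(self) -> dict:
        return {
            "variables": [
                {"name": v.name, "levels": list(v.levels), "reference": v.reference}
                for v in self.variables
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateDesign":
        return cls(
            tuple(
                CategoricalVariable(v["name"], tuple(v["levels"]), v["reference"])
                for v in d["variables"]
            )
        )


def default_study_design() -> CovariateDesign:
    """The study's 11-variable covariate design (19 dummy terms).

    Reference levels follow the reported hazard-ratio tables.  The
    ``child_age`` variable is time-varying: its band is re-derived from
    the child's age at each visit rather than sampled once.
    """
    return CovariateDesign(
        (
            CategoricalVariable("slum", ("Korogocho", "Viwandani"), "Korogocho"),
            CategoricalVariable("sex", ("Female", "Male"), "Female"),
            CategoricalVariable(
                "ethnicity", ("Kikuyu", "Luhya", "Luo", "Kamba", "Other"), "Kikuyu"
            ),
            CategoricalVariable("child_age", ("0-5", "6-11", "12-23", "24-36"), "0-5"),
            CategoricalVariable("food_security", ("Secure", "Moderate", "Severe"), "Secure"),
            CategoricalVariable("marital_status", ("Never Married", "Ever Married"), "Never Married"),
            CategoricalVariable(
                "mother_education", ("Less than Primary", "Primary", "Post Primary"), "Less than Primary"
            ),
            CategoricalVariable("sanitation", ("No", "Yes"), "No"),
            CategoricalVariable("breastfeeding", ("No", "Yes"), "No"),
            CategoricalVariable("safe_water", ("No", "Yes"), "No"),
            CategoricalVariable("wealth", ("lowest", "middle", "highest"), "lowest"),
        )
    )


@dataclass(frozen=True)
class ModelParameters:
    """Baseline log-intensities and covariate coefficients.

    ``baseline_log_intensity[i]`` is log(q_uv at the reference profile)
    for the i-th pair in the structure's canonical order;
    ``coefficients[i]`` is that transition's coefficient vector over the
    design's dummy terms (shape ``(n_transitions, n_dummies)``; the
    second dimension is 0 for a covariate-free model).
    """

    baseline_log_intensity: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        b = np.atleast_1d(np.asarray(self.baseline_log_intensity, dtype=float))
        c = np.asarray(self.coefficients, dtype=float)
        if c.ndim != 2 or c.shape[0] != b.shape[0]:
            raise ValueError(
                "coefficients must be (n_transitions, n_dummies) with one row per baseline"
            )
        object.__setattr__(self, "baseline_log_intensity", b)
        object.__setattr__(self, "coefficients", c)

    @property
    def n_transitions(self) -> int:
        return self.baseline_log_intensity.shape[0]

    @property
    def n_dummies(self) -> int:
        return self.coefficients.shape[1]

    @classmethod
    def from_baselines(
        cls, baseline_intensities: Sequence[float], n_dummies: int = 0
    ) -> "ModelParameters":
        """Parameters from natural-scale baseline rates, zero coefficients."""
        b = np.log(np.asarray(baseline_intensities, dtype=float))
        return cls(b, np.zeros((len(b), n_dummies)))


def parameter_count(structure: TransitionStructure, design: CovariateDesign | None = None) -> int:
    """Number of free parameters: |allowed| x (1 + number of dummy terms).

    The six-transition adjacent structure gives 6 without covariates and
    120 with the full 19-dummy design.
    """
    if structure.n_transitions == 0:
        raise ValueError("structure has no allowed transitions")
    per = 1 if design is None else 1 + design.n_dummies
    return structure.n_transitions * per


def assemble_intensity(params: ModelParameters, structure: TransitionStructure) -> IntensityMatrix:
    """Build the reference-profile intensity matrix from parameters.

    Allowed off-diagonal entries are ``exp(baseline_log_intensity)``;
    disallowed entries are zero; diagonals are negated row sums.
    """
    if params.n_transitions != structure.n_transitions:
        raise StructureError(
            f"parameters cover {params.n_transitions} transitions, "
            f"structure has {structure.n_transitions}"
        )
    q = np.zeros((N_STATES, N_STATES))
    for i, (u, v) in enumerate(structure.pairs):
        q[u - 1, v - 1] = np.exp(params.baseline_log_intensity[i])
    np.fill_diagonal(q, -q.sum(axis=1))
    return IntensityMatrix(q, structure)


def save_config(
    path: str | Path,
    structure: TransitionStructure,
    design: CovariateDesign | None = None,
    state_labels: Sequence[str] = STATE_LABELS,
) -> None:
    """Write structure/design to a YAML (or .json) config file."""
    doc = {"states": list(state_labels), "structure": structure.to_dict()}
    if design is not None:
        doc["design"] = design.to_dict()
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> tuple[TransitionStructure, CovariateDesign | None]:
    """Read a config written by :func:`save_config`."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    structure = TransitionStructure.from_dict(doc["structure"])
    design = CovariateDesign.from_dict(doc["design"]) if "design" in doc else None
    return structure, design
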