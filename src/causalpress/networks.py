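"""Exact representation and inference for three-variable binary causal networks.

The experimental task teaches participants one of three causal structures over
binary variables ``X1``, ``Y``, ``X2`` (``Y`` is the middle/shared variable):

* **chain**: ``X1 -> Y -> X2``
* **common cause**: ``X1 <- Y -> X2``
* **common effect**: ``X1 -> Y <- X2``

Variables take value 1 ("non-normal" state present) or 0 (absent).  A network
is parametrized either by the case counts shown to participants during
learning (eight non-negative integers over the joint states) or by explicit
conditional probability distributions; for the common-effect structure the two
causes combine through a Noisy-OR gate,

    P(Y=1 | x1, x2) = 1 - (1 - leak) * (1 - s1)**x1 * (1 - s2)**x2.

The normative (correct) answer to every probability query follows from the
joint distribution by exact enumeration over its eight states.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Structure",
    "VARIABLES",
    "STATE_LABELS",
    "Query",
    "JointTable",
    "ChainParams",
    "CommonCauseParams",
    "CommonEffectParams",
    "NetworkSpec",
    "InvalidParametrizationError",
    "UndefinedConditionalError",
    "noisy_or",
    "joint_from_cases",
    "joint_from_cpds",
    "conditional",
    "enumerate_queries",
    "normative_table",
    "normative_frame",
    "TABLE_CHAIN_COUNTS",
    "TABLE_COMMON_EFFECT_COUNTS",
    "table_spec",
]

VARIABLES = ("X1", "Y", "X2")

#: CSV/display labels for conditioning states; ``None`` encodes "unknown".
STATE_LABELS: Mapping[Optional[int], str] = {0: "absent", None: "unknown", 1: "present"}
STATE_FROM_LABEL = {v: k for k, v in STATE_LABELS.items()}

#: Case counts shown during learning, keyed by joint state (x1, y, x2).
#: The chain and common-cause structures share one parametrization.
TABLE_CHAIN_COUNTS: Mapping[tuple, int] = {
    (1, 1, 1): 9, (1, 1, 0): 3, (1, 0, 1): 1, (1, 0, 0): 3,
    (0, 1, 1): 3, (0, 1, 0): 1, (0, 0, 1): 3, (0, 0, 0): 9,
}
TABLE_COMMON_EFFECT_COUNTS: Mapping[tuple, int] = {
    (1, 1, 1): 6, (1, 1, 0): 4, (1, 0, 1): 2, (1, 0, 0): 4,
    (0, 1, 1): 4, (0, 1, 0): 0, (0, 0, 1): 4, (0, 0, 0): 8,
}


class Structure(str, enum.Enum):
    CHAIN = "chain"
    COMMON_CAUSE = "common_cause"
    COMMON_EFFECT = "common_effect"

    @property
    def family(self) -> str:
        """Analysis family: chain and common cause share a joint ('cc')."""
        return "ce" if self is Structure.COMMON_EFFECT else "cc"


class InvalidParametrizationError(ValueError):
    """Raised when case counts or CPD parameters are invalid."""


class UndefinedConditionalError(ValueError):
    """Raised when a conditional is requested on a zero-probability event."""


@dataclass(frozen=True)
class Query:
    """One probability query: P(queried = 1 | states of the two others).

    ``given`` maps each non-queried variable name to 0 (absent), 1 (present)
    or ``None`` (unknown; marginalized out).
    """

    queried: str
    given: tuple  # ((var, state), (var, state)) in canonical variable order

    def __post_init__(self):
        if self.queried not in VARIABLES:
            raise ValueError(f"unknown variable {self.queried!r}")
        others = tuple(v for v in VARIABLES if v != self.queried)
        names = tuple(v for v, _ in self.given)
        if names != others:
            raise ValueError(
                f"conditioning slots must be {others} in order, got {names}"
            )
        for _, s in self.given:
            if s not in (0, 1, None):
                raise ValueError(f"state must be 0, 1 or None, got {s!r}")

    @staticmethod
    def make(queried: str, **states: Optional[int]) -> "Query":
        """Build a query from keyword states, e.g. ``Query.make('X1', Y=1, X2=None)``."""
        others = tuple(v for v in VARIABLES if v != queried)
        return Query(queried, tuple((v, states.get(v)) for v in others))

    @property
    def given_map(self) -> dict:
        return dict(self.given)

    def label(self) -> str:
        conds = ", ".join(
            f"{v}={'?' if s is None else s}" for v, s in self.given
        )
        return f"P({self.queried}=1 | {conds})"

    def item_id(self, family: str) -> str:
        """Stable identifier for the inference item (random-effect grouping)."""
        states = "".join("u" if s is None else str(s) for _, s in self.given)
        return f"{family}:{self.queried}:{states}"


@dataclass(frozen=True)
class JointTable:
    """Exact joint distribution over the eight (x1, y, x2) states."""

    probs: np.ndarray = field(repr=False)  # shape (2, 2, 2), indexed [x1, y, x2]

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (2, 2, 2):
            raise InvalidParametrizationError("joint table must have shape (2,2,2)")
        if (p < -1e-15).any():
            raise InvalidParametrizationError("joint probabilities must be >= 0")
        if abs(p.sum() - 1.0) > 1e-12:
            raise InvalidParametrizationError("joint probabilities must sum to 1")
        object.__setattr__(self, "probs", p)

    def prob(self, x1: int, y: int, x2: int) -> float:
        return float(self.probs[x1, y, x2])

    def marginal(self, var: str) -> float:
        """P(var = 1)."""
        axis = VARIABLES.index(var)
        return float(np.take(self.probs, 1, axis=axis).sum())

    def as_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(
            list(itertools.product((0, 1), repeat=3)), names=["x1", "y", "x2"]
        )
        return pd.Series([self.probs[s] for s in idx], index=idx, name="prob")


def noisy_or(s1: float, s2: float, leak: float, x1: int, x2: int) -> float:
    """Noisy-OR gate: probability of the effect given cause states.

    Independent generative causes with strengths ``s1``, ``s2`` and a leak
    (background) probability: P(Y=1|x1,x2) = 1 - (1-leak)(1-s1)^x1 (1-s2)^x2.
    """
    for name, v in (("s1", s1), ("s2", s2), ("leak", leak)):
        if not 0.0 <= v <= 1.0:
            raise InvalidParametrizationError(f"{name} must be in [0,1], got {v}")
    return 1.0 - (1.0 - leak) * (1.0 - s1) ** x1 * (1.0 - s2) ** x2


@dataclass(frozen=True)
class ChainParams:
    """X1 -> Y -> X2 with link CPDs shared by both edges."""

    base_x1: float = 0.5
    link_present: float = 0.75  # P(child=1 | parent=1)
    link_absent: float = 0.25   # P(child=1 | parent=0)


@dataclass(frozen=True)
class CommonCauseParams:
    """X1 <- Y -> X2."""

    base_y: float = 0.5
    link_present: float = 0.75
    link_absent: float = 0.25


@dataclass(frozen=True)
class CommonEffectParams:
    """X1 -> Y <- X2 with a Noisy-OR gate on Y."""

    base_x1: float = 0.5
    base_x2: float = 0.5
    strength_x1: float = 0.5
    strength_x2: float = 0.5
    leak: float = 0.0


CPDParams = Union[ChainParams, CommonCauseParams, CommonEffectParams]


@dataclass(frozen=True)
class NetworkSpec:
    """A structure plus one parametrization (case counts or CPD parameters)."""

    structure: Structure
    case_counts: Optional[Mapping[tuple, int]] = None
    cpd_params: Optional[CPDParams] = None

    def joint(self) -> JointTable:
        if (self.case_counts is None) == (self.cpd_params is None):
            raise InvalidParametrizationError(
                "exactly one of case_counts / cpd_params must be given"
            )
        if self.case_counts is not None:
            return joint_from_cases(self.case_counts)
        return joint_from_cpds(self.structure, self.cpd_params)


def table_spec(structure: Union[Structure, str]) -> NetworkSpec:
    """The built-in learning-phase parametrization for a structure."""
    structure = Structure(structure)
    counts = (
        TABLE_COMMON_EFFECT_COUNTS
        if structure is Structure.COMMON_EFFECT
        else TABLE_CHAIN_COUNTS
    )
    return NetworkSpec(structure, case_counts=counts)


def joint_from_cases(counts: Mapping[tuple, Union[int, float]]) -> JointTable:
    """Joint distribution from learning-sample case counts (count/total)."""
    arr = np.zeros((2, 2, 2))
    for state in itertools.product((0, 1), repeat=3):
        c = counts.get(state, 0)
        if c < 0:
            raise InvalidParametrizationError("case counts must be non-negative")
        arr[state] = c
    total = arr.sum()
    if total <= 0:
        raise InvalidParametrizationError("case counts must sum to a positive total")
    return JointTable(arr / total)


def _check_unit(name: str, v: float) -> float:
    if not 0.0 <= v <= 1.0:
        raise InvalidParametrizationError(f"{name} must be in [0,1], got {v}")
    return v


def joint_from_cpds(structure: Union[Structure, str], params: CPDParams) -> JointTable:
    """Joint distribution as the factorized product of the structure's CPDs."""
    structure = Structure(structure)
    arr = np.zeros((2, 2, 2))

    def bern(p: float, v: int) -> float:
        return p if v == 1 else 1.0 - p

    if structure is Structure.CHAIN:
        if not isinstance(params, ChainParams):
            raise InvalidParametrizationError("chain structure requires ChainParams")
        b = _check_unit("base_x1", params.base_x1)
        lp = _check_unit("link_present", params.link_present)
        la = _check_unit("link_absent", params.link_absent)
        for x1, y, x2 in itertools.product((0, 1), repeat=3):
            p_y = lp if x1 == 1 else la
            p_x2 = lp if y == 1 else la
            arr[x1, y, x2] = bern(b, x1) * bern(p_y, y) * bern(p_x2, x2)
    elif structure is Structure.COMMON_CAUSE:
        if not isinstance(params, CommonCauseParams):
            raise InvalidParametrizationError(
                "common-cause structure requires CommonCauseParams"
            )
        b = _check_unit("base_y", params.base_y)
        lp = _check_unit("link_present", params.link_present)
        la = _check_unit("link_absent", params.link_absent)
        for x1, y, x2 in itertools.product((0, 1), repeat=3):
            p_x = lp if y == 1 else la
            arr[x1, y, x2] = bern(b, y) * bern(p_x, x1) * bern(p_x, x2)
    else:
        if not isinstance(params, CommonEffectParams):
            raise InvalidParametrizationError(
                "common-effect structure requires CommonEffectParams"
            )
        b1 = _check_unit("base_x1", params.base_x1)
        b2 = _check_unit("base_x2", params.base_x2)
        for x1, y, x2 in itertools.product((0, 1), repeat=3):
            p_y = noisy_or(params.strength_x1, params.strength_x2, params.leak, x1, x2)
            arr[x1, y, x2] = bern(b1, x1) * bern(b2, x2) * bern(p_y, y)
    return JointTable(arr)


def conditional(joint: JointTable, query: Query) -> float:
    """Exact P(queried = 1 | stated conditions), marginalizing unknowns."""
    q_axis = VARIABLES.index(query.queried)
    num = 0.0
    den = 0.0
    for state in itertools.product((0, 1), repeat=3):
        ok = True
        for var, s in query.given:
            if s is not None and state[VARIABLES.index(var)] != s:
                ok = False
                break
        if not ok:
            continue
        p = joint.probs[state]
        den += p
        if state[q_axis] == 1:
            num += p
    if den <= 0.0:
        raise UndefinedConditionalError(
            f"conditioning event of {query.label()} has probability zero"
        )
    return num / den


def enumerate_queries() -> list:
    """All 27 queries in canonical order.

    Queried variable cycles through (X1, Y, X2); the two conditioning slots
    (in variable order) each cycle through (absent, unknown, present).
    """
    out = []
    for queried in VARIABLES:
        others = tuple(v for v in VARIABLES if v != queried)
        for s1, s2 in itertools.product((0, None, 1), repeat=2):
            out.append(Query(queried, ((others[0], s1), (others[1], s2))))
    return out


def normative_table(spec: NetworkSpec) -> dict:
    """Map from each of the 27 queries to its exact normative probability."""
    joint = spec.joint()
    return {q: conditional(joint, q) for q in enumerate_queries()}


def normative_frame(
    structures: Sequence[Union[Structure, str]] = tuple(Structure),
) -> pd.DataFrame:
    """Normative tables as a tidy frame (one row per structure x query)."""
    rows = []
    for s in structures:
        s = Structure(s)
        for q, p in normative_table(table_spec(s)).items():
            (v1, s1), (v2, s2) = q.given
            rows.append(
                {
                    "structure": s.value,
                    "queried": q.queried,
                    "state_other1": STATE_LABELS[s1],
                    "state_other2": STATE_LABELS[s2],
                    "normative_prob": round(p, 6),
                }
            )
    return pd.DataFrame(rows)
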