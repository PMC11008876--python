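"""Synthetic participants for the time-pressure causal judgment task.

The generator is a *descriptive emulator*, not a process theory: the minimal
shrinkage-plus-bias response model that reproduces the qualitative behavioral
structure reported for this task —

* probability responses on a 0-100 scale, rounded to integer percent;
* conservative shrinkage toward 50 that grows with external time pressure
  (shorter deadlines) and internal time pressure (elapsed fraction of the
  deadline before responding);
* a Markov-violation bias: the state of the screened-off variable shifts
  responses additively, by default identically across deadlines;
* attenuated explaining away on common-effect trials with the effect present;
* confidence negatively related to realized shrinkage and noise;
* a non-compliant (constant-50 or uniform-random) subpopulation to exercise
  the exclusion rules.

Response times are drawn first, from a deadline-specific truncated lognormal,
so that elapsed-time shrinkage can depend on them; deadline misses occur with
a small configurable probability.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .design import DEADLINES_S, build_participant_design, assign_counterbalance
from .networks import (
    Query,
    Structure,
    conditional,
    normative_table,
    table_spec,
)

__all__ = [
    "RTModel",
    "ConfidenceModel",
    "ResponseModelParams",
    "SimulatedResponse",
    "trial_roles",
    "simulate_trial",
    "simulate_cohort",
    "make_noncompliant",
]


@dataclass(frozen=True)
class RTModel:
    """Truncated-lognormal response-time model per deadline (seconds)."""

    meanlog: Mapping[int, float] = field(
        default_factory=lambda: {6: np.log(3.2), 9: np.log(4.2), 20: np.log(6.5)}
    )
    sdlog: float = 0.35
    miss_prob: float = 0.002

    def draw(self, deadline_s: int, rng: np.random.Generator) -> float:
        mu = self.meanlog[int(deadline_s)]
        for _ in range(1000):
            rt = float(np.exp(rng.normal(mu, self.sdlog)))
            if rt < deadline_s:
                return rt
        return 0.99 * deadline_s


@dataclass(frozen=True)
class ConfidenceModel:
    """Confidence report model: high baseline, lowered by shrinkage and noise."""

    intercept: float = 85.0
    shrink_loading: float = -90.0   # per unit of realized shrinkage weight
    noise_loading: float = -0.6     # per percentage point of |noise draw|
    obs_sd: float = 8.0


@dataclass(frozen=True)
class ResponseModelParams:
    """Generative parameters of one synthetic participant.

    The realized shrinkage weight on a trial is
    ``lam = clip(shrink_base + shrink_deadline_gain[dl] + shrink_time_gain * t_frac, 0, 1)``
    with ``t_frac = rt_s / deadline_s``, and the response is
    ``clip(round((1 - lam) * m + lam * 50 + noise), 0, 100)`` where ``m`` is
    100 times the (bias-adjusted) normative probability.
    """

    noise_sd: float = 10.0                # response noise, percentage points
    shrink_base: float = 0.05             # baseline pull toward 50
    shrink_deadline_gain: Mapping[int, float] = field(
        default_factory=lambda: {6: 0.12, 9: 0.06, 20: 0.0}
    )
    shrink_time_gain: float = 0.35        # extra pull per unit elapsed fraction
    markov_bias: float = 8.0              # pp shift per screened-off state
    away_attenuation: float = 0.15        # 0 = no explaining away, 1 = normative
    rt_model: RTModel = field(default_factory=RTModel)
    confidence_model: ConfidenceModel = field(default_factory=ConfidenceModel)
    compliant: bool = True
    noncompliant_mode: str = "constant50"  # or "uniform"

    def __post_init__(self):
        if not 0.0 <= self.away_attenuation <= 1.0:
            raise ValueError("away_attenuation must be in [0,1]")
        if not 0.0 <= self.shrink_base <= 1.0:
            raise ValueError("shrink_base must be in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimulatedResponse:
    response: Optional[int]   # integer percent, None when missed
    rt_s: float
    confidence: Optional[int]
    missed: bool


@functools.lru_cache(maxsize=8)
def _oracle(structure: str) -> dict:
    return normative_table(table_spec(structure))


def trial_roles(structure: str, query: Query) -> dict:
    """Classify a trial for the bias terms.

    Returns ``{"markov_state": s or None, "away_state": s or None,
    "away_baseline": p or None}`` where ``s`` is the -1/0/+1 state of the
    relevant third variable.  Chain/common-cause trials are Markov-relevant
    when a terminal variable is queried with the middle variable known;
    common-effect trials when the effect is unknown.  Explaining-away trials
    are common-effect queries of a cause with the effect present; their
    baseline is the normative answer with the other cause unknown.
    """
    fam = Structure(structure).family
    out = {"markov_state": None, "away_state": None, "away_baseline": None}
    if query.queried == "Y":
        return out
    given = query.given_map
    y = given["Y"]
    other = next(s for v, s in query.given if v != "Y")
    code = 0 if other is None else (1 if other == 1 else -1)
    if fam == "cc":
        if y is not None:
            out["markov_state"] = code
    else:
        if y is None:
            out["markov_state"] = code
        elif y == 1:
            out["away_state"] = code
            other_var = next(v for v, _ in query.given if v != "Y")
            base_q = Query.make(query.queried, Y=1, **{other_var: None})
            out["away_baseline"] = _oracle(Structure(structure).value)[base_q]
    return out


def simulate_trial(
    trial,
    normative: float,
    params: ResponseModelParams,
    rng: np.random.Generator,
) -> SimulatedResponse:
    """Simulate one trial.

    ``trial`` is a mapping with at least ``structure``, ``deadline_s``,
    ``queried``, ``state_other1``, ``state_other2`` (a design-table row).
    ``normative`` is the exact answer from the network oracle.
    """
    from .design import query_from_row

    deadline = int(trial["deadline_s"])
    rt = params.rt_model.draw(deadline, rng)
    if rng.random() < params.rt_model.miss_prob:
        return SimulatedResponse(None, float(deadline), None, True)

    cm = params.confidence_model
    if not params.compliant:
        if params.noncompliant_mode == "constant50":
            resp = 50
        elif params.noncompliant_mode == "uniform":
            resp = int(rng.integers(0, 101))
        else:
            raise ValueError(f"unknown noncompliant_mode {params.noncompliant_mode!r}")
        conf = int(np.clip(round(rng.uniform(0, 100)), 0, 100))
        return SimulatedResponse(resp, rt, conf, False)

    query = query_from_row(trial)
    roles = trial_roles(trial["structure"], query)

    m_prob = float(normative)
    if roles["away_state"] is not None:
        base = roles["away_baseline"]
        m_prob = base + params.away_attenuation * (m_prob - base)
    elif roles["markov_state"] is not None:
        m_prob = m_prob + params.markov_bias * roles["markov_state"] / 100.0
    m = 100.0 * float(np.clip(m_prob, 0.0, 1.0))

    t_frac = rt / deadline
    lam = float(
        np.clip(
            params.shrink_base
            + params.shrink_deadline_gain[deadline]
            + params.shrink_time_gain * t_frac,
            0.0,
            1.0,
        )
    )
    eps = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
    resp = int(np.clip(round((1.0 - lam) * m + lam * 50.0 + eps), 0, 100))
    conf = int(
        np.clip(
            round(
                cm.intercept
                + cm.shrink_loading * lam
                + cm.noise_loading * abs(eps)
                + (rng.normal(0.0, cm.obs_sd) if cm.obs_sd > 0 else 0.0)
            ),
            0,
            100,
        )
    )
    return SimulatedResponse(resp, rt, conf, False)


def _trial_rng(master_seed: int, pid: int, trial_index: int) -> np.random.Generator:
    # Substream keyed by (participant, trial): cohorts are extensible without
    # reshuffling earlier participants.
    return np.random.default_rng(
        np.random.SeedSequence((int(master_seed) % (2**32), int(pid), int(trial_index)))
    )


def simulate_cohort(
    n_participants: int,
    params: Optional[ResponseModelParams] = None,
    master_seed: int = 0,
    experiment: str = "exp1",
    participant_sampler: Optional[
        Callable[[int, np.random.Generator], ResponseModelParams]
    ] = None,
    scheme_seed: Optional[int] = None,
    participant_ids: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Simulate a full cohort; reproducible given ``master_seed``.

    Either fixed ``params`` for everyone or a ``participant_sampler`` drawing
    per-participant parameters from its own substream.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if params is None and participant_sampler is None:
        params = ResponseModelParams()
    scheme_seed = master_seed if scheme_seed is None else scheme_seed
    ids = (
        list(participant_ids)
        if participant_ids is not None
        else list(range(n_participants))
    )
    oracles = {s.value: _oracle(s.value) for s in Structure}

    frames = []
    for pid in ids:
        assignment = assign_counterbalance(pid, scheme_seed)
        design = build_participant_design(assignment, shuffle_seed=master_seed, experiment=experiment)
        p = params
        if participant_sampler is not None:
            p = participant_sampler(pid, _trial_rng(master_seed, pid, 10**6))
        responses, rts, confs, missed = [], [], [], []
        from .design import query_from_row

        for _, row in design.iterrows():
            q = query_from_row(row)
            normative = oracles[row["structure"]][q]
            sim = simulate_trial(
                row, normative, p, _trial_rng(master_seed, pid, int(row["trial_index"]))
            )
            responses.append(sim.response)
            rts.append(sim.rt_s)
            confs.append(sim.confidence)
            missed.append(sim.missed)
        design = design.copy()
        design["response"] = pd.array(responses, dtype="Int64")
        design["rt_s"] = np.round(rts, 6)
        design["confidence"] = pd.array(confs, dtype="Int64")
        design["missed"] = missed
        frames.append(design)
    return pd.concat(frames, ignore_index=True)


def make_noncompliant(
    params: Optional[ResponseModelParams] = None, mode: str = "constant50"
) -> ResponseModelParams:
    """A non-compliant responder configuration (random or constant-50)."""
    if mode not in ("constant50", "uniform"):
        raise ValueError("mode must be 'constant50' or 'uniform'")
    base = params if params is not None else ResponseModelParams()
    return replace(base, compliant=False, noncompliant_mode=mode)
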