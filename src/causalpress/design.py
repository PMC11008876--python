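"""Per-participant trial design of the time-pressure causal judgment task.

Each participant works through three cover-story domains; each domain is
paired with one causal structure (a bijection counterbalanced across
participants) and split into three blocks with response deadlines of 6, 9 and
20 seconds.  Every block asks all 27 possible queries once, giving
27 x 3 x 3 = 243 trials per participant.

The counterbalancing scheme is a balanced Latin-square cycling: the
structure-to-domain bijection cycles with period 3 and the deadline base order
cycles through all six permutations, so every bijection and every deadline
order appears equally often in any 18 consecutive participant ids.  Within a
participant, the deadline order of each domain is the participant's base order
rotated by the domain index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .networks import STATE_LABELS, Query, Structure, enumerate_queries

__all__ = [
    "DOMAINS",
    "DEADLINES_S",
    "CounterbalanceAssignment",
    "assign_counterbalance",
    "build_participant_design",
    "build_cohort_design",
    "query_from_row",
    "DESIGN_COLUMNS",
]

DOMAINS = ("meteorology", "sociology", "economics")
DEADLINES_S = (6, 9, 20)

_STRUCTURES = tuple(Structure)
_DEADLINE_ORDERS = tuple(itertools.permutations(DEADLINES_S))  # 6 base orders

DESIGN_COLUMNS = [
    "participant_id",
    "experiment",
    "domain",
    "structure",
    "deadline_s",
    "block_index",
    "trial_index",
    "queried",
    "state_other1",
    "state_other2",
]


@dataclass(frozen=True)
class CounterbalanceAssignment:
    participant_id: int
    structure_by_domain: Tuple[Tuple[str, Structure], ...]  # bijection
    deadline_order_by_domain: Tuple[Tuple[int, ...], ...]   # one order per domain
    nonnormal_is_high: Tuple[bool, ...]  # label flag per domain (pure labeling)

    @property
    def mapping(self) -> dict:
        return dict(self.structure_by_domain)


def assign_counterbalance(
    participant_id: int, scheme_seed: int = 0
) -> CounterbalanceAssignment:
    """Deterministic counterbalance slot for one participant.

    The 18 scheme slots (3 structure-domain bijections x 6 deadline orders)
    are cycled by ``(participant_id + scheme_seed) % 18``.
    """
    idx = (int(participant_id) + int(scheme_seed)) % 18
    shift = idx % 3
    base_order = _DEADLINE_ORDERS[idx // 3]
    mapping = tuple(
        (DOMAINS[d], _STRUCTURES[(d + shift) % 3]) for d in range(3)
    )
    orders = tuple(
        tuple(base_order[(j + d) % 3] for j in range(3)) for d in range(3)
    )
    # Label assignment is pure labeling (value 1 always means "non-normal
    # present"); the flags are carried only so exports can record them.
    flag_bits = (participant_id + scheme_seed) // 18
    flags = tuple(bool((flag_bits >> d) & 1) for d in range(3))
    return CounterbalanceAssignment(int(participant_id), mapping, orders, flags)


def build_participant_design(
    assignment: CounterbalanceAssignment,
    shuffle_seed: int = 0,
    experiment: str = "exp1",
) -> pd.DataFrame:
    """The full 243-trial design for one participant.

    Query order within each (domain, deadline) block is shuffled by
    ``shuffle_seed``; the multiset of trials is seed-independent.
    """
    queries = enumerate_queries()
    rows = []
    trial_index = 0
    block_index = 0
    for d, domain in enumerate(DOMAINS):
        structure = assignment.mapping[domain]
        for deadline in assignment.deadline_order_by_domain[d]:
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    (int(shuffle_seed) % (2**32), assignment.participant_id % (2**32), d, deadline)
                )
            )
            order = rng.permutation(len(queries))
            for k in order:
                q = queries[k]
                (v1, s1), (v2, s2) = q.given
                rows.append(
                    {
                        "participant_id": assignment.participant_id,
                        "experiment": experiment,
                        "domain": domain,
                        "structure": structure.value,
                        "deadline_s": deadline,
                        "block_index": block_index,
                        "trial_index": trial_index,
                        "queried": q.queried,
                        "state_other1": STATE_LABELS[s1],
                        "state_other2": STATE_LABELS[s2],
                    }
                )
                trial_index += 1
            block_index += 1
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def build_cohort_design(
    n_participants: int,
    scheme_seed: int = 0,
    shuffle_seed: int = 0,
    experiment: str = "exp1",
    participant_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Stacked designs for a cohort of participants (ids 0..n-1 by default)."""
    ids = list(participant_ids) if participant_ids is not None else list(range(n_participants))
    frames = [
        build_participant_design(
            assign_counterbalance(pid, scheme_seed), shuffle_seed, experiment
        )
        for pid in ids
    ]
    return pd.concat(frames, ignore_index=True)


def query_from_row(row) -> Query:
    """Reconstruct the Query object from a design/trial table row."""
    from .networks import STATE_FROM_LABEL, VARIABLES

    queried = row["queried"]
    others = tuple(v for v in VARIABLES if v != queried)
    s1 = STATE_FROM_LABEL[row["state_other1"]]
    s2 = STATE_FROM_LABEL[row["state_other2"]]
    return Query(queried, ((others[0], s1), (others[1], s2)))
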