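"""Derived measures, trial codings, and exclusion rules on a trial table.

The shared trial-table schema is the design table plus ``response`` (0-100,
integer percent), ``rt_s``, optional ``confidence``, and ``missed``.  This
module adds:

* ``normative`` (exact oracle answer), ``error_pp`` (absolute response error
  in percentage points) and ``error_offset`` (error + 0.01, strictly positive
  for Gamma-log modelling);
* the exclusion rules: missed-deadline trials, responses faster than 1.5 s,
  and participants whose overall mean error exceeds 18 percentage points (the
  threshold at which a constant-50 responder sits, given the design's mean
  distance of the normative answers from 50);
* within-participant z-scores of RT (and confidence);
* the Markov-violation coding (``screened_off`` in {-1,0,+1}, ``mid_var`` in
  {0,1}), the explaining-away coding (``away_var``, ``recoded_response`` with
  the -28.6/+11.4 shifts that make the normative pattern flat at 71.4), and
  the signed conservatism measure (movement from the normative answer toward
  50, positive = conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .design import query_from_row
from .networks import Structure, normative_table, table_spec

__all__ = [
    "ExclusionReport",
    "annotate_normative_and_error",
    "apply_exclusions",
    "zscore_rt",
    "zscore_confidence",
    "code_markov",
    "code_explaining_away",
    "conservatism",
    "spike_rate_50",
    "AWAY_SHIFT_ABSENT",
    "AWAY_SHIFT_PRESENT",
]

#: Recoding shifts that flatten the normative explaining-away pattern
#: (1 - 0.286 = 0.714 and 0.6 + 0.114 = 0.714), in percentage points.
AWAY_SHIFT_ABSENT = -28.6
AWAY_SHIFT_PRESENT = 11.4

_STATE_CODE = {"absent": -1, "unknown": 0, "present": 1}


def _default_oracles() -> Mapping[str, dict]:
    return {s.value: normative_table(table_spec(s)) for s in Structure}


def annotate_normative_and_error(
    table: pd.DataFrame, oracles: Optional[Mapping[str, dict]] = None
) -> pd.DataFrame:
    """Add ``normative``, ``error_pp``, ``error_offset``, ``family``, ``item``.

    ``oracles`` maps structure name -> {Query: probability}; defaults to the
    built-in learning-phase parametrization.  ``item`` is the inference-item
    identifier used as a crossed random-effect grouping (the 27 canonical
    queries crossed with the chain/common-cause-pooled vs common-effect
    family).
    """
    oracles = oracles if oracles is not None else _default_oracles()
    out = table.copy()
    normative = np.empty(len(out))
    items = []
    families = []
    for i, (_, row) in enumerate(out.iterrows()):
        q = query_from_row(row)
        fam = Structure(row["structure"]).family
        try:
            normative[i] = oracles[row["structure"]][q]
        except KeyError:
            raise KeyError(f"query {q.label()} not in oracle for {row['structure']}")
        items.append(q.item_id(fam))
        families.append(fam)
    out["normative"] = normative
    out["family"] = families
    out["item"] = items
    resp = out["response"].astype("Float64").to_numpy(dtype=float, na_value=np.nan)
    if np.nanmin(resp) < 0 or np.nanmax(resp) > 100:
        raise ValueError("responses must be in [0, 100]")
    out["error_pp"] = np.abs(resp - 100.0 * normative)
    out["error_offset"] = out["error_pp"] + 0.01
    return out


@dataclass
class ExclusionReport:
    """Counts and percentages for each exclusion step, in application order."""

    n_input: int = 0
    n_missed: int = 0
    pct_missed: float = 0.0
    n_fast: int = 0
    pct_fast: float = 0.0
    rt_floor_s: float = 1.5
    error_cut_pp: float = 18.0
    participant_mean_error: dict = field(default_factory=dict)
    excluded_participants: list = field(default_factory=list)
    n_excluded_participant_trials: int = 0
    n_retained: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def apply_exclusions(
    table: pd.DataFrame, rt_floor: float = 1.5, error_cut: float = 18.0
) -> Tuple[pd.DataFrame, ExclusionReport]:
    """Apply the exclusion rules in order; idempotent.

    1. drop missed-deadline trials;
    2. drop trials with ``rt_s`` < ``rt_floor`` (non-compliant fast responses);
    3. drop participants whose mean ``error_pp`` over the remaining trials
       exceeds ``error_cut`` (a constant-50 responder falls just above it).
    """
    if len(table) == 0:
        raise ValueError("empty trial table")
    if "error_pp" not in table.columns:
        raise ValueError("table must be annotated (run annotate_normative_and_error)")
    rep = ExclusionReport(n_input=len(table), rt_floor_s=rt_floor, error_cut_pp=error_cut)

    t = table.loc[~table["missed"].astype(bool)].copy()
    rep.n_missed = rep.n_input - len(t)
    rep.pct_missed = 100.0 * rep.n_missed / rep.n_input

    kept = t.loc[t["rt_s"] >= rt_floor].copy()
    rep.n_fast = len(t) - len(kept)
    rep.pct_fast = 100.0 * rep.n_fast / max(len(t), 1)

    means = kept.groupby("participant_id")["error_pp"].mean()
    rep.participant_mean_error = {int(k): float(v) for k, v in means.items()}
    bad = means.index[means > error_cut]
    rep.excluded_participants = [int(b) for b in bad]
    rep.n_excluded_participant_trials = int(kept["participant_id"].isin(bad).sum())
    kept = kept.loc[~kept["participant_id"].isin(bad)].copy()
    rep.n_retained = len(kept)
    return kept.reset_index(drop=True), rep


def _zscore_within(table: pd.DataFrame, col: str, out_col: str) -> pd.DataFrame:
    out = table.copy()
    sizes = out.groupby("participant_id")[col].transform("size")
    if (sizes < 2).any():
        bad = out.loc[sizes < 2, "participant_id"].unique()
        raise ValueError(f"participants with < 2 rows cannot be z-scored: {list(bad)}")
    grp = out.groupby("participant_id")[col]
    out[out_col] = (out[col] - grp.transform("mean")) / grp.transform(lambda s: s.std(ddof=1))
    return out


def zscore_rt(table: pd.DataFrame) -> pd.DataFrame:
    """Within-participant z-score of RT (``rt_z``); run after exclusions."""
    return _zscore_within(table, "rt_s", "rt_z")


def zscore_confidence(table: pd.DataFrame) -> pd.DataFrame:
    """Within-participant z-score of confidence (``conf_z``)."""
    out = table.copy()
    out["confidence"] = out["confidence"].astype("Float64").to_numpy(dtype=float, na_value=np.nan)
    return _zscore_within(out, "confidence", "conf_z")


def code_markov(table: pd.DataFrame) -> pd.DataFrame:
    """Markov-violation coding.

    Chain/common-cause rows querying a terminal variable with the middle
    variable known get ``screened_off`` = state of the other terminal
    (-1/0/+1) and ``mid_var`` = the middle variable's value.  Common-effect
    rows querying a cause with the effect *unknown* get ``screened_off`` =
    state of the other cause.  All other rows are left uncoded (NaN).
    """
    out = table.copy()
    so = np.full(len(out), np.nan)
    mv = np.full(len(out), np.nan)
    for i, (_, row) in enumerate(out.iterrows()):
        if row["queried"] == "Y":
            continue
        q = query_from_row(row)
        given = q.given_map
        y = given["Y"]
        other_state = next(s for v, s in q.given if v != "Y")
        code = 0 if other_state is None else int(np.sign(other_state * 2 - 1))
        fam = Structure(row["structure"]).family
        if fam == "cc" and y is not None:
            so[i] = code
            mv[i] = y
        elif fam == "ce" and y is None:
            so[i] = code
    out["screened_off"] = so
    out["mid_var"] = mv
    return out


def code_explaining_away(table: pd.DataFrame) -> pd.DataFrame:
    """Explaining-away coding on common-effect trials with the effect present.

    ``away_var`` is the -1/0/+1 state of the non-queried cause and
    ``recoded_response`` shifts responses so the normative pattern is flat:
    response - 28.6 when the other cause is absent, response + 11.4 when it
    is present.
    """
    out = table.copy()
    av = np.full(len(out), np.nan)
    rec = np.full(len(out), np.nan)
    resp = out["response"].astype("Float64").to_numpy(dtype=float, na_value=np.nan)
    for i, (_, row) in enumerate(out.iterrows()):
        if Structure(row["structure"]).family != "ce" or row["queried"] == "Y":
            continue
        q = query_from_row(row)
        if q.given_map["Y"] != 1:
            continue
        other_state = next(s for v, s in q.given if v != "Y")
        code = 0 if other_state is None else int(np.sign(other_state * 2 - 1))
        av[i] = code
        shift = {-1: AWAY_SHIFT_ABSENT, 0: 0.0, 1: AWAY_SHIFT_PRESENT}[code]
        rec[i] = resp[i] + shift
    out["away_var"] = av
    out["recoded_response"] = rec
    return out


def conservatism(table: pd.DataFrame) -> pd.DataFrame:
    """Signed movement of the response from the normative answer toward 50.

    Positive values are conservative (response between the normative answer
    and 50, or at 50); negative values are more extreme than normative.
    Rows whose normative answer is exactly .5 cannot be represented and are
    flagged ``normative_50``; rows whose response falls strictly on the
    opposite side of 50 from the normative answer are flagged
    ``opposite_side``.  Flagged rows get NaN conservatism.
    """
    out = table.copy()
    resp = out["response"].astype("Float64").to_numpy(dtype=float, na_value=np.nan)
    norm = 100.0 * out["normative"].to_numpy(dtype=float)
    cons = np.where(norm > 50.0, norm - resp, resp - norm)
    reason = np.array([None] * len(out), dtype=object)
    at50 = np.isclose(norm, 50.0)
    reason[at50] = "normative_50"
    opposite = (~at50) & ((resp - 50.0) * (norm - 50.0) < 0)
    reason[opposite] = "opposite_side"
    cons = np.where(pd.isna(reason), cons, np.nan)
    out["conservatism"] = cons
    out["conservatism_excluded_reason"] = reason
    return out


def spike_rate_50(table: pd.DataFrame) -> pd.DataFrame:
    """Proportion of responses in [49.5, 50.5] per (participant, deadline).

    Returns a tidy frame with columns participant_id, deadline_s, spike_rate,
    n_trials.  Cells with no retained trials are absent (flag by reindexing
    if a complete grid is needed).
    """
    t = table.loc[table["response"].notna()]
    resp = t["response"].astype(float)
    spike = (resp >= 49.5) & (resp <= 50.5)
    g = (
        t.assign(spike=spike.to_numpy())
        .groupby(["participant_id", "deadline_s"], as_index=False)
        .agg(spike_rate=("spike", "mean"), n_trials=("spike", "size"))
    )
    return g
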