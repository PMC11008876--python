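"""Optional adapter for the study's public trial-level data deposit.

The experiments' human data are publicly deposited (OSF project ``bz9vj``).
This adapter maps a downloaded trial-level CSV onto the shared trial-table
schema so the metrics and analysis battery can run on it.  It is a stub: the
column mapping below covers the obvious trial-level fields and may need
adjustment to the deposit's exact export; nothing in the package or its tests
depends on it, and no network access is attempted here.
"""

from __future__ import annotations

from typing import Mapping, Optional

import pandas as pd

#: candidate deposit column -> schema column
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "subject": "participant_id",
    "participant": "participant_id",
    "domain": "domain",
    "structure": "structure",
    "deadline": "deadline_s",
    "block": "block_index",
    "trial": "trial_index",
    "queried": "queried",
    "state1": "state_other1",
    "state2": "state_other2",
    "response": "response",
    "rt": "rt_s",
    "confidence": "confidence",
}


def load_osf_trials(
    path,
    experiment: str = "exp1",
    column_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Load a deposit CSV and rename columns onto the shared schema.

    Raises with the list of unmapped schema columns if the file does not
    cover the required fields.
    """
    from .pipeline import TRIAL_SCHEMA

    raw = pd.read_csv(path)
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    present = {src: dst for src, dst in cmap.items() if src in raw.columns}
    df = raw.rename(columns=present)
    df["experiment"] = experiment
    if "missed" not in df.columns:
        df["missed"] = df["response"].isna() if "response" in df.columns else False
    required = [c for c in TRIAL_SCHEMA if c not in ("confidence",)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"deposit file does not map onto the trial schema; missing {missing}. "
            "Pass an explicit column_map."
        )
    return df[[c for c in TRIAL_SCHEMA if c in df.columns]]
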