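"""Run configuration, presets, and the simulate -> metrics -> stats pipeline."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import metrics as mx
from .simulate import (
    ConfidenceModel,
    ResponseModelParams,
    RTModel,
    make_noncompliant,
    simulate_cohort,
)
from .stats import analysis_battery, rm_anova_spikes

__all__ = [
    "RunConfig",
    "PRESETS",
    "preset_params",
    "prepare_trials",
    "run_pipeline",
    "plot_mean_responses",
    "TRIAL_SCHEMA",
]

log = logging.getLogger("causalpress")

#: Column dictionary of the shared trial-table CSV (UTF-8, comma-delimited).
TRIAL_SCHEMA = {
    "participant_id": "int",
    "experiment": "exp1|exp2",
    "domain": "meteorology|sociology|economics",
    "structure": "chain|common_cause|common_effect",
    "deadline_s": "6|9|20",
    "block_index": "int",
    "trial_index": "int",
    "queried": "X1|Y|X2",
    "state_other1": "absent|unknown|present",
    "state_other2": "absent|unknown|present",
    "response": "int 0-100 (empty when missed)",
    "rt_s": "float seconds",
    "confidence": "int 0-100 (empty when missed)",
    "missed": "bool",
}


def _normative_params() -> ResponseModelParams:
    return ResponseModelParams(
        noise_sd=0.0,
        shrink_base=0.0,
        shrink_deadline_gain={6: 0.0, 9: 0.0, 20: 0.0},
        shrink_time_gain=0.0,
        markov_bias=0.0,
        away_attenuation=1.0,
        rt_model=RTModel(miss_prob=0.0),
        confidence_model=ConfidenceModel(obs_sd=0.0),
    )


def _null_params() -> ResponseModelParams:
    # No deadline- or time-dependent effects: deadline/RT terms in the battery
    # are true nulls (Markov bias stays, constant across deadlines).
    return replace(
        ResponseModelParams(),
        shrink_deadline_gain={6: 0.0, 9: 0.0, 20: 0.0},
        shrink_time_gain=0.0,
    )


def _noncompliant_mix_sampler(frac: float = 0.35) -> Callable:
    base = ResponseModelParams()

    def sampler(pid: int, rng: np.random.Generator) -> ResponseModelParams:
        if rng.random() < frac:
            mode = "uniform" if rng.random() < 0.5 else "constant50"
            return make_noncompliant(base, mode=mode)
        return base

    return sampler


PRESETS: Dict[str, dict] = {
    "paper-like": {"params": ResponseModelParams, "sampler": None},
    "normative": {"params": _normative_params, "sampler": None},
    "null": {"params": _null_params, "sampler": None},
    "noncompliant-mix": {"params": None, "sampler": _noncompliant_mix_sampler},
}


def preset_params(name: str):
    """(params, sampler) pair for a named preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    params = cfg["params"]() if cfg["params"] is not None else None
    sampler = cfg["sampler"]() if cfg["sampler"] is not None else None
    return params, sampler


@dataclass
class RunConfig:
    """Everything needed for a reproducible simulate -> analyze run."""

    experiment: str = "exp1"
    n_participants: int = 26
    master_seed: int = 0
    preset: str = "paper-like"
    rt_floor_s: float = 1.5
    error_cut_pp: float = 18.0
    analyses: Optional[Sequence[str]] = None  # None = all for the experiment
    outdir: str = "causalpress_run"

    def __post_init__(self):
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError("experiment must be 'exp1' or 'exp2'")
        if self.rt_floor_s <= 0 or self.error_cut_pp <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def prepare_trials(
    trials: pd.DataFrame,
    rt_floor: float = 1.5,
    error_cut: float = 18.0,
    experiment: str = "exp1",
):
    """Annotate, exclude, z-score and code a raw trial table.

    Returns ``(prepared_table, ExclusionReport)`` where the table carries all
    derived columns the analysis battery needs.
    """
    ann = mx.annotate_normative_and_error(trials)
    kept, report = mx.apply_exclusions(ann, rt_floor=rt_floor, error_cut=error_cut)
    kept = mx.zscore_rt(kept)
    if experiment == "exp2":
        kept = mx.zscore_confidence(kept)
    kept = mx.code_markov(kept)
    kept = mx.code_explaining_away(kept)
    kept = mx.conservatism(kept)
    return kept, report


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Simulate a cohort, apply metrics and exclusions, run the battery.

    Returns a dict with the trial table, prepared table, exclusion report,
    fitted summaries and the spike-rate ANOVA; optionally writes everything
    under ``config.outdir``.
    """
    params, sampler = preset_params(config.preset)
    trials = simulate_cohort(
        config.n_participants,
        params=params,
        master_seed=config.master_seed,
        experiment=config.experiment,
        participant_sampler=sampler,
    )
    prepared, report = prepare_trials(
        trials, config.rt_floor_s, config.error_cut_pp, config.experiment
    )
    fits = analysis_battery(prepared, which=config.analyses, experiment=config.experiment)
    spikes = mx.spike_rate_50(prepared)
    spike_anova = (
        rm_anova_spikes(spikes) if spikes["participant_id"].nunique() >= 2 else None
    )
    result = {
        "config": dataclasses.asdict(config),
        "trials": trials,
        "prepared": prepared,
        "exclusion_report": report,
        "fits": fits,
        "spike_rates": spikes,
        "spike_anova": spike_anova,
    }
    if write:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        trials.to_csv(out / "trials.csv", index=False)
        prepared.to_csv(out / "trials_prepared.csv", index=False)
        with open(out / "exclusion_report.json", "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        with open(out / "fits.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "fits": {k: v.to_dict() for k, v in fits.items()},
                    "spike_anova": spike_anova,
                },
                fh,
                indent=2,
                default=float,
            )
        config.to_yaml(out / "config.yaml")
        logging.basicConfig()
        log.info(
            "run complete: %d participants, %d retained trials, %d excluded participants",
            config.n_participants,
            report.n_retained,
            len(report.excluded_participants),
        )
    return result


def plot_mean_responses(prepared: pd.DataFrame, path=None):
    """Mean response per inference with normative markers, per family.

    One panel per structure family; X axis is the canonical inference id,
    dots are cohort mean responses, crosses the normative answers.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(12, 7), sharey=True)
    for ax, fam in zip(axes, ("cc", "ce")):
        sub = prepared[prepared["family"] == fam]
        g = sub.groupby("item").agg(
            mean_resp=("response", "mean"), normative=("normative", "first")
        )
        g = g.sort_index()
        x = np.arange(len(g))
        ax.plot(x, g["mean_resp"], "o", color="tab:red", label="mean response")
        ax.plot(x, 100 * g["normative"], "x", color="black", label="normative")
        ax.axhline(50, ls="--", lw=0.8, color="grey")
        ax.set_xticks(x)
        ax.set_xticklabels(g.index, rotation=90, fontsize=6)
        ax.set_ylabel("response (%)")
        ax.set_title({"cc": "chain / common cause", "ce": "common effect"}[fam])
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
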