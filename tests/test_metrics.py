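"""Derived measures, codings, and exclusion rules."""

import numpy as np
import pandas as pd
import pytest

from causalpress.design import build_participant_design, assign_counterbalance
from causalpress.metrics import (
    annotate_normative_and_error,
    apply_exclusions,
    code_explaining_away,
    code_markov,
    conservatism,
    spike_rate_50,
    zscore_rt,
)
from causalpress.pipeline import preset_params
from causalpress.simulate import make_noncompliant, simulate_cohort


def _constant_responder_table(response=50):
    d = build_participant_design(assign_counterbalance(0), 0)
    d["response"] = response
    d["rt_s"] = 3.0
    d["confidence"] = 70
    d["missed"] = False
    return d


class TestAnnotation:
    def test_error_definition(self):
        t = _constant_responder_table(60)
        ann = annotate_normative_and_error(t)
        row = ann[(ann["normative"] == 0.75)].iloc[0]
        assert row["error_pp"] == pytest.approx(15.0)
        assert row["error_offset"] == pytest.approx(15.01)

    def test_constant50_design_mean_error_rounds_to_18(self):
        """The design's normative answers average 18 pp from 50: the basis of
        the 18% exclusion criterion."""
        ann = annotate_normative_and_error(_constant_responder_table(50))
        assert round(ann["error_pp"].mean()) == 18
        # identical statement on the oracle itself
        assert ann["error_pp"].mean() == pytest.approx(
            np.abs(100 * ann["normative"] - 50).mean()
        )

    def test_response_out_of_range_rejected(self):
        t = _constant_responder_table(120)
        with pytest.raises(ValueError):
            annotate_normative_and_error(t)


class TestExclusions:
    def test_fast_trials_removed(self):
        t = _constant_responder_table(75)
        t.loc[t.index[:10], "rt_s"] = 1.2
        ann = annotate_normative_and_error(t)
        kept, rep = apply_exclusions(ann, error_cut=50.0)
        assert rep.n_fast == 10
        assert (kept["rt_s"] >= 1.5).all()

    def test_missed_trials_removed_first(self):
        t = _constant_responder_table(75)
        t.loc[t.index[:5], "missed"] = True
        t.loc[t.index[:5], "rt_s"] = 1.0  # also fast: counted as missed, not fast
        kept, rep = apply_exclusions(annotate_normative_and_error(t), error_cut=50.0)
        assert rep.n_missed == 5
        assert rep.n_fast == 0

    def test_constant50_participant_excluded_at_boundary(self):
        ann = annotate_normative_and_error(_constant_responder_table(50))
        kept, rep = apply_exclusions(ann)
        assert rep.excluded_participants == [0]
        assert len(kept) == 0
        assert rep.participant_mean_error[0] > 18.0

    def test_uniform_responder_excluded_normative_retained(self):
        params, _ = preset_params("normative")
        good = simulate_cohort(1, params=params, master_seed=1)
        bad = simulate_cohort(
            1,
            params=make_noncompliant(mode="uniform"),
            master_seed=2,
            participant_ids=[1],
        )
        ann = annotate_normative_and_error(pd.concat([good, bad], ignore_index=True))
        kept, rep = apply_exclusions(ann)
        assert rep.excluded_participants == [1]
        assert set(kept["participant_id"]) == {0}

    def test_idempotent(self, paperlike_prepared):
        prepared, _ = paperlike_prepared
        again, rep = apply_exclusions(prepared)
        assert len(again) == len(prepared)
        assert rep.excluded_participants == []

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            apply_exclusions(pd.DataFrame())


class TestZScores:
    def test_rt_z_mean_zero_sd_one(self, paperlike_prepared):
        prepared, _ = paperlike_prepared
        g = prepared.groupby("participant_id")["rt_z"]
        assert np.allclose(g.mean(), 0.0, atol=1e-9)
        assert np.allclose(g.std(ddof=1), 1.0, atol=1e-9)

    def test_scale_invariance_across_participants(self):
        t = _constant_responder_table(60)
        t2 = t.copy()
        t2["participant_id"] = 1
        t2["rt_s"] = t2["rt_s"] * 4 + 2  # different RT scale, same shape
        rng = np.random.default_rng(0)
        jitter = rng.normal(0, 0.2, len(t))
        t["rt_s"] += jitter
        t2["rt_s"] += 4 * jitter
        both = zscore_rt(pd.concat([t, t2], ignore_index=True))
        a = both[both["participant_id"] == 0]["rt_z"].to_numpy()
        b = both[both["participant_id"] == 1]["rt_z"].to_numpy()
        assert np.allclose(a, b, atol=1e-9)

    def test_zscore_changes_after_row_removal(self):
        t = _constant_responder_table(60)
        rng = np.random.default_rng(1)
        t["rt_s"] = rng.uniform(1.0, 5.0, len(t))
        before = zscore_rt(t)
        subset = t[t["rt_s"] >= 1.5]
        after = zscore_rt(subset)
        merged = before.loc[subset.index, "rt_z"].to_numpy()
        assert not np.allclose(merged, after["rt_z"].to_numpy())

    def test_single_row_participant_raises(self):
        t = _constant_responder_table(60).head(1)
        with pytest.raises(ValueError):
            zscore_rt(t)


class TestMarkovCoding:
    def test_examples(self):
        t = annotate_normative_and_error(_constant_responder_table(60))
        coded = code_markov(t)
        # chain: query X1, Y present, X2 unknown -> screened_off 0, mid_var 1
        r = coded[
            (coded["structure"].isin(["chain", "common_cause"]))
            & (coded["queried"] == "X1")
            & (coded["state_other1"] == "present")
            & (coded["state_other2"] == "unknown")
        ].iloc[0]
        assert r["screened_off"] == 0 and r["mid_var"] == 1
        # CE: query X2, Y unknown, X1 present -> screened_off +1
        r = coded[
            (coded["structure"] == "common_effect")
            & (coded["queried"] == "X2")
            & (coded["state_other1"] == "present")
            & (coded["state_other2"] == "unknown")
        ].iloc[0]
        assert r["screened_off"] == 1 and np.isnan(r["mid_var"])
        # chain with Y unknown: not Markov-relevant
        r = coded[
            (coded["structure"].isin(["chain", "common_cause"]))
            & (coded["queried"] == "X1")
            & (coded["state_other1"] == "unknown")
        ]
        assert r["screened_off"].isna().all()

    def test_markov_design_confound_free(self, oracles):
        """At fixed mid_var the three screened-off levels share one normative
        value, so any response effect is behavioral, not designed in."""
        t = annotate_normative_and_error(_constant_responder_table(50))
        coded = code_markov(t)
        sub = coded[coded["screened_off"].notna() & (coded["family"] == "cc")]
        for (_, mv), grp in sub.groupby(["queried", "mid_var"]):
            assert grp["normative"].nunique() == 1


class TestAwayCoding:
    def test_normative_recoding_is_flat_at_714(self, normative_trials):
        ann = annotate_normative_and_error(normative_trials)
        coded = code_explaining_away(ann)
        sub = coded[coded["away_var"].notna()]
        assert set(sub["away_var"]) == {-1.0, 0.0, 1.0}
        for lvl, grp in sub.groupby("away_var"):
            assert grp["recoded_response"].to_numpy() == pytest.approx(71.4, abs=0.5)

    def test_shift_values(self):
        t = annotate_normative_and_error(_constant_responder_table(60))
        coded = code_explaining_away(t)
        sub = coded[coded["away_var"].notna()]
        assert sub.loc[sub["away_var"] == -1, "recoded_response"].iloc[0] == pytest.approx(31.4)
        assert sub.loc[sub["away_var"] == 1, "recoded_response"].iloc[0] == pytest.approx(71.4)
        assert sub.loc[sub["away_var"] == 0, "recoded_response"].iloc[0] == pytest.approx(60.0)
        # only CE trials querying a cause with the effect present are coded
        assert (sub["structure"] == "common_effect").all()
        y_state = np.where(sub["queried"] == "X1", sub["state_other1"], sub["state_other2"])
        assert (y_state == "present").all()


class TestConservatism:
    @pytest.mark.parametrize(
        "normative,response,expected",
        [
            (0.9, 70, 20.0),
            (0.75, 80, -5.0),
            (0.25, 40, 15.0),
            (0.75, 50, 25.0),  # response at 50 is maximally conservative
        ],
    )
    def test_signed_movement(self, normative, response, expected):
        t = _constant_responder_table(response).head(1)
        ann = annotate_normative_and_error(t)
        ann["normative"] = normative
        out = conservatism(ann)
        assert out["conservatism"].iloc[0] == pytest.approx(expected)

    def test_exclusion_rules(self):
        t = _constant_responder_table(40).head(2)
        ann = annotate_normative_and_error(t)
        ann.loc[ann.index[0], "normative"] = 0.75  # response 40: opposite side
        ann.loc[ann.index[1], "normative"] = 0.5   # normative exactly 50
        out = conservatism(ann)
        assert list(out["conservatism_excluded_reason"]) == [
            "opposite_side",
            "normative_50",
        ]
        assert out["conservatism"].isna().all()

    def test_reflection_antisymmetry(self):
        """Reflecting response and normative about 50 preserves conservatism."""
        t = _constant_responder_table(70).head(1)
        ann = annotate_normative_and_error(t)
        ann["normative"] = 0.9
        a = conservatism(ann)["conservatism"].iloc[0]
        ann2 = ann.copy()
        ann2["response"] = 30
        ann2["normative"] = 0.1
        b = conservatism(ann2)["conservatism"].iloc[0]
        assert a == pytest.approx(b)


class TestSpikeRate:
    def test_constant50_rate_one(self):
        ann = annotate_normative_and_error(_constant_responder_table(50))
        rates = spike_rate_50(ann)
        assert (rates["spike_rate"] == 1.0).all()
        assert len(rates) == 3  # one participant x three deadlines

    def test_normative_rate_matches_design_fraction(self, normative_trials, oracles):
        """Noise-free normative responders spike exactly on the queries whose
        normative answer is .5 (5 of 27 chain/common-cause, 8 of 27
        common-effect: 18 of the 81 trials in every deadline cell)."""
        ann = annotate_normative_and_error(normative_trials)
        rates = spike_rate_50(ann)
        expected = np.isclose(ann["normative"], 0.5).mean()
        assert rates["spike_rate"].to_numpy() == pytest.approx(expected, abs=1e-12)
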