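"""Mixed-model battery: fits, EMMs, contrasts, Bayes factors, RM-ANOVA."""

import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from causalpress.pipeline import prepare_trials, preset_params
from causalpress.simulate import simulate_cohort
from causalpress.stats import (
    ModelSpec,
    analysis_battery,
    bayes_factor,
    emmeans_and_contrasts,
    fit_mixed,
    rm_anova_spikes,
)


def _toy_mixed_data(seed=42, n_p=6, n_i=5, sd_p=4.0, sd_i=2.0, effect=(0.0, 4.0, 8.0)):
    rng = np.random.default_rng(seed)
    pe = rng.normal(0, sd_p, n_p)
    ie = rng.normal(0, sd_i, n_i)
    rows = []
    for p in range(n_p):
        for i in range(n_i):
            for k, dl in enumerate((6, 9, 20)):
                rows.append(
                    (p, i, dl, 50 + pe[p] + ie[i] + effect[k] + rng.normal(0, 6))
                )
    return pd.DataFrame(rows, columns=["participant_id", "item", "deadline_s", "y"])


class TestFitMixed:
    def test_zero_random_variance_matches_ols(self):
        """With no random-effect variance the mixed fit reproduces ordinary
        regression coefficients (small-instance oracle equivalence)."""
        df = _toy_mixed_data(seed=3, sd_p=0.0, sd_i=0.0)
        fs = fit_mixed(df, ModelSpec("y", ["C(deadline_s)"]))
        ols = smf.ols("y ~ C(deadline_s)", df).fit()
        for name, value in ols.params.items():
            assert fs.params[name] == pytest.approx(value, abs=1e-4)

    def test_matches_lme4_on_small_fixture(self, tmp_path):
        """Independent oracle: lme4's ML fixed effects on the same data."""
        df = _toy_mixed_data(seed=42)
        fs = fit_mixed(df, ModelSpec("y", ["C(deadline_s)"]))
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
d$deadline_s <- factor(d$deadline_s, levels=c(6,9,20))
m <- lmer(y ~ deadline_s + (1|participant_id) + (1|item), data=d, REML=FALSE)
cat(fixef(m), sep=",")
"""
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        r_fe = [float(v) for v in proc.stdout.strip().split(",")]
        py_fe = [
            fs.params["Intercept"],
            fs.params["C(deadline_s)[T.9]"],
            fs.params["C(deadline_s)[T.20]"],
        ]
        assert py_fe == pytest.approx(r_fe, abs=1e-3)

    def test_gamma_constant_dependent(self):
        df = _toy_mixed_data(seed=1).assign(err=5.0)
        fs = fit_mixed(df, ModelSpec("err", ["C(deadline_s)"], family="gamma_log"))
        assert fs.params["Intercept"] == pytest.approx(np.log(5.0), abs=1e-8)
        slopes = [v for k, v in fs.params.items() if k != "Intercept"]
        assert np.allclose(slopes, 0.0, atol=1e-8)
        assert fs.method == "gamma_glm_participant_fe_cluster"
        assert any("fallback" in n for n in fs.notes)

    def test_gamma_requires_positive_dependent(self):
        df = _toy_mixed_data(seed=1).assign(err=0.0)
        with pytest.raises(ValueError):
            fit_mixed(df, ModelSpec("err", ["C(deadline_s)"], family="gamma_log"))

    def test_unknown_family_and_missing_dependent(self):
        df = _toy_mixed_data()
        with pytest.raises(ValueError):
            fit_mixed(df, ModelSpec("y", ["C(deadline_s)"], family="poisson"))
        with pytest.raises(ValueError):
            fit_mixed(df, ModelSpec("nope", ["C(deadline_s)"]))


class TestEmmeans:
    def test_balanced_one_factor_equals_cell_means(self):
        df = _toy_mixed_data(seed=7, sd_p=0.0, sd_i=0.0)
        fs = fit_mixed(df, ModelSpec("y", ["C(deadline_s)"]))
        emmeans_and_contrasts(fs, "deadline_s")
        emm = fs.emmeans["deadline_s"].set_index("level")["mean"]
        raw = df.groupby("deadline_s")["y"].mean()
        for lvl in (6, 9, 20):
            assert emm[lvl] == pytest.approx(raw[lvl], abs=1e-4)

    def test_three_levels_three_tukey_contrasts(self):
        df = _toy_mixed_data(seed=8)
        fs = fit_mixed(df, ModelSpec("y", ["C(deadline_s)"]))
        emmeans_and_contrasts(fs, "deadline_s")
        con = fs.contrasts["deadline_s"]
        assert len(con) == 3
        assert (con["p_tukey"] >= con["p_unadjusted"] - 1e-12).all()

    def test_absent_factor_raises(self):
        df = _toy_mixed_data(seed=8)
        fs = fit_mixed(df, ModelSpec("y", ["C(deadline_s)"]))
        with pytest.raises(KeyError):
            emmeans_and_contrasts(fs, "domain")


class TestBayesFactor:
    def test_identical_models_give_bf_one(self):
        df = _toy_mixed_data(seed=9)
        a = fit_mixed(df, ModelSpec("y", ["C(deadline_s)"]))
        b = fit_mixed(df, ModelSpec("y", ["C(deadline_s)"]))
        assert bayes_factor(a, b) == pytest.approx(1.0, abs=1e-6)

    def test_strong_effect_large_bf(self):
        df = _toy_mixed_data(seed=10, effect=(0.0, 10.0, 20.0))
        full = fit_mixed(df, ModelSpec("y", ["C(deadline_s)"]))
        reduced = fit_mixed(df, ModelSpec("y", ["1"]))
        assert bayes_factor(full, reduced) > 10

    def test_null_effect_favors_reduced(self):
        df = _toy_mixed_data(seed=11, effect=(0.0, 0.0, 0.0))
        full = fit_mixed(df, ModelSpec("y", ["C(deadline_s)"]))
        reduced = fit_mixed(df, ModelSpec("y", ["1"]))
        assert bayes_factor(full, reduced) < 1.0

    def test_non_nested_raises(self):
        df = _toy_mixed_data(seed=12).assign(x=np.arange(90) % 3)
        a = fit_mixed(df, ModelSpec("y", ["C(deadline_s)"]))
        b = fit_mixed(df, ModelSpec("y", ["x"]))
        with pytest.raises(ValueError):
            bayes_factor(a, b)


class TestBattery:
    @pytest.fixture(scope="class")
    def fits(self, paperlike_prepared):
        prepared, _ = paperlike_prepared
        return analysis_battery(prepared, experiment="exp2", compute_bf=False)

    def test_all_named_analyses_run(self, fits):
        assert {
            "rt_manipulation",
            "overall_error",
            "markov_cc",
            "markov_ce",
            "away",
            "conservatism",
            "error_confidence",
            "markov_cc_confidence",
            "away_confidence",
            "conservatism_confidence",
        } <= set(fits)

    def test_rt_manipulation_detects_deadline(self, fits):
        """RT grows with deadline by construction: the manipulation check."""
        fs = fits["rt_manipulation"]
        assert fs.pvalue("C(deadline_s)") < 1e-6
        emm = fs.emmeans["deadline_s"].set_index("level")["mean"]
        assert emm[6] < emm[9] < emm[20]

    def test_away_failure_detected(self, fits):
        """Attenuated explaining away leaves a large AwayVar effect on the
        recoded response (flat at 71.4 only for a normative responder)."""
        assert fits["away"].pvalue("C(away_var)") < 1e-4

    def test_unknown_analysis_and_missing_columns(self, paperlike_prepared):
        prepared, _ = paperlike_prepared
        with pytest.raises(KeyError):
            analysis_battery(prepared, which=["nonexistent"])
        broken = prepared.drop(columns=["screened_off"])
        with pytest.raises((ValueError, KeyError)):
            analysis_battery(broken, which=["markov_cc"], compute_bf=False)

    def test_simplification_drops_null_three_way(self):
        """A sole highest-order interaction with p >= .05 is removed once and
        the model refit (exp2 conservatism model has the unique three-way)."""
        trials = simulate_cohort(5, master_seed=23, experiment="exp2")
        prepared, _ = prepare_trials(trials, experiment="exp2")
        fits = analysis_battery(
            prepared, which=["conservatism_confidence"], experiment="exp2",
            compute_bf=False,
        )
        fs = fits["conservatism_confidence"]
        # generator has no three-way structure; the term should be dropped
        assert fs.dropped_interaction == "C(deadline_s):rt_z:conf_z"
        assert "C(deadline_s):rt_z:conf_z" not in set(fs.term_tests["term"])


class TestSpikeAnova:
    def test_identical_rates_give_zero_f(self):
        rates = pd.DataFrame(
            {
                "participant_id": np.repeat(np.arange(5), 3),
                "deadline_s": np.tile([6, 9, 20], 5),
                "spike_rate": np.repeat(np.linspace(0.1, 0.5, 5), 3),
            }
        )
        res = rm_anova_spikes(rates)
        assert res["F"] == 0.0
        assert res["p"] == 1.0

    def test_strong_deadline_effect_detected(self):
        rng = np.random.default_rng(0)
        rows = []
        for p in range(10):
            base = rng.uniform(0.1, 0.2)
            for dl, bump in ((6, 0.3), (9, 0.15), (20, 0.0)):
                rows.append((p, dl, base + bump + rng.normal(0, 0.02)))
        res = rm_anova_spikes(
            pd.DataFrame(rows, columns=["participant_id", "deadline_s", "spike_rate"])
        )
        assert res["p"] < 0.001
        assert res["bf10"] > 10

    def test_missing_cells_raise(self):
        rates = pd.DataFrame(
            {"participant_id": [0, 0, 1], "deadline_s": [6, 9, 6], "spike_rate": [0.1, 0.2, 0.3]}
        )
        with pytest.raises(ValueError):
            rm_anova_spikes(rates)

    def test_bf_reciprocity(self, paperlike_prepared):
        from causalpress.metrics import spike_rate_50

        prepared, _ = paperlike_prepared
        res = rm_anova_spikes(spike_rate_50(prepared))
        assert res["bf01"] == pytest.approx(1.0 / res["bf10"])
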