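"""The mixed-model analysis battery on a simulated cohort.

Fits linear mixed models with crossed random intercepts (participants x
inference items) and a Gamma-log error model, then prints the omnibus tests
that carry the study's headline conclusions.
"""

from causalpress import analysis_battery, prepare_trials, simulate_cohort

trials = simulate_cohort(n_participants=8, master_seed=3)
prepared, _ = prepare_trials(trials)
fits = analysis_battery(
    prepared,
    which=["rt_manipulation", "markov_cc", "away", "conservatism"],
    compute_bf=True,
)

fs = fits["rt_manipulation"]
print("RT ~ Deadline (manipulation check):")
print(fs.term_tests[["term", "statistic", "df_num", "p"]].round(3).to_string(index=False))

fs = fits["markov_cc"]
print("\nMarkov violations (chain/common-cause subset):")
print(fs.term_tests[["term", "statistic", "p"]].round(3).to_string(index=False))
ix = "C(screened_off):C(deadline_s)"
print(f"BF01 for {ix}: {1 / fs.bayes_factors[ix]:.1f} "
      "(evidence that the violation is deadline-insensitive, as generated)")

fs = fits["away"]
print("\nExplaining away (recoded response):")
emm = fs.emmeans["away_var"].round(2)
print(emm.to_string(index=False))
print("-> far from flat at 71.4: the generator's attenuated explaining away "
      "shows up as a large AwayVar effect "
      f"(p = {fs.pvalue('C(away_var)'):.2g}).")

fs = fits["conservatism"]
print("\nConservatism ~ Deadline x RT:")
print(fs.term_tests[["term", "statistic", "p"]].round(4).to_string(index=False))
print("EMM per deadline:", fs.emmeans["deadline_s"].round(2).to_dict(orient="records"))
print("-> shrinkage toward 50 grows under time pressure: largest at the 6 s "
      "deadline, positive RT slope within deadlines.")
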