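# Methods

## Normative oracle

Each three-variable network (chain, common cause, common effect over binary
variables X1, Y, X2; value 1 = the "non-normal" state present) is represented
by its exact 8-state joint distribution, built either from learning-phase
case counts (count / total) or from CPDs (base rates, link probabilities, and
a Noisy-OR gate for the common effect). Conditionals are computed by direct
enumeration: sum the joint over states consistent with the conditioning
event, marginalizing unknowns. Probabilities are double precision; equality
assertions use a 1e-12 tolerance, and comparisons against printed values
round half-up to the printed precision. The built-in parametrization (counts
summing to 32 per structure) makes chain and common cause share one joint, so
those structures are pooled as one analysis family throughout.

Queries are canonically ordered — queried variable in (X1, Y, X2),
conditioning states of the two other variables (in variable order) in
(absent, unknown, present) — giving stable item identifiers. The "high"/"low"
label counterbalancing of the original task is treated as pure labeling:
value 1 always means the non-normal state, and the assignment flags are
carried only for export. The Noisy-OR leak parameter is exposed but defaults
to 0 (the effect cannot occur without a cause).

## Trial design

243 trials per participant: 3 domains × 3 deadline blocks (6/9/20 s) × all
27 queries. The counterbalancing procedure of the original lab is not
published, so a balanced Latin-square cycling stands in for it: the
structure→domain bijection cycles with period 3, the deadline base order
cycles through all 6 permutations (18 scheme slots), and each domain's block
order is the participant's base order rotated by the domain index. Over any
18 consecutive participant ids every bijection appears 6 times and every
deadline order 3 times. Query order within a block is shuffled by a seed that
never changes the trial multiset. The learning phase is not simulated: its
content is fully summarized by the network parametrization.

## Synthetic participants

The generator is a descriptive emulator — the minimal shrinkage-plus-bias
model reproducing the qualitative behavioral structure — not a cognitive
process theory. Per trial:

1. RT is drawn first from a deadline-specific lognormal truncated at the
   deadline (median 3.2/4.2/6.5 s at 6/9/20 s, log-sd 0.35), so elapsed-time
   shrinkage can depend on it. A deadline is missed with probability 0.002
   (the original cohorts missed ~0.2 % of trials); with the RT medians above
   ~1.5–2 % of compliant responses fall under the 1.5 s compliance floor.
2. The bias-adjusted target m is 100× the normative answer, except:
   on Markov-relevant trials a bias β (default 8 pp) times the screened-off
   state (−1/0/+1) is added, identically across deadlines, so the generative
   ScreenedOff × Deadline interaction is exactly zero — the observed null is
   built in as the default; on common-effect trials with the effect present,
   the normative explaining-away shift away from the Xj-unknown baseline
   (71.4) is scaled by an attenuation α ∈ [0, 1] (default 0.15; 1 would be
   fully normative, and human cohorts barely explain away).
3. The shrinkage weight is λ = clip(λ0 + gD(deadline) + gT · rt/deadline, 0, 1)
   with λ0 = 0.05, gD = 0.12/0.06/0 at 6/9/20 s, gT = 0.35; the response is
   clip(round((1 − λ)·m + λ·50 + ε), 0, 100) with ε ~ N(0, 10 pp), rounded to
   integer percent as in the task.
4. Confidence (0–100) is 85 − 90·λ − 0.6·|ε| plus N(0, 8) observation noise:
   negatively loaded on realized shrinkage, hence negatively correlated with
   conservatism.

Defaults were chosen once against the reported magnitudes: mean error per
deadline ≈ 12/10/9 pp (reported ≈ 14.5/13.8/12.6), conservatism EMMs
≈ 8.5/6/3 pp (reported 6.4/4.9/5.0), a conservatism–RT slope of ~1–2 pp per
RT-SD under short deadlines (reported 1.9/1.5/0.1). Non-compliant responders
(constant-50 or uniform-random) exercise the exclusion rules; the
"noncompliant-mix" preset draws ~35 % non-compliant participants, near the
original dropout rates (37–54 %).

What the generator does *not* emulate: sequential within-trial dynamics (no
evidence accumulation or sampling process), domain or content effects,
individual-difference distributions beyond the compliant/non-compliant split,
and any learning across trials. Passing tests therefore show that the
pipeline recovers effects of this descriptive structure at these noise
levels — not that the pipeline would behave identically on human data.

Seeding: one master seed; each (participant, trial) pair gets its own
substream, so enlarging a cohort never reshuffles earlier participants, and
equal seeds give byte-identical tables.

## Metrics and exclusions

Error is |response − 100·normative| on the 0–100 scale with responses already
integer-rounded; the +0.01 offset is applied only to form the strictly
positive Gamma dependent, never for reporting. Exclusions run in order:
missed deadlines, RT < 1.5 s, then participants whose mean remaining error
exceeds 18 pp. The 18 pp threshold is the design's own property — the mean
distance of the normative answers from 50 is 18.26 pp, so a constant-50
responder sits just above the cut — and the operation is idempotent. RT is
z-scored within participants *after* exclusions (the original order is
unstated; the choice is switchable by calling `zscore_rt` earlier).
Normative values are not rounded before error computation (also unstated in
the source; flagged here rather than guessed — responses are integers, so the
difference is at most 0.5 pp).

Conservatism is the signed movement from the normative answer toward 50,
computed for every annotated trial with normative ≠ .5; rows with normative
exactly .5 are flagged (the measure is undefined there, 22 % of the design),
and rows on the strictly opposite side of 50 from the normative answer are
flagged and dropped; a response exactly at 50 is retained as maximally
conservative. The implemented trial set is thus "all inferences with a
non-50 normative answer", which contains every conflict and ambiguous
inference; restricting further is a caller-side filter.

## Statistical battery

Gaussian models: linear mixed models with crossed random intercepts for
participants and inference items (the 27 canonical queries × the pooled
chain/common-cause vs common-effect family), fitted by maximum likelihood via
statsmodels' variance-component formulation. The backend provides no
Satterthwaite degrees of freedom, so omnibus tests are Wald F with residual
denominator df; every fit summary carries this flag. Error models: a Gamma
GLMM with crossed intercepts is not available in this stack, so the recorded
fallback is a Gamma GLM (log link) with participant fixed effects and
cluster-robust SEs clustered by participant, tested by Wald chi-square;
effects are multiplicative. Degenerate fits (zero variance components,
constant dependents) fall back to pseudoinverse Wald statistics and
mean-seeded IRLS starts rather than failing.

Estimated marginal means average the linear predictor over the levels of the
other categorical predictors with equal weights, covariates at their mean;
Gamma means are back-transformed. Pairwise contrasts are Tukey-adjusted via
the studentized range distribution. Bayes factors use the BIC approximation
BF10 = exp((BIC_reduced − BIC_full)/2) from ML fits — directional,
order-of-magnitude evidence only; no claim of matching any specific BF
calibration. Model simplification removes a *sole* highest-order interaction
once when its p ≥ .05, then stops; ties at the top order are left in place.
The spike-rate analysis is a one-way repeated-measures ANOVA on the
proportion of responses in [49.5, 50.5] per participant × deadline, with
zero-between-cell variance handled exactly (F = 0).

## Validation problem sizes

The statistical properties are validated by simulation at deliberately small
cohort sizes: type-I calibration of the ScreenedOff × Deadline test and the
spike-rate ANOVA uses 200 replicates of 6-participant cohorts under the null
generator (no deadline- or elapsed-time-dependent parameters), with the
rejection rate required to fall in the 99 % binomial band [0.01, 0.10] around
the nominal 5 %; parameter recovery uses 8-participant cohorts on matched
seeds over 3-point grids in β, gT and gD; oracle equivalence checks the mixed
fit against ordinary regression on data with zero random-effect variance, and
against lme4's ML fixed effects on a small fixture.

## Known limitations

* Wald instead of Satterthwaite F means mildly anticonservative small-sample
  p-values for the gaussian models; the calibration test bounds the damage at
  the sizes used.
* The Gamma fallback conditions on participants as fixed effects, which is
  not identical to integrating over a random intercept; item-level clustering
  in the error models is not modelled.
* BIC Bayes factors implicitly assume a unit-information prior; their
  magnitudes are not comparable across software.
* The response model's linear λ(t) cannot reproduce arbitrarily strong
  deadline-specific micro/macro dissociations; response-scale censoring at
  0/100 slightly compresses effects for extreme normative answers.
* The counterbalancing scheme is a documented stand-in, not a claim about the
  original lab procedure.
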