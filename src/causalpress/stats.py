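"""Mixed-effects analysis battery for the trial table.

Gaussian models are linear mixed models with crossed random intercepts for
participants and inference items, fitted by maximum likelihood with
statsmodels' variance-component formulation (a single super-group containing
both sets of intercept dummies).  Omnibus tests per fixed term are Wald F
tests (residual denominator degrees of freedom; Satterthwaite adjustment is
not available in this backend, which every ``FitSummary`` flags).

Error models use a Gamma distribution with a log link.  A Gamma GLMM with
crossed random intercepts is not available here, so the documented fallback
is a Gamma GLM with participant fixed effects and cluster-robust standard
errors (clustered by participant); omnibus tests are Wald chi-square.

Bayes factors are BIC approximations, ``BF10 = exp((BIC_reduced -
BIC_full)/2)`` from ML fits: directional and order-of-magnitude evidence, not
a reproduction of any particular BF calibration.

Estimated marginal means average the model prediction over the levels of the
other categorical predictors (equal weights) with covariates at their mean;
pairwise contrasts are Tukey-adjusted through the studentized range
distribution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "FitSummary",
    "fit_mixed",
    "emmeans_and_contrasts",
    "bayes_factor",
    "analysis_battery",
    "rm_anova_spikes",
    "BATTERY_ANALYSES",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description for :func:`fit_mixed`."""

    dependent: str
    fixed_effects: Sequence[str]
    family: str = "gaussian_identity"  # or "gamma_log"
    random_intercepts: Sequence[str] = ("participant_id", "item")

    @property
    def formula(self) -> str:
        return f"{self.dependent} ~ " + " + ".join(self.fixed_effects)


@dataclass
class FitSummary:
    """Fitted-model output: coefficients, omnibus tests, EMMs, contrasts, BFs."""

    formula: str
    family: str
    method: str
    n_obs: int
    params: Dict[str, float]
    bse: Dict[str, float]
    term_tests: pd.DataFrame          # term, statistic, df_num, df_den, p, kind
    llf: float
    bic: float
    converged: bool
    notes: List[str] = field(default_factory=list)
    emmeans: Dict[str, pd.DataFrame] = field(default_factory=dict)
    contrasts: Dict[str, pd.DataFrame] = field(default_factory=dict)
    bayes_factors: Dict[str, float] = field(default_factory=dict)
    dropped_interaction: Optional[str] = None
    # fitting internals kept for EMM computation; not serialized
    _result: object = field(default=None, repr=False)
    _design_info: object = field(default=None, repr=False)
    _data: pd.DataFrame = field(default=None, repr=False)

    def pvalue(self, term: str) -> float:
        row = self.term_tests.loc[self.term_tests["term"] == term]
        if len(row) == 0:
            raise KeyError(f"term {term!r} not in fitted model")
        return float(row["p"].iloc[0])

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "family": self.family,
            "method": self.method,
            "n_obs": self.n_obs,
            "params": self.params,
            "bse": self.bse,
            "term_tests": self.term_tests.to_dict(orient="records"),
            "llf": self.llf,
            "bic": self.bic,
            "converged": self.converged,
            "notes": list(self.notes),
            "emmeans": {k: v.to_dict(orient="records") for k, v in self.emmeans.items()},
            "contrasts": {k: v.to_dict(orient="records") for k, v in self.contrasts.items()},
            "bayes_factors": self.bayes_factors,
            "dropped_interaction": self.dropped_interaction,
        }


def _term_order(term: str) -> int:
    return term.count(":") + 1


def _wald_stat(b: np.ndarray, V: np.ndarray) -> float:
    """b' V^{-1} b with a pseudoinverse fallback for degenerate fits."""
    try:
        x = np.linalg.solve(V, b)
    except np.linalg.LinAlgError:
        x = np.linalg.pinv(V) @ b
    return float(abs(b @ x))


def _model_columns(spec: ModelSpec) -> List[str]:
    # crude but sufficient: variables named in the formula
    import re

    cols = set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", " ".join(spec.fixed_effects)))
    cols.discard("C")
    cols.add(spec.dependent)
    return [c for c in cols]


def fit_mixed(table: pd.DataFrame, spec: ModelSpec) -> FitSummary:
    """Fit the model described by ``spec`` on ``table``.

    Rows with missing values in any model variable are dropped.  Gaussian
    models get the two crossed random intercepts; Gamma-log models use the
    participant-fixed-effects fallback (recorded in ``notes``).
    """
    cols = [c for c in _model_columns(spec) if c in table.columns]
    need = cols + [c for c in spec.random_intercepts if c in table.columns]
    data = table.dropna(subset=[c for c in need if c in table.columns]).copy()
    if spec.dependent not in data.columns:
        raise ValueError(f"dependent {spec.dependent!r} not in table")
    n = len(data)
    notes: List[str] = []

    if spec.family == "gaussian_identity":
        vc = {g: f"0 + C({g})" for g in spec.random_intercepts}
        model = smf.mixedlm(
            spec.formula,
            data,
            groups=np.ones(n),
            vc_formula=vc,
            re_formula="0",
        )
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                result = model.fit(reml=False, method="lbfgs", maxiter=200)
            except Exception:
                result = None
            if result is None or not np.all(np.isfinite(result.fe_params)):
                try:
                    result = model.fit(reml=False)
                except Exception as exc:  # pragma: no cover - last resort
                    raise RuntimeError(f"mixed model failed to fit: {exc}")
        if not getattr(result, "converged", True):
            notes.append("optimizer did not report convergence (boundary fit likely)")
            converged = bool(np.all(np.isfinite(result.fe_params)))
        di = model.data.design_info
        fe = result.fe_params
        cov = result.cov_params().iloc[: len(fe), : len(fe)]
        k_fe = len(fe)
        df_den = max(n - k_fe, 1)
        rows = []
        for term in di.term_names:
            if term == "Intercept":
                continue
            sl = di.term_name_slices[term]
            idx = list(range(sl.start, sl.stop))
            b = fe.values[idx]
            V = cov.values[np.ix_(idx, idx)]
            chi2 = _wald_stat(b, V)
            q = len(idx)
            fstat = chi2 / q
            rows.append(
                {
                    "term": term,
                    "statistic": fstat,
                    "df_num": q,
                    "df_den": df_den,
                    "p": float(sps.f.sf(fstat, q, df_den)),
                    "kind": "wald_F",
                }
            )
        # ML BIC: fixed effects + variance components + residual variance
        k = k_fe + len(spec.random_intercepts) + 1
        bic = -2.0 * result.llf + k * np.log(n)
        notes.append("Wald F with residual df (no Satterthwaite adjustment in backend)")
        fs = FitSummary(
            formula=spec.formula,
            family=spec.family,
            method="mixedlm_ml_crossed_vc",
            n_obs=n,
            params={k_: float(v) for k_, v in fe.items()},
            bse={k_: float(v) for k_, v in result.bse_fe.items()},
            term_tests=pd.DataFrame(rows, columns=["term", "statistic", "df_num", "df_den", "p", "kind"]),
            llf=float(result.llf),
            bic=float(bic),
            converged=converged,
            notes=notes,
            _result=result,
            _design_info=di,
            _data=data,
        )
        return fs

    if spec.family == "gamma_log":
        y = data[spec.dependent]
        if (y <= 0).any():
            raise ValueError("gamma_log requires a strictly positive dependent")
        formula = spec.formula + " + C(participant_id)"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.glm(
                formula,
                data,
                family=sm.families.Gamma(link=sm.families.links.Log()),
            )
            fit_kwds = dict(
                cov_type="cluster",
                cov_kwds={"groups": data["participant_id"].to_numpy()},
                maxiter=200,
            )
            try:
                result = model.fit(**fit_kwds)
            except ValueError:
                # degenerate (e.g. constant) dependent: seed IRLS at the mean
                start = np.zeros(model.exog.shape[1])
                start[0] = np.log(float(y.mean()))
                result = model.fit(start_params=start, **fit_kwds)
        di = model.data.design_info
        params = result.params
        cov = result.cov_params()
        rows = []
        for term in di.term_names:
            if term == "Intercept" or term == "C(participant_id)":
                continue
            sl = di.term_name_slices[term]
            idx = list(range(sl.start, sl.stop))
            b = params.values[idx]
            V = cov.values[np.ix_(idx, idx)]
            chi2 = _wald_stat(b, V)
            q = len(idx)
            rows.append(
                {
                    "term": term,
                    "statistic": chi2,
                    "df_num": q,
                    "df_den": np.nan,
                    "p": float(sps.chi2.sf(chi2, q)),
                    "kind": "wald_chi2",
                }
            )
        k = len(params) + 1  # + dispersion
        bic = -2.0 * result.llf + k * np.log(n)
        notes.append(
            "gamma GLMM with crossed random intercepts unavailable; fallback: "
            "Gamma GLM + participant fixed effects + cluster-robust SE"
        )
        notes.append("log link: effects are multiplicative")
        return FitSummary(
            formula=spec.formula,
            family=spec.family,
            method="gamma_glm_participant_fe_cluster",
            n_obs=n,
            params={k_: float(v) for k_, v in params.items()},
            bse={k_: float(v) for k_, v in result.bse.items()},
            term_tests=pd.DataFrame(rows, columns=["term", "statistic", "df_num", "df_den", "p", "kind"]),
            llf=float(result.llf),
            bic=float(bic),
            converged=bool(result.converged) if hasattr(result, "converged") else True,
            notes=notes,
            _result=result,
            _design_info=di,
            _data=data,
        )

    raise ValueError(f"unknown family {spec.family!r}")


def _factor_levels(fs: FitSummary) -> Dict[str, list]:
    """Categorical variables in the design and their levels (from the data)."""
    levels = {}
    di = fs._design_info
    for fac, info in di.factor_infos.items():
        if info.type == "categorical":
            name = fac.name()  # e.g. "C(deadline_s)"
            var = name[2:-1] if name.startswith("C(") else name
            levels[var] = list(info.categories)
    return levels


def _numeric_vars(fs: FitSummary) -> List[str]:
    di = fs._design_info
    out = []
    for fac, info in di.factor_infos.items():
        if info.type == "numerical":
            out.append(fac.name())
    return out


def _emm_rows(fs: FitSummary, factor: str) -> Dict[object, np.ndarray]:
    """Averaged design rows (L vectors) per level of ``factor``."""
    levels = _factor_levels(fs)
    if factor not in levels:
        raise KeyError(f"factor {factor!r} not a categorical term of the model")
    other_cats = {k: v for k, v in levels.items() if k != factor}
    num_means = {v: float(fs._data.eval(v).mean()) for v in _numeric_vars(fs)}
    out = {}
    for lev in levels[factor]:
        combos = (
            list(itertools.product(*other_cats.values()))
            if other_cats
            else [()]
        )
        grid = pd.DataFrame(
            [
                {factor: lev, **dict(zip(other_cats.keys(), combo)), **num_means}
                for combo in combos
            ]
        )
        X = np.asarray(patsy.dmatrix(fs._design_info, grid, return_type="matrix"))
        out[lev] = X.mean(axis=0)
    return out


def emmeans_and_contrasts(
    fs: FitSummary, factor: str, response_scale: bool = True
) -> FitSummary:
    """Attach estimated marginal means and Tukey pairwise contrasts for a factor.

    EMMs average over the levels of other categorical predictors with equal
    weight and hold covariates at their mean.  For the Gamma-log family the
    means are back-transformed to the response scale (contrasts stay on the
    link scale).  Results are stored on (and returned with) the summary.
    """
    Ls = _emm_rows(fs, factor)
    if fs.family == "gaussian_identity":
        beta = fs._result.fe_params.values
        cov = fs._result.cov_params().iloc[: len(beta), : len(beta)].values
        df_den = max(fs.n_obs - len(beta), 1)
    else:
        beta = fs._result.params.values
        cov = fs._result.cov_params().values
        df_den = 1e6  # Wald z
    emm_rows = []
    for lev, L in Ls.items():
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        if fs.family == "gamma_log" and response_scale:
            emm_rows.append(
                {"level": lev, "mean": np.exp(est), "se": np.exp(est) * se,
                 "link_mean": est, "link_se": se}
            )
        else:
            emm_rows.append({"level": lev, "mean": est, "se": se})
    k = len(Ls)
    con_rows = []
    for (la, La), (lb, Lb) in itertools.combinations(Ls.items(), 2):
        d = La - Lb
        est = float(d @ beta)
        se = float(np.sqrt(d @ cov @ d))
        t = est / se if se > 0 else np.inf * np.sign(est)
        p_un = 2 * sps.t.sf(abs(t), df_den)
        p_adj = float(sps.studentized_range.sf(abs(t) * np.sqrt(2), k, df_den))
        con_rows.append(
            {
                "a": la,
                "b": lb,
                "estimate": est,
                "se": se,
                "stat": t,
                "p_unadjusted": p_un,
                "p_tukey": max(p_adj, p_un) if np.isfinite(t) else p_adj,
            }
        )
    fs.emmeans[factor] = pd.DataFrame(emm_rows)
    fs.contrasts[factor] = pd.DataFrame(con_rows)
    return fs


def bayes_factor(full: FitSummary, reduced: FitSummary) -> float:
    """BIC-approximate BF10 for the term(s) dropped from ``full``.

    Requires the reduced model to be nested in the full model and fitted on
    the same observations.
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError("models must be fitted on the same observations")
    full_terms = set(full.term_tests["term"])
    red_terms = set(reduced.term_tests["term"])
    if not red_terms <= full_terms:
        raise ValueError("reduced model is not nested in full model")
    return float(np.exp((reduced.bic - full.bic) / 2.0))


def _fit_with_bf(
    table: pd.DataFrame,
    spec: ModelSpec,
    bf_terms: Sequence[str] = (),
    simplify: bool = True,
) -> FitSummary:
    """Fit, optionally drop a sole insignificant highest-order interaction
    (once), and compute BIC Bayes factors for the requested terms."""
    fs = fit_mixed(table, spec)
    if simplify:
        terms = list(fs.term_tests["term"])
        inter = [t for t in terms if _term_order(t) > 1]
        if inter:
            top = max(_term_order(t) for t in inter)
            top_terms = [t for t in inter if _term_order(t) == top]
            if len(top_terms) == 1 and fs.pvalue(top_terms[0]) >= 0.05:
                dropped = top_terms[0]
                reduced_fixed = [t for t in terms if t != dropped]
                fs2 = fit_mixed(
                    table,
                    ModelSpec(
                        spec.dependent,
                        reduced_fixed,
                        spec.family,
                        spec.random_intercepts,
                    ),
                )
                fs2.dropped_interaction = dropped
                fs2.notes.append(
                    f"highest-order interaction {dropped} removed (p >= .05) and refit"
                )
                fs = fs2
    for term in bf_terms:
        if term not in set(fs.term_tests["term"]):
            continue
        reduced_fixed = [t for t in fs.term_tests["term"] if t != term]
        if not reduced_fixed:
            reduced_fixed = ["1"]
        red = fit_mixed(
            table,
            ModelSpec(spec.dependent, reduced_fixed, spec.family, spec.random_intercepts),
        )
        fs.bayes_factors[term] = bayes_factor(fs, red)
    return fs


def _battery_specs(experiment: str) -> Dict[str, dict]:
    """Named analyses: subset rule, model, EMM factor, BF terms."""
    specs: Dict[str, dict] = {
        "rt_manipulation": {
            "subset": lambda t: t,
            "spec": ModelSpec("rt_s", ["C(deadline_s)"]),
            "emm": "deadline_s",
            "bf": (),
            "simplify": False,
        },
        "overall_error": {
            "subset": lambda t: t,
            "spec": ModelSpec(
                "error_offset", ["rt_z * C(deadline_s)"], family="gamma_log"
            ),
            "emm": "deadline_s",
            "bf": (),
            "simplify": False,
        },
        "markov_cc": {
            "subset": lambda t: t[(t["family"] == "cc") & t["screened_off"].notna()],
            "spec": ModelSpec(
                "response",
                ["C(screened_off) * (C(deadline_s) + rt_z + C(mid_var))"],
            ),
            "emm": "screened_off",
            "bf": ("C(screened_off):C(deadline_s)", "C(screened_off):rt_z"),
            "simplify": False,
        },
        "markov_ce": {
            "subset": lambda t: t[(t["family"] == "ce") & t["screened_off"].notna()],
            "spec": ModelSpec(
                "response", ["C(screened_off) * (C(deadline_s) + rt_z)"]
            ),
            "emm": "screened_off",
            "bf": ("C(screened_off):C(deadline_s)", "C(screened_off):rt_z"),
            "simplify": False,
        },
        "away": {
            "subset": lambda t: t[t["away_var"].notna()],
            "spec": ModelSpec(
                "recoded_response", ["C(away_var) * (C(deadline_s) + rt_z)"]
            ),
            "emm": "away_var",
            "bf": ("C(away_var):C(deadline_s)", "C(away_var):rt_z"),
            "simplify": False,
        },
        "conservatism": {
            "subset": lambda t: t[t["conservatism"].notna()],
            "spec": ModelSpec("conservatism", ["C(deadline_s) * rt_z"]),
            "emm": "deadline_s",
            "bf": ("C(deadline_s):rt_z", "rt_z", "C(deadline_s)"),
            "simplify": False,
        },
    }
    if experiment == "exp2":
        specs["error_confidence"] = {
            "subset": lambda t: t,
            "spec": ModelSpec(
                "error_offset",
                ["rt_z * C(deadline_s)", "conf_z * (rt_z + C(deadline_s))"],
                family="gamma_log",
            ),
            "emm": None,
            "bf": (),
            "simplify": False,
        }
        specs["markov_cc_confidence"] = {
            "subset": specs["markov_cc"]["subset"],
            "spec": ModelSpec(
                "response",
                [
                    "C(screened_off) * (C(deadline_s) + rt_z)",
                    "C(screened_off) * C(mid_var) * conf_z",
                ],
            ),
            "emm": None,
            "bf": ("C(screened_off):conf_z",),
            "simplify": False,
        }
        specs["away_confidence"] = {
            "subset": specs["away"]["subset"],
            "spec": ModelSpec(
                "recoded_response",
                ["C(away_var) * (C(deadline_s) + rt_z + conf_z)"],
            ),
            "emm": None,
            "bf": ("C(away_var):conf_z",),
            "simplify": False,
        }
        specs["conservatism_confidence"] = {
            "subset": specs["conservatism"]["subset"],
            "spec": ModelSpec("conservatism", ["C(deadline_s) * rt_z * conf_z"]),
            "emm": None,
            "bf": ("conf_z",),
            "simplify": True,  # unique three-way interaction: drop if p >= .05
        }
    return specs


BATTERY_ANALYSES = tuple(_battery_specs("exp2").keys())


def analysis_battery(
    table: pd.DataFrame,
    which: Optional[Sequence[str]] = None,
    experiment: str = "exp1",
    compute_bf: bool = True,
    compute_emm: bool = True,
) -> Dict[str, FitSummary]:
    """Run the named analyses on a fully coded trial table.

    ``table`` must carry ``error_offset``, ``rt_z``, ``screened_off``,
    ``mid_var``, ``away_var``, ``recoded_response``, ``conservatism`` (and
    ``conf_z`` for exp2 analyses).
    """
    specs = _battery_specs(experiment)
    names = list(specs) if which is None else list(which)
    out: Dict[str, FitSummary] = {}
    for name in names:
        if name not in specs:
            raise KeyError(f"unknown analysis {name!r}; choose from {sorted(specs)}")
        cfg = specs[name]
        sub = cfg["subset"](table)
        missing = [
            c
            for c in _model_columns(cfg["spec"])
            if c not in sub.columns
        ]
        if missing:
            raise ValueError(f"analysis {name!r} needs missing columns {missing}")
        fs = _fit_with_bf(
            sub,
            cfg["spec"],
            bf_terms=cfg["bf"] if compute_bf else (),
            simplify=cfg["simplify"],
        )
        if compute_emm and cfg["emm"] is not None:
            emmeans_and_contrasts(fs, cfg["emm"])
        out[name] = fs
    return out


def rm_anova_spikes(rates: pd.DataFrame) -> dict:
    """One-way repeated-measures ANOVA on 50%-spike rates across deadlines.

    ``rates`` has columns participant_id, deadline_s, spike_rate (one row per
    cell; missing cells raise).  Returns F, df, p and the BIC-approximate
    Bayes factor for the deadline effect.
    """
    wide = rates.pivot(index="participant_id", columns="deadline_s", values="spike_rate")
    if wide.isna().any().any():
        raise ValueError("missing (participant, deadline) cells in spike rates")
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise ValueError("need >= 2 participants and >= 2 deadline levels")
    n, k = wide.shape
    data = wide.to_numpy(dtype=float)
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    if ss_cond <= 1e-15:
        F, p = 0.0, 1.0
    elif ss_err <= 1e-15:
        F, p = np.inf, 0.0
    else:
        F = (ss_cond / df1) / (ss_err / df2)
        p = float(sps.f.sf(F, df1, df2))
    # BIC BF via OLS with subject dummies vs subject + condition dummies
    long = wide.reset_index().melt(
        id_vars="participant_id", var_name="deadline_s", value_name="rate"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m0 = smf.ols("rate ~ C(participant_id)", long).fit()
        m1 = smf.ols("rate ~ C(participant_id) + C(deadline_s)", long).fit()
    bf10 = float(np.exp((m0.bic - m1.bic) / 2.0))
    return {
        "F": float(F),
        "df1": df1,
        "df2": df2,
        "p": float(p),
        "bf10": bf10,
        "bf01": float(np.inf if bf10 == 0 else 1.0 / bf10),
        "n_participants": n,
    }
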