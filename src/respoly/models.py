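"""Ecological and statistical models of the study.

* ``abundance_model`` — linear model of pelagic crayfish abundance
  (square-root CPUE) on littoral abundance, predation pressure, littoral
  habitat availability, invasion time and their two-way interactions, with
  backward elimination of nonsignificant interactions and VIF diagnostics.
* ``trait_lmm`` — linear mixed model of a trait on habitat, sex (optionally
  their interaction) with a lake random intercept, REML, per-term F tests
  and post-hoc habitat contrasts within sex.
* ``lr_glmm`` — beta-family GLMM (logit link) of littoral reliance on
  habitat with a lake random intercept, fit by adaptive Gauss-Hermite
  quadrature; habitat tested by likelihood ratio.
* ``lr_on_shape`` — beta regression of littoral reliance on body and chela
  discriminant scores.
* ``sex_ratio_test`` — paired-by-lake t test of sex-ratio difference
  between habitats.
* ``report`` — assembles all stage outputs into a JSON-able bundle plus a
  Markdown summary.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.optimize import minimize
from scipy.special import expit, gammaln

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.outliers_influence import variance_inflation_factor


@dataclass
class ModelFit:
    name: str
    formula: str
    coefficients: pd.DataFrame          # term, estimate, se, stat, p
    tests: pd.DataFrame                 # term, statistic, df_num, df_den, p
    diagnostics: Dict[str, object] = dc_field(default_factory=dict)
    contrasts: Optional[pd.DataFrame] = None
    notes: List[str] = dc_field(default_factory=list)


# ---------------------------------------------------------------------------
# Abundance LM (16-lake habitat-use stage)
# ---------------------------------------------------------------------------

MAIN_EFFECTS = ["cpue_littoral", "bpue_predators", "pct_littoral", "invasion_year"]


def abundance_model(env: pd.DataFrame, alpha: float = 0.05,
                    family_correct: bool = True) -> ModelFit:
    """LM of sqrt(pelagic CPUE) on the four lake predictors + 2-way interactions.

    The full model is fit first; the least-significant interaction (type-II F)
    is removed iteratively until every remaining interaction clears the
    retention threshold. Because retention is a selection over a family of
    six tests, the threshold defaults to ``alpha / 6`` (Bonferroni over the
    family; ``family_correct=False`` reverts to per-test ``alpha``) — without
    the correction a spurious interaction survives in ~30% of null datasets
    and distorts main-effect inference. Main effects are always retained.
    VIF is computed on the main-effects design and flagged at >= 5.
    """
    df = env.copy()
    if df[MAIN_EFFECTS].isna().any().any():
        raise ValueError("missing predictor values")
    df["resp"] = np.sqrt(df["cpue_pelagic"].astype(float))
    if df["resp"].var() == 0:
        raise ValueError("response has zero variance")

    interactions = [f"{a}:{b}" for a, b in itertools.combinations(MAIN_EFFECTS, 2)]
    threshold = alpha / len(interactions) if family_correct else alpha
    kept = list(interactions)
    notes = []
    while True:
        formula = "resp ~ " + " + ".join(MAIN_EFFECTS + kept)
        fit = smf.ols(formula, data=df).fit()
        if not kept:
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = anova_lm(fit, typ=2)
        pvals = {t: aov.loc[t, "PR(>F)"] for t in kept if t in aov.index}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < threshold:
            break
        kept.remove(worst)
        notes.append(f"removed interaction {worst} (p={pvals[worst]:.3f})")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = anova_lm(fit, typ=2)
    tests = pd.DataFrame({
        "term": aov.index[:-1],
        "statistic": aov["F"][:-1],
        "df_num": aov["df"][:-1].astype(int),
        "df_den": int(fit.df_resid),
        "p": aov["PR(>F)"][:-1],
    }).reset_index(drop=True)

    x_main = sm.add_constant(df[MAIN_EFFECTS].astype(float))
    vif = pd.Series(
        [variance_inflation_factor(x_main.to_numpy(), i + 1)
         for i in range(len(MAIN_EFFECTS))], index=MAIN_EFFECTS, name="VIF")
    if (vif >= 5).any():
        notes.append(f"VIF >= 5 for {list(vif[vif >= 5].index)}: "
                     "multicollinearity suspected")
        if np.isinf(vif).any():
            raise ValueError(f"perfectly collinear predictors: VIF table\n{vif}")

    coef = pd.DataFrame({
        "term": fit.params.index, "estimate": fit.params.values,
        "se": fit.bse.values, "stat": fit.tvalues.values,
        "p": fit.pvalues.values,
    })
    return ModelFit("abundance_lm", fit.model.formula, coef, tests,
                    diagnostics={"vif": vif.to_dict(), "r2": float(fit.rsquared),
                                 "n": int(fit.nobs)},
                    notes=notes)


# ---------------------------------------------------------------------------
# Trait LMM
# ---------------------------------------------------------------------------

def _cell_rows(design_info, cells: List[Dict[str, object]]) -> np.ndarray:
    from patsy import dmatrix
    rows = dmatrix(design_info, pd.DataFrame(cells), return_type="dataframe")
    return rows.to_numpy()


def trait_lmm(df: pd.DataFrame, response: str,
              with_interaction: bool = True,
              predictors: Sequence[str] = ("habitat", "sex")) -> ModelFit:
    """Random-intercept LMM of a trait on habitat (and sex) by REML.

    Factors are sum-coded so per-term Wald F tests are type-III-like. The
    denominator df is a residual-df approximation
    ``N - rank(X) - (n_lakes - 1)``; with this study's sample sizes it is
    essentially equivalent to a Satterthwaite approximation. When the
    habitat x sex interaction is significant (p < 0.05), habitat contrasts
    within each sex are reported from the estimated marginal means.
    """
    df = df.dropna(subset=[response]).copy()
    lakes = df["lake"].unique()
    terms = [f"C({p}, Sum)" for p in predictors]
    rhs = " * ".join(terms) if with_interaction and len(terms) > 1 \
        else " + ".join(terms)
    formula = f"{response} ~ {rhs}"
    notes = []
    if len(lakes) < 2:
        notes.append("single lake: random effect dropped, plain LM fitted")
        fit = smf.ols(formula, data=df).fit()
        params, bse, cov = fit.params, fit.bse, fit.cov_params()
        df_den = int(fit.df_resid)
        design_info = fit.model.data.design_info
        lake_var = 0.0
        resid_var = float(fit.mse_resid)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data=df, groups=df["lake"])
            fit = model.fit(reml=True)
        params = fit.fe_params
        bse = fit.bse_fe
        cov = fit.cov_params().iloc[:len(params), :len(params)]
        df_den = int(len(df) - len(params) - (len(lakes) - 1))
        design_info = fit.model.data.design_info
        lake_var = float(fit.cov_re.iloc[0, 0])
        resid_var = float(fit.scale)

    coef = pd.DataFrame({
        "term": params.index, "estimate": params.values,
        "se": np.asarray(bse)[:len(params)],
        "stat": params.values / np.asarray(bse)[:len(params)],
    })
    coef["p"] = 2 * st.t.sf(np.abs(coef["stat"]), df_den)

    # per-term F tests (1 df per term for 2-level factors, sum coding)
    test_rows = []
    for term in params.index:
        if term == "Intercept":
            continue
        f_stat = float((params[term] / np.asarray(bse)[list(params.index).index(term)]) ** 2)
        p = float(st.f.sf(f_stat, 1, df_den))
        test_rows.append({"term": term, "statistic": f_stat,
                          "df_num": 1, "df_den": df_den, "p": p})
    tests = pd.DataFrame(test_rows)

    contrasts = None
    inter_rows = tests[tests["term"].str.contains(":")]
    if with_interaction and len(inter_rows) and \
            float(inter_rows["p"].iloc[0]) < 0.05 and "sex" in predictors:
        cov_arr = np.asarray(cov)
        rows = []
        for sex in sorted(df["sex"].unique()):
            cells = [{"habitat": h, "sex": sex} for h in ("littoral", "pelagic")]
            x = _cell_rows(design_info, cells)
            L = x[0] - x[1]
            est = float(L @ params.values)
            se = float(np.sqrt(L @ cov_arr @ L))
            t = est / se
            rows.append({"contrast": f"littoral - pelagic | sex={sex}",
                         "estimate": est, "se": se, "t_ratio": t,
                         "df": df_den, "p": 2 * st.t.sf(abs(t), df_den)})
        contrasts = pd.DataFrame(rows)

    return ModelFit(f"lmm_{response}", formula, coef, tests,
                    diagnostics={"lake_variance": lake_var,
                                 "residual_variance": resid_var,
                                 "n": int(len(df)),
                                 "df_method": "residual approximation"},
                    contrasts=contrasts, notes=notes)


# ---------------------------------------------------------------------------
# Beta GLMM by Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def _beta_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    a = mu * phi
    b = (1 - mu) * phi
    return (gammaln(phi) - gammaln(a) - gammaln(b)
            + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y))


class BetaMixedFit:
    """Result of a logit-link beta GLMM with one random intercept."""

    def __init__(self, params, cov, loglik, names, n_groups, n_obs):
        self.params = pd.Series(params, index=names)
        self.cov = cov
        self.loglik = loglik
        self.names = names
        self.n_groups = n_groups
        self.n_obs = n_obs

    @property
    def sigma_group(self) -> float:
        return float(np.exp(self.params["log_sigma_u"]))

    @property
    def phi(self) -> float:
        return float(np.exp(self.params["log_phi"]))


def _fit_beta_mixed(y: np.ndarray, X: np.ndarray, group_idx: np.ndarray,
                    names: List[str], n_quad: int = 20,
                    start: Optional[np.ndarray] = None) -> BetaMixedFit:
    """Maximize the GH-quadrature marginal likelihood.

    Parameters are the fixed effects (logit scale), log precision phi and log
    random-intercept SD. The random intercept integrates out per group with
    ``n_quad`` Gauss-Hermite nodes. The surface is smooth but gradient
    methods stall on the log-scale nuisance parameters, so Nelder-Mead with
    tight tolerances does the work (optionally warm-started).
    """
    n_groups = group_idx.max() + 1
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)

    def negll(theta):
        beta = theta[:-2]
        log_phi, log_sig = theta[-2], theta[-1]
        phi = np.exp(np.clip(log_phi, -10, 15))
        sigma = np.exp(np.clip(log_sig, -15, 5))
        eta0 = X @ beta                             # n
        # n x q linear predictors
        eta = eta0[:, None] + np.sqrt(2.0) * sigma * nodes[None, :]
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        ll_obs = _beta_loglik(y[:, None], mu, phi)   # n x q
        # sum within groups, then log-sum-exp over nodes
        ll_grp = np.zeros((n_groups, len(nodes)))
        np.add.at(ll_grp, group_idx, ll_obs)
        ll_grp = ll_grp + log_w[None, :]
        m = ll_grp.max(axis=1, keepdims=True)
        ll = (m.squeeze(1) + np.log(np.exp(ll_grp - m).sum(axis=1))).sum()
        return -ll

    # initialize from a fixed-effects-only beta regression
    from statsmodels.othermod.betareg import BetaModel
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        init_fit = BetaModel(y, X).fit(disp=False)
    beta0 = np.asarray(init_fit.params)[:X.shape[1]]
    phi0 = float(np.asarray(init_fit.params)[-1])
    starts = [np.concatenate([beta0, [np.log(max(phi0, 1.0)), np.log(0.1)]])]
    if start is not None:
        starts.insert(0, np.asarray(start, float))

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for x0 in starts:
            res = minimize(negll, x0, method="Nelder-Mead",
                           options={"maxiter": 4000, "xatol": 1e-7,
                                    "fatol": 1e-9})
            if best is None or res.fun < best.fun:
                best = res
    res = best
    from statsmodels.tools.numdiff import approx_hess
    try:
        hess = approx_hess(res.x, negll)
        cov = np.linalg.inv(hess)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError("non-PD Hessian")
    except np.linalg.LinAlgError:
        cov = None
    return BetaMixedFit(res.x, cov, -res.fun, names, n_groups, len(y))


def lr_glmm(df: pd.DataFrame, response: str = "LR_clamped") -> ModelFit:
    """Beta GLMM of littoral reliance: habitat fixed, lake random intercept.

    Habitat is tested by likelihood-ratio chi-square against the
    intercept-only (plus random effect) null. Predicted per-habitat means
    (logit back-transformed at the random-effect mode) are reported with
    delta-method SEs.
    """
    df = df.dropna(subset=[response]).copy()
    y = df[response].to_numpy(float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("response must lie strictly inside (0, 1): "
                         "clamp littoral reliance before modeling")
    lakes, group_idx = np.unique(df["lake"], return_inverse=True)
    hab = (df["habitat"] == "pelagic").to_numpy(float)
    X1 = np.column_stack([np.ones_like(hab), hab])
    X0 = X1[:, :1]

    fit1 = _fit_beta_mixed(y, X1, group_idx,
                           ["Intercept", "habitat[pelagic]", "log_phi", "log_sigma_u"])
    # warm-start the null from the alternative (and refit the alternative from
    # the null) so the likelihood-ratio compares converged optima
    p1 = fit1.params.values
    fit0 = _fit_beta_mixed(y, X0, group_idx,
                           ["Intercept", "log_phi", "log_sigma_u"],
                           start=np.concatenate([[p1[0] + 0.5 * p1[1]], p1[2:]]))
    p0 = fit0.params.values
    fit1b = _fit_beta_mixed(y, X1, group_idx, fit1.names,
                            start=np.concatenate([[p0[0], 0.0], p0[1:]]))
    if fit1b.loglik > fit1.loglik:
        fit1 = fit1b
    chi2 = max(0.0, 2 * (fit1.loglik - fit0.loglik))
    p = float(st.chi2.sf(chi2, 1))

    se = np.sqrt(np.diag(fit1.cov)) if fit1.cov is not None else np.full(4, np.nan)
    coef = pd.DataFrame({
        "term": fit1.names, "estimate": fit1.params.values, "se": se,
        "stat": fit1.params.values / se,
    })
    coef["p"] = 2 * st.norm.sf(np.abs(coef["stat"]))
    tests = pd.DataFrame([{"term": "habitat", "statistic": chi2,
                           "df_num": 1, "df_den": np.nan, "p": p}])

    preds = {}
    b = fit1.params
    cov = fit1.cov
    for label, code in (("littoral", 0.0), ("pelagic", 1.0)):
        L = np.array([1.0, code, 0.0, 0.0])
        eta = float(L @ fit1.params.values)
        mu = float(expit(eta))
        if cov is not None:
            se_eta = float(np.sqrt(L @ cov @ L))
            se_mu = se_eta * mu * (1 - mu)
        else:
            se_mu = np.nan
        preds[label] = {"mean": mu, "se": se_mu}

    return ModelFit("lr_beta_glmm", f"{response} ~ habitat + (1|lake)", coef, tests,
                    diagnostics={"predicted_means": preds,
                                 "sigma_lake": fit1.sigma_group,
                                 "phi": fit1.phi,
                                 "loglik": fit1.loglik,
                                 "n": int(len(df))})


def lr_on_shape(df: pd.DataFrame, response: str = "LR_clamped") -> ModelFit:
    """Beta regression (logit link) of littoral reliance on DFA shape scores."""
    from statsmodels.othermod.betareg import BetaModel
    needed = [response, "body_dfa", "chela_dfa"]
    sub = df.dropna(subset=needed)
    if sub.empty:
        raise ValueError("no complete cases joining littoral reliance with "
                         "body and chela DFA scores")
    for covariate in ("body_dfa", "chela_dfa"):
        if sub[covariate].var() == 0:
            raise ValueError(f"constant covariate {covariate}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = BetaModel.from_formula(
            f"{response} ~ body_dfa + chela_dfa", data=sub).fit(disp=False)
    coef = pd.DataFrame({
        "term": fit.params.index, "estimate": fit.params.values,
        "se": fit.bse.values, "stat": fit.tvalues.values,
        "p": fit.pvalues.values,
    })
    tests = coef[coef["term"].isin(["body_dfa", "chela_dfa"])].copy()
    tests = tests.rename(columns={"stat": "statistic"})[["term", "statistic", "p"]]
    return ModelFit("lr_on_shape_betareg", f"{response} ~ body_dfa + chela_dfa",
                    coef, tests, diagnostics={"n": int(len(sub)),
                                              "loglik": float(fit.llf)})


# ---------------------------------------------------------------------------
# Small auxiliary tests and report assembly
# ---------------------------------------------------------------------------

def sex_ratio_test(specimens: pd.DataFrame) -> Dict[str, float]:
    """Paired-by-lake t test of female proportion, littoral vs. pelagic."""
    props = (specimens.assign(is_f=lambda d: (d["sex"] == "F").astype(float))
             .groupby(["lake", "habitat"])["is_f"].mean().unstack())
    diff = (props["littoral"] - props["pelagic"]).dropna()
    t, p = st.ttest_1samp(diff, 0.0)
    return {"t": float(t), "df": int(len(diff) - 1), "p": float(p)}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if obj is None or isinstance(obj, (str, bool)):
        return obj
    if hasattr(obj, "__dict__"):
        return _jsonable(vars(obj))
    return str(obj)


def report(sections: Dict[str, object], path_json=None, path_md=None) -> Dict:
    """Assemble stage outputs into a JSON bundle and a Markdown summary.

    ``sections`` may hold any subset of the pipeline's stages; absent stages
    are marked as such in the Markdown so partial runs are explicit.
    """
    bundle = _jsonable(sections)
    if path_json is not None:
        with open(path_json, "w") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)
    if path_md is not None:
        lines = ["# Resource-polymorphism analysis report", ""]
        for name in ("environment", "morphometrics", "trophic", "popgen",
                     "pst_fst"):
            lines.append(f"## {name}")
            if name not in sections:
                lines.append("_stage not run_")
            else:
                lines.append("```json")
                lines.append(json.dumps(bundle[name], indent=2, sort_keys=True)[:4000])
                lines.append("```")
            lines.append("")
        with open(path_md, "w") as fh:
            fh.write("\n".join(lines))
    return bundle
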